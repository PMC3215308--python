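"""Minimum-free-energy mRNA secondary structure behind a pluggable engine.

The engine contract is small: ``fold(seq) -> FoldResult`` returning a
non-crossing pair list and a non-positive energy, deterministically. The
built-in engine is interval dynamic programming that minimizes a weighted
pair pseudo-energy (GC -1.0, AU -0.8, GU -0.5 by default) with a minimum
hairpin loop of 3 unpaired bases — a Nussinov-style model, deliberately
not a thermodynamic nearest-neighbor one: it is self-contained and exactly
checkable against exhaustive enumeration. Real thermodynamics is available
through the optional RNAfold adapter, which satisfies the same contract.

Pair indices are 1-based with i < j throughout; the hairpin constraint is
j - i >= 4 (at least 3 unpaired bases enclosed).
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field

from .errors import GeneDesignError
from .metrics import ProfileTrack, profile
from .seqcore import NucSequence

#: default pair pseudo-energies on the DNA-internal alphabet (AU pairs as A-T)
DEFAULT_PAIR_ENERGIES = {
    ("G", "C"): -1.0,
    ("C", "G"): -1.0,
    ("A", "T"): -0.8,
    ("T", "A"): -0.8,
    ("G", "T"): -0.5,
    ("T", "G"): -0.5,
}

MIN_HAIRPIN_LOOP = 3


@dataclass
class FoldResult:
    """A secondary structure: pair list, dot-bracket, and its energy."""

    sequence: str  # RNA alphabet, for display
    pairs: list[tuple[int, int]]  # 1-based, i < j, sorted by i
    energy: float
    engine: str = ""
    units: str = "pseudo-energy"

    @property
    def dot_bracket(self) -> str:
        return pairs_to_dot_bracket(len(self.sequence), self.pairs)

    def to_ct(self, path=None, name: str = "structure") -> str:
        """Connect-table (CT) text for the structure."""
        partner = {}
        for i, j in self.pairs:
            partner[i] = j
            partner[j] = i
        n = len(self.sequence)
        lines = [f"{n}\t{name} energy = {self.energy:g}"]
        for i in range(1, n + 1):
            lines.append(
                f"{i}\t{self.sequence[i - 1]}\t{i - 1}\t{(i + 1) % (n + 1)}\t{partner.get(i, 0)}\t{i}"
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def pairs_to_dot_bracket(n: int, pairs: list[tuple[int, int]]) -> str:
    chars = ["."] * n
    for i, j in pairs:
        if not (1 <= i < j <= n):
            raise GeneDesignError(f"pair ({i},{j}) out of range for length {n}")
        if chars[i - 1] != "." or chars[j - 1] != ".":
            raise GeneDesignError(f"base in pair ({i},{j}) is already paired")
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def dot_bracket_to_pairs(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise GeneDesignError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise GeneDesignError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise GeneDesignError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


class FoldEngine:
    """Engine contract: deterministic fold() with energy <= 0."""

    name = "abstract"
    units = "pseudo-energy"
    has_pair_probabilities = False

    def fold(self, seq: NucSequence) -> FoldResult:  # pragma: no cover - contract
        raise NotImplementedError

    def energy(self, seq: NucSequence) -> float:
        return self.fold(seq).energy


class BuiltinFoldEngine(FoldEngine):
    """Interval DP maximizing weighted pairings (minimizing pseudo-energy).

    E(i, j) = min( E(i+1, j),
                   min over k >= i+4 pairable with i of
                       e(i, k) + E(i+1, k-1) + E(k+1, j) )

    Traceback ties prefer pairing i with the smallest admissible k, and
    prefer pairing over leaving i unpaired when energies tie, so output is
    deterministic.
    """

    units = "pseudo-energy"
    has_pair_probabilities = False

    def __init__(
        self,
        pair_energies: dict[tuple[str, str], float] | None = None,
        min_loop: int = MIN_HAIRPIN_LOOP,
    ) -> None:
        self.pair_energies = dict(pair_energies or DEFAULT_PAIR_ENERGIES)
        if any(e >= 0 for e in self.pair_energies.values()):
            raise GeneDesignError("pair pseudo-energies must be negative")
        self.min_loop = min_loop
        self.name = "nussinov-weighted"

    def fold(self, seq: NucSequence) -> FoldResult:
        s = seq.residues
        n = len(s)
        gap = self.min_loop + 1  # minimal j - i for a pair
        E = [[0.0] * n for _ in range(n)]
        for span in range(gap, n):
            for i in range(0, n - span):
                j = i + span
                best = E[i + 1][j] if i + 1 <= j else 0.0
                for k in range(i + gap, j + 1):
                    e = self.pair_energies.get((s[i], s[k]))
                    if e is None:
                        continue
                    inner = E[i + 1][k - 1] if i + 1 <= k - 1 else 0.0
                    outer = E[k + 1][j] if k + 1 <= j else 0.0
                    cand = e + inner + outer
                    if cand < best:
                        best = cand
                E[i][j] = best
        pairs: list[tuple[int, int]] = []

        def trace(i: int, j: int) -> None:
            while i < j:
                target = E[i][j]
                paired = False
                for k in range(i + gap, j + 1):
                    e = self.pair_energies.get((s[i], s[k]))
                    if e is None:
                        continue
                    inner = E[i + 1][k - 1] if i + 1 <= k - 1 else 0.0
                    outer = E[k + 1][j] if k + 1 <= j else 0.0
                    if e + inner + outer == target:
                        pairs.append((i + 1, k + 1))
                        trace(i + 1, k - 1)
                        i = k + 1
                        paired = True
                        break
                if not paired:
                    i += 1

        if n:
            trace(0, n - 1)
        energy = E[0][n - 1] if n else 0.0
        return FoldResult(
            sequence=seq.as_rna(),
            pairs=sorted(pairs),
            energy=energy,
            engine=self.name,
            units=self.units,
        )


class RNAfoldEngine(FoldEngine):
    """Optional adapter around the ViennaRNA ``RNAfold`` executable.

    Satisfies the same contract with true thermodynamic energies in
    kcal/mol. Only available when RNAfold is on PATH.
    """

    units = "kcal/mol"
    has_pair_probabilities = False
    name = "rnafold"

    def __init__(self, executable: str = "RNAfold") -> None:
        if shutil.which(executable) is None:
            raise GeneDesignError(f"{executable!r} not found on PATH")
        self.executable = executable

    def fold(self, seq: NucSequence) -> FoldResult:
        proc = subprocess.run(
            [self.executable, "--noPS"],
            input=seq.as_rna() + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
        lines = proc.stdout.strip().splitlines()
        struct_line = lines[-1]
        structure, _, energy_part = struct_line.partition(" ")
        energy = float(energy_part.strip().strip("()"))
        pairs = dot_bracket_to_pairs(structure)
        return FoldResult(
            sequence=seq.as_rna(),
            pairs=pairs,
            energy=min(energy, 0.0),
            engine=self.name,
            units=self.units,
        )


_default_engine: FoldEngine | None = None


def default_engine() -> FoldEngine:
    global _default_engine
    if _default_engine is None:
        _default_engine = BuiltinFoldEngine()
    return _default_engine


def fold_mfe(seq: NucSequence, engine: FoldEngine | None = None) -> FoldResult:
    """Predict the minimum-(pseudo-)energy structure of a sequence."""
    return (engine or default_engine()).fold(seq)


def binding_energy(seq: NucSequence, engine: FoldEngine | None = None) -> float:
    """Folding (binding) energy of the MFE structure; always <= 0."""
    return (engine or default_engine()).energy(seq)


def energy_profile(
    seq: NucSequence,
    engine: FoldEngine | None = None,
    window: int = 60,
    step: int = 10,
) -> ProfileTrack:
    """Moving-window binding-energy profile (delegates to metrics.profile)."""
    eng = engine or default_engine()
    return profile(
        seq,
        lambda sub: eng.energy(sub),
        window=window,
        step=step,
        metric_name=f"binding-energy[{eng.name}]",
    )
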