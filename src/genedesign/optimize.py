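"""Sequence-modifying algorithms that preserve the encoded protein.

Three operations share one contract: whatever happens — success, failure,
iteration-budget exhaustion — the returned sequence translates to exactly
the input's protein, and a fixed seed reproduces the outcome bit for bit.

* ``codon_optimize``  — Monte-Carlo resampling of every codon from a
  slot look-up table (LUT), so output codon frequencies converge to the
  target usage.
* ``silent_remove``   — eliminates unwanted motifs (restriction sites,
  polyA signals, cryptic splice sites) by synonymous substitution inside
  the codons the motif covers, re-scanning the whole sequence after each
  change since substitutions can create new sites.
* ``mrna_optimize``   — drives the folding (pseudo-)energy into a target
  range by escalating rounds of synonymous substitutions: k random changes
  per proposal, with k growing by one after a stall.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .codon_usage import AdaptivenessTable, CodonLUT, build_lut
from .errors import OptimizationError
from .folding import FoldEngine, default_engine
from .seqcore import GeneticCode, NucSequence, STANDARD_CODE, translate


@dataclass
class OptimizationOutcome:
    """Result of one optimization run.

    ``changes`` logs (1-based codon position, old codon, new codon) in the
    order applied; ``metrics`` carries the achieved objective value(s).
    """

    sequence: NucSequence
    success: bool
    iterations: int
    changes: list[tuple[int, str, str]] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)
    message: str = ""

    def changes_to_tsv(self, path=None) -> str:
        lines = ["codon_position\told\tnew"]
        lines += [f"{p}\t{o}\t{n}" for p, o, n in self.changes]
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _as_lut(source, code: GeneticCode) -> CodonLUT:
    if isinstance(source, CodonLUT):
        return source
    if isinstance(source, AdaptivenessTable):
        return build_lut(source, code=code)
    return build_lut(source, code=code)


def _assert_protein_preserved(before: NucSequence, after: NucSequence, code: GeneticCode) -> None:
    if translate(before, code).residues != translate(after, code).residues:
        raise OptimizationError("internal error: translated protein changed")


def codon_optimize(
    seq: NucSequence,
    lut: CodonLUT,
    seed: int,
    mode: str = "all-positions",
    per_position_probability: float = 1.0,
    code: GeneticCode = STANDARD_CODE,
) -> OptimizationOutcome:
    """Monte-Carlo codon optimization against a look-up table.

    Every codon position is independently resampled by drawing one of the
    LUT's ``granularity`` slots (in ``per-position-probability`` mode only a
    fraction of positions is touched). Single-codon amino acids and stop
    codons are never changed.
    """
    if mode not in ("all-positions", "per-position-probability"):
        raise OptimizationError(f"unknown mode {mode!r}")
    rng = random.Random(seed)
    codons = seq.codons()
    out: list[str] = []
    changes: list[tuple[int, str, str]] = []
    for idx, codon in enumerate(codons):
        aa = code.codon_to_aa[codon]
        if aa == "*" or code.degeneracy[aa] == 1:
            out.append(codon)
            continue
        if mode == "per-position-probability" and rng.random() > per_position_probability:
            out.append(codon)
            continue
        if aa not in lut.slots:
            raise OptimizationError(f"amino acid {aa!r} absent from the look-up table")
        new = lut.sample(aa, rng)
        out.append(new)
        if new != codon:
            changes.append((idx + 1, codon, new))
    result = NucSequence("".join(out), name=seq.name, alphabet_kind=seq.alphabet_kind)
    _assert_protein_preserved(seq, result, code)
    return OptimizationOutcome(
        sequence=result, success=True, iterations=1, changes=changes
    )


def _find_any(s: str, targets: list[str]) -> tuple[int, str] | None:
    """Leftmost occurrence (0-based start, motif) of any target, else None."""
    best: tuple[int, str] | None = None
    for t in targets:
        p = s.find(t)
        if p != -1 and (best is None or p < best[0]):
            best = (p, t)
    return best


def _count_sites(s: str, targets: list[str]) -> int:
    n = 0
    for t in targets:
        start = s.find(t)
        while start != -1:
            n += 1
            start = s.find(t, start + 1)
    return n


def silent_remove(
    seq: NucSequence,
    targets: list[str],
    adapt_or_lut,
    seed: int = 0,
    max_attempts: int = 100,
    code: GeneticCode = STANDARD_CODE,
) -> OptimizationOutcome:
    """Remove every occurrence of the target motifs by silent substitution.

    Per occurrence: the motif's footprint is truncated to the codons it
    fully covers (falling back to all overlapping codons if it covers
    none), then random synonymous replacements are drawn inside that region
    until the occurrence disappears, up to ``max_attempts`` draws. After
    each successful removal the whole sequence is re-scanned, since a
    substitution can create a new site elsewhere. Occurrences that no
    synonymous substitution can break (e.g. a motif spanning only Met/Trp
    codons) are reported as irremovable with ``success=False``.
    """
    targets = [t.upper().replace("U", "T") for t in targets]
    if any(not t or set(t) - set("ACGT") for t in targets):
        raise OptimizationError("targets must be plain non-empty DNA motifs")
    lut = _as_lut(adapt_or_lut, code)
    rng = random.Random(seed)
    codons = seq.codons()
    changes: list[tuple[int, str, str]] = []
    irremovable: list[tuple[int, str]] = []
    skip: set[tuple[int, str]] = set()
    iterations = 0
    guard = 0
    while True:
        guard += 1
        if guard > 10000:
            raise OptimizationError("silent_remove failed to converge")
        s = "".join(codons)
        # leftmost unskipped occurrence of any target
        hit = None
        for t in targets:
            start = s.find(t)
            while start != -1:
                if (start, t) not in skip and (hit is None or start < hit[0]):
                    hit = (start, t)
                    break
                start = s.find(t, start + 1)
        if hit is None:
            break
        start, motif = hit
        end = start + len(motif)
        first_full = (start + 2) // 3  # first codon fully inside the site
        last_full = end // 3  # one past the last fully covered codon
        if first_full < last_full:
            region = list(range(first_full, last_full))
        else:
            region = list(range(start // 3, (end + 2) // 3))
        mutable = [
            i for i in region
            if code.degeneracy[code.codon_to_aa[codons[i]]] > 1
            and code.codon_to_aa[codons[i]] != "*"
        ]
        if not mutable:
            irremovable.append((start + 1, motif))
            skip.add((start, motif))
            continue
        removed = False
        trial_changes: list[tuple[int, str, str]] = []
        for _ in range(max_attempts):
            iterations += 1
            i = rng.choice(mutable)
            aa = code.codon_to_aa[codons[i]]
            alternatives = [c for c in lut.codons(aa) if c != codons[i]]
            if not alternatives:
                alternatives = [c for c in code.synonyms[aa] if c != codons[i]]
            new = rng.choice(alternatives)
            old = codons[i]
            codons[i] = new
            trial_changes.append((i + 1, old, new))
            if "".join(codons)[start:end] != motif:
                removed = True
                break
        if removed:
            # substitutions never change length, so skipped positions stay valid
            changes.extend(trial_changes)
        else:
            # revert the fruitless trial and give this occurrence up
            for i, old, _ in reversed(trial_changes):
                codons[i - 1] = old
            irremovable.append((start + 1, motif))
            skip.add((start, motif))
    result = NucSequence("".join(codons), name=seq.name, alphabet_kind=seq.alphabet_kind)
    _assert_protein_preserved(seq, result, code)
    remaining = _count_sites(result.residues, targets)
    success = not irremovable and remaining == 0
    msg = ""
    if irremovable:
        msg = "irremovable site(s) at 1-based position(s): " + ", ".join(
            f"{p} ({m})" for p, m in irremovable
        )
    return OptimizationOutcome(
        sequence=result,
        success=success,
        iterations=iterations,
        changes=changes,
        metrics={"remaining_sites": remaining},
        message=msg,
    )


def _range_distance(energy: float, emin: float, emax: float) -> float:
    if energy < emin:
        return emin - energy
    if energy > emax:
        return energy - emax
    return 0.0


def _mutable_positions(codons: list[str], code: GeneticCode) -> list[int]:
    return [
        i
        for i, c in enumerate(codons)
        if code.codon_to_aa[c] != "*" and code.degeneracy[code.codon_to_aa[c]] > 1
    ]


def mrna_optimize(
    seq: NucSequence,
    engine: FoldEngine | None = None,
    energy_min: float = -math.inf,
    energy_max: float = math.inf,
    lut: CodonLUT | None = None,
    adapt: AdaptivenessTable | None = None,
    seed: int = 0,
    max_iterations: int = 1000,
    stall: int = 50,
    code: GeneticCode = STANDARD_CODE,
) -> OptimizationOutcome:
    """Drive the folding energy of a coding sequence into [min, max].

    Proposals apply k random synonymous substitutions to the best sequence
    so far; a proposal is accepted if its energy enters the range or moves
    strictly toward it. k starts at 1 and is raised by one after ``stall``
    consecutive rejections, mirroring the idea of gradually increasing the
    number of mutations while out of range.
    """
    if energy_min > energy_max:
        raise OptimizationError("energy_min must not exceed energy_max")
    engine = engine or default_engine()
    source = lut if lut is not None else adapt
    if source is None:
        # uniform synonymous draws when no usage preference is supplied
        source = {
            aa: {c: 1.0 / len(code.synonyms[aa]) for c in code.synonyms[aa]}
            for aa in code.amino_acids()
        }
    lut = _as_lut(source, code)
    rng = random.Random(seed)
    best = seq.codons()
    best_energy = engine.energy(seq)
    best_dist = _range_distance(best_energy, energy_min, energy_max)
    changes: list[tuple[int, str, str]] = []
    if best_dist == 0.0:
        return OptimizationOutcome(
            sequence=seq, success=True, iterations=0, metrics={"energy": best_energy}
        )
    mutable = _mutable_positions(best, code)
    if not mutable:
        return OptimizationOutcome(
            sequence=seq,
            success=False,
            iterations=0,
            metrics={"energy": best_energy},
            message="no synonymous substitutions are possible",
        )
    k = 1
    rejected = 0
    for it in range(1, max_iterations + 1):
        trial = list(best)
        trial_changes: list[tuple[int, str, str]] = []
        for _ in range(min(k, len(mutable))):
            i = rng.choice(mutable)
            aa = code.codon_to_aa[trial[i]]
            alternatives = [c for c in lut.codons(aa) if c != trial[i]]
            if not alternatives:
                alternatives = [c for c in code.synonyms[aa] if c != trial[i]]
            new = rng.choice(alternatives)
            trial_changes.append((i + 1, trial[i], new))
            trial[i] = new
        cand = NucSequence("".join(trial), name=seq.name, alphabet_kind=seq.alphabet_kind)
        energy = engine.energy(cand)
        dist = _range_distance(energy, energy_min, energy_max)
        if dist < best_dist:
            best, best_energy, best_dist = trial, energy, dist
            changes.extend(trial_changes)
            k, rejected = 1, 0
            if best_dist == 0.0:
                result = cand
                _assert_protein_preserved(seq, result, code)
                return OptimizationOutcome(
                    sequence=result,
                    success=True,
                    iterations=it,
                    changes=changes,
                    metrics={"energy": best_energy},
                )
        else:
            rejected += 1
            if rejected >= stall:
                k += 1
                rejected = 0
    result = NucSequence("".join(best), name=seq.name, alphabet_kind=seq.alphabet_kind)
    _assert_protein_preserved(seq, result, code)
    return OptimizationOutcome(
        sequence=result,
        success=False,
        iterations=max_iterations,
        changes=changes,
        metrics={"energy": best_energy},
        message=f"max_iterations exhausted; best energy {best_energy:g} "
        f"outside [{energy_min:g}, {energy_max:g}]",
    )


def windowed_mrna_optimize(
    seq: NucSequence,
    engine: FoldEngine | None = None,
    energy_min: float = -math.inf,
    energy_max: float = math.inf,
    window: int = 60,
    step: int = 10,
    lut: CodonLUT | None = None,
    adapt: AdaptivenessTable | None = None,
    seed: int = 0,
    max_iterations: int = 500,
    stall: int = 25,
    code: GeneticCode = STANDARD_CODE,
) -> OptimizationOutcome:
    """Window-by-window energy-range optimization of a long sequence.

    Windows are processed left to right; proposals mutate only codons
    overlapping the current window and are accepted only when the window's
    distance to the range shrinks without pushing an earlier (already
    satisfied) window out of range — keeping the total number of base
    changes small. Returns success only if every window ends in range.
    """
    engine = engine or default_engine()
    source = lut if lut is not None else adapt
    if source is None:
        source = {
            aa: {c: 1.0 / len(code.synonyms[aa]) for c in code.synonyms[aa]}
            for aa in code.amino_acids()
        }
    lut = _as_lut(source, code)
    rng = random.Random(seed)
    codons = seq.codons()
    L = len(seq)
    if window > L:
        starts = [0]
    else:
        starts = list(range(0, L - window + 1, step))
    changes: list[tuple[int, str, str]] = []
    iterations = 0

    def window_energy(cd: list[str], ws: int) -> float:
        sub = "".join(cd)[ws : ws + window]
        return engine.energy(NucSequence(sub))

    def window_dist(cd: list[str], ws: int) -> float:
        return _range_distance(window_energy(cd, ws), energy_min, energy_max)

    failed_windows: list[int] = []
    for wi, ws in enumerate(starts):
        dist = window_dist(codons, ws)
        if dist == 0.0:
            continue
        lo, hi = ws // 3, min(len(codons), (ws + window + 2) // 3)
        mutable = [
            i
            for i in range(lo, hi)
            if code.codon_to_aa[codons[i]] != "*"
            and code.degeneracy[code.codon_to_aa[codons[i]]] > 1
        ]
        if not mutable:
            failed_windows.append(ws + 1)
            continue
        k, rejected = 1, 0
        for _ in range(max_iterations):
            iterations += 1
            trial = list(codons)
            trial_changes: list[tuple[int, str, str]] = []
            for _ in range(min(k, len(mutable))):
                i = rng.choice(mutable)
                aa = code.codon_to_aa[trial[i]]
                alternatives = [c for c in lut.codons(aa) if c != trial[i]]
                if not alternatives:
                    alternatives = [c for c in code.synonyms[aa] if c != trial[i]]
                new = rng.choice(alternatives)
                trial_changes.append((i + 1, trial[i], new))
                trial[i] = new
            new_dist = window_dist(trial, ws)
            # only earlier windows overlapping the mutated codon span can move
            earlier_ok = all(
                window_dist(trial, prev) == 0.0
                for prev in starts[:wi]
                if prev + window > lo * 3
            )
            if new_dist < dist and earlier_ok:
                codons = trial
                changes.extend(trial_changes)
                dist = new_dist
                k, rejected = 1, 0
                if dist == 0.0:
                    break
            else:
                rejected += 1
                if rejected >= stall:
                    k += 1
                    rejected = 0
        if dist > 0.0:
            failed_windows.append(ws + 1)
    result = NucSequence("".join(codons), name=seq.name, alphabet_kind=seq.alphabet_kind)
    _assert_protein_preserved(seq, result, code)
    # post-verification pass over every window
    bad = [
        ws + 1
        for ws in starts
        if _range_distance(
            engine.energy(result.slice(ws, min(L, ws + window))), energy_min, energy_max
        )
        > 0.0
    ]
    success = not bad
    return OptimizationOutcome(
        sequence=result,
        success=success,
        iterations=iterations,
        changes=changes,
        metrics={"out_of_range_windows": bad},
        message="" if success else f"windows out of range at 1-based starts: {bad}",
    )
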