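"""Codon usage tables, RSCU / relative adaptiveness w, and the Monte-Carlo LUT.

Relative synonymous codon usage for codon j of amino acid i is

    RSCU_ij = X_ij * k_i / sum_j X_ij

with k_i the degeneracy of the family, and the relative adaptiveness is
w_ij = RSCU_ij / RSCU_i,max, floored at 0.01 so that a codon absent from
the reference set never zeroes out a geometric mean. The floor is applied
once, at table construction, so every consumer sees floored values.

Stop codons never participate in RSCU, w, or the look-up table.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

from .errors import TableError, SequenceError
from .seqcore import GeneticCode, NucSequence, STANDARD_CODE

W_FLOOR = 0.01

_CUTG_FIELD = re.compile(r"([ACGTUacgtu]{3})\s+([0-9.]+)\s*\(\s*([0-9]+)\s*\)")


@dataclass
class CodonUsageTable:
    """Per-codon counts for a reference gene set.

    Always carries all 64 codons; absent codons hold count 0. Per-thousand
    frequencies are stored when the source file provides them.
    """

    counts: dict[str, float]
    per_thousand: dict[str, float] | None = None
    organism: str = ""

    def __post_init__(self) -> None:
        full = {}
        for codon, n in self.counts.items():
            codon = codon.upper().replace("U", "T")
            if n < 0:
                raise TableError(f"negative count for codon {codon}")
            full[codon] = full.get(codon, 0) + n
        for codon in STANDARD_CODE.codons:
            full.setdefault(codon, 0)
        if len(full) != 64:
            bad = sorted(set(full) - set(STANDARD_CODE.codons))
            raise TableError(f"unknown codons in table: {bad}")
        self.counts = full

    @property
    def total(self) -> float:
        return sum(self.counts.values())

    def fractions(self, code: GeneticCode = STANDARD_CODE) -> dict[str, dict[str, float]]:
        """Within-family codon fractions per amino acid (stops excluded).

        Zero-total families fall back to uniform fractions.
        """
        out: dict[str, dict[str, float]] = {}
        for aa in code.amino_acids():
            syns = code.synonyms[aa]
            total = sum(self.counts[c] for c in syns)
            if total > 0:
                out[aa] = {c: self.counts[c] / total for c in syns}
            else:
                out[aa] = {c: 1.0 / len(syns) for c in syns}
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# codon\tcount\n")
            for codon in STANDARD_CODE.codons:
                fh.write(f"{codon}\t{self.counts[codon]:g}\n")


def usage_from_sequence(seq: NucSequence) -> CodonUsageTable:
    """Tally codon usage of one coding-frame sequence."""
    if len(seq) == 0:
        warnings.warn("empty sequence: returning an all-zero usage table")
        return CodonUsageTable({})
    counts: dict[str, float] = {}
    for codon in seq.codons():
        counts[codon] = counts.get(codon, 0) + 1
    return CodonUsageTable(counts, organism=seq.name)


def read_cutg(path) -> CodonUsageTable:
    """Read a per-organism CUTG ("Codon Usage Tabulated from GenBank") table.

    The dialect is the Kazusa CodonFrequency-style layout: 64 fields of the
    form ``UUU 17.6( 714298)`` arranged four per line, RNA alphabet. A
    two-column ``codon<TAB>count`` TSV (comments with '#') is also accepted.
    """
    with open(path) as fh:
        lines = fh.readlines()
    text = "".join(lines)
    fields = _CUTG_FIELD.findall(text)
    if fields:
        if len(fields) != 64:
            # locate the last line contributing a field for a useful message
            n_seen, last_line = 0, 0
            for i, line in enumerate(lines, start=1):
                n_here = len(_CUTG_FIELD.findall(line))
                if n_here:
                    last_line = i
                n_seen += n_here
            raise TableError(
                f"malformed CUTG table: expected 64 codon fields, found {len(fields)}"
                f" (last codon field on line {last_line})"
            )
        counts: dict[str, float] = {}
        per_thousand: dict[str, float] = {}
        for codon, freq, count in fields:
            codon = codon.upper().replace("U", "T")
            if codon in counts:
                raise TableError(f"duplicate codon {codon} in CUTG table")
            counts[codon] = float(count)
            per_thousand[codon] = float(freq)
        return CodonUsageTable(counts, per_thousand=per_thousand)
    # TSV fallback
    counts = {}
    for i, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise TableError(f"malformed codon/count line {i}: {line!r}")
        codon = parts[0].upper().replace("U", "T")
        try:
            count = float(parts[1])
        except ValueError as exc:
            raise TableError(f"bad count on line {i}: {parts[1]!r}") from exc
        if codon in counts:
            raise TableError(f"duplicate codon {codon} on line {i}")
        counts[codon] = count
    if len(counts) != 64:
        raise TableError(
            f"malformed table: expected 64 codons, found {len(counts)}"
        )
    return CodonUsageTable(counts)


@dataclass
class AdaptivenessTable:
    """RSCU, per-family RSCU_max, and floored relative adaptiveness w."""

    rscu: dict[str, float]
    rscu_max: dict[str, float]
    w: dict[str, float]
    code: GeneticCode = field(default_factory=lambda: STANDARD_CODE, repr=False)

    def fractions(self) -> dict[str, dict[str, float]]:
        """Expected within-family sampling fractions implied by RSCU.

        RSCU_ij = fraction_ij * k_i, so fraction = RSCU / k.
        """
        out: dict[str, dict[str, float]] = {}
        for aa in self.code.amino_acids():
            k = self.code.degeneracy[aa]
            out[aa] = {c: self.rscu[c] / k for c in self.code.synonyms[aa]}
        return out


def compute_rscu(
    table: CodonUsageTable, code: GeneticCode = STANDARD_CODE
) -> AdaptivenessTable:
    """Compute RSCU, RSCU_max and floored w from a usage table.

    A family whose reference total is zero gets uniform RSCU = 1 and w = 1
    for all its codons (with a warning): with no information, no synonymous
    codon is preferred.
    """
    rscu: dict[str, float] = {}
    rscu_max: dict[str, float] = {}
    w: dict[str, float] = {}
    for aa in code.amino_acids():
        syns = code.synonyms[aa]
        k = len(syns)
        total = sum(table.counts[c] for c in syns)
        if total == 0:
            warnings.warn(
                f"amino acid {aa}: zero reference counts; assigning uniform RSCU=1, w=1"
            )
            for c in syns:
                rscu[c] = 1.0
                w[c] = 1.0
            rscu_max[aa] = 1.0
            continue
        fam_rscu = {c: table.counts[c] * k / total for c in syns}
        m = max(fam_rscu.values())
        rscu_max[aa] = m
        for c in syns:
            rscu[c] = fam_rscu[c]
            w[c] = max(fam_rscu[c] / m, W_FLOOR)
    return AdaptivenessTable(rscu=rscu, rscu_max=rscu_max, w=w, code=code)


class CodonLUT:
    """Slot-array look-up table for Monte-Carlo synonymous codon sampling.

    Each amino acid owns an array of ``granularity`` slots; a codon with
    expected fraction f occupies ~f*granularity slots (largest-remainder
    rounding, remainder slots to the largest fractions first). Sampling a
    uniform slot index then reproduces the target codon distribution.
    """

    def __init__(self, slots: dict[str, list[str]], granularity: int) -> None:
        self.granularity = granularity
        self.slots = slots

    def slot_counts(self, aa: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        for codon in self.slots[aa]:
            counts[codon] = counts.get(codon, 0) + 1
        return counts

    def sample(self, aa: str, rng) -> str:
        """Draw one synonymous codon for ``aa`` (rng: random.Random)."""
        return self.slots[aa][rng.randrange(self.granularity)]

    def codons(self, aa: str) -> tuple[str, ...]:
        return tuple(sorted(set(self.slots[aa])))


def build_lut(
    source,
    granularity: int = 1000,
    code: GeneticCode = STANDARD_CODE,
) -> CodonLUT:
    """Build the Monte-Carlo look-up table.

    ``source`` may be an :class:`AdaptivenessTable`, a
    :class:`CodonUsageTable`, or a per-amino-acid mapping of expected codon
    fractions ``{aa: {codon: fraction}}`` summing to 1 per family.
    """
    if isinstance(source, AdaptivenessTable):
        fractions = source.fractions()
    elif isinstance(source, CodonUsageTable):
        fractions = source.fractions(code)
    else:
        fractions = source
    slots: dict[str, list[str]] = {}
    for aa, fam in fractions.items():
        if aa == "*":
            continue
        if granularity < len(fam):
            raise TableError(
                f"granularity {granularity} smaller than family size {len(fam)} for {aa}"
            )
        total = sum(fam.values())
        if any(f < 0 for f in fam.values()):
            raise TableError(f"negative fraction in family {aa}")
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise TableError(f"fractions for {aa} sum to {total}, expected 1")
        # largest-remainder apportionment; ties to the larger fraction, then
        # alphabetical codon, for determinism
        base = {c: int(math.floor(f * granularity)) for c, f in fam.items()}
        remainder = granularity - sum(base.values())
        order = sorted(
            fam, key=lambda c: (-(fam[c] * granularity - base[c]), -fam[c], c)
        )
        for c in order[:remainder]:
            base[c] += 1
        arr: list[str] = []
        for c in sorted(base):
            arr.extend([c] * base[c])
        slots[aa] = arr
    return CodonLUT(slots, granularity)
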