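"""Gene-level indices: GC content, CAI, Nc, variant-space size, and the
generic moving-window profiler.

CAI (Sharp & Li) is the geometric mean of relative adaptiveness over the
gene's codons,

    CAI = exp( (1/L) * sum_ij X_ij ln w_ij )

where L counts codons excluding Met (ATG) and Trp (TGG) — the two
non-degenerate amino acids — and stop codons.

Nc (Wright's effective number of codons) is assembled from per-amino-acid
codon homozygosities

    F_hat_i = (n * sum_j p_j^2 - 1) / (n - 1)

averaged within each degeneracy class m in {2, 3, 4, 6}:

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

Nc is 20 for a gene using a single codon per amino acid and 61 for uniform
synonymous usage. When isoleucine (the only 3-fold amino acid of the
standard code) is absent or rare, F3 is reconstructed from the other
classes with Fuglsang's estimator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

from .codon_usage import AdaptivenessTable, CodonUsageTable, usage_from_sequence
from .errors import SequenceError
from .seqcore import GeneticCode, NucSequence, STANDARD_CODE

#: codons excluded from CAI along with stops: the single-codon amino acids
CAI_EXCLUDED_CODONS = frozenset({"ATG", "TGG"})

DEGENERACY_CLASSES = (2, 3, 4, 6)


def gc_content(seq: NucSequence) -> float:
    """GC content as a percentage (0-100)."""
    if len(seq) == 0:
        raise SequenceError("GC content of an empty sequence is undefined")
    gc = seq.residues.count("G") + seq.residues.count("C")
    return 100.0 * gc / len(seq)


def cai(
    seq: NucSequence,
    adapt: AdaptivenessTable,
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Codon adaptation index of a coding-frame sequence, in (0, 1]."""
    log_sum = 0.0
    n = 0
    for codon in seq.codons():
        if code.codon_to_aa[codon] == "*" or codon in CAI_EXCLUDED_CODONS:
            continue
        log_sum += math.log(adapt.w[codon])
        n += 1
    if n == 0:
        raise SequenceError(
            "CAI undefined: no countable codons (sequence contains only Met/Trp/stop codons)"
        )
    return math.exp(log_sum / n)


@dataclass
class HomozygosityTable:
    """Per-amino-acid codon homozygosity and per-degeneracy-class averages.

    ``f_hat[aa]`` is None when the amino acid occurs fewer than twice
    (the n-1 denominator vanishes); undefined entries are excluded from the
    class averages. ``class_avg[m]`` is None when no amino acid of class m
    has a defined homozygosity.
    """

    f_hat: dict[str, float | None]
    n_obs: dict[str, int]
    class_avg: dict[int, float | None]


def codon_homozygosity(
    source: NucSequence | CodonUsageTable,
    code: GeneticCode = STANDARD_CODE,
) -> HomozygosityTable:
    """Codon homozygosity F_hat per amino acid and class averages F_bar_m.

    Only amino acids with degeneracy in {2, 3, 4, 6} participate (Met and
    Trp carry no synonymous information).
    """
    usage = source if isinstance(source, CodonUsageTable) else usage_from_sequence(source)
    f_hat: dict[str, float | None] = {}
    n_obs: dict[str, int] = {}
    sums: dict[int, list[float]] = {m: [] for m in DEGENERACY_CLASSES}
    for aa in code.amino_acids():
        k = code.degeneracy[aa]
        if k not in DEGENERACY_CLASSES:
            continue
        counts = [usage.counts[c] for c in code.synonyms[aa]]
        n = int(sum(counts))
        n_obs[aa] = n
        if n < 2:
            f_hat[aa] = None
            continue
        sum_p2 = sum((x / n) ** 2 for x in counts)
        f = (n * sum_p2 - 1.0) / (n - 1.0)
        f_hat[aa] = f
        sums[k].append(f)
    class_avg: dict[int, float | None] = {
        m: (sum(v) / len(v) if v else None) for m, v in sums.items()
    }
    return HomozygosityTable(f_hat=f_hat, n_obs=n_obs, class_avg=class_avg)


def fuglsang_f3(f2: float, f4: float, f6: float) -> float:
    """Fuglsang's reconstruction of the 3-fold class homozygosity.

    Averages three transformations of the other class averages; each maps
    the uniform-usage limit (1/m) to 1/3 and the single-codon limit (1) to 1.
    """
    t2 = 1.0 / (2.0 / f2 - 1.0)
    t4 = 1.0 / ((2.0 / 3.0) / f4 + 1.0 / 3.0)
    t6 = 1.0 / ((2.0 / 5.0) / f6 + 3.0 / 5.0)
    return (t2 + t4 + t6) / 3.0


def nc_from_class_averages(
    f2: float, f3: float, f4: float, f6: float, cap: bool = True
) -> float:
    """Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, optionally capped at 61."""
    value = 2.0 + 9.0 / f2 + 1.0 / f3 + 5.0 / f4 + 3.0 / f6
    return min(value, 61.0) if cap else value


def nc(
    seq: NucSequence | CodonUsageTable,
    code: GeneticCode = STANDARD_CODE,
    *,
    ile_rare_threshold: int = 5,
    cap: bool = True,
) -> float:
    """Effective number of codons of a coding sequence, in [20, 61].

    If isoleucine occurs fewer than ``ile_rare_threshold`` times, the
    3-fold class average is taken from Fuglsang's estimator instead of the
    observed value. The finite-sample estimator can exceed 61; the result
    is capped at 61 by default since the index is defined on [20, 61].
    """
    table = codon_homozygosity(seq, code)
    avg = table.class_avg
    missing = [m for m in (2, 4, 6) if not avg[m]]
    if missing:
        raise SequenceError(
            f"Nc undefined: degeneracy class(es) {missing} have no defined "
            "homozygosity (each amino acid in them occurs fewer than twice, or "
            "the class average is zero)"
        )
    n_ile = sum(n for aa, n in table.n_obs.items() if code.degeneracy[aa] == 3)
    f3 = avg[3]
    if f3 is None or f3 == 0 or n_ile < ile_rare_threshold:
        f3 = fuglsang_f3(avg[2], avg[4], avg[6])
    return nc_from_class_averages(avg[2], f3, avg[4], avg[6], cap=cap)


@dataclass(frozen=True)
class VariantCount:
    """A possibly astronomically large count, kept in log10 space."""

    log10: float

    @property
    def exponent(self) -> int:
        return int(math.floor(self.log10))

    @property
    def mantissa(self) -> float:
        return 10.0 ** (self.log10 - self.exponent)

    def __float__(self) -> float:
        try:
            return 10.0 ** self.log10
        except OverflowError:
            return math.inf

    def __str__(self) -> str:
        return f"{self.mantissa:.3g}e{self.exponent:+d}"


#: average number of synonymous codons over the 18 multi-codon amino acids
AVG_SYNONYMOUS_MULTIPLICITY = 3.28


def variant_count(n_aa: int) -> VariantCount:
    """Size of the synonymous variant space of an average n_aa-residue protein.

    Assuming equal amino-acid frequencies, 18 of 20 residues are degenerate
    with on average 3.28 synonymous codons, giving 3.28 ** ((18/20) * n_aa)
    possible coding sequences. Returned in log10 form to avoid overflow.
    """
    if n_aa < 0:
        raise ValueError("n_aa must be non-negative")
    return VariantCount(log10=(18.0 / 20.0) * n_aa * math.log10(AVG_SYNONYMOUS_MULTIPLICITY))


@dataclass
class ProfileTrack:
    """Moving-window profile: one row per window, 1-based inclusive coords."""

    rows: list[tuple[int, int, float]]
    window: int
    step: int
    metric_name: str = ""

    def values(self) -> list[float]:
        return [v for _, _, v in self.rows]

    def min(self) -> float:
        return min(self.values())

    def to_tsv(self, path=None) -> str:
        lines = ["start\tend\tvalue"]
        lines += [f"{s}\t{e}\t{v:g}" for s, e, v in self.rows]
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def profile(
    seq: NucSequence,
    metric: Callable[[NucSequence], float],
    window: int = 60,
    step: int = 10,
    *,
    metric_name: str = "",
    clip_tail: bool = False,
) -> ProfileTrack:
    """Apply ``metric`` to a moving window over ``seq``.

    Windows start at 1, 1+step, 1+2*step, ... (1-based) while a full window
    fits; the trailing partial window is dropped unless ``clip_tail``. A
    window longer than the sequence yields a single clipped window with a
    warning.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    L = len(seq)
    rows: list[tuple[int, int, float]] = []
    if window > L:
        warnings.warn(
            f"window ({window}) exceeds sequence length ({L}); returning one clipped window"
        )
        rows.append((1, L, metric(seq)))
        return ProfileTrack(rows, window, step, metric_name)
    start = 0
    while start + window <= L:
        sub = seq.slice(start, start + window)
        rows.append((start + 1, start + window, metric(sub)))
        start += step
    if clip_tail and start < L:
        sub = seq.slice(start, L)
        rows.append((start + 1, L, metric(sub)))
    return ProfileTrack(rows, window, step, metric_name)
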