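"""Synthetic test-sequence generation.

Generates random coding sequences whose codon frequencies follow a given
codon usage table, optionally with planted repeats, restriction sites, or
polyadenylation-signal motifs for exercising the search and removal
tools. Everything is seeded and deterministic.

Planting overwrites bases in place (length is preserved); when a planted
motif must keep the reading frame meaningful, use
:func:`plant_site_in_frame`, which back-computes codons so the construct
stays a valid coding sequence containing the motif.
"""

from __future__ import annotations

import random

from .codon_usage import CodonUsageTable, build_lut
from .errors import SequenceError
from .seqcore import GeneticCode, NucSequence, ProteinSequence, STANDARD_CODE, translate

#: a small E. coli-flavoured reference usage table: counts per codon for a
#: biased reference gene set, used as the default fixture table. Counts are
#: synthetic (crafted to be clearly non-uniform), not measured data.
def biased_reference_table(seed: int = 7, scale: int = 1000) -> CodonUsageTable:
    """A deterministic, clearly biased 64-codon reference table.

    Within each family, codon c_r (r = 0..k-1, alphabetical) receives a
    count proportional to 2^r, scaled by ``scale``; stop codons get equal
    small counts. The geometric weighting guarantees a unique maximal
    codon per family, hence a unique w = 1 codon.
    """
    counts: dict[str, float] = {}
    code = STANDARD_CODE
    for aa in code.amino_acids(include_stop=True):
        syns = code.synonyms[aa]
        for r, codon in enumerate(syns):
            counts[codon] = scale * (2**r) if aa != "*" else 10
    return CodonUsageTable(counts, organism=f"synthetic-biased-{seed}")


def random_protein(n_aa: int, seed: int = 0, alphabet: str | None = None) -> ProteinSequence:
    """Uniform random protein of ``n_aa`` residues (no stops)."""
    rng = random.Random(seed)
    letters = alphabet or "ACDEFGHIKLMNPQRSTVWY"
    return ProteinSequence("".join(rng.choice(letters) for _ in range(n_aa)))


def random_coding_sequence(
    n_codons: int,
    usage: CodonUsageTable | None = None,
    seed: int = 0,
    code: GeneticCode = STANDARD_CODE,
    granularity: int = 1000,
) -> NucSequence:
    """Random coding sequence drawn from a codon usage table.

    Amino acids are drawn uniformly; each codon is then drawn from the
    usage table's within-family distribution via the Monte-Carlo look-up
    table (uniform synonymous usage if no table is given).
    """
    rng = random.Random(seed)
    if usage is None:
        fractions = {
            aa: {c: 1.0 / len(code.synonyms[aa]) for c in code.synonyms[aa]}
            for aa in code.amino_acids()
        }
        lut = build_lut(fractions, granularity=granularity, code=code)
    else:
        lut = build_lut(usage, granularity=granularity, code=code)
    aas = code.amino_acids()
    out = [lut.sample(rng.choice(aas), rng) for _ in range(n_codons)]
    return NucSequence("".join(out), name=f"synthetic-{seed}")


def random_dna(n: int, seed: int = 0, gc: float = 0.5) -> NucSequence:
    """Random DNA with an expected GC fraction ``gc``."""
    rng = random.Random(seed)
    out = []
    for _ in range(n):
        if rng.random() < gc:
            out.append(rng.choice("GC"))
        else:
            out.append(rng.choice("AT"))
    return NucSequence("".join(out), name=f"random-{seed}")


def plant_motif(seq: NucSequence, motif: str, position: int) -> NucSequence:
    """Overwrite bases so ``motif`` appears at 0-based ``position``."""
    motif = motif.upper().replace("U", "T")
    if position < 0 or position + len(motif) > len(seq):
        raise SequenceError("motif does not fit at the requested position")
    s = seq.residues
    return NucSequence(
        s[:position] + motif + s[position + len(motif) :],
        name=seq.name,
        alphabet_kind=seq.alphabet_kind,
    )


def plant_repeat(
    seq: NucSequence, motif: str, positions: list[int]
) -> NucSequence:
    """Plant the same motif at several 0-based positions (a direct repeat)."""
    out = seq
    for p in positions:
        out = plant_motif(out, motif, p)
    return out


def plant_site_in_frame(
    seq: NucSequence,
    motif: str,
    codon_index: int,
    code: GeneticCode = STANDARD_CODE,
) -> NucSequence:
    """Overwrite whole codons starting at ``codon_index`` with a motif padded
    to a codon boundary, keeping the result a translatable coding sequence.

    The motif is padded on the right with 'A' up to a multiple of 3. The
    encoded protein changes at the overwritten codons (this is a fixture
    generator, not a silent edit); the result still translates cleanly
    unless the motif itself introduces a stop codon, which is rejected.
    """
    motif = motif.upper().replace("U", "T")
    padded = motif + "A" * (-len(motif) % 3)
    start = codon_index * 3
    out = plant_motif(seq, padded, start)
    if "*" in translate(out, code).residues:
        raise SequenceError("planted motif introduces a stop codon in frame")
    return out
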