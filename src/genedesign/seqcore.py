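"""Sequence types, the standard genetic code, and elementary manipulations.

The internal alphabet is DNA (``T``). RNA input is accepted everywhere and
normalized to DNA on entry; the original alphabet is remembered on the
sequence object so downstream display (e.g. folding output) can convert
back. Coordinates are 0-based half-open internally; every user-facing
report is 1-based inclusive.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from Bio.Data import CodonTable
from Bio import SeqIO

from .errors import SequenceError

DNA_LETTERS = frozenset("ACGT")
AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY*")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class NucSequence:
    """A nucleotide sequence over {A,C,G,T}.

    ``alphabet_kind`` records whether the input was DNA or RNA; residues are
    always stored as DNA. Zero-length sequences are permitted so that null
    (invisible) construct components can be represented.
    """

    residues: str
    name: str = ""
    alphabet_kind: str = "dna"  # "dna" | "rna"

    def __post_init__(self) -> None:
        bad = set(self.residues) - DNA_LETTERS
        if bad:
            raise SequenceError(f"invalid residues {sorted(bad)} in sequence {self.name!r}")
        if self.alphabet_kind not in ("dna", "rna"):
            raise SequenceError(f"alphabet_kind must be 'dna' or 'rna', got {self.alphabet_kind!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def as_rna(self) -> str:
        """Residues in the RNA alphabet (T shown as U)."""
        return self.residues.replace("T", "U")

    def codons(self) -> list[str]:
        if len(self.residues) % 3:
            raise SequenceError(
                f"sequence length {len(self.residues)} is not a multiple of 3"
            )
        return [self.residues[i : i + 3] for i in range(0, len(self.residues), 3)]

    def slice(self, start: int, end: int, name: str | None = None) -> "NucSequence":
        """0-based half-open slice keeping metadata."""
        return NucSequence(self.residues[start:end], name or self.name, self.alphabet_kind)


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence in one-letter code; '*' denotes a stop."""

    residues: str
    name: str = ""

    def __post_init__(self) -> None:
        bad = set(self.residues) - AA_LETTERS
        if bad:
            raise SequenceError(f"invalid amino-acid letters {sorted(bad)} in {self.name!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


class GeneticCode:
    """A codon -> amino-acid mapping plus synonymous-family bookkeeping.

    Built from the NCBI translation tables (standard code id 1 by default).
    Stops are represented as '*'. ``degeneracy[aa]`` is the number of
    synonymous codons k for that amino acid.
    """

    def __init__(self, table_id: int = 1) -> None:
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.codon_to_aa: dict[str, str] = dict(table.forward_table)
        for stop in table.stop_codons:
            self.codon_to_aa[stop] = "*"
        if len(self.codon_to_aa) != 64:
            raise SequenceError(f"translation table {table_id} does not define 64 codons")
        self.synonyms: dict[str, tuple[str, ...]] = {}
        by_aa: dict[str, list[str]] = {}
        for codon in sorted(self.codon_to_aa):
            by_aa.setdefault(self.codon_to_aa[codon], []).append(codon)
        for aa, codons in by_aa.items():
            self.synonyms[aa] = tuple(codons)
        self.degeneracy: dict[str, int] = {aa: len(c) for aa, c in self.synonyms.items()}

    @property
    def codons(self) -> tuple[str, ...]:
        return tuple(sorted(self.codon_to_aa))

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in self.codons if self.codon_to_aa[c] != "*")

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in self.codons if self.codon_to_aa[c] == "*")

    def amino_acids(self, include_stop: bool = False) -> tuple[str, ...]:
        aas = sorted(self.synonyms)
        if not include_stop:
            aas = [a for a in aas if a != "*"]
        return tuple(aas)


STANDARD_CODE = GeneticCode(1)


def parse_sequence(text: str, name: str = "") -> NucSequence:
    """Parse free text (raw or FASTA-ish) into a :class:`NucSequence`.

    Header lines (starting '>' or ';'), whitespace and digits are stripped;
    letters are uppercased; U is normalized to T and flags the sequence as
    RNA. Any other letter is rejected, naming the offending character and
    its 1-based position in the cleaned sequence.
    """
    lines = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith(">") or stripped.startswith(";"):
            if stripped.startswith(">") and not name:
                name = stripped[1:].split()[0] if len(stripped) > 1 else ""
            continue
        lines.append(line)
    cleaned = "".join(
        ch for ch in "".join(lines).upper() if not ch.isspace() and not ch.isdigit()
    )
    for pos, ch in enumerate(cleaned, start=1):
        if ch not in "ACGTU":
            raise SequenceError(
                f"invalid character {ch!r} at position {pos} (1-based, after cleanup)"
            )
    kind = "rna" if "U" in cleaned else "dna"
    return NucSequence(cleaned.replace("U", "T"), name=name, alphabet_kind=kind)


def translate(seq: NucSequence, code: GeneticCode = STANDARD_CODE) -> ProteinSequence:
    """Translate a coding-frame sequence; stops render as '*'.

    A trailing partial codon is an error — the caller must trim explicitly.
    """
    return ProteinSequence(
        "".join(code.codon_to_aa[c] for c in seq.codons()), name=seq.name
    )


def reverse_complement(seq: NucSequence) -> NucSequence:
    return NucSequence(
        seq.residues.translate(_COMPLEMENT)[::-1], name=seq.name, alphabet_kind=seq.alphabet_kind
    )


def revcomp(residues: str) -> str:
    """Reverse complement of a plain DNA string (internal helper)."""
    return residues.translate(_COMPLEMENT)[::-1]


def back_translate(
    protein: ProteinSequence,
    code: GeneticCode = STANDARD_CODE,
    policy: str = "first-codon",
    *,
    w: dict[str, float] | None = None,
    seed: int | None = None,
    stop_codon: str | None = None,
) -> NucSequence:
    """Back-translate a protein under a codon-choice policy.

    policy:
        ``first-codon``  — alphabetically first synonymous codon (deterministic);
        ``max-w``        — codon with maximal relative adaptiveness (requires ``w``);
        ``random``       — uniform draw among synonyms (requires ``seed``).

    '*' in the protein requires an explicit ``stop_codon``; otherwise it is
    rejected, since no policy can pick a stop meaningfully.
    """
    if policy not in ("first-codon", "max-w", "random"):
        raise SequenceError(f"unknown back-translation policy {policy!r}")
    if policy == "max-w" and w is None:
        raise SequenceError("policy 'max-w' requires a w (relative adaptiveness) mapping")
    rng = random.Random(seed) if policy == "random" else None
    out: list[str] = []
    for aa in protein.residues:
        if aa == "*":
            if stop_codon is None:
                raise SequenceError("protein contains '*' but no stop_codon policy was given")
            out.append(stop_codon)
            continue
        syns = code.synonyms[aa]
        if policy == "first-codon":
            out.append(syns[0])
        elif policy == "max-w":
            out.append(max(syns, key=lambda c: (w.get(c, 0.0), c)))
        else:
            out.append(rng.choice(syns))
    return NucSequence("".join(out), name=protein.name)


# --- FASTA I/O (multi-record) -------------------------------------------------

def read_fasta(path) -> list[NucSequence]:
    """Read a (multi-)FASTA file of nucleotide records."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(parse_sequence(str(rec.seq), name=rec.id))
    return records


def write_fasta(path, sequences: list[NucSequence], width: int = 70) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(sequences):
            fh.write(f">{seq.name or f'seq{i + 1}'}\n")
            for j in range(0, len(seq.residues), width):
                fh.write(seq.residues[j : j + width] + "\n")
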