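"""Shared fixtures: reference usage tables and a CUTG-format fixture file."""

from __future__ import annotations

import pytest

from genedesign import STANDARD_CODE, CodonUsageTable, compute_rscu
from genedesign.synthetic import biased_reference_table


@pytest.fixture(scope="session")
def biased_table() -> CodonUsageTable:
    """Deterministic, clearly biased 64-codon reference table."""
    return biased_reference_table()


@pytest.fixture(scope="session")
def biased_adapt(biased_table):
    return compute_rscu(biased_table)


def cutg_text(table: CodonUsageTable) -> str:
    """Render a usage table in the Kazusa CodonFrequency-style CUTG layout.

    Four fields per line, RNA alphabet, 'codon  per-thousand( count )'.
    """
    total = table.total
    fields = []
    for codon in STANDARD_CODE.codons:
        count = table.counts[codon]
        per_k = 1000.0 * count / total if total else 0.0
        fields.append(f"{codon.replace('T', 'U')} {per_k:4.1f}({int(count):7d})")
    lines = ["  ".join(fields[i : i + 4]) for i in range(0, 64, 4)]
    return "\n".join(lines) + "\n"


@pytest.fixture()
def cutg_file(tmp_path, biased_table):
    path = tmp_path / "reference.cutg"
    path.write_text(cutg_text(biased_table))
    return path
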