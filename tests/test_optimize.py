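"""Protein-preserving optimizers: Monte-Carlo, silent removal, energy-range."""

import itertools
import math
import random

import pytest
from scipy import stats

from genedesign import (
    BuiltinFoldEngine,
    NucSequence,
    STANDARD_CODE,
    build_lut,
    codon_optimize,
    mrna_optimize,
    search_queries,
    silent_remove,
    translate,
    windowed_mrna_optimize,
)
from genedesign.synthetic import biased_reference_table, random_coding_sequence

ALA_FRACTIONS = {"A": {"GCA": 0.1, "GCC": 0.2, "GCG": 0.3, "GCT": 0.4}}


class TestCodonOptimize:
    def test_empirical_fractions_follow_lut(self):
        """10,000 alanines resampled from the 0.1/0.2/0.3/0.4 LUT pass a
        chi-square goodness-of-fit test at alpha = 0.01."""
        lut = build_lut(ALA_FRACTIONS)
        seq = NucSequence("GCT" * 10_000)
        out = codon_optimize(seq, lut, seed=42)
        counts = {c: 0 for c in ALA_FRACTIONS["A"]}
        for codon in out.sequence.codons():
            counts[codon] += 1
        observed = [counts[c] for c in sorted(counts)]
        expected = [ALA_FRACTIONS["A"][c] * 10_000 for c in sorted(counts)]
        assert stats.chisquare(observed, expected).pvalue > 0.01
        assert translate(out.sequence).residues == "A" * 10_000

    def test_met_trp_stop_untouched(self, biased_adapt):
        lut = build_lut(biased_adapt)
        seq = NucSequence("ATGTGGTAA")
        out = codon_optimize(seq, lut, seed=0)
        assert out.sequence.residues == "ATGTGGTAA"
        assert out.changes == []

    def test_determinism(self, biased_adapt):
        lut = build_lut(biased_adapt)
        seq = random_coding_sequence(100, biased_reference_table(), seed=5)
        a = codon_optimize(seq, lut, seed=9)
        b = codon_optimize(seq, lut, seed=9)
        assert a.sequence.residues == b.sequence.residues
        assert a.changes == b.changes

    def test_distributional_fixed_point(self):
        """Resampling from a LUT built from the input's own usage leaves the
        codon distribution unchanged (chi-square on before vs after)."""
        from genedesign import usage_from_sequence

        seq = random_coding_sequence(4000, biased_reference_table(), seed=13)
        usage = usage_from_sequence(seq)
        lut = build_lut(usage)
        out = codon_optimize(seq, lut, seed=31)
        after = usage_from_sequence(out.sequence)
        code = STANDARD_CODE
        for aa in ("L", "A", "G", "K"):
            fam = code.synonyms[aa]
            before_counts = [usage.counts[c] for c in fam]
            n = sum(before_counts)
            if n < 50:
                continue
            after_counts = [after.counts[c] for c in fam]
            expected = [max(x, 1e-9) / n * sum(after_counts) for x in before_counts]
            assert stats.chisquare(after_counts, expected).pvalue > 0.01

    def test_change_log_positions(self, biased_adapt):
        lut = build_lut(biased_adapt)
        seq = NucSequence("AAAAAA")  # K K
        out = codon_optimize(seq, lut, seed=1)
        for pos, old, new in out.changes:
            assert old != new
            assert out.sequence.codons()[pos - 1] == new


class TestSilentRemove:
    def test_ecori_inside_coding_region(self, biased_adapt):
        """GAA GAA TTC GAA (E E F E): the GAATTC at base 4 must vanish while
        the protein stays EEFE and only codons 2-4 may change."""
        seq = NucSequence("GAAGAATTCGAA")
        out = silent_remove(seq, ["GAATTC"], biased_adapt, seed=2)
        assert out.success
        assert "GAATTC" not in out.sequence.residues
        assert translate(out.sequence).residues == "EEFE"
        assert all(2 <= pos <= 4 for pos, _, _ in out.changes)
        # exhaustive check: some synonymous variant of codons 2-4 avoids the site
        code = STANDARD_CODE
        options = [code.synonyms[aa] for aa in "EFE"]
        assert any(
            "GAATTC" not in "GAA" + "".join(combo) + ""
            for combo in itertools.product(*options)
        )

    def test_absent_target_is_identity(self, biased_adapt):
        seq = NucSequence("AAAGGGCCCTTT")
        out = silent_remove(seq, ["GAATTC"], biased_adapt, seed=0)
        assert out.sequence.residues == seq.residues
        assert out.changes == [] and out.success

    def test_met_trp_site_irremovable(self, biased_adapt):
        seq = NucSequence("ATGTGG")
        out = silent_remove(seq, ["ATGTGG"], biased_adapt, seed=0)
        assert not out.success
        assert "irremovable" in out.message
        assert translate(out.sequence).residues == "MW"

    def test_substitution_created_sites_also_removed(self, biased_adapt):
        """Global re-scan: after each removal the whole sequence is checked
        again, so no target survives anywhere."""
        rng = random.Random(0)
        for trial in range(10):
            seq = random_coding_sequence(60, biased_reference_table(), seed=200 + trial)
            out = silent_remove(seq, ["GAATTC", "GGATCC"], biased_adapt, seed=trial)
            if out.success:
                assert "GAATTC" not in out.sequence.residues
                assert "GGATCC" not in out.sequence.residues

    @pytest.mark.parametrize("trial", range(50))
    def test_planted_ecori_fixtures(self, biased_adapt, trial):
        """50 random coding fixtures with a planted in-frame EcoRI site:
        removal succeeds, search finds zero occurrences, protein preserved."""
        seq = random_coding_sequence(40, biased_reference_table(), seed=500 + trial)
        # plant GAATTC on a codon boundary: GAA TTC codes E F
        pos = 3 * (3 + trial % 30)
        s = seq.residues[:pos] + "GAATTC" + seq.residues[pos + 6 :]
        seq = NucSequence(s)
        protein = translate(seq).residues
        out = silent_remove(seq, ["GAATTC"], biased_adapt, seed=trial)
        assert out.success
        (hit,) = search_queries(out.sequence, "GAATTC")
        assert hit.count == 0
        assert translate(out.sequence).residues == protein


class TestMrnaOptimize:
    def test_already_in_range_no_changes(self):
        seq = NucSequence("AAAAAAAAA")  # folds to 0
        out = mrna_optimize(seq, energy_min=-1.0, energy_max=0.0, seed=0)
        assert out.success and out.iterations == 0 and out.changes == []

    def test_destabilize_toy_hairpin(self):
        """ACA AGC CCA CTA (T S P L) folds to -1.8; a range of [-1, 0]
        forces synonymous substitutions that weaken the pairing.

        Feasibility pre-verified by exhaustive search over all synonymous
        variants of the 4-codon toy."""
        seq = NucSequence("ACAAGCCCACTA")
        engine = BuiltinFoldEngine()
        assert engine.energy(seq) < -1.0
        code = STANDARD_CODE
        protein = translate(seq).residues
        options = [code.synonyms[aa] for aa in protein]
        feasible = any(
            -1.0 <= engine.energy(NucSequence("".join(combo))) <= 0.0
            for combo in itertools.product(*options)
        )
        assert feasible
        out = mrna_optimize(
            seq, engine, energy_min=-1.0, energy_max=0.0, seed=3, max_iterations=2000
        )
        assert out.success
        assert -1.0 <= out.metrics["energy"] <= 0.0
        assert translate(out.sequence).residues == protein

    def test_unsatisfiable_unique_coding_fails(self):
        seq = NucSequence("ATGATGATG")
        out = mrna_optimize(seq, energy_min=-100.0, energy_max=-50.0, seed=0)
        assert not out.success
        assert out.sequence.residues == seq.residues

    def test_determinism(self):
        seq = NucSequence("ACAAGCCCACTA")
        kwargs = dict(energy_min=-1.0, energy_max=0.0, seed=17, max_iterations=500)
        a = mrna_optimize(seq, **kwargs)
        b = mrna_optimize(seq, **kwargs)
        assert a.sequence.residues == b.sequence.residues
        assert a.changes == b.changes


class TestWindowedMrnaOptimize:
    def test_satisfying_input_unchanged(self):
        seq = NucSequence("A" * 120)
        out = windowed_mrna_optimize(seq, energy_min=-5.0, energy_max=0.0, seed=0)
        assert out.success and out.sequence.residues == seq.residues

    def test_every_window_verified_post_hoc(self):
        seq = random_coding_sequence(50, seed=3)  # 150 bases
        engine = BuiltinFoldEngine()
        out = windowed_mrna_optimize(
            seq,
            engine,
            energy_min=-12.0,
            energy_max=0.0,
            window=60,
            step=30,
            seed=5,
            max_iterations=300,
        )
        assert translate(out.sequence).residues == translate(seq).residues
        if out.success:
            L = len(out.sequence)
            for ws in range(0, L - 60 + 1, 30):
                e = engine.energy(out.sequence.slice(ws, ws + 60))
                assert -12.0 <= e <= 0.0
        else:
            assert out.metrics["out_of_range_windows"]

    def test_fewer_changes_than_full_resampling(self, biased_adapt):
        """Windowed optimization touches few codons compared with resampling
        every position."""
        lut = build_lut(biased_adapt)
        seq = random_coding_sequence(50, biased_reference_table(), seed=21)
        out = windowed_mrna_optimize(
            seq, energy_min=-30.0, energy_max=0.0, window=60, step=30, seed=7
        )
        full = codon_optimize(seq, lut, seed=7)
        assert len(out.changes) <= len(full.changes)
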