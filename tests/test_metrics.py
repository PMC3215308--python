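"""GC content, CAI, codon homozygosity / Nc, variant count, profiles."""

import math
import random

import pytest

from genedesign import (
    CodonUsageTable,
    NucSequence,
    SequenceError,
    STANDARD_CODE,
    back_translate,
    cai,
    codon_homozygosity,
    compute_rscu,
    fuglsang_f3,
    gc_content,
    nc,
    nc_from_class_averages,
    profile,
    translate,
    variant_count,
)
from genedesign.synthetic import random_protein


class TestGCContent:
    @pytest.mark.parametrize(
        "seq,expected", [("GGCC", 100.0), ("AATT", 0.0), ("ACGT", 50.0)]
    )
    def test_examples(self, seq, expected):
        assert gc_content(NucSequence(seq)) == expected

    def test_empty_rejected(self):
        with pytest.raises(SequenceError):
            gc_content(NucSequence(""))


class TestCAI:
    def test_two_codon_geometric_mean(self):
        """AAA (w=1) + AAG (w=1/3): CAI = exp((ln 1 + ln 1/3)/2) = 3^(-1/2)."""
        with pytest.warns(UserWarning):
            adapt = compute_rscu(CodonUsageTable({"AAA": 3, "AAG": 1}))
        value = cai(NucSequence("AAAAAG"), adapt)
        assert value == pytest.approx(3 ** -0.5, rel=1e-12)
        # independent oracle: per-codon product then L-th root
        assert value == pytest.approx((1.0 * (1 / 3)) ** (1 / 2), rel=1e-12)

    def test_all_optimal_gene_scores_one(self, biased_adapt):
        prot = random_protein(50, seed=3)
        seq = back_translate(prot, policy="max-w", w=biased_adapt.w)
        assert cai(seq, biased_adapt) == pytest.approx(1.0, abs=1e-12)

    def test_met_trp_only_is_undefined(self, biased_adapt):
        with pytest.raises(SequenceError, match="Met/Trp"):
            cai(NucSequence("ATGTGG"), biased_adapt)

    def test_met_trp_and_stops_excluded_from_l(self, biased_adapt):
        """Appending ATG/TGG/TAA leaves CAI unchanged."""
        seq = NucSequence("AAAAAGCTG")
        base = cai(seq, biased_adapt)
        assert cai(NucSequence(seq.residues + "ATGTGGTAA"), biased_adapt) == pytest.approx(base)

    def test_reference_scale_invariance(self, biased_table):
        adapt1 = compute_rscu(biased_table)
        adapt2 = compute_rscu(
            CodonUsageTable({c: 7 * n for c, n in biased_table.counts.items()})
        )
        seq = NucSequence("AAAAAGCTGGAAGAT")
        assert cai(seq, adapt1) == pytest.approx(cai(seq, adapt2), rel=1e-12)
        assert 0.0 < cai(seq, adapt1) <= 1.0


class TestHomozygosity:
    def test_lysine_even_split(self):
        """Lys {AAA:2, AAG:2}: F = (4*0.5 - 1)/3 = 1/3."""
        table = codon_homozygosity(NucSequence("AAA" + "AAA" + "AAG" + "AAG"))
        assert table.f_hat["K"] == pytest.approx(1 / 3)

    def test_single_observation_undefined(self):
        table = codon_homozygosity(NucSequence("AAA"))
        assert table.n_obs["K"] == 1
        assert table.f_hat["K"] is None

    def test_exclusive_codon_gives_one(self):
        table = codon_homozygosity(NucSequence("AAAAAAAAA"))
        assert table.f_hat["K"] == pytest.approx(1.0)


class TestNc:
    def test_extreme_bias_endpoint(self):
        assert nc_from_class_averages(1, 1, 1, 1) == 20.0

    def test_uniform_usage_endpoint(self):
        assert nc_from_class_averages(1 / 2, 1 / 3, 1 / 4, 1 / 6) == 61.0

    def test_fuglsang_limits(self):
        assert fuglsang_f3(1.0, 1.0, 1.0) == pytest.approx(1.0)
        assert fuglsang_f3(0.5, 0.25, 1 / 6) == pytest.approx(1 / 3)

    def test_uniform_simulated_gene_near_61(self):
        """10,000 codons uniform within families: Nc slightly below 61.

        Finite-n homozygosity (n/k - 1)/(n - 1) slightly exceeds 1/k, so the
        estimator lands just under the 61 ceiling.
        """
        rng = random.Random(11)
        code = STANDARD_CODE
        aas = code.amino_acids()
        seq = "".join(rng.choice(code.synonyms[rng.choice(aas)]) for _ in range(10_000))
        value = nc(NucSequence(seq))
        assert 59.0 <= value <= 61.0

    def test_synonymous_permutation_invariance(self):
        rng = random.Random(5)
        code = STANDARD_CODE
        codons = [rng.choice(code.synonyms[rng.choice(code.amino_acids())]) for _ in range(600)]
        base = nc(NucSequence("".join(codons)))
        rng.shuffle(codons)  # permuting codon order never changes counts
        assert nc(NucSequence("".join(codons))) == pytest.approx(base)

    def test_fuglsang_used_when_ile_absent(self):
        """A gene with no Ile still gets a defined Nc via the estimator."""
        rng = random.Random(2)
        code = STANDARD_CODE
        aas = tuple(a for a in code.amino_acids() if a != "I")
        seq = "".join(rng.choice(code.synonyms[rng.choice(aas)]) for _ in range(3000))
        value = nc(NucSequence(seq))
        assert 20.0 <= value <= 61.0

    def test_undefined_class_reported(self):
        with pytest.raises(SequenceError, match="Nc undefined"):
            nc(NucSequence("AAA"))  # every class has n < 2


class TestVariantCount:
    def test_astronomical_scale_example(self):
        vc = variant_count(250)
        assert vc.exponent == 116
        assert vc.mantissa == pytest.approx(1.18, abs=0.005)

    def test_empty_protein(self):
        assert float(variant_count(0)) == 1.0

    def test_log_linearity_and_direct_exponentiation(self):
        slope = 0.9 * math.log10(3.28)
        for n in (1, 10, 50, 100):
            vc = variant_count(n)
            assert vc.log10 == pytest.approx(slope * n, rel=1e-12)
            assert float(vc) == pytest.approx(3.28 ** (0.9 * n), rel=1e-9)


class TestProfile:
    def test_window_geometry_defaults(self):
        track = profile(NucSequence("A" * 100), gc_content)
        assert [s for s, _, _ in track.rows] == [1, 11, 21, 31, 41]
        assert all(e - s + 1 == 60 for s, e, _ in track.rows)

    def test_all_a_zero_track(self):
        track = profile(NucSequence("A" * 100), gc_content, window=10, step=10)
        assert track.values() == [0.0] * 10

    def test_constant_metric_rows_equal(self):
        track = profile(NucSequence("ACGT" * 30), lambda s: 42.0, window=16, step=7)
        assert set(track.values()) == {42.0}

    def test_tiling_matches_direct_slices(self):
        seq = NucSequence("ACGTGGCCAATTACGGCCTA")
        track = profile(seq, gc_content, window=5, step=5)
        for i, (s, e, v) in enumerate(track.rows):
            assert v == gc_content(seq.slice(i * 5, i * 5 + 5))

    def test_window_longer_than_sequence_clips_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            track = profile(NucSequence("ACGT"), gc_content, window=10, step=5)
        assert track.rows == [(1, 4, 50.0)]
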