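"""Repeat discovery (with smart filter) and multi-query search."""

import random

import pytest

from genedesign import (
    NucSequence,
    SearchError,
    find_repeats,
    load_predefined_set,
    reverse_complement,
    search_queries,
)
from genedesign.search import DIRECT, REVCOMP, RepeatFinding, split_queries
from genedesign.seqcore import revcomp


# --- independent brute-force oracle ------------------------------------------

def brute_force_repeats(s: str, min_len: int) -> set[tuple[str, tuple[tuple[int, str], ...]]]:
    """All-pairs enumeration over every motif length >= min_len, followed by
    the same containment (smart) filter the implementation documents."""
    groups: dict[str, list[tuple[int, str]]] = {}
    for ell in range(min_len, len(s) + 1):
        for i in range(len(s) - ell + 1):
            motif = s[i : i + ell]
            if motif in groups:
                continue
            rc = revcomp(motif)
            occs = [(p, DIRECT) for p in _matches(s, motif)]
            if rc != motif:
                occs += [(p, REVCOMP) for p in _matches(s, rc)]
            occs.sort()
            if len(occs) >= 2 or rc == motif:
                groups[motif] = occs
    findings = [
        RepeatFinding(m, [(p + 1, o) for p, o in occ]) for m, occ in groups.items()
    ]
    kept = set()
    for f in findings:
        contained = any(
            g.length > f.length
            and all(
                any(gp <= fp and fp + f.length <= gp + g.length for gp, _ in g.occurrences)
                for fp, _ in f.occurrences
            )
            for g in findings
        )
        if not contained:
            kept.add((f.motif, tuple(f.occurrences)))
    return kept


def _matches(s: str, motif: str) -> list[int]:
    out, start = [], s.find(motif)
    while start != -1:
        out.append(start)
        start = s.find(motif, start + 1)
    return out


class TestFindRepeats:
    def test_direct_repeat(self):
        findings = find_repeats(NucSequence("AAGGAAGG"), min_len=4)
        assert len(findings) == 1
        f = findings[0]
        assert f.motif == "AAGG"
        assert f.occurrences == [(1, DIRECT), (5, DIRECT)]
        assert f.consecutive  # occurrences abut

    def test_palindrome_single_site(self):
        findings = find_repeats(NucSequence("GAATTC"), min_len=6)
        assert len(findings) == 1
        assert findings[0].palindromic
        assert findings[0].motif == "GAATTC"

    def test_too_short_sequence_warns_empty(self):
        with pytest.warns(UserWarning):
            assert find_repeats(NucSequence("ACG"), min_len=4) == []

    def test_min_len_floor_enforced(self):
        with pytest.raises(SearchError):
            find_repeats(NucSequence("ACGTACGT"), min_len=2)

    def test_reverse_complement_repeat_detected(self):
        # CCAATTGG-like: plant a motif and its reverse complement
        seq = NucSequence("AAGGCTTA" + "CCCCC" + revcomp("AAGGCTTA"))
        findings = find_repeats(seq, min_len=8)
        assert any(
            {o for _, o in f.occurrences} == {DIRECT, REVCOMP} for f in findings
        )

    def test_seed_extension_to_maximal_motif(self):
        seq = NucSequence("TTAAGGCCATT" + "G" * 6 + "TTAAGGCCATT")
        findings = find_repeats(seq, min_len=4)
        assert any(f.motif == "TTAAGGCCATT" for f in findings)

    def test_smart_filter_suppresses_contained_findings(self):
        seq = NucSequence("TTAAGGCCATT" + "G" * 6 + "TTAAGGCCATT")
        with_filter = find_repeats(seq, min_len=4, smart_filter=True)
        without = find_repeats(seq, min_len=4, smart_filter=False)
        assert len(with_filter) <= len(without)
        long = next(f for f in with_filter if f.motif == "TTAAGGCCATT")
        for f in with_filter:
            if f is long:
                continue
            assert not all(
                any(gp <= p and p + f.length <= gp + long.length for gp, _ in long.occurrences)
                for p, _ in f.occurrences
            )

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_random_sequences(self, seed):
        rng = random.Random(1000 + seed)
        s = "".join(rng.choice("ACGT") for _ in range(200))
        got = {
            (f.motif, tuple(f.occurrences))
            for f in find_repeats(NucSequence(s), min_len=8)
        }
        assert got == brute_force_repeats(s, 8)

    def test_revcomp_symmetry(self):
        rng = random.Random(77)
        s = "".join(rng.choice("ACGT") for _ in range(120))
        s = s[:30] + s[10:18] + s[38:]  # plant one duplicate window
        fwd = find_repeats(NucSequence(s), min_len=8)
        rev = find_repeats(reverse_complement(NucSequence(s)), min_len=8)
        assert sorted(min(f.motif, revcomp(f.motif)) for f in fwd) == sorted(
            min(f.motif, revcomp(f.motif)) for f in rev
        )


class TestSearchQueries:
    def test_enzyme_name_resolution(self):
        hits = search_queries(NucSequence("GAATTCGAATTC"), "EcoRI")
        (h,) = hits
        assert h.motif == "GAATTC"
        assert h.count == 2
        assert [p for p, _ in h.locations] == [1, 7]

    def test_overlapping_occurrences_counted(self):
        (h,) = search_queries(NucSequence("AAAA"), "AAA")
        assert h.count == 2
        assert [p for p, _ in h.locations] == [1, 2]

    def test_zero_count_hits_included(self):
        hits = search_queries(NucSequence("ACGT"), "EcoRI, GGGG")
        assert [h.count for h in hits] == [0, 0]
        assert hits[0].motif == "GAATTC"

    def test_unknown_enzyme_is_per_token_error(self):
        hits = search_queries(NucSequence("GAATTC"), "NoSuchEnzyme,EcoRI")
        assert hits[0].error and hits[0].count == 0
        assert hits[1].count == 1

    def test_both_strands(self):
        # GGTCTC is BsaI-like, non-palindromic; its rc is GAGACC
        seq = NucSequence("GGTCTCAAAGAGACC")
        (h,) = search_queries(seq, "GGTCTC", both_strands=True)
        assert h.count == 2
        assert {o for _, o in h.locations} == {DIRECT, REVCOMP}

    def test_counts_match_naive_scan(self):
        rng = random.Random(9)
        s = "".join(rng.choice("ACGT") for _ in range(500))
        for motif in ("ACG", "GAATTC", "TTTT"):
            (h,) = search_queries(NucSequence(s), motif)
            assert h.count == len(_matches(s, motif))

    def test_token_splitting(self):
        assert split_queries("a\tb,c\nd,,\n") == ["a", "b", "c", "d"]


class TestPredefinedSets:
    def test_polya_contains_canonical_signal(self):
        assert "AATAAA" in split_queries(load_predefined_set("polyA-signals"))

    def test_restriction_set_contains_ecori(self):
        tokens = split_queries(load_predefined_set("common-restriction-sites"))
        assert "EcoRI" in tokens
        hits = search_queries(NucSequence("GAATTC"), "EcoRI")
        assert hits[0].motif == "GAATTC"

    def test_unknown_set_rejected(self):
        with pytest.raises(SearchError, match="nosuchset"):
            load_predefined_set("nosuchset")
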