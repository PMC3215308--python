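"""Repeated-sequence discovery and multi-query / restriction-site search.

Repeat search slides a seed window of ``min_len`` bases over the sequence
and compares it against the whole sequence in both orientations; matching
seed groups are extended to maximal length, and the "smart filter" then
suppresses findings whose every occurrence lies inside an occurrence of a
longer finding. Palindromic sites (equal to their own reverse complement)
are reportable from a single occurrence; consecutive (tandem) repeats are
flagged when occurrences abut.

All reported positions are 1-based starts; overlapping occurrences are all
counted.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

from .errors import SearchError
from .seqcore import NucSequence, revcomp

DIRECT = "direct"
REVCOMP = "reverse-complement"

PREDEFINED_SETS = {
    "common-restriction-sites": "restriction_enzymes.tsv",
    "polyA-signals": "polya_signals.txt",
    "cryptic-splice-sites": "splice_sites.txt",
}


@dataclass
class RepeatFinding:
    """One repeated (or palindromic) motif and all its occurrences.

    ``occurrences`` holds (1-based start, orientation) pairs, sorted by
    start; orientation is 'direct' or 'reverse-complement'.
    """

    motif: str
    occurrences: list[tuple[int, str]]
    palindromic: bool = False
    consecutive: bool = False

    @property
    def length(self) -> int:
        return len(self.motif)

    @property
    def count(self) -> int:
        return len(self.occurrences)


@dataclass
class QueryHit:
    """Occurrences of one query token (motif or enzyme name)."""

    query: str
    motif: str | None
    count: int
    locations: list[tuple[int, str]] = field(default_factory=list)
    error: str | None = None


def _all_matches(seq: str, motif: str) -> list[int]:
    """0-based start positions of all (overlapping) occurrences."""
    out = []
    start = seq.find(motif)
    while start != -1:
        out.append(start)
        start = seq.find(motif, start + 1)
    return out


def _occurrence_set(seq: str, motif: str) -> list[tuple[int, str]]:
    """All occurrences of motif or its reverse complement (0-based)."""
    rc = revcomp(motif)
    occs = [(p, DIRECT) for p in _all_matches(seq, motif)]
    if rc != motif:
        occs += [(p, REVCOMP) for p in _all_matches(seq, rc)]
    return sorted(occs)


def _extend_group(seq: str, motif: str, occs: list[tuple[int, str]]) -> tuple[str, list[tuple[int, str]]]:
    """Jointly extend a matched group to maximal length.

    A direct occurrence at p matches motif at seq[p : p+len]; a
    reverse-complement occurrence matches revcomp(motif) there, so growing
    the motif on the right grows the rc occurrence on its left, and vice
    versa. Extension proceeds while every occurrence agrees on the added
    base and no two coordinate systems collide with sequence ends.
    """
    L = len(seq)
    ell = len(motif)
    occ = list(occs)
    if len(occ) < 2:
        # a lone (palindromic) site has nothing to co-vary with; extending it
        # would trivially swallow the whole sequence
        return motif, sorted(occ)

    def try_extend(side: str):
        nonlocal motif, ell, occ
        while True:
            candidate = None
            new_occ = []
            ok = True
            for p, orient in occ:
                # growing the motif rightwards grows a direct occurrence on
                # its right and a reverse-complement occurrence on its left
                # in sequence coordinates (and vice versa for leftwards)
                if (side == "right") == (orient == DIRECT):
                    pos = p + ell
                else:
                    pos = p - 1
                if pos < 0 or pos >= L:
                    ok = False
                    break
                base = seq[pos]
                if orient == REVCOMP:
                    base = revcomp(base)
                if candidate is None:
                    candidate = base
                elif base != candidate:
                    ok = False
                    break
                new_occ.append((pos if pos == p - 1 else p, orient))
            if not ok:
                return
            motif = motif + candidate if side == "right" else candidate + motif
            ell += 1
            occ = new_occ

    try_extend("right")
    try_extend("left")
    return motif, sorted(occ)


def find_repeats(
    seq: NucSequence,
    min_len: int = 8,
    smart_filter: bool = True,
    *,
    min_len_floor: int = 4,
) -> list[RepeatFinding]:
    """Find direct, reverse-complement, palindromic and tandem repeats.

    Returns findings sorted by (first occurrence, -length, motif). With the
    smart filter on, findings wholly contained in a longer finding's
    occurrences are suppressed.
    """
    if min_len < min_len_floor:
        raise SearchError(f"min_len must be >= {min_len_floor}")
    s = seq.residues
    if len(s) < min_len:
        warnings.warn("sequence shorter than min_len: no repeats can be found")
        return []
    found: dict[tuple[str, tuple[tuple[int, str], ...]], RepeatFinding] = {}
    for i in range(len(s) - min_len + 1):
        seed = s[i : i + min_len]
        occs = _occurrence_set(s, seed)
        palindromic = seed == revcomp(seed)
        if len(occs) < 2 and not palindromic:
            continue
        motif, occ = _extend_group(s, seed, occs)
        palindromic = motif == revcomp(motif)
        if palindromic:
            # both orientations coincide on a palindrome: collapse to direct
            occ = sorted({(p, DIRECT) for p, _ in occ})
        key = (motif, tuple(occ))
        if key in found:
            continue
        starts = sorted(p for p, _ in occ)
        consecutive = any(
            b == a + len(motif) for a, b in zip(starts, starts[1:])
        )
        found[key] = RepeatFinding(
            motif=motif,
            occurrences=[(p + 1, o) for p, o in occ],  # report 1-based
            palindromic=palindromic,
            consecutive=consecutive,
        )
    findings = list(found.values())
    if smart_filter:
        findings = [
            f
            for f in findings
            if not any(_is_contained_1based(f, g) for g in findings if g is not f)
        ]
    findings.sort(key=lambda f: (f.occurrences[0][0], -f.length, f.motif))
    return findings


def _is_contained_1based(inner: RepeatFinding, outer: RepeatFinding) -> bool:
    if outer.length <= inner.length:
        return False
    outer_ivals = [(p, p + outer.length) for p, _ in outer.occurrences]
    return all(
        any(os <= p and p + inner.length <= oe for os, oe in outer_ivals)
        for p, _ in inner.occurrences
    )


# --- multi-query search -------------------------------------------------------

_MOTIF_RE = re.compile(r"^[ACGTUacgtu]+$")


def load_enzyme_table() -> dict[str, str]:
    """Packaged table of common restriction enzymes (name -> site)."""
    text = (
        resources.files("genedesign.data").joinpath("restriction_enzymes.tsv").read_text()
    )
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, site = line.split("\t")
        table[name.lower()] = site.upper()
    return table


def load_predefined_set(name: str) -> str:
    """Return a packaged query set as newline-delimited text.

    Known sets: common-restriction-sites (enzyme names), polyA-signals,
    cryptic-splice-sites (motifs).
    """
    if name not in PREDEFINED_SETS:
        raise SearchError(
            f"unknown predefined set {name!r}; available: {sorted(PREDEFINED_SETS)}"
        )
    text = resources.files("genedesign.data").joinpath(PREDEFINED_SETS[name]).read_text()
    tokens = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens.append(line.split("\t")[0])
    return "\n".join(tokens)


def split_queries(text: str) -> list[str]:
    """Split a query list on tab, comma, or newline."""
    tokens = re.split(r"[\t,\r\n]+", text)
    return [t.strip() for t in tokens if t.strip()]


def search_queries(
    seq: NucSequence,
    queries: str,
    both_strands: bool = False,
) -> list[QueryHit]:
    """Search every query token; enzyme names resolve to recognition motifs.

    One hit per token (zero counts included); an unknown enzyme name yields
    an error entry without aborting the other tokens. Overlapping
    occurrences are all counted; positions are 1-based starts on the given
    strand (reverse-complement matches report the match start on the input
    sequence, strand 'reverse-complement').
    """
    enzymes = load_enzyme_table()
    s = seq.residues
    hits: list[QueryHit] = []
    for token in split_queries(queries):
        if _MOTIF_RE.match(token):
            motif = token.upper().replace("U", "T")
        elif token.lower() in enzymes:
            motif = enzymes[token.lower()]
        else:
            hits.append(
                QueryHit(query=token, motif=None, count=0, error=f"unknown enzyme name {token!r}")
            )
            continue
        locations = [(p + 1, DIRECT) for p in _all_matches(s, motif)]
        if both_strands:
            rc = revcomp(motif)
            if rc != motif:
                locations += [(p + 1, REVCOMP) for p in _all_matches(s, rc)]
        locations.sort()
        hits.append(QueryHit(query=token, motif=motif, count=len(locations), locations=locations))
    return hits


def hits_to_tsv(hits: list[QueryHit], path=None) -> str:
    lines = ["query\tmotif\tcount\tpositions"]
    for h in hits:
        pos = ";".join(f"{p}{'+' if o == DIRECT else '-'}" for p, o in h.locations)
        lines.append(f"{h.query}\t{h.motif or ''}\t{h.count}\t{pos or h.error or ''}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
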