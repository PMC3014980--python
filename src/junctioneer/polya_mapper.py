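"""Mapping of 3' RACE reads to a reference 3' region and polyadenylation-site
tallying.

3' RACE clones are Sanger-quality sequences that end in an untemplated
poly(A) tail.  The pipeline is: trim the terminal A-run (allowing a small
error fraction), match the templated insert to the reference 3' UTR with a
strict no-indel tolerance, and report the cleavage position 1-based relative
to the first nucleotide after the stop codon (the convention used on
polyadenylation-profile figure axes).

When the reference continues with genomic A's past the last templated base,
the true cleavage position is ambiguous.  By default the most 3' consistent
position is reported (``a_ambiguity='max3'``, maximal templated extension),
which prevents genomic A-runs from inflating apparent site heterogeneity;
``'min5'`` reports the most 5' consistent position instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .locus_io import Feature, SequenceRecord, revcomp


@dataclass(frozen=True)
class RaceRead:
    """A 3' RACE read split into templated insert and untemplated tail."""

    id: str
    seq: str
    insert: str
    tail: str

    def __post_init__(self) -> None:
        if self.insert + self.tail != self.seq:
            raise ValueError("insert + tail must reconstruct the read")

    @property
    def tail_len(self) -> int:
        return len(self.tail)


@dataclass(frozen=True)
class PolyASite:
    pos_after_stop: int         # 1-based, relative to first nt after the stop codon
    count: int
    fraction: float             # percent of all accepted reads
    feature_overlap: str = "none"   # none | LTR | TE | other


@dataclass(frozen=True)
class PolyASiteTable:
    sites: tuple                # all sites, ascending position
    n_reads: int
    min_count: int
    overlap_summary: dict = field(default_factory=dict)

    @property
    def reported_sites(self) -> tuple:
        return tuple(s for s in self.sites if s.count >= self.min_count)

    @property
    def n_sites_reported(self) -> int:
        return len(self.reported_sites)

    @property
    def span(self) -> Optional[tuple]:
        rep = self.reported_sites
        if not rep:
            return None
        return (rep[0].pos_after_stop, rep[-1].pos_after_stop)

    def to_frame(self, reported_only: bool = True) -> pd.DataFrame:
        rows = self.reported_sites if reported_only else self.sites
        return pd.DataFrame(
            [
                {
                    "pos_after_stop": s.pos_after_stop,
                    "count": s.count,
                    "fraction_pct": s.fraction,
                    "feature_overlap": s.feature_overlap,
                }
                for s in rows
            ]
        )


# ---------------------------------------------------------------------------
# Tail trimming
# ---------------------------------------------------------------------------

def trim_tail(read_id: str, seq: str, min_tail: int = 8,
              max_mismatch_frac: float = 0.1) -> tuple[Optional[RaceRead], str]:
    """Identify and trim the longest untemplated 3' A-run of a read.

    All suffix cut points are enumerated; the longest suffix with at least
    ``min_tail`` bases, at most ``max_mismatch_frac`` non-A bases, and
    starting with an A is trimmed.  Returns (RaceRead, "") on acceptance or
    (None, reason) on rejection; rejection is a category, not an exception.
    """
    seq = seq.upper()
    if not seq:
        return None, "empty_read"
    is_a = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("A")
    non_a_from = np.cumsum(~is_a[::-1])[::-1]   # non-A count in seq[i:]
    n = len(seq)
    for i in range(n - min_tail + 1):
        tail_len = n - i
        if is_a[i] and non_a_from[i] <= max_mismatch_frac * tail_len:
            return RaceRead(read_id, seq, seq[:i], seq[i:]), ""
    return None, "no_polya_tail"


# ---------------------------------------------------------------------------
# Site assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteAssignment:
    read_id: str
    pos_after_stop: Optional[int]
    reason: str = ""            # non-empty when unmapped

    @property
    def mapped(self) -> bool:
        return self.pos_after_stop is not None


def _match_loci(insert: str, ref: str, allowed: int) -> list:
    """All (start, distance) best-scoring ungapped matches of insert in ref."""
    n, m = len(ref), len(insert)
    if m > n:
        return []
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    ins_arr = np.frombuffer(insert.encode(), dtype=np.uint8)
    best = allowed + 1
    loci = []
    # fast path: exact occurrences
    start = ref.find(insert)
    while start != -1:
        loci.append((start, 0))
        start = ref.find(insert, start + 1)
    if loci:
        return loci
    for start in range(n - m + 1):
        dist = int((ref_arr[start:start + m] != ins_arr).sum())
        if dist < best:
            best = dist
            loci = [(start, dist)]
        elif dist == best:
            loci.append((start, dist))
    return [(s, d) for s, d in loci if d <= allowed]


def assign_site(read: RaceRead, ref_3utr, stop_pos: int, strand: str = "+",
                a_ambiguity: str = "max3", min_insert: int = 20) -> SiteAssignment:
    """Assign a read's cleavage/polyadenylation position on the reference.

    The templated insert is matched ungapped with at most 1 mismatch per
    50 nt; the cleavage position is the last templated base, adjusted for
    templated-A ambiguity per ``a_ambiguity``, and reported 1-based relative
    to ``stop_pos`` (the 0-based index of the first base after the stop
    codon).  Ambiguous (multi-locus) or short inserts are returned unmapped
    with a reason.
    """
    ref = ref_3utr.seq if isinstance(ref_3utr, SequenceRecord) else str(ref_3utr).upper()
    if strand == "-":
        stop_pos = len(ref) - stop_pos
        ref = revcomp(ref)
    elif strand != "+":
        raise ValueError("strand must be '+' or '-'")
    insert = read.insert
    if len(insert) < min_insert:
        return SiteAssignment(read.id, None, "short_insert")
    loci = _match_loci(insert, ref, allowed=len(insert) // 50)
    if not loci:
        return SiteAssignment(read.id, None, "no_match")
    if len(loci) > 1:
        return SiteAssignment(read.id, None, "ambiguous")
    start, _ = loci[0]
    end = start + len(insert) - 1          # last templated base, 0-based
    if a_ambiguity == "max3":
        # maximal templated extension: walk the trimmed tail bases forward
        # while they match the reference in order.  Mismatch-tolerant tail
        # trimming can strip templated bases adjacent to the cleavage site
        # (an A-rich suffix with an embedded non-A); matching the actual
        # tail sequence, not just A's, re-assigns them as templated.
        for k in range(read.tail_len):
            if end + 1 < len(ref) and ref[end + 1] == read.tail[k]:
                end += 1
            else:
                break
    elif a_ambiguity == "min5":
        while end > start and ref[end] == "A":
            end -= 1
    else:
        raise ValueError("a_ambiguity must be 'max3' or 'min5'")
    pos = end - stop_pos + 1
    if pos < 1:
        return SiteAssignment(read.id, None, "upstream_of_stop")
    return SiteAssignment(read.id, pos)


# ---------------------------------------------------------------------------
# Tallying and feature overlap
# ---------------------------------------------------------------------------

def tally_sites(assignments: Iterable, min_count: int = 2) -> PolyASiteTable:
    """Per-position counts and fractions over all accepted (mapped) reads.

    Sites seen fewer than ``min_count`` times are suppressed from the
    reported list but remain in the totals, mirroring the convention of
    plotting polyadenylation sites only when they occur more than once.
    Fractions over all (unfiltered) sites sum to exactly 100.
    """
    positions = []
    for a in assignments:
        if isinstance(a, SiteAssignment):
            if a.mapped:
                positions.append(a.pos_after_stop)
        elif a is not None:
            positions.append(int(a))
    if not positions:
        raise ValueError("no accepted assignments to tally")
    total = len(positions)
    counts: dict = {}
    for p in positions:
        counts[p] = counts.get(p, 0) + 1
    sites = tuple(
        PolyASite(pos, c, 100.0 * c / total) for pos, c in sorted(counts.items())
    )
    return PolyASiteTable(sites=sites, n_reads=total, min_count=min_count)


_OVERLAP_PRIORITY = {"LTR": 0, "TE": 1, "TIR": 1, "repeat": 2, "other": 2}
_OVERLAP_LABEL = {"LTR": "LTR", "TE": "TE", "TIR": "TE", "repeat": "other",
                  "other": "other"}


def annotate_overlap(table: PolyASiteTable, features: Sequence[Feature],
                     stop_pos: int) -> PolyASiteTable:
    """Label each site with the feature class containing it (LTR > TE > other)
    and attach a per-class summary of event fractions.

    A site at ``pos_after_stop`` p corresponds to reference position
    ``stop_pos + p - 1`` (0-based); containment is start <= coord < end.
    """
    labeled = []
    for site in table.sites:
        coord = stop_pos + site.pos_after_stop - 1
        containing = [
            f for f in features
            if f.start <= coord < f.end and f.type in _OVERLAP_PRIORITY
        ]
        if containing:
            containing.sort(key=lambda f: _OVERLAP_PRIORITY[f.type])
            label = _OVERLAP_LABEL[containing[0].type]
        else:
            label = "none"
        labeled.append(replace(site, feature_overlap=label))
    summary: dict = {}
    for site in labeled:
        summary[site.feature_overlap] = summary.get(site.feature_overlap, 0.0) \
            + site.fraction
    return PolyASiteTable(
        sites=tuple(labeled),
        n_reads=table.n_reads,
        min_count=table.min_count,
        overlap_summary=summary,
    )


def map_reads(raw_reads: Iterable[tuple], ref_3utr, stop_pos: int,
              min_tail: int = 8, max_mismatch_frac: float = 0.1,
              min_count: int = 2, a_ambiguity: str = "max3"):
    """End-to-end convenience: trim, assign and tally a set of (id, seq) reads.

    Returns (PolyASiteTable, rejected) where rejected maps read id -> reason.
    """
    rejected: dict = {}
    assignments = []
    for read_id, seq in raw_reads:
        race, reason = trim_tail(read_id, seq, min_tail, max_mismatch_frac)
        if race is None:
            rejected[read_id] = reason
            continue
        assignment = assign_site(race, ref_3utr, stop_pos, a_ambiguity=a_ambiguity)
        if assignment.mapped:
            assignments.append(assignment)
        else:
            rejected[read_id] = assignment.reason
    table = tally_sites(assignments, min_count=min_count)
    return table, rejected
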