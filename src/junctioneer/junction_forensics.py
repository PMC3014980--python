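"""Mechanistic classification of rearrangement junctions.

Given an alignment between a reference allele and a derived allele, gaps are
turned into :class:`Junction` objects and classified into the event taxonomy
of tandem-locus evolution:

* ``te_insertion`` — an insertion matching a user-supplied transposable-
  element library, flanked by a target-site duplication (TSD);
* ``nhej_filler`` — a deletion scar whose short insertion decomposes into
  filler fragments copied (either strand) from within a window of the break
  ends, the hallmark of non-homologous end-joining;
* ``tandem_duplication`` — an insertion that is a near-identical copy of the
  adjacent reference sequence, as produced by unequal crossover at a short
  exact anchor;
* ``uxo_deletion`` — a clean deletion whose endpoints fall in a shared
  (micro)homology or long flanking repeat, consistent with unequal
  crossover / single-strand annealing;
* ``unclassified`` — anything else (a valid outcome).

All detectors are deterministic, and exact-match searches treat any window
containing ``N`` as never matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import edlib
import numpy as np

from .locus_io import SequenceRecord, revcomp
from .pairwise_compare import AlignmentResult


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Junction:
    """A localized difference between a reference and a derived sequence."""

    ref_id: str
    alt_id: str
    ref_del: tuple              # (start, end) on ref; start == end when empty
    alt_ins: str                # inserted sequence on alt ("" when empty)
    alt_pos: int                # position on alt where the insertion begins
    left_flank: str             # ref context 5' of the junction
    right_flank: str            # ref context 3' of the junction
    alt_left_flank: str = ""
    alt_right_flank: str = ""
    ref_del_seq: str = ""       # the deleted reference sequence itself

    def __post_init__(self) -> None:
        if self.ref_del[1] == self.ref_del[0] and not self.alt_ins:
            raise ValueError("junction must have a deletion or an insertion")

    @property
    def del_len(self) -> int:
        return self.ref_del[1] - self.ref_del[0]


@dataclass(frozen=True)
class TsdCall:
    tsd_seq: str
    tsd_len: int
    element_interval: tuple
    element_id: Optional[str] = None


@dataclass(frozen=True)
class FillerFragment:
    frag_seq: str               # as it appears in the insertion
    frag_len: int
    donor_side: str             # 'upstream' | 'downstream' of the deletion
    donor_offset: int           # bp from the nearer deletion endpoint
    donor_strand: str           # '+' | '-'
    start_in_insert: int = 0


@dataclass(frozen=True)
class FillerDecomposition:
    fragments: tuple
    remainder: tuple            # ((start_in_insert, seq), ...) unexplained pieces
    insert_len: int

    @property
    def explained_fraction(self) -> float:
        if self.insert_len == 0:
            return 1.0
        return sum(f.frag_len for f in self.fragments) / self.insert_len

    def reconstruct(self) -> str:
        pieces = [(f.start_in_insert, f.frag_seq) for f in self.fragments]
        pieces += [(s, seq) for s, seq in self.remainder]
        return "".join(seq for _, seq in sorted(pieces))


@dataclass(frozen=True)
class TandemDupCall:
    period: int
    n_copies: int
    unit_interval: tuple
    copy_identity_pct: float
    anchor_seq: str
    anchor_len: int


@dataclass(frozen=True)
class FlankingRepeatCall:
    repeat_seq_len: int
    left_interval: tuple
    right_interval: tuple
    identity_pct: float


@dataclass(frozen=True)
class EventCall:
    kind: str                   # te_insertion | nhej_filler | tandem_duplication |
                                # uxo_deletion | recombination | unclassified
    junction: Junction
    confidence: str = "weak"    # strong | weak
    tsd: Optional[TsdCall] = None
    filler: Optional[FillerDecomposition] = None
    tandem_dup: Optional[TandemDupCall] = None
    flanking_repeat: Optional[FlankingRepeatCall] = None
    te_id: Optional[str] = None
    notes: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ClassifyParams:
    window: int = 100           # filler donor search window W
    min_frag: int = 4           # smallest attributable filler fragment
    max_tsd: int = 20
    min_tsd: int = 2
    min_copy_identity: float = 98.0
    flank_repeat_min_len: int = 50
    flank_repeat_min_identity: float = 95.0
    uxo_min_anchor: int = 4
    te_min_identity: float = 80.0
    te_min_coverage: float = 0.8
    filler_min_explained: float = 0.5
    min_sv_len: int = 5
    merge_dist: int = 10


# ---------------------------------------------------------------------------
# Junction calling from an alignment
# ---------------------------------------------------------------------------

def call_junctions(result: AlignmentResult, min_sv_len: int = 5,
                   flank_w: int = 100, merge_dist: int = 10) -> list[Junction]:
    """Convert alignment gaps >= ``min_sv_len`` into Junction objects.

    Gap runs separated by fewer than ``merge_dist`` matched bases are merged
    into one variant region, and region boundaries are re-derived by maximal
    exact flank extension.  Affine DP can legally shuffle a short insertion
    against deleted reference bases; maximal-flank normalization restores the
    canonical junction placement that mechanistic interpretation relies on.
    """
    if result.unalignable:
        return []
    ref, alt = result.a, result.b
    anchors = [s for s in result.segments if s[1] - s[0] >= merge_dist]
    virtual = [(0, 0, 0, 0)] + anchors + \
        [(len(ref), len(ref), len(alt), len(alt))]
    junctions = []
    for left, right in zip(virtual, virtual[1:]):
        la0, la1, lb0, lb1 = left
        ra0, ra1, rb0, rb1 = right
        if la1 == ra0 and lb1 == rb0:
            continue            # anchors are contiguous: no variant region
        # re-derive boundaries by maximal exact prefix/suffix matching over
        # the span between the flanking anchors' midpoints.  Affine DP
        # prefers aligning insert bases against deleted reference
        # (mismatches are cheaper than longer gaps) and can absorb junction
        # bases into the anchor blocks; exact matching from well inside the
        # anchors restores the canonical (maximal-flank, 5'-preferring)
        # junction placement.
        j = _normalized_junction(
            result,
            (la0 + la1) // 2, (ra0 + ra1) // 2,
            (lb0 + lb1) // 2, (rb0 + rb1) // 2,
            flank_w,
        )
        if j is not None and max(j.del_len, len(j.alt_ins)) >= min_sv_len:
            junctions.append(j)
    return junctions


def _normalized_junction(result: AlignmentResult, ra0, ra1, rb0, rb1,
                         flank_w) -> Optional[Junction]:
    ref, alt = result.a, result.b
    # maximal exact prefix extension into the region
    while ra0 < ra1 and rb0 < rb1 and ref[ra0] == alt[rb0]:
        ra0 += 1
        rb0 += 1
    # maximal exact suffix extension
    while ra1 > ra0 and rb1 > rb0 and ref[ra1 - 1] == alt[rb1 - 1]:
        ra1 -= 1
        rb1 -= 1
    if ra1 == ra0 and rb1 == rb0:
        return None
    return Junction(
        ref_id=result.a_id,
        alt_id=result.b_id,
        ref_del=(ra0, ra1),
        alt_ins=alt[rb0:rb1],
        alt_pos=rb0,
        left_flank=ref[max(0, ra0 - flank_w):ra0],
        right_flank=ref[ra1:ra1 + flank_w],
        alt_left_flank=alt[max(0, rb0 - flank_w):rb0],
        alt_right_flank=alt[rb1:rb1 + flank_w],
        ref_del_seq=ref[ra0:ra1],
    )


# ---------------------------------------------------------------------------
# Target-site duplications
# ---------------------------------------------------------------------------

def _clean_eq(x: str, y: str) -> bool:
    return x == y and len(x) > 0 and "N" not in x


def detect_tsd(seq, element_interval: tuple, max_tsd: int = 20,
               min_tsd: int = 2) -> Optional[TsdCall]:
    """Longest exact direct repeat abutting both ends of an element.

    Returns the maximal TSD of ``min_tsd``..``max_tsd`` bp (extending the
    reported repeat by one base on either side breaks the duplication), or
    None when no abutting repeat of at least ``min_tsd`` bp exists.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else str(seq).upper()
    start, end = element_interval
    if not (0 <= start <= end <= len(s)):
        raise ValueError(f"element interval {element_interval} out of range")
    if max_tsd < min_tsd:
        raise ValueError("max_tsd must be >= min_tsd")
    limit = min(max_tsd, start, len(s) - end)
    for t in range(limit, min_tsd - 1, -1):
        if _clean_eq(s[start - t:start], s[end:end + t]):
            return TsdCall(s[start - t:start], t, (start, end))
    return None


def junction_tsd(j: Junction, max_tsd: int = 20,
                 min_tsd: int = 2) -> Optional[tuple]:
    """TSD evidence at an insertion junction.

    A TE insertion with a TSD leaves, after maximal-flank junction
    normalization, an insertion that either ends with a copy of the bases
    immediately 5' of it, or begins with a copy of the bases immediately 3'
    of it (the duplicated target site).  Returns (TsdCall, element_seq) with
    element coordinates relative to the insertion, or None.
    """
    ins = j.alt_ins
    if not ins:
        return None
    limit = min(max_tsd, len(ins) - 1)
    for t in range(limit, min_tsd - 1, -1):
        if len(j.alt_left_flank) >= t and _clean_eq(ins[-t:], j.alt_left_flank[-t:]):
            return TsdCall(ins[-t:], t, (0, len(ins) - t)), ins[:-t]
        if len(j.alt_right_flank) >= t and _clean_eq(ins[:t], j.alt_right_flank[:t]):
            return TsdCall(ins[:t], t, (t, len(ins))), ins[t:]
    return None


# ---------------------------------------------------------------------------
# NHEJ filler decomposition
# ---------------------------------------------------------------------------

def _window_occurrences(frag: str, window: str, side: str) -> list:
    """All (offset, strand) occurrences of frag in a donor window.

    Offsets measure the distance between the deletion endpoint and the nearer
    edge of the donor occurrence: for the downstream window (which begins at
    the deletion endpoint) the offset is the occurrence start; for the
    upstream window (which ends at the deletion endpoint) it is the distance
    from the occurrence end to the window end.
    """
    hits = []
    if "N" in frag:
        return hits
    for strand, needle in (("+", frag), ("-", revcomp(frag))):
        start = window.find(needle)
        while start != -1:
            if "N" not in window[start:start + len(needle)]:
                if side == "downstream":
                    offset = start
                else:
                    offset = len(window) - (start + len(needle))
                hits.append((offset, side, strand))
            start = window.find(needle, start + 1)
    return hits


def decompose_filler(j: Junction, window: int = 100,
                     min_frag: int = 4) -> FillerDecomposition:
    """Greedy left-to-right decomposition of an insertion into filler DNA.

    Each fragment is the maximal prefix of the remaining insertion found
    exactly (either strand) within ``window`` bp of either deletion endpoint.
    Donor ties break to the nearest occurrence, then downstream over
    upstream, then + strand.  Stretches shorter than ``min_frag`` remain as
    unexplained remainder.  The strand-adjusted concatenation of fragments
    plus remainder reconstructs the insertion character-for-character.
    """
    ins = j.alt_ins
    if not ins:
        raise ValueError("junction has no insertion to decompose")
    up = j.left_flank[-window:] if window else ""
    down = j.right_flank[:window] if window else ""
    fragments: list[FillerFragment] = []
    remainder: list[tuple] = []
    i = 0
    rem_start = None
    while i < len(ins):
        best = None
        for length in range(len(ins) - i, min_frag - 1, -1):
            frag = ins[i:i + length]
            hits = _window_occurrences(frag, down, "downstream") + \
                _window_occurrences(frag, up, "upstream")
            if hits:
                # nearest occurrence; ties: downstream over upstream, then +
                hits.sort(key=lambda h: (h[0], h[1] != "downstream", h[2] != "+"))
                best = (length, hits[0])
                break
        if best is None:
            if rem_start is None:
                rem_start = i
            i += 1
            continue
        if rem_start is not None:
            remainder.append((rem_start, ins[rem_start:i]))
            rem_start = None
        length, (offset, side, strand) = best
        fragments.append(
            FillerFragment(ins[i:i + length], length, side, offset, strand, i)
        )
        i += length
    if rem_start is not None:
        remainder.append((rem_start, ins[rem_start:]))
    return FillerDecomposition(tuple(fragments), tuple(remainder), len(ins))


# ---------------------------------------------------------------------------
# Tandem duplications
# ---------------------------------------------------------------------------

def _byte_view(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8)


def _candidate_periods(s: str, min_period: int, k: int = 16) -> list:
    """Candidate array periods from distances between repeated k-mers."""
    from collections import defaultdict
    positions: dict = defaultdict(list)
    for i in range(len(s) - k + 1):
        km = s[i:i + k]
        if "N" not in km:
            positions[km].append(i)
    votes: dict = defaultdict(int)
    for pos in positions.values():
        for a, b in zip(pos, pos[1:]):
            d = b - a
            if d >= min_period:
                votes[d] += 1
    return sorted(votes, key=lambda d: (-votes[d], d))


def _solid_runs(m: np.ndarray, max_gap: int, min_core: int = 16) -> list:
    """Maximal match runs whose ends are solid.

    Exact runs of consecutive True shorter than ``min_core`` are chance
    matches at random-sequence identity (p = 4^-16 per position for a core);
    runs are seeded by cores and bridged across interruptions up to
    ``max_gap``, so array boundaries are defined by exact homology, not by
    chance matches glued to the edges.
    """
    if not m.any():
        return []
    idx = np.flatnonzero(m)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    exact = [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]
    cores = [(s, e) for s, e in exact if e - s >= min_core]
    if not cores:
        return []
    runs = [list(cores[0])]
    for s, e in cores[1:]:
        if s - runs[-1][1] <= max_gap:
            runs[-1][1] = e
        else:
            runs.append([s, e])
    return [tuple(r) for r in runs]


def detect_tandem_duplication(seq, min_period: int = 50,
                              min_copy_identity: float = 98.0,
                              max_gap: int = 50) -> list[TandemDupCall]:
    """All maximal tandem arrays with period >= min_period.

    For each candidate period p (from repeated 16-mer spacings) the boolean
    profile m[i] = (seq[i] == seq[i+p]) is scanned for maximal runs (single
    mismatches bridged up to ``max_gap``) of length >= p whose identity meets
    the threshold.  The reported anchor is the maximal exact duplication
    boundary: the run extends past the last full copy by exactly the length
    of the homology shared between the array start and the inter-copy
    junction, so ``anchor_len = run_len - (n_copies - 1) * period``.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else str(seq).upper()
    n = len(s)
    if n < 2 * min_period:
        return []
    x = _byte_view(s)
    n_mask = x == ord("N")
    calls: list[TandemDupCall] = []
    for p in _candidate_periods(s, min_period):
        if p > n // 2:
            continue
        m = (x[:-p] == x[p:]) & ~n_mask[:-p] & ~n_mask[p:]
        for start, end in _solid_runs(m, max_gap):
            run_len = end - start
            # edge SNPs can trim the solid run by up to a core length per side
            if run_len < p - 32:
                continue
            identity = 100.0 * float(m[start:end].mean())
            if identity < min_copy_identity:
                continue
            n_copies = int(round(run_len / p)) + 1
            anchor_len = max(0, run_len - (n_copies - 1) * p)
            anchor_seq = s[start:start + anchor_len] if anchor_len else ""
            calls.append(
                TandemDupCall(
                    period=p,
                    n_copies=n_copies,
                    unit_interval=(start, start + p),
                    copy_identity_pct=identity,
                    anchor_seq=anchor_seq,
                    anchor_len=anchor_len,
                )
            )
    return _fundamental_arrays(calls)


def _fundamental_arrays(calls: list) -> list:
    """Drop harmonic calls: keep the smallest period among overlapping arrays."""
    calls = sorted(calls, key=lambda c: (c.unit_interval[0], c.period))
    kept: list[TandemDupCall] = []
    for call in calls:
        s0 = call.unit_interval[0]
        e0 = s0 + call.period * (call.n_copies - 1) + call.anchor_len
        redundant = False
        for other in kept:
            s1 = other.unit_interval[0]
            e1 = s1 + other.period * (other.n_copies - 1) + other.anchor_len
            overlap = min(e0, e1) - max(s0, s1)
            if overlap > 0.5 * (e0 - s0) and other.period <= call.period:
                redundant = True
                break
        if not redundant:
            kept.append(call)
    return kept


# ---------------------------------------------------------------------------
# Flanking repeats
# ---------------------------------------------------------------------------

def detect_flanking_repeats(seq, insert_interval: tuple, min_len: int = 50,
                            min_identity: float = 95.0) -> Optional[FlankingRepeatCall]:
    """Longest near-exact direct repeat pair immediately bracketing an insertion."""
    s = seq.seq if isinstance(seq, SequenceRecord) else str(seq).upper()
    start, end = insert_interval
    if not (0 <= start <= end <= len(s)):
        raise ValueError(f"insert interval {insert_interval} out of range")
    limit = min(start, len(s) - end)
    for length in range(limit, min_len - 1, -1):
        left = _byte_view(s[start - length:start])
        right = _byte_view(s[end:end + length])
        clean = (left != ord("N")) & (right != ord("N"))
        if not clean.all():
            continue
        identity = 100.0 * float((left == right).mean())
        if identity >= min_identity:
            return FlankingRepeatCall(
                repeat_seq_len=length,
                left_interval=(start - length, start),
                right_interval=(end, end + length),
                identity_pct=identity,
            )
    return None


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _te_library_match(element: str, te_library, params: ClassifyParams):
    """Best TE-library entry matching the element on either strand."""
    if not element or not te_library:
        return None
    best = None
    for entry in te_library:
        if len(element) < params.te_min_coverage * len(entry.seq):
            continue
        for strand, query in (("+", element), ("-", revcomp(element))):
            res = edlib.align(query, entry.seq, mode="HW", task="distance")
            identity = 100.0 * (1.0 - res["editDistance"] / max(len(query), 1))
            if identity >= params.te_min_identity:
                if best is None or identity > best[1]:
                    best = (entry.id, identity, strand)
    return best


def _adjacent_identity(j: Junction, side: str,
                       ref_seq: Optional[str] = None) -> float:
    """Identity of the insertion vs the same-length adjacent reference window."""
    ins = j.alt_ins
    if ref_seq is not None:
        d0, d1 = j.ref_del
        ref_win = (ref_seq[max(0, d0 - len(ins)):d0] if side == "left"
                   else ref_seq[d1:d1 + len(ins)])
    else:
        ref_win = (j.left_flank[-len(ins):] if side == "left"
                   else j.right_flank[:len(ins)])
    if len(ref_win) < len(ins) or not ins:
        return 0.0
    res = edlib.align(ins, ref_win, mode="NW", task="distance")
    return 100.0 * (1.0 - res["editDistance"] / len(ins))


def classify_event(j: Junction, te_library=None,
                   params: Optional[ClassifyParams] = None,
                   ref_seq: Optional[str] = None) -> EventCall:
    """Deterministic precedence classification of a junction.

    Precedence: (1) te_insertion when the insertion matches a TE-library
    entry and a TSD exists; (2) tandem_duplication when the insertion is a
    near-identical copy of adjacent reference; (3) nhej_filler when a
    deletion's insertion is at least half explained by filler fragments;
    (4) uxo_deletion when a clean deletion's endpoints share homology;
    otherwise unclassified.  Confidence is strong when the decisive evidence
    exceeds its threshold by at least twofold.
    """
    params = params or ClassifyParams()
    ins = j.alt_ins

    # (1) TE insertion with TSD
    tsd_hit = junction_tsd(j, params.max_tsd, params.min_tsd)
    if ins and tsd_hit and te_library:
        tsd, element = tsd_hit
        te = _te_library_match(element, te_library, params)
        if te is not None:
            te_id, identity, strand = te
            strong = identity >= (100 + params.te_min_identity) / 2 \
                and tsd.tsd_len >= 2 * params.min_tsd
            return EventCall(
                "te_insertion", j,
                confidence="strong" if strong else "weak",
                tsd=TsdCall(tsd.tsd_seq, tsd.tsd_len, tsd.element_interval, te_id),
                te_id=te_id,
                notes={"te_identity_pct": identity, "te_strand": strand},
            )

    # (2) tandem duplication: insertion copies adjacent reference
    if ins:
        ident = max(_adjacent_identity(j, "left", ref_seq),
                    _adjacent_identity(j, "right", ref_seq))
        if ident >= params.min_copy_identity and len(ins) >= params.min_sv_len:
            dup = _junction_dup_call(j, ident)
            strong = ident >= 100 - (100 - params.min_copy_identity) / 2
            return EventCall(
                "tandem_duplication", j,
                confidence="strong" if strong else "weak",
                tandem_dup=dup,
            )

    # (3) NHEJ with filler DNA
    if j.del_len > 0 and ins:
        decomp = decompose_filler(j, params.window, params.min_frag)
        if decomp.explained_fraction >= params.filler_min_explained:
            repeat = None
            if ref_seq is not None:
                repeat = detect_flanking_repeats(
                    ref_seq, j.ref_del, params.flank_repeat_min_len,
                    params.flank_repeat_min_identity,
                )
            strong = decomp.explained_fraction >= min(
                1.0, 2 * params.filler_min_explained
            )
            return EventCall(
                "nhej_filler", j,
                confidence="strong" if strong else "weak",
                filler=decomp,
                flanking_repeat=repeat,
            )

    # (4) unequal-crossover deletion: clean deletion anchored in shared repeat
    if j.del_len > 0 and not ins:
        anchor = _deletion_anchor(j)
        repeat = None
        if ref_seq is not None:
            repeat = detect_flanking_repeats(
                ref_seq, j.ref_del, params.flank_repeat_min_len,
                params.flank_repeat_min_identity,
            )
        if anchor >= params.uxo_min_anchor or repeat is not None:
            strong = anchor >= 2 * params.uxo_min_anchor or repeat is not None
            return EventCall(
                "uxo_deletion", j,
                confidence="strong" if strong else "weak",
                flanking_repeat=repeat,
                notes={"endpoint_anchor_len": anchor},
            )

    return EventCall("unclassified", j)


def _deletion_anchor(j: Junction) -> int:
    """Maximal exact homology shared by the two deletion endpoints.

    Unequal crossover (or single-strand annealing) at an exact anchor of
    length t collapses two anchor copies into one, so the retained left
    flank's suffix equals the deleted sequence's suffix (ref[d0-t:d0] ==
    ref[d1-t:d1]), and symmetrically the retained right flank's prefix
    equals the deleted sequence's prefix.  Returns the larger of the two.
    """
    deleted = j.ref_del_seq
    suffix = 0
    left = j.left_flank
    while suffix < min(len(left), len(deleted)) \
            and left[-1 - suffix] == deleted[-1 - suffix] \
            and deleted[-1 - suffix] != "N":
        suffix += 1
    prefix = 0
    right = j.right_flank
    while prefix < min(len(right), len(deleted)) \
            and right[prefix] == deleted[prefix] and deleted[prefix] != "N":
        prefix += 1
    return max(suffix, prefix)


def _junction_dup_call(j: Junction, identity: float) -> TandemDupCall:
    ins = j.alt_ins
    p = len(ins)
    fwd = 0
    while fwd < min(p, len(j.alt_right_flank)) and ins[fwd] == j.alt_right_flank[fwd]:
        fwd += 1
    bwd = 0
    while bwd < min(p, len(j.alt_left_flank)) \
            and ins[-1 - bwd] == j.alt_left_flank[-1 - bwd]:
        bwd += 1
    anchor_len = min(fwd + bwd, p)
    return TandemDupCall(
        period=p,
        n_copies=2,
        unit_interval=(j.alt_pos, j.alt_pos + p),
        copy_identity_pct=identity,
        anchor_seq=ins[:fwd] if fwd else "",
        anchor_len=anchor_len,
    )
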