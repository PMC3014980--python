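"""Seeded generators for canonical junction architectures.

These build, from scratch, synthetic loci carrying the classic rearrangement
architectures of tandem-array evolution: an NHEJ deletion scar inside a
tandem array (element excision, exonucleolytic resection, single filler
fragment, flanking direct repeats left by a less-than-one-unit deletion),
a two-fragment filler junction with donors on both sides of the break, and
a tandem duplication generated by unequal crossover at a short exact anchor.

Each builder asserts the uniqueness constraints the architecture requires
(e.g. no spurious donor occurrence nearer than the planted one) and
resamples from its seeded stream until they hold, so the expected detector
output is exact by construction and the builders are deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .locus_io import SequenceRecord, revcomp
from .synthetic_locus import (FillerSpec, SimConfig, apply_excision_nhej,
                              apply_te_insertion, random_seq)


@dataclass(frozen=True)
class ScarFixture:
    """An NHEJ deletion scar in a tandem array, with exact expectations."""

    ref: SequenceRecord
    alt: SequenceRecord
    deletion: tuple            # on ref
    filler_seq: str
    donor_offset: int
    donor_side: str
    flanking_repeat_len: int


def _occurrences(needle: str, haystack: str) -> list:
    out = []
    start = haystack.find(needle)
    while start != -1:
        out.append(start)
        start = haystack.find(needle, start + 1)
    return out


def _window_hits(frag: str, up: str, down: str) -> list:
    """(offset, side, strand) occurrences with decompose_filler geometry."""
    hits = []
    for strand, needle in (("+", frag), ("-", revcomp(frag))):
        for p in _occurrences(needle, down):
            hits.append((p, "downstream", strand))
        for p in _occurrences(needle, up):
            hits.append((len(up) - (p + len(needle)), "upstream", strand))
    return hits


def nhej_scar_in_array(seed: int = 0, period: int = 1500, repeat_len: int = 203,
                       filler: str = "AACCTATGT", donor_offset: int = 27,
                       window: int = 100) -> ScarFixture:
    """A mobile element inserted into one unit of a two-copy tandem array is
    abortively excised; resection removes almost a full unit and NHEJ closes
    the break with one short filler fragment copied from just downstream of
    the deletion endpoint.

    Because the deletion spans ``period - repeat_len`` bases of a tandem
    array, the filler insertion ends up bracketed by exact direct repeats of
    ``repeat_len`` bp.  Expected calls: one nhej_filler event, filler length
    ``len(filler)``, donor offset ``donor_offset`` downstream, flanking
    repeats of exactly ``repeat_len`` bp.
    """
    rng = np.random.default_rng(seed)
    flank = 800
    a_phase = 600                       # deletion start phase within the unit
    del_len = period - repeat_len
    end_phase = (a_phase + del_len) % period
    donor_phase = end_phase + donor_offset
    for _ in range(200):
        unit = list(random_seq(rng, period))
        unit[donor_phase:donor_phase + len(filler)] = filler
        # junction boundaries must not extend by chance
        if unit[a_phase] == filler[0]:
            unit[a_phase] = "G" if filler[0] != "G" else "C"
        if unit[end_phase - 1] == filler[-1]:
            unit[end_phase - 1] = "G" if filler[-1] != "G" else "C"
        # greedy decomposition must stop exactly at the filler end
        if unit[donor_phase + len(filler)] == unit[end_phase]:
            unit[donor_phase + len(filler)] = \
                "G" if unit[end_phase] != "G" else "C"
        unit = "".join(unit)
        ref_seq = random_seq(rng, flank) + unit * 2 + random_seq(rng, flank)
        d0 = flank + a_phase
        d1 = d0 + del_len
        up_win = ref_seq[d0 - window:d0]
        down_win = ref_seq[d1:d1 + window]
        hits = _window_hits(filler, up_win, down_win)
        if hits != [(donor_offset, "downstream", "+")]:
            continue

        # narrate the event through the simulator: insert, excise, repair
        element = random_seq(rng, 1200)
        m0 = d0 + 150                   # element insertion point on ref
        intermediate, _ = apply_te_insertion(ref_seq, element, m0, 0)
        cfg = SimConfig(seed=seed, filler_window=window)
        alt_seq, rec = apply_excision_nhej(
            intermediate, (m0, m0 + len(element)), cfg, rng,
            fillers=[FillerSpec("downstream", donor_offset, len(filler), "+")],
            resection=(m0 - d0, d1 - m0),
        )
        assert rec.payload["insert"] == filler
        assert alt_seq == ref_seq[:d0] + filler + ref_seq[d1:]
        return ScarFixture(
            ref=SequenceRecord("array_allele", ref_seq),
            alt=SequenceRecord("scarred_allele", alt_seq),
            deletion=(d0, d1),
            filler_seq=filler,
            donor_offset=donor_offset,
            donor_side="downstream",
            flanking_repeat_len=repeat_len,
        )
    raise RuntimeError("could not satisfy fixture constraints")


@dataclass(frozen=True)
class TwoFragmentFixture:
    ref: SequenceRecord
    alt: SequenceRecord
    deletion: tuple
    insert: str
    expected_fragments: tuple   # ((seq, side, offset, strand), ...)


def two_fragment_filler(seed: int = 0, del_len: int = 1410,
                        frag_down: str = "ATAATTGGG", down_offset: int = 59,
                        frag_up: str = "TCAC", up_offset: int = 21,
                        window: int = 100) -> TwoFragmentFixture:
    """A deletion repaired by NHEJ with two filler fragments: a 9-mer copied
    from downstream of the break and an adjacent 4-mer copied from upstream.

    The short upstream fragment occurs frequently by chance, so the builder
    enforces that the planted occurrence is the nearest one in either donor
    window; expected decomposition is then exact.
    """
    rng = np.random.default_rng(seed)
    insert = frag_down + frag_up
    for _ in range(2000):
        left = random_seq(rng, 600)
        deleted = random_seq(rng, del_len)
        right = random_seq(rng, 600)
        ref_seq = left + deleted + right
        d0, d1 = len(left), len(left) + del_len
        ref_seq = (ref_seq[:d0 - up_offset - len(frag_up)] + frag_up
                   + ref_seq[d0 - up_offset:])
        ref_seq = (ref_seq[:d1 + down_offset] + frag_down
                   + ref_seq[d1 + down_offset + len(frag_down):])
        if ref_seq[d0] == insert[0] or ref_seq[d1 - 1] == insert[-1]:
            continue
        up_win = ref_seq[d0 - window:d0]
        down_win = ref_seq[d1:d1 + window]
        # greedy must stop after frag_down: donor continuation must differ
        if down_win[down_offset + len(frag_down)] == frag_up[0]:
            continue
        down_hits = _window_hits(frag_down, up_win, down_win)
        if down_hits != [(down_offset, "downstream", "+")]:
            continue
        up_hits = sorted(_window_hits(frag_up, up_win, down_win))
        if not up_hits or up_hits[0] != (up_offset, "upstream", "+"):
            continue
        if len(up_hits) > 1 and up_hits[1][0] == up_offset:
            continue
        # no longer prefix of the insert may match anywhere in the windows
        if _window_hits(insert[:len(frag_down) + 1], up_win, down_win):
            continue
        alt_seq = ref_seq[:d0] + insert + ref_seq[d1:]
        return TwoFragmentFixture(
            ref=SequenceRecord("pre_deletion_allele", ref_seq),
            alt=SequenceRecord("repaired_allele", alt_seq),
            deletion=(d0, d1),
            insert=insert,
            expected_fragments=(
                (frag_down, "downstream", down_offset, "+"),
                (frag_up, "upstream", up_offset, "+"),
            ),
        )
    raise RuntimeError("could not satisfy fixture constraints")


@dataclass(frozen=True)
class AnchoredDupFixture:
    seq: SequenceRecord
    period: int
    anchor_seq: str
    array_start: int


def anchored_tandem_duplication(seed: int = 0, period: int = 1269,
                                anchor: str = "TCGATGCC") -> AnchoredDupFixture:
    """The product of unequal crossover at a short exact anchor: an ancestor
    carrying the anchor at two sites ``period`` bp apart is recombined with
    itself, duplicating the intervening sequence in tandem.

    The product is U + (anchor+X) + (anchor+X) + anchor + Y; the detector
    must report the period and recover the anchor length exactly because the
    homology run at the copy distance extends past the last full copy by
    precisely the anchor length.
    """
    rng = np.random.default_rng(seed)
    x_len = period - len(anchor)
    for _ in range(200):
        x = random_seq(rng, x_len)
        y = random_seq(rng, 600)
        u = random_seq(rng, 600)
        if anchor in x or anchor in y[:50] or anchor in u[-50:]:
            continue
        if x[0] == y[0] or u[-1] == x[-1]:
            continue
        unit = anchor + x
        product = u + unit + unit + anchor + y
        return AnchoredDupFixture(
            seq=SequenceRecord("uxo_product", product),
            period=period,
            anchor_seq=anchor,
            array_start=len(u),
        )
    raise RuntimeError("could not satisfy fixture constraints")
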