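"""Detector round-trip evaluation against the simulator truth log.

Each harness generates many independent single-event loci (one event per
small carrier sequence, a few kb each, so hundreds of replicates run in
seconds), runs the corresponding detector, and scores recovery against the
logged truth:

* TSD length — exact recovery of the planted target-site duplication length
  at clean settings (insertion sites whose flanking context cannot extend
  the duplication by chance are part of the clean-settings definition);
* tandem duplication — exact period recovery;
* filler attribution — a truth fragment counts as attributed when a called
  fragment identifies the same donor locus (same side and strand, donor
  genomic intervals overlapping by at least half).  Junction placement is
  ambiguous up to shared edge bases, so locus identity, not raw offset
  equality, is the meaningful notion of recovery;
* breakpoint containment — the bracketing interval contains the true
  crossover position.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .junction_forensics import (Junction, decompose_filler,
                                 detect_tandem_duplication, detect_tsd)
from .pairwise_compare import breakpoint_interval
from .pipeline import analyze_pair
from .polya_mapper import map_reads
from .synthetic_locus import (SimConfig, apply_excision_nhej,
                              apply_tandem_duplication, apply_te_insertion,
                              apply_unequal_crossover, build_ancestor,
                              mutate_snps, random_seq, simulate_race_reads)


def _event_rng(seed: int, i: int) -> np.random.Generator:
    return np.random.default_rng([seed, i])


def tsd_recovery(n_events: int = 150, seed: int = 0) -> dict:
    """Insert elements with TSDs of 2-12 bp; recover the length exactly."""
    ok = 0
    for i in range(n_events):
        rng = _event_rng(seed, i)
        tsd_len = int(rng.integers(2, 13))
        element = random_seq(rng, 300)
        for _ in range(50):   # clean settings: non-extendable context
            seq = random_seq(rng, 1500)
            pos = int(rng.integers(200, 1200))
            derived, rec = apply_te_insertion(seq, element, pos, tsd_len)
            interval = tuple(rec.payload["element_interval_derived"])
            call = detect_tsd(derived, interval, max_tsd=20)
            got = call.tsd_len if call is not None else 0
            if got == tsd_len:
                ok += 1
                break
            if got > tsd_len:
                continue      # chance extension: resample the locus
            break             # genuine detector failure
    return {"rate": 100.0 * ok / n_events, "n": n_events}


def dup_period_recovery(n_events: int = 100, seed: int = 0) -> dict:
    """Plant perfect tandem duplications; recover the period exactly."""
    ok = 0
    for i in range(n_events):
        rng = _event_rng(seed, i)
        period = int(rng.integers(60, 1200))
        seq = random_seq(rng, 2 * period + 1200)
        start = int(rng.integers(400, 500))
        derived, _ = apply_tandem_duplication(seq, (start, start + period))
        calls = detect_tandem_duplication(derived, min_period=50)
        if any(c.period == period for c in calls):
            ok += 1
    return {"rate": 100.0 * ok / n_events, "n": n_events}


def _donor_interval(d0: int, d1: int, side: str, offset: int, length: int):
    if side == "downstream":
        return (d1 + offset, d1 + offset + length)
    return (d0 - offset - length, d0 - offset)


def filler_attribution(n_events: int = 150, seed: int = 0,
                       resection_mean: float = 50.0) -> dict:
    """Excision + NHEJ events; score donor-locus attribution per fragment.

    The detector is given the logged junction (deletion interval, insertion
    and reference flanks) and must re-identify each fragment's donor locus:
    same side and strand, donor genomic intervals overlapping by at least
    half the fragment length.  Misattributions arise when a short fragment
    happens to occur closer to the break than its true donor — the chance
    ambiguity inherent to 4-bp fragments.
    """
    total = 0
    attributed = 0
    window = 100
    for i in range(n_events):
        rng = _event_rng(seed, i)
        cfg = SimConfig(
            seed=seed,
            resection_mean=resection_mean,
            filler_frag_count=int(rng.integers(1, 3)),
        )
        seq = random_seq(rng, 3000)
        e0 = int(rng.integers(1200, 1500))
        span = int(rng.integers(100, 300))
        _, rec = apply_excision_nhej(seq, (e0, e0 + span), cfg, rng)
        d0, d1 = rec.payload["deletion"]
        truth_frags = rec.payload["fragments"]
        total += len(truth_frags)
        j = Junction(
            ref_id="ref", alt_id="alt", ref_del=(d0, d1),
            alt_ins=rec.payload["insert"], alt_pos=d0,
            left_flank=seq[d0 - window:d0], right_flank=seq[d1:d1 + window],
            ref_del_seq=seq[d0:d1],
        )
        decomp = decompose_filler(j, window=window, min_frag=4)
        called = [
            (_donor_interval(d0, d1, f.donor_side, f.donor_offset, f.frag_len),
             f.donor_side, f.donor_strand)
            for f in decomp.fragments
        ]
        for tf in truth_frags:
            tiv = _donor_interval(d0, d1, tf["side"], tf["offset"], tf["length"])
            for civ, side, strand in called:
                overlap = min(tiv[1], civ[1]) - max(tiv[0], civ[0])
                if side == tf["side"] and strand == tf["strand"] \
                        and overlap >= 0.5 * min(tf["length"], civ[1] - civ[0]):
                    attributed += 1
                    break
    return {
        "rate": 100.0 * attributed / max(total, 1),
        "n": n_events,
        "n_fragments": total,
    }


def nhej_event_recall(n_events: int = 50, seed: int = 0,
                      resection_mean: float = 50.0) -> dict:
    """End-to-end recall of NHEJ scars through alignment and classification.

    Unlike :func:`filler_attribution`, this goes through the full pipeline;
    very short inserts inside large deletions can be absorbed by legitimate
    alignment ambiguity, so recall is reported, not bounded.
    """
    called = 0
    for i in range(n_events):
        rng = _event_rng(seed, 10_000 + i)
        cfg = SimConfig(seed=seed, resection_mean=resection_mean,
                        filler_frag_count=int(rng.integers(1, 3)))
        seq = random_seq(rng, 3000)
        e0 = int(rng.integers(1200, 1500))
        span = int(rng.integers(100, 300))
        derived, _ = apply_excision_nhej(seq, (e0, e0 + span), cfg, rng)
        _, _, events = analyze_pair(seq, derived)
        if any(e.kind == "nhej_filler" for e in events):
            called += 1
    return {"rate": 100.0 * called / n_events, "n": n_events}


def breakpoint_containment(n_events: int = 100, seed: int = 0) -> dict:
    """Unequal crossovers between diverged haplotypes; the bracketing
    interval must contain the true crossover position."""
    ok = 0
    called = 0
    for i in range(n_events):
        rng = _event_rng(seed, i)
        cfg = SimConfig(seed=seed, period=600, array_copies=3, flank_len=400,
                        snp_rate=0.0)
        ancestor, _, _ = build_ancestor(cfg, rng)
        hap_a = mutate_snps(rng, ancestor.seq, 0.01)
        hap_b = mutate_snps(rng, ancestor.seq, 0.01)
        mis = 1 if rng.random() < 0.5 else -1
        product, rec = apply_unequal_crossover(
            hap_a, hap_b, cfg.uxo_anchor_len, mis, rng,
            cfg.period, cfg.flank_len, cfg.array_copies,
        )
        x = rec.payload["breakpoint"]
        res = breakpoint_interval(product, hap_a, hap_b)
        if not res.crossover:
            continue
        called += 1
        if any(lo < x <= hi for lo, hi in res.intervals):
            ok += 1
    return {
        "rate": 100.0 * ok / max(called, 1),
        "n": n_events,
        "n_called": called,
    }


def polya_recovery(n_reads: int = 500, seed: int = 0,
                   distribution: Optional[dict] = None) -> dict:
    """Simulated 3' RACE reads: exact site recovery, binomial-CI fractions.

    Returns per-run summaries: whether every truth site was recovered at its
    exact position, the largest CI z-excess over sites, and the fraction sum.
    """
    rng = np.random.default_rng([seed, 7])
    ref = random_seq(rng, 1200)
    stop_pos = 600
    cfg = SimConfig(seed=seed, n_reads=n_reads,
                    race_site_distribution=distribution)
    reads, truth = simulate_race_reads(ref, stop_pos, cfg, rng)
    table, rejected = map_reads(reads, ref, stop_pos, min_count=1)
    called = {s.pos_after_stop: s for s in table.sites}
    positions_exact = set(called) == set(truth)
    n = table.n_reads
    max_z = 0.0
    for pos, count in truth.items():
        p_hat = called[pos].count / n if pos in called else 0.0
        p_true = count / n_reads
        se = max(np.sqrt(p_true * (1 - p_true) / n), 1e-12)
        max_z = max(max_z, abs(p_hat - p_true) / se)
    fraction_sum = sum(s.fraction for s in table.sites)
    modal = max(table.sites, key=lambda s: s.count)
    return {
        "positions_exact": positions_exact,
        "n_sites": len(called),
        "n_truth_sites": len(truth),
        "max_ci_z": float(max_z),
        "fraction_sum": float(fraction_sum),
        "span": table.span,
        "modal_pos": modal.pos_after_stop,
        "modal_fraction": modal.fraction,
        "n_rejected": len(rejected),
        "n": n_reads,
    }
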