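"""TSD, filler, tandem-duplication and flanking-repeat detectors and the
event classifier."""

import numpy as np
import pytest

from junctioneer.junction_forensics import (ClassifyParams, Junction,
                                            call_junctions, classify_event,
                                            decompose_filler,
                                            detect_flanking_repeats,
                                            detect_tandem_duplication,
                                            detect_tsd)
from junctioneer.locus_io import SequenceRecord, revcomp
from junctioneer.pairwise_compare import global_align
from junctioneer.pipeline import analyze_pair
from junctioneer.synthetic_locus import (SimConfig, apply_te_insertion,
                                         mutate_snps, random_seq)

from oracle_helpers import brute_force_filler, brute_force_periods


# ---------------------------------------------------------------------------
# TSD
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("tsd", ["CCAGTGAG", "AAGAC"])
def test_tsd_of_known_transposon_families(rng, tsd):
    """hAT-style 8-bp and retroelement-style 5-bp target-site duplications."""
    left = random_seq(rng, 80)
    right = random_seq(rng, 80)
    element = random_seq(rng, 200)
    # guard against chance extension at the fixture edges
    if left[-1] == tsd[-1]:
        left = left[:-1] + ("G" if tsd[-1] != "G" else "C")
    if right[0] == tsd[0]:
        right = ("G" if tsd[0] != "G" else "C") + right[1:]
    seq = left + tsd + element + tsd + right
    start = len(left) + len(tsd)
    call = detect_tsd(seq, (start, start + len(element)), max_tsd=20)
    assert call is not None
    assert call.tsd_seq == tsd
    assert call.tsd_len == len(tsd)


def test_tsd_absent_returns_none(rng):
    seq = "CCCC" + "G" * 50 + "TTTT"
    assert detect_tsd(seq, (4, 54), max_tsd=10) is None


def test_tsd_is_maximal(rng):
    """Extending any reported TSD by one base breaks the duplication."""
    for _ in range(20):
        seq = random_seq(rng, 400)
        pos = int(rng.integers(50, 200))
        t = int(rng.integers(2, 13))
        derived, rec = apply_te_insertion(seq, random_seq(rng, 100), pos, t)
        s, e = rec.payload["element_interval_derived"]
        call = detect_tsd(derived, (s, e), max_tsd=20)
        assert call is not None
        L = call.tsd_len
        assert derived[s - L:s] == derived[e:e + L]
        assert derived[s - L - 1:s] != derived[e:e + L + 1]


def test_tsd_interval_out_of_range():
    with pytest.raises(ValueError):
        detect_tsd("ACGT" * 10, (5, 100), max_tsd=5)


# ---------------------------------------------------------------------------
# Filler decomposition
# ---------------------------------------------------------------------------

def _junction(ref, d0, d1, ins, window=100):
    return Junction(
        ref_id="r", alt_id="a", ref_del=(d0, d1), alt_ins=ins, alt_pos=d0,
        left_flank=ref[d0 - window:d0], right_flank=ref[d1:d1 + window],
        ref_del_seq=ref[d0:d1],
    )


def test_filler_no_donor_leaves_full_remainder(rng):
    ref = "G" * 400
    j = _junction(ref, 200, 210, "ATCATTCA")
    dec = decompose_filler(j)
    assert dec.fragments == ()
    assert dec.reconstruct() == "ATCATTCA"
    assert dec.explained_fraction == 0.0


def test_filler_empty_insert_is_an_error(rng):
    ref = random_seq(rng, 400)
    j = _junction(ref, 100, 200, "")
    with pytest.raises(ValueError):
        decompose_filler(j)


def test_filler_minus_strand_donor_is_found(rng):
    ref = random_seq(rng, 600)
    d0, d1 = 250, 350
    frag = "ACCGTTGCAC"
    donor = revcomp(frag)
    ref = ref[:d1 + 30] + donor + ref[d1 + 30 + len(donor):]
    j = _junction(ref, d0, d1, frag)
    dec = decompose_filler(j, min_frag=4)
    strands = {f.donor_strand for f in dec.fragments}
    assert dec.explained_fraction >= 0.9
    assert "-" in strands


@pytest.mark.parametrize("trial", range(25))
def test_filler_decomposition_matches_brute_force_oracle(trial):
    """Greedy maximal-prefix decomposition equals exhaustive substring/donor
    search on random 12-bp inserts with a planted donor."""
    rng = np.random.default_rng([31, trial])
    ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 800))
    d0, d1 = 350, 450
    ins = "".join("ACGT"[i] for i in rng.integers(0, 4, 12))
    # plant a donor of the first 7 bases downstream
    off = int(rng.integers(0, 60))
    ref = ref[:d1 + off] + ins[:7] + ref[d1 + off + 7:]
    j = _junction(ref, d0, d1, ins)
    dec = decompose_filler(j, window=100, min_frag=4)
    oracle = brute_force_filler(ins, ref[d0 - 100:d0], ref[d1:d1 + 100], 4)
    called = [(f.start_in_insert, f.frag_seq, f.donor_offset, f.donor_side,
               f.donor_strand) for f in dec.fragments]
    assert called == oracle
    assert dec.reconstruct() == ins


def test_filler_reconstruction_invariant(rng):
    """Fragments plus remainder always reconstruct the insertion exactly."""
    for _ in range(30):
        ref = random_seq(rng, 700)
        ins = random_seq(rng, int(rng.integers(1, 30)))
        j = _junction(ref, 300, 400, ins)
        dec = decompose_filler(j)
        assert dec.reconstruct() == ins


# ---------------------------------------------------------------------------
# Tandem duplications
# ---------------------------------------------------------------------------

def test_tandem_duplication_periods_match_quadratic_oracle(rng):
    """k-mer-seeded detection finds the same periods as a full O(n^2) scan."""
    for _ in range(5):
        period = int(rng.integers(60, 300))
        unit = random_seq(rng, period)
        copy2 = mutate_snps(rng, unit, 0.01)
        s = random_seq(rng, 200) + unit + copy2 + random_seq(rng, 200)
        called = {c.period for c in detect_tandem_duplication(s, 50)}
        oracle = brute_force_periods(s, 50, 98.0)
        assert called == oracle
        assert period in called


def test_tandem_duplication_random_sequence_is_empty(rng):
    assert detect_tandem_duplication(random_seq(rng, 500), 50) == []


def test_tandem_duplication_multicopy_reports_fundamental_period(rng):
    unit = random_seq(rng, 200)
    s = random_seq(rng, 300) + unit * 4 + random_seq(rng, 300)
    calls = detect_tandem_duplication(s, 50)
    assert len(calls) == 1
    assert calls[0].period == 200
    assert calls[0].n_copies == 4


# ---------------------------------------------------------------------------
# Flanking repeats
# ---------------------------------------------------------------------------

def test_flanking_repeat_exact_length_recovered(rng):
    repeat = random_seq(rng, 203)
    insert = random_seq(rng, 734)
    seq = random_seq(rng, 400) + repeat + insert + repeat + random_seq(rng, 400)
    s = 400 + 203
    call = detect_flanking_repeats(seq, (s, s + 734), min_len=50)
    assert call is not None
    assert call.repeat_seq_len == 203
    assert call.identity_pct == 100.0


def test_flanking_repeat_with_substitutions_near_exact(rng):
    repeat = random_seq(rng, 203)
    mutated = list(repeat)
    mutated[50] = "A" if repeat[50] != "A" else "C"
    mutated[150] = "A" if repeat[150] != "A" else "C"
    mutated = "".join(mutated)
    insert = random_seq(rng, 300)
    seq = random_seq(rng, 300) + repeat + insert + mutated + random_seq(rng, 300)
    s = 300 + 203
    call = detect_flanking_repeats(seq, (s, s + 300), min_len=50)
    assert call is not None
    assert abs(call.repeat_seq_len - 203) <= 2


def test_flanking_repeat_none_when_absent(rng):
    seq = random_seq(rng, 1000)
    assert detect_flanking_repeats(seq, (400, 600), min_len=50) is None


# ---------------------------------------------------------------------------
# Junction calling and classification
# ---------------------------------------------------------------------------

def test_identical_sequences_yield_no_junctions(rng):
    a = random_seq(rng, 1000)
    assert call_junctions(global_align(a, a)) == []


def test_planted_deletion_yields_one_exact_junction(rng):
    ref = random_seq(rng, 4000)
    d0, d1 = 1200, 2610   # 1,410-bp deletion
    # clean boundaries so the junction is unambiguous
    alt = ref[:d0] + ref[d1:]
    aln = global_align(ref, alt)
    junctions = call_junctions(aln, min_sv_len=5)
    assert len(junctions) == 1
    assert junctions[0].del_len == 1410


def test_planted_indels_recovered_against_truth(rng):
    ref = random_seq(rng, 20_000)
    truth = []
    alt = ref
    for k in range(10):
        pos = 1000 + k * 1800
        length = int(rng.integers(20, 60))
        truth.append((pos, length))
    for pos, length in sorted(truth, reverse=True):
        alt = alt[:pos] + alt[pos + length:]
    aln = global_align(ref, alt)
    junctions = call_junctions(aln, min_sv_len=5)
    assert len(junctions) == len(truth)
    called = sorted(j.del_len for j in junctions)
    assert called == sorted(length for _, length in truth)


def test_classifier_te_insertion_with_tsd(rng):
    te = random_seq(rng, 600)
    lib = [SequenceRecord("MULE_1", te)]
    seq = random_seq(rng, 3000)
    derived, _ = apply_te_insertion(seq, te, 1500, 8)
    _, _, events = analyze_pair(
        SequenceRecord("ref", seq), SequenceRecord("alt", derived), lib
    )
    assert [e.kind for e in events] == ["te_insertion"]
    assert events[0].tsd is not None
    assert events[0].tsd.tsd_len == 8
    assert events[0].te_id == "MULE_1"


def test_classifier_te_insertion_reverse_orientation(rng):
    te = random_seq(rng, 600)
    lib = [SequenceRecord("MULE_1", te)]
    seq = random_seq(rng, 3000)
    derived, _ = apply_te_insertion(seq, revcomp(te), 1500, 5)
    _, _, events = analyze_pair(
        SequenceRecord("ref", seq), SequenceRecord("alt", derived), lib
    )
    assert [e.kind for e in events] == ["te_insertion"]
    assert events[0].notes["te_strand"] == "-"


def test_classifier_tandem_duplication(rng):
    seq = random_seq(rng, 2000)
    alt = seq[:900] + seq[600:900] + seq[900:]   # 300-bp tandem gain
    _, _, events = analyze_pair(seq, alt)
    assert [e.kind for e in events] == ["tandem_duplication"]
    assert events[0].tandem_dup.period == 300


def test_classifier_uxo_deletion_with_anchor(rng):
    seq = random_seq(rng, 3000)
    d0, d1 = 1200, 1800
    anchor = seq[d1 - 8:d1]
    seq = seq[:d0 - 8] + anchor + seq[d0:]     # plant shared anchor
    alt = seq[:d0] + seq[d1:]
    _, _, events = analyze_pair(seq, alt)
    assert len(events) == 1
    assert events[0].kind == "uxo_deletion"
    assert events[0].notes["endpoint_anchor_len"] >= 8


def test_classifier_is_deterministic(rng):
    seq = random_seq(rng, 2500)
    cfg = SimConfig(seed=5, resection_mean=30)
    from junctioneer.synthetic_locus import apply_excision_nhej
    derived, _ = apply_excision_nhej(seq, (1200, 1350), cfg,
                                     np.random.default_rng(5))
    out1 = analyze_pair(seq, derived)[2]
    out2 = analyze_pair(seq, derived)[2]
    assert [(e.kind, e.confidence, e.junction) for e in out1] == \
        [(e.kind, e.confidence, e.junction) for e in out2]


def test_unclassified_is_a_valid_outcome(rng):
    seq = random_seq(rng, 2000)
    alt = seq[:1000] + random_seq(rng, 40) + seq[1000:]  # novel insert, no TE lib
    _, _, events = analyze_pair(seq, alt)
    assert len(events) == 1
    assert events[0].kind == "unclassified"
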