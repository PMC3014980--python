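"""Tail trimming, site assignment, tallying and feature overlap."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from junctioneer.locus_io import Feature, revcomp
from junctioneer.polya_mapper import (RaceRead, annotate_overlap, assign_site,
                                      map_reads, tally_sites, trim_tail)
from junctioneer.synthetic_locus import (SimConfig, canonical_site,
                                         random_seq, simulate_race_reads)


def _no_trailing_a(rng, n):
    s = random_seq(rng, n)
    while s.endswith("A"):
        s = s[:-1] + "CGT"[int(rng.integers(0, 3))]
    return s


class TestTrimTail:
    def test_clean_terminal_run(self):
        body = "CGT" * 20   # no A-rich suffix to tempt tolerant trimming
        read, reason = trim_tail("r1", body + "A" * 20)
        assert reason == ""
        assert read.tail_len == 20
        assert read.insert == body

    def test_read_without_tail_is_rejected(self, rng):
        read, reason = trim_tail("r1", _no_trailing_a(rng, 50))
        assert read is None
        assert reason == "no_polya_tail"

    def test_insert_plus_tail_reconstructs_read(self, rng):
        seq = _no_trailing_a(rng, 40) + "A" * 12
        read, _ = trim_tail("r", seq)
        assert read.insert + read.tail == seq

    @given(st.integers(0, 5000))
    def test_longest_valid_suffix_matches_enumeration_oracle(self, seed):
        """Trimming picks the longest suffix cut point satisfying the
        min-length, leading-A and mismatch-fraction constraints."""
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 30) + "".join(
            "A" if rng.random() < 0.9 else "C" for _ in range(25)
        )
        min_tail, frac = 8, 0.1
        best = None
        for i in range(len(seq) - min_tail + 1):
            tail = seq[i:]
            non_a = sum(1 for c in tail if c != "A")
            if tail[0] == "A" and non_a <= frac * len(tail):
                best = i
                break
        read, reason = trim_tail("r", seq, min_tail, frac)
        if best is None:
            assert read is None
        else:
            assert read is not None
            assert len(read.insert) == best

    def test_tolerated_mismatch_in_tail(self):
        seq = "CCGTTGCGTGCCGT" + "A" * 7 + "C" + "A" * 8
        read, reason = trim_tail("r", seq, min_tail=8, max_mismatch_frac=0.1)
        assert read is not None
        assert read.tail_len == 16


class TestAssignSite:
    def _setup(self, rng, site=301, stop_pos=120):
        ref = random_seq(rng, 600)
        end = stop_pos + site - 1
        while ref[end + 1] == "A":   # canonical position by construction
            ref = ref[:end + 1] + "G" + ref[end + 2:]
        return ref, end

    def test_exact_position_301_after_stop(self, rng):
        ref, end = self._setup(rng)
        read = RaceRead("r", ref[:end + 1] + "A" * 15, ref[:end + 1], "A" * 15)
        res = assign_site(read, ref, 120)
        assert res.pos_after_stop == 301

    def test_templated_a_shifts_position_3prime(self, rng):
        ref, end = self._setup(rng)
        ref = ref[:end + 1] + "AA" + ref[end + 3:]
        ref = ref[:end + 3] + "G" + ref[end + 4:]
        read = RaceRead("r", ref[:end + 1] + "A" * 15, ref[:end + 1], "A" * 15)
        res = assign_site(read, ref, 120)
        assert res.pos_after_stop == 303   # maximal templated extension

    def test_min5_mode_reports_most_5prime_consistent(self, rng):
        ref, end = self._setup(rng)
        # make the last two templated bases A's
        ref = ref[:end - 1] + "AA" + ref[end + 1:]
        insert = ref[:end + 1]
        read = RaceRead("r", insert + "A" * 15, insert, "A" * 15)
        res = assign_site(read, ref, 120, a_ambiguity="min5")
        assert res.pos_after_stop == 299

    def test_short_insert_unmapped(self, rng):
        read = RaceRead("r", "ACGTACGTAA" + "A" * 10, "ACGTACGT", "AA" + "A" * 10)
        res = assign_site(read, random_seq(rng, 300), 50)
        assert not res.mapped
        assert res.reason == "short_insert"

    def test_ambiguous_insert_unmapped(self, rng):
        unit = random_seq(rng, 80)
        ref = unit + unit + random_seq(rng, 100)
        insert = unit[:40]
        read = RaceRead("r", insert + "A" * 12, insert, "A" * 12)
        res = assign_site(read, ref, 10)
        assert not res.mapped
        assert res.reason == "ambiguous"

    def test_strand_safety(self, rng):
        """Reverse-complementing reference and mirroring the stop coordinate
        gives the same position via the strand flag."""
        ref, end = self._setup(rng)
        read = RaceRead("r", ref[:end + 1] + "A" * 15, ref[:end + 1], "A" * 15)
        fwd = assign_site(read, ref, 120, strand="+")
        rev = assign_site(read, revcomp(ref), len(ref) - 120, strand="-")
        assert fwd.pos_after_stop == rev.pos_after_stop


class TestTally:
    def test_single_site_is_100_percent(self):
        table = tally_sites([301] * 10)
        assert table.n_sites_reported == 1
        assert table.sites[0].fraction == 100.0

    def test_modal_site_fraction(self):
        positions = [301] * 36 + list(range(150, 214))   # 36 + 64 = 100 reads
        table = tally_sites(positions, min_count=1)
        modal = max(table.sites, key=lambda s: s.count)
        assert modal.pos_after_stop == 301
        assert modal.fraction == 36.0

    def test_fractions_sum_to_100_exactly(self, rng):
        positions = [int(p) for p in rng.integers(100, 400, size=500)]
        table = tally_sites(positions, min_count=2)
        assert sum(s.fraction for s in table.sites) == pytest.approx(100.0, abs=1e-9)

    def test_min_count_suppresses_but_keeps_totals(self):
        table = tally_sites([200] * 5 + [210], min_count=2)
        assert table.n_reads == 6
        assert table.n_sites_reported == 1
        assert len(table.sites) == 2
        assert table.sites[0].fraction == pytest.approx(500 / 6)

    def test_filtering_monotonicity(self, rng):
        positions = [int(p) for p in rng.integers(100, 150, size=300)]
        reported = [
            tally_sites(positions, min_count=k).n_sites_reported
            for k in range(1, 10)
        ]
        assert reported == sorted(reported, reverse=True)

    def test_zero_reads_is_an_error(self):
        with pytest.raises(ValueError):
            tally_sites([])


class TestOverlap:
    def test_sites_upstream_of_te_have_zero_te_fraction(self):
        table = tally_sites([10, 20, 30], min_count=1)
        feats = [Feature("u", "TE", 500, 900)]
        out = annotate_overlap(table, feats, stop_pos=100)
        assert all(s.feature_overlap == "none" for s in out.sites)
        assert out.overlap_summary == {"none": pytest.approx(100.0)}

    def test_ltr_partition_reproduces_event_fractions(self):
        """7 minor sites upstream of a retroelement (21% of events) and 12
        sites inside its LTR (79%) split exactly."""
        upstream = list(range(150, 157))
        ltr_sites = list(range(270, 282))
        positions = upstream * 3 + ltr_sites * 6 + [270] * 7
        # 7*3=21 upstream, 12*6+7=79 inside -> 21% / 79%
        table = tally_sites(positions, min_count=1)
        feats = [Feature("u", "LTR", 100 + 247 - 1, 100 + 400)]
        out = annotate_overlap(table, feats, stop_pos=100)
        assert out.overlap_summary["none"] == pytest.approx(21.0)
        assert out.overlap_summary["LTR"] == pytest.approx(79.0)
        assert sum(1 for s in out.sites if s.feature_overlap == "LTR") == 12

    def test_labels_match_interval_tree_oracle(self, rng):
        intervaltree = pytest.importorskip("intervaltree")
        positions = [int(p) for p in rng.integers(1, 500, size=200)]
        table = tally_sites(positions, min_count=1)
        feats = []
        for k in range(15):
            s = int(rng.integers(0, 700))
            e = s + int(rng.integers(5, 60))
            feats.append(Feature("u", ["LTR", "TE", "other"][k % 3], s, e))
        stop_pos = 50
        out = annotate_overlap(table, feats, stop_pos)
        tree = intervaltree.IntervalTree()
        prio = {"LTR": 0, "TE": 1, "other": 2}
        for f in feats:
            tree[f.start:f.end] = f.type
        for site in out.sites:
            coord = stop_pos + site.pos_after_stop - 1
            hits = sorted((prio[iv.data] for iv in tree[coord]))
            expected = ["LTR", "TE", "other"][hits[0]] if hits else "none"
            assert site.feature_overlap == expected


class TestEndToEnd:
    def test_simulated_reads_recover_distribution(self, rng):
        ref = random_seq(rng, 900)
        cfg = SimConfig(seed=3, n_reads=300)
        reads, truth = simulate_race_reads(ref, 400, cfg, rng)
        table, rejected = map_reads(reads, ref, 400, min_count=1)
        assert rejected == {}
        called = {s.pos_after_stop: s.count for s in table.sites}
        assert called == truth

    def test_point_distribution_single_site(self, rng):
        ref = random_seq(rng, 600)
        cfg = SimConfig(seed=4, n_reads=50,
                        race_site_distribution={150: 1.0})
        reads, truth = simulate_race_reads(ref, 300, cfg, rng)
        table, _ = map_reads(reads, ref, 300, min_count=1)
        assert len(table.sites) == 1
        assert table.sites[0].pos_after_stop == canonical_site(ref, 300, 150)
        assert table.sites[0].fraction == 100.0
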