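"""Frame fidelity: filtering, P-sites, windows, ambiguity, change-points."""

import numpy as np
import pytest

import riboscan as rs
from riboscan.refio import AlignedRead


def _read(five_prime=1000, length=28, mismatches=0, unique=True, strand="+"):
    return AlignedRead("chrT", strand, five_prime, length, mismatches, unique, "r")


class TestFilterReads:
    def test_three_criteria_counted_separately(self):
        reads = [
            _read(length=27),
            _read(mismatches=1),
            _read(unique=False),
            _read(length=29),
            _read(),
        ]
        kept, report = rs.filter_reads(reads)
        assert len(kept) == 1 and kept[0] == reads[-1]
        assert (report.dropped_length, report.dropped_mismatch, report.dropped_multimap) == (2, 1, 1)
        assert report.retained == 1

    def test_all_clean_is_identity(self):
        reads = [_read(five_prime=p) for p in range(100, 110)]
        kept, report = rs.filter_reads(reads)
        assert kept == reads and report.retained == 10

    def test_length_parameter_respected(self):
        reads = [_read(length=30) for _ in range(3)]
        kept, _ = rs.filter_reads(reads, length=30)
        assert len(kept) == 3


class TestAssignPsites:
    def test_plus_strand_offset_twelve(self):
        track = rs.assign_psites([_read(five_prime=1000)])
        assert track.get("chrT", "+", 1012) == 1

    def test_minus_strand_mirrored(self):
        track = rs.assign_psites([_read(five_prime=1027, strand="-")])
        assert track.get("chrT", "-", 1015) == 1

    def test_offset_zero_is_identity(self):
        track = rs.assign_psites([_read(five_prime=1000)], offset=0)
        assert track.get("chrT", "+", 1000) == 1

    def test_out_of_bounds_psites_dropped_and_counted(self, toy_refs):
        genome, _, _, _ = toy_refs
        track = rs.assign_psites([_read(five_prime=395)], genome)  # psite 407 > 400
        assert track.total_psites == 0
        assert track.dropped_out_of_bounds == 1


class TestFrameOf:
    def test_frames_inside_cds(self, toy_refs):
        _, orfs, _, _ = toy_refs
        orf = orfs["ORFP"]  # CDS 101..130, plus
        assert rs.frame_of("chrT", "+", 101, orf) == 0
        assert rs.frame_of("chrT", "+", 102, orf) == 1
        assert rs.frame_of("chrT", "+", 103, orf) == 2
        assert rs.frame_of("chrT", "+", 100, orf) is None
        assert rs.frame_of("chrT", "+", 131, orf) is None

    def test_minus_strand_frames_run_from_high_coordinate(self, toy_refs):
        _, orfs, _, _ = toy_refs
        orf = orfs["ORFM"]  # CDS 201..230, minus: first CDS nt is 230
        assert rs.frame_of("chrT", "-", 230, orf) == 0
        assert rs.frame_of("chrT", "-", 229, orf) == 1
        assert rs.frame_of("chrT", "+", 230, orf) is None  # wrong strand


class TestWindowOrf:
    @pytest.mark.parametrize(
        "length,expected_k",
        [(600, 3), (6000, 9), (2700, 9), (900, 3), (1350, 5), (300, 3)],
    )
    def test_window_counts(self, length, expected_k):
        assert len(rs.window_orf(length)) == expected_k

    def test_windows_tile_without_overlap_codon_aligned(self):
        for length in (300, 603, 1200, 2700, 5000 * 3):
            bounds = rs.window_orf(length)
            assert bounds[0][0] == 1 and bounds[-1][1] == length
            for (s1, e1), (s2, e2) in zip(bounds, bounds[1:]):
                assert s2 == e1 + 1
                assert (s2 - 1) % 3 == 0
            sizes = [e - s + 1 for s, e in bounds]
            assert max(sizes) - min(sizes) <= 3

    def test_exact_2700_gives_nine_windows_of_300(self):
        bounds = rs.window_orf(2700)
        assert [e - s + 1 for s, e in bounds] == [300] * 9


class TestFrameProfile:
    def _brute_force(self, track, orf):
        """Independent per-read loop over window bounds."""
        bounds = rs.window_orf(len(orf.spliced_cds))
        counts = [[0, 0, 0] for _ in bounds]
        counter = track.positions(orf.chrom_id, orf.strand)
        for pos, n in counter.items():
            local = orf.local_offset(pos)
            if local is None:
                continue
            nt = local + 1
            for w, (s, e) in enumerate(bounds):
                if s <= nt <= e:
                    counts[w][local % 3] += n
        return [tuple(c) for c in counts]

    def test_matches_brute_force_on_small_instances(self, toy_refs):
        genome, orfs, _, _ = toy_refs
        rng = np.random.default_rng(3)
        reads = [
            _read(five_prime=int(rng.integers(85, 125)))
            for _ in range(50)
        ]
        track = rs.assign_psites(reads, genome)
        profiles = rs.frame_profile(track, list(orfs.values()))
        for orf_id, wins in profiles.items():
            assert [w.counts for w in wins] == self._brute_force(track, orfs[orf_id])

    def test_conservation_window_sums_equal_in_cds_psites(self, frameshift_sim):
        genome, orfs, _, _, track = frameshift_sim
        profiles = rs.frame_profile(track, orfs)
        for orf in orfs:
            in_cds = sum(n for _, n in rs.frames.orf_frame_counts(track, orf))
            assert sum(w.total for w in profiles[orf.orf_id]) == in_cds

    def test_empty_track_gives_all_zero_profiles(self, frameshift_sim):
        _, orfs, _, _, _ = frameshift_sim
        profiles = rs.frame_profile(rs.PSiteTrack(), orfs)
        assert all(w.total == 0 for ws in profiles.values() for w in ws)


class TestCallAmbiguities:
    def test_pure_frame0_not_ambiguous(self, frameshift_sim):
        _, orfs, _, _, track = frameshift_sim
        profiles = rs.frame_profile(track, orfs)
        calls = {c.orf_id: c for c in rs.call_ambiguities(profiles)}
        assert not calls["ORF0001"].ambiguous
        assert not calls["ORF0003"].ambiguous

    def test_programmed_shift_flags_downstream_windows(self, frameshift_sim):
        _, orfs, _, _, track = frameshift_sim
        profiles = rs.frame_profile(track, orfs)
        calls = {c.orf_id: c for c in rs.call_ambiguities(profiles)}
        call = calls["ORF0002"]
        assert call.ambiguous and call.dominant_offframe == 1
        # shift at codon 100 of a 300-codon ORF: windows after nt 300 offend
        bounds = rs.window_orf(900)
        expected = [i + 1 for i, (s, e) in enumerate(bounds) if s > 300]
        assert set(expected) <= set(call.offending_windows)

    def test_offframe_fraction_boundary_is_inclusive(self):
        win = lambda f0, f1: rs.WindowFrameProfile("X", 1, (1, 300), (f0, f1, 0))
        at = rs.call_ambiguities({"X": [win(50, 50)]})  # exactly 0.5
        below = rs.call_ambiguities({"X": [win(51, 49)]})  # 0.49
        assert at[0].ambiguous and not below[0].ambiguous

    def test_min_window_reads_boundary(self):
        win = lambda n: rs.WindowFrameProfile("X", 1, (1, 300), (0, n, 0))
        assert rs.call_ambiguities({"X": [win(32)]})[0].ambiguous
        assert not rs.call_ambiguities({"X": [win(31)]})[0].ambiguous


class TestLocateTransition:
    def test_recovers_programmed_shift_position(self, frameshift_sim):
        _, orfs, _, _, track = frameshift_sim
        orf = next(o for o in orfs if o.orf_id == "ORF0002")
        nt = rs.locate_transition(track, orf, 1)
        assert abs(nt - 301) <= 3  # shift at codon 100 -> off-frame from nt 301

    def test_no_offframe_reads_gives_none(self, frameshift_sim):
        _, orfs, _, _, track = frameshift_sim
        orf = next(o for o in orfs if o.orf_id == "ORF0001")
        assert rs.locate_transition(track, orf, 1) is None

    def test_shift_at_first_codon_degenerate(self):
        spec = rs.SimulationSpec(
            orf_specs=[rs.OrfSpec(600)],
            events=[rs.EventSpec("frameshift", "ORF0001", 1, shift=+1, penetrance=1.0)],
            depth=30,
            seed=17,
        )
        genome, orfs = rs.make_genome(spec)
        reads, _ = rs.simulate_footprints(genome, orfs, spec)
        track = rs.assign_psites(rs.filter_reads(reads)[0], genome)
        nt = rs.locate_transition(track, orfs[0], 1)
        assert nt is not None and nt <= 6


class TestGlobalFrameSummary:
    def _noisy_tracks(self, rate_a, rate_b, n_orfs=60, seed=29):
        spec = lambda rate, s: rs.SimulationSpec(
            orf_specs=[rs.OrfSpec(600)] * n_orfs, depth=15, offframe_rate=rate, seed=s
        )
        genome, orfs = rs.make_genome(spec(rate_a, seed))
        reads_a, _ = rs.simulate_footprints(genome, orfs, spec(rate_a, seed))
        reads_b, _ = rs.simulate_footprints(genome, orfs, spec(rate_b, seed + 1))
        track_a = rs.assign_psites(reads_a, genome)
        track_b = rs.assign_psites(reads_b, genome)
        return track_a, track_b, orfs

    def test_identical_tracks_null_statistic(self, frameshift_sim):
        _, orfs, _, _, track = frameshift_sim
        s = rs.global_frame_summary(track, track, orfs)
        assert s.statistic == pytest.approx(0, abs=1e-12)
        assert s.pvalue == pytest.approx(1.0)
        assert sum(s.fractions_a) == pytest.approx(1.0, abs=1e-9)

    def test_doubled_offframe_rate_detected(self):
        track_a, track_b, orfs = self._noisy_tracks(0.1, 0.2)
        s = rs.global_frame_summary(track_a, track_b, orfs)
        assert s.pvalue < 0.01
        assert s.fractions_a[0] > s.fractions_b[0]

    def test_all_frame0_both_samples(self):
        track_a, track_b, orfs = self._noisy_tracks(0.0, 0.0)
        s = rs.global_frame_summary(track_a, track_b, orfs)
        assert s.fractions_a[0] == 1.0 and s.fractions_b[0] == 1.0

    def test_too_few_qualifying_orfs_is_error(self, frameshift_sim):
        _, orfs, _, _, track = frameshift_sim
        with pytest.raises(ValueError, match="need >= 3"):
            rs.global_frame_summary(track, rs.PSiteTrack(), orfs)
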