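"""Tests for track I/O, validation, preprocessing, and the stability metric."""

from __future__ import annotations

import io

import numpy as np
import pytest

from tetherflight import (
    ExperimentDesign,
    HeadingTrack,
    PhaseSpec,
    bin_samples,
    detect_cessations,
    filter_individuals,
    individual_vector,
    mean_abs_turn_rate,
    read_tracks,
    segment_phases,
    signed_angle_diff,
    write_tracks,
)

GRID = 0.9  # encoder step


def varying(n, start=0):
    """n samples that change every sample (on the encoder grid)."""
    return (GRID * (np.arange(start, start + n) % 360)).astype(float) % 360.0


# ---------------------------------------------------------------- I/O


def test_read_minimal_csv():
    csv = "individual_id,t_s,azimuth_deg\nm1,0.0,10\nm1,0.2,10.9\n"
    tracks, report = read_tracks(io.StringIO(csv))
    assert len(tracks) == 1
    assert tracks[0].n_samples == 2
    assert report.n_rows_kept == 2
    assert tracks[0].azimuth_deg == pytest.approx([10.0, 10.9])


def test_read_rejects_out_of_range_azimuth():
    csv = "individual_id,t_s,azimuth_deg\nm1,0.0,10\nm1,0.2,400\nm1,0.4,-5\nm1,0.6,20\n"
    tracks, report = read_tracks(io.StringIO(csv))
    assert tracks[0].n_samples == 2
    assert len(report.rejected_rows) == 2
    assert "400" in report.rejected_rows[0][1]


def test_read_collapses_duplicate_timestamps():
    csv = "individual_id,t_s,azimuth_deg\nm1,0.0,10\nm1,0.0,10\nm1,0.2,11.7\n"
    tracks, report = read_tracks(io.StringIO(csv))
    assert tracks[0].n_samples == 2
    assert report.n_duplicates_collapsed == 1


def test_read_errors_name_the_problem():
    with pytest.raises(ValueError, match="azimuth_deg"):
        read_tracks(io.StringIO("individual_id,t_s\nm1,0.0\n"))
    with pytest.raises(ValueError, match="row"):
        read_tracks(io.StringIO("individual_id,t_s,azimuth_deg\nm1,0.0,north\n"))
    with pytest.raises(ValueError):
        read_tracks(io.StringIO("individual_id,t_s,azimuth_deg\n"))


def test_write_read_roundtrip(make_track):
    tr1 = make_track(varying(50), individual_id="a", group="grp1")
    tr2 = make_track(varying(30, start=7), individual_id="b", group="grp1")
    buf = io.StringIO()
    write_tracks([tr1, tr2], buf)
    buf.seek(0)
    back, report = read_tracks(buf)
    assert [tr.individual_id for tr in back] == ["a", "b"]
    for orig, rt in zip([tr1, tr2], back):
        assert np.allclose(rt.t, orig.t)
        assert np.allclose(rt.azimuth_deg, orig.azimuth_deg)
        assert rt.group == orig.group
    assert not report.rejected_rows


def test_track_invariants():
    with pytest.raises(ValueError):
        HeadingTrack("m1", t=np.array([0.0, 0.0]), azimuth_deg=np.array([1.0, 2.0]))
    tr = HeadingTrack("m1", t=np.array([0.0, 0.2]), azimuth_deg=np.array([365.0, -10.0]))
    assert tr.azimuth_deg == pytest.approx([5.0, 350.0])  # constructor normalizes
    assert HeadingTrack("m", np.array([0.0, 0.2]), np.array([0.9, 1.8])).is_quantized()
    assert not HeadingTrack("m", np.array([0.0, 0.2]), np.array([0.9, 1.0])).is_quantized()


# ---------------------------------------------------------------- cessations


def test_cessation_twelve_seconds_inside_varying_track(make_track):
    az = np.concatenate([varying(100), np.full(60, 45.0), varying(100, start=60)])
    track = make_track(az)  # constant on [20.0, 32.0): next change at t=32.0
    intervals = detect_cessations(track, window_s=10.0)
    assert intervals == [(20.0, 32.0)]
    assert intervals[0][1] - intervals[0][0] == pytest.approx(12.0)


def test_cessation_none_when_always_changing(make_track):
    assert detect_cessations(make_track(varying(200))) == []


def test_cessation_below_threshold_boundary(make_track):
    # constant for exactly 9.8 s (change arrives at t = start + 9.8)
    az = np.concatenate([varying(100), np.full(49, 45.0), varying(100, start=60)])
    track = make_track(az)
    assert detect_cessations(track, window_s=10.0) == []
    # at exactly 10.0 s the stall is detected (>= window)
    az = np.concatenate([varying(100), np.full(50, 45.0), varying(100, start=60)])
    assert len(detect_cessations(make_track(az), window_s=10.0)) == 1


def test_cessation_intervals_disjoint_and_long_enough(make_track):
    az = np.concatenate(
        [np.full(70, 9.0), varying(30), np.full(55, 18.0), varying(40), np.full(80, 27.0)]
    )
    track = make_track(az)
    intervals = detect_cessations(track, window_s=10.0)
    assert len(intervals) == 3
    for (s0, e0), (s1, _) in zip(intervals, intervals[1:]):
        assert e0 <= s1
    assert all(e - s >= 10.0 for s, e in intervals)


def test_cessation_window_validation(make_track):
    with pytest.raises(ValueError):
        detect_cessations(make_track(varying(10)), window_s=0.0)


# ---------------------------------------------------------------- inclusion rule


def _track_with_stalls(make_track, n_stalls):
    parts = [varying(60)]
    for k in range(n_stalls):
        parts.append(np.full(60, GRID * (10 + k)))  # 12-s stalls, distinct values
        parts.append(varying(60, start=100 + 60 * k))
    return make_track(np.concatenate(parts))


def test_inclusion_rule_boundary(make_track):
    ok = _track_with_stalls(make_track, 3)
    bad = _track_with_stalls(make_track, 4)
    kept, excluded = filter_individuals([ok, bad], max_cessations=3)
    assert kept == [ok]
    assert len(excluded) == 1
    assert excluded[0].n_cessations == 4


def test_inclusion_rule_empty_input():
    assert filter_individuals([]) == ([], [])


# ---------------------------------------------------------------- segmentation


def test_segment_default_design_counts(make_track, five_phase_design):
    track = make_track(varying(7500))  # 1500 s at 5 Hz
    slices = segment_phases(track, five_phase_design)
    assert list(slices) == ["I", "II", "III", "IV", "V"]
    assert all(sl.n_samples == 1500 for sl in slices.values())
    # conservation: slices partition the in-design samples
    assert sum(sl.n_samples for sl in slices.values()) == track.n_samples


def test_segment_boundary_sample_goes_to_later_phase(make_track, five_phase_design):
    track = make_track(varying(7500))
    slices = segment_phases(track, five_phase_design)
    assert slices["II"].t[0] == pytest.approx(300.0)
    assert slices["I"].t[-1] == pytest.approx(299.8)


def test_segment_single_phase_design(make_track, single_phase_design):
    track = make_track(varying(300))  # 60 s
    slices = segment_phases(track, single_phase_design)
    assert slices["I"].n_samples == 300


def test_segment_short_track_lists_missing_phases(make_track, five_phase_design):
    track = make_track(varying(3000))  # 600 s: phases III-V missing
    with pytest.raises(ValueError) as err:
        segment_phases(track, five_phase_design)
    assert "III" in str(err.value) and "V" in str(err.value)


# ---------------------------------------------------------------- binning


def test_bin_counts_and_conservation(make_track, five_phase_design):
    track = make_track(varying(7500))
    sl = segment_phases(track, five_phase_design)["II"]
    bins = bin_samples(sl, bin_s=30.0)
    assert len(bins) == 10
    assert all(b.defined for b in bins)
    assert sum(b.n_samples for b in bins) == sl.n_samples
    whole = bin_samples(sl, bin_s=300.0)
    assert len(whole) == 1 and whole[0].n_samples == sl.n_samples


def test_bin_incomplete_flagged(make_track, five_phase_design):
    # drop most samples of one 30-s window: its bin must be undefined
    track = make_track(varying(7500))
    keep = (track.t < 330.0) | (track.t >= 355.0)  # bin [330, 360) keeps 5/150
    thin = HeadingTrack("m1", track.t[keep], track.azimuth_deg[keep])
    sl = segment_phases(thin, five_phase_design)["II"]
    bins = bin_samples(sl, bin_s=30.0)
    flags = [b.defined for b in bins]
    assert flags[1] is False
    assert sum(flags) == 9


def test_bin_trailing_partial_flagged(make_track, single_phase_design):
    sl = segment_phases(make_track(varying(300)), single_phase_design)["I"]
    bins = bin_samples(sl, bin_s=25.0)  # 60 s -> 2 full bins + 10-s tail
    assert len(bins) == 3
    assert [b.defined for b in bins] == [True, True, False]


def test_bin_validation(make_track, single_phase_design):
    sl = segment_phases(make_track(varying(300)), single_phase_design)["I"]
    with pytest.raises(ValueError):
        bin_samples(sl, bin_s=0.0)


# ---------------------------------------------------------------- vectors & stability


def test_individual_vector_from_slice(make_track, single_phase_design):
    sl = segment_phases(make_track(np.full(300, 45.0)), single_phase_design)["I"]
    v = individual_vector(sl)
    assert v.r == pytest.approx(1.0)
    assert v.mean_dir == pytest.approx(45.0)
    assert v.phase_id == "I"


def test_mean_abs_turn_constant_heading(make_track):
    res = mean_abs_turn_rate(make_track(np.full(100, 77.4)))
    assert res.mean_abs_turn == pytest.approx(0.0)
    assert res.n_steps == 19


def test_mean_abs_turn_alternating_headings(make_track):
    # 0 and 90 alternating at the second marks -> 90 deg/s by definition
    az = np.tile(np.concatenate([np.zeros(5), np.full(5, 90.0)]), 10)
    res = mean_abs_turn_rate(make_track(az))
    assert res.mean_abs_turn == pytest.approx(90.0)


def test_mean_abs_turn_rotation_invariant(make_track):
    rng = np.random.default_rng(5)
    az = (np.round(rng.uniform(0, 360, 200) / GRID) * GRID) % 360.0
    base = mean_abs_turn_rate(make_track(az))
    rot = mean_abs_turn_rate(make_track(az).rotated(137.0))
    assert rot.mean_abs_turn == pytest.approx(base.mean_abs_turn, abs=1e-9)


def test_mean_abs_turn_needs_two_seconds(make_track):
    with pytest.raises(ValueError):
        mean_abs_turn_rate(make_track(np.array([0.0, 1.0])))


def test_mean_abs_turn_wraps_through_north(make_track):
    # 350 -> 10 is a 20-degree turn, not 340
    az = np.concatenate([np.full(5, 350.0), np.full(5, 10.0), np.full(5, 350.0)])
    res = mean_abs_turn_rate(make_track(az))
    assert res.mean_abs_turn == pytest.approx(20.0)


# ---------------------------------------------------------------- design


def test_design_yaml_roundtrip(tmp_path, five_phase_design):
    path = tmp_path / "design.yaml"
    five_phase_design.to_yaml(path)
    back = ExperimentDesign.from_file(path)
    assert back == five_phase_design


def test_design_validation():
    with pytest.raises(ValueError):
        PhaseSpec(phase_id="I", duration_s=-5.0)
    with pytest.raises(ValueError):
        PhaseSpec(phase_id="I", magnetic_condition="XMF")
    with pytest.raises(ValueError):
        ExperimentDesign([])
    with pytest.raises(ValueError):
        ExperimentDesign([PhaseSpec(phase_id="I"), PhaseSpec(phase_id="I")])


def test_design_conflict_detection():
    aligned = PhaseSpec("I", magnetic_condition="NMF", cue_azimuth_deg=180, expected_dir_deg=180)
    conflict = PhaseSpec("II", magnetic_condition="CMF", cue_azimuth_deg=180, expected_dir_deg=180)
    realigned = PhaseSpec("IV", magnetic_condition="CMF", cue_azimuth_deg=0, expected_dir_deg=180)
    assert not aligned.is_conflict()
    assert conflict.is_conflict()
    assert not realigned.is_conflict()
    assert conflict.magnetic_goal_deg == pytest.approx(0.0)
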