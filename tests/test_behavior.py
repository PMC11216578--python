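"""Behaviour-stage unit and property tests.

The oracle values here are hand-derived from the definitions: a single
30-cm jump at 60 Hz smoothed over the 5-frame window gives 1800/5 = 360
cm/s; a reaction time of 2.0 s falls in the third 750-ms loom window; the
area of the 7-cm centre disc is pi*49/1024 of the 32-cm arena.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import loomlab.behavior as bhv
from loomlab.behavior import ArenaConfig


def _traj(xs, ys, fps=60.0):
    t = np.arange(len(xs)) / fps
    return pd.DataFrame({"time_s": t, "x_cm": xs, "y_cm": ys})


class TestComputeSpeed:
    def test_stationary_is_zero(self):
        traj = _traj(np.zeros(100), np.zeros(100))
        assert np.allclose(bhv.compute_speed(traj)["speed"], 0.0)

    def test_uniform_motion_constant(self):
        x = np.arange(200) * (10.0 / 60.0)  # 10 cm/s
        speed = bhv.compute_speed(_traj(x, np.zeros_like(x)))["speed"]
        assert np.allclose(speed, 10.0)

    def test_single_jump_smoothed_peak(self):
        # one 30-cm displacement in one frame: 1800 cm/s raw, 360 over the
        # 5-frame centred window
        x = np.zeros(61)
        x[31:] = 30.0
        speed = bhv.compute_speed(_traj(x, np.zeros_like(x)))["speed"]
        assert np.isclose(speed.max(), 1800.0 / 5.0)

    def test_duplicate_timestamps_rejected(self):
        traj = _traj(np.zeros(5), np.zeros(5))
        traj.loc[2, "time_s"] = traj.loc[1, "time_s"]
        with pytest.raises(ValueError):
            bhv.compute_speed(traj)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_windowed_mean(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 200)
        x = np.cumsum(rng.normal(0, 0.3, n))
        y = np.cumsum(rng.normal(0, 0.3, n))
        speed = bhv.compute_speed(_traj(x, y))["speed"].to_numpy()
        inst = np.hypot(np.diff(x), np.diff(y)) * 60.0
        inst = np.concatenate([[inst[0]], inst])
        brute = np.array(
            [inst[max(i - 2, 0) : i + 3].mean() for i in range(n)]
        )
        assert np.allclose(speed, brute)


class TestClosedLoop:
    def test_never_leaving_shelter_empty_log(self):
        cfg = ArenaConfig()
        traj = _traj(np.full(300, -11.5), np.full(300, -11.5))
        assert len(bhv.emulate_closed_loop(traj, cfg)) == 0

    def test_refractory_merges_close_crossings(self):
        cfg = ArenaConfig()
        # cross out at t=1 s, back in, out again 10 s later
        n = 60 * 15
        x = np.full(n, -11.5)
        x[60:120] = 2.0  # ~13.5 cm from shelter -> beyond 10 cm
        x[660:720] = 2.0
        traj = _traj(x, np.full(n, -11.5))
        log = bhv.emulate_closed_loop(traj, cfg)
        assert len(log) == 1

    def test_round_trip_with_generator(self, wt_session):
        params, tracked, stim, _ = wt_session
        log = bhv.emulate_closed_loop(tracked, params.arena_config())
        assert np.allclose(log["onset_s"].to_numpy(), stim["onset_s"].to_numpy())

    def test_consecutive_onsets_respect_refractory(self, wt_session):
        _, _, stim, _ = wt_session
        if len(stim) > 1:
            assert np.all(np.diff(stim["onset_s"]) >= 30.0)


def _escape_trial(peak_speed, entry_s, rt_s, fps=60.0):
    """Synthesise a speed trace + occupancy for one trial (onset at 5 s)."""
    n = int(20 * fps)
    t = np.arange(n) / fps
    speed = np.zeros(n)
    onset = 5.0
    i_peak = int((onset + rt_s) * fps)
    speed[i_peak] = peak_speed
    in_shelter = np.zeros(n, dtype=bool)
    in_shelter[int((onset + entry_s) * fps) :] = True
    return onset, pd.DataFrame({"time_s": t, "speed": speed}), in_shelter


class TestClassifyEscape:
    def test_fast_return_high_speed_is_escape(self):
        onset, speed, occ = _escape_trial(25.0, entry_s=6.5, rt_s=1.0)
        m = bhv.classify_escape(onset, speed, occ)
        assert m.is_escape and m.looms_to_escape == "2"

    def test_slow_peak_is_no_response(self):
        # returns in time but never reaches the 20 cm/s criterion
        onset, speed, occ = _escape_trial(15.0, entry_s=6.5, rt_s=1.0)
        m = bhv.classify_escape(onset, speed, occ)
        assert not m.is_escape and m.looms_to_escape == "NR"

    def test_reaction_time_2s_is_third_loom(self):
        onset, speed, occ = _escape_trial(40.0, entry_s=3.0, rt_s=2.0)
        m = bhv.classify_escape(onset, speed, occ)
        assert m.looms_to_escape == "3"
        assert np.isclose(m.reaction_time, 2.0, atol=1 / 60)

    def test_loom_boundary_belongs_to_later_loom(self):
        onset, speed, occ = _escape_trial(40.0, entry_s=3.0, rt_s=0.75)
        assert bhv.classify_escape(onset, speed, occ).looms_to_escape == "2"

    def test_late_reaction_is_beyond_fifth_loom(self):
        onset, speed, occ = _escape_trial(40.0, entry_s=6.0, rt_s=4.5)
        assert bhv.classify_escape(onset, speed, occ).looms_to_escape == ">5"

    def test_in_shelter_at_onset_flagged_invalid(self):
        onset, speed, occ = _escape_trial(40.0, entry_s=3.0, rt_s=1.0)
        occ[:] = True
        assert not bhv.classify_escape(onset, speed, occ).valid

    def test_vigour_threshold_monotonicity(self, wt_session):
        params, tracked, stim, _ = wt_session
        cfg = params.arena_config()
        speed = bhv.compute_speed(tracked)
        occ = bhv.shelter_occupancy(tracked, cfg)
        vmaxes = [
            bhv.classify_escape(row["onset_s"], speed, occ, cfg).max_escape_speed
            for _, row in stim.iterrows()
        ]
        counts = [
            sum(1 for v in vmaxes if np.isfinite(v) and v >= thr)
            for thr in (10.0, 20.0, 30.0, 50.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestImmediateSpeedChange:
    def _trials(self, rows):
        return pd.DataFrame(rows)

    def test_equal_speeds_no_change(self):
        trials = self._trials(
            [
                {"genotype": "wt", "s_at": 10.0, "s_im": 10.0},
                {"genotype": "wt", "s_at": 12.0, "s_im": 12.0},
                {"genotype": "wt", "s_at": 8.0, "s_im": 8.0},
            ]
        )
        out = bhv.immediate_speed_change(trials)
        assert (out["category"] == "no_change").all()

    def test_one_sd_rule(self):
        # pooled s_at sd = 2; s_im - s_at = 5 > 1 SD -> increase
        trials = self._trials(
            [
                {"genotype": "wt", "s_at": 10.0, "s_im": 15.0},
                {"genotype": "wt", "s_at": 12.0, "s_im": 12.5},
                {"genotype": "wt", "s_at": 14.0, "s_im": 8.0},
            ]
        )
        out = bhv.immediate_speed_change(trials)
        assert list(out["category"]) == ["increase", "no_change", "decrease"]

    def test_category_partition(self, wt_session):
        params, tracked, stim, _ = wt_session
        speed = bhv.compute_speed(tracked)
        rows = []
        for _, r in stim.iterrows():
            s_at, s_im = bhv.window_speeds(r["onset_s"], speed)
            rows.append({"genotype": "wt", "s_at": s_at, "s_im": s_im})
        out = bhv.immediate_speed_change(pd.DataFrame(rows))
        assert out["category"].isin(["increase", "decrease", "no_change"]).all()
        assert len(out) == len(stim)

    def test_log_ratio(self):
        trials = self._trials(
            [
                {"genotype": "wt", "s_at": 10.0, "s_im": 100.0},
                {"genotype": "wt", "s_at": 10.0, "s_im": 1.0},
            ]
        )
        out = bhv.immediate_speed_change(trials)
        assert np.allclose(out["log_speed_ratio"], [1.0, -1.0])


class TestShelterExits:
    def test_never_exits(self):
        cfg = ArenaConfig()
        traj = _traj(np.full(200, -11.5), np.full(200, -11.5))
        assert len(bhv.detect_shelter_exits(traj, cfg)) == 0

    def test_single_loop_to_corner(self):
        cfg = ArenaConfig()
        # out to the far corner and back, 2 s each way
        steps = np.linspace(0, 1, 120)
        x = np.concatenate([-11.5 + steps * 25, 13.5 - steps * 25])
        traj = _traj(x, x)
        exits = bhv.detect_shelter_exits(traj, cfg)
        assert len(exits) == 1
        assert bool(exits["entered_threat_zone"].iloc[0])

    def test_round_trip_exit_count(self, wt_session):
        params, tracked, _, truth = wt_session
        cfg = params.arena_config()
        exits = bhv.detect_shelter_exits(tracked, cfg)
        expected = truth.exits[
            truth.exits["full_exit"] & truth.exits["completed"]
        ]
        assert len(exits) == len(expected)


class TestOccupancy:
    def test_parked_at_centre(self):
        cfg = ArenaConfig()
        traj = _traj(np.zeros(600), np.zeros(600))
        m = bhv.occupancy_metrics(traj, cfg)
        assert m["pct_time_center"] == 100.0 and m["pct_time_edge"] == 0.0

    def test_parked_in_shelter(self):
        cfg = ArenaConfig()
        traj = _traj(np.full(600, -11.5), np.full(600, -11.5))
        assert bhv.occupancy_metrics(traj, cfg)["pct_time_out"] == 0.0

    def test_uniform_positions_match_area_ratio(self):
        cfg = ArenaConfig()
        rng = np.random.default_rng(1)
        n = 36000
        x = rng.uniform(-16, 16, n)
        y = rng.uniform(-16, 16, n)
        m = bhv.occupancy_metrics(_traj(x, y), cfg)
        expect = 100.0 * math.pi * 7.0**2 / 32.0**2
        assert abs(m["pct_time_center"] - expect) < 1.0


class TestPositionalCovariates:
    def _traj_with_pose(self, snout, back):
        df = _traj([5.0, 5.0], [5.0, 5.0])
        df["snout_x"], df["snout_y"] = snout
        df["back_x"], df["back_y"] = back
        return df

    @pytest.mark.parametrize(
        "snout, expected",
        [
            ((-12.0, -12.0), 0.0),  # snout towards the shelter
            ((6.0, 6.0), 180.0),  # directly away
        ],
    )
    def test_heading_collinear(self, snout, expected):
        cfg = ArenaConfig()
        traj = self._traj_with_pose(snout, (5.0, 5.0))
        out = bhv.positional_covariates(0.0, traj, cfg)
        assert np.isclose(out["heading_angle"], expected, atol=1e-6)

    def test_heading_right_angle(self):
        cfg = ArenaConfig(shelter_center=(0.0, -10.0))
        # back at origin, snout along +x, shelter along -y -> 90 deg
        traj = _traj([0.0, 0.0], [0.0, 0.0])
        traj["snout_x"], traj["snout_y"] = 2.0, 0.0
        traj["back_x"], traj["back_y"] = 0.0, 0.0
        out = bhv.positional_covariates(0.0, traj, cfg)
        assert np.isclose(out["heading_angle"], 90.0)

    def test_missing_pose_gives_nan_heading(self):
        cfg = ArenaConfig()
        traj = _traj([5.0, 5.0], [5.0, 5.0])
        out = bhv.positional_covariates(0.0, traj, cfg)
        assert math.isnan(out["heading_angle"])
        assert np.isfinite(out["distance_to_shelter"])


class TestAggregateCohort:
    def test_single_trial_mean_is_trial(self):
        df = pd.DataFrame(
            [{"animal": "a", "genotype": "wt", "day": 0, "is_escape": True,
              "reaction_time": 0.5, "max_escape_speed": 60.0}]
        )
        agg = bhv.aggregate_cohort(df)
        assert agg["per_animal"]["reaction_time"].iloc[0] == 0.5

    def test_two_animal_genotype_mean(self):
        df = pd.DataFrame(
            [
                {"animal": "a", "genotype": "wt", "day": 0, "is_escape": True,
                 "reaction_time": 0.4, "max_escape_speed": 60.0},
                {"animal": "b", "genotype": "wt", "day": 0, "is_escape": True,
                 "reaction_time": 0.8, "max_escape_speed": 40.0},
            ]
        )
        agg = bhv.aggregate_cohort(df)
        assert np.isclose(agg["per_genotype"]["reaction_time"].iloc[0], 0.6)

    def test_zero_escape_animal_kept_in_counts(self):
        df = pd.DataFrame(
            [
                {"animal": "a", "genotype": "wt", "day": 0, "is_escape": True,
                 "reaction_time": 0.4, "max_escape_speed": 60.0},
                {"animal": "b", "genotype": "wt", "day": 0, "is_escape": False,
                 "reaction_time": np.nan, "max_escape_speed": np.nan},
            ]
        )
        agg = bhv.aggregate_cohort(df)
        per = agg["per_animal"]
        assert set(per["animal"]) == {"a", "b"}
        assert per.loc[per["animal"] == "b", "n_escapes"].iloc[0] == 0
        # the genotype reaction-time average excludes the non-escaper
        assert np.isclose(agg["per_genotype"]["reaction_time"].iloc[0], 0.4)
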