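"""Trajectory planning and insertion-simulation contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vascaccess as va
from vascaccess.needle import (NeedleGeometry, NeedlePlan, PlanningError,
                               TissueParams, Waypoint, confirm_by_image,
                               flashback_sample, plan_duration,
                               plan_trajectory, simulate_insertion)
from vascaccess.phantom import BModeFrame
from vascaccess.segmentation import VesselFit


def _fit(depth=20.0, radius=5.0, lateral=0.0):
    return VesselFit(center_mm=(lateral, depth),
                     semi_axes_mm=(radius, radius), rotation_deg=0.0,
                     boundary_points_mm=np.empty((0, 2)), cls="vein")


def _vein_instance(diameter=10.0, ecc=1.0, tenting=0.0):
    vein = va.VesselGeometry(0.0, 20.0, diameter, 0.6, ecc)
    artery = va.VesselGeometry(-14.0, 12.0, 6.0, 1.2, 1.0)
    return va.AnatomyInstance(artery=artery, vein=vein,
                              bifurcation_cc_mm=-40.0,
                              state=va.NORMOTENSIVE,
                              tenting_capacity_mm=max(tenting, 0.0),
                              rng_seed=0)


def _no_noise(tenting=0.0, **kw):
    return TissueParams(tenting_capacity_mm=tenting, kickback_sd_mm=0.0,
                        kickback_sd_deg=0.0, capacity_jitter_sd=0.0, **kw)


class TestPlanTrajectory:
    def test_worked_waypoint_geometry(self):
        # entry offset 15, centroid depth 20 -> centroid 25 mm along path,
        # walls at 20 and 30 mm for a 10 mm vessel
        plan = plan_trajectory(_fit(), NeedleGeometry(entry_offset_mm=15.0))
        positions = {wp.label: wp.position_mm for wp in plan.waypoints}
        speeds = [wp.speed_mm_s for wp in plan.waypoints]
        assert positions == {"A": 29.0, "B": 25.0, "C": 30.0,
                             "D": 20.0, "E": 25.0}
        assert speeds == [45.0, 20.0, 10.0, 10.0, 10.0]
        assert plan.posterior_wall_mm - positions["A"] == pytest.approx(1.0)

    def test_depth_equal_to_entry_offset_gives_45_degrees(self):
        plan = plan_trajectory(_fit(depth=15.0),
                               NeedleGeometry(entry_offset_mm=15.0))
        assert plan.angle_deg == pytest.approx(45.0)

    def test_path_longer_than_needle_rejected(self):
        geometry = NeedleGeometry(entry_offset_mm=15.0, needle_length_mm=90.0)
        with pytest.raises(PlanningError):
            plan_trajectory(_fit(depth=89.0), geometry)

    def test_waypoint_ordering_invariant(self):
        plan = plan_trajectory(_fit(depth=22.0, radius=4.0))
        pos = {wp.label: wp.position_mm for wp in plan.waypoints}
        assert pos["D"] < pos["B"] == pos["E"] < pos["A"] < pos["C"]


class TestPlanDuration:
    def test_hand_summed_worked_example(self):
        plan = plan_trajectory(_fit(), NeedleGeometry(entry_offset_mm=15.0))
        oracle = 29 / 45 + 4 / 20 + 5 / 10 + 10 / 10 + 5 / 10
        assert plan_duration(plan) == pytest.approx(oracle, abs=1e-12)
        assert plan_duration(plan) <= 3.0

    @settings(derandomize=True, deadline=None)
    @given(st.floats(min_value=12.0, max_value=30.0),
           st.floats(min_value=1.5, max_value=6.0))
    def test_matches_independent_leg_sum_oracle(self, depth, radius):
        plan = plan_trajectory(_fit(depth=depth, radius=radius))
        total, position = 0.0, 0.0
        for wp in plan.waypoints:
            total += abs(wp.position_mm - position) / wp.speed_mm_s
            position = wp.position_mm
        assert plan_duration(plan) == pytest.approx(total, abs=1e-9)

    def test_degenerate_plan_single_leg(self):
        wps = (Waypoint("A", 29.0, 45.0), Waypoint("B", 25.0, 20.0),
               Waypoint("C", 30.0, 10.0), Waypoint("D", 20.0, 10.0),
               Waypoint("E", 25.0, 10.0))
        plan = NeedlePlan(angle_deg=53.13, anterior_wall_mm=20.0,
                          centroid_mm=25.0, posterior_wall_mm=30.0,
                          waypoints=wps)
        first_leg_only = 29.0 / 45.0
        assert plan_duration(plan) >= first_leg_only


class TestFlashbackSample:
    def test_punctured_tip_at_centroid_reads_blood(self):
        assert flashback_sample(25.0, 20.0, 30.0, punctured=True)

    def test_unpunctured_tip_reads_no_blood(self):
        assert not flashback_sample(25.0, 20.0, 30.0, punctured=False)

    def test_retracted_tip_reads_no_blood(self):
        assert not flashback_sample(0.0, 20.0, 30.0, punctured=True)


def hand_stepped_trace(plan, radius, capacity, rate=100.0):
    """Independent step-by-step kinematic oracle at the sample rate.

    Walks the waypoint legs in v*dt steps, tracks anterior-wall
    deflection with recovery on reversal, punctures when deflection
    exceeds capacity, and stops at the first intra-luminal sample after
    puncture.  Returns (punctured, stop_position or None, leg_label).
    """
    dt = 1.0 / rate
    anterior = plan.centroid_mm - radius
    posterior = plan.centroid_mm + radius
    s, punctured = 0.0, False
    for wp in plan.waypoints:
        direction = 1.0 if wp.position_mm >= s else -1.0
        while (s - wp.position_mm) * direction < -1e-12:
            s += direction * min(wp.speed_mm_s * dt, abs(wp.position_mm - s))
            if not punctured and s > anterior and (s - anterior) > capacity:
                punctured = True
            if punctured and anterior < s < posterior:
                return True, s, wp.label
    return punctured, None, None


class TestSimulateInsertion:
    def test_zero_tenting_immediate_success(self):
        plan = plan_trajectory(_fit(), NeedleGeometry(entry_offset_mm=15.0))
        res = simulate_insertion(plan, _vein_instance(), _no_noise(), 0.0,
                                 seed=1)
        assert res.success and res.attempts == 1
        assert plan.anterior_wall_mm < res.stop_position_mm <= 29.0
        assert not res.posterior_wall_punctured

    def test_matches_hand_stepped_trace_under_heavy_tenting(self):
        """9.5 mm capacity on a 10 mm vessel defeats the first advance leg
        (max deflection 9 mm at waypoint A) but punctures on the dither
        leg to C, exactly as the step oracle predicts."""
        plan = plan_trajectory(_fit(), NeedleGeometry(entry_offset_mm=15.0))
        capacity = 9.5
        res = simulate_insertion(plan, _vein_instance(tenting=capacity),
                                 _no_noise(tenting=capacity), 0.0, seed=2)
        punctured, stop, leg = hand_stepped_trace(plan, 5.0, capacity)
        assert punctured and leg == "C"
        assert res.success
        assert res.stop_position_mm == pytest.approx(stop, abs=1e-9)
        assert res.stop_position_mm > 29.0  # beyond A, on the dither leg

    def test_capacity_beyond_chord_fails_every_attempt(self):
        plan = plan_trajectory(_fit(), NeedleGeometry(entry_offset_mm=15.0))
        res = simulate_insertion(plan, _vein_instance(tenting=11.0),
                                 _no_noise(tenting=11.0), 0.0, seed=3)
        assert not res.success
        assert res.attempts == TissueParams().max_attempts_per_trial

    def test_large_lateral_error_misses_lumen(self):
        plan = plan_trajectory(_fit(), NeedleGeometry(entry_offset_mm=15.0))
        res = simulate_insertion(plan, _vein_instance(), _no_noise(), 8.0,
                                 seed=4)
        assert not res.success and res.flashback_time_s is None

    def test_deterministic_given_seed(self):
        plan = plan_trajectory(_fit())
        tissue = TissueParams(tenting_capacity_mm=4.0)
        a = simulate_insertion(plan, _vein_instance(tenting=4.0), tissue,
                               0.5, seed=11)
        b = simulate_insertion(plan, _vein_instance(tenting=4.0), tissue,
                               0.5, seed=11)
        assert a == b

    def test_invalid_seed_rejected(self):
        plan = plan_trajectory(_fit())
        with pytest.raises(ValueError):
            simulate_insertion(plan, _vein_instance(), _no_noise(), 0.0,
                               seed=None)


class TestInsertionInvariants:
    def test_stop_on_flashback_and_posterior_safety_1000_trials(self):
        """Every successful stop is intra-luminal and never beyond C; with
        kickback and lateral error inside the insertion window the
        posterior wall survives all 1000 seeded trials."""
        plan = plan_trajectory(_fit(), NeedleGeometry(entry_offset_mm=15.0))
        anatomy = _vein_instance(tenting=3.0)
        rng = np.random.default_rng(0)
        for seed in range(1000):
            lateral = rng.uniform(-1.0, 1.0)  # inside the 1 mm window
            tissue = TissueParams(tenting_capacity_mm=3.0,
                                  kickback_sd_mm=0.0, kickback_sd_deg=0.0,
                                  capacity_jitter_sd=0.3)
            res = simulate_insertion(plan, anatomy, tissue, lateral,
                                     seed=seed)
            assert not res.posterior_wall_punctured
            if res.success:
                assert res.tip_in_lumen_at_stop
                assert res.stop_position_mm <= plan.posterior_wall_mm

    def test_first_leg_puncture_stops_before_waypoint_a(self):
        plan = plan_trajectory(_fit(), NeedleGeometry(entry_offset_mm=15.0))
        for capacity in (0.5, 2.0, 5.0, 7.5):
            res = simulate_insertion(plan, _vein_instance(tenting=capacity),
                                     _no_noise(tenting=capacity), 0.0, seed=6)
            assert res.success
            assert res.stop_position_mm <= 29.0 + 1e-9

    @staticmethod
    def _success_rate(plan, anatomy, tenting, lateral, n=500):
        wins = 0
        for seed in range(n):
            tissue = TissueParams(tenting_capacity_mm=tenting,
                                  kickback_sd_mm=0.3, kickback_sd_deg=0.3,
                                  capacity_jitter_sd=0.3,
                                  max_attempts_per_trial=2)
            if simulate_insertion(plan, anatomy, tissue, lateral,
                                  seed=seed).success:
                wins += 1
        return wins / n

    def test_success_non_increasing_in_tenting(self):
        plan = plan_trajectory(_fit(), NeedleGeometry(entry_offset_mm=15.0))
        rates = [self._success_rate(plan, _vein_instance(tenting=c), c, 0.0)
                 for c in (2.0, 6.0, 9.0, 12.0)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_success_non_increasing_in_lateral_error(self):
        plan = plan_trajectory(_fit(), NeedleGeometry(entry_offset_mm=15.0))
        anatomy = _vein_instance(tenting=6.0)
        rates = [self._success_rate(plan, anatomy, 6.0, err)
                 for err in (0.0, 2.0, 4.0, 4.8)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))


def _toy_frame(pixels):
    return BModeFrame(pixels=np.asarray(pixels, dtype=np.uint8),
                      pixel_spacing_mm=1.0, probe_lateral_mm=0.0,
                      probe_cc_mm=0.0)


class TestConfirmByImage:
    def test_identical_frames_not_confirmed(self):
        pre = _toy_frame(np.full((5, 5), 100))
        assert confirm_by_image(pre, pre, (0.0, 2.5), 5.0) is False

    def test_bright_streak_in_roi_confirmed_hand_computed(self):
        """3-px streak of +120 in a 5x5 ROI: mean |diff| over the 25-px ROI
        is 3*120/25 = 14.4, above the default threshold of 8."""
        pre = np.full((5, 5), 100)
        post = pre.copy()
        post[2, 1:4] += 120
        pre_f, post_f = _toy_frame(pre), _toy_frame(post)
        assert abs(np.abs(post - pre).mean() - 14.4) < 1e-12
        assert confirm_by_image(pre_f, post_f, (0.0, 2.5), 5.0) is True

    def test_change_outside_roi_not_confirmed(self):
        pre = np.full((40, 40), 100)
        post = pre.copy()
        post[35:, 35:] = 250  # far corner, outside the 3 mm ROI
        assert confirm_by_image(_toy_frame(pre), _toy_frame(post),
                                (-15.0, 5.0), 3.0) is False

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confirm_by_image(_toy_frame(np.zeros((5, 5))),
                             _toy_frame(np.zeros((6, 6))), (0, 0), 2.0)
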