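"""Curving rate, bearing, segment extraction, probes and perturbations."""

import math

import numpy as np
import pytest

from klinosim.analysis import (
    CycleSegment,
    aser_aiy_sweep,
    bearing,
    block_gap_junctions,
    curving_rate,
    cycle_segments,
    inhibit_smb,
    klinotaxis_ensemble,
    step_response,
    trajectory_samples,
)
from klinosim.circuit import GAP_AIY, GAP_AIZ
from klinosim.environment import Environment
from klinosim.errors import (
    DegenerateSegmentError,
    InvalidPerturbationError,
    UndefinedBearingError,
)
from klinosim.fixtures import blank_parameters, make_fixture
from klinosim.simulator import AssayConfig, run_assay


def _arc_segment(kappa, arc_len, start_angle=0.0):
    """Three points equally spaced (arc length) on a circle of curvature kappa."""
    r = 1.0 / kappa
    angles = start_angle + np.array([0.0, arc_len, 2 * arc_len]) * kappa
    pts = np.column_stack([r * np.sin(angles), r * (1 - np.cos(angles))])
    return CycleSegment(start=tuple(pts[0]), mid=tuple(pts[1]),
                        end=tuple(pts[2]))


class TestCurvingRate:
    def test_straight_line_has_zero_curving(self):
        seg = CycleSegment((0, 0), (1, 1), (2, 2))
        assert curving_rate(seg) == 0.0

    @pytest.mark.parametrize("kappa", [0.5, 2.0])
    def test_circular_arc_matches_chord_geometry_oracle(self, kappa):
        # on a circle the angle between the two half-window chords is the
        # turning over ONE span (arc s), while the path length is both
        # chords, so the estimator reads kappa/2 in the short-arc limit:
        # exactly kappa * x / (2 sin x) with x = s*kappa/2
        s = 0.1 / kappa
        seg = _arc_segment(kappa, arc_len=s)
        x = s * kappa / 2
        expected = kappa * x / (2 * math.sin(x))
        assert curving_rate(seg) == pytest.approx(expected, rel=1e-9)
        assert curving_rate(seg) == pytest.approx(kappa / 2, rel=0.02)

    def test_mirror_reflection_negates_curving(self):
        seg = _arc_segment(1.5, 0.2)
        mirror = CycleSegment(
            start=(seg.start[0], -seg.start[1]),
            mid=(seg.mid[0], -seg.mid[1]),
            end=(seg.end[0], -seg.end[1]))
        assert curving_rate(mirror) == pytest.approx(-curving_rate(seg))

    def test_degenerate_segment_is_rejected(self):
        with pytest.raises(DegenerateSegmentError):
            curving_rate(CycleSegment((0, 0), (0, 0), (1, 0)))

    def test_rigid_motion_equivariance(self):
        seg = _arc_segment(1.2, 0.3)
        rot, shift = 0.8, np.array([2.0, -1.0])
        R = np.array([[math.cos(rot), -math.sin(rot)],
                      [math.sin(rot), math.cos(rot)]])
        moved = CycleSegment(*(tuple(R @ np.asarray(p) + shift)
                               for p in (seg.start, seg.mid, seg.end)))
        assert curving_rate(moved) == pytest.approx(curving_rate(seg),
                                                    abs=1e-12)


class TestBearing:
    def test_heading_at_peak_gives_zero(self):
        seg = CycleSegment((0, 0), (1, 0), (2, 0))
        assert bearing(seg, peak=(5.0, 0.0)) == 0.0

    def test_peak_left_perpendicular_gives_plus_half_pi(self):
        seg = CycleSegment((0, 0), (1, 0), (2, 0))
        assert bearing(seg, peak=(1.0, 3.0)) == pytest.approx(math.pi / 2)

    def test_moving_away_maps_to_plus_pi(self):
        seg = CycleSegment((1, 0), (2, 0), (3, 0))
        assert bearing(seg, peak=(0.0, 0.0)) == pytest.approx(math.pi)

    def test_midpoint_on_peak_is_undefined(self):
        seg = CycleSegment((0, 0), (1, 0), (2, 0))
        with pytest.raises(UndefinedBearingError):
            bearing(seg, peak=(1.0, 0.0))


class TestCycleSegments:
    def test_count_and_warmup_exclusion(self, gaussian_env, neutral_motor_z):
        params, _ = make_fixture("osc_only")
        duration, T, n = 200.0, params.T, 3
        cfg = AssayConfig(environment=gaussian_env, duration=duration,
                          initial_heading=0.0,
                          initial_motor_z=neutral_motor_z)
        traj = run_assay(params, cfg)
        segs = cycle_segments(traj, T, n=n)
        expected = int((duration / T - n) // n) - 1
        assert len(segs) == expected
        # first segment starts after the three warm-up cycles
        assert segs[0].start[0] == traj.x[int(round(n * T / traj.dt))]

    def test_straight_mover_samples_have_zero_curving(self, gaussian_env,
                                                      neutral_motor_z):
        params, _ = make_fixture("dead")
        cfg = AssayConfig(environment=gaussian_env, duration=120.0,
                          initial_heading=2.0,
                          initial_motor_z=neutral_motor_z)
        traj = run_assay(params, cfg)
        rows = trajectory_samples(traj, gaussian_env, params.T)
        assert rows
        assert all(abs(r["curving"]) < 1e-9 for r in rows)


class TestPerturbations:
    @pytest.fixture()
    def params(self):
        p = blank_parameters(w_osc=2.0)
        p.w_on = {"AIYL": 3.0, "AIYR": 2.0}
        p.w_off = {"AIYL": -4.0, "AIYR": -5.0}
        p.w_chem = dict(p.w_chem)
        p.w_chem[("AIZL", "SMBDL")] = p.w_chem[("AIZL", "SMBVL")] = 6.0
        p.w_chem[("AIZR", "SMBDR")] = p.w_chem[("AIZR", "SMBVR")] = -2.0
        p.w_self = {"left": 1.0, "right": 2.0}
        p.g = {GAP_AIY: 1.0, GAP_AIZ: 0.5}
        return p

    def test_sweep_first_variant_is_identity(self, params):
        variants = aser_aiy_sweep(params)
        assert variants[0].to_dict() == params.to_dict()

    def test_sweep_increments_are_exact(self, params):
        variants = aser_aiy_sweep(params, increment=1.5, n_steps=15)
        assert len(variants) == 16
        for k, var in enumerate(variants):
            assert var.w_off["AIYL"] == params.w_off["AIYL"] + 1.5 * k
            assert var.w_off["AIYR"] == params.w_off["AIYR"] + 1.5 * k
            # everything else untouched
            assert var.w_on == params.w_on
            assert var.w_chem == params.w_chem

    def test_inhibit_smb_factor_one_is_identity(self, params):
        assert inhibit_smb(params, factor=1.0).to_dict() == params.to_dict()

    def test_inhibit_smb_scales_only_motor_synapses(self, params):
        out = inhibit_smb(params, factor=0.9)
        assert out.w_chem[("AIZL", "SMBDL")] == pytest.approx(6.0 * 0.9)
        assert out.w_self["left"] == pytest.approx(0.9)
        assert out.w_chem[("AIYL", "AIZL")] == params.w_chem[("AIYL", "AIZL")]
        assert out.w_on == params.w_on and out.theta == params.theta

    def test_inhibit_smb_bias_mode(self, params):
        out = inhibit_smb(params, mode="reduce_bias", bias_delta=0.7)
        for n in ("SMBDL", "SMBVL", "SMBDR", "SMBVR"):
            assert out.theta[n] == params.theta[n] - 0.7
        assert out.theta["AIYL"] == params.theta["AIYL"]

    def test_inhibit_smb_invalid_factor(self, params):
        with pytest.raises(InvalidPerturbationError):
            inhibit_smb(params, factor=1.5)
        with pytest.raises(InvalidPerturbationError):
            inhibit_smb(params, factor=0.0)

    def test_block_gap_junctions(self, params):
        blocked = block_gap_junctions(params)
        assert all(g == 0.0 for g in blocked.g.values())
        assert blocked.w_chem == params.w_chem
        assert block_gap_junctions(blocked).to_dict() == blocked.to_dict()


class TestStepResponse:
    def test_zero_magnitude_matches_reference(self):
        params, _ = make_fixture("inhibitory_chain")
        resp = step_response(params, magnitude=0.0, settle_periods=2,
                             total_periods=5)
        np.testing.assert_array_equal(resp.traj.z_state,
                                      resp.reference.z_state)

    def test_positive_step_drives_transient_on_response(self):
        params, _ = make_fixture("inhibitory_chain")
        resp = step_response(params, magnitude=0.05, sign=1,
                             settle_periods=2, total_periods=8)
        t = resp.traj.t
        after = (t > resp.step_time) & (t < resp.step_time + params.N)
        assert resp.traj.z_on[after].max() > 0.0
        # once both averaging windows have passed the step, z_on returns to 0
        late = t > resp.step_time + (params.N + params.M) + 1.0
        assert resp.traj.z_on[late].max() == pytest.approx(0.0, abs=1e-12)

    def test_double_inhibition_raises_second_interneuron_release(self):
        # ASER -(inhibitory)-> AIYL -(inhibitory)-> AIZL: an OFF step
        # (concentration drop) disinhibits AIZL, raising its release
        params, _ = make_fixture("inhibitory_chain")
        resp = step_response(params, magnitude=0.05, sign=-1,
                             settle_periods=2, total_periods=8)
        k_aizl = 2  # canonical neuron order: AIYL, AIYR, AIZL, ...
        i_step = int(round(resp.step_time / resp.traj.dt))
        baseline = resp.traj.z_state[i_step - 1, k_aizl]
        peak = resp.traj.z_state[i_step:, k_aizl].max()
        assert peak > baseline + 1e-3

    def test_gap_block_changes_step_response(self):
        params, _ = make_fixture("inhibitory_chain")
        params.g = {GAP_AIY: 1.5, GAP_AIZ: 1.0}
        blocked = block_gap_junctions(params)
        r1 = step_response(params, 0.05, sign=-1, settle_periods=2,
                           total_periods=6)
        r2 = step_response(blocked, 0.05, sign=-1, settle_periods=2,
                           total_periods=6)
        assert np.max(np.abs(r1.traj.z_state - r2.traj.z_state)) > 0.0

    def test_half_cycle_delay_shifts_the_step_time(self):
        params, _ = make_fixture("inhibitory_chain")
        r0 = step_response(params, 0.05, settle_periods=2, total_periods=4)
        r_half = step_response(params, 0.05, phase_delay=0.5,
                               settle_periods=2, total_periods=4)
        assert r_half.step_time - r0.step_time == pytest.approx(params.T / 2)


def test_signed_curving_components_balance_for_evolved_circuit(gaussian_env):
    """Leftward and rightward curving components of a competent circuit
    grow as the translational gradient turns negative, while their average
    stays near zero (dorsoventral symmetry)."""
    from klinosim.presets import best_constrained_parameters

    params = best_constrained_parameters()
    stats = klinotaxis_ensemble(params, gaussian_env, n_runs=400, seed=9)
    sc = stats.signed_components("trans_grad", bins=6).dropna()
    strong = sc[sc["positive"] > 1.0]
    assert len(strong) >= 2
    assert (strong["average"].abs() < 0.3 * strong["positive"]).all()
    # steering is vigorous down-gradient, gentle up-gradient
    assert sc["positive"].iloc[0] > 5 * sc["positive"].iloc[-1]


def test_ensemble_of_straight_movers_has_flat_curving(gaussian_env):
    params, _ = make_fixture("dead")
    stats = klinotaxis_ensemble(params, gaussian_env, n_runs=5,
                                run_duration=100.0, seed=4)
    assert len(stats.samples) > 0
    assert np.allclose(stats.samples["curving"], 0.0, atol=1e-9)
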