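"""Helical parameter extraction: frames, steps, axes, ensembles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import helixloop as hl
from helixloop.helix_analyze import (
    axis_and_helical_params,
    bp_parameters,
    fit_base_frame,
    fluctuation_summary,
    parameter_series,
    step_parameters,
    step_screw_axis,
)
from helixloop.helix_build import BpFrame, IntraBpParams, StepParams, advance_frame
from helixloop.templates import BASE_TEMPLATES
from conftest import random_frame

finite_angle = st.floats(-45.0, 45.0)
finite_shift = st.floats(-2.0, 2.0)


class TestFitBaseFrame:
    def test_identity(self):
        tpl = BASE_TEMPLATES["G"]
        fit = fit_base_frame(dict(tpl), tpl)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.frame.triad, np.eye(3), atol=1e-12)
        assert np.allclose(fit.frame.origin, 0.0, atol=1e-12)

    def test_known_rigid_transform_recovered(self, rng):
        tpl = BASE_TEMPLATES["C"]
        for _ in range(20):
            rot = Rotation.random(random_state=rng).as_matrix()
            trans = rng.normal(0, 10, 3)
            moved = {n: rot @ xyz + trans for n, xyz in tpl.items()}
            fit = fit_base_frame(moved, tpl)
            assert np.abs(fit.frame.triad - rot).max() < 1e-10
            assert np.abs(fit.frame.origin - trans).max() < 1e-10
            assert fit.rmsd < 1e-10

    def test_noisy_fit_error_scales_with_noise(self, rng):
        """With 0.1 A isotropic noise on a planar base the fitted RMSD
        matches the sigma*sqrt((3k-6)/k) degrees-of-freedom prediction and
        the frame stays within a few degrees of the truth on average."""
        tpl = BASE_TEMPLATES["A"]
        k = len(tpl)
        sigma = 0.1
        angles, rmsds = [], []
        for _ in range(100):
            rot = Rotation.random(random_state=rng).as_matrix()
            trans = rng.normal(0, 5, 3)
            moved = {
                n: rot @ xyz + trans + rng.normal(0, sigma, 3) for n, xyz in tpl.items()
            }
            fit = fit_base_frame(moved, tpl)
            err = Rotation.from_matrix(fit.frame.triad.T @ rot).magnitude()
            angles.append(np.degrees(err))
            rmsds.append(fit.rmsd)
        expected_rmsd = sigma * np.sqrt((3 * k - 6) / k)
        assert np.mean(rmsds) == pytest.approx(expected_rmsd, rel=0.15)
        assert np.mean(angles) < 3.0

    def test_collinear_atoms_rejected(self):
        tpl = {"A1": np.array([0.0, 0, 0]), "A2": np.array([1.0, 0, 0]),
               "A3": np.array([2.0, 0, 0])}
        with pytest.raises(ValueError, match="collinear"):
            fit_base_frame(dict(tpl), tpl)

    def test_mirror_image_rejected(self):
        tpl = BASE_TEMPLATES["G"]
        # reflect through the xy-plane plus an out-of-plane marker so the
        # mirrored set cannot be reached by any proper rotation
        mirrored = {n: np.array([x, y, -z]) for n, (x, y, z) in
                    ((n, tuple(v)) for n, v in tpl.items())}
        with pytest.raises(ValueError, match="reflection"):
            fit_base_frame(mirrored, tpl)

    def test_too_few_atoms_rejected(self):
        tpl = BASE_TEMPLATES["G"]
        two = {k: tpl[k] for k in list(tpl)[:2]}
        with pytest.raises(ValueError):
            fit_base_frame(two, two)


class TestBpParameters:
    def test_identical_frames_all_zero(self, rng):
        f = random_frame(rng)
        res = bp_parameters(f, f)
        assert np.allclose(
            [*res.params.translation(), *res.params.rotation_deg()], 0.0, atol=1e-12
        )
        assert not res.broken

    def test_pure_propeller(self):
        f1 = BpFrame(origin=np.zeros(3), triad=np.eye(3))
        rot = Rotation.from_euler("y", -20, degrees=True).as_matrix()
        f2 = BpFrame(origin=np.zeros(3), triad=rot)
        res = bp_parameters(f1, f2)
        assert res.params.propeller == pytest.approx(-20.0, abs=1e-10)
        assert res.params.buckle == pytest.approx(0.0, abs=1e-10)
        assert res.params.opening == pytest.approx(0.0, abs=1e-10)

    def test_strand_exchange_flips_signs(self, rng):
        for _ in range(10):
            f1 = random_frame(rng)
            v = rng.normal(0, 10, 3)
            w = rng.normal(0, 0.5, 3)
            t2 = f1.triad @ Rotation.from_rotvec(np.radians(v)).as_matrix()
            f2 = BpFrame(origin=f1.origin + rng.normal(0, 1, 3), triad=t2)
            a = bp_parameters(f1, f2).params
            b = bp_parameters(f2, f1).params
            assert np.allclose(a.rotation_deg(), -b.rotation_deg(), atol=1e-9)
            assert np.allclose(a.translation(), -b.translation(), atol=1e-9)

    def test_large_rotation_flags_broken_pair(self):
        f1 = BpFrame(origin=np.zeros(3), triad=np.eye(3))
        rot = Rotation.from_euler("z", 120, degrees=True).as_matrix()
        assert bp_parameters(f1, BpFrame(origin=np.zeros(3), triad=rot)).broken


class TestStepParameters:
    def test_pure_twist_step(self):
        f1 = BpFrame(origin=np.zeros(3), triad=np.eye(3))
        f2 = advance_frame(f1, StepParams(rise=3.4, twist=36.0))
        p = step_parameters(f1, f2)
        assert np.allclose(
            [p.shift, p.slide, p.rise, p.tilt, p.roll, p.twist],
            [0, 0, 3.4, 0, 0, 36.0],
            atol=1e-12,
        )

    def test_pure_roll_step(self):
        f1 = BpFrame(origin=np.zeros(3), triad=np.eye(3))
        f2 = advance_frame(f1, StepParams(rise=3.4, twist=0.0, roll=6.0))
        p = step_parameters(f1, f2)
        assert p.roll == pytest.approx(6.0, abs=1e-12)
        assert p.twist == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        shift=finite_shift, slide=finite_shift, rise=st.floats(1.0, 5.0),
        tilt=finite_angle, roll=finite_angle, twist=st.floats(-60.0, 60.0),
    )
    def test_generator_analyzer_inverse(self, shift, slide, rise, tilt, roll, twist):
        """Rebuild-then-extract is the identity for any physical step."""
        rng = np.random.default_rng(42)
        f1 = random_frame(rng)
        step = StepParams(shift, slide, rise, tilt, roll, twist)
        f2 = advance_frame(f1, step)
        p = step_parameters(f1, f2)
        assert np.abs(p.translation() - step.translation()).max() < 1e-8
        assert np.abs(p.rotation_deg() - step.rotation_deg()).max() < 1e-8

    def test_invariant_under_global_rigid_motion(self, rng):
        f1 = random_frame(rng)
        f2 = advance_frame(f1, StepParams(0.5, -0.3, 3.3, 2.0, 6.0, 34.0))
        rot = Rotation.random(random_state=rng).as_matrix()
        trans = rng.normal(0, 20, 3)
        g1 = BpFrame(origin=rot @ f1.origin + trans, triad=rot @ f1.triad)
        g2 = BpFrame(origin=rot @ f2.origin + trans, triad=rot @ f2.triad)
        p, q = step_parameters(f1, f2), step_parameters(g1, g2)
        assert np.abs(p.translation() - q.translation()).max() < 1e-9
        assert np.abs(p.rotation_deg() - q.rotation_deg()).max() < 1e-9


class TestAxisParams:
    def test_ideal_b_form(self):
        df = axis_and_helical_params(hl.straight_duplex(25, form="B"))
        assert df[["Xdisp", "Ydisp", "inclination", "tip"]].abs().max().max() < 1e-9
        assert np.allclose(df["H-twist"], 36.0, atol=1e-9)
        assert np.allclose(df["H-rise"], 3.4, atol=1e-9)

    def test_constructed_displacement_recovered(self):
        df = axis_and_helical_params(
            hl.helical_duplex(30, h_twist=32.0, h_rise=2.8, xdisp=-4.0, ydisp=1.5)
        )
        assert np.allclose(df["Xdisp"], -4.0, atol=1e-6)
        assert np.allclose(df["Ydisp"], 1.5, atol=1e-6)

    def test_constructed_inclination_tip_recovered(self):
        df = axis_and_helical_params(
            hl.helical_duplex(30, h_twist=33.0, h_rise=2.9, inclination=10.0, tip=-4.0)
        )
        assert np.allclose(df["inclination"], 10.0, atol=1e-6)
        assert np.allclose(df["tip"], -4.0, atol=1e-6)

    def test_screw_axis_against_fixed_point_oracle(self, rng):
        """The step screw axis maps axis points onto themselves plus the
        axial advance (defining property of a screw transform)."""
        f1 = random_frame(rng)
        f2 = advance_frame(f1, StepParams(0.4, -0.6, 3.2, 3.0, 7.0, 34.8))
        axis, point, h_twist, h_rise, flagged = step_screw_axis(f1, f2)
        assert not flagged
        r_lab = f2.triad @ f1.triad.T
        d = f2.origin - r_lab @ f1.origin
        for lam in (-5.0, 0.0, 5.0):
            p = point + lam * axis
            image = r_lab @ p + d
            assert np.abs(image - (p + h_rise * axis)).max() < 1e-9

    def test_straight_translation_flagged(self):
        f1 = BpFrame(origin=np.zeros(3), triad=np.eye(3))
        f2 = BpFrame(origin=np.array([0, 0, 3.4]), triad=np.eye(3))
        f3 = BpFrame(origin=np.array([0, 0, 6.8]), triad=np.eye(3))
        df = axis_and_helical_params(hl.DuplexPath(frames=(f1, f2, f3)))
        assert df["flagged"].all()
        assert np.allclose(df["H-rise"], 3.4, atol=1e-12)


class TestParameterSeries:
    def test_discard_fraction(self):
        ens = hl.sample_trajectory(8, 300, rng=0)
        table = parameter_series(list(ens.snapshots), discard=1.0 / 3.0, axis=False)
        assert table.n_snapshots == 200

    def test_constant_trajectory_constant_series(self):
        path = hl.straight_duplex(10)
        table = parameter_series([path] * 12, discard=0.0, axis=False)
        twist = table.series("step", "twist").to_numpy()
        assert np.ptp(twist) < 1e-12

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            parameter_series([hl.straight_duplex(5), hl.straight_duplex(6)])

    def test_intra_parameters_from_strand_frames(self, rng):
        ens = hl.sample_trajectory(
            10, 30,
            intra_means=IntraBpParams(propeller=-11.0),
            intra_sds=IntraBpParams(0.05, 0.05, 0.05, 1.0, 2.0, 1.0),
            rng=rng,
        )
        table = parameter_series(
            list(ens.snapshots), strand_frames=list(ens.strand_frames),
            discard=0.0, axis=False,
        )
        prop = table.series("bp", "propeller").to_numpy().ravel()
        assert abs(prop.mean() + 11.0) < 3 * 2.0 / np.sqrt(prop.size)


class TestFluctuationSummary:
    def _table(self, roll_sd, rng, n_snap=120):
        ens = hl.sample_trajectory(
            10, n_snap,
            step_sds=StepParams(0.1, 0.1, 0.1, 1.0, roll_sd, 2.0),
            rng=rng,
        )
        return parameter_series(list(ens.snapshots), discard=0.0, axis=False)

    def test_self_comparison_is_zero(self, rng):
        t = self._table(5.0, rng)
        summary = fluctuation_summary(t, t)
        assert np.allclose(summary.table["delta_sd"], 0.0)

    def test_known_sd_difference_recovered(self):
        t_hi = self._table(5.0, np.random.default_rng(1))
        t_lo = self._table(4.0, np.random.default_rng(2))
        summary = fluctuation_summary(t_hi, t_lo)
        row = summary.table[summary.table.parameter == "roll"].iloc[0]
        assert row.delta_sd == pytest.approx(1.0, abs=0.15)
        assert row.se_delta_sd > 0

    def test_constant_series_flagged_degenerate(self):
        path = hl.straight_duplex(8)
        t = parameter_series([path] * 20, discard=0.0, axis=False)
        summary = fluctuation_summary(t, t)
        assert summary.table["degenerate"].all()

    def test_too_few_snapshots_flags_blocks_unavailable(self):
        path = hl.straight_duplex(8)
        t = parameter_series([path] * 5, discard=0.0, axis=False)
        summary = fluctuation_summary(t, t)
        assert not summary.blocks_available
        assert np.isnan(summary.table["se_delta_sd"]).all()

    def test_mismatched_parameter_sets_rejected(self, rng):
        ens = hl.sample_trajectory(8, 15, rng=rng)
        with_intra = parameter_series(
            list(ens.snapshots), strand_frames=list(ens.strand_frames),
            discard=0.0, axis=False,
        )
        without = parameter_series(list(ens.snapshots), discard=0.0, axis=False)
        with pytest.raises(ValueError):
            fluctuation_summary(with_intra, without)
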