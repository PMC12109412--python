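"""Minicircle topology, curvature/register profiles and kink detection."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import helixloop as hl
from helixloop.helix_analyze import parameter_series
from helixloop.helix_build import BpFrame, DuplexPath, IntraBpParams, KinkSpec, StepParams
from helixloop.minicircle_analyze import detect_kinks, mean_curvature_profile


def untwisted_circle(n: int, x_sign: float = 1.0) -> DuplexPath:
    """A closed circle whose bp x axes all point radially (x_sign=+1:
    toward the center) with no accumulated twist — a register test rig."""
    radius = n * 3.4 / (2 * np.pi)
    frames = []
    for k in range(n):
        a = 2 * np.pi * k / n
        radial = np.array([np.cos(a), np.sin(a), 0.0])
        tangent = np.array([-np.sin(a), np.cos(a), 0.0])
        x = -x_sign * radial  # x_sign=+1 -> x toward center
        y = np.cross(tangent, x)
        frames.append(
            BpFrame(origin=radius * radial, triad=np.column_stack([x, y, tangent]),
                    bp_id=k + 1)
        )
    return DuplexPath(frames=tuple(frames), closed=True)


class TestWrithe:
    def test_planar_polygon_is_zero(self):
        assert abs(hl.writhe(hl.minicircle(93, turns=9).origins)) < 1e-6

    def test_rigid_rotation_invariance(self, rng):
        path = hl.deform_out_of_plane(hl.minicircle(93, turns=9), 10.0, rng=rng)
        w0 = hl.writhe(path.origins)
        rot = Rotation.random(random_state=rng).as_matrix()
        w1 = hl.writhe(path.origins @ rot.T + rng.normal(0, 50, 3))
        assert abs(w0 - w1) < 1e-9

    def test_against_refinement_oracle(self):
        """The polygon writhe of an out-of-plane curve converges to the
        value on a much finer discretization of the same smooth curve."""

        def curve(ts):
            return np.column_stack(
                [np.cos(ts), np.sin(2 * ts) / 1.5, 0.6 * np.sin(ts)]
            )

        coarse = hl.writhe(curve(np.linspace(0, 2 * np.pi, 120, endpoint=False)))
        fine = hl.writhe(curve(np.linspace(0, 2 * np.pi, 2400, endpoint=False)))
        assert abs(coarse - fine) < 1e-3

    def test_open_path_rejected(self):
        with pytest.raises(ValueError):
            hl.writhe(np.zeros((5, 3)), closed=False)


class TestLinkingNumber:
    @pytest.mark.parametrize("turns", [9, 10])
    def test_uniform_planar_circle(self, turns):
        topo = hl.linking_number(hl.minicircle(93, turns=turns))
        assert topo.Lk == turns
        assert topo.Tw == pytest.approx(turns, abs=1e-9)
        assert abs(topo.Wr) < 1e-9

    def test_open_path_rejected(self):
        with pytest.raises(ValueError):
            hl.linking_number(hl.straight_duplex(10))

    def test_conserved_under_deformation(self, rng):
        """Smooth out-of-plane deformation without strand passage changes
        Tw and Wr but not their sum."""
        base = hl.minicircle(93, turns=9)
        for _ in range(5):
            topo = hl.linking_number(hl.deform_out_of_plane(base, 10.0, rng=rng))
            assert abs(topo.Lk_real - 9.0) < 0.01

    def test_whites_theorem_against_gauss_oracle(self, rng):
        """Tw + Wr equals the Gauss linking integral of the axis with an
        offset ribbon curve."""
        base = hl.minicircle(93, turns=9)
        for _ in range(3):
            path = hl.deform_out_of_plane(base, 8.0, rng=rng)
            topo = hl.linking_number(path)
            origins = path.origins
            tang = np.roll(origins, -1, axis=0) - origins
            tang /= np.linalg.norm(tang, axis=1, keepdims=True)
            us = []
            for i, f in enumerate(path.frames):
                u = f.x - (f.x @ tang[i]) * tang[i]
                us.append(u / np.linalg.norm(u))
            lk_gauss = hl.gauss_linking_number(origins, origins + 1.0 * np.array(us))
            assert abs(topo.Lk_real - lk_gauss) < 1e-3


class TestCurvature:
    def test_ideal_circle_uniform_exterior_angle(self):
        curv = hl.curvature_profile(hl.minicircle(93, turns=9))
        assert np.allclose(curv, 360.0 / 93.0, atol=1e-9)

    def test_open_path_rejected(self):
        with pytest.raises(ValueError):
            hl.curvature_profile(hl.straight_duplex(20))

    def test_total_curvature_at_least_full_turn(self, rng):
        path = hl.deform_out_of_plane(hl.minicircle(93, turns=9), 10.0, rng=rng)
        assert hl.curvature_profile(path).sum() >= 360.0 - 1e-6
        planar = hl.curvature_profile(hl.minicircle(93, turns=9))
        assert planar.sum() == pytest.approx(360.0, abs=1e-6)

    def test_injected_roll_spike_peaks_at_that_step(self):
        """An extra 50-degree roll at one step shows up as a curvature
        peak there and baseline elsewhere."""
        frames = [BpFrame(origin=np.zeros(3), triad=np.eye(3), bp_id=1)]
        from helixloop.helix_build import advance_frame

        for k in range(92):
            roll = 50.0 if k == 45 else 0.0
            frames.append(
                advance_frame(frames[-1], StepParams(rise=3.4, twist=0.0, roll=roll))
            )
        # close the polygon artificially for the profile by marking closed
        path = DuplexPath(frames=tuple(frames), closed=True)
        curv = hl.curvature_profile(path)
        # the 50-degree turn is shared by the two vertices flanking the
        # kinked step; everywhere else (away from the artificial closing
        # edge) the path is straight
        assert curv[45] + curv[46] == pytest.approx(50.0, abs=1e-6)
        interior = np.delete(curv, [0, 45, 46, 92])
        assert interior.max() < 1e-6


class TestRegister:
    def test_major_groove_inward_reads_minus_90(self):
        """x pointing away from the center means the -x (major groove)
        side faces the bend center: register -90 at every bp."""
        reg = hl.register_profile(untwisted_circle(93, x_sign=-1.0))
        assert np.allclose(reg, -90.0, atol=1e-6)

    def test_minor_groove_inward_reads_plus_90(self):
        reg = hl.register_profile(untwisted_circle(93, x_sign=1.0))
        assert np.allclose(reg, 90.0, atol=1e-6)

    def test_values_in_half_open_interval(self, rng):
        path = hl.deform_out_of_plane(hl.minicircle(93, turns=9), 6.0, rng=rng)
        reg = hl.register_profile(path)
        ok = ~np.isnan(reg)
        assert ((reg[ok] > -180.0) & (reg[ok] <= 180.0)).all()

    def test_flipping_x_convention_flips_sign(self):
        """Flipping the bp x and z axes (keeping a right-handed triad)
        negates every register value."""
        path = untwisted_circle(31, x_sign=-1.0)
        flipped_frames = tuple(
            BpFrame(
                origin=f.origin,
                triad=np.column_stack([-f.x, f.y, -f.z]),
                bp_id=f.bp_id,
            )
            for f in path.frames
        )
        flipped = DuplexPath(frames=flipped_frames, closed=True)
        a = hl.register_profile(path)
        b = hl.register_profile(flipped)
        assert np.allclose(a, -b, atol=1e-6)

    def test_zero_curvature_is_undefined(self):
        # a closed path with two long straight stretches: register is NaN
        # only where curvature falls below the floor
        pts = np.array(
            [[x, 0.0, 0.0] for x in range(12)]
            + [[11.0, 1.0, 0.0]]
            + [[x, 2.0, 0.0] for x in range(11, -1, -1)]
            + [[-1.0, 1.0, 0.0]]
        )
        frames = []
        n = len(pts)
        for k in range(n):
            t = pts[(k + 1) % n] - pts[k]
            t = t / np.linalg.norm(t)
            x = np.array([0.0, 0.0, 1.0])
            x = x - (x @ t) * t
            x /= np.linalg.norm(x)
            frames.append(
                BpFrame(origin=pts[k], triad=np.column_stack([x, np.cross(t, x), t]),
                        bp_id=k + 1)
            )
        path = DuplexPath(frames=tuple(frames), closed=True)
        reg = hl.register_profile(path)
        assert np.isnan(reg).any()
        assert (~np.isnan(reg)).any()


def kink_table(kinks=(), n_snapshots=150, seed=5):
    """Parameter table of a synthetic 93-bp ensemble with optional
    injected kinks, via the full sampling -> extraction pipeline."""
    ens = hl.sample_trajectory(
        93,
        n_snapshots,
        step_means=StepParams(rise=3.4, twist=34.8, roll=0.0),
        step_sds=StepParams(0.2, 0.2, 0.2, 3.0, 5.0, 4.0),
        intra_means=IntraBpParams(propeller=-10.0),
        intra_sds=IntraBpParams(0.1, 0.1, 0.1, 4.0, 6.0, 3.0),
        kinks=tuple(kinks),
        rng=seed,
    )
    return parameter_series(
        list(ens.snapshots),
        strand_frames=list(ens.strand_frames),
        discard=1.0 / 3.0,
        axis=False,
    )


class TestDetectKinks:
    def test_unperturbed_ensemble_has_no_calls(self):
        assert detect_kinks(kink_table()) == []

    def test_type_ii_signature_called_with_exact_range(self):
        table = kink_table([KinkSpec(steps=(54, 55, 56, 57, 58), roll=-60.0,
                                     propeller=55.0)])
        calls = detect_kinks(table)
        assert len(calls) == 1
        assert calls[0].step_range == (54, 55, 56, 57, 58)
        assert calls[0].kink_type == "II"
        assert calls[0].min_roll < -30.0
        assert calls[0].max_propeller > 30.0

    def test_type_i_single_step_intact_pairing(self):
        table = kink_table([KinkSpec(steps=(5,), roll=-55.0, propeller=0.0)])
        calls = detect_kinks(table)
        assert len(calls) == 1
        assert calls[0].step_range == (5,)
        assert calls[0].kink_type == "I"
        assert not calls[0].broken_pair

    def test_broken_pair_makes_single_step_type_ii(self):
        table = kink_table([KinkSpec(steps=(20,), roll=-55.0, broken=True)])
        calls = detect_kinks(table)
        assert len(calls) == 1
        assert calls[0].kink_type == "II"
        assert calls[0].broken_pair

    def test_monotone_in_thresholds(self):
        """Loosening the roll threshold or the dwell requirement never
        removes a flagged step."""
        table = kink_table(
            [KinkSpec(steps=(5,), roll=-55.0), KinkSpec(steps=(54, 55), roll=-40.0)]
        )
        strict = detect_kinks(table, roll_threshold=-35.0, min_frames=100)
        loose = detect_kinks(table, roll_threshold=-30.0, min_frames=50)
        strict_steps = {s for c in strict for s in c.step_range}
        loose_steps = {s for c in loose for s in c.step_range}
        assert strict_steps <= loose_steps

    def test_missing_propeller_series_rejected(self):
        ens = hl.sample_trajectory(20, 20, rng=1)
        table = parameter_series(list(ens.snapshots), discard=0.0, axis=False)
        with pytest.raises(ValueError):
            detect_kinks(table)


class TestEnsembleCurvature:
    def test_mean_profile_of_noisy_circles_is_flat(self, rng):
        base = hl.minicircle(61, turns=6)
        paths = [hl.deform_out_of_plane(base, 1.0, rng=rng) for _ in range(20)]
        profile = mean_curvature_profile(paths)
        assert profile.shape == (61,)
        assert abs(profile.mean() - 360.0 / 61.0) < 0.5
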