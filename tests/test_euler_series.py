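"""zyz Euler angles, transfer rotations, periodic differences, gauge potential."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

import helixgauge as hg
from helixgauge import axis_frame, euler_series
from helixgauge.errors import ContentError

from conftest import random_rotation, run_on_points

GRID = [0.1, 1.5, 3.0, 4.5, 5.9]          # covers all four atan2 quadrants
BETAS = [0.05, 0.3, 1.5, 2.8]


class TestZyzMatrix:
    def test_identity(self):
        np.testing.assert_allclose(hg.zyz_matrix(0, 0, 0), np.eye(3), atol=1e-15)

    @pytest.mark.parametrize("alpha,gamma", [(0.3, 0.9), (5.0, 2.2)])
    def test_gimbal_identity(self, alpha, gamma):
        # (alpha, 0, gamma) composes to a single z-rotation by alpha+gamma
        np.testing.assert_allclose(
            hg.zyz_matrix(alpha, 0.0, gamma), hg.zyz_matrix(alpha + gamma, 0.0, 0.0),
            atol=1e-12,
        )

    def test_closed_form_entries(self):
        R = hg.zyz_matrix(0.5, 0.3, 0.2)
        assert R[2, 2] == pytest.approx(np.cos(0.3), abs=1e-15)
        assert R[0, 2] == pytest.approx(np.cos(0.5) * np.sin(0.3), abs=1e-15)

    @pytest.mark.parametrize("alpha", GRID)
    @pytest.mark.parametrize("beta", BETAS)
    def test_against_scipy_oracle(self, alpha, beta):
        gamma = 2.2
        oracle = Rotation.from_euler("ZYZ", [alpha, beta, gamma]).as_matrix()
        np.testing.assert_allclose(hg.zyz_matrix(alpha, beta, gamma), oracle, atol=1e-12)


class TestExtractZyz:
    @pytest.mark.parametrize("alpha", GRID)
    @pytest.mark.parametrize("beta", BETAS)
    @pytest.mark.parametrize("gamma", GRID)
    def test_round_trip_grid(self, alpha, beta, gamma):
        out = hg.extract_zyz(hg.zyz_matrix(alpha, beta, gamma))
        np.testing.assert_allclose(out, (alpha, beta, gamma), atol=1e-10)

    def test_angles_land_in_period(self):
        # alpha = 5.9 exercises the +2pi shift of the negative atan2 branch
        a, b, g = hg.extract_zyz(hg.zyz_matrix(5.9, 0.3, 0.2))
        assert 0 <= a < 2 * np.pi and 0 <= g < 2 * np.pi
        np.testing.assert_allclose((a, b, g), (5.9, 0.3, 0.2), atol=1e-10)

    def test_gimbal_convention(self):
        assert hg.extract_zyz(np.eye(3)) == (0.0, 0.0, 0.0)
        a, b, g = hg.extract_zyz(hg.zyz_matrix(2.0, 0.0, 0.0))
        assert (b, g) == (0.0, 0.0)
        assert a == pytest.approx(2.0, abs=1e-12)

    def test_non_orthogonal_rejected(self):
        with pytest.raises(ValueError):
            hg.extract_zyz(np.diag([1.0, 1.0, 2.0]))

    @given(st.integers(0, 2**31 - 1))
    def test_random_rotation_round_trip(self, seed):
        R = random_rotation(np.random.default_rng(seed))
        a, b, g = hg.extract_zyz(R)
        np.testing.assert_allclose(hg.zyz_matrix(a, b, g), R, atol=1e-9)


class TestPeriodicDifference:
    @pytest.mark.parametrize(
        "pair,expected",
        [
            ((0.1, 0.7), 0.6),
            ((6.2, 0.1), 0.1 + 2 * np.pi - 6.2),     # right-handed period edge
            ((0.1, 5.9), 5.9 - 0.1 - 2 * np.pi),     # left-handed wrap
        ],
    )
    def test_wrap_cases(self, pair, expected):
        assert hg.periodic_difference(np.array(pair))[0] == pytest.approx(expected, abs=1e-12)

    def test_wrap_matches_exhaustive_candidate_oracle(self):
        rng = np.random.default_rng(3)
        theta = rng.uniform(0, 2 * np.pi, size=40)
        diffs = hg.periodic_difference(theta)
        for d, raw in zip(diffs, np.diff(theta)):
            candidates = [raw + k * 2 * np.pi for k in (-2, -1, 0, 1, 2)]
            best = min(candidates, key=abs)
            assert d == pytest.approx(best, abs=1e-12)
            assert -np.pi < d <= np.pi

    @given(st.lists(st.floats(0, 2 * np.pi - 1e-9), min_size=2, max_size=30))
    def test_closed_cycle_sums_to_zero_mod_2pi(self, angles):
        cycle = np.array(angles + [angles[0]])
        total = hg.periodic_difference(cycle).sum()
        assert abs((total + np.pi) % (2 * np.pi) - np.pi) < 1e-9


def _frameset(matrices):
    """FrameSet from explicit row-stacked (n, b, t) matrices."""
    n = len(matrices)
    f = axis_frame.FrameSet(
        tangents=np.stack([m[2] for m in matrices]),
        binormals=np.stack([m[1] for m in matrices]),
        normals=np.stack([m[0] for m in matrices]),
        valid=np.ones(n, dtype=bool),
        site_range=(0, n - 1),
    )
    return f


class TestRotationSeries:
    def test_identical_frames_give_identity(self):
        frames = _frameset([np.eye(3)] * 5)
        series = hg.rotation_series(frames)
        for k in range(4):
            np.testing.assert_allclose(series.relative[k], np.eye(3), atol=1e-12)
            np.testing.assert_allclose(series.cumulative[k], np.eye(3), atol=1e-12)

    def test_constant_z_screw_accumulates(self):
        step = hg.zyz_matrix(0.6, 0, 0)
        mats = [np.linalg.matrix_power(step, k) for k in range(6)]
        series = hg.rotation_series(_frameset(mats))
        for k in range(6):
            np.testing.assert_allclose(
                series.cumulative[k], np.linalg.matrix_power(step, k), atol=1e-9
            )

    def test_reconstructs_frames_from_anchor(self, b_results):
        frames, series = b_results.frames, b_results.rotations
        (start, end), = series.segments
        anchor = frames.matrix(start)
        for k in range(start, end + 1):
            np.testing.assert_allclose(
                series.cumulative[k] @ anchor, frames.matrix(k), atol=1e-9
            )

    def test_random_frames_product_oracle(self):
        rng = np.random.default_rng(5)
        mats = [random_rotation(rng) for _ in range(8)]
        series = hg.rotation_series(_frameset(mats))
        acc = np.eye(3)
        for k in range(7):
            acc = series.relative[k] @ acc
            np.testing.assert_allclose(series.cumulative[k + 1], acc, atol=1e-12)
            np.testing.assert_allclose(series.relative[k], mats[k + 1] @ mats[k].T, atol=1e-12)

    def test_rotations_are_proper(self, b_results):
        series = b_results.rotations
        for k in range(len(series)):
            R = series.relative[k]
            if np.isnan(R).any():
                continue
            np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-9)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_no_consecutive_valid_frames_rejected(self):
        frames = _frameset([np.eye(3)] * 4)
        frames.valid[:] = [True, False, True, False]
        with pytest.raises(ContentError):
            hg.rotation_series(frames)


class TestGaugePotential:
    def test_ideal_duplex_recovers_twist(self, b_spec, b_results):
        assert b_results.mean_gauge == pytest.approx(b_spec.twist, rel=0.02)

    def test_gauge_equals_chi_step(self, b_results):
        euler = b_results.euler
        np.testing.assert_array_equal(euler.d_rho, euler.d_chi)

    def test_differences_in_period(self, b_results):
        for arr in (b_results.euler.d_alpha, b_results.euler.d_beta, b_results.euler.d_chi):
            vals = arr[~np.isnan(arr)]
            assert np.all(vals > -np.pi) and np.all(vals <= np.pi)

    def test_angles_in_period(self, b_results):
        for arr in (b_results.euler.alpha, b_results.euler.beta,
                    b_results.euler.gamma, b_results.euler.chi):
            vals = arr[~np.isnan(arr)]
            assert np.all(vals >= 0) and np.all(vals < 2 * np.pi)

    @pytest.mark.parametrize("n_bp", [10, 20, 50])
    def test_blind_spot_count_is_four(self, n_bp):
        res = hg.ChiralStateModel.from_structure(hg.ideal_duplex(hg.HelixSpec(n_bp=n_bp))).fit()
        assert int(res.euler.evaluable.sum()) == n_bp - 4
        assert res.stats.n_blind == 4
        assert res.stats.n_valid + res.stats.n_invalid + res.stats.n_blind == n_bp

    def test_mirror_antisymmetry(self, b_results, mirror_results):
        assert mirror_results.mean_gauge == pytest.approx(-b_results.mean_gauge, abs=1e-9)

    def test_rotated_structure_same_gauge(self, b_duplex):
        # the gauge potential must not depend on how the PDB frame is oriented
        rng = np.random.default_rng(17)
        rot = random_rotation(rng)
        moved = [
            (cid, [
                hg.NucleotideUnit(
                    u.chain_id, u.residue_index, u.residue_name,
                    {k: rot @ v for k, v in u.atom_coords.items()},
                ) for u in units
            ])
            for cid, units in b_duplex
        ]
        base = hg.ChiralStateModel.from_structure(b_duplex).fit().mean_gauge
        turned = hg.ChiralStateModel.from_structure(moved).fit().mean_gauge
        assert turned == pytest.approx(base, abs=1e-9)
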