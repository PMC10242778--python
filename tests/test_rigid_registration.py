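import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smlm_register import (
    ICPConfig,
    RigidTransform2D,
    apply_transform,
    estimate_rigid,
    icp,
)
from smlm_register.rigid_registration import DegenerateConfigurationError

from conftest import random_table


def grid_search_theta(moving, reference, resolution=1e-3, span=0.1):
    """Independent 1D grid search: for each theta the optimal translation is
    closed-form (centroid difference), so only the angle needs searching."""
    cm, cr = moving.mean(axis=0), reference.mean(axis=0)
    best = (np.inf, None)
    for theta in np.arange(-span, span, resolution):
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        resid = (moving - cm) @ rot.T + cr - reference
        cost = np.sum(resid**2)
        if cost < best[0]:
            best = (cost, theta)
    return best[1]


class TestTransform:
    def test_compose_with_inverse_is_identity(self, rng):
        t = RigidTransform2D(theta=0.7, tx=123.4, ty=-56.7)
        pts = rng.uniform(-1e4, 1e4, size=(100, 2))
        back = t.inverse().apply(t.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_rotation_determinant_is_plus_one(self, rng):
        for theta in rng.uniform(-np.pi, np.pi, size=20):
            assert np.linalg.det(RigidTransform2D(theta=theta).rotation) == pytest.approx(1.0)

    def test_composition_order(self):
        a = RigidTransform2D(theta=0.3, tx=10, ty=0)
        b = RigidTransform2D(theta=-0.1, tx=0, ty=5)
        p = np.array([3.0, 4.0])
        np.testing.assert_allclose(a.compose(b).apply(p), a.apply(b.apply(p)), atol=1e-12)


class TestEstimateRigid:
    def test_identity_on_identical_sets(self, rng):
        pts = rng.uniform(0, 1000, size=(5, 2))
        t = estimate_rigid(pts, pts)
        assert abs(t.theta) < 1e-12
        assert abs(t.tx) < 1e-9 and abs(t.ty) < 1e-9

    def test_recovers_known_rotation_and_shift(self, rng):
        ref = rng.uniform(0, 10000, size=(5, 2))
        true = RigidTransform2D(theta=0.01, tx=500.0, ty=-300.0)
        mov = true.inverse().apply(ref)
        est = estimate_rigid(mov, ref)
        assert est.theta == pytest.approx(0.01, abs=1e-9)
        assert est.tx == pytest.approx(500.0, abs=1e-6)
        assert est.ty == pytest.approx(-300.0, abs=1e-6)

    def test_matches_grid_search_oracle(self, rng):
        ref = rng.uniform(0, 5000, size=(3, 2))
        true = RigidTransform2D(theta=0.037, tx=200.0, ty=90.0)
        mov = true.inverse().apply(ref)
        est = estimate_rigid(mov, ref)
        resid = est.apply(mov) - ref
        assert np.sqrt(np.mean(resid**2)) < 1e-9
        theta_grid = grid_search_theta(mov, ref)
        assert est.theta == pytest.approx(theta_grid, abs=1e-3)

    def test_too_few_pairs_raises(self):
        with pytest.raises(DegenerateConfigurationError):
            estimate_rigid(np.array([[0.0, 0.0]]), np.array([[1.0, 1.0]]))

    def test_coincident_moving_points_raise(self):
        mov = np.zeros((4, 2))
        ref = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        with pytest.raises(DegenerateConfigurationError, match="coincide"):
            estimate_rigid(mov, ref)

    @given(
        theta=st.floats(-3.0, 3.0),
        tx=st.floats(-1e4, 1e4),
        ty=st.floats(-1e4, 1e4),
        seed=st.integers(0, 2**16),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_exact_on_noiseless_rigid_pairs(self, theta, tx, ty, seed):
        rng = np.random.default_rng(seed)
        ref = rng.uniform(-5e3, 5e3, size=(6, 2))
        true = RigidTransform2D(theta=theta, tx=tx, ty=ty)
        mov = true.inverse().apply(ref)
        est = estimate_rigid(mov, ref)
        assert np.linalg.det(est.rotation) == pytest.approx(1.0)
        resid = est.apply(mov) - ref
        assert np.sqrt(np.mean(resid**2)) < 1e-6  # nm, on a 10 µm field


class TestICP:
    def test_identical_sets_give_identity_quickly(self, rng):
        pts = rng.uniform(0, 3e4, size=(8, 2))
        res = icp(pts, pts)
        assert res.converged and res.n_iterations <= 2
        assert abs(res.transform.theta) < 1e-12
        assert np.hypot(res.transform.tx, res.transform.ty) < 1e-9

    def test_recovers_transform_with_spurious_landmarks(self, rng):
        ref = rng.uniform(0, 3e4, size=(10, 2))
        true = RigidTransform2D(theta=0.005, tx=800.0, ty=-400.0)
        mov = np.vstack([true.inverse().apply(ref), rng.uniform(0, 3e4, size=(3, 2))])
        res = icp(mov, ref)
        aligned = res.transform.apply(mov[:10])
        rms = np.sqrt(np.mean(np.sum((aligned - ref) ** 2, axis=1)))
        assert rms < 1.0
        matched_movers = {m for m, _ in res.matched_pairs}
        assert matched_movers.issuperset(range(10))
        assert not matched_movers & {10, 11, 12}  # spurious ended as outliers

    def test_jittered_beads_register_below_prior_misalignment(self):
        tre_after = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            beads = rng.uniform(0, 3.3e4, size=(8, 2))
            true = RigidTransform2D(theta=0.01, tx=1000.0, ty=0.0)
            ref_obs = beads + rng.normal(0, 20, size=beads.shape)
            mov_obs = true.inverse().apply(beads + rng.normal(0, 20, size=beads.shape))
            res = icp(mov_obs, ref_obs)
            d = np.linalg.norm(res.transform.apply(true.inverse().apply(beads)) - beads, axis=1)
            tre_after.append(d.mean())
            assert d.mean() < 1000.0
        # per-channel jitter sigma=20 → residual TRE on the sigma*sqrt(2) scale
        assert np.mean(tre_after) < 3 * 20 * np.sqrt(2)

    def test_mean_distance_non_increasing(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ref = rng.uniform(0, 3e4, size=(12, 2))
            true = RigidTransform2D(theta=0.015, tx=-900.0, ty=600.0)
            mov = true.inverse().apply(ref) + rng.normal(0, 10, size=ref.shape)
            res = icp(mov, ref)
            diffs = np.diff(res.mean_distances)
            assert np.all(diffs <= 1e-9)

    def test_too_few_landmarks_raises(self):
        with pytest.raises(DegenerateConfigurationError):
            icp(np.array([[0.0, 0.0]]), np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_non_convergence_warns(self, rng):
        ref = rng.uniform(0, 3e4, size=(10, 2))
        mov = RigidTransform2D(theta=0.01, tx=500, ty=0).apply(ref)
        with pytest.warns(UserWarning, match="did not converge"):
            res = icp(mov, ref, ICPConfig(max_iterations=1))
        assert not res.converged


class TestApplyTransform:
    def test_identity_bitwise_equal(self, rng):
        t = random_table(rng, n=100)
        out = apply_transform(t, RigidTransform2D.identity())
        assert np.array_equal(out.xy, t.xy)

    def test_pure_translation(self, rng):
        t = random_table(rng, n=50)
        out = apply_transform(t, RigidTransform2D(tx=100.0, ty=0.0))
        np.testing.assert_allclose(out.xy, t.xy + [100.0, 0.0], rtol=0, atol=1e-12)
        assert out.frames.tolist() == t.frames.tolist()
        assert out.data["intensity"].tolist() == t.data["intensity"].tolist()

    def test_apply_then_inverse_round_trip(self, rng):
        t = random_table(rng, n=10_000, field=3e4)
        tr = RigidTransform2D(theta=0.25, tx=1234.5, ty=-678.9)
        back = apply_transform(apply_transform(t, tr), tr.inverse())
        assert np.max(np.abs(back.xy - t.xy)) < 1e-6
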