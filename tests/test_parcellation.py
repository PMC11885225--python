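"""Parcel assignment, PCA time-course extraction, symmetric
orthogonalization, and cross-subject sign alignment."""

from itertools import product

import numpy as np
import pytest

from ephys_batch.parcellation import (
    ParcelAssignment,
    ParcelTimeCourses,
    _corr,
    _offdiag,
    apply_sign_flips,
    assign_parcels,
    extract_parcel_timecourses,
    sign_flip,
    symmetric_orthogonalize,
)
from ephys_batch.source_recon import make_sphere_grid
from ephys_batch.synthetic import SimulationSpec, simulate_multisubject_parcels


def _label_volume():
    """20 mm cube voxels in a 10x10x10 volume centered on the head origin:
    label 1 for x-voxel < 5, label 2 for x-voxel >= 5, background ring 0."""
    vol = np.zeros((10, 10, 10), dtype=int)
    vol[1:5, 1:9, 1:9] = 1
    vol[5:9, 1:9, 1:9] = 2
    affine = np.eye(4) * 20.0
    affine[:3, 3] = -100.0  # voxel (5,5,5) maps to world origin
    affine[3, 3] = 1.0
    return vol, affine


class TestAssign:
    def test_matches_bruteforce_voxel_lookup(self):
        vol, affine = _label_volume()
        grid = make_sphere_grid((0, 0, 0), 0.07, 0.011)
        asg = assign_parcels(grid, vol, affine)
        inv = np.linalg.inv(affine)
        for idx, p in enumerate(grid.positions):
            v = inv[:3, :3] @ (p * 1000.0) + inv[:3, 3]
            v = (np.sign(v) * np.floor(np.abs(v) + 0.5)).astype(int)
            expected = (
                vol[tuple(v)]
                if np.all((v >= 0) & (v < 10))
                else 0
            )
            assert asg.parcel_id[idx] == expected

    def test_background_voxel_gives_zero(self):
        vol, affine = _label_volume()
        grid = make_sphere_grid((0, 0, 0.08), 0.005, 0.004)  # near top edge
        asg = assign_parcels(grid, vol, affine)
        assert set(np.unique(asg.parcel_id)) <= {0, 1, 2}

    def test_identity_affine_voxel_center_hits_label(self):
        vol = np.zeros((5, 5, 5), dtype=int)
        vol[2, 3, 1] = 7

        class G:
            positions = np.array([[0.002, 0.003, 0.001]])  # mm 2,3,1

        asg = assign_parcels(G(), vol, np.eye(4))
        assert asg.parcel_id[0] == 7

    def test_out_of_volume_counts_unmapped(self):
        vol = np.ones((4, 4, 4), dtype=int)

        class G:
            positions = np.array([[1.0, 1.0, 1.0]])  # far outside

        asg = assign_parcels(G(), vol, np.eye(4))
        assert asg.parcel_id[0] == 0
        assert asg.n_unmapped == 1


class TestExtract:
    def _assignment(self, ids):
        names = {0: "background"}
        names.update({i: f"p{i}" for i in sorted(set(ids)) if i != 0})
        return ParcelAssignment(np.asarray(ids), names)

    def test_single_dipole_parcel_is_proportional(self, rng):
        x = rng.standard_normal((3, 500))
        asg = self._assignment([1, 2, 2])
        ptc = extract_parcel_timecourses(x, asg)
        xc = x[0] - x[0].mean()
        r = np.corrcoef(ptc.data[0], xc)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-12

    def test_two_identical_dipoles_give_pc1_everything(self, rng):
        base = rng.standard_normal(400)
        x = np.vstack([base, base, rng.standard_normal(400)])
        asg = self._assignment([1, 1, 2])
        ptc = extract_parcel_timecourses(x, asg)
        r = np.corrcoef(ptc.data[0], base - base.mean())[0, 1]
        assert abs(abs(r) - 1.0) < 1e-10

    def test_weights_equal_leading_eigenvector(self, rng):
        x = rng.standard_normal((4, 600))
        x[1] += 0.8 * x[0]
        asg = self._assignment([1, 1, 1, 1])
        ptc = extract_parcel_timecourses(x, asg)
        xc = x - x.mean(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(xc @ xc.T / 599)
        w = evecs[:, -1]
        recon = w @ xc
        r = np.corrcoef(ptc.data[0], recon)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-10
        # scaling: mean member variance
        assert ptc.data[0].var(ddof=1) == pytest.approx(
            xc.var(axis=1, ddof=1).mean()
        )

    def test_zero_variance_parcel_yields_zero_trace(self):
        x = np.zeros((2, 100))
        asg = self._assignment([1, 1])
        ptc = extract_parcel_timecourses(x, asg)
        assert np.all(ptc.data == 0)


def _gram_schmidt_rescaled(X):
    Q = np.zeros_like(X)
    for i in range(X.shape[0]):
        v = X[i] - sum((X[i] @ Q[j]) * Q[j] for j in range(i))
        Q[i] = v / np.linalg.norm(v)
    d = np.einsum("ij,ij->i", X, Q)
    return d[:, None] * Q


class TestOrthogonalize:
    def test_orthogonal_input_is_fixed_point(self, rng):
        A = rng.standard_normal((300, 3))
        A -= A.mean(axis=0, keepdims=True)  # zero-mean orthonormal basis
        X = np.diag([3.0, 2.0, 1.5]) @ np.linalg.qr(A)[0].T
        Y = symmetric_orthogonalize(X)
        assert np.allclose(Y, X, atol=1e-8)

    def test_output_rows_uncorrelated(self, rng):
        X = rng.standard_normal((3, 500))
        X = (np.eye(3) + 0.5 * rng.standard_normal((3, 3))) @ X
        Y = symmetric_orthogonalize(X)
        C = np.corrcoef(Y)
        assert np.abs(C - np.eye(3)).max() < 1e-8

    def test_closer_to_input_than_gram_schmidt(self):
        for s in range(20):
            rng = np.random.default_rng(200 + s)
            X = rng.standard_normal((5, 400))
            X = (np.eye(5) + 0.3 * rng.standard_normal((5, 5))) @ X
            Xd = X - X.mean(axis=1, keepdims=True)
            Y = symmetric_orthogonalize(X)
            G = _gram_schmidt_rescaled(Xd)
            assert np.linalg.norm(Xd - Y) < np.linalg.norm(Xd - G)

    def test_idempotent(self, rng):
        X = rng.standard_normal((4, 300))
        Y = symmetric_orthogonalize(X)
        Y2 = symmetric_orthogonalize(Y)
        assert np.allclose(Y, Y2, atol=1e-6 * np.abs(Y).max())

    def test_rank_deficient_input_rejected(self, rng):
        X = rng.standard_normal((3, 200))
        X[2] = X[0] + X[1]
        with pytest.raises(ValueError, match="rank"):
            symmetric_orthogonalize(X)

    def test_leakage_pipeline_moves_correlations_toward_identity(self, rng):
        truth = rng.standard_normal((6, 800))
        leak = np.eye(6) + 0.3 * rng.standard_normal((6, 6))
        mixed = leak @ truth
        pre = np.corrcoef(mixed)
        post = np.corrcoef(symmetric_orthogonalize(mixed))
        eye = np.eye(6)
        assert np.linalg.norm(post - eye) < np.linalg.norm(pre - eye)

    def test_preserves_parceltimecourses_metadata(self, rng):
        ptc = ParcelTimeCourses(
            rng.standard_normal((3, 300)), ["a", "b", "c"], 100.0, "s1", "r1"
        )
        out = symmetric_orthogonalize(ptc)
        assert out.parcel_names == ["a", "b", "c"]
        assert out.subject_id == "s1"


class TestSignFlip:
    def test_identical_covariances_already_optimal(self, rng):
        x = rng.standard_normal((4, 1000))
        sol = sign_flip([x, x.copy()], n_init=4, n_iter=10, seed=0)
        covs = np.cov(x)
        t = _offdiag(covs)
        for f in sol.flips:
            flipped = _corr(_offdiag(np.outer(f, f) * covs), t)
            assert flipped == pytest.approx(1.0)

    def test_planted_two_subject_flips_recovered_up_to_global_sign(self, rng):
        x = rng.standard_normal((6, 3000))
        f_true = np.array([1, -1, 1, 1, -1, -1], dtype=float)
        y = f_true[:, None] * x
        sol = sign_flip([x, y], n_init=6, n_iter=20, seed=1)
        # residual frames must agree up to a global sign per subject
        h0 = sol.flips[0]
        h1 = sol.flips[1] * f_true
        assert np.array_equal(h0, h1) or np.array_equal(h0, -h1)

    def test_multisubject_planted_flips_recovered(self):
        spec = SimulationSpec(n_subjects=5, n_parcels=10, seed=21,
                              duration=40.0)
        ptcs, true = simulate_multisubject_parcels(spec)
        sol = sign_flip(ptcs, n_init=5, n_iter=30, seed=2)
        frames = [f * t for f, t in zip(sol.flips, true)]
        ref = frames[0]
        for h in frames[1:]:
            assert np.array_equal(h, ref) or np.array_equal(h, -ref)

    def test_objective_trace_non_decreasing(self, rng):
        ptcs = [rng.standard_normal((5, 300)) for _ in range(3)]
        sol = sign_flip(ptcs, n_init=4, n_iter=15, seed=3)
        assert np.all(np.diff(sol.objective_trace) >= -1e-12)

    def test_greedy_equals_bruteforce_for_small_p(self):
        for s in range(12):
            rng = np.random.default_rng(300 + s)
            P = int(rng.integers(2, 5))
            ptcs = [rng.standard_normal((P, 200)) for _ in range(3)]
            sol = sign_flip(ptcs, n_init=8, n_iter=30, seed=s)
            covs = [np.cov(m) for m in ptcs]
            t = _offdiag(covs[sol.template_subject])
            for f, C in zip(sol.flips, covs):
                greedy = _corr(_offdiag(np.outer(f, f) * C), t)
                brute = max(
                    _corr(_offdiag(np.outer(g, g) * C), t)
                    for g in (
                        np.array(bits, dtype=float)
                        for bits in product([-1, 1], repeat=P)
                    )
                )
                assert greedy == pytest.approx(brute, abs=1e-12)

    def test_objective_invariant_under_global_sign(self, rng):
        x = rng.standard_normal((4, 500))
        C = np.cov(x)
        t = _offdiag(np.cov(rng.standard_normal((4, 500))))
        for bits in product([-1, 1], repeat=4):
            f = np.array(bits, dtype=float)
            assert _corr(_offdiag(np.outer(f, f) * C), t) == pytest.approx(
                _corr(_offdiag(np.outer(-f, -f) * C), t)
            )

    def test_apply_flips_flips_rows(self, rng):
        ptcs = [
            ParcelTimeCourses(rng.standard_normal((3, 100)), ["a", "b", "c"])
            for _ in range(2)
        ]
        sol = sign_flip([p.data for p in ptcs], n_init=2, n_iter=5, seed=0)
        out = apply_sign_flips(ptcs, sol)
        for o, p, f in zip(out, ptcs, sol.flips):
            assert np.array_equal(o.data, f[:, None] * p.data)

    def test_single_subject_or_parcel_rejected(self, rng):
        with pytest.raises(ValueError):
            sign_flip([rng.standard_normal((3, 100))])
        with pytest.raises(ValueError):
            sign_flip([rng.standard_normal((1, 100))] * 2)
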