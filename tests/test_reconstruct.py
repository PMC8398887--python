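"""Monitoring-phase OMP reconstruction and PRD/PRDN quality metrics."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgcs import compress, evaluate_record, omp_single, prd, prdn, reconstruct_frame
from ecgcs.preprocess import FrameSet
from ecgcs.sensing import CompressedFrame

from conftest import sparse_instance


class TestOmpSingle:
    def test_orthogonal_columns_single_step(self):
        A = np.eye(6)
        y = 2.0 * A[:, 3]
        alpha, iters = omp_single(y, A)
        assert iters == 1
        assert alpha[3] == pytest.approx(2.0)
        assert np.count_nonzero(alpha) == 1

    def test_residuals_nonincreasing(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((10, 20))
        y = rng.standard_normal(10)
        prev = np.linalg.norm(y)
        for k in range(1, 5):
            alpha, _ = omp_single(y, A, max_atoms=k, res_tol=0.0)
            resid = np.linalg.norm(y - A @ alpha)
            assert resid <= prev + 1e-12
            prev = resid

    def test_matches_exhaustive_three_subset_oracle(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((8, 16))
        A /= np.linalg.norm(A, axis=0)
        v = np.zeros(16)
        rows = [2, 9, 14]
        v[rows] = [1.5, -1.1, 0.9]
        y = A @ v
        alpha, _ = omp_single(y, A, max_atoms=3, res_tol=1e-10)
        best, best_r = None, np.inf
        for sub in combinations(range(16), 3):
            coef, *_ = np.linalg.lstsq(A[:, sub], y, rcond=None)
            r = np.linalg.norm(y - A[:, sub] @ coef)
            if r < best_r:
                best, best_r = set(sub), r
        assert set(np.flatnonzero(alpha).tolist()) == best == set(rows)

    def test_zero_measurement_returns_zero(self):
        alpha, iters = omp_single(np.zeros(5), np.random.default_rng(1).standard_normal((5, 9)))
        assert iters == 0 and np.all(alpha == 0)


class TestReconstructFrame:
    def test_exactly_sparse_frame_identity_sensing(self, psi1_64):
        X, gen, _ = sparse_instance(2, psi1_64, K=3, F=1, snr_db=None)
        sub = psi1_64.restrict(gen)
        x = X[:, 0]
        cf = CompressedFrame(y=x.copy(), p_sent=None, frame_index=0)
        res = reconstruct_frame(cf, np.eye(64), sub, res_tol=1e-10)
        assert prd(x, res.x_hat) < 1e-6
        assert np.allclose(res.x_hat, sub.matrix @ res.alpha_hat)

    def test_bias_frame_recovered_with_one_atom(self, psi1_64):
        sub = psi1_64.restrict([])
        x = np.full(64, 5.0 / 64)
        for usr in (1, 4, 8):
            frames, _ = compress(x.reshape(-1, 1), usr)
            from ecgcs.sensing import build_phi
            phi = build_phi(frames[0].p_sent, usr)
            res = reconstruct_frame(frames[0], phi, sub)
            assert res.iterations == 1
            assert prd(x, res.x_hat) < 1e-8

    def test_zero_frame_reconstructs_to_zero(self, psi1_64):
        sub = psi1_64.restrict([3])
        cf = CompressedFrame(y=np.zeros(16), p_sent=None, frame_index=0)
        res = reconstruct_frame(cf, np.ones((16, 64)), sub)
        assert np.all(res.x_hat == 0)

    def test_dimension_mismatch_rejected(self, psi1_64):
        cf = CompressedFrame(y=np.zeros(10), p_sent=None, frame_index=0)
        with pytest.raises(ValueError):
            reconstruct_frame(cf, np.ones((16, 64)), psi1_64.restrict([1]))


class TestMetrics:
    def test_prd_worked_examples(self):
        x = np.array([3.0, 4.0])
        assert prd(x, x) == 0.0
        assert prd(x, np.zeros(2)) == pytest.approx(100.0)
        assert prd(x, np.array([0.0, 4.0])) == pytest.approx(60.0)

    def test_prdn_worked_examples(self):
        x = np.array([1.0, 3.0])
        assert prdn(x, x) == 0.0
        assert prdn(x, np.array([1.0, 1.0])) == pytest.approx(100.0 * 2 / np.sqrt(2))

    def test_prdn_invariant_to_common_dc_shift(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50)
        x_hat = x + 0.1 * rng.standard_normal(50)
        assert prdn(x + 7.0, x_hat + 7.0) == pytest.approx(prdn(x, x_hat))

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-1e3, 1e3).filter(lambda c: abs(c) > 1e-6), st.integers(0, 50))
    def test_prd_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(20) + 1.0
        x_hat = x + 0.3 * rng.standard_normal(20)
        assert prd(c * x, c * x_hat) == pytest.approx(prd(x, x_hat), rel=1e-9)

    def test_degenerate_references_rejected(self):
        with pytest.raises(ValueError):
            prd(np.zeros(4), np.ones(4))
        with pytest.raises(ValueError):
            prdn(np.full(4, 2.0), np.ones(4))


class TestEvaluateRecord:
    def _frameset(self, X):
        return FrameSet(X=X, N=X.shape[0], align_frac=0.3,
                        frame_origins=np.zeros(X.shape[1], dtype=np.int64))

    def test_identical_frames_mean_equals_single(self, psi1_64):
        X, gen, _ = sparse_instance(4, psi1_64, K=3, F=1, snr_db=None)
        Xrep = np.repeat(X, 4, axis=1)
        stream, _ = compress(Xrep, usr=2)
        out = evaluate_record(self._frameset(Xrep), stream, psi1_64.restrict(gen), usr=2)
        assert out["per_frame_prd"].size == 4
        assert out["mean_prd"] == pytest.approx(out["per_frame_prd"][0])

    def test_mean_within_per_frame_range(self, psi1_64):
        X, gen, _ = sparse_instance(5, psi1_64, K=3, F=6)
        stream, _ = compress(X, usr=2)
        out = evaluate_record(self._frameset(X), stream, psi1_64.restrict(gen), usr=2)
        assert out["per_frame_prd"].min() <= out["mean_prd"] <= out["per_frame_prd"].max()

    def test_trained_dictionary_beats_bias_only(self, psi1_64):
        X, gen, _ = sparse_instance(6, psi1_64, K=4, F=10)
        stream, _ = compress(X, usr=4)
        frames = self._frameset(X)
        good = evaluate_record(frames, stream, psi1_64.restrict(gen), usr=4)
        bare = evaluate_record(frames, stream, psi1_64.restrict([]), usr=4)
        assert good["mean_prd"] < bare["mean_prd"]

    def test_zero_frames_skipped_not_scored(self, psi1_64):
        X, gen, _ = sparse_instance(7, psi1_64, K=2, F=3)
        X[:, 1] = 0.0
        stream, _ = compress(X, usr=2)
        out = evaluate_record(self._frameset(X), stream, psi1_64.restrict(gen), usr=2)
        assert out["skipped"] == 1
        assert out["per_frame_prd"].size == 2
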