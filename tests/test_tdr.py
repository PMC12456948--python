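"""Targeted dimensionality reduction against planted models and naive oracles."""

import numpy as np
import pandas as pd
import pytest

from revdyn import tdr


def make_tensor(N=6, M=5, K=40, seed=0, noise=0.0, coef=None, regressors=None):
    rng = np.random.default_rng(seed)
    if regressors is None:
        regressors = pd.DataFrame(
            {"a": rng.standard_normal(K), "b": rng.standard_normal(K)}
        )
    Z = regressors.to_numpy()
    V = Z.shape[1]
    if coef is None:
        coef = rng.standard_normal((N, M, V))
    bias = rng.standard_normal((N, M))
    values = np.einsum("nmv,kv->nmk", coef, Z) + bias[:, :, None]
    values += noise * rng.standard_normal(values.shape)
    tensor = tdr.ActivityTensor(values=values, time_axis=np.arange(M) * 20.0)
    return tensor, regressors, coef, bias


class TestBinSpikeCounts:
    def test_no_spikes_all_zero(self):
        t = tdr.bin_spike_counts([[np.array([])] * 3], span=(0, 1000))
        assert t.values.sum() == 0
        assert t.source == "spike_counts"

    def test_counts_match_naive_interval_counting(self):
        rng = np.random.default_rng(1)
        spikes = [[np.sort(rng.uniform(0, 2000, 50)) for _ in range(4)] for _ in range(3)]
        t = tdr.bin_spike_counts(spikes, span=(0, 2000))
        for i in range(3):
            for k in range(4):
                for j, c in enumerate(t.time_axis):
                    naive = np.sum(
                        (spikes[i][k] >= c - 150) & (spikes[i][k] < c + 150)
                    )
                    assert t.values[i, j, k] == naive

    def test_homogeneous_rate_mean_count(self):
        """A 10 Hz homogeneous train averages ~3 spikes per 300 ms window."""
        rng = np.random.default_rng(2)
        spikes = [
            [np.sort(rng.uniform(0, 3000, rng.poisson(30))) for _ in range(200)]
        ]
        t = tdr.bin_spike_counts(spikes, span=(0, 3000))
        assert t.values.mean() == pytest.approx(3.0, rel=0.05)

    def test_empty_span_rejected(self):
        with pytest.raises(ValueError):
            tdr.bin_spike_counts([[np.array([])]], span=(0, 100))


class TestRegression:
    def test_planted_model_recovered_exactly(self):
        tensor, regressors, coef, bias = make_tensor(noise=0.0)
        got, got_bias, _ = tdr.regress_activity(tensor, regressors, zscore=False)
        assert np.allclose(got, coef, atol=1e-8)
        assert np.allclose(got_bias, bias, atol=1e-8)

    def test_orthonormal_regressors_equal_covariance(self):
        """With orthonormal centered regressors OLS equals the cross-trial covariance."""
        K = 64
        base = np.linalg.qr(np.random.default_rng(3).standard_normal((K, 2)))[0]
        base -= base.mean(axis=0)
        base, _ = np.linalg.qr(base)
        regressors = pd.DataFrame({"a": base[:, 0], "b": base[:, 1]})
        tensor, _, _, _ = make_tensor(K=K, regressors=regressors, noise=0.1, seed=4)
        coef, _, _ = tdr.regress_activity(tensor, regressors, zscore=False)
        Y = tensor.values
        expect = np.einsum("nmk,kv->nmv", Y - Y.mean(axis=2, keepdims=True), base)
        assert np.allclose(coef, expect, atol=1e-8)

    def test_constant_regressor_rejected(self):
        tensor, regressors, *_ = make_tensor()
        regressors = regressors.assign(flat=1.0)
        with pytest.raises(ValueError, match="flat"):
            tdr.regress_activity(tensor, regressors)

    def test_collinear_design_rejected(self):
        tensor, regressors, *_ = make_tensor()
        regressors = regressors.assign(dup=regressors["a"] * 2.0)
        with pytest.raises(ValueError, match="rank-deficient"):
            tdr.regress_activity(tensor, regressors)

    def test_too_few_trials_rejected(self):
        tensor, regressors, *_ = make_tensor(K=3)
        with pytest.raises(ValueError, match="trials"):
            tdr.regress_activity(tensor, regressors.iloc[:3])


class TestSelectAndOrthogonalize:
    def test_max_norm_selection_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        coef = rng.standard_normal((8, 11, 3))
        for j, v in enumerate(["x", "y", "z"]):
            vec, t_max = tdr.select_task_vector(coef, ["x", "y", "z"], v)
            norms = [np.linalg.norm(coef[:, t, j]) for t in range(11)]
            assert t_max == int(np.argmax(norms))
            assert np.allclose(vec, coef[:, t_max, j])

    def test_tie_takes_earliest_time(self):
        coef = np.zeros((4, 5, 1))
        coef[:, 1, 0] = [1, 0, 0, 0]
        coef[:, 3, 0] = [0, 1, 0, 0]  # same norm, later time
        _, t_max = tdr.select_task_vector(coef, ["v"], "v")
        assert t_max == 1

    def test_qr_properties_and_span(self):
        rng = np.random.default_rng(6)
        coef = rng.standard_normal((10, 7, 3))
        bias = np.zeros((10, 7))
        tv = tdr.orthogonalize(coef, bias, ["rev", "choice", "reward"])
        Q = tv.ortho
        assert np.allclose(Q.T @ Q, np.eye(3), atol=1e-10)
        # first orthonormal vector is the normalized raw reversal vector
        w0 = tv.raw[:, 0] / np.linalg.norm(tv.raw[:, 0])
        assert np.allclose(Q[:, 0], w0, atol=1e-10)
        # span preserved: projectors agree
        P_raw = tv.raw @ np.linalg.pinv(tv.raw)
        assert np.allclose(Q @ Q.T, P_raw, atol=1e-8)

    def test_near_dependent_vectors_rejected(self):
        coef = np.zeros((6, 2, 2))
        coef[:, 0, 0] = [1, 1, 1, 1, 1, 1]
        coef[:, 0, 1] = coef[:, 0, 0] * (1 + 1e-12)
        with pytest.raises(ValueError, match="dependent"):
            tdr.orthogonalize(coef, np.zeros((6, 2)), ["a", "b"])


class TestProject:
    def test_unit_vector_picks_neuron_row(self):
        tensor, *_ = make_tensor()
        w = np.zeros(tensor.n_neurons)
        w[2] = 1.0
        assert np.allclose(tdr.project(tensor, w), tensor.values[2])

    def test_linear_and_matches_naive_loop(self):
        tensor, *_ = make_tensor()
        rng = np.random.default_rng(7)
        w1, w2 = rng.standard_normal((2, tensor.n_neurons))
        assert np.allclose(
            tdr.project(tensor, w1 + 2 * w2),
            tdr.project(tensor, w1) + 2 * tdr.project(tensor, w2),
        )
        naive = np.zeros((tensor.n_times, tensor.n_trials))
        for i in range(tensor.n_neurons):
            naive += w1[i] * tensor.values[i]
        assert np.allclose(tdr.project(tensor, w1), naive)
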