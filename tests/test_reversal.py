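"""Reversal-aligned analyses: integration, contraction, separability."""

import numpy as np
import pytest

from revdyn import reversal


def toy_aligned(nb=5, K=3, nt=4, seed=0, rewards=None):
    rng = np.random.default_rng(seed)
    T = 20
    projections = [rng.standard_normal((nt, T)) for _ in range(nb)]
    reversals = list(10 + rng.integers(-2, 3, nb))
    if rewards is None:
        rewards = [rng.integers(0, 2, T) for _ in range(nb)]
    return reversal.align_to_reversal(
        projections, reversals, rewards, K=K, time_axis=np.arange(nt) * 20.0
    ), projections, reversals, rewards


class TestAlign:
    def test_full_window_retained(self):
        aligned, projections, reversals, _ = toy_aligned()
        assert aligned.valid.all()
        for b in range(5):
            for j, rel in enumerate(aligned.rel_trials):
                k = reversals[b] + rel
                assert np.allclose(aligned.x[b, j], projections[b][:, k - 1])

    def test_truncated_window_flagged(self):
        rng = np.random.default_rng(1)
        proj = [rng.standard_normal((3, 12))]
        aligned = reversal.align_to_reversal(proj, [3], [np.ones(12)], K=10)
        assert not aligned.valid.all()
        # relative trials -10..-3 and +10 fall outside the 12-trial block
        assert aligned.n_truncated == 9
        assert np.isnan(aligned.x[0, 0]).all()

    def test_round_trip_indexing(self):
        aligned, *_ = toy_aligned()
        for b in range(aligned.n_blocks):
            for rel in aligned.rel_trials:
                k = aligned.absolute_trial(b, rel)
                assert k - aligned.reversal_trials[b] == rel

    def test_K_too_large_rejected(self):
        with pytest.raises(ValueError):
            reversal.align_to_reversal(
                [np.zeros((3, 8))], [4], [np.ones(8)], K=8
            )


class TestUpdateTerms:
    def test_matches_stratified_mean_on_toy(self):
        aligned, *_ = toy_aligned(nb=5)
        terms = reversal.update_terms(aligned)
        for j in range(len(terms.rel_trials)):
            for t in range(len(terms.time_axis)):
                plus, minus = [], []
                for b in range(5):
                    if not (aligned.valid[b, j] and aligned.valid[b, j + 1]):
                        continue
                    d = aligned.x[b, j + 1, t] - aligned.x[b, j, t]
                    (plus if aligned.rewards[b, j] == 1 else minus).append(d)
                if plus:
                    assert terms.R_plus[j, t] == pytest.approx(np.mean(plus))
                else:
                    assert np.isnan(terms.R_plus[j, t]) and terms.n_plus[j] == 0
                if minus:
                    assert terms.R_minus[j, t] == pytest.approx(np.mean(minus))

    def test_single_outcome_leaves_other_stratum_missing(self):
        aligned, *_ = toy_aligned(rewards=[np.ones(20, int)] * 5)
        terms = reversal.update_terms(aligned)
        assert np.isnan(terms.R_minus).all()
        assert (terms.n_minus == 0).all()
        assert np.isfinite(terms.R_plus).all()

    def test_decomposition_identity(self):
        """f+ R+ + f- R- equals the unconditional mean difference exactly."""
        aligned, *_ = toy_aligned(nb=8, K=4, nt=3, seed=3)
        terms = reversal.update_terms(aligned)
        dx = aligned.x[:, 1:, :] - aligned.x[:, :-1, :]
        uncond = np.nanmean(dx, axis=0)
        got = terms.unconditional()
        ok = (terms.n_plus + terms.n_minus) > 0
        assert np.allclose(got[ok], uncond[ok], atol=1e-12)
        fp, fm = terms.f_plus[ok], terms.f_minus[ok]
        assert np.allclose(fp + fm, 1.0, atol=1e-12)


class TestPredictIntegration:
    def test_telescoping_matches_cumsum(self):
        aligned, *_ = toy_aligned(nb=6, K=4, seed=4)
        terms = reversal.update_terms(aligned)
        out = reversal.predict_integration(aligned, terms, t_index=1)
        for _, row in out.iterrows():
            b = row["block"]
            pred = row["predicted"]
            sel = np.flatnonzero(~np.isnan(pred))
            increments = []
            for j in sel[:-1]:
                R = terms.R_plus if aligned.rewards[b, j] == 1 else terms.R_minus
                increments.append(R[j, 1])
            expect = pred[sel[0]] + np.concatenate([[0.0], np.cumsum(increments)])
            assert np.allclose(pred[sel], expect, atol=1e-12)

    def test_zero_updates_give_flagged_constant_prediction(self):
        aligned, *_ = toy_aligned(nb=4, K=2, seed=5)
        zeroed = reversal.update_terms(aligned)
        zeroed.R_plus[:] = 0.0
        zeroed.R_minus[:] = 0.0
        out = reversal.predict_integration(aligned, zeroed, t_index=0)
        assert out["accuracy"].isna().all()  # constant series has no correlation


class TestTimeDerivative:
    def test_linear_ramp_and_constant(self):
        t = np.arange(50) * 20.0
        assert np.allclose(reversal.time_derivative(3.0 * t, 20.0), 3.0)
        assert np.allclose(reversal.time_derivative(np.full(50, 2.0), 20.0), 0.0)

    def test_sine_matches_cosine(self):
        step = 1.0
        t = np.arange(0, 1000, step)
        w = 2 * np.pi / 400
        got = reversal.time_derivative(np.sin(w * t), step)
        assert np.allclose(got[1:-1], w * np.cos(w * t)[1:-1], atol=w * w * step**2)


class TestContraction:
    def test_exact_ar1_recovered(self):
        z = 0.8 ** np.arange(12)
        x = z - z.mean() + 5.0  # window-mean centering removes the offset
        # single window of length 11
        a, starts = reversal.contraction_factor(x, L=11)
        z0 = x - x.mean()
        expect = np.dot(z0[:-1], z0[1:]) / np.dot(z0[:-1], z0[:-1])
        assert a[0] == pytest.approx(expect, abs=1e-12)

    def test_equals_no_intercept_ols_oracle(self):
        rng = np.random.default_rng(6)
        x = np.cumsum(rng.standard_normal(61))
        factors, starts = reversal.contraction_factor(x, L=10)
        for a, s in zip(factors, starts):
            seg = x[s : s + 11]
            z = seg - seg.mean()
            slope = np.linalg.lstsq(z[:-1, None], z[1:], rcond=None)[0][0]
            assert a == pytest.approx(slope, abs=1e-12)

    def test_constant_window_degenerate(self):
        with pytest.raises(ZeroDivisionError):
            reversal.contraction_factor(np.ones(12), L=11)

    def test_noisy_ar1_windows_match_independent_ols(self):
        """Per-window estimates equal an independently coded no-intercept OLS."""
        rng = np.random.default_rng(7)
        a_true = 0.9
        x = np.empty(3001)
        x[0] = rng.standard_normal()
        for t in range(3000):
            x[t + 1] = a_true * x[t] + 0.3 * rng.standard_normal()
        factors, starts = reversal.contraction_factor(x, L=30)
        for a, s in zip(factors, starts):
            seg = x[s : s + 31]
            z = seg - seg.mean()
            oracle = float(np.linalg.lstsq(z[:-1, None], z[1:], rcond=None)[0][0])
            assert a == pytest.approx(oracle, abs=1e-12)
        # pooled estimate sits near the generating coefficient
        assert abs(np.mean(factors) - a_true) < 0.1


class TestSeparability:
    def test_monotone_trajectories_give_unit_spearman(self):
        K, nt = 4, 3
        nb = 6
        x = np.zeros((nb, 2 * K + 1, nt))
        rel = np.arange(-K, K + 1)
        for j, r in enumerate(rel):
            # pre: increasing with trial order; post: decreasing
            x[:, j, :] = r if r <= 0 else -r
        aligned = reversal.AlignedSubspaceActivity(
            x=x, valid=np.ones((nb, 2 * K + 1), bool),
            rewards=np.ones((nb, 2 * K + 1)), rel_trials=rel,
            time_axis=np.arange(nt) * 20.0,
            reversal_trials=np.full(nb, 10),
        )
        terms = reversal.update_terms(aligned)
        stats_ = reversal.separability_stats(terms, aligned)
        assert np.allclose(stats_.spearman_pre, 1.0)
        assert np.allclose(stats_.spearman_post, 1.0)

    def test_rank_correlation_matches_rank_then_pearson(self):
        aligned, *_ = toy_aligned(nb=6, K=4, nt=3, seed=8)
        terms = reversal.update_terms(aligned)
        stats_ = reversal.separability_stats(terms, aligned)
        mean_traj = np.nanmean(aligned.x, axis=0)
        rel = aligned.rel_trials
        pre = rel < 0
        from scipy.stats import rankdata, pearsonr

        for t in range(3):
            ranks_x = rankdata(rel[pre])
            ranks_y = rankdata(mean_traj[pre, t])
            expect = pearsonr(ranks_x, ranks_y).statistic
            assert stats_.spearman_pre[t] == pytest.approx(expect, abs=1e-12)
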