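"""Trajectory mixtures: EM ascent, likelihood oracle, BIC, posterior QC, profiling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from csfaging.simulate import simulate_trajectory_panel
from csfaging.trajectory import (
    GbtaFit,
    GbtaSpec,
    bic,
    fit_gbta,
    model_search,
    occ,
    posterior_qc,
    profile_groups,
)


def naive_mixture_loglik(panel, pi, coefficients, sigma):
    """Independent enumeration oracle: explicit loops, scipy densities."""
    total = 0.0
    for _, obs in panel.groupby("participant_id"):
        lik = 0.0
        for g, p in enumerate(pi):
            prod = p
            for _, row in obs.iterrows():
                mu = np.polynomial.polynomial.polyval(row.time_bin - 3.0, coefficients[g])
                prod *= stats.norm.pdf(row.value, mu, sigma[g])
            lik += prod
        total += math.log(lik)
    return total


class TestFitGbta:
    def test_single_flat_group_closed_form(self):
        panel, _ = simulate_trajectory_panel(50, group_means=(2.0,), group_probs=(1.0,), seed=0)
        fit = fit_gbta(panel, GbtaSpec(n_groups=1, orders=0, n_starts=1))
        y = panel["value"].to_numpy()
        assert fit.pi == pytest.approx([1.0])
        assert fit.coefficients[0][0] == pytest.approx(y.mean(), abs=1e-8)
        assert fit.sigma[0] == pytest.approx(y.std(), abs=1e-6)  # MLE (ddof 0)
        assert np.allclose(fit.posteriors.to_numpy(), 1.0)

    def test_em_loglik_nondecreasing(self):
        rng = np.random.default_rng(1)
        panel = pd.DataFrame(
            {
                "participant_id": np.repeat([f"p{i}" for i in range(30)], 3),
                "time_bin": np.tile([1, 3, 5], 30),
                "value": rng.normal(0, 5, 90),
            }
        )
        fit = fit_gbta(panel, GbtaSpec(n_groups=3, orders=1, n_starts=2, seed=2))
        trace = np.asarray(fit.loglik_trace)
        assert (np.diff(trace) >= -1e-9 * np.maximum(np.abs(trace[:-1]), 1.0)).all()

    def test_two_planted_flat_groups_recovered(self):
        panel, _ = simulate_trajectory_panel(
            100, group_means=(-5.0, 5.0), group_probs=(0.5, 0.5), sigma=1.0,
            retention_prob=1.0, seed=3,
        )
        fit = fit_gbta(panel, GbtaSpec(n_groups=2, orders=0, n_starts=3, seed=3))
        assert fit.coefficients[0][0] == pytest.approx(-5.0, abs=0.3)
        assert fit.coefficients[1][0] == pytest.approx(5.0, abs=0.3)
        assert np.abs(fit.pi - 0.5).max() < 0.05

    def test_loglik_matches_enumeration_oracle(self):
        """Tiny instance: fitted loglik equals the brute-force mixture sum."""
        panel = pd.DataFrame(
            {
                "participant_id": ["a", "a", "b", "b", "c", "c", "d", "d"],
                "time_bin": [1, 2, 1, 2, 4, 5, 4, 5],
                "value": [-3.1, -2.9, -3.3, -2.8, 3.0, 3.2, 2.7, 3.1],
            }
        )
        fit = fit_gbta(panel, GbtaSpec(n_groups=2, orders=0, n_starts=2, seed=4))
        oracle = naive_mixture_loglik(panel, fit.pi, fit.coefficients, fit.sigma)
        assert fit.loglik == pytest.approx(oracle, abs=1e-10)

    def test_groups_canonically_ordered_by_intercept(self):
        panel, _ = simulate_trajectory_panel(
            120, group_means=(4.0, -4.0, 0.0), group_probs=(0.3, 0.3, 0.4), sigma=1.0, seed=5
        )
        fit = fit_gbta(panel, GbtaSpec(n_groups=3, orders=0, n_starts=3, seed=5))
        intercepts = [c[0] for c in fit.coefficients]
        assert intercepts == sorted(intercepts)
        assert np.abs(fit.posteriors.sum(axis=1) - 1.0).max() < 1e-8
        assert abs(fit.pi.sum() - 1.0) < 1e-12

    def test_more_groups_than_participants_rejected(self):
        panel, _ = simulate_trajectory_panel(3, group_means=(0.0,), group_probs=(1.0,), seed=6)
        with pytest.raises(ValueError, match="participants"):
            fit_gbta(panel, GbtaSpec(n_groups=10))

    def test_censored_model_loglik_below_uncensored_at_same_params(self):
        """Censoring replaces density with tail mass for boundary values and
        still yields a finite, valid fit."""
        panel, _ = simulate_trajectory_panel(40, group_means=(0.0,), group_probs=(1.0,), sigma=2.0, seed=7)
        clipped = panel.copy()
        clipped["value"] = clipped["value"].clip(-2.0, 2.0)
        fit = fit_gbta(clipped, GbtaSpec(n_groups=1, orders=0, censor_low=-2.0, censor_high=2.0, n_starts=1))
        assert np.isfinite(fit.loglik)
        assert fit.sigma[0] > 0


class TestBic:
    def test_arithmetic(self):
        fit = GbtaFit(
            spec=GbtaSpec(n_groups=1), pi=np.array([1.0]), coefficients=[np.array([0.0])],
            sigma=np.array([1.0]), loglik=-100.0, n_params=4, n_participants=273,
            n_obs=800, posteriors=pd.DataFrame(np.ones((1, 1))), converged=True,
        )
        assert bic(fit, 273) == pytest.approx(-100.0 - 2.0 * math.log(273))
        with pytest.raises(ValueError):
            bic(fit, 0)

    def test_useless_quadratic_term_penalised(self):
        panel, _ = simulate_trajectory_panel(
            150, group_means=(0.0,), group_probs=(1.0,), sigma=2.0, retention_prob=1.0, seed=8
        )
        flat = fit_gbta(panel, GbtaSpec(n_groups=1, orders=0, n_starts=1))
        quad = fit_gbta(panel, GbtaSpec(n_groups=1, orders=2, n_starts=1))
        assert quad.bic < flat.bic


class TestModelSearch:
    def test_single_candidate_returned(self):
        panel, _ = simulate_trajectory_panel(40, seed=9)
        table, best = model_search(panel, G_range=(2,), order_menu=(0,), seed=9, n_starts=2)
        assert len(table) == 1
        assert best.spec.n_groups == 2

    def test_table_accounts_for_every_candidate(self):
        panel, _ = simulate_trajectory_panel(40, seed=10)
        table, _ = model_search(panel, G_range=range(1, 4), order_menu=(0, 1), seed=10, n_starts=1)
        assert len(table) == 6

    def test_planted_two_groups_selected(self):
        panel, _ = simulate_trajectory_panel(
            150, group_means=(-5.0, 5.0), group_probs=(0.5, 0.5), sigma=1.5, seed=11
        )
        _, best = model_search(panel, G_range=range(1, 5), order_menu=(0,), seed=11, n_starts=3)
        assert best.spec.n_groups == 2

    def test_failures_recorded_not_raised(self):
        panel, _ = simulate_trajectory_panel(5, group_means=(0.0,), group_probs=(1.0,), seed=12)
        table, best = model_search(panel, G_range=(1, 50), order_menu=(0,), seed=12, n_starts=1)
        assert (table["error"] != "").sum() == 1
        assert best.spec.n_groups == 1


class TestOcc:
    def test_chance_classification_is_one(self):
        assert occ(0.4, 0.4) == pytest.approx(1.0)

    def test_worked_example(self):
        assert occ(0.9, 0.5) == pytest.approx(9.0)

    def test_perfect_assignment_is_infinite(self):
        assert math.isinf(occ(1.0, 0.3))

    def test_matches_direct_formula_on_grid(self):
        for app in np.linspace(0.05, 0.95, 10):
            for pi in np.linspace(0.1, 0.9, 9):
                expected = (app / (1 - app)) / (pi / (1 - pi))
                assert occ(app, pi) == pytest.approx(expected, abs=1e-12)

    def test_invalid_pi_rejected(self):
        with pytest.raises(ValueError):
            occ(0.8, 0.0)


def make_fit_with_posteriors(post, pi):
    post = np.asarray(post, dtype=float)
    G = post.shape[1]
    return GbtaFit(
        spec=GbtaSpec(n_groups=G), pi=np.asarray(pi, dtype=float),
        coefficients=[np.array([float(g)]) for g in range(G)], sigma=np.ones(G),
        loglik=0.0, n_params=G + 1, n_participants=post.shape[0], n_obs=post.shape[0],
        posteriors=pd.DataFrame(post, index=[f"p{i}" for i in range(post.shape[0])]),
        converged=True,
    )


class TestPosteriorQc:
    def test_perfect_posteriors_pass(self):
        post = np.repeat(np.eye(2), 10, axis=0)
        qc = posterior_qc(make_fit_with_posteriors(post, [0.5, 0.5]))
        assert qc.passed
        assert (qc.table["app"] == 1.0).all()
        assert np.isinf(qc.table["occ"]).all()

    def test_low_app_group_identified(self):
        post = np.vstack([np.tile([0.6, 0.4], (10, 1)), np.tile([0.05, 0.95], (10, 1))])
        qc = posterior_qc(make_fit_with_posteriors(post, [0.35, 0.65]))
        assert not qc.passed
        assert 1 in qc.failing_groups

    def test_empty_group_fails_with_reason(self):
        post = np.tile([0.9, 0.1], (12, 1))
        qc = posterior_qc(make_fit_with_posteriors(post, [0.9, 0.1]))
        assert not qc.passed
        assert "no modally assigned" in qc.table.loc[1, "reason"]

    def test_separation_sweep(self):
        """Well-separated four flat groups pass QC; groups only ~1 SD apart
        fail on the odds of correct classification."""
        strong, _ = simulate_trajectory_panel(
            250, group_means=(-9.0, -3.0, 3.0, 9.0), group_probs=(0.25,) * 4,
            sigma=1.0, seed=13,
        )
        weak, _ = simulate_trajectory_panel(
            250, group_means=(-1.5, -0.5, 0.5, 1.5), group_probs=(0.1, 0.4, 0.4, 0.1),
            sigma=1.0, seed=13,
        )
        qc_strong = posterior_qc(fit_gbta(strong, GbtaSpec(n_groups=4, orders=0, n_starts=3, seed=13)))
        qc_weak = posterior_qc(fit_gbta(weak, GbtaSpec(n_groups=4, orders=0, n_starts=3, seed=13)))
        assert qc_strong.passed
        assert not qc_weak.passed
        assert not qc_weak.table["occ_ok"].all()


class TestProfileGroups:
    def fit_from_panel(self, n=200, seed=14):
        panel, groups = simulate_trajectory_panel(
            n, group_means=(-5.0, 5.0), group_probs=(0.5, 0.5), sigma=1.0, seed=seed
        )
        fit = fit_gbta(panel, GbtaSpec(n_groups=2, orders=0, n_starts=2, seed=seed))
        return fit, groups

    def test_group_sizes_partition_panel(self):
        fit, _ = self.fit_from_panel()
        profile = profile_groups(fit, pd.DataFrame({"participant_id": fit.posteriors.index, "age": 50.0}))
        assert sum(profile.attrs["group_sizes"].values()) == fit.n_participants

    def test_planted_sex_imbalance_detected(self):
        fit, groups = self.fit_from_panel()
        rng = np.random.default_rng(15)
        sex = {
            pid: ("female" if rng.random() < (0.9 if groups[pid] == 0 else 0.2) else "male")
            for pid in fit.posteriors.index
        }
        cov = pd.DataFrame({"participant_id": list(sex), "sex": list(sex.values())})
        profile = profile_groups(fit, cov)
        p = profile.loc[profile["variable"] == "sex", "p"].iloc[0]
        assert p < 0.01

    def test_single_group_runs_no_tests(self):
        panel, _ = simulate_trajectory_panel(40, group_means=(0.0,), group_probs=(1.0,), seed=16)
        fit = fit_gbta(panel, GbtaSpec(n_groups=1, orders=0, n_starts=1))
        cov = pd.DataFrame({"participant_id": fit.posteriors.index, "age": 50.0, "sex": "female"})
        profile = profile_groups(fit, cov)
        assert profile["p"].isna().all()
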