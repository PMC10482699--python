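"""Beta-binomial differential-abundance engine.

The MLE path is cross-checked against three independent oracles: a logistic
GLM fitted by IRLS in the binomial (phi -> 0) limit, a nested dense grid
search over (beta0, beta_group, phi) using scipy's betabinom pmf as the
objective, and random admissible parameter points that must never beat the
returned optimum.
"""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import special, stats

from pyrotraits.diffabund import (
    BetaBinomialFit,
    ContrastDesign,
    bh_adjust,
    fit_beta_binomial,
    likelihood_ratio_test,
    log2_fold_change,
    fit_taxa,
    wald_test,
)


def make_design(n=16, seed=7, totals=50_000.0):
    r = np.random.default_rng(seed)
    grp = np.array([0.0, 1.0] * (n // 2))
    ph = r.normal(5, 1, n)
    return ContrastDesign([f"s{i}" for i in range(n)], grp, ph, np.full(n, totals))


# fixed 8-sample fixture for the grid-search oracle: counts / totals
FIXTURE_COUNTS = np.array([12.0, 45.0, 9.0, 38.0, 15.0, 52.0, 7.0, 61.0])
FIXTURE_TOTALS = np.array([4000.0, 5000.0, 3500.0, 4500.0, 5000.0, 6000.0, 4000.0, 5500.0])
FIXTURE_GROUP = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0])


def fixture_design():
    return ContrastDesign(
        [f"s{i}" for i in range(8)],
        FIXTURE_GROUP,
        np.empty((8, 0)),  # no covariates: oracle model is (b0, bg, phi)
        FIXTURE_TOTALS,
    )


def oracle_loglik(b0, bg, phi, counts=FIXTURE_COUNTS, totals=FIXTURE_TOTALS, grp=FIXTURE_GROUP):
    """Independent objective: scipy's beta-binomial pmf."""
    mu = special.expit(b0 + bg * grp)
    a = mu * (1 - phi) / phi
    b = (1 - mu) * (1 - phi) / phi
    return stats.betabinom.logpmf(counts, totals.astype(int), a, b).sum()


class TestFitBetaBinomial:
    def test_exchangeable_arms_give_null_effect(self):
        n = 12
        design = ContrastDesign(
            [f"s{i}" for i in range(n)],
            np.array([0.0, 1.0] * (n // 2)),
            np.zeros(n),
            np.full(n, 100.0),
        )
        fit = fit_beta_binomial(np.full(n, 10.0), design)
        assert abs(fit.beta[1]) < 1e-6
        assert wald_test(fit) == pytest.approx(1.0, abs=1e-3)

    def test_binomial_limit_matches_irls_oracle(self):
        design = make_design(n=40, seed=1)
        X = design.matrix()
        r = np.random.default_rng(11)
        mu = special.expit(X @ np.array([-6.0, 1.0, 0.3]))
        counts = r.binomial(design.totals.astype(int), mu).astype(float)
        fit = fit_beta_binomial(counts, design)
        glm = sm.GLM(
            np.column_stack([counts, design.totals - counts]),
            X,
            family=sm.families.Binomial(),
        ).fit()
        assert fit.phi < 1e-4
        assert np.max(np.abs(fit.beta - glm.params)) < 1e-4

    def test_mle_matches_nested_grid_search(self):
        """Coarse-to-fine grid over (b0, bg, phi), final resolution 1e-3."""
        design = fixture_design()
        fit = fit_beta_binomial(FIXTURE_COUNTS, design)

        lo = np.array([-8.0, -2.0, np.log(1e-5)])
        hi = np.array([-2.0, 4.0, np.log(0.5)])
        best = None
        for _ in range(6):  # each pass shrinks the box 5x around the argmax
            axes = [np.linspace(lo[j], hi[j], 21) for j in range(3)]
            B0, BG, LP = np.meshgrid(*axes, indexing="ij")
            vals = np.array(
                [
                    oracle_loglik(b0, bg, np.exp(lp))
                    for b0, bg, lp in zip(B0.ravel(), BG.ravel(), LP.ravel())
                ]
            )
            k = np.argmax(vals)
            best = vals[k]
            centre = np.array([B0.ravel()[k], BG.ravel()[k], LP.ravel()[k]])
            width = (hi - lo) / 5.0
            lo, hi = centre - width / 2, centre + width / 2
        at_mle = oracle_loglik(fit.beta[0], fit.beta[1], fit.phi)
        assert at_mle >= best - 1e-3

    def test_mle_beats_random_admissible_points(self):
        design = fixture_design()
        fit = fit_beta_binomial(FIXTURE_COUNTS, design)
        at_mle = oracle_loglik(fit.beta[0], fit.beta[1], fit.phi)
        r = np.random.default_rng(5)
        for _ in range(100):
            b0 = r.uniform(-10, 0)
            bg = r.uniform(-3, 5)
            phi = r.uniform(1e-5, 0.9)
            assert oracle_loglik(b0, bg, phi) <= at_mle + 1e-9

    def test_all_zero_taxon_flagged_not_raised(self):
        design = make_design()
        fit = fit_beta_binomial(np.zeros(16), design)
        assert not fit.estimable
        assert np.isnan(wald_test(fit))
        lfc, se = log2_fold_change(fit, design)
        assert np.isnan(lfc) and np.isnan(se)

    def test_separation_flagged_and_bounded(self):
        design = make_design()
        counts = np.where(design.group_indicator == 1, 200.0, 0.0)
        fit = fit_beta_binomial(counts, design)
        assert fit.separated
        assert np.all(np.abs(fit.beta) <= 30.0)


class TestLog2FoldChange:
    def test_known_ratio(self):
        # mu1 = 0.04, mu0 = 0.01: fold change 4, log2 = 2
        fit = BetaBinomialFit(
            beta=np.array([special.logit(0.01), special.logit(0.04) - special.logit(0.01)]),
            phi=0.01,
            covariance=np.eye(3),
            loglik=0.0,
            converged=True,
            n_samples=8,
        )
        lfc, _ = log2_fold_change(fit, None)
        assert lfc == pytest.approx(2.0, abs=1e-12)

    def test_equal_means_give_zero(self):
        fit = BetaBinomialFit(
            beta=np.array([-3.0, 0.0]), phi=0.01, covariance=np.eye(3),
            loglik=0.0, converged=True, n_samples=8,
        )
        assert log2_fold_change(fit, None)[0] == pytest.approx(0.0)

    def test_fixture_ratio_matches_grid_argmax(self):
        design = fixture_design()
        fit = fit_beta_binomial(FIXTURE_COUNTS, design)
        lfc, se = log2_fold_change(fit, design)
        mu1 = special.expit(fit.beta[0] + fit.beta[1])
        mu0 = special.expit(fit.beta[0])
        assert lfc == pytest.approx(np.log2(mu1 / mu0), abs=1e-3)
        assert se > 0


class TestWaldTest:
    def test_zero_statistic_gives_p_one(self):
        fit = BetaBinomialFit(
            beta=np.array([-3.0, 0.0]), phi=0.01, covariance=np.eye(3),
            loglik=0.0, converged=True, n_samples=16,
        )
        assert wald_test(fit) == pytest.approx(1.0)

    def test_large_sample_normal_quantile(self):
        # with many samples the t reference approaches the normal one
        se = 1.0
        fit = BetaBinomialFit(
            beta=np.array([0.0, 1.959964]), phi=0.01,
            covariance=np.eye(3) * se, loglik=0.0, converged=True, n_samples=100_000,
        )
        assert wald_test(fit) == pytest.approx(0.05, abs=1e-3)

    def test_agrees_with_lrt_on_fixture(self):
        design = make_design(seed=3)
        r = np.random.default_rng(21)
        mu = np.where(design.group_indicator == 1, 0.02, 0.005)
        theta = 0.98 / 0.02
        p = r.beta(mu * theta, (1 - mu) * theta)
        counts = r.binomial(design.totals.astype(int), p).astype(float)
        fit = fit_beta_binomial(counts, design)
        p_wald = wald_test(fit)
        p_lrt = likelihood_ratio_test(counts, design, fit)
        assert (p_wald < 0.05) == (p_lrt < 0.05)


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([0.05]).tolist() == [0.05]

    def test_step_up_by_hand(self):
        # ranks 1..4 of m=4: q_i = min_j>=i p_j * 4 / j = 0.04 for all
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_nan_passthrough(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # m = 2 among the finite entries
        assert np.allclose(q[[0, 2]], [0.02, 0.04])

    def test_capped_at_one(self):
        assert np.all(bh_adjust([0.5, 0.9, 0.99]) <= 1.0)


class TestCalibration:
    def test_log2fc_estimate_unbiased(self):
        """Mean estimated log2fc within +-0.2 of the generating value 2."""
        design = make_design(seed=2)
        theta = 0.98 / 0.02  # phi = 0.02
        estimates = []
        for rep in range(200):
            r = np.random.default_rng(1000 + rep)
            mu = np.where(design.group_indicator == 1, 0.005 * 4, 0.005)
            p = r.beta(mu * theta, (1 - mu) * theta)
            counts = r.binomial(design.totals.astype(int), p).astype(float)
            fit = fit_beta_binomial(counts, design)
            estimates.append(log2_fold_change(fit, design)[0])
        assert abs(np.mean(estimates) - 2.0) < 0.2


class TestTestTaxa:
    def test_prevalence_floor_and_q_values(self, rng):
        n = 16
        design = make_design()
        counts = rng.integers(0, 50, size=(10, n)).astype(float)
        counts[0] = 0.0
        counts[1, :] = 0.0
        counts[1, 0] = 3.0  # present in one sample only: below the floor
        results = fit_taxa(counts, [f"t{i}" for i in range(10)], design)
        tested = {r.taxon_id for r in results}
        assert "t0" not in tested and "t1" not in tested
        qs = np.array([r.q_value for r in results])
        ps = np.array([r.p_value for r in results])
        assert np.all(qs[np.isfinite(qs)] >= ps[np.isfinite(qs)] - 1e-12)
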