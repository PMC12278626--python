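"""Line-model priors, marginal likelihoods, Gibbs proportions, classification."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from scipy.special import gammaln

from sexde import linemodels as lm
from sexde.linemodels import (
    LineModelConfig,
    LineModelSpec,
    classify_genes,
    compute_scale,
    default_models,
    estimate_r_lkhood,
    gibbs_proportions,
    marginal_loglik,
    posterior_probs,
    prior_covariance,
)
from sexde.simulate import SimulationConfig, simulate_effect_pairs


class TestPriorCovariance:
    def test_slope_zero_degenerates_on_first_axis(self):
        cov = prior_covariance(LineModelSpec("a", 0.0, scale=0.3))
        assert np.allclose(cov, np.diag([0.09, 0.0]))

    def test_slope_inf_degenerates_on_second_axis(self):
        cov = prior_covariance(LineModelSpec("a", math.inf, scale=0.3))
        assert np.allclose(cov, np.diag([0.0, 0.09]))

    def test_slope_one_formula(self):
        s = 0.2
        cov = prior_covariance(LineModelSpec("a", 1.0, scale=s, cor=0.995))
        assert np.allclose(cov, [[s**2, 0.995 * s**2], [0.995 * s**2, s**2]])

    def test_opposite_slope_negative_offdiagonal(self):
        s = lm.DEFAULT_SCALE
        cov = prior_covariance(LineModelSpec("OPPOSITE", -1.0, cor=0.990))
        assert cov[0, 1] == pytest.approx(-0.990 * s**2)
        assert np.all(np.linalg.eigvalsh(cov) >= -1e-12)

    def test_invalid_cor(self):
        with pytest.raises(ValueError):
            LineModelSpec("a", 1.0, cor=1.0)


class TestMarginalLoglik:
    def test_origin_ordering_follows_determinant(self):
        b = np.array([0.0, 0.0])
        se = np.array([0.05, 0.05])
        models = default_models()
        ll = [marginal_loglik(b, se, m)[0] for m in models]
        dets = []
        for m in models:
            cov = prior_covariance(m) + np.diag(se**2)
            dets.append(np.linalg.det(cov))
        assert np.argsort(ll) == pytest.approx(np.argsort([-d for d in dets]))

    def test_dataset1_specific_pair_prefers_prenatal(self):
        b = np.array([0.5, 0.01])
        se = np.array([0.05, 0.05])
        models = {m.name: m for m in default_models()}
        assert (
            marginal_loglik(b, se, models["PRENATAL"])[0]
            > marginal_loglik(b, se, models["SHARED1"])[0]
        )

    @pytest.mark.parametrize("x", [0.05, 0.2, 0.5])
    def test_symmetric_pair_prefers_shared_over_opposite(self, x):
        b = np.array([x, x])
        se = np.array([0.04, 0.04])
        models = {m.name: m for m in default_models()}
        assert (
            marginal_loglik(b, se, models["SHARED1"])[0]
            > marginal_loglik(b, se, models["OPPOSITE"])[0]
        )

    def test_matches_numerical_integration_of_hierarchy(self):
        """Marginal density equals the integral over the latent effect pair."""
        b = np.array([0.25, 0.12])
        se = np.array([0.06, 0.09])
        spec = LineModelSpec("SHARED1", 1.0)
        cov_p = prior_covariance(spec)
        obs = stats.multivariate_normal(cov=np.diag(se**2))
        prior = stats.multivariate_normal(cov=cov_p, allow_singular=False)

        def integrand(b2, b1):
            beta = np.array([b1, b2])
            return prior.pdf(beta) * obs.pdf(b - beta)

        val, _ = integrate.dblquad(integrand, -1.5, 1.5, -1.5, 1.5, epsabs=1e-12)
        assert marginal_loglik(b, se, spec)[0] == pytest.approx(np.log(val), abs=1e-6)

    def test_matches_1d_integration_for_degenerate_prior(self):
        """Slope-0 prior lives on the first axis: 1-D latent integral."""
        b = np.array([0.3, -0.05])
        se = np.array([0.05, 0.08])
        spec = LineModelSpec("PRENATAL", 0.0)

        def integrand(beta1):
            return (
                stats.norm.pdf(beta1, scale=spec.scale)
                * stats.norm.pdf(b[0] - beta1, scale=se[0])
                * stats.norm.pdf(b[1], scale=se[1])
            )

        val, _ = integrate.quad(integrand, -2, 2, epsabs=1e-13)
        assert marginal_loglik(b, se, spec)[0] == pytest.approx(np.log(val), abs=1e-8)

    def test_se_must_be_positive(self):
        with pytest.raises(ValueError):
            marginal_loglik(np.array([0.1, 0.1]), np.array([0.0, 0.1]),
                            LineModelSpec("a", 1.0))


def _toy_pairs(n=5, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "b_prenatal": rng.normal(0, 0.3, n),
            "se_prenatal": rng.uniform(0.03, 0.1, n),
            "b_adult": rng.normal(0, 0.3, n),
            "se_adult": rng.uniform(0.03, 0.1, n),
        }
    )


class TestPosteriorProbs:
    def test_single_model_gives_unit_pp(self):
        pairs = _toy_pairs()
        config = LineModelConfig(models=(LineModelSpec("only", 1.0),))
        pp = posterior_probs(pairs, config, np.array([1.0]))
        assert np.allclose(pp.to_numpy(), 1.0)

    def test_overwhelming_likelihood_dominates(self):
        pairs = pd.DataFrame(
            {
                "gene_id": ["g"],
                "b_prenatal": [0.6],
                "se_prenatal": [0.005],
                "b_adult": [0.001],
                "se_adult": [0.005],
            }
        )
        config = LineModelConfig()
        pp = posterior_probs(pairs, config, np.full(6, 1 / 6))
        assert pp.loc["g", "PRENATAL"] > 0.999

    def test_matches_direct_normalization_oracle(self):
        """Row-by-row densities via scipy multivariate normal, normalized."""
        pairs = _toy_pairs(5, seed=3)
        config = LineModelConfig()
        pi = np.array([0.3, 0.2, 0.2, 0.1, 0.1, 0.1])
        pp = posterior_probs(pairs, config, pi)
        for i, row in pairs.iterrows():
            b = np.array([row["b_prenatal"], row["b_adult"]])
            se = np.array([row["se_prenatal"], row["se_adult"]])
            dens = []
            for m in config.models:
                cov = prior_covariance(m) + np.diag(se**2)
                dens.append(stats.multivariate_normal(cov=cov).pdf(b))
            expected = pi * np.array(dens)
            expected /= expected.sum()
            assert np.allclose(pp.iloc[i].to_numpy(), expected, atol=1e-12)

    def test_rows_sum_to_one(self):
        pairs = _toy_pairs(50, seed=4)
        pp = posterior_probs(pairs, LineModelConfig(), np.full(6, 1 / 6))
        assert np.allclose(pp.sum(axis=1), 1.0, atol=1e-9)


class TestGibbs:
    def test_zero_genes_returns_dirichlet_prior_mean(self):
        res = gibbs_proportions(_toy_pairs(0), LineModelConfig())
        assert np.allclose(res.proportions, 1 / 6)

    def test_shared1_dominated_simulation(self):
        cfg = SimulationConfig(
            n_genes=2000, seed=5, se_range=(0.01, 0.05),
            category_proportions=(0, 0, 0, 1.0, 0, 0, 0),
            n_escape_genes=1, n_inactive_genes=1,
        )
        pairs, _ = simulate_effect_pairs(cfg)
        res = gibbs_proportions(pairs, LineModelConfig(seed=1))
        assert res.proportions["SHARED1"] >= 0.9

    def test_seed_reproducibility(self):
        pairs = _toy_pairs(100, seed=6)
        r1 = gibbs_proportions(pairs, LineModelConfig(seed=9))
        r2 = gibbs_proportions(pairs, LineModelConfig(seed=9))
        pd.testing.assert_series_equal(r1.proportions, r2.proportions)
        pd.testing.assert_frame_equal(r1.posterior, r2.posterior)

    def test_burn_in_validation(self):
        with pytest.raises(ValueError):
            LineModelConfig(n_iter=100, burn_in=100)


def test_axis_swap_symmetry():
    """Swapping the two datasets and mapping slopes s -> 1/s leaves PPs unchanged."""
    pairs = _toy_pairs(40, seed=8)
    config = LineModelConfig()
    pi = np.full(6, 1 / 6)
    pp = posterior_probs(pairs, config, pi)

    swapped = pairs.rename(
        columns={
            "b_prenatal": "b_adult",
            "b_adult": "b_prenatal",
            "se_prenatal": "se_adult",
            "se_adult": "se_prenatal",
        }
    )
    s = lm.DEFAULT_SCALE
    swapped_models = (
        LineModelSpec("PRENATAL", math.inf, s),  # was slope 0
        LineModelSpec("SHARED0.5", 2.0, 0.5 * s),
        LineModelSpec("SHARED1", 1.0, s),
        LineModelSpec("SHARED2", 0.5, 2.0 * s),
        LineModelSpec("ADULT", 0.0, s),  # was slope inf
        LineModelSpec("OPPOSITE", -1.0, s, lm.DEFAULT_COR_OPPOSITE),
    )
    pp_swapped = posterior_probs(
        swapped, LineModelConfig(models=swapped_models), pi
    )
    assert np.allclose(pp.to_numpy(), pp_swapped.to_numpy(), atol=1e-6)


def test_vanishing_se_pins_gene_to_its_line():
    models = default_models()
    pi = np.full(6, 1 / 6)
    points = {
        "PRENATAL": (0.3, 0.0),
        "SHARED0.5": (0.3, 0.15),
        "SHARED1": (0.3, 0.3),
        "SHARED2": (0.15, 0.3),
        "ADULT": (0.0, 0.3),
        "OPPOSITE": (0.3, -0.3),
    }
    for name, (b1, b2) in points.items():
        pairs = pd.DataFrame(
            {
                "gene_id": ["g"],
                "b_prenatal": [b1],
                "se_prenatal": [1e-4],
                "b_adult": [b2],
                "se_adult": [1e-4],
            }
        )
        pp = posterior_probs(pairs, LineModelConfig(), pi)
        assert pp.iloc[0].idxmax() == name


class TestClassify:
    def _pp(self, rows):
        return pd.DataFrame(
            rows,
            columns=["PRENATAL", "SHARED0.5", "SHARED1", "SHARED2", "ADULT", "OPPOSITE"],
            index=[f"g{i}" for i in range(len(rows))],
        )

    def test_threshold_rules(self):
        pp = self._pp(
            [
                [0.95, 0.01, 0.01, 0.01, 0.01, 0.01],  # prenatal-specific
                [0.10, 0.40, 0.30, 0.20, 0.0, 0.0],  # shared, unspecified
                [0.05, 0.85, 0.05, 0.0, 0.0, 0.05],  # shared / SHARED0.5
                [0.30, 0.10, 0.10, 0.10, 0.30, 0.10],  # unclassified
                [0.01, 0.01, 0.01, 0.01, 0.95, 0.01],  # adult-specific
                [0.05, 0.02, 0.02, 0.01, 0.05, 0.85],  # opposite
            ]
        )
        out = classify_genes(pp)
        assert list(out["category"]) == [
            "prenatal-specific",
            "shared",
            "shared",
            "unclassified",
            "adult-specific",
            "opposite",
        ]
        assert out.loc["g1", "shared_sublabel"] == "unspecified"
        assert out.loc["g2", "shared_sublabel"] == "SHARED0.5"

    def test_malformed_rows_rejected(self):
        pp = self._pp([[0.5, 0.1, 0.1, 0.1, 0.1, 0.0]])  # sums to 0.9
        with pytest.raises(ValueError):
            classify_genes(pp)


class TestComputeScale:
    def test_constant_magnitudes(self):
        assert compute_scale(np.full(50, 0.4)) == pytest.approx(0.2)
        assert compute_scale(np.array([-0.4, 0.4, -0.4, 0.4])) == pytest.approx(0.2)

    def test_percentile_with_outlier(self):
        v = np.array([0.1] * 100 + [0.6])
        # 95th percentile of |logFC| is 0.1 -> scale 0.05
        assert compute_scale(v) == pytest.approx(0.05, abs=1e-6)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            compute_scale(np.array([]))


class TestEstimateRLkhood:
    def test_identical_null_effects_give_one(self):
        rng = np.random.default_rng(0)
        lfc = rng.normal(size=100)
        p = np.full(100, 0.5)
        assert estimate_r_lkhood(lfc, p, lfc, p) == pytest.approx(1.0)

    def test_independent_null_effects_near_zero(self):
        rng = np.random.default_rng(1)
        n = 4000
        l1, l2 = rng.normal(size=n), rng.normal(size=n)
        p1, p2 = rng.uniform(size=n), rng.uniform(size=n)
        assert abs(estimate_r_lkhood(l1, p1, l2, p2)) < 0.05

    def test_filter_is_strict_in_both_datasets(self):
        lfc = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        p1 = np.array([0.05, 0.5, 0.5, 0.5, 0.5])
        p2 = np.array([0.5, 0.05, 0.5, 0.5, 0.5])
        # genes 0 and 1 must be excluded; exactly 3 genes remain
        r = estimate_r_lkhood(lfc, p1, lfc, p2)
        assert r == pytest.approx(1.0)
        with pytest.raises(ValueError):
            estimate_r_lkhood(lfc, np.full(5, 0.01), lfc, p2)
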