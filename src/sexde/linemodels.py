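"""Bayesian line-model classification of paired effect sizes.

Each gene contributes an estimated effect pair (b1, b2) with standard
errors — here the sex logFC in the prenatal and adult dataset.  Competing
hypotheses about the true pair (beta1, beta2) are "line models": thin
bivariate Gaussian priors concentrated along a line through the origin
with a given slope.  The default set:

    PRENATAL   slope 0     effect only in dataset 1
    SHARED0.5  slope 0.5   shared, twice as large in dataset 1
    SHARED1    slope 1     shared, equal magnitude
    SHARED2    slope 2     shared, twice as large in dataset 2
    ADULT      slope inf   effect only in dataset 2
    OPPOSITE   slope -1    equal magnitude, opposite sign

Each model's prior covariance is built from its slope, a scale (prior sd
of the dataset-1 effect; default 0.1971916, the 95th percentile of
|logFC| in a prenatal brain sex-DE analysis divided by 2) and a
correlation controlling the allowed deviation from the line (0.995, or
0.990 for OPPOSITE).  The marginal likelihood of the observed pair under a
model is a zero-mean bivariate normal with covariance prior + observation
noise, where the observation covariance allows a correlation (r_lkhood)
between the two estimators when the datasets share individuals.

Mixture proportions over the models are estimated by Gibbs sampling
(model assignments | proportions, then Dirichlet proportions | counts),
and genes are classified by thresholding posterior probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEFAULT_SCALE = 0.1971916
DEFAULT_COR = 0.995
DEFAULT_COR_OPPOSITE = 0.990

SHARED_MODELS = ("SHARED0.5", "SHARED1", "SHARED2")


@dataclass(frozen=True)
class LineModelSpec:
    """One line hypothesis: slope, scale and concentration of the prior."""

    name: str
    slope: float  # may be math.inf
    scale: float = DEFAULT_SCALE
    cor: float = DEFAULT_COR

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not abs(self.cor) < 1:
            raise ValueError("|cor| must be < 1")


def default_models(
    scale: float = DEFAULT_SCALE,
    cor: float = DEFAULT_COR,
    cor_opposite: float = DEFAULT_COR_OPPOSITE,
) -> list[LineModelSpec]:
    return [
        LineModelSpec("PRENATAL", 0.0, scale, cor),
        LineModelSpec("SHARED0.5", 0.5, scale, cor),
        LineModelSpec("SHARED1", 1.0, scale, cor),
        LineModelSpec("SHARED2", 2.0, scale, cor),
        LineModelSpec("ADULT", math.inf, scale, cor),
        LineModelSpec("OPPOSITE", -1.0, scale, cor_opposite),
    ]


@dataclass(frozen=True)
class LineModelConfig:
    models: tuple[LineModelSpec, ...] = tuple(default_models())
    r_lkhood: float = 0.0  # correlation between the two effect estimators
    n_iter: int = 2000
    burn_in: int = 200
    dirichlet_prior: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if not abs(self.r_lkhood) < 1:
            raise ValueError("|r_lkhood| must be < 1")
        if self.dirichlet_prior <= 0:
            raise ValueError("dirichlet_prior must be positive")

    @property
    def model_names(self) -> list[str]:
        return [m.name for m in self.models]


@dataclass
class LineModelResult:
    posterior: pd.DataFrame  # genes x models, rows sum to 1
    proportions: pd.Series
    proportions_se: pd.Series
    categories: pd.Series | None = None


def prior_covariance(spec: LineModelSpec) -> np.ndarray:
    """2x2 prior covariance of the true effect pair under one line model.

    sd1 = scale, sd2 = |slope| * scale, off-diagonal sign(slope)*cor*sd1*sd2.
    slope 0 and inf degenerate onto the two axes.
    """
    s = spec.scale
    if spec.slope == 0.0:
        return np.array([[s**2, 0.0], [0.0, 0.0]])
    if math.isinf(spec.slope):
        return np.array([[0.0, 0.0], [0.0, s**2]])
    sd1 = s
    sd2 = abs(spec.slope) * s
    off = math.copysign(1.0, spec.slope) * spec.cor * sd1 * sd2
    return np.array([[sd1**2, off], [off, sd2**2]])


def _total_covariances(
    se: np.ndarray, models: tuple[LineModelSpec, ...], r_lkhood: float
) -> np.ndarray:
    """Per-gene, per-model total covariance prior + observation (g, k, 2, 2)."""
    g = se.shape[0]
    obs = np.zeros((g, 2, 2))
    obs[:, 0, 0] = se[:, 0] ** 2
    obs[:, 1, 1] = se[:, 1] ** 2
    obs[:, 0, 1] = obs[:, 1, 0] = r_lkhood * se[:, 0] * se[:, 1]
    priors = np.stack([prior_covariance(m) for m in models])  # k x 2 x 2
    return obs[:, None, :, :] + priors[None, :, :, :]


def marginal_loglik(
    b: np.ndarray,
    se: np.ndarray,
    spec: LineModelSpec,
    r_lkhood: float = 0.0,
) -> np.ndarray:
    """Log marginal density of observed pairs under one line model.

    Zero-mean bivariate normal at b with covariance
    prior(spec) + [[se1^2, r se1 se2], [r se1 se2, se2^2]].
    """
    b = np.atleast_2d(np.asarray(b, float))
    se = np.atleast_2d(np.asarray(se, float))
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    cov = _total_covariances(se, (spec,), r_lkhood)[:, 0]
    return _bvn_logpdf(b, cov)


def _bvn_logpdf(b: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Vectorized zero-mean bivariate normal log density."""
    det = cov[..., 0, 0] * cov[..., 1, 1] - cov[..., 0, 1] ** 2
    if np.any(det <= 0):
        raise ValueError("singular total covariance")
    inv00 = cov[..., 1, 1] / det
    inv11 = cov[..., 0, 0] / det
    inv01 = -cov[..., 0, 1] / det
    b1 = b[..., 0]
    b2 = b[..., 1]
    quad = inv00 * b1**2 + 2 * inv01 * b1 * b2 + inv11 * b2**2
    return -math.log(2 * math.pi) - 0.5 * np.log(det) - 0.5 * quad


def loglik_matrix(pairs: pd.DataFrame, config: LineModelConfig) -> np.ndarray:
    """Genes x models log marginal likelihoods."""
    b = pairs[["b_prenatal", "b_adult"]].to_numpy(float)
    se = pairs[["se_prenatal", "se_adult"]].to_numpy(float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    cov = _total_covariances(se, config.models, config.r_lkhood)
    return _bvn_logpdf(b[:, None, :], cov)


def posterior_probs(
    pairs: pd.DataFrame,
    config: LineModelConfig,
    proportions: np.ndarray,
) -> pd.DataFrame:
    """Per-gene posterior probabilities at fixed mixture proportions."""
    pi = np.asarray(proportions, float)
    if abs(pi.sum() - 1.0) > 1e-8 or np.any(pi < 0):
        raise ValueError("proportions must lie on the simplex")
    ll = loglik_matrix(pairs, config)
    pp = _softmax_rows(ll + np.log(np.maximum(pi, 1e-300))[None, :])
    return pd.DataFrame(pp, index=pairs["gene_id"], columns=config.model_names)


def _softmax_rows(logw: np.ndarray) -> np.ndarray:
    m = logw.max(axis=1, keepdims=True)
    w = np.exp(logw - m)
    return w / w.sum(axis=1, keepdims=True)


def gibbs_proportions(
    pairs: pd.DataFrame, config: LineModelConfig
) -> LineModelResult:
    """Gibbs sampler for mixture proportions over the line models.

    Alternates sampling per-gene model assignments from the current
    membership probabilities and proportions from the Dirichlet
    posterior.  Reports the posterior mean and SD of the proportions over
    post-burn-in sweeps, and the Rao-Blackwellized posterior-probability
    matrix (mean of per-sweep membership probabilities).
    """
    k = len(config.models)
    names = config.model_names
    if len(pairs) == 0:
        # prior-only posterior: Dirichlet mean and SD
        a = np.full(k, config.dirichlet_prior)
        a0 = a.sum()
        mean = a / a0
        sd = np.sqrt(a * (a0 - a) / (a0**2 * (a0 + 1)))
        return LineModelResult(
            posterior=pd.DataFrame(columns=names),
            proportions=pd.Series(mean, index=names),
            proportions_se=pd.Series(sd, index=names),
        )
    rng = np.random.default_rng(config.seed)
    ll = loglik_matrix(pairs, config)
    g = ll.shape[0]
    pi = np.full(k, 1.0 / k)
    keep = config.n_iter - config.burn_in
    pi_draws = np.empty((keep, k))
    pp_sum = np.zeros((g, k))
    for it in range(config.n_iter):
        pp = _softmax_rows(ll + np.log(np.maximum(pi, 1e-300))[None, :])
        # vectorized categorical draw per gene
        u = rng.random((g, 1))
        assign = (pp.cumsum(axis=1) < u).sum(axis=1)
        counts = np.bincount(assign, minlength=k)
        pi = rng.dirichlet(config.dirichlet_prior + counts)
        if it >= config.burn_in:
            pi_draws[it - config.burn_in] = pi
            pp_sum += pp
    posterior = pp_sum / keep
    posterior /= posterior.sum(axis=1, keepdims=True)
    return LineModelResult(
        posterior=pd.DataFrame(posterior, index=pairs["gene_id"], columns=names),
        proportions=pd.Series(pi_draws.mean(axis=0), index=names),
        proportions_se=pd.Series(pi_draws.std(axis=0, ddof=1), index=names),
    )


def classify_genes(
    posterior: pd.DataFrame, threshold: float = 0.8
) -> pd.DataFrame:
    """Category labels from the posterior-probability matrix.

    shared            sum of the shared-model PPs > threshold
                      (sub-label: the single shared model whose own PP
                      exceeds the threshold, else "unspecified")
    prenatal-specific PRENATAL PP > threshold
    adult-specific    ADULT PP > threshold
    opposite          OPPOSITE PP > threshold
    unclassified      otherwise
    """
    rows_ok = np.allclose(posterior.sum(axis=1), 1.0, atol=1e-6)
    if not rows_ok or (posterior.to_numpy() < -1e-9).any():
        raise ValueError("malformed posterior-probability rows")
    shared_cols = [c for c in SHARED_MODELS if c in posterior.columns]
    shared_pp = posterior[shared_cols].sum(axis=1)
    category = pd.Series("unclassified", index=posterior.index, dtype=object)
    sub = pd.Series("", index=posterior.index, dtype=object)
    if "PRENATAL" in posterior:
        category[posterior["PRENATAL"] > threshold] = "prenatal-specific"
    if "ADULT" in posterior:
        category[posterior["ADULT"] > threshold] = "adult-specific"
    if "OPPOSITE" in posterior:
        category[posterior["OPPOSITE"] > threshold] = "opposite"
    is_shared = shared_pp > threshold
    category[is_shared] = "shared"
    sub[is_shared] = "unspecified"
    for c in shared_cols:
        sub[is_shared & (posterior[c] > threshold)] = c
    return pd.DataFrame({"category": category, "shared_sublabel": sub})


def compute_scale(logfc: np.ndarray) -> float:
    """Prior scale: 95th percentile of |logFC| divided by 2.

    Computed over the discovery (dataset-1) sex-DE genes with linear
    interpolation between order statistics.  The shipped default constant
    (0.1971916) is the value this rule yields on a large prenatal brain
    dataset.
    """
    logfc = np.asarray(logfc, float)
    if logfc.size == 0:
        raise ValueError("empty logFC vector")
    return float(np.percentile(np.abs(logfc), 95, method="linear") / 2.0)


def estimate_r_lkhood(
    logfc1: np.ndarray,
    p1: np.ndarray,
    logfc2: np.ndarray,
    p2: np.ndarray,
    p_threshold: float = 0.10,
) -> float:
    """Estimator correlation for dataset pairs sharing individuals.

    Pearson correlation of the logFCs over genes that are not strongly
    sex-DE (p > 0.10) in both datasets; those genes carry mostly noise,
    so their correlation reflects the estimators, not shared signal.
    """
    logfc1, p1 = np.asarray(logfc1, float), np.asarray(p1, float)
    logfc2, p2 = np.asarray(logfc2, float), np.asarray(p2, float)
    keep = (p1 > p_threshold) & (p2 > p_threshold)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 genes pass the null-gene filter")
    return float(np.corrcoef(logfc1[keep], logfc2[keep])[0, 1])
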