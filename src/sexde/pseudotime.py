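"""Covariate-adjusted latent developmental trajectory (pseudotime).

Fits, per sample, a single latent coordinate z from normalized expression
of the most variable genes under the factor model

    y_gn = mu_g + c_g z_n + alpha_g x_n + beta_g x_n z_n + eps_gn

where x is the sex indicator.  Sex enters both additively (alpha) and
through a sex-by-pseudotime interaction loading (beta), so genes may have
different trajectories in the two sexes.

Inference is penalized alternating least squares: per-gene ridge
regressions given z, then per-sample posterior means of z under a unit
normal prior given the loadings.  Each half-step minimizes the same
penalized objective, which is therefore non-increasing sweep by sweep.
z is initialized at the first principal component of the sex-centered
matrix (see fit_trajectory) and standardized on exit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TrajectoryFit:
    z: pd.Series  # per-sample latent pseudotime, standardized
    mu: pd.Series
    c: pd.Series  # per-gene trajectory loading
    alpha: pd.Series  # per-gene sex effect
    beta: pd.Series  # per-gene sex x pseudotime loading
    objective_trace: np.ndarray
    converged: bool
    genes_used: list[str] = field(default_factory=list)


def select_variable_genes(values: pd.DataFrame, k: int) -> list[str]:
    """Top-k genes by variance of log2 expression.

    Ties are broken by lexicographic gene id so the selection is
    deterministic.  The returned set should be excluded from downstream
    pseudotime-DE reporting.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > values.shape[0]:
        raise ValueError(f"k={k} exceeds the {values.shape[0]} available genes")
    var = values.var(axis=1, ddof=1)
    order = sorted(values.index, key=lambda g: (-var[g], str(g)))
    return [str(g) for g in order[:k]]


def fit_trajectory(
    values: pd.DataFrame,
    sex: pd.Series,
    tol: float = 1e-6,
    max_iter: int = 500,
    ridge: float = 1e-6,
    seed: int | None = None,
) -> TrajectoryFit:
    """Alternating least-squares fit of the latent trajectory.

    ``values``: genes x samples log2 expression on the selected genes.
    ``sex``: per-sample labels ("female"/"male") or a 0/1 indicator;
    female is coded 1, so alpha > 0 means female-biased.
    ``seed`` only disambiguates exact symmetry; the fit is deterministic.
    """
    y = values.to_numpy(float)
    y = y - y.mean(axis=1, keepdims=True)
    g, n = y.shape
    x = _sex_indicator(sex.loc[values.columns])

    # init: first right singular vector of the sex-centered matrix.
    # Centering within each sex keeps the initial z out of the span of the
    # sex covariate; otherwise, in data without a real trajectory, the
    # latent coordinate and the sex term are interchangeable and the factor
    # can absorb the sex effects it is meant to adjust for.
    y0 = y.copy()
    for grp in (x == 1.0, x == 0.0):
        if grp.any():
            y0[:, grp] -= y0[:, grp].mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(y0, full_matrices=False)
    z = vt[0]
    # deterministic sign at init: largest-magnitude coordinate positive
    if z[np.argmax(np.abs(z))] < 0:
        z = -z
    z = (z - z.mean()) / z.std()

    trace = []
    prev = np.inf
    converged = False
    theta = np.zeros((4, g))
    for _ in range(max_iter):
        # gene step: ridge regression of each gene on [1, z, x, x*z]
        d = np.column_stack([np.ones(n), z, x, x * z])
        a = d.T @ d + ridge * np.eye(4)
        theta = np.linalg.solve(a, d.T @ y.T)  # 4 x g
        mu, c, alpha, beta = theta
        # sample step: posterior mean of z under N(0, 1) prior
        resid = y - mu[:, None] - alpha[:, None] * x[None, :]
        coef = c[:, None] + beta[:, None] * x[None, :]  # g x n
        num = np.einsum("gn,gn->n", coef, resid)
        den = np.einsum("gn,gn->n", coef, coef) + 1.0
        z = num / den
        fit = mu[:, None] + coef * z[None, :]
        obj = float(
            np.sum((y - fit) ** 2)
            + ridge * np.sum(theta**2)
            + np.sum(z**2)
        )
        trace.append(obj)
        if prev - obj < tol * max(abs(prev), 1.0):
            converged = True
            break
        prev = obj
    if not converged:
        warnings.warn("trajectory fit did not converge; returning last iterate")

    sd = z.std()
    if sd == 0:
        raise RuntimeError("degenerate trajectory: z collapsed to a constant")
    z_std = (z - z.mean()) / sd
    mu, c, alpha, beta = theta
    idx = values.index
    return TrajectoryFit(
        z=pd.Series(z_std, index=values.columns, name="pseudotime"),
        mu=pd.Series(mu, index=idx),
        c=pd.Series(c * sd, index=idx),
        alpha=pd.Series(alpha, index=idx),
        beta=pd.Series(beta * sd, index=idx),
        objective_trace=np.asarray(trace),
        converged=converged,
        genes_used=[str(i) for i in idx],
    )


def _sex_indicator(sex: pd.Series) -> np.ndarray:
    if sex.dtype == object or str(sex.dtype) == "category":
        vals = set(sex.unique())
        if not vals <= {"female", "male"}:
            raise ValueError(f"unrecognized sex labels: {vals}")
        return (sex == "female").to_numpy(float)
    return sex.to_numpy(float)


def orient_pseudotime(
    fit: TrajectoryFit, anchor: pd.Series | None = None
) -> TrajectoryFit:
    """Fix the sign of z.

    With an ordinal anchor (e.g. reported developmental stage), z is
    negated if its Kendall correlation with the anchor is negative.
    Without one, the sign is set so the largest-|c| gene loads positively.
    Idempotent.
    """
    if anchor is not None:
        anchor = anchor.loc[fit.z.index]
        if anchor.nunique() < 2:
            warnings.warn("constant anchor; falling back to the loading rule")
            anchor = None
    if anchor is not None:
        tau, _ = stats.kendalltau(fit.z.to_numpy(), anchor.to_numpy())
        flip = tau < 0
    else:
        flip = fit.c.iloc[int(np.argmax(np.abs(fit.c.to_numpy())))] < 0
    if not flip:
        return fit
    return TrajectoryFit(
        z=-fit.z,
        mu=fit.mu,
        c=-fit.c,
        alpha=fit.alpha,
        beta=-fit.beta,
        objective_trace=fit.objective_trace,
        converged=fit.converged,
        genes_used=fit.genes_used,
    )


def stage_correlation(z: pd.Series, stages: pd.Series) -> tuple[float, float]:
    """Kendall tau-b between pseudotime and ordinal stages, with p value.

    Categorical stages should be converted to an ordered numeric code
    before calling.
    """
    stages = stages.loc[z.index]
    if stages.nunique() < 2:
        raise ValueError("stage variable has fewer than 2 distinct values")
    tau, p = stats.kendalltau(z.to_numpy(float), stages.to_numpy(float))
    return float(tau), float(p)


def permuted_sex_sensitivity(
    values: pd.DataFrame,
    sex: pd.Series,
    individual: pd.Series,
    n_perm: int,
    seed: int,
    n_variable_genes: int = 500,
    q_threshold: float = 0.01,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Stability of pseudotime-DE under permuted sex covariates.

    Sex labels are permuted across individuals (all samples of an
    individual move together), the trajectory and pseudotime-DE are
    recomputed, and each permutation reports the percentage overlap of
    significant pseudotime-DE genes and the Pearson correlation of
    pseudotime effect sizes with the unpermuted analysis.
    """
    from . import diffexpr

    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    cols = ["overlap_pct", "pearson_r"]
    if n_perm == 0:
        return pd.DataFrame(columns=cols)

    sel = select_variable_genes(values, min(n_variable_genes, values.shape[0]))

    def _run(sex_labels: pd.Series, anchor: pd.Series | None = None):
        # the latent coordinate is sign-indeterminate; permuted refits are
        # oriented against the baseline so effect sizes are comparable
        fit = orient_pseudotime(
            fit_trajectory(values.loc[sel], sex_labels, tol=tol, max_iter=max_iter),
            anchor,
        )
        de = diffexpr.fit_gene_models(
            values, sex_labels, fit.z, individual=individual,
            exclude_from_pseudotime=sel,
        )
        tab = de.tables["pseudotime"]
        return set(tab.index[tab["qvalue"] < q_threshold]), tab["logFC"], fit.z

    sig0, lfc0, z0 = _run(sex.loc[values.columns])

    rng = np.random.default_rng(seed)
    ind_sex = (
        pd.DataFrame({"individual": individual.loc[values.columns],
                      "sex": sex.loc[values.columns]})
        .drop_duplicates("individual")
        .set_index("individual")["sex"]
    )
    rows = []
    for _ in range(n_perm):
        perm = pd.Series(
            rng.permutation(ind_sex.to_numpy()), index=ind_sex.index
        )
        sex_perm = individual.loc[values.columns].map(perm)
        sig, lfc, _ = _run(sex_perm, anchor=z0)
        overlap = 100.0 * len(sig0 & sig) / len(sig0) if sig0 else float("nan")
        common = lfc0.index.intersection(lfc.index)
        r = float(np.corrcoef(lfc0.loc[common], lfc.loc[common])[0, 1])
        rows.append({"overlap_pct": overlap, "pearson_r": r})
    return pd.DataFrame(rows)
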