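"""Per-gene differential expression for sex, pseudotime, and interaction.

Each gene is fit by least squares on the design
``[1, sex, pseudotime, sex x pseudotime, extra covariates]`` with repeated
samples per individual handled by cluster-robust covariance clustered on
individual (bias-reduced CR2 with Satterthwaite df by default; classic CR1
with t on #clusters - #parameters as an option).  This keeps
the estimand of a mixed model with a random individual intercept (the
group-level female - male contrast) while staying deterministic and
dependency-free.  Positive logFC = female-biased (log2 female/male), or
increasing along pseudotime.

False-discovery control is Storey's q-value with the pi0 smoother;
the replication rate pi1 uses the fixed lambda = 0.5 estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TERMS = ("sex", "pseudotime", "interaction")


@dataclass
class DEFit:
    """Three DE tables (one per term), each with logFC, SE, t, p, q."""

    tables: dict[str, pd.DataFrame]
    df_resid: int
    n_clusters: int
    design_columns: list[str]

    def significant(self, term: str, q_threshold: float = 0.01) -> pd.Index:
        tab = self.tables[term]
        return tab.index[tab["qvalue"] < q_threshold]


@dataclass
class QValueResult:
    pi0: float
    qvalues: np.ndarray
    lam: float | np.ndarray


def _build_design(
    sex: np.ndarray,
    pseudotime: np.ndarray,
    extra: pd.DataFrame | None,
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(sex), sex, pseudotime, sex * pseudotime]
    names = ["intercept", "sex", "pseudotime", "interaction"]
    if extra is not None:
        for name in extra.columns:
            col = extra[name]
            if col.dtype == object or str(col.dtype) == "category":
                dummies = pd.get_dummies(col, prefix=name, drop_first=True)
                for dname in dummies.columns:
                    cols.append(dummies[dname].to_numpy(float))
                    names.append(str(dname))
            else:
                cols.append(col.to_numpy(float))
                names.append(str(name))
    x = np.column_stack(cols)
    return x, names


def fit_gene_models(
    values: pd.DataFrame,
    sex: pd.Series,
    pseudotime: pd.Series,
    individual: pd.Series | None = None,
    extra_covariates: pd.DataFrame | None = None,
    exclude_from_pseudotime: list[str] | None = None,
    q_lambda: float | None = None,
    cov_type: str = "CR2",
) -> DEFit:
    """Fit all genes and extract the three DE tables.

    ``values``: genes x samples normalized log2 expression.
    ``exclude_from_pseudotime``: genes used to infer the trajectory; they
    are dropped from the pseudotime-DE table (and its q-values) only.
    ``cov_type``: "CR2" (bias-reduced, Satterthwaite df; default) or
    "CR1" (classic small-sample factor, t on #clusters - #parameters).
    """
    from .pseudotime import _sex_indicator

    samples = values.columns
    x_sex = _sex_indicator(sex.loc[samples])
    z = pseudotime.loc[samples].to_numpy(float)
    extra = extra_covariates.loc[samples] if extra_covariates is not None else None
    x, names = _build_design(x_sex, z, extra)
    n, p = x.shape

    rank = np.linalg.matrix_rank(x)
    if rank < p:
        bad = _collinear_columns(x, names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    if individual is None:
        clusters = np.arange(n)
    else:
        clusters = pd.factorize(individual.loc[samples])[0]
    n_clusters = int(clusters.max()) + 1
    if n_clusters <= p:
        raise ValueError(
            f"{n_clusters} clusters <= {p} parameters; cannot form cluster-robust df"
        )
    if n < p + 2:
        raise ValueError("need at least p + 2 samples")

    y = values.to_numpy(float).T  # n x g
    a = x.T @ x
    a_inv = np.linalg.inv(a)
    coefs = a_inv @ x.T @ y  # p x g
    resid = y - x @ coefs  # n x g

    term_idx = {"sex": 1, "pseudotime": 2, "interaction": 3}
    se, tstat, pvals, dof = _cluster_robust_inference(
        x, a_inv, coefs, resid, clusters, n_clusters, cov_type,
        list(term_idx.values()),
    )

    genes = values.index
    tables: dict[str, pd.DataFrame] = {}
    for term, j in term_idx.items():
        tab = pd.DataFrame(
            {
                "logFC": coefs[j],
                "SE": se[j],
                "t": tstat[j],
                "p": pvals[j],
            },
            index=genes,
        )
        if term == "pseudotime" and exclude_from_pseudotime:
            tab = tab.drop(index=[g for g in exclude_from_pseudotime if g in tab.index])
        q = storey_qvalues(tab["p"].to_numpy(), lambda_fixed=q_lambda)
        tab["qvalue"] = q.qvalues
        tables[term] = tab
    return DEFit(
        tables=tables, df_resid=int(np.min(dof)), n_clusters=n_clusters,
        design_columns=names,
    )


def _cluster_robust_inference(
    x: np.ndarray,
    a_inv: np.ndarray,
    coefs: np.ndarray,
    resid: np.ndarray,
    clusters: np.ndarray,
    n_clusters: int,
    cov_type: str,
    terms: list[int],
):
    """Cluster-robust SEs, t and p for the requested coefficients.

    CR1: Liang-Zeger sandwich with the G/(G-1) * (n-1)/(n-p) small-sample
    factor and t on df = G - p.  CR2: Bell-McCaffrey bias-reduced
    linearization — per-cluster residuals are inflated by
    (I - H_cc)^{-1/2} — with per-coefficient Satterthwaite degrees of
    freedom.  CR1 is anti-conservative at moderate cluster counts; CR2 is
    the default.  Only the requested coefficient variances are formed.
    """
    n, p = x.shape
    g = coefs.shape[1]
    cluster_idx = [np.flatnonzero(clusters == c) for c in range(n_clusters)]
    var = np.zeros((p, g))
    if cov_type == "CR1":
        h = a_inv @ x.T
        for idx in cluster_idx:
            m = h[:, idx] @ resid[idx, :]
            var += m**2
        var *= (n_clusters / (n_clusters - 1)) * ((n - 1) / (n - p))
        dof = np.full(p, n_clusters - p, dtype=float)
    elif cov_type == "CR2":
        # adjustment and df matrices depend on the design only
        adj = []
        for idx in cluster_idx:
            xc = x[idx]
            hcc = xc @ a_inv @ xc.T
            evals, evecs = np.linalg.eigh(np.eye(len(idx)) - hcc)
            evals = np.maximum(evals, 1e-12)
            omega = evecs @ np.diag(evals**-0.5) @ evecs.T
            adj.append(omega @ xc)  # n_c x p
        for idx, m_c in zip(cluster_idx, adj):
            s = (a_inv @ m_c.T) @ resid[idx, :]  # p x g
            var += s**2
        dof = np.full(p, n_clusters - p, dtype=float)
        hat = x @ a_inv @ x.T
        for j in terms:
            # Satterthwaite df of the CR2 variance for coefficient j
            u = np.zeros((n, n_clusters))
            for c, (idx, m_c) in enumerate(zip(cluster_idx, adj)):
                w = np.zeros(n)
                w[idx] = m_c @ a_inv[:, j]
                u[:, c] = w - hat.T @ w
            s_mat = u.T @ u
            tr = np.trace(s_mat)
            dof[j] = tr**2 / np.sum(s_mat**2)
    else:
        raise ValueError(f"unknown cov_type {cov_type!r}")
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coefs / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof[:, None])
    return se, tstat, pvals, dof[terms]


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Name columns involved in the rank deficiency (constant or dependent)."""
    bad = []
    for j in range(1, x.shape[1]):
        sub = np.delete(x, j, axis=1)
        if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(x):
            bad.append(names[j])
    return bad or names[1:]


def storey_qvalues(
    p: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    lambda_fixed: float | None = None,
) -> QValueResult:
    """Storey q-values with smoother-based pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the
    grid 0.05..0.95 (step 0.05), smoothed with a cubic fit, and read off
    at the largest lambda; with ``lambda_fixed`` the single-point estimate
    is used instead.  q_(i) = pi0 * m * p_(i) / i with a cumulative
    minimum from the largest p down.
    """
    p = np.asarray(p, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if lambda_fixed is not None:
        pi0 = np.mean(p > lambda_fixed) / (1.0 - lambda_fixed)
        lam: float | np.ndarray = lambda_fixed
    else:
        if lambda_grid is None:
            lambda_grid = np.arange(0.05, 0.96, 0.05)
        lam = lambda_grid
        pi0_l = np.array([np.mean(p > l) / (1.0 - l) for l in lambda_grid])
        if lambda_grid.size >= 4:
            coef = np.polyfit(lambda_grid, pi0_l, 3)
            pi0 = float(np.polyval(coef, lambda_grid.max()))
        else:
            pi0 = float(pi0_l[-1])
    pi0 = float(min(max(pi0, 0.0), 1.0))
    if pi0 == 0.0:
        pi0 = np.finfo(float).tiny  # degenerate; avoid all-zero q

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueResult(pi0=pi0, qvalues=q, lam=lam)


def pi1_replication(p_replication: np.ndarray) -> float:
    """Replication rate pi1 = 1 - pi0 at lambda = 0.5, clipped to [0, 1].

    ``p_replication`` are the replication-dataset p-values of the genes
    significant in the discovery dataset.
    """
    p = np.asarray(p_replication, float)
    if p.size == 0:
        raise ValueError("empty replication p-value vector")
    pi0 = np.mean(p > 0.5) / 0.5
    return float(min(max(1.0 - pi0, 0.0), 1.0))


def sign_bias_test(n_biased: int, n_total: int) -> float:
    """Exact two-sided binomial test of direction balance against 0.5.

    Used for, e.g., an excess of male-biased genes among all sex-DE genes.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_biased <= n_total:
        raise ValueError("n_biased must lie in [0, n_total]")
    return float(stats.binomtest(n_biased, n_total, 0.5).pvalue)
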