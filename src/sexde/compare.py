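"""Cross-life-stage comparison statistics and gene-list enrichment.

Comparison of two sex-DE analyses: overlap of significant genes with a
hypergeometric test, direction consistency with an exact binomial test,
Pearson correlation of effect sizes, and the replication rate pi1 in both
directions.  Gene-list enrichment combines an upper-tail hypergeometric
test with an expression-matched permutation test: random query-sized gene
sets are drawn with the query's composition over expression-level bins,
which corrects for sex-DE genes being on average more highly expressed
than the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEFit, pi1_replication, sign_bias_test


@dataclass
class ComparisonReport:
    n_universe: int
    n_sig1: int
    n_sig2: int
    n_overlap: int
    overlap_by_direction: dict[str, int]
    consistency_pct: float
    consistency_p: float
    pearson_r: float
    pearson_p: float
    pi1_1to2: float
    pi1_2to1: float
    overlap_hypergeom_p: float


def compare_sexde(
    de1: DEFit | pd.DataFrame,
    de2: DEFit | pd.DataFrame,
    q_threshold: float = 0.01,
) -> ComparisonReport:
    """Compare the sex-DE results of two datasets on their shared universe.

    Consistency is the percentage of dataset-1-significant genes whose
    t statistic has the same sign in dataset 2, tested against 50% with
    an exact binomial test; Pearson r is computed over the same genes.
    """
    t1 = de1.tables["sex"] if isinstance(de1, DEFit) else de1
    t2 = de2.tables["sex"] if isinstance(de2, DEFit) else de2
    universe = t1.index.intersection(t2.index)
    if len(universe) == 0:
        raise ValueError("the two datasets share no genes")
    t1, t2 = t1.loc[universe], t2.loc[universe]

    sig1 = t1.index[t1["qvalue"] < q_threshold]
    sig2 = t2.index[t2["qvalue"] < q_threshold]
    overlap = sig1.intersection(sig2)

    by_dir = {
        "both_female": int(((t1.loc[overlap, "logFC"] > 0) & (t2.loc[overlap, "logFC"] > 0)).sum()),
        "both_male": int(((t1.loc[overlap, "logFC"] < 0) & (t2.loc[overlap, "logFC"] < 0)).sum()),
        "discordant": int(((t1.loc[overlap, "logFC"] * t2.loc[overlap, "logFC"]) < 0).sum()),
        "only_1": int(len(sig1) - len(overlap)),
        "only_2": int(len(sig2) - len(overlap)),
    }

    if len(sig1) > 0:
        same = (np.sign(t1.loc[sig1, "t"]) == np.sign(t2.loc[sig1, "t"])).to_numpy()
        consistency = 100.0 * same.mean()
        consistency_p = sign_bias_test(int(same.sum()), len(sig1))
        r, rp = stats.pearsonr(t1.loc[sig1, "logFC"], t2.loc[sig1, "logFC"])
        pi1_12 = pi1_replication(t2.loc[sig1, "p"].to_numpy())
    else:
        consistency, consistency_p, r, rp, pi1_12 = (
            float("nan"), float("nan"), float("nan"), float("nan"), float("nan"),
        )
    pi1_21 = (
        pi1_replication(t1.loc[sig2, "p"].to_numpy()) if len(sig2) else float("nan")
    )

    hg_p = stats.hypergeom.sf(
        len(overlap) - 1, len(universe), len(sig1), len(sig2)
    )
    return ComparisonReport(
        n_universe=len(universe),
        n_sig1=len(sig1),
        n_sig2=len(sig2),
        n_overlap=len(overlap),
        overlap_by_direction=by_dir,
        consistency_pct=float(consistency),
        consistency_p=float(consistency_p),
        pearson_r=float(r),
        pearson_p=float(rp),
        pi1_1to2=pi1_12,
        pi1_2to1=pi1_21,
        overlap_hypergeom_p=float(hg_p),
    )


@dataclass
class EnrichmentResult:
    n_query: int
    n_annotation: int
    n_universe: int
    overlap: int
    relative_enrichment: float
    hypergeom_p: float
    permutation_p: float | None = None
    significant: bool | None = None


def hypergeom_enrichment(
    query: set, annotation: set, universe: set
) -> EnrichmentResult:
    """Upper-tail hypergeometric overlap test P[X >= observed]."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    annotation = set(annotation) & universe
    k = len(query & annotation)
    m, nq, na = len(universe), len(query), len(annotation)
    p = float(stats.hypergeom.sf(k - 1, m, na, nq))
    expected = nq * na / m
    rel = k / expected if expected > 0 else float("nan")
    return EnrichmentResult(
        n_query=nq,
        n_annotation=na,
        n_universe=m,
        overlap=k,
        relative_enrichment=float(rel),
        hypergeom_p=p,
    )


def matched_permutation_p(
    query: set,
    annotation: set,
    universe: set,
    expression: pd.Series,
    n_perm: int = 1000,
    n_bins: int = 10,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Permutation p with expression-matched random gene sets.

    Universe genes are binned by expression decile; each permutation draws
    (without replacement, per bin) a random set with the query's per-bin
    composition and records its overlap with the annotation.  Returns the
    +1-corrected upper-tail p and the permuted overlap counts.
    """
    universe = sorted(set(universe))
    query = set(query) & set(universe)
    annotation = set(annotation) & set(universe)
    expr = expression.loc[universe]
    bins = pd.qcut(expr.rank(method="first"), q=n_bins, labels=False)
    observed = len(query & annotation)

    bin_members: dict[int, np.ndarray] = {}
    need: dict[int, int] = {}
    for b in range(n_bins):
        members = np.array([g for g, bb in zip(universe, bins) if bb == b], dtype=object)
        bin_members[b] = members
        n_q = sum(1 for g in query if g in set(members))
        need[b] = n_q
        if n_q > members.size:
            raise ValueError(
                f"expression bin {b} has {members.size} genes but the query needs {n_q}"
            )
    rng = np.random.default_rng(seed)
    ann = set(annotation)
    perm_overlap = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        total = 0
        for b in range(n_bins):
            if need[b] == 0:
                continue
            draw = rng.choice(bin_members[b], size=need[b], replace=False)
            total += sum(1 for g in draw if g in ann)
        perm_overlap[i] = total
    p = (1 + int((perm_overlap >= observed).sum())) / (n_perm + 1)
    return float(p), perm_overlap


def significance_filter(
    hypergeom_p: float,
    permutation_p: float,
    n_lists: int,
    n_gene_groups: int,
    alpha: float = 0.05,
    perm_alpha: float = 0.05,
) -> bool:
    """Bonferroni-style joint significance rule for enrichment results.

    Significant iff the hypergeometric p beats alpha / (n_lists *
    n_gene_groups) and the permutation p beats perm_alpha.
    """
    if alpha <= 0 or perm_alpha <= 0:
        raise ValueError("thresholds must be positive")
    threshold = alpha / (n_lists * n_gene_groups)
    return bool(hypergeom_p < threshold and permutation_p < perm_alpha)


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Chi-square test (Yates continuity correction) for two proportions."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must lie within their group sizes")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if table.sum() == 0:
        raise ValueError("empty table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


def xci_category_table(
    categories: pd.Series, xci_class: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sharing of sex-DE by X-inactivation class.

    Counts shared vs non-shared genes per XCI class (escape, inactive,
    variable, unknown, autosomal) and runs pairwise two-proportion
    chi-square tests between classes.  Classes with no genes are omitted.
    """
    import warnings

    idx = categories.index.intersection(xci_class.index)
    categories, xci_class = categories.loc[idx], xci_class.loc[idx]
    rows = []
    for cls, sub in categories.groupby(xci_class):
        n = len(sub)
        if n == 0:
            warnings.warn(f"XCI class {cls} has no genes; omitted")
            continue
        shared = int((sub == "shared").sum())
        rows.append(
            {"xci_class": cls, "n": n, "shared": shared, "shared_pct": 100.0 * shared / n}
        )
    counts = pd.DataFrame(rows).set_index("xci_class")
    tests = []
    classes = list(counts.index)
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            chi2, p = two_proportion_test(
                int(counts.loc[a, "shared"]), int(counts.loc[a, "n"]),
                int(counts.loc[b, "shared"]), int(counts.loc[b, "n"]),
            )
            tests.append({"class_a": a, "class_b": b, "chi2": chi2, "p": p})
    return counts, pd.DataFrame(tests)
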