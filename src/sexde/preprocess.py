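"""Sex assignment from marker genes, expression filtering, normalization.

Sample sex is assigned from raw counts on two sex-restricted expression
markers: the summed counts of chromosome-Y protein-coding genes (male) and
the XIST count (female).  Samples that satisfy neither rule are left
unassigned and dropped downstream.

Between-sample normalization is trimmed mean of M-values (TMM) with the
canonical 30%/5% trimming on M/A values and precision weighting, followed
by a log2-CPM transform with a small prior count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass(frozen=True)
class SexCheckThresholds:
    """Raw-count cutoffs separating male and female samples.

    ``hdbr()`` uses one symmetric cutoff of 7000 on both markers;
    ``gtex()`` uses 1000 on the chrY sum and 150 on XIST.
    """

    chry_sum_cutoff: float
    xist_cutoff: float

    def __post_init__(self):
        if self.chry_sum_cutoff <= 0 or self.xist_cutoff <= 0:
            raise ValueError("sex-check cutoffs must be positive")

    @classmethod
    def hdbr(cls) -> "SexCheckThresholds":
        return cls(chry_sum_cutoff=7000, xist_cutoff=7000)

    @classmethod
    def gtex(cls) -> "SexCheckThresholds":
        return cls(chry_sum_cutoff=1000, xist_cutoff=150)


def find_marker_genes(gene_table: pd.DataFrame) -> tuple[str, list[str]]:
    """Locate the XIST gene and the chrY protein-coding genes.

    Uses the ``marker`` column when present ("xist"/"chrY"), otherwise
    falls back to ``gene_id == "XIST"`` and ``chromosome == "chrY"``.
    """
    if "marker" in gene_table.columns:
        xist = gene_table.loc[gene_table["marker"] == "xist", "gene_id"]
        chry = gene_table.loc[gene_table["marker"] == "chrY", "gene_id"]
    else:
        xist = gene_table.loc[gene_table["gene_id"] == "XIST", "gene_id"]
        chry = gene_table.loc[gene_table.get("chromosome", "") == "chrY", "gene_id"]
    if len(xist) == 0:
        raise KeyError("gene table does not identify an XIST marker gene")
    if len(chry) == 0:
        raise KeyError("gene table does not identify chrY protein-coding genes")
    return str(xist.iloc[0]), [str(g) for g in chry]


def assign_sex(
    counts: pd.DataFrame,
    gene_table: pd.DataFrame,
    thresholds: SexCheckThresholds | None = None,
) -> pd.DataFrame:
    """Per-sample sex labels from marker-gene counts.

    male   : chrY sum > cutoff  and XIST < cutoff
    female : chrY sum < cutoff  and XIST > cutoff
    otherwise unassigned (to be removed from analysis).

    Returns a DataFrame indexed by sample with columns
    ``chry_sum, xist_count, sex``.
    """
    if thresholds is None:
        thresholds = SexCheckThresholds.hdbr()
    xist_gene, chry_genes = find_marker_genes(gene_table)
    missing = [g for g in [xist_gene, *chry_genes] if g not in counts.index]
    if missing:
        raise KeyError(f"marker genes absent from count matrix: {missing}")
    chry_sum = counts.loc[chry_genes].sum(axis=0)
    xist = counts.loc[xist_gene]
    male = (chry_sum > thresholds.chry_sum_cutoff) & (xist < thresholds.xist_cutoff)
    female = (chry_sum < thresholds.chry_sum_cutoff) & (xist > thresholds.xist_cutoff)
    sex = pd.Series("unassigned", index=counts.columns, dtype=object)
    sex[male] = "male"
    sex[female] = "female"
    return pd.DataFrame(
        {"chry_sum": chry_sum, "xist_count": xist, "sex": sex}
    )


def cpm(counts: pd.DataFrame, lib_size: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million; column sums equal 1e6 for raw library sizes."""
    if lib_size is None:
        lib_size = counts.sum(axis=0)
    if (lib_size <= 0).any():
        bad = list(lib_size.index[lib_size <= 0])
        raise ValueError(f"zero or negative library size for samples: {bad}")
    return counts / lib_size * 1e6


def filter_low_expression(
    counts: pd.DataFrame, cpm_threshold: float = 1.0, min_samples: int = 10
) -> pd.Series:
    """Keep genes with CPM > threshold in strictly more than ``min_samples``.

    Returns a boolean mask indexed by gene.
    """
    c = cpm(counts)
    n_pass = (c > cpm_threshold).sum(axis=1)
    return n_pass > min_samples


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    do_weighting: bool = True,
) -> float:
    """Log2 TMM factor of one sample against the reference.

    Genes with zero counts in either sample are excluded pairwise; the
    remaining log-ratios (M) are trimmed by 30% on M and 5% on average
    abundance (A), and averaged with inverse asymptotic-variance weights.
    """
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("sample shares no expressed genes with the reference")
    o, r = obs[pos].astype(float), ref[pos].astype(float)
    log_r = np.log2((o / lib_obs) / (r / lib_ref))
    abs_e = (np.log2(o / lib_obs) + np.log2(r / lib_ref)) / 2.0
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 0.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 0.0
    if do_weighting:
        f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(log_r[keep])
    return 0.0 if not np.isfinite(f) else float(f)


def tmm_factors(
    counts: pd.DataFrame,
    reference: str | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    do_weighting: bool = True,
) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean 1.

    The reference is the sample whose 75th count-fraction percentile is
    closest to the mean over samples, unless given explicitly.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    mat = counts.to_numpy(float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    if reference is None:
        f75 = np.quantile(mat / lib, 0.75, axis=0, method="linear")
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.columns.get_loc(reference)
    log_f = np.array(
        [
            _tmm_pair(
                mat[:, i], mat[:, ref_idx], lib[i], lib[ref_idx],
                logratio_trim, sum_trim, do_weighting,
            )
            for i in range(mat.shape[1])
        ]
    )
    factors = 2.0 ** log_f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


@dataclass
class NormalizedMatrix:
    """log2-CPM values with the normalization metadata used to build them."""

    values: pd.DataFrame  # genes x samples, log2 CPM
    factors: pd.Series
    lib_size: pd.Series
    kept: pd.Series  # boolean mask over the input genes

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def log_cpm(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
    kept: pd.Series | None = None,
) -> NormalizedMatrix:
    """log2((count + prior) / effective library * 1e6).

    The effective library is the raw library size times the TMM factor.
    Monotone in counts and finite everywhere for prior_count > 0.
    """
    lib = counts.sum(axis=0)
    if factors is None:
        factors = tmm_factors(counts)
    eff_lib = lib * factors
    if kept is None:
        kept = pd.Series(True, index=counts.index)
    sub = counts.loc[kept[kept].index]
    vals = np.log2(
        (sub.to_numpy(float) + prior_count) / eff_lib.to_numpy()[None, :] * 1e6
    )
    values = pd.DataFrame(vals, index=sub.index, columns=counts.columns)
    return NormalizedMatrix(values=values, factors=factors, lib_size=lib, kept=kept)


def normalize(
    counts: pd.DataFrame,
    cpm_threshold: float = 1.0,
    min_samples: int = 10,
    prior_count: float = 0.5,
) -> NormalizedMatrix:
    """Filter low-expression genes, compute TMM factors, return log2-CPM."""
    kept = filter_low_expression(counts, cpm_threshold, min_samples)
    factors = tmm_factors(counts.loc[kept[kept].index])
    return log_cpm(counts, factors=factors, prior_count=prior_count, kept=kept)
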