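"""Synthetic cohorts with known ground truth.

Generates the two study conditions the rest of the package is exercised on:
a "prenatal" cohort with a strong developmental trajectory and an "adult"
cohort without one.  Gene-level sex effects are drawn from a mixture of
sharing categories (prenatal-specific, shared at 0.5x/1x/2x relative
magnitude, adult-specific, opposite, null), so every downstream stage has a
parameter-recovery test without any external download.

Geometry of the categories (log2 female/male effects):

==========  ==============================
category    constraint
==========  ==============================
null        beta_prenatal = beta_adult = 0
PRENATAL    beta_adult = 0
SHARED0.5   beta_adult = 0.5 * beta_prenatal
SHARED1     beta_adult = beta_prenatal
SHARED2     beta_adult = 2 * beta_prenatal
ADULT       beta_prenatal = 0
OPPOSITE    beta_adult = -beta_prenatal
==========  ==============================

Counts are negative binomial on a log2-linear mean model
``mu_g + delta_g * t_n + x_n * beta_g`` with ``x_n = 1`` for female samples,
so a positive logFC downstream means female-biased.  Marker genes (one
XIST-like gene expressed only in females, several chrY-like genes expressed
only in males) are appended for the sex-assignment stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CATEGORIES = (
    "null",
    "PRENATAL",
    "SHARED0.5",
    "SHARED1",
    "SHARED2",
    "ADULT",
    "OPPOSITE",
)

#: slope of beta_adult on beta_prenatal for each non-null category
CATEGORY_SLOPES = {
    "PRENATAL": 0.0,
    "SHARED0.5": 0.5,
    "SHARED1": 1.0,
    "SHARED2": 2.0,
    "ADULT": math.inf,
    "OPPOSITE": -1.0,
}

STAGES = ("prenatal", "adult")

_REGIONS = ("telencephalon", "diencephalon", "cortex", "hippocampus")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohorts.

    Defaults are the package's study conditions: cohort sizes give a
    desk-scale analogue of a two-dataset bulk RNA-seq comparison with
    repeated samples per individual, the category mixture is dominated by
    prenatal-specific and shared-with-attenuation effects, and sex-effect
    magnitudes sit on the scale of bulk-brain sex biases (mean |logFC|
    well below 1).
    """

    n_genes: int = 2500
    n_individuals_per_stage: int = 60
    samples_per_individual: tuple[int, int] = (1, 3)
    sex_ratio: float = 0.5  # fraction of female individuals
    #: mixture over CATEGORIES, in that order
    category_proportions: tuple[float, ...] = (
        0.055,
        0.60,
        0.28,
        0.02,
        0.0,
        0.005,
        0.04,
    )
    effect_magnitude: float = 0.2  # sd of the non-null effect draw, log2 units
    pseudotime_effect_sd: float = 0.5  # log2 units per unit time
    interaction_effect_sd: float = 0.0  # sex x time interaction, default off
    nb_dispersion: float = 0.08
    library_size_range: tuple[float, float] = (2e6, 6e6)
    n_marker_genes_y: int = 5
    n_escape_genes: int = 25
    n_inactive_genes: int = 75
    #: log-uniform range of the per-gene standard errors for effect pairs;
    #: the true SE distribution of real logFC estimates is not known, this
    #: range is a stand-in spanning the relevant effect scale
    se_range: tuple[float, float] = (0.02, 0.2)
    baseline_log2_range: tuple[float, float] = (2.0, 9.0)
    marker_mean_count: float = 30000.0
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.category_proportions) - 1.0) > 1e-12:
            raise ValueError(
                "category_proportions must sum to 1, got "
                f"{sum(self.category_proportions)!r}"
            )
        if len(self.category_proportions) != len(CATEGORIES):
            raise ValueError(
                f"category_proportions must have {len(CATEGORIES)} entries "
                f"(order {CATEGORIES})"
            )
        if any(p < 0 for p in self.category_proportions):
            raise ValueError("category proportions must be non-negative")
        for name in ("n_genes", "n_individuals_per_stage", "n_marker_genes_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.samples_per_individual
        if not (1 <= lo <= hi):
            raise ValueError("samples_per_individual must be a range 1 <= lo <= hi")
        if not 0.0 < self.sex_ratio < 1.0:
            raise ValueError("sex_ratio must be in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.se_range[0] <= 0 or self.se_range[1] < self.se_range[0]:
            raise ValueError("se_range must be 0 < lo <= hi")
        if self.n_escape_genes + self.n_inactive_genes >= self.n_genes:
            raise ValueError("X-linked genes must not exhaust the gene set")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth attached to a simulated dataset."""

    genes: pd.DataFrame  # gene_id, chromosome, xci_class, category, betas, delta
    samples: pd.DataFrame | None = None  # sample_id, individual_id, sex, stage, time


def _substream(config: SimulationConfig, index: int) -> np.random.Generator:
    """Fixed-index substream; gene truth is shared across stage calls."""
    ss = np.random.SeedSequence(config.seed, spawn_key=(index,))
    return np.random.default_rng(ss)


# fixed substream indices: gene truth must be identical across stage calls
_STREAM_GENES = 0
_STREAM_PAIRS = 1
_STREAM_STAGE = {"prenatal": 2, "adult": 3}


def _draw_effect_pairs(
    categories: np.ndarray, sigma: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """True (beta_prenatal, beta_adult) respecting the category geometry."""
    n = categories.shape[0]
    beta_pre = np.zeros(n)
    beta_ad = np.zeros(n)
    base = rng.normal(0.0, sigma, size=n)
    for cat, slope in CATEGORY_SLOPES.items():
        mask = categories == cat
        if not mask.any():
            continue
        if math.isinf(slope):
            beta_ad[mask] = base[mask]
        else:
            beta_pre[mask] = base[mask]
            beta_ad[mask] = slope * base[mask]
    return beta_pre, beta_ad


def gene_truth(config: SimulationConfig) -> pd.DataFrame:
    """Gene-level ground truth shared by both cohorts.

    Regular genes draw a sharing category from ``category_proportions``.
    X-linked genes escaping inactivation are forced into female-biased
    SHARED1 effects (escape is established early and stably maintained);
    inactive X genes follow the ordinary mixture like autosomal genes.
    Marker genes are appended last.
    """
    config.validate()
    rng = _substream(config, _STREAM_GENES)
    n = config.n_genes
    ids = np.array([f"G{i:05d}" for i in range(n)])
    cat_idx = rng.choice(len(CATEGORIES), size=n, p=np.asarray(config.category_proportions))
    categories = np.array(CATEGORIES)[cat_idx].astype(object)

    chromosome = np.array(["autosome"] * n, dtype=object)
    xci_class = np.array(["autosomal"] * n, dtype=object)
    x_linked = rng.choice(n, size=config.n_escape_genes + config.n_inactive_genes, replace=False)
    escape = x_linked[: config.n_escape_genes]
    inactive = x_linked[config.n_escape_genes:]
    chromosome[x_linked] = "chrX"
    xci_class[escape] = "escape"
    xci_class[inactive] = "inactive"
    categories[escape] = "SHARED1"

    beta_pre, beta_ad = _draw_effect_pairs(
        np.asarray(categories, dtype=object), config.effect_magnitude, rng
    )
    # escapees: female-biased shared effects (beta > 0)
    beta_pre[escape] = np.abs(rng.normal(0.0, config.effect_magnitude, size=escape.size))
    beta_ad[escape] = beta_pre[escape]

    delta = rng.normal(0.0, config.pseudotime_effect_sd, size=n)
    gamma = (
        rng.normal(0.0, config.interaction_effect_sd, size=n)
        if config.interaction_effect_sd > 0
        else np.zeros(n)
    )
    baseline = rng.uniform(*config.baseline_log2_range, size=n)

    genes = pd.DataFrame(
        {
            "gene_id": ids,
            "chromosome": chromosome,
            "xci_class": xci_class,
            "marker": "",
            "true_category": categories,
            "true_beta_prenatal": beta_pre,
            "true_beta_adult": beta_ad,
            "true_delta": delta,
            "true_interaction": gamma,
            "baseline_log2": baseline,
        }
    )

    markers = [
        {
            "gene_id": "XIST_like",
            "chromosome": "chrX",
            "xci_class": "escape",
            "marker": "xist",
        }
    ] + [
        {
            "gene_id": f"Y{i:03d}",
            "chromosome": "chrY",
            "xci_class": "na",
            "marker": "chrY",
        }
        for i in range(config.n_marker_genes_y)
    ]
    marker_df = pd.DataFrame(markers)
    for col in (
        "true_category",
        "true_beta_prenatal",
        "true_beta_adult",
        "true_delta",
        "true_interaction",
        "baseline_log2",
    ):
        marker_df[col] = "marker" if col == "true_category" else 0.0
    return pd.concat([genes, marker_df], ignore_index=True)


def simulate_effect_pairs(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Observed effect-size pairs, the direct input of the line models.

    For each gene, the true pair follows the category geometry and the
    observed pair is ``b = beta + N(0, se^2)`` with per-gene SEs drawn
    log-uniformly from ``config.se_range`` (independently per dataset,
    matching non-overlapping cohorts).
    """
    config.validate()
    rng = _substream(config, _STREAM_PAIRS)
    n = config.n_genes
    cat_idx = rng.choice(len(CATEGORIES), size=n, p=np.asarray(config.category_proportions))
    categories = np.array(CATEGORIES)[cat_idx].astype(object)
    beta_pre, beta_ad = _draw_effect_pairs(categories, config.effect_magnitude, rng)
    lo, hi = config.se_range
    se1 = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    se2 = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    b1 = beta_pre + rng.normal(0.0, 1.0, size=n) * se1
    b2 = beta_ad + rng.normal(0.0, 1.0, size=n) * se2
    ids = [f"G{i:05d}" for i in range(n)]
    pairs = pd.DataFrame(
        {
            "gene_id": ids,
            "b_prenatal": b1,
            "se_prenatal": se1,
            "b_adult": b2,
            "se_adult": se2,
        }
    )
    truth = SyntheticTruth(
        genes=pd.DataFrame(
            {
                "gene_id": ids,
                "true_category": categories,
                "true_beta_prenatal": beta_pre,
                "true_beta_adult": beta_ad,
            }
        )
    )
    return pairs, truth


def _sample_table(
    config: SimulationConfig, stage: str, rng: np.random.Generator
) -> pd.DataFrame:
    n_ind = config.n_individuals_per_stage
    n_female = int(round(n_ind * config.sex_ratio))
    sexes = np.array(["female"] * n_female + ["male"] * (n_ind - n_female), dtype=object)
    rng.shuffle(sexes)
    # developmental time uniform on (0, 1), stratified within each sex so
    # the time distribution is balanced between the sexes (the study
    # condition: no male/female difference in developmental stage); a
    # chance sex-time imbalance would alias with sex effects, because sex
    # differences in expression and in developmental progression are not
    # separable when the trajectory is latent
    times = np.empty(n_ind)
    for grp in ("female", "male"):
        idx = np.flatnonzero(sexes == grp)
        k = idx.size
        strata = (rng.permutation(k) + rng.uniform(0.0, 1.0, size=k)) / k
        times[idx] = strata
    lo, hi = config.samples_per_individual
    counts = rng.integers(lo, hi + 1, size=n_ind)
    rows = []
    for i in range(n_ind):
        ind = f"{stage[:3]}_ind{i:03d}"
        for s in range(counts[i]):
            rows.append(
                {
                    "sample_id": f"{ind}_s{s}",
                    "individual_id": ind,
                    "sex": sexes[i],
                    "stage": stage,
                    "time": times[i],
                    "region": _REGIONS[rng.integers(0, len(_REGIONS))],
                }
            )
    return pd.DataFrame(rows)


def simulate_counts(
    config: SimulationConfig, stage: str
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Negative-binomial count matrix for one cohort.

    Returns ``(counts, samples, genes, truth)``; counts has genes in rows
    and samples in columns.  The prenatal cohort carries the developmental
    trajectory (per-gene ``delta * t``); the adult cohort has no time
    signal, emulating a life stage without an active developmental program.
    Both calls with the same config share the same gene-level truth.
    """
    config.validate()
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    genes = gene_truth(config)
    rng = _substream(config, _STREAM_STAGE[stage])
    samples = _sample_table(config, stage, rng)
    n_samples = len(samples)

    regular = genes["marker"] == ""
    reg = genes[regular]
    beta = (
        reg["true_beta_prenatal"] if stage == "prenatal" else reg["true_beta_adult"]
    ).to_numpy()
    delta = reg["true_delta"].to_numpy() if stage == "prenatal" else np.zeros(regular.sum())
    gamma = reg["true_interaction"].to_numpy() if stage == "prenatal" else np.zeros(regular.sum())

    x = (samples["sex"] == "female").to_numpy(float)
    t = samples["time"].to_numpy()
    # gene x sample log2 mean of the relative expression level
    eta = (
        reg["baseline_log2"].to_numpy()[:, None]
        + delta[:, None] * t[None, :]
        + beta[:, None] * x[None, :]
        + gamma[:, None] * (x * t)[None, :]
    )
    rel = np.exp2(eta)
    prop = rel / rel.sum(axis=0, keepdims=True)
    lib = rng.uniform(*config.library_size_range, size=n_samples)
    mean = prop * lib[None, :]

    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mean))

    # marker genes: strictly sex-restricted expression
    xist_mean = np.where(x == 1.0, config.marker_mean_count, 0.0)
    y_mean = np.where(x == 0.0, config.marker_mean_count / 2.0, 0.0)

    def _nb(m: np.ndarray) -> np.ndarray:
        out = np.zeros_like(m, dtype=np.int64)
        pos = m > 0
        out[pos] = rng.negative_binomial(r, r / (r + m[pos]))
        return out

    marker_rows = [_nb(xist_mean)]
    for _ in range(config.n_marker_genes_y):
        marker_rows.append(_nb(y_mean))
    marker_counts = np.vstack(marker_rows)

    all_counts = np.vstack([counts, marker_counts])
    count_df = pd.DataFrame(
        all_counts, index=genes["gene_id"].to_numpy(), columns=samples["sample_id"]
    )
    count_df.index.name = "gene_id"
    truth = SyntheticTruth(genes=genes, samples=samples)
    return count_df, samples, genes, truth


def write_outputs(
    outdir,
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    genes: pd.DataFrame,
    stage: str,
) -> None:
    """Plain-TSV export of one simulated cohort."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts.to_csv(outdir / f"counts_{stage}.tsv", sep="\t")
    samples.to_csv(outdir / f"samples_{stage}.tsv", sep="\t", index=False)
    genes.to_csv(outdir / f"genes_{stage}.tsv", sep="\t", index=False)
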