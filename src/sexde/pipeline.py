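"""End-to-end orchestration of the sex-DE workflow.

Composes the stages — sex check, normalization, pseudotime, differential
expression per cohort, effect-pair join, line-model classification and
cross-stage comparison — on either simulated cohorts or user-provided
count tables.  Identical config and seed give identical outputs; all
randomness flows from the single top-level seed through fixed named
substreams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare, diffexpr, linemodels, preprocess, pseudotime
from .simulate import STAGES, SimulationConfig, simulate_counts

log = logging.getLogger("sexde")


@dataclass
class PipelineConfig:
    outdir: str = "sexde_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_variable_genes: int = 1000
    pseudotime_tol: float = 1e-6
    pseudotime_max_iter: int = 500
    q_threshold: float = 0.01
    cpm_threshold: float = 1.0
    min_samples_expressed: int = 10
    prior_count: float = 0.5
    scale: float = linemodels.DEFAULT_SCALE
    cor: float = linemodels.DEFAULT_COR
    cor_opposite: float = linemodels.DEFAULT_COR_OPPOSITE
    r_lkhood: float = 0.0
    n_iter: int = 2000
    burn_in: int = 200

    def validate(self) -> None:
        self.simulation.validate()
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")
        if self.n_variable_genes <= 0:
            raise ValueError("n_variable_genes must be positive")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.pop("simulation", {})
        for key in ("samples_per_individual", "category_proportions",
                    "library_size_range", "se_range", "baseline_log2_range"):
            if key in sim and isinstance(sim[key], list):
                sim[key] = tuple(sim[key])
        return cls(simulation=SimulationConfig(**sim), **d)


def effect_pair_join(
    de_prenatal: diffexpr.DEFit,
    de_adult: diffexpr.DEFit,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Effect-pair table over the union of significant sex-DE genes.

    A gene enters if significant (q < threshold) in either dataset and
    tested in both; genes missing from one dataset are dropped with their
    count logged.
    """
    t1 = de_prenatal.tables["sex"]
    t2 = de_adult.tables["sex"]
    sig = t1.index[t1["qvalue"] < q_threshold].union(
        t2.index[t2["qvalue"] < q_threshold]
    )
    if len(sig) == 0:
        raise ValueError("no significant sex-DE genes in either dataset")
    common = sig.intersection(t1.index).intersection(t2.index)
    dropped = len(sig) - len(common)
    if dropped:
        log.info("effect_pair_join: dropped %d genes missing in one dataset", dropped)
    return pd.DataFrame(
        {
            "gene_id": common,
            "b_prenatal": t1.loc[common, "logFC"].to_numpy(),
            "se_prenatal": t1.loc[common, "SE"].to_numpy(),
            "b_adult": t2.loc[common, "logFC"].to_numpy(),
            "se_adult": t2.loc[common, "SE"].to_numpy(),
        }
    ).reset_index(drop=True)


def analyze_stage(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    genes: pd.DataFrame,
    config: PipelineConfig,
    thresholds: preprocess.SexCheckThresholds | None = None,
):
    """Sex check -> normalize -> pseudotime -> DE for one cohort.

    Returns ``(de_fit, trajectory, sexcheck_table, norm)`` with unassigned
    samples removed and marker genes excluded from the DE universe.
    """
    sexcheck = preprocess.assign_sex(counts, genes, thresholds)
    keep_samples = sexcheck.index[sexcheck["sex"] != "unassigned"]
    counts = counts[keep_samples]
    sex = sexcheck.loc[keep_samples, "sex"]

    marker_ids = set(genes.loc[genes["marker"] != "", "gene_id"])
    counts_nomarker = counts.loc[[g for g in counts.index if g not in marker_ids]]
    norm = preprocess.normalize(
        counts_nomarker,
        cpm_threshold=config.cpm_threshold,
        min_samples=config.min_samples_expressed,
        prior_count=config.prior_count,
    )

    k = min(config.n_variable_genes, norm.values.shape[0] - 1)
    sel = pseudotime.select_variable_genes(norm.values, k)
    fit = pseudotime.fit_trajectory(
        norm.values.loc[sel], sex,
        tol=config.pseudotime_tol, max_iter=config.pseudotime_max_iter,
    )
    anchor = samples.set_index("sample_id").loc[keep_samples, "time"] \
        if "time" in samples.columns else None
    fit = pseudotime.orient_pseudotime(fit, anchor)

    individual = samples.set_index("sample_id").loc[keep_samples, "individual_id"]
    de = diffexpr.fit_gene_models(
        norm.values, sex, fit.z, individual=individual,
        exclude_from_pseudotime=sel,
    )
    return de, fit, sexcheck, norm


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full synthetic-data workflow; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    sim = dataclasses.replace(config.simulation, seed=config.seed)
    results = {}
    des = {}
    for stage in STAGES:
        log.info("simulating %s cohort", stage)
        counts, samples, genes, truth = simulate_counts(sim, stage)
        counts.to_csv(outdir / f"counts_{stage}.tsv", sep="\t")
        samples.to_csv(outdir / f"samples_{stage}.tsv", sep="\t", index=False)
        genes.to_csv(outdir / f"genes_{stage}.tsv", sep="\t", index=False)
        log.info("analyzing %s cohort", stage)
        de, fit, sexcheck, norm = analyze_stage(counts, samples, genes, config)
        sexcheck.to_csv(outdir / f"sexcheck_{stage}.tsv", sep="\t")
        fit.z.to_frame().to_csv(outdir / f"pseudotime_{stage}.tsv", sep="\t")
        for term, tab in de.tables.items():
            tab.to_csv(outdir / f"de_{stage}_{term}.tsv", sep="\t")
        anchor = samples.set_index("sample_id")["time"].loc[fit.z.index]
        tau, tau_p = pseudotime.stage_correlation(fit.z, anchor)
        results[stage] = {
            "n_samples_assigned": int((sexcheck["sex"] != "unassigned").sum()),
            "n_genes_kept": int(norm.values.shape[0]),
            "n_sex_de": int(len(de.significant("sex", config.q_threshold))),
            "n_pseudotime_de": int(len(de.significant("pseudotime", config.q_threshold))),
            "pseudotime_kendall_tau": tau,
            "pseudotime_kendall_p": tau_p,
            "trajectory_converged": bool(fit.converged),
        }
        des[stage] = de
        results[f"_truth_{stage}"] = truth

    pairs = effect_pair_join(des["prenatal"], des["adult"], config.q_threshold)
    pairs.to_csv(outdir / "effect_pairs.tsv", sep="\t", index=False)

    lm_config = linemodels.LineModelConfig(
        models=tuple(linemodels.default_models(config.scale, config.cor,
                                               config.cor_opposite)),
        r_lkhood=config.r_lkhood,
        n_iter=config.n_iter,
        burn_in=config.burn_in,
        seed=config.seed + 1,
    )
    lm = linemodels.gibbs_proportions(pairs, lm_config)
    cats = linemodels.classify_genes(lm.posterior)
    lm.posterior.to_csv(outdir / "linemodel_pp.tsv", sep="\t")
    pd.DataFrame(
        {"estimate": lm.proportions, "se": lm.proportions_se}
    ).to_csv(outdir / "linemodel_proportions.tsv", sep="\t")
    cats.to_csv(outdir / "linemodel_categories.tsv", sep="\t")

    report = compare.compare_sexde(des["prenatal"], des["adult"], config.q_threshold)
    truth_genes = results.pop("_truth_prenatal").genes
    results.pop("_truth_adult")
    xci = truth_genes.set_index("gene_id")["xci_class"]
    counts_tab, tests_tab = compare.xci_category_table(
        cats["category"], xci.loc[xci.index.intersection(cats.index)]
    )
    counts_tab.to_csv(outdir / "xci_sharing.tsv", sep="\t")
    tests_tab.to_csv(outdir / "xci_tests.tsv", sep="\t", index=False)

    results["comparison"] = {
        k: (v if not isinstance(v, dict) else v)
        for k, v in asdict(report).items()
    }
    results["proportions"] = lm.proportions.to_dict()
    results["proportions_se"] = lm.proportions_se.to_dict()
    results["categories"] = cats["category"].value_counts().to_dict()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    return outdir
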