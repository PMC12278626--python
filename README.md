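# sexde

Sex-differential gene expression (sex-DE) across life stages of the human
forebrain, as a tested, reusable pipeline.

Male-female differences in brain-related phenotypes are widespread, but
when the underlying transcriptomic sex biases arise — already during fetal
development, or only in adulthood — requires comparing differential
expression between a prenatal and an adult cohort. This package implements
the full analysis chain for that comparison and a synthetic-data generator
with known ground truth, so every stage has a parameter-recovery test
without any external download. It is aimed at computational biologists who
want to run, audit, or extend this style of two-cohort sex-DE analysis.

## What it does

1. **Sample sex assignment** from marker-gene counts: a sample is male iff
   the summed counts of chrY protein-coding genes exceed a cutoff and the
   *XIST* count is below one, female for the reverse, otherwise removed
   (symmetric 7000/7000 cutoffs for HDBR-style data; 1000/150 for
   GTEx-style data).
2. **Normalization**: CPM filtering (CPM > 1 in more than 10 samples), TMM
   normalization factors (30%/5% trimming on M/A values, precision-weighted,
   bit-compatible with edgeR's `calcNormFactors`), log2-CPM with a prior
   count.
3. **Pseudotime**: a per-sample latent developmental coordinate *z* fit on
   the most variable genes under
   `y_gn = mu_g + c_g z_n + alpha_g x_n + beta_g x_n z_n + eps`,
   with sex *x* as an interacting covariate, by penalized alternating least
   squares with a unit-normal prior on *z*.
4. **Differential expression** per gene for sex, pseudotime and their
   interaction (`expression ~ sex + pseudotime + sex:pseudotime`), with
   repeated samples per individual handled by cluster-robust covariance
   (bias-reduced CR2 with Satterthwaite degrees of freedom; CR1
   available), Storey q-values (q < 0.01), and the pi1 replication rate
   (1 − pi0 at lambda = 0.5).
5. **Line models**: each gene's effect pair (b_prenatal, b_adult) is
   classified among six bivariate-Gaussian "line" hypotheses — PRENATAL
   (slope 0), SHARED0.5, SHARED1, SHARED2 (slopes 0.5/1/2), ADULT
   (slope infinity), OPPOSITE (slope −1) — with prior scale 0.1971916
   (95th percentile of |logFC| / 2) and correlation 0.995 (0.990 for
   OPPOSITE). Mixture proportions are estimated by Gibbs sampling (2000
   iterations, 200 burn-in) and genes labelled by posterior probability
   (PP > 0.8; shared = sum of the three shared PPs).
6. **Comparison & enrichment**: direction consistency with an exact
   binomial test, Pearson correlation of effect sizes, overlap
   hypergeometric tests, XCI-escape contingency analyses (Yates-corrected
   chi-square), and gene-list enrichment with expression-matched permutation
   backgrounds.

Throughout, logFC is log2(female/male): positive = female-biased.

## Worked example

```python
from sexde.pipeline import PipelineConfig, run_pipeline
import json

outdir = run_pipeline(PipelineConfig(outdir="demo_run", seed=1))
print(json.loads((outdir / "summary.json").read_text())["proportions"])
```

This simulates a prenatal cohort (60 individuals, 1–3 samples each, with a
developmental trajectory) and an adult cohort (no trajectory), assigns
sample sex from the markers, normalizes, fits pseudotime, runs the three DE
analyses per cohort, joins the union of significant sex-DE genes into
effect pairs, and estimates the line-model mixture. With seed 1 it prints:

```
{'PRENATAL': 0.668, 'SHARED0.5': 0.249, 'SHARED1': 0.048,
 'SHARED2': 0.003, 'ADULT': 0.003, 'OPPOSITE': 0.029}
```

meaning two-thirds of the detected sex effects are prenatal-specific and a
quarter are shared with a twice-smaller adult effect — close to the
generator's ground truth for the genes entering the comparison (the
`summary.json` in the run directory also reports the per-cohort sex-DE
counts, the Kendall correlation of pseudotime with true developmental time,
0.96 here, and the cross-cohort consistency statistics). The same workflow
is available from the shell:

```bash
sexde run-all --outdir demo_run --seed 1
sexde simulate --outdir sim --seed 1          # cohorts as TSV
sexde sexcheck --counts sim/counts_prenatal.tsv --genes sim/genes_prenatal.tsv --out sex.tsv
sexde linemodels --pairs pairs.tsv --seed 1 --out-prefix lm
```

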