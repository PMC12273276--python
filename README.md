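# methclass

Ordered DNA-methylation classes in metastatic melanoma: discovery, cohort
transfer, methylation–expression integration, gene-signature scoring, and
survival / stage-progression association.

## The problem

Metastatic melanomas stratify into four reproducible DNA-methylation
classes with progressively increasing global methylation — **DEM** <
**LOW** < **INT** < **CIMP** (the CpG-island methylator phenotype at the
top). The class a lesion belongs to tracks with its transcriptional
programs (immune-high vs proliferative/differentiated), its immune
contexture, its likelihood of progressing to a later AJCC stage, and the
patient's overall survival; merged **DEM+LOW** vs **INT+CIMP** groups
separate relapse risk under adjuvant immune-checkpoint blockade.

`methclass` packages that analysis as a reusable pipeline for anyone
working with bulk methylation (RRBS/array β values) plus RNA-seq in tumor
cohorts:

1. **Discovery** — select the top fraction (default 1%) most variable CpG
   sites, consensus-cluster the samples (resampled hierarchical clustering,
   1 − Pearson distance, average linkage), pick k from the consensus-CDF
   delta-area curve, and order the clusters by mean β.
2. **Transfer** — classify a new cohort with a nearest-centroid model
   (correlation distance over the discovery panel) and report per-sample
   margins.
3. **Integration** — aggregate site β to promoters, run one-vs-rest
   differential methylation (Wilcoxon rank-sum, Δβ effect) and expression
   (Welch t + label permutation), cross them into
   up/down × hypo/hyper quadrants, and test gene-set over-representation
   (hypergeometric, BH).
4. **Signatures** — per-sample median-z signature scores, HI/LO
   dichotomization at the cohort median, chi-square class association,
   preranked GSEA, a signed-consistency upstream-regulator activation z,
   and cross-cohort correlation-filtered signature derivation.
5. **Outcomes** — Kaplan–Meier curves, log-rank tests, median follow-up,
   and the class × stage-progression contingency analysis with a CNS
   (IVM1D) breakdown.
6. **Synthetic cohorts** — a generator that plants all of the structure
   above (β gradients, purity mixing, promoter–expression anticorrelation,
   immune-signature enrichment in LOW, class-dependent hazards and
   progression rates) so every stage can be validated against ground truth.

## Model in brief

A CpG's β value is the methylated-read fraction M/(M+U) ∈ [0, 1]. For
sample *s* and class *c*, the generator draws pure-tumor β at site *i*
from Beta(μ_{ic}κ, (1−μ_{ic})κ) and mixes with a fixed normal profile:

    β_obs = p_s · β_tumor + (1 − p_s) · β_normal,   p_s = tumor purity

with μ_{ic} = hypo + span · σ(−t_i/τ + f_{ic} + b_c): a shared island
susceptibility gradient t_i, per-class site fingerprints f_{ic}, and a
class propensity b_c solved so each class's mean β over informative
island sites equals its configured value (0.05 / 0.15 / 0.35 / 0.60).
Survival is exponential with class hazard ratios (DEM 1.8, LOW 1.0,
INT 2.0, CIMP 2.8 vs LOW; baseline median 60 months) under administrative
censoring. See `docs/methods.md` for every assumption and default.

## Worked example

```python
from methclass import SimulationConfig, simulate_cohort, MethylationClassModel

beta, expr, sheet, truth = simulate_cohort(SimulationConfig(), seed=1)
res = MethylationClassModel(beta).fit(n_resamples=200, seed=1)
print(res.summary())
```

```
Methylation class discovery
===========================
samples: 160   panel sites: 200 (top 1.00% of 20000 evaluable)
chosen k: 4   resamples: 200   subsample: 80%

delta-area by k: 2:0.503  3:0.249  4:0.201  5:0.009  6:0.009

   class     n  mean beta
     DEM    40     0.0543
     LOW    40     0.1090
     INT    40     0.6206
    CIMP    40     0.6770
```

The delta-area curve flattens after k = 4 (0.201 → 0.009), so four classes
are kept; their mean panel β increases strictly, which fixes the
DEM→CIMP ordering. Classifying a second, independently simulated cohort
with the fitted centroids:

```python
beta2 = simulate_cohort(SimulationConfig(), seed=2)[0]
calls = res.predict(beta2.beta)
print(calls.head(4))
```

```
          label    merged    margin  n_shared status
sample_id
SIM000      DEM   DEM+LOW  0.338105       200     ok
SIM001      LOW   DEM+LOW  0.769449       200     ok
SIM002      INT  INT+CIMP  0.750622       200     ok
SIM003     CIMP  INT+CIMP  0.335834       200     ok
```

`margin` is the distance gap to the second-best centroid — a confidence
gate for low-quality samples. On this cohort all 160 calls match the
generator's latent classes.

The same flow is available from the shell:

```bash
methclass simulate --seed 1 --out bundle/
methclass discover --beta bundle/beta.tsv --seed 1 --out disc/
methclass classify --model disc/centroid_model.json --beta bundle/beta.tsv
methclass run --config config.yaml     # full pipeline + manifest
methclass report runs/demo/            # markdown + JSON summary
```

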