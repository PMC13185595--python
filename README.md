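# thermolag

Optimal growth temperature (OGT) prediction from genome composition,
with a phylogenetic diagnosis of *why* it fails: genome composition
adapts slowly, so species whose OGT shifted recently — psychrophiles in
particular — are systematically mispredicted, and gene presence/absence
features recover part of that loss.

The package is aimed at microbial comparative genomicists who want to
study (or stress-test) composition-based phenotype predictors under
controlled evolutionary scenarios. It pairs a synthetic-data generator
(trees, OGT histories with jumps, genomes whose composition tracks a
*lagged* OGT, OGT-coupled gene gain/loss, noisy OGT databases) with the
full analysis stack the problem needs:

* **features** — 531 genome-composition features: base/codon/amino-acid
  /2-mer fractions, IVYWREL, structural-RNA base composition and
  per-length folding energy (built-in weighted base-pair maximization,
  pluggable external engine), and 21 start-codon-proximal features
  normalized as `log2(F_i / F_rep)`.
* **curation** — conventional-temperature exclusion (25/28/30/37 °C),
  cross-source averaging, completeness/contamination filtering,
  one-mesophile-per-genus downsampling by quality score.
* **predictor** — Lasso / SVR under leave-one-phylum-out
  cross-validation with per-fold normalization and per-fold gene-list
  derivation (leakage-free by construction and by test).
* **phylo** — weighted squared-change parsimony (exact two-pass),
  dOGT/dOGT* tables, 2-state Mk ancestral states with ML rates,
  gain/loss-vs-OGT event shifts, Blomberg's K, trait autocorrelation.
* **genes** — within-genus extreme-pair screen and psychrophile screen
  (Fisher exact tests, Bonferroni over informative genes), top-50×2
  gene selection, copy-number feature augmentation, hypergeometric
  pathway enrichment.

Key quantities: a species' **dOGT** is its OGT minus the reconstructed
OGT of its genus's most recent common ancestor (dOGT* generalizes to
deeper ranks); the model's **signed error** is predicted − observed.
The central result is that signed error correlates negatively with
dOGT, and that the correlation fades with taxonomic depth.

## Worked example

One pipeline run — simulate, curate, featurize, screen, predict,
reconstruct — from a single seed:

```bash
thermolag run-all --seed 42 --out results/demo
```

which prints (standard 200-species conditions, curated through the
noisy synthetic OGT databases):

```
composition R2=0.677 RMSE=4.77 | +genes R2=0.719 RMSE=4.45 -> results/demo
```

and writes `metrics.json`, `report.md`, prediction tables, dOGT and
gene-screen tables under `results/demo/`. The numbered scripts under
`analysis/` run the same stages at the standard 200-species conditions;
`analysis/07_mechanism.py` is the headline replicated study:

```
10 replicates x 200 species
error vs true dOGT: mean r = -0.647
|slope| genus 0.530 -> phylum 0.180 (attenuates with depth)
gene-feature improvement: shifted +0.72 degC, stable -0.01 degC
planted gene recovered in 100% of replicates
psychrophile MAE 5.64 -> 5.37 degC with gene features
```

Reading: a composition-only model over-predicts recently cooled species
(r ≈ −0.65 between signed error and true dOGT); measuring OGT change
against deeper ancestors weakens the association (slope 0.53 → 0.18),
showing composition catches up over time; adding the screened genes'
copy numbers improves recently shifted species by ≈ 0.7 °C while
leaving stable species untouched; and the planted OGT-coupled ortholog
is rediscovered by the extreme-pair screen in every replicate.

The library surface mirrors the CLI — e.g.

```python
from thermolag.synthetic import SimConfig, simulate_tree, simulate_ogt
from thermolag.phylo import asr_squared_change, blomberg_k

cfg = SimConfig(n_tips=200, seed=1)
tree, taxonomy = simulate_tree(cfg)
history = simulate_ogt(tree, cfg)
anc = asr_squared_change(tree, history.tip_values)
k = blomberg_k(tree, history.tip_values)
```

See `docs/methods.md` for the generative model, every default and why,
numerical choices, and known limitations.

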