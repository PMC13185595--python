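# Methods

`thermolag` studies a genotype-to-phenotype problem: predicting a
prokaryote's optimal growth temperature (OGT) from genome composition,
and understanding why such predictions fail for species whose OGT has
shifted recently — psychrophiles above all. Because the real inputs
(reference genomes, curated OGT databases, a genome-scale phylogeny)
are large external resources, the package is built around a synthetic
data generator that reproduces the *statistical structure* the analysis
assumes. Every downstream stage (feature extraction, curation,
leave-one-phylum-out regression, ancestral reconstruction, gene
screens) is ordinary analysis code that would run unchanged on real
tables in the same formats.

## The generative model

**Tree.** A Yule (pure-birth) process with rate `birth_rate` (default 1)
is grown to `n_tips` extant lineages (default 200) and cut at a final
exponential waiting time, giving an ultrametric tree with strictly
positive branch lengths. A nested taxonomy is derived by slicing the
tree at fixed fractions of its height (phylum 0.25, class 0.40, order
0.55, family 0.65, genus 0.72 from the root); each lineage crossing a
cut founds one taxon, so taxa are monophyletic by construction and the
taxonomy is exactly consistent with the topology. With 200 tips this
yields roughly 4–6 phyla and 40–60 genera, enough for
leave-one-phylum-out folds and for genus-level ancestor estimates.

**OGT.** The trait starts near 30 °C at the root (Normal(30, 3²)) and
evolves by Brownian motion with scale `bm_sigma` = 5 °C per
√(branch length), plus, on 5 % of branches, a jump of magnitude
~|Normal(15, 3.75²)| °C with configurable sign bias (symmetric by
default; a psychrophile-biased preset makes jumps predominantly
negative). Values are clipped to the biological range [0, 105] °C and
clipping is logged. These values give a mesophile-heavy distribution
with sd ≈ 12–14 °C and a realistic minority of psychrophiles and
thermophiles. Jump branches and all ancestral values are recorded, so
estimators can be validated against the simulated truth.

**Lagged composition.** Genome composition does not track OGT
instantaneously. Along each root-to-tip lineage a *lagged OGT* is
propagated: per branch of length ℓ the lagged value closes a fraction
`1 − 2^(−ℓ/halflife)` of its gap to the true end-of-branch OGT
(`lag_halflife` = 1 branch-length unit by default — about two typical
terminal branches, so a recent jump is only ~30–50 % absorbed). This is
the simplest lag with a single interpretable parameter; nothing in the
underlying biology pins its timescale, so it is an explicit simulation
knob.

**Genomes.** Each species gets `genome_size` = 60 coding sequences with
log-normal lengths (median 150 codons, clipped to [70, 400]). Codons
are drawn from a log-linear multinomial whose per-codon sensitivity to
the *lagged* OGT rewards GC-rich codons and IVYWREL-encoding codons and
penalizes small-polar residues — a caricature of known thermophily
correlates that gives the regression a learnable, monotone signal.
Structural RNAs (one tRNA of 76 nt and 5S/16S/23S-like sequences of
110/150/200 nt; deliberately miniature, not biological lengths) are
random sequences with an exact GC count set by a linear map from lagged
OGT (GC = 0.30 + 0.50·OGT/105). One deliberately *fast-adapting*
feature responds to current OGT instead: below 20 °C, guanines in the
first 30 nt after the start codon are replaced by A with probability
0.45·(20 − OGT)/20, emulating a start-proximal G depletion in cold
species. No substitution model, secondary structure, or realistic gene
content is simulated.

**Gene content.** 500 orthologs evolve presence/absence along the tree
as exact two-state Markov chains with branch-constant rates (baseline
gain = loss = 0.02 per branch-length unit, ≈ 4 events per gene per
tree). Twenty genes are OGT-coupled: on a branch with OGT change Δ,
"warm" genes multiply their gain rate by `exp(coupling·max(0,Δ)/10)` and
their loss rate by `exp(coupling·max(0,−Δ)/10)` ("cold" genes mirror
this). With `coupling` = 4 a ±15 °C jump flips a coupled gene with
probability ≈ 0.8 while diffusion branches are mildly affected — strong
enough that gene content genuinely carries recent-shift information, as
the mechanism under study presumes. Copy number 2 is assigned with
probability 0.05 where a gene is present. Events are recorded per
branch as net state changes (a flip hides any even number of hidden
events, which is immaterial at these rates).

**OGT databases.** Three noisy sources each cover ~85 % of species with
Normal(0, 0.5²) measurement error rounded to 0.1 °C, and park 10 % of
records at a conventional incubation temperature (25/28/30/37 °C),
reproducing the artifact the curation stage must remove. A metadata
table draws completeness as 100 − Exp(1.5) and contamination as
Exp(1.5), so a realistic minority of genomes fails the quality filter.

## Feature extraction

The default manifest has 531 features: 4 genome base fractions + GC +
64 codon fractions + 20 amino-acid fractions + 400 amino-acid 2-mer
fractions + the IVYWREL sum + tRNA base fractions (4) and per-length
folding energy (1) + per-rRNA base fractions (3×4) and energies (3) +
21 start-codon features. The inventory is configurable; its size is
asserted against the manifest, not hard-coded. Codon usage is computed
over sense codons (stop columns are zero so the 64 still sum to 1);
GTG/TTG starts count as their literal codon but translate as M.
Multiple tRNA/rRNA copies are averaged.

Start-region features follow the normalization
`F_norm,i = log2(F_i / F_rep)`: base composition uses 10-nt windows
starting at 1-based position *i* after the start codon with the
position-50 window as representative, and the guanine feature is
`F_norm,5`; amino-acid composition uses residue positions 1–4 (counted
from the first residue after the initiator) against the full-length
mean, averaged over the four positions. Genes shorter than 59 nt after
the start (bases) or 60 codons (amino acids) are excluded and counted.
A zero `F` or `F_rep` flags the entry as missing rather than silently
zeroing it; with only 60 genes per synthetic genome, rare amino acids
would hit zero counts often, so the pipeline applies a Laplace
pseudocount of 0.5 (default 0, which keeps the exact log-identity
`F_i = F_rep ⇒ F_norm = 0` testable).

Folding energy is a Nussinov-style dynamic program maximizing weighted
base pairs (GC = 3, AU = 2, GU = 1; minimum hairpin loop 3), negated so
stabler is more negative, and divided by sequence length to remove the
length confound. It is a deliberate simplification of thermodynamic
folding with the same monotone behavior on GC-content gradients; an
external engine (e.g. `RNAfold`) can be plugged in and raises a
configuration error when unavailable rather than falling back silently.
A numba-compiled kernel is used when numba is importable; a pure-Python
path gives identical results.

## Curation

Per source, records whose OGT equals 25/28/30/37 °C (compared after
rounding to 0.1 °C, since sources print inconsistently) are removed
*before* cross-source averaging — the order matters when one source
parks a species at 37 and another reports 36.5, and the per-source
reading matches how the exclusion is defined. Species names are matched
after whitespace/case normalization. The quality filter keeps
completeness > 95 and contamination < 5 (strict). Downsampling keeps,
per genus, the single mesophile (20 ≤ OGT < 40) maximizing
Q = completeness − 5·contamination, ties broken by species id for
determinism; species outside the mesophile band are never removed, and
the operation is idempotent.

## Prediction

Leave-one-phylum-out cross-validation: each fold holds out one whole
phylum. Feature min/max normalization is computed from the training
fold only (held-out values may leave [0, 1] and are not clipped), and —
for the gene-augmented feature set — the OGT-associated gene list is
re-derived inside each training fold, so nothing about the held-out
phylum can leak into model construction; a mutation test asserts this.
Models are Lasso (α grid 0.001–0.01) and SVR (C ∈ {0.1, 1, 10, 100},
ε ∈ {0.001, 0.01, 0.1}); the grid point maximizing the overall CV R² is
selected, which is reported as a known mild optimism since no outer
test set exists (a caveat inherited from the analysis design). The
gene-augmented model reuses the composition model's hyperparameters for
a like-for-like comparison. Training uses the mesophile-downsampled
pool; species removed by downsampling are still predicted by their
phylum's fold model, and metrics are reported both over the training
pool and over all species.

## Gene screens

The extreme-pair screen pops (max, min) OGT species per genus while the
gap is ≥ 10 °C, at most three pairs per genus, each species used once —
congeneric pairing is the phylogeny control. Fisher's exact tests
(presence = copy ≥ 1) report the two-sided p plus both one-sided tails;
genes fixed (all present or all absent) in the tested union are
uninformative and excluded from the Bonferroni denominator *m*, which
is always reported. The psychrophile screen contrasts OGT < 20 °C
against the rest under the same machinery. The top 50 genes by raw p
from each screen are concatenated and de-duplicated (≤ 100 genes) and
enter the predictor as min-max-normalized copy numbers. Pathway
over-representation uses the hypergeometric upper tail with
Benjamini–Hochberg q-values.

A calibration note: with slowly evolving genes the pair screen is
strongly *conservative* under the null (paired congeners usually share
their gene state, emptying the 2×2 table), while the psychrophile
screen is *anti-conservative* (psychrophiles cluster phylogenetically
and gene states are autocorrelated). The nominal ≈ 5 % false-positive
rate is recovered in the exchangeable regime — fast gene turnover
(gain = loss = 5) — which is what the null-calibration experiment uses;
the structured-null behavior of both screens is a real property of
Fisher tests on phylogenetic data, not a bug.

## Phylogenetic evolution

*Squared-change parsimony* (branch-length-weighted; an unweighted mode
exists) minimizes Σ (x_parent − x_child)²/ℓ exactly via a two-pass
electrical-network elimination; it equals the GLS/Brownian point
estimates, is invariant to uniform branch rescaling, and is verified
against a generic quadratic minimizer. Zero branch lengths are replaced
by 10⁻⁸ × tree height and logged; polytomies are accepted throughout.
dOGT is each species' OGT minus the reconstruction at the MRCA of its
genus (dOGT* for family/order/class/phylum); clades with ≤ 5 species
are skipped, and a non-monophyletic named clade is logged and
represented by its MRCA.

The *Mk model* (2-state, ER by default, ARD optional) estimates rates
by maximum likelihood over log-rates bounded in [10⁻⁶, 50] with the
pruning algorithm, and computes marginal ancestral states by the
down-pass/rerooting recursion; the root prior is the fitted chain's
stationary distribution (flat optional). All-constant tip states leave
the rates unidentified: they are pinned at the lower bound and the
result flagged degenerate. Event calling assigns each node its
max-marginal state (ties resolve to the parent's state to avoid
spurious events); a branch whose states differ is a gain or loss, and
its OGT shift is the child reconstruction (or observed tip value) minus
the parent reconstruction.

*Blomberg's K* is the observed MSE₀/MSE ratio (deviations about the GLS
phylogenetic mean; MSE under the tree covariance) over its Brownian
expectation from the trace formula. *Trait autocorrelation* places all
unordered tip pairs into equal-count patristic-distance bins (default
10) and reports the symmetrized Pearson correlation per bin. For
class-specific signal (psychrophiles vs thermophiles) both supported
modes are exposed — pruning the tree to the class or using a 0/1
indicator trait on the full tree — since either reading is defensible;
the analysis scripts report the indicator version.

## Replicated experiments and problem sizes

The headline study (`thermolag.experiments.mechanism_study`) averages
10 replicates of the full pipeline at 200 tips — chosen as the smallest
size at which every rank keeps usable clade counts and the group means
stabilize. Per replicate it measures: the Pearson correlation between
signed composition-only error and true dOGT (mean ≈ −0.65); the OLS
slope of error on dOGT* per rank (|slope| falls from ≈ 0.53 at genus to
≈ 0.18 at phylum); the pooled improvement from gene features
(≈ +0.7 °C for |dOGT| ≥ 10 species, ≈ 0 for stable species); and
whether the first planted coupled gene ranks in the pair screen's top
50 (10/10 replicates). Blomberg's K calibration uses 200 Brownian
traits on one fixed 100-tip tree (mean ≈ 1.02); the null screen uses
3 × 500 exchangeable genes (fraction p < 0.05 ≈ 0.051). The same
functions back `scripts/acceptance.py`, the test suite and
`analysis/07_mechanism.py`, so every reported number is recomputed at
run time.

## Known limitations

* The composition→OGT map is monotone and low-dimensional by design;
  real genomes carry weaker, higher-dimensional, lineage-confounded
  signal, so absolute accuracies here say nothing about real-data
  accuracy — only the *relative* patterns (lag signature, rank
  attenuation, gene rescue) are the point.
* Binary gene presence cannot encode shift magnitude; the gene rescue
  relies on several coupled genes acting as a graded signature.
* Fisher screens ignore phylogeny beyond the pairing device; under
  slow gene turnover their null behavior departs from nominal in both
  directions (see above).
* The Mk event caller uses hard max-marginal assignments; soft
  (probability-weighted) event shifts are not implemented.
* Structural RNAs are composition-only miniatures; folding energies are
  weighted pair counts, not thermodynamic free energies.
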