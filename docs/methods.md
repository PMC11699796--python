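# Methods

This note documents the models, the numerical choices, and the design
decisions behind `fermtx`, in the order the pipeline runs them.

## Data model

Counts are genes × samples non-negative integers; fractional values are
rejected because the downstream negative-binomial model is a count model
and the supported counting tools emit integers.  The sample table is the
single authority for sample order: count columns are reordered to it before
any design matrix is built.  Each strain contributes one transcriptome and
strains act as replicates within their subpopulation; missing metabolite
values are allowed and handled pairwise-complete wherever they are used.

## Normalization and the NB Wald engine

Two expression scales are used deliberately: global overviews (PCA, sample
correlation heatmaps) use `log2(1 + CPM)` on raw library sizes, while the
QTT model uses `log2(1 + count/s_j)` on median-of-ratios size factors — a
variance-stabilizing-like scale tied to the same normalization the DE model
uses.  Both are exposed and switchable.

The DE engine is a deliberately simple, fully specified stand-in for the
heavyweight count-model packages:

* **Size factors** are the median over reference genes (nonzero in every
  sample) of `count_ij / geomean_i`.  If no reference gene exists the
  caller is told to fall back to raw library sizes.
* **Dispersion** (`var = μ + φμ²`): per-gene method-of-moments
  `φ̂ = max(1e-8, (var − mean)/mean²)` on normalized counts, a log-linear
  trend `log φ = a + b·log mean` least-squares fitted over genes above the
  floor, and shrinkage `φ* = exp(0.5·log φ_trend + 0.5·log φ̂)`.  The MoM
  estimate uses deviations from the gene's global mean, so genuine group
  differences inflate it; this costs power on strongly spiked genes but
  never miscalibrates the null.  Equality with any external DE package is
  a non-goal.
* **Wald test**: per gene, NB GLM with log link, design
  `[1, focal indicator]`, offsets `log s_j`, fixed `φ*`.  Fisher scoring is
  vectorised across genes (the two-column design has a closed-form weighted
  least-squares update); convergence is a relative deviance change below
  1e-8, at most 100 iterations; non-converged genes get a missing p-value
  and are excluded from the BH denominator.  Standard errors come from the
  expected information `X'WX`, `W = μ/(1+φμ)`; the linear predictor is
  clipped to ±30 to keep separated genes (zero counts in one group) finite
  — such genes drift to a large |log2FC| with a larger SE and are not
  spuriously significant.  Monte-Carlo calibration with known φ (4 vs 19
  samples, φ = 0.05, 2000 null genes) gives empirical type-I error ≈ 0.05.
* Genes with zero counts in all samples are dropped before estimation.
* Reported means in the DEG summary are rounded to the nearest integer,
  half away from zero.

## Cluster-specific signatures

Within each contrast and direction, *all* DEGs of that direction are ranked
by ascending adjusted p (ties: larger |log2FC| first, then gene ID); a
candidate must rank within `ceil(0.5 · n_direction)` *and* exceed
|log2FC| > 1.6.  Ranking before the fold-change filter keeps the rule
monotone: tightening the fold-change threshold can only remove candidates,
and widening the rank fraction can only add them.  Uniqueness is at the
gene level — a gene up in one subpopulation and down in another is present
in two and removed.  Whether the study ranked per direction or over the
pooled DEG list is not decidable from its description; per-direction is the
default and the pooled variant is a switch.

## QTT regression

The per-gene model is ordinary least squares of expression on
`[1, LA, PC_1..K, HF_1..N]` with a two-sided t test on the lactic-acid
coefficient at `n − (2 + K + N)` degrees of freedom, BH across genes, and
an inclusive `padj ≤ 0.001` call threshold.  The estimated hidden factors
are treated as fixed covariates (no degrees-of-freedom correction for their
estimation) — standard surrogate-variable practice and a known
approximation.

**Hidden factors (two-step SVA).**  (1) Every gene is residualized on the
primary model matrix (intercept + lactic acid by default; metabolite
covariates can be appended).  (2) N is the number of leading singular
values of the residual matrix whose variance share exceeds the 95th
percentile of shares from 100 within-gene permutations of the residuals;
each permuted matrix is re-residualized before decomposition so observed
and permuted spectra have the same rank deficit, and the count stops at the
first failing factor.  (3) Each surrogate's sample scores are re-estimated
from the SVD of the *original* centered expression restricted to the genes
(top 10%, minimum 25) most correlated with the residual eigenvector, taking
the candidate direction best matching it, sign-aligned and scaled to unit
variance.  Step 3 matters: residual singular vectors are orthogonalized
against the phenotype, so they cannot absorb a confounder's
phenotype-correlated component — re-estimating on the original scale
restores it.  With a planted confounder (r = 0.8 with the phenotype,
loading on 10% decoy genes) this correction removes essentially all decoy
false-positive QTT calls relative to the SVA-free model.

**PC selection guard.**  The population-structure PCs are taken from the
expression matrix, but not blindly as the first K.  Two kinds of components
are skipped, with the next-ranked components used instead:

* components nearly collinear with the phenotype (|r| > 0.8).  When a
  coherent phenotype-linked module exists — the generator's default plants
  one on 5% of genes — the leading PC reproduces the phenotype almost
  exactly (r ≈ 0.999 in simulation) and including it makes α
  unidentifiable (measured sensitivity drops to zero);
* components largely explained by the phenotype plus the surrogates
  (joint R² > 0.5).  A near-duplicate regressor pair (an orthogonalized PC
  next to its re-estimated surrogate) lets tiny phenotype contamination of
  either copy be amplified until the design reconstructs the phenotype —
  measured on simulated data, the residual phenotype spread collapsed from
  2.48 to 0.07 g/L before this guard existed.

Both thresholds are configuration fields.  The number of surrogates is
additionally capped at `(n − 2 − K)/2` to preserve residual degrees of
freedom at n = 23.

**What the model cannot do.**  Lactic-acid production tiers are
subpopulation-determined, so a gene spiked in exactly one subpopulation is
*genuinely* correlated with lactic acid across this panel.  Surrogate
variables recover the group contrasts orthogonal to the phenotype (same-tier
contrasts), but the tier direction itself is indistinguishable from signal;
no expression-plus-phenotype method can separate the two.  On synthetic
data with per-group spiked DEGs, such genes are therefore called QTTs even
though the generator did not link them to the phenotype — a confounding
limitation of the design, not an estimator error (α̂ on true module genes
stays unbiased, bias ≈ −0.03).  Recovery operating characteristics
(sensitivity ≥ 0.8, FDR ≤ 0.05) are therefore quantified on planted designs
drawn from the QTT model itself, with the study's lactic-acid spread.

## Correlations, networks, enrichment

Spearman's rho uses average ranks and the t approximation
`t = ρ√((n−2)/(1−ρ²))` on n−2 df (exact permutation reserved for test
oracles; at n = 23 the approximation is well within two-fold of exact down
to n = 8).  |ρ| = 1 reports p = 0.  Network edges are unadjusted p < 0.05,
matching the edge rule of the underlying study design; a BH mode exists but
is off by default.  The enrichment universe defaults to all genes surviving
the all-zero drop; the hypergeometric p is the upper tail `P(X ≥ k)`.
Accumulated fold-change sums log2FC over DEGs only (an all-genes variant is
a switch).  Metabolite correlations use pairwise-complete observations and
report the per-pair n.

## Synthetic data generator

The generator emulates the study conditions: 23 samples in six
subpopulations (3,4,4,4,4,4), ~5000 genes, NB counts (`var = μ + φμ²`,
φ = 0.05) with log-normal baselines (log2 mean 7, sd 1.8 — typical bulk
RNA-seq depth of a few hundred counts per gene) and log-normal size factors
(log-sd 0.25).  Lactic acid follows the study's three production tiers
(1 g/L Asia; 3.5 g/L Americas, Canada-trees, Europe/Domestic-1; 7.5 g/L
Europe/Domestic-2, Europe-Mix) with a 0.6 g/L within-group strain spread.
Per group, 60 genes carry spiked fold-changes (|log2FC| ~ U(1,4), 70%
down — differential expression in the study was dominated by
downregulation); 5% of genes form a lactic-acid-linked module with α = 1 on
the log2 mean (three of them designated focal "LDH-like" genes); one hidden
batch factor loads 30% of genes (loadings N(0, 0.5²)) and can optionally be
drawn correlated with the phenotype for confounding experiments.

End-point metabolites are drawn through a Gaussian copula anchored on the
normal scores of the realized end-point lactic acid, so the configured rank
correlations (lactic–glycerol −0.85, glycerol–ethanol 0.66) are hit
regardless of the lactic marginal; the unspecified lactic–ethanol entry is
set by conditional independence given glycerol to keep the latent
correlation matrix positive definite.  Remaining metabolites (residual
sugars, acetic acid, pH, total acidity, PAN, ammonia) are independent
Gaussians at oenologically plausible values.

What the generator does *not* emulate: GC/length biases, isoform structure,
mean-dependent dispersion trends, strain-level phylogenetic correlation
within subpopulations, or any coupling between the spiked DEG sets and real
pathway membership.  Passing tests therefore demonstrate the statistical
machinery under the stated model, not agreement with the study's specific
gene lists — which cannot be reproduced without the unreleased raw data.

## Problem sizes used in tests

Monte-Carlo checks run at sizes chosen to make the assertions stable:
2000 genes for null calibration and spiked power (4 vs 19 samples), 20
seeds × 2000 genes for QTT recovery, 10 seeds for the confounder
comparison, n = 100 samples for copula fidelity and n = 200 for dispersion
recovery; the full pipeline closure runs a 700-gene profile.  The
acceptance script states its sizes inline and completes in seconds.
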