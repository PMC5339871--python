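# Methods

This note records the models, defaults and numerical choices behind
`radnet`, and what the synthetic-cohort tests do and do not establish.

## Diffusion tensor and scalar metrics

The tensor is fitted by ordinary log-linear least squares on
ln(S_i/S_0) = −b·gᵢᵀDgᵢ over the six unique components, requiring ≥ 6
non-collinear unit directions (rank-checked design matrix). The estimator is
closed-form and exact on noiseless forward simulations, which is what makes
it testable to machine precision; weighted or nonlinear variants would
change noise propagation, not the contract. Eigenvalues are reported sorted
descending; AD = λ₁, RD = (λ₂+λ₃)/2, MD = mean, FA = √(3/2)·‖λ−MD‖/‖λ‖ with
FA ≡ 0 for the all-zero tensor. Negative eigenvalues from noisy fits are
*not* clipped: the metrics are computed as-is and the result carries a
`negative_eigenvalues` flag, so QC can drop the voxel instead of receiving a
silently deflated FA. Images are never touched: metric maps enter as flat
arrays with a mask, and the per-sample trait is the ROI **median** — robust
to the heavy right tails of diffusivity inside heterogeneous tissue.

## Expression preprocessing

The package accepts any log-scale genes × samples matrix; chip-level
processing is out of scope. Quantile normalisation (reference distribution =
row means of the column-sorted matrix; ties receive the mean of the spanned
reference values) is available and on by default in the pipeline; because
every downstream statistic is correlation- or rank-based, the exact
normalisation is secondary. Variance filtering keeps the top-k genes in
stable input order. Sample alignment across expression/traits/survival is by
identifier intersection, failing hard when empty and warning with the
dropped ids otherwise.

## Trait redundancy

Diffusivity metrics derived from one tensor are near-collinear across a
cohort and correlate with essentially the same genes. The pipeline computes
per-trait gene-correlation profiles (Spearman), groups traits by
single-linkage on profile correlation (threshold 0.9 — comfortably between
the ~0.999 collinearity of AD/RD/MD and the ~0.15 chance correlation with
FA), and carries one representative per group. The representative is a
config key, defaulting to MD, the conventional summary of the diffusivity
triplet. Redundancy is resolved *before* gene screening so each retained
trait is screened once.

## Co-expression network

Unsigned adjacency |cor|^β (signed variant available). Soft power:

* `soft_threshold_select` implements the scale-free criterion — smallest β
  in 1..20 whose connectivity histogram gives R² ≥ 0.8 in the
  log10(freq) ~ log10(k) regression over 10 equal-width bins (empty bins
  dropped), falling back to the argmax with a flag. Equal-width binning is
  used because equal-count bins make every bin frequency identical and the
  regression degenerate.
* The pipeline's default, however, is the tabulated sample-size
  recommendation (`recommended_power`: unsigned 9/8/7/6 for n < 20 / < 30 /
  ≤ 40 / > 40). On latent-factor cohorts of this size the scale-free
  criterion is unreliable — it can select extreme powers at which the static
  tree cut strands most genes, occasionally detecting no modules at all —
  which is exactly the regime the community tables were written for.
  Scale-free selection remains available (`power_selection: scale-free`) and
  any fixed power can be set explicitly.

TOM follows the standard form ω_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)
with unit diagonal; 1 − ω is the clustering dissimilarity. Module detection
is deliberately simpler than the dynamic hybrid tree cut: average-linkage
clustering, a static cut at height 0.995, size filter (default minimum 10;
genes in smaller clusters are relabelled 0/unassigned), then iterative
merging of modules whose eigengenes correlate above 1 − merge_height
(default 0.25, i.e. merge above r = 0.75). Final labels are contiguous
integers sorted by descending size. The static cut trades the adaptive
behaviour of dynamic cutting for full determinism and a specifiable
contract; the planted-recovery tests quantify what it achieves (ARI ≥ 0.9 on
five 50-gene modules at intra-correlation 0.64, n = 40, β = 7).

Eigengenes are the first right singular vector of the gene-standardised
module submatrix, rescaled to unit variance and sign-oriented to correlate
positively with the module's mean standardised profile — PC sign is
otherwise arbitrary and would break cross-platform determinism. kME is the
gene × eigengene Pearson matrix; hub genes are module members ranked by own-
module kME with lexicographic tie-break. Module–trait association uses
Pearson correlation (Spearman optional) with the two-sided t approximation
at n − 2 df. Network export writes the ω ≥ threshold edge list plus a node
table with intramodular connectivity (sum of ω to same-module genes).

## Gene screening and subgrouping

Spearman ρ is computed as Pearson on midranks. For n ≤ 10 the two-sided
p-value is the exhaustive permutation probability over all n! trait orders
(evaluated in vectorised chunks; at n = 8 that is 40 320 orders), which also
gives perfectly monotone genes the attainable floor 2/n! rather than an
unattainable zero; for larger n the t approximation
t = ρ√((n−2)/(1−ρ²)) is used. Benjamini–Hochberg adjustment is the standard
step-up (via statsmodels). Gene selection applies |ρ| ≥ 0.6 with the FDR cut
default-off (q ≤ 1.0) as an independent knob; an optional Fisher's exact
test quantifies overlap between a trait's signature and a module's
membership (2×2 over the gene universe).

Sample subgrouping clusters on 1 − Spearman correlation between sample
profiles over the signature genes, average linkage, cut to exactly k = 2
(configurable). Clusters are named I/II by *ascending trait mean*, so
"cluster II = higher trait" holds by construction regardless of dendrogram
order. Note this distance only separates groups when the signature is
two-sided (genes correlating in both directions); a purely one-directional
signature is a per-sample constant shift that profile correlation cannot
see. Real trait signatures are two-sided, and the synthetic cohort plants
them accordingly (below).

## Pre-ranked GSEA

Walking the ranking, hits add |score|^exponent normalised over the set's
hits (exponent default 1; 0 recovers the unweighted Kolmogorov–Smirnov
form), misses subtract 1/(N − N_hits); ES is the running sum's extremum of
maximal absolute deviation, and the leading edge is the members at or before
it (at or after, for negative ES). Because the ranking is fixed, the null
permutes gene labels: each permutation re-draws the set's positions
uniformly. The vectorised null evaluates only the 2·|set| candidate extrema
per permutation (values just after and just before each hit), which an
explicit running-sum cross-check in the tests confirms to 1e-12.

Nominal p is calibrated against the same-sign side of the null,
(1 + #extreme) / (1 + #same-sign) — dividing by the full permutation count
would halve the attainable range and destroy null uniformity (the
calibration tests check uniformity by KS at 200 replicates). NES divides ES
by the mean |null ES| of matching sign. FWER uses the max-statistic
construction — per permutation, the maximum |normalised null ES| over all
sets — and is clipped from below at the nominal p so the finite-sample
estimate never undercuts it. All p-values are add-one smoothed. Sets are
restricted to the ranked universe and size-filtered (defaults 5–500).

## Survival

Kaplan–Meier, log-rank and Cox fits are thin, contract-checked surfaces over
lifelines. The KM median is the earliest time with S(t) ≤ 0.5, reported as
undefined when never reached. Cox uses Efron tie handling; monotone partial
likelihoods (perfect separation) are detected, refitted with a small ridge
penalty for a finite estimate, and flagged non-converged. Group summaries
report both the censoring-naive mean ± SD of observed times (a common
descriptive convention, labelled as such) and the KM median. Both the
log-rank p and the Cox Wald p appear in the pipeline report, since either
may be the headline test.

## Synthetic cohorts

The generator is the package's study design, not a convenience fixture:

* **Modules.** Member gene g of module m is s_g·√c·f_m + √(1−c)·ε with one
  latent N(0,1) factor f_m per module, noise ε, c = `intra_cor`, and loading
  sign s_g. E|cor| within a module is exactly c; memory is O(genes). The
  cohort default plants five 50-gene modules at c = 0.64 among 500 genes
  with 40% negative loadings (`neg_fraction = 0.4`), emulating the two-sided
  signatures of real modules; `generate_expression` alone defaults to
  all-positive loadings, where mean within-module r = c exactly.
* **Traits.** MD tracks one module's factor, FA another's; by default the
  noise is orthogonalised in-sample so the realised correlation equals the
  0.8 target exactly in every cohort (the same exact-control principle as
  the modules — otherwise cohort-level luck in the realised link dominates
  end-to-end behaviour). AD and RD are affine copies of MD plus small
  jitter (pairwise r > 0.95 by construction; exactly 1 at zero jitter).
  Scaling constants put diffusivities near 1.0 and FA in [0, 1]; every
  downstream statistic is scale-invariant, so the units are cosmetic.
* **Survival.** Exponential times with hazard h₀·exp(β·z(trait)),
  h₀ = ln2/12 (baseline median 12 time units, a months-scale cohort);
  default β = −ln 4 per SD of MD (higher MD protective). Censoring is
  independent uniform on [0, T_max] with T_max solved by bisection so the
  expected censored fraction hits the requested rate (default 0.1).
* **Gene sets.** One set per planted module (exact membership) plus random
  decoys (default 5 × 40 genes); names recorded in the truth object.

Cohort sizes: `generate_cohort` defaults to 21 samples, the scale of a small
prospective imaging cohort; the pipeline's synthetic default and the
recovery/acceptance checks use 40 samples — the size at which module
recovery and survival power are reliably measurable on a desk — with the
module count, sizes and effect strengths above. Problem sizes in the test
suite (10 recovery seeds, 200 calibration replicates, 50 hazard-recovery
replicates, 20 end-to-end seeds, 1000 GSEA permutations) are the package's
chosen verification scale.

What the synthetic tests do **not** show: robustness to batch effects, probe
collapse, array QC failures, non-Gaussian expression noise, informative
censoring, or imaging confounds (partial volume, oedema boundaries) — none
of which the generator models. Passing tests establish that the machinery
recovers what it is designed to recover under its stated noise model, with
calibrated nulls; they are not evidence about any particular real cohort.

## Determinism

Every stochastic step takes an explicit seed. The pipeline fans one global
seed into per-stage seeds (seed × 1 000 003 + CRC32 of the stage name,
mod 2³¹), records them in the run log, and writes all floating-point tables
with 12 significant digits; two runs with the same config produce
byte-identical artifacts, which the tests assert literally.

## Known limitations

* The static tree cut needs a cut height matched to the soft power; the
  shipped defaults are tuned for the recommended-power regime, and extreme
  powers push genes into the unassigned bucket.
* The exhaustive Spearman permutation p is exponential in n and enabled only
  for n ≤ 10; at typical cohort sizes the t approximation is used.
* GSEA's gene-label permutation null ignores inter-gene correlation; FWER
  control is with respect to that null, as is conventional for pre-ranked
  analyses.
* Univariate survival only: no clinical covariates, time-varying effects or
  competing risks.
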