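# Methods

`consortium-net` infers interaction structure in a crude-oil-degrading
bacterial consortium followed over serial transfer passages: which genera
co-occur (positively or negatively), which are structurally keystone, and
which track the degradation efficiency of the oil fractions. This note
records the statistical model behind each stage, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the known limitations.

## Data model

A study is a samples × taxa abundance matrix with per-sample generation
(`G1`…`G4`) and replicate labels, plus degradation records: residual oil
masses (g) for an abiotic control and the bio-treatment, per sample and
oil fraction (TPH and the SARA fractions). Degradation efficiency is

    eff = (residual_control − residual_treatment) / residual_control,

a fraction ≤ 1 that may be negative when the treatment residual exceeds
the control (observed in practice for resins/asphaltenes); negative
values are reported, never clipped. Internally all abundances are
fractions (row-closed to 1); percentages exist only in reports.

## Why a compositionality-preserving null

Relative abundances are compositional: closure forces negative
correlation between taxa even when the underlying absolute abundances
are independent. A naive correlation threshold therefore floods the
network with spurious negative edges. The permutation null used here
(a ReBoot-style scheme) permutes one taxon's values across samples,
re-closes every sample to sum 1, and recomputes the measure — the null
distribution then carries the same closure bias as the observed score,
so the test calibrates against it. For a pair (i, j) the permuted taxon
is the first-indexed member, a fixed convention that keeps every pair's
null reproducible.

The observed statistic entering the p-value is the bootstrap mean over
resampled samples (B resamples), which damps the influence of single
outlier samples; `use_bootstrap=False` substitutes the raw observed
score. The empirical two-sided p with add-one correction is

    p = (1 + #{ |null_k − null_mean| ≥ |boot_mean − null_mean| }) / (P + 1).

## The five measures

* **Bray–Curtis** dissimilarity `1 − 2Σmin/(Σx+Σy)` — unsigned, in [0,1].
* **Pearson** and **Spearman** (Pearson on mid-ranks; ties averaged).
* **Mutual information** in nats on equal-frequency bins. Bin labels come
  from mid-ranks (`floor((rank − 0.5)·bins/n)`), so tied values share a
  bin, a constant vector occupies one bin (MI exactly 0), and a tie-free
  identical pair at n divisible by bins gives exactly log(bins). Default
  bins = floor(√n) capped at 8 — a variance/resolution compromise robust
  to skewed abundances.
* **GBLM**: componentwise L2-boosted linear regression. All predictors
  and the target are z-scored; each of M iterations picks the predictor
  most correlated with the current residual and moves its coefficient by
  ν times the univariate least-squares fit. Defaults ν = 0.1; M = 500
  for standalone fits, M = 100 inside the permutation machinery where
  hundreds of refits per taxon are batched (the tables are small enough
  that boosting has long plateaued by 100 steps at ν = 0.1). With a
  single relevant predictor and M→∞ the path converges to the OLS fit.
  The pairwise GBLM score is the mean of the two directed coefficients
  (j → i and i → j); directedness of the original formulation is not
  recoverable, so symmetrization is a declared convention.

Pairs undefined under one measure (zero variance, all-zero vectors) drop
out of that measure's evidence only; the ensemble degrades gracefully.

## Merging, signs, edges

Per-measure p-values for one pair are merged with **Brown's method**: the
Fisher statistic −2Σlog p is referred to a scaled χ², with scale and df
estimated from the empirical covariance of −2 log p across the measures'
shared permutation draws (each draw converted to its within-null
empirical p). When the covariance cannot be estimated the merge falls
back to plain Fisher. Perfectly dependent repeats therefore merge to
approximately the single p rather than inflating like pᵏ.

Edge sign is a majority vote: Pearson, Spearman and GBLM vote their
coefficient sign; Bray–Curtis votes positive when observed dissimilarity
is below its null mean; MI abstains. An exact tie is `conflict` and the
pair is excluded from the network. Edges are pairs with BH q ≤ 0.05
(threshold configurable) within one generation's family of pairs —
generations are corrected separately because each generation's network
is built and interpreted separately. Edge weight is the mean
standardized effect |observed − null_mean|/null_sd over the measures
supporting the winning sign. All taxa of the input table remain as
nodes, so isolated taxa are visible with zero centralities.

## Key-scores

Raw centralities are computed on absolute edge weights: degree is node
strength Σ|w|; shortest-path distance is 1/|w|; closeness is *harmonic*
closeness (sum of reciprocal distances), chosen because the inferred
networks are routinely disconnected and isolated nodes must score
exactly zero; betweenness is weighted shortest-path betweenness. Each
index is homogenized — divided by its sum over nodes — which puts the
three on a common unitless scale (and matches the O(10⁻²) magnitude of
published per-node values over tens of nodes). Then

    key_score = degree + closeness − betweenness,

high for well-connected, central, non-bottleneck nodes. Ranking is by
key-score, ties broken by higher degree then lexicographic taxon ID.
Strength (not edge count) is the default "degree" because the networks
are weighted; both raw values are exposed.

## Taxon-function association

For each genus and oil fraction, all five measures are computed between
the genus's relative abundance and the efficiency vector, each
standardized against its own permutation null (efficiencies shuffled,
P times) into a signed z. Pearson/Spearman/GBLM carry their own sign;
MI and Bray–Curtis are unsigned, so their |z| takes Spearman's
direction — this makes the combined statistic exactly antisymmetric
under response negation. The **combined coefficient** is the sum of the
five signed z's: unbounded, typically O(10) for strong drivers, which is
the natural scale of published per-genus coefficients (e.g. 19.48); such
printed values are treated as ranking evidence, not reproduction
targets. Its p-value comes from the permutation distribution of the
combined statistic itself, and BH runs over taxa within a fraction.
Because the five z's are computed on the same few samples they are
strongly dependent (Pearson–Spearman z correlation ≈ 0.95), so the
combined null SD is ≈ 3.8, not √5; under the null the 95th percentile of
|combined| sits near 7.5, well below the perfect-dependence ceiling of
~10 but above what independence would suggest.

By default the association pools all generations jointly (n = 12 in the
study design); a `generation` argument restricts to one transfer.

Group comparisons (control vs treatment, across generations) use
Wilcoxon–Mann–Whitney and Kruskal–Wallis with exact enumeration at the
tiny group sizes of triplicate designs (asymptotic approximations are
invalid at n = 3) and tie-corrected approximations otherwise. Alpha
diversity is Shannon H in nats with Pielou evenness H/ln(S_observed);
beta diversity is the pairwise Bray–Curtis matrix. Core taxa are those
present in > 80% of all samples with mean relative abundance > 0.2%
("present" means > 1e-9 after closure); shared/unique sets are plain
presence bookkeeping per generation.

## Synthetic data: what it emulates

The generator mirrors the study design: 4 generations × 3 replicates
(12 samples), 30 genera, sequencing depth 50,000. Log-scale latent
abundances are multivariate normal with a correlation matrix carrying
the planted pairwise associations (repaired toward the identity by
shrinkage if not positive definite — the default fixture plants ten
*disjoint* pairs of magnitude 0.8, block-diagonal and PD by
construction, so the planted magnitude holds exactly). Per-taxon base
log-means are drawn once from N(0, 1.5²), giving the uneven,
few-dominant-genera profile typical of enrichment cultures; generation
drift multiplies a taxon by drift^g (g = 0 for G1), emulating keystones
fading and competitors rising over transfers. Counts are multinomial at
fixed depth on the closed latent composition, so downstream methods face
genuine compositional and sampling noise.

Degradation responses are linear in the standardized log-latent
abundances of designated keystones (β in efficiency units per SD),
optionally with pairwise synergy terms on the standardized log-product,
plus N(0, noise_sd = 0.05) replicate noise, clipped to [−0.2, 1].
Control residuals are fixed masses (10 g TPH per culture, SARA split in
field-typical ratios) and treatment residuals are back-computed so the
efficiency identity holds exactly.

Not emulated: read-level errors, chimeras, taxonomic misassignment,
phylogenetic correlation between taxa, overdispersion beyond
multinomial, and any feedback of community composition on itself across
generations. Passing recovery tests therefore show that the inference
machinery works when its generative assumptions approximately hold —
not that real amplicon data satisfy those assumptions.

## Numerical choices and degenerate inputs

* All randomness flows from `numpy.random.default_rng` (PCG64) seeds;
  one global seed fans out to per-stage child seeds via `SeedSequence`,
  so identical seed + config reproduce byte-identical outputs.
* Empirical p-values use the add-one rule, so p ≥ 1/(P+1) always.
* Constant vectors: correlation undefined (pair dropped from that
  measure), MI defined as 0, boosting ignores zero-variance columns.
* Correlation-matrix repair: shrink (1−λ)R + λI over a λ grid until the
  smallest eigenvalue exceeds 1e-8.
* Ties in ranks use mid-ranks everywhere (Spearman, MI binning, rank
  tests with tie-corrected variance).
* Exact enumeration limits: Mann–Whitney exact for tie-free groups of
  ≤ 8; Kruskal–Wallis enumeration up to 50,000 label arrangements.

## Problem sizes used in the shipped checks

Calibration and recovery checks run at 30 taxa × 40 samples with P = 200
permutations and B = 100 bootstraps (50 seeds for calibration, 3 fixed
seeds pooled for edge recovery), and the function-link recovery at the
study's own 4 × 3 = 12-sample design over 50 seeds — sizes chosen so the
whole suite completes comfortably on a laptop-class single core while
the Monte-Carlo margins stay interpretable.

## Known limitations

* With triplicate generations (n = 3 per network) the permutation null
  has only six atoms and the merged χ² extrapolates far beyond them;
  per-generation networks at that depth are illustrative, not
  inferential. The recovery claims in the tests are made at n = 40.
* Brown's merge is an approximation; at extreme significance (all
  measures at the empirical floor 1/(P+1)) merged p-values depend on the
  estimated inter-measure dependence and are accurate only to
  Monte-Carlo order.
* The GBLM component is a concrete componentwise-L2-boosting
  instantiation of a "generalized boosted linear model"; other boosting
  variants would give different sparse coefficients.
* The combined taxon-function coefficient is a declared convention (sum
  of five permutation-standardized z's); its absolute scale is
  comparable across taxa within one run but not across studies with
  different P or sample size.
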