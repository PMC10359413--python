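# Methods

`lipidsig` analyses gas-chromatographic fatty-acid (FA) profiles of
synovial tissue, expressed as mol-% of total lipid side chains, from two
diagnosis groups — rheumatoid arthritis (RA) and osteoarthritis (OA).
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic data can and cannot show.

## Profile model and per-variable statistics

A profile is a samples × variables matrix.  Raw columns are individual
acyl or alkenyl (DMA) chains named in `C:Dn-x` shorthand; the parser
enforces the grammar (carbons ≥ 2, a series suffix exactly when the
chain is unsaturated, `DMA` prefix for dimethyl acetals).  Raw mol-%
must be non-negative and sum to 100 per sample within ±0.5 (published
tables round to two decimals); a renormalisation helper is provided.

Derived variables are appended from an editable YAML recipe file:
class sums (SFA, MUFA, PUFA, n-3/n-6 PUFA, total DMA, C20–24 SFA), the
n-3/n-6 ratio, product/precursor ratios, a double bond index and an
average chain length.  The exact formulas behind "product/precursor
ratio" and "double bond index" vary between laboratories, so they are
explicit configuration, not code:

- double bond index = Σ(mol-%ᵢ · nDBᵢ)/100, average chain length =
  Σ(mol-%ᵢ · nCᵢ)/100 (mol-%-weighted means over all measured chains);
- n-6 product/precursor ratio = (Σ C20–22 n-6 PUFAs)/18:2n-6, and the
  n-3 analogue over 18:3n-3.

Z-scores are computed per variable across samples with the *population*
standard deviation (ddof = 0); "the standard deviation" of a Z-score
formula carries no Bessel correction unless stated, and the choice is
configurable.  Zero-variance variables are rejected by name rather than
silently yielding NaN.

Between-diagnosis tests use the two-sided Mann–Whitney U: the exact
null distribution when both groups have ≤ 12 samples and there are no
ties (the 8 + 8 design lands here), otherwise the normal approximation
with continuity and tie correction.  No multiplicity correction is
applied to the per-variable flags; a Benjamini–Hochberg column is
emitted alongside for readers who want it.  Sex ratios and similar 2×2
contingencies use Fisher's exact test (two-sided, summed hypergeometric
tail).

## FA group identification

Variables are clustered on correlation distance d = 1 − r (not 1 − |r|:
anti-correlated variables are *not* grouped) with the Ward criterion
applied to the unsquared distances — the `ward.D` variant used by
hclust/ClustVis, which scipy does not implement (scipy's `ward` is
`ward.D2` on Euclidean input).  The agglomeration is a direct
Lance–Williams recurrence; ties are broken by merging the pair whose
smallest member labels sort lexicographically first, so trees are
deterministic across platforms (the implementation is verified against
R `hclust(method = "ward.D")` in the test suite).  The default cut is
K = 5 groups, but group identification is ultimately a judgement call,
so a manually curated variable → group table always overrides the cut.

## Data enrichment and random forests

The K collinear groups carry largely redundant information, which
permits *data enrichment*: for each of B = 1000 iterations one variable
is drawn uniformly per group (with replacement across iterations), and
all n = 16 samples are emitted with those K Z-scores and their copied
diagnosis — B × n = 16,000 pseudo-samples with K = 5 features.  Rows
are fully traceable: the provenance table records the (iteration,
sample, drawn variable) of every cell.

Classification uses a random forest of 100 trees (entropy criterion,
depth cap 16, min split 2, min leaf 1, 5 candidate features per split,
bootstrap resampling) — the same parameter block for the enriched and
the plain run.  Per repeat (default R = 100) a fresh stratified 80/20
train/test split is drawn; accuracy is measured on the held-out 20% and
impurity-based feature importances (normalised to sum to 1) come from
the training data only.  Means over repeats are reported.  One global
seed fans out to per-repeat seeds through a counter, so results are
bit-for-bit reproducible.  Notes:

- The split is stratified; an unstratified split at these sizes can
  produce class-free test sets.  Splits are re-drawn (and logged) in the
  pathological case where a class is missing from training.
- Enriched rows from the same source sample can land in both train and
  test; the enriched accuracy therefore measures the *redundancy* of the
  group representation (whether one variable per group identifies a
  sample's profile), not out-of-sample diagnosis prediction.  This is
  why it approaches 100% while the plain 16-sample run stays near 75%
  and leave-one-out discriminant accuracy near 65%.
- Impurity importance is biased under correlated features, so a
  permutation-importance option is provided for cross-checking rankings.
- `max_features = 5` is clamped to the feature count on datasets with
  fewer than 5 features; the study-shaped runs (5 or 40+ features) are
  unaffected.

## Discriminant analysis

Canonical LDA with equal priors and the pooled within-groups covariance
W: functions are eigenvectors of W⁻¹B, samples are assigned to the
nearest class centroid in discriminant space (equivalently, smallest
Mahalanobis distance under W).  With g classes there are min(g − 1, p)
functions; eigenvalues are reported as percentages of between-group
variance (two classes ⇒ one function with 100%).  When p ≥ n the pooled
covariance is singular; the default ridge λ = 10⁻⁶ · trace(W)/p makes
the handling explicit and reportable (commercial packages regularise
silently), and a QR-based collinearity pruner is available instead.
Each function is oriented so the alphabetically first class has a
negative mean score.  Resubstitution accuracy (optimistic) and
leave-one-out accuracy (honest; full refit per fold) are both reported.

## Pathway analysis

The reaction network is a directed graph over FA chains with three edge
kinds and fixed stoichiometry: elongation (+2 C), chain shortening
(−2 C), desaturation (+1 double bond); the n-series is preserved except
where Δ9 desaturation of a saturated chain creates one.  The default
table (an editable TSV keyed by position-aware nomenclature, because
double-bond position matters: n-3 and n-6 chains are not
interconvertible) is a best-effort reconstruction of the standard
mammalian map — the SFA elongation ladder 14:0→…→26:0, the Δ9/MUFA
branches, and the n-6/n-3 routes including the C24
elongation–desaturation–shortening loops that produce 22:5n-6 and
22:6n-3.

Edges between measured chains are *direct*; a directed chain whose
interior nodes are all unmeasured is contracted into an *effective*
edge (path recorded), so e.g. 22:5n-3 → 22:6n-3 appears even when the
C24 intermediates were not measured.  Per node, the level change score
(mean_RA − mean_OA)/mean_OA quantifies the RA shift against the OA
reference.  Per edge, the substrate–product Pearson correlation is
computed on mol-% *within each diagnosis separately* (Pearson r is
location/scale invariant, so mol-% and Z-scores give identical r) and
classified at α = 0.05 into significant in neither / OA only / RA only /
both.  A significant within-diagnosis correlation marks the reaction as
a candidate dominant biosynthesis route of the product in that
diagnosis — edge direction always comes from the chemistry, never from
the (symmetric) correlation, and no multiplicity correction is applied
across edges.  DMAs and derived variables stay out of the network.
Exports: GraphML, DOT, TSV edge table.

## Synthetic data

The generator emulates the statistical shape of the cohort: per group g
a single latent factor f, and per variable j in g

    x = δ_g·[class] + √ρ·f + √(1−ρ)·ε,

so variables have unit variance, intra-group correlation ρ (default
0.8), and a between-diagnosis mean shift of δ_g SD (default
(0, 0, 0, 1.5, 0)).  Defaults: 8 + 8 samples, 5 groups × 8 variables.
Optional planted substrate→product correlations (per diagnosis, exact
in-sample r by construction) support the pathway power and calibration
studies.  Mol-% mode maps x through a logistic-normal closure,
100·softmax(b + τ·x), with fixed baseline log-abundances b spanning
roughly 0.1–15 mol-% and temperature τ = 0.15 (≈ 15% CV per chain,
typical of GC-FID profiles; with this τ the observed post-closure
intra-group correlations match the emulated r ≈ 0.7–0.8 regime).  The
softmax is monotone in b + τx, so within-sample magnitude ranks of the
underlying weights are preserved.  Z-mode skips the closure and returns
the latent matrix, matching the Z-score pipeline exactly.

`study_shaped_fixture(seed)` is the canonical 16 × 40 mol-% dataset
(group 4 carries the 1.5 SD effect) used throughout the tests and the
acceptance script (fixed seed 0 there, as the stand-in for a fixed
cohort dataset).  What the fixture does *not* emulate: lipid-class
structure (PL vs TAG), chromatographic noise, patient covariates (age,
BMI, medication), or any biologically meaningful assignment of effects
to specific chains — passing tests show the pipeline recovers planted
statistical structure at the study's sample size, not that any
particular FA matters in arthritis.

## Problem sizes and numerical choices

- Enrichment runs: B = 1000, R = 100 forests for headline numbers;
  power/calibration studies use B = 300, R = 3 per replicate over 20–100
  replicate datasets, which bounds each study to a few minutes while the
  replicate count, not forest noise, dominates the uncertainty.
- The 20-seed group-ranking power study plants a 3 SD single-group
  effect (a clearly separating group); at the cohort's default 1.5 SD
  and n = 8 + 8 the realised group shift fluctuates by ±0.45 SD, so a
  null group occasionally overtakes the planted one — a property of the
  sample size, not of the classifier.
- The weak-effect LOO study uses 1 group × 4 variables: at p ≥ n the
  leave-one-out signal of a 1 SD effect is swamped by estimation noise
  of the regularised discriminant.
- Mol-% closure tolerance ±0.5; Z-score variance tolerance 1e-9; exact
  Mann–Whitney switches to the tie-corrected approximation on any tie;
  Fisher and Mann–Whitney p-values match brute-force enumeration to
  1e-12 in the tests.

## Known limitations

- The default reaction table is a literature-style reconstruction; site
  measurements (e.g. odd-chain or n-7 PUFA routes) may require edits.
- Impurity importances on correlated features should be read as group
  evidence, not per-variable attribution; use the permutation option.
- The enrichment accuracy is not a diagnostic claim (see above); the
  honest predictive estimate at n = 16 is the leave-one-out accuracy.
- `GroupStatsTable` significance flags are unadjusted per-variable
  tests, as is conventional for descriptive FA tables.
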