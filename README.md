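# lipidsig

Fatty-acid signature analysis of arthritic synovium.

Synovial membrane from rheumatoid arthritis (RA) and osteoarthritis
(OA) patients carries distinct fatty-acid (FA) profiles — measured by
gas chromatography as mol-% of total lipid side chains.  At a typical
cohort size (8 + 8 samples, ~40 chains plus derived sums and ratios)
the statistical questions are awkward: variables are compositional,
strongly collinear, and far more numerous than samples.  `lipidsig`
implements a pipeline built for exactly this regime:

1. **Profiles** — nomenclature-aware parsing of `C:Dn-x` chain labels,
   derived class sums / product–precursor ratios / double-bond and
   chain-length indices, Z-score normalisation
   Z = (x − ⟨x⟩)/σ, and per-variable exact Mann–Whitney U tests with
   means ± SE.
2. **FA grouping** — Pearson correlation of all variable pairs and
   hierarchical clustering with correlation distance (1 − r) and Ward
   linkage on unsquared distances (`ward.D`, as in hclust/ClustVis),
   cut into K = 5 collinear groups (manual override supported).
3. **Data enrichment + random forests** — the groups are redundant, so
   the 16-sample table is enriched: per iteration one variable per
   group is drawn and every sample emitted with the copied diagnosis,
   giving 1000 × 16 = 16,000 pseudo-samples with 5 features.  100
   forests (100 trees, entropy, depth ≤ 16, stratified 80/20 splits)
   yield mean test accuracy and mean impurity importance per group —
   and, without enrichment, per variable.
4. **Discriminant analysis** — canonical LDA (equal priors, pooled
   within-groups covariance, explicit ridge when p ≥ n) with % variance
   per function, structure coefficients, resubstitution and
   leave-one-out accuracy.
5. **Pathway analysis** — a directed elongation/desaturation reaction
   network over the measured chains (unmeasured intermediates bridged
   by *effective* edges), per-chain level change scores
   (mean_RA − mean_OA)/mean_OA, and per-edge within-diagnosis Pearson
   significance classes (OA-only / RA-only / both / neither) at
   α = 0.05.
6. **Synthetic data** — a generator that plants the assumed structure
   (correlated groups, diagnosis effects, per-diagnosis edge
   correlations, logistic-normal mol-% closure) with ground truth, used
   for power, calibration and recovery testing throughout.

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
simulated cohort (16 samples, 40 chains, 5 planted groups, a 1.5 SD
diagnosis effect on group 4, mol-% closure):

```
python analysis/01_simulate_cohort.py
python analysis/02_profile_stats.py
python analysis/03_group_fas.py
python analysis/04_rf_enrichment.py
python analysis/05_discriminant.py
python analysis/06_pathway.py
```

Output (abridged):

```
5-group cut vs planted partition: ARI = 1.000
median intra-group r = 0.764; median inter-group |r| = 0.229
enriched dataset: 16000 rows x 5 group slots
mean test accuracy with enrichment:    100.0%
mean test accuracy without enrichment: 77.0%
group importances: {1: 0.177, 2: 0.04, 3: 0.263, 4: 0.332, 5: 0.188}
1 discriminant function(s); function 1 carries 100.0% of the between-group variance
resubstitution accuracy: 100%
leave-one-out accuracy:  69%
network: 38 nodes, 36 edges (2 effective, bridging unmeasured intermediates)
edge significance classes: {'sig_neither': 17, 'sig_RA_only': 5, 'sig_OA_only': 5, 'sig_both': 3}
```

Reading this: clustering recovers the five planted FA groups exactly
(ARI 1.0) and their members correlate strongly (median r 0.76 within vs
0.23 between).  Enrichment makes the diagnosis almost perfectly
recoverable — the group representation loses no class information —
while the honest small-sample estimates (plain forests 77%,
leave-one-out LDA 69%) stay far lower; the effect-carrying group 4
dominates the importance ranking (0.33).  The reaction network flags
elongation steps feeding the shifted long-chain FAs as RA-significant.

The same steps are available as a CLI (`lipidsig stats|group|rf|lda|
pathway|synth|run`) for user-supplied TSV/CSV/XLSX tables, e.g.:

```
lipidsig synth --seed 7 --out cohort.tsv
lipidsig run --input cohort.tsv --seed 7 --outdir out/
```

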