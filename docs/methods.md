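# Methods

## Data model and preprocessing

Input is a tidy table of raw quantification-cycle values at
technical-replicate resolution: `gene, sample, sample_type, setting,
condition, replicate, cq`. A *setting* is one experimental unit on which the
stability algorithms run (e.g. one cell line at one radiation dose, or one
patient's paired pre/post tissue); each setting contains control and treated
samples. Cq values must lie in (0, max_cycles], max_cycles = 45 by default —
a sanity bound, not a biological claim. A configurable token (default `ND`)
marks non-detected reactions; these are kept distinct from *missing*
replicates (absent rows), because a non-detect is a biological signal (no
amplifiable template) while a missing replicate is a technical accident.

Preprocessing order in the fitted pipeline:

1. **Non-detects** (`mark_nondetects`). Default policy
   `drop_gene_in_setting`: a gene with ≥1 non-detect replicate anywhere in a
   setting is excluded from that setting's analysis; `drop_sample` removes
   the affected sample instead. A setting left with <2 genes or <2 samples is
   an error. All removals are logged and recorded in metadata.
2. **Imputation** (`impute_missing_replicates`). A missing replicate is
   replaced by the geometric mean of the cell's observed replicate Cq values;
   at least `min_observed = 2` observed replicates are required, otherwise
   the unresolved cells are reported and the caller must decide. Imputation
   is idempotent and never touches observed values.
3. **Replicate collapse** (`collapse_replicates`). Default arithmetic mean of
   Cq across technical replicates — Cq is already a log-scale quantity, so an
   arithmetic mean of Cq corresponds to a geometric mean of abundances; a
   geometric-mean collapse of Cq values is available by configuration and the
   choice is recorded in provenance. The stability algorithms consume
   collapsed matrices; whether collapsed or replicate-level values feed the
   algorithms is a genuine degree of freedom in this workflow, and the
   collapsed convention was chosen and is recorded.

## Stability statistics

All four statistics consume raw Cq with no amplification-efficiency
transform, and all SDs use the n−1 denominator. Lower values mean more
stable; within-algorithm ranks are ascending with average ties.

**Comparative delta-Ct.** value(i) = mean over k≠i of
SD_s(Cq_is − Cq_ks). Since Cq is log2 abundance, the pairwise difference is
the log2 expression ratio of two genes, and its SD measures how much that
ratio wobbles across samples.

**geNorm.** The initial M_i is algebraically identical to the delta-Ct value
(this identity is asserted in tests on random matrices). The gene with the
highest M is removed and M recomputed until two genes remain; each gene's
reported value is its M at its removal round, the final two genes share ranks
1.5/1.5 and report their final-round M. Exclusion-argmax ties (measure-zero
on real data) are broken by removing the lexicographically first gene_id, so
results are reproducible. The V_n/V_{n+1} optimal-gene-number statistic is
out of scope.

**BestKeeper.** The ranking key is the per-gene SD of raw Cq. Diagnostics:
the BestKeeper index (per-sample geometric mean of Cq across genes) and each
gene's Pearson r against the index; r is reported NaN when either side has
zero variance. The original tool's descriptive spread ("SD [±Cq]") is
interpreted as the sample SD. Note BestKeeper's SD is *not* invariant to
per-sample loading shifts (the other three statistics are); this asymmetry is
asserted in tests. With paired settings (2 collapsed samples) r degenerates
to ±1 and is reported as-is — the SD ranking key remains meaningful.

**NormFinder.** Let z_gs = Cq_gs − mean_g(Cq_·s) (sample-centred Cq, removing
loading differences). Ungrouped: value = SD across samples of the doubly
centred residuals z_is − mean_s(z_is). Grouped by condition label: for each
group γ, bias d_iγ = z̄_iγ − z̄_i and intra-group variance s²_iγ; value =
mean_γ(|d_iγ| + √(s²_iγ/n_γ)). Plain (unshrunk) estimators are used; the
original method's variance-shrinkage corrections are not reproduced. Default
grouping is `auto`: grouped when every condition group has ≥2 samples,
otherwise ungrouped — with paired control/treated settings (one sample per
group) the pipeline therefore runs ungrouped, and the mode used is recorded
in each table's diagnostics.

## Rank aggregation

Per setting, the comprehensive rank of a gene is the geometric mean of its
four within-algorithm ranks (bounded by their min and max; monotone in each).
Combined ranks are geometric means of per-setting comprehensive ranks over
the settings where the gene is present; the dispersion reported alongside is
the sample SD (n−1) of those per-setting ranks. Comprehensive ranks stay
real-valued — they are **not** re-ranked to integers per setting before the
cross-setting combination, and the real-valued per-setting values are what
enters the statistical comparison. Genes excluded from some settings by
non-detects are combined over their available settings and flagged with
`n_settings`, rather than dropped from the study-level comparison.

Expression level is summarized separately (it is a suitability criterion, not
a stability one): per sample type, the per-gene arithmetic mean of collapsed
Cq over all samples, with ascending-Cq ranks (rank 1 = highest expression)
and the count of contributing values; genes never detected in a sample type
are reported as not detected.

## Statistical comparison

The per-gene vectors of per-setting comprehensive ranks (35 values per gene
under the default design) enter a one-way permutational ANOVA: the observed
one-way F, then gene labels permuted uniformly `n_perm` times (default 1000)
with group sizes fixed, p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1). The add-one
estimator avoids zero p-values; a zero-total-variance input is defined as
F = 0, p = 1. A single integer seed drives the permutation stream.

Dunn's post-hoc test runs on the joint midrank transform with the standard
tie correction Σ(t³−t)/(12(N−1)) and group-specific n in the variance;
two-sided normal p-values are Bonferroni-multiplied by the number of gene
pairs and capped at 1. The reported difference matrix is on the original
comprehensive-rank scale — differences of per-gene means, row minus column —
constructed directly from the mean vector so antisymmetry is exact and
additivity d(a,b) + d(b,c) = d(a,c) holds to machine precision. The rendered
comparison table prints the lower triangle with two-decimal differences,
three-decimal adjusted p-values (`< 0.001` below that), and stars pairs
significant at alpha (default 0.05).

## Synthetic data generator

The generative model is normal on the Cq (log) scale — the conventional qPCR
error model:

    Cq_{gsr} = mu_g + a_s + delta_g * 1[s treated] + w_{g,setting} + eps_{gsr}

| parameter | meaning | default |
|---|---|---|
| `mu_g` | baseline Cq per gene | panel of 14, 16–26 cycles |
| `loading_sd` | SD of per-sample loading shift a_s | 0.3 cycles |
| `gene_setting_sd` | SD of per-setting gene wobble w | 0.2 cycles |
| `noise_sd` | technical-replicate SD eps | 0.15 cycles |
| `effect_of[g]` | treatment effect delta_g | 0 (stable genes) |
| `missing_replicate_prob` | one replicate of a cell missing | 0.02 |
| `dropout_prob_ffpe` | gene non-detected in an FFPE setting | 0.05 |
| `replicates` | technical replicates per reaction | 3 |

The default design mirrors the study layout: 14 genes; 10 cell lines × 2
doses, 3 organoid, 8 fresh-frozen, 4 FFPE settings, each a control/treated
pair — 35 settings, hence 35 comprehensive rank values per gene. Baseline Cq
values are plausible placeholders (high expressers GAPDH/ACTB/B2M low Cq, TBP
in the lower-expression half), chosen within 15–30 cycles and exposed in
configuration; no published Cq levels are claimed. Treatment effects are
additive in cycles (multiplicative in abundance). Noise SDs were chosen as
realistic qPCR magnitudes: technical-replicate scatter well under half a
cycle, loading shifts a few tenths of a cycle.

What the simulator does *not* emulate: amplification-efficiency differences
between assays, inter-plate calibration drift, correlated (co-regulated) gene
responses, heavy-tailed outliers, and degradation gradients within FFPE
blocks beyond all-or-none non-detects. Passing tests on simulated data
therefore demonstrate correctness of the computations and calibration of the
inference under the stated noise model, not robustness to those real-data
phenomena.

## Numerical conventions and problem sizes

- Pairwise SD matrices are computed from the gene covariance matrix
  (Var_i + Var_k − 2Cov_ik), clipped at 0 before the square root; agreement
  with naive loops is verified to 1e−12 on random matrices.
- Ranks use average ties throughout; rank sums are conserved.
- Determinism: one integer seed governs each simulation and each permutation
  stream; identical configuration and seed give identical outputs.
- Test-suite problem sizes: oracle equivalence on 100 random 5-gene ×
  6-sample matrices; null calibration over 200 simulated studies at 199
  permutations each; effect recovery over 100 studies. These sizes keep the
  statistical checks sharp while the whole suite runs in a couple of minutes.

## Known limitations

- **Mild anticonservatism of the omnibus test on aggregated ranks.** Within a
  setting, the 14 comprehensive ranks are tied to a fixed sum, so genes'
  values are negatively correlated within settings. The permutational ANOVA
  permutes labels freely (as the workflow prescribes), which ignores this
  block structure; under a fully null simulation the p-value distribution is
  close to, but not exactly, uniform (KS distance ≈ 0.1 over hundreds of null
  studies, P(p < 0.05) ≈ 0.08). This is a property of the procedure, not of
  the implementation — the F statistic and the permutation estimator match
  independent oracles to machine precision. Conclusions resting on p-values
  near the threshold should keep this in mind.
- BestKeeper's Pearson-r diagnostic is uninformative (±1) in two-sample
  paired settings; the SD ranking key is unaffected.
- No amplification-efficiency correction (Pfaffl-type), melt-curve QC, or
  instrument-native file parsing; inputs are assumed to be clean Cq tables.
- NormFinder here uses unshrunk variance estimators; with very few samples
  per group the original shrinkage variant can rank differently.
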