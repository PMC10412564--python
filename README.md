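# refstab

Reference-gene (housekeeping-gene) expression-stability analysis for qPCR
quantification-cycle (Cq) data.

Accurate qPCR normalization requires a reference gene whose expression is
stable under the experimental conditions at hand — and classic choices such
as *ACTB* or *GAPDH* are often not. `refstab` implements the standard
candidate-screening workflow used in reference-gene validation studies (for
example, screening housekeeping genes in irradiated colorectal-cancer cell
lines, organoids and patient tissues): starting from replicate-level raw Cq
values it computes four per-gene stability statistics per experimental
setting, aggregates them RefFinder-style into comprehensive ranks, combines
ranks across settings, and statistically compares genes' stability.

## The statistics

For a collapsed gene × sample Cq matrix (Cq is a log2-scale inverse measure
of abundance; all SDs use the n−1 denominator):

- **comparative delta-Ct** — for gene *i*, the mean over partner genes *k* of
  SD<sub>s</sub>(Cq<sub>is</sub> − Cq<sub>ks</sub>); a stable gene keeps a
  constant log-ratio with every partner.
- **geNorm** — the same average pairwise variation *M*, with stepwise
  exclusion of the highest-*M* gene until two remain; a gene's reported *M*
  is its value at the round of removal.
- **BestKeeper** — per-gene SD of raw Cq, with the BestKeeper index
  (per-sample geometric mean of Cq) and each gene's Pearson *r* against it as
  diagnostics.
- **NormFinder** — variance decomposition of sample-centred Cq into
  inter-group bias |d<sub>gγ</sub>| and intra-group variance
  s²<sub>gγ</sub>, combined as mean<sub>γ</sub>(|d<sub>gγ</sub>| +
  √(s²<sub>gγ</sub>/n<sub>γ</sub>)); falls back to the pooled (ungrouped)
  residual SD when a condition group has fewer than two samples.

Per setting, a gene's **comprehensive rank** is the geometric mean of its four
within-algorithm ranks; the **combined rank** is the geometric mean of its
per-setting comprehensive ranks. Genes are then compared with a one-way
**permutational ANOVA** (gene labels permuted, F recomputed; p =
(1 + #{F<sub>perm</sub> ≥ F<sub>obs</sub>})/(B + 1)) and **Dunn's post-hoc
test** on joint midranks with Bonferroni correction.

A seeded simulator (`refstab.simulate`) draws replicate-level datasets under
the full study design — 14 genes; 10 cell lines × 2 radiation doses, 3
organoid, 8 fresh-frozen and 4 FFPE paired settings; 3 technical replicates;
sporadic missing replicates and FFPE non-detects — so the whole pipeline is
testable without external data.

## Worked example

Simulate a study in which one gene (*ACTB*) responds to treatment by 2 Cq
cycles, then fit the stability model:

```python
import refstab as r

params = r.SimulationParams(effect_of={"ACTB": 2.0}, seed=1)
ds = r.simulate_dataset(r.make_study_design(), params)
res = r.ReferenceGeneStability(ds, n_perm=1000, seed=1).fit()

print(res.combined_frame().head(4))
print(f"F = {res.comparison.f_obs:.3f}, p = {res.comparison.p_perm:.4f}")
```

```
      combined_rank    sd  n_settings
gene
B2M           4.946 2.244          35
PPIA          5.133 1.878          35
IPO8          5.231 2.176          35
GUSB          5.357 2.008          35
F = 27.636, p = 0.0010
```

Every gene carries 35 per-setting comprehensive rank values (20 cell-line +
3 organoid + 8 fresh-frozen + 4 FFPE). The destabilized gene lands at the
bottom of the table with a combined rank of 13.65 out of 14, and the omnibus
permutation test is significant at its resolution floor (p = 1/1001 ≈ 0.001
at 1000 permutations). `res.summary()` prints the full ranking plus the
Dunn/Bonferroni pairwise table; `res.to_dir("out/")` writes TSV matrices and
a JSON summary. Genes non-detected in a setting (here *GAPDH*, dropped from
two FFPE settings in this draw) are combined over the settings where they
were measured, shown by `n_settings`.

The same pipeline is available from the shell:

```sh
refstab simulate --seed 1 --out data/
refstab rank --input data/cq_data.csv --out results/
refstab combine --input results/comprehensive_ranks.tsv --out results/
refstab compare --input results/comprehensive_ranks.tsv --seed 1 --out results/
refstab report --input data/cq_data.csv --seed 1 --out results/
```

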