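# lfqdiff

A differential-abundance pipeline for label-free quantitative (LFQ)
proteomics of small two-group clinical cohorts — the kind of study that
compares, say, liver tissue from chemotherapy-treated patients against
untreated controls, with each patient's lysate measured in technical
duplicate.

Such studies share a statistical shape: a protein-by-run intensity matrix
with left-censored missing values (low-abundance proteins drop out), a
handful of patients, technical replicates that must not be mistaken for
independent samples, and two complementary questions — *which proteins
changed?* and *how few proteins suffice to tell the groups apart?*
`lfqdiff` answers both with:

- **Preprocessing** — keep proteins detected in >50% of runs, log2
  transform, and impute missing cells from a *downshifted normal*: for each
  sample with observed mean μ and SD σ, draws from
  N(μ − 1.8σ, (0.3σ)²), mimicking values below the detection limit.
- **Replicate-aware exploration** — average-linkage (UPGMA) clustering with
  technical-pair concordance, PCA with per-pair replicate-shift measurement
  and component subtraction.
- **Moderated permutation testing** — the SAM-style statistic
  `d = Δ / (SE + s0)` with `SE = √(s₁²/n₁ + s₂²/n₂)`, where Δ is the
  treated-minus-control mean log2 difference and the constant `s0`
  (default 0.05) stops minute fold changes with minute variances from being
  called. Technical replicates are averaged into patient values first, and
  the FDR is estimated by permuting group labels over *patients* (default
  5000 draws from the C(15,8) = 6435 distinct assignments):
  `q_i = min(1, E[V_i]/R_i)` with monotone enforcement in |d|. A protein is
  significant when the unmoderated Welch p < 0.05 **and** q < 0.05.
  Fold changes are reported signed: `FC = 2^Δ` for Δ ≥ 0, else `−2^(−Δ)`.
- **RFE–SVM panel selection** — rank all proteins by recursively training a
  linear SVM (cost 100) and eliminating the lowest-|weight| features so the
  survivor count shrinks by 1.414 per round; estimate the error of each
  nested panel by leave-one-patient-out CV (cost 10) with per-fold
  re-ranking and fold-internal z-scoring, and return the smallest panel
  attaining the minimal error.
- **Enrichment** — one-sided Fisher overrepresentation against GMT gene
  sets with BH FDR, a permutation test for interaction enrichment on a
  user-supplied network, and a two-list overlap test — all against the
  background of detected proteins, not the genome.
- **Synthetic data** — a generator that emulates the study design
  (8 + 7 patients × 2 replicates, ~6000 proteins, log-normal intensities,
  correlated replicates, abundance-dependent dropout, planted effects) so
  every stage is testable end to end.

A packaged reference table (`lfqdiff.load_significant_table_fixture()`)
carries the 55 differentially abundant proteins reported for a published
FOLFOX-treated vs control liver cohort, used by the summary and overlap
utilities as a worked example.

## Worked example

```python
import lfqdiff as L

# 1. summarise the packaged reference table
table = L.load_significant_table_fixture()
print(L.summarize_significant(table).to_string(index=False))
```

```
direction  n  median_fc  q1_fc  q3_fc
       up 21        2.4    2.0    3.1
     down 34       -2.4   -3.3   -2.0
```

21 proteins up with median fold change +2.4, 34 down with median −2.4 —
the canonical summary of that cohort's result table.

```python
# 2. a full synthetic run
m, design, truth = L.generate_study(n_proteins=2000, planted_fraction=0.025, seed=1)
filtered = L.filter_by_detection(m)                       # >50% detection
logged   = L.log2_transform(filtered)
imputed  = L.impute_downshifted(logged, L.ImputationParams(seed=1))
fit = L.DifferentialAbundanceModel(
    imputed, design, L.ModeratedTestParams(n_permutations=1000, seed=1)
).fit()
print(fit.summary())
```

```
Differential abundance (s0-moderated Welch, permutation FDR)
==============================================================
proteins tested              1916
patients (treated/control)    8 / 7
s0 constant                  0.05  (mode: additive_constant)
permutations                 1000  (seed 1)
alpha_p / alpha_fdr          0.05 / 0.05
significant proteins           33  (1.7%)
--------------------------------------------------------------
direction  n  median_fc  q1_fc  q3_fc
       up 14        2.3    2.1    2.8
     down 19       -2.6   -2.9   -2.3
```

1916 of 2000 simulated proteins pass the detection filter; 33 are called
significant — 31 of them among the 47 surviving planted effects — with
fold changes near the planted magnitude (2^1.25 ≈ 2.4).

The same pipeline is available from the shell:

```sh
lfqdiff simulate --seed 1 --outdir run/        # write intensity + design TSVs
lfqdiff all --seed 1 --outdir run/             # full pipeline + manifest
lfqdiff report                                 # reference-table summaries
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from
scratch: it prints the reference-table summary and the two-list overlap
test, simulates a full-scale study (6000 proteins, 8 + 7 patients in
duplicate), runs filtering → imputation → exploration → moderated
permutation test → RFE–SVM selection with the default parameters, and
writes the result map as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
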