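# Methods

This note documents the statistical model behind `lfqdiff`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions fixed where the field leaves a
choice.

## Data model and preprocessing

The input is a protein-group × run intensity matrix on a linear scale with
zeros (or NaN) encoding missing values, plus a design table mapping every
run to a patient, a group (`treated`/`control`) and a technical-replicate
index. Technical replicates are repeated measurements of one lysate and are
never treated as independent units anywhere in the pipeline.

Stage order is fixed as **filter → log2 → impute**:

1. **Detection filter.** A protein is retained iff it is observed in
   *strictly* more than `min_fraction` (default 0.5) of runs. The strict
   inequality matters at the boundary: 15 of 30 runs is removed, 16 kept.
2. **log2 transform.** Missing cells stay missing; observed values must be
   positive.
3. **Downshifted-normal imputation.** Missing intensities in LFQ data are
   left-censored — proteins near the detection limit drop out — so missing
   cells in sample *s* are drawn from
   N(μ_s − shift·σ_s, (width·σ_s)²) with defaults shift = 1.8,
   width = 0.3, where μ_s, σ_s are the mean and SD (n−1 convention) of the
   *observed* values of that sample column only; imputed values never feed
   back into μ_s, σ_s, and observed cells are never altered. Per-sample
   statistics are the default because column abundance distributions differ
   between runs; a whole-matrix mode exists behind `per_sample=False`.

Row standardisation for clustering/PCA uses the population (n) convention;
the asymmetry with the sample-level n−1 convention is deliberate and only
matters as a documented, reproducible choice — the source conventions are
not recorded anywhere authoritative.

No between-sample normalisation (median centring, quantile) is applied: LFQ
intensities are assumed already normalised by the upstream quantification.

## Replicate-aware exploration

Samples are clustered with average linkage (UPGMA) on Euclidean distances
between (z-scored) column vectors. A technical pair is *concordant* when
its two runs form a two-leaf cluster — they are each other's first merge —
the most literal reading of "grouped together at the first order of
clustering". PCA treats samples as observations and proteins as variables,
centring but not rescaling the already z-scored protein dimension;
component signs are fixed by forcing the largest-magnitude loading
positive, so reported score shifts are reproducible. The replicate-shift
utility reports per-pair score differences on every component, and
"subtracting component k" zeroes that score column; the intra/inter
distance ratio (mean within-pair distance over mean distance between
patient centroids) before and after quantifies how much of the technical
displacement that component carried.

## Moderated test and permutation FDR

Replicates are first averaged per patient on the log2 scale, so the
patient — the exchangeable unit — is the column of the tested matrix.
For each protein with treated/control means m₁, m₂ and variances s₁², s₂²:

    Δ  = m₁ − m₂
    SE = √(s₁²/n₁ + s₂²/n₂)
    d  = Δ / (SE + s0)                (moderated statistic)
    t  = Δ / SE                       (Welch statistic)

`welch_p` is the two-sided p of *t* with Welch–Satterthwaite degrees of
freedom and is never moderated; `s0` (default 0.05) enters only *d*, the
statistic ranked and permuted for the FDR. This reconciles reporting plain
Welch p-values alongside s0-tuned relevance calls: s0 raises the effective
significance bar for proteins with small fold changes and lowers it for
large ones. In `sd_percentile` mode the constant is instead the given
quantile of the per-protein SE distribution.

The FDR permutes group labels over patients, drawing uniformly **without
replacement** from the C(n, n₁) distinct assignments with the identity
excluded; requesting at least that many runs makes the test exact over all
of them (the default 5000 is a proper subsample of the 6435 assignments of
an 8-vs-7 design). One shared permutation stream is applied to every
protein per run, preserving between-protein correlation under the null.
For protein *i*:

    E[V_i] = (1/B) Σ_b #{ j : |d_bj| ≥ |d_i| }      (mean null exceedance)
    R_i    = #{ j : |d_j| ≥ |d_i| }                 (observed exceedance)
    q_i    = min(1, E[V_i] / R_i)

followed by enforcement that q is non-increasing in |d| (suffix minimum
over the |d|-descending order; ties broken stably by protein id). The mean
(not median) of null counts is used, and no π₀ estimate is applied. A
protein is significant when `welch_p < 0.05` **and** `q < 0.05`. The
per-protein coefficient of variation is SD/mean of the linear-scale
patient values pooled over both groups.

Known behaviour worth stating: with ~15 patients the per-protein
permutation tail cannot go far below ~10⁻³, and when many proteins carry a
real effect, relabelings close to the true grouping contribute real signal
to the null exceedances. Mid-strength effects (≈2.5–3 patient-level SDs)
therefore plateau around q ≈ 0.05–0.3 even when their Welch p is small;
this is a property of small-cohort permutation FDRs, not of the estimator
variant, and BH on the Welch p-values shows the same plateau.

The distinct assignments are materialised explicitly, which is intended
for cohort-scale designs (≲ a few hundred thousand assignments); genomic
designs with huge C(n, n₁) are out of scope.

## RFE–SVM panel selection

Features (proteins) are z-scored and a linear SVM (libsvm `SVC`, dual
tolerance 1e-4, cost 100) is trained on all surviving features; the
lowest-|weight| features are eliminated so the survivor count becomes
`round(n / 1.414)` (round-half-away-from-zero, minimum step one, i.e. the
count roughly halves every two rounds) until one feature remains.
Eliminated features are appended below the survivors — later rounds above
earlier ones, within a round by descending |weight|, ties by protein id —
yielding a total ranking. Because correlated informative features share
weight, RFE may discard one of a redundant pair in late rounds; the
ranking answers "smallest panel", not "all markers".

Generalisation error per panel size is estimated by leave-one-patient-out
CV with cost 10: inside each fold the features are z-scored with
training-fold statistics **and re-ranked by RFE on the training fold
alone**, so the held-out patient never influences selection. The
optimistic variant that reuses the all-data ranking is available behind a
flag purely to demonstrate the leakage (it deflates the error on
label-permuted data) and should not be used for reporting. The minimal
panel is the smallest evaluated size attaining the global minimum error,
taking the top-k of the full-data ranking; with 15 patients the error grid
is multiples of 1/15, so e.g. 20% = 3/15 is exactly representable.

## Enrichment statistics

All tests are one-sided in the enrichment direction and run against the
background of detection-filtered proteins (the "tested universe"), not the
genome — expected overlaps scale with the universe, and a genome background
would overstate enrichment. Overrepresentation per gene set is the
hypergeometric upper tail of the 2×2 table after intersecting set members
with the background, BH-adjusted across sets. Gene symbols join the
intensity matrix to annotations; multi-protein groups keep their
semicolon-joined id and contribute their first symbol. The network test
compares the observed within-query edge count to uniformly drawn node sets
of equal size (`p = (1 + #null ≥ obs)/(1 + n_random)`, so p ≥ 1/(1+B)); a
degree-binned null is available for graphs with skewed degree
distributions. The two-list overlap test is the same hypergeometric tail
on |A∩B| given |A|, |B| and the background size.

## Synthetic generator

The generator states one concrete world: 8 treated + 7 control patients,
2 technical replicates, 6000 proteins. On the log2 scale

    x[i,p,r] = base_i + Δ_i·1[p treated] + u[i,p] + b_i·1[r=2] + ε[i,p,r]

with `base ~ N(25, 2²)` (a typical LFQ dynamic range), patient effect
`u ~ N(0, 0.4²)`, replicate noise `ε ~ N(0, 0.25²)` and an optional
run-order batch direction `b ~ N(0, replicate_batch_sd²)` (default off)
applied to the second replicate. The variance split encodes technical <
biological variability, consistent with published per-protein CVs of
0.4–2.2 on the linear scale. One percent of proteins (configurable) carry
Δ = ±1.25 log2 (|FC| ≈ 2.4, the magnitude scale of real calls). Dropout is
MNAR: cell x is missing with probability `expit(−(x − 21.5))`, giving
≈10% overall missingness concentrated at low abundance — the regime the
downshifted-normal imputation presumes.

What a green test on this world does **not** establish: real LFQ data have
protein-protein correlation (complexes, pathways), heavier-than-normal
tails, peptide-level quantification artefacts and shared-peptide protein
grouping, none of which are simulated. Power statements (e.g. sensitivity
of the permutation FDR at Δ = 1.25) are statements about this world's
variance components; cohorts with tighter biology will do better, noisier
ones worse.

## Numerical conventions and edge cases

- Identical constant groups: d = 0, welch_p = 1 (0/0 treated as "no
  evidence"). Zero SE with nonzero Δ gives p = 0 and, with s0 > 0, a
  finite d.
- Zero-variance rows are an error at z-scoring (they carry no information
  and would divide by zero); samples with fewer than three observed values
  are an error at imputation, named individually.
- All randomness flows through `numpy.random.default_rng(seed)`; the
  pipeline derives every stage seed from one global seed, and rerunning a
  config is file-hash identical.
- Ranking and q-value ties break stably by protein id, making outputs
  invariant to row and column order.
- Fold changes serialise at two decimals (reference-table style); other
  floats at six significant digits; intensity tables round-trip bit-exactly
  via shortest-repr decimals.
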