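# Methods

`setscope` implements two quantitative procedures used to study cell-type-
specific gene expression in the preoptic area (POA) of the hypothalamus: a
gene-set over-representation pipeline for single-cell RNA-seq cell
identities, and a per-cell RNAscope (smFISH) molecule-quantification
scheme. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## The enrichment pipeline

### Model and procedure

The input is a genes × cells UMI count matrix with a fixed identity label
per cell (cluster labels are supplied, never computed here) and a gene set
of interest (here: imprinted genes, each maternally or paternally
expressed). The question is whether the set is over-represented among the
genes upregulated in any one identity group.

1. **Normalization.** Each cell's counts are scaled to a common total
   (default: the median cell total) and log(1 + x)-transformed. The scale
   target and log base (e or 2) are configurable because public datasets
   come with their own published normalizations; on a given dataset the
   upregulation *counts* are robust to this choice but exact q-values are
   not.
2. **Detection filter.** Genes detected (non-zero) in fewer than
   `min_cells = 20` cells across the dataset are dropped. The filtered
   gene list is the *universe* for every later step — eligibility and the
   Fisher margins are relative to it, not to the genome.
3. **Upregulation screen.** For each gene and each identity group, a
   one-sided Wilcoxon rank-sum test asks whether expression in the group
   is greater than in all remaining cells. Midranks handle ties; see
   "Numerical choices" for the exact/approximate split.
4. **Horizontal BH.** The p-value matrix (genes × identities) is corrected
   with a Benjamini–Hochberg step-up whose family is, by default, the
   *row*: each gene's p-values across identity groups. The term
   "horizontal" is exactly this row-wise family. Because the choice of
   family is a genuine modelling decision, `bh_family` also accepts
   `per_group` (column-wise) and `global`.
5. **Calls.** A gene is upregulated in a group iff q ≤ 0.05 (inclusive)
   and log2 fold change > 1 (strict). Fold change is
   (mean_in + ε)/(mean_out + ε) on normalized values with ε = 1e-9
   guarding genes silent outside the group.
6. **Gated ORA.** Per group, the 2×2 table (set × upregulated) is tested
   with a one-sided Fisher exact test, i.e. the hypergeometric upper tail
   P[X ≥ a]. A group enters the test only if at least 5% of the
   dataset-intersected set is upregulated in it (exact real comparison,
   no rounding: with 74 set genes the floor is 3.7, so 4 qualifies).
   Bonferroni correction multiplies by the number of *eligible* groups
   only; ineligible groups keep their raw Fisher p and an empty corrected
   p. The mean linear fold change of set genes versus all other
   filter-passing genes is reported per group as a descriptive contrast
   (a switch restricts it to upregulated genes).

Top hits are ordered by Fisher p with ties broken by larger overlap `a`,
then identity name, so output order is deterministic.

### Numerical choices

- Rank-sum p-values: exact enumeration of all label assignments when the
  combined sample size is ≤ 12 (the permutation p-value counts the
  observed assignment, so it is never 0 and all-tied data gives exactly
  1). Above that, a normal approximation with tie-corrected variance and
  a 0.5 continuity correction. At single-cell sample sizes (hundreds to
  thousands of cells per comparison) only the approximation branch runs.
- Midranks are computed once per gene over all cells and reused for every
  identity group, making the full screen one ranking pass plus per-group
  rank sums.
- BH q-values are clipped at 1; p-values must lie in (0, 1] and the
  hypergeometric tail is clamped away from exact 0 (float underflow) to
  honour the declared codomain.
- Degenerate inputs fail loudly: zero-total cells are named in the error,
  a filter that removes every gene raises, an upregulated gene outside
  the universe raises, and a gene set disjoint from the universe is a
  logged warning with a degenerate (a = b = 0) table.
- Gene-symbol matching between set and dataset is case-insensitive exact
  match with an optional user-supplied mapping hook (symbol → dataset
  identifier); unmatched set genes are reported, not fatal, since a probe
  may simply not have been sequenced in a given dataset.

## The RNAscope quantification scheme

### From objects to molecules

The pipeline consumes per-cell *object tables* (cell id, channel,
integral intensity of each detected fluorescent object) produced by the
microscope software, plus a *no-probe-control* table of per-cell maximum
intensities from an adjacent section processed without probes. Pixel-level
processing (segmentation, the 25 µm cytoplasm ring, background rolling
ball) happens upstream and is out of scope.

- **Threshold.** Per channel, threshold = mean + 3·SD of the control
  cells' maximum intensities. The control cells are a sample of the
  background process, so the SD uses the n−1 denominator; at least two
  control cells are required.
- **Cluster resolution.** Each above-threshold object's molecule count is
  round((integral − background) / single-signal mean intensity) with
  round-half-up, clamped to ≥ 1 — an object that passed the detection
  threshold represents at least one molecule. No rounding rule is imposed
  by the source protocol; half-up is this package's choice and is
  documented in the function contract. The single-signal mean intensity
  and average background are *supplied* calibration values (they depend
  on acquisition settings); a helper estimates the single-signal
  intensity as the median of the lower half of the object-intensity
  distribution, but it is never applied silently.
- **Counts.** Per cell and channel, molecule counts are the sum of
  resolved objects; cells with no objects count 0 (a full cell roster can
  be supplied so silent cells are retained).

### Summaries

- **Positivity.** A cell is positive for a channel iff its count meets
  the channel's minimum-molecule rule (defaults used throughout the
  tests: Gal 2+, Calcr 2+, c-Fos 5+; Magel2 "expressing" defaults to 1+
  and is configurable because no published cut exists). Composite classes
  (e.g. Gal+/Calcr+) are conjunctions and non-exclusive.
- **Per-1000 normalization.** Positive-cell counts are rescaled to a rate
  per 1000 cells in the region, making sections and animals comparable.
- **H-score.** The percentage of cells with 0 molecules is weighted 0,
  1–3 weighted 1, 4–9 weighted 2, 10–15 weighted 3, 16+ weighted 4;
  the score is the weighted sum, in [0, 400]. It is linear under mixing
  of populations, which the tests exploit.
- **Aggregation.** The animal is the experimental unit: summaries pool a
  given animal's sections before any cross-animal statistic. (Whether to
  pool per section instead is not settled by the source protocol; pooled
  per animal is the default here.)
- **Group contrasts.** Mann-Whitney/Wilcoxon rank-sum (exact enumeration
  up to 12 combined observations, tie-corrected normal approximation with
  continuity correction above — per-cell comparisons involve thousands of
  cells, firmly the approximation regime), Kruskal-Wallis with the tie
  correction divisor 1 − Σ(t³−t)/(N³−N) and a χ² reference with k−1 df,
  and two-sided Dunn post-hoc z-tests Bonferroni-corrected over all
  pairs.

## Synthetic data

`simulate_counts` draws gene baseline means from a log-normal
(defaults μ = −1.0, σ = 1.0 on the natural-log scale) and counts from a
negative binomial parameterized by (mean, dispersion) with variance
mean + mean²/dispersion (default dispersion 2.0) — the standard
UMI-regime noise model. The default *alternative* plants 20 of a 74-gene
set at fold 4 in one of 10 identities of 200 cells each, with 1000 genes
total; `planted_identity=None` gives the matched null. One integer seed
drives a single generator; identical seeds give bit-identical output.

`simulate_spots` draws cells from labelled types with per-channel Poisson
molecule means. The default census echoes a POA-like composition: a small
Gal/Calcr population with high Magel2 (mean 5.8), Gal-only and Calcr-only
populations (Magel2 means 3.0 / 3.3), and a large background population
(Magel2 mean 1.5). Molecules emit as single objects with Gaussian
intensity (mean 300, SD 30 a.u.) over a background offset (20 a.u.), or —
with probability `cluster_prob` — merge into one cluster whose intensity
is the sum of its member singles. Control maxima are folded-Gaussian
noise (SD 10 a.u.) over background, so the derived thresholds sit far
below single-molecule intensity.

**What the synthetic data does not capture:** real tissue's segmentation
errors, optical crowding and partial-volume effects, spatial correlation
between neighbouring cells, per-section intensity drift, library-size and
cell-type-specific capture-efficiency variation in scRNA-seq, and
correlated gene modules. Passing tests therefore demonstrate correctness
of the *computations* under the stated generative assumptions, not
fidelity of any biological estimate on real tissue. In-vivo percentages
reported from real images (e.g. Magel2 positivity rates or c-Fos
reductions) are not reproducible from code and are exercised only as
synthetic scenarios with matching structure.

## Problem sizes used in tests and the acceptance script

Chosen as the package's own desk-scale defaults: null calibration runs
200 simulations at 800 genes × 10 identities × 60 cells (the acceptance
script uses 60 such runs); planted-signal recovery runs 100 (script: 40)
simulations at the default alternative; the noise-free RNAscope recovery
uses 500 cells. The full-dataset benchmark (GEO accession GSE113576 with
the original authors' cluster labels, 15/74 and 9/74 upregulated set
genes in the two reported neuron subpopulations) requires downloading the
public dataset and staging it under `data/GSE113576/`; the corresponding
test fails with an explanatory message when the files are absent.

## Known limitations

- The rank-sum normal approximation is anti-conservative for very small
  groups with heavy zero-inflation; the 20-cell filter and the group
  sizes of real datasets keep the screen away from that regime.
- The "horizontal" BH family is a modelling commitment; swapping the
  family changes q-values and hence upregulation counts.
- Eligibility gating means the Bonferroni family size is data-dependent;
  p-values across configurations with different eligible-group counts are
  not directly comparable.
- Cluster resolution assumes cluster intensity is additive in member
  molecules; optical saturation in dense clusters would bias counts low.
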