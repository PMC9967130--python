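# Methods

`ionframe` implements an MS1 ion-current label-free quantification (LFQ)
workflow for DDA proteomics cohorts — the strategy in which every peptide
precursor identified anywhere in a cohort is quantified in *every* run by
integrating MS1 ion current inside a fixed m/z–retention-time window on a
common, aligned timescale.  Because extraction does not depend on a run
having its own MS2 identification, the protein-level output has no
structural missingness, which is the property that motivates the design.
Downstream, the package implements the differential-abundance gating,
six-pattern metastasis classification, median-split survival screen and
over-representation statistics used in comparative exosome-proteomics
studies of tumor cell-line panels.

## Pipeline model and assumptions

**Input contract.** Centroided MS1 peak lists plus MS2 precursor events per
run (mzML or a documented TSV dialect), and a *pre-filtered* PSM table
(peptide-spectrum matches surviving upstream search, FDR control, and
protein grouping, with a uniqueness flag).  Identification quality control
is upstream of this package; the table is trusted as given.

**Retention-time alignment** (`align`).  Each run's base-peak chromatogram
(BPC; per-scan maximum peak intensity) is binned at 5 s and log-compressed;
a banded dynamic-time-warping (DTW) path against the reference run's BPC,
constrained to a Sakoe–Chiba band of ±120 s, is condensed into anchors
every 60 s (per-segment medians, then a running-median smoothing of anchor
shifts over five segments, which suppresses isolated path excursions where
the chromatogram is locally flat).  The warp is the monotone
piecewise-linear interpolant through those anchors, extended to the full RT
domain by edge-slope extrapolation; out-of-domain RTs clamp with a warning.
The alignment *score* of a pair is the Pearson correlation of the warped,
binned, log-compressed BPCs (bounded in [−1, 1]).  The reference run
maximizes the sum of two ranks: mean pairwise alignment score (compared at
0.01 resolution, so near-identical alignments tie) and total BPC intensity;
remaining ties break to the lexicographically smallest run id.  BPC-based
DTW is a declared substitute for proprietary full-ion-map alignment; on
simulated cohorts it recovers injected linear drifts (slope 1.02, offset
10 s) to within ~4 s over the central 80 % of a 20-minute gradient.

**Frame extraction** (`frames`).  MS2 events of the same peptide+charge are
merged by single linkage when precursor m/z agrees within 10 ppm and
aligned RT within 60 s (both windows closed; the defaults are the
conventional 10 ppm / 1 min extraction window).  Each merged target gets an
intensity-weighted mean m/z center and median RT center.  For every target
and every run, the trace is the most intense peak within ±10 ppm per MS1
scan inside the ±30 s window (robust to neighboring isotopes); the area is
the trapezoidal integral of that trace over RT.  A window holding a single
scan integrates as intensity × median MS1 cycle time; an empty window
yields area 0.  Charge states are separate targets and are summed at
peptide roll-up.  Extraction is linear in intensity and invariant to peak
order within scans.

**Normalization** (`quant.normalize`).  Median-of-log-ratios against the
frame-wise geometric-mean run, using only frames observed (> 0) in every
run; factors are recentred to geometric mean 1 and divide each run's
areas.  The procedure is idempotent and scale-equivariant, and recovers
injected per-run biases in [0.5, 2] with Pearson r > 0.99 at measurement
CV 0.10.

**Peptide outlier removal** (`quant.detect_peptide_outliers`).  Within one
protein's peptide × sample matrix of log2 normalized areas, rows are
centred (only profile shape matters) and the first principal component is
taken as the consensus profile, oriented so the median peptide projection
is positive.  Each peptide's residual is the distance to its PC1 fit with
negative projections clamped to zero — for concordant peptides this is the
ordinary orthogonal residual, while an anti-correlated peptide scores its
full profile norm instead of hiding inside the PC1 subspace.  Peptides are
flagged when the residual exceeds median + 3 × MAD (MAD scaled by 1.4826
for normal consistency).  Guards: proteins with two peptides are never
flagged, and at least two peptides always survive.  Measured operating
characteristics at defaults: ≥ 95 % recall of injected anti-correlated
peptides among five concordant ones, ≤ 5 % false flags on clean proteins.

**Protein roll-up** (`quant.aggregate_protein`).  Sum of surviving unique
peptides (sum preserves the linearity of extraction); proteins with fewer
than two surviving unique peptides are dropped, mirroring the two-unique-
peptide identification contract.  Remaining zero cells are floored to half
the smallest positive value of the matrix so every cell is positive and all
ratios are computable; on noise-free simulations the resulting ratios equal
the planted fold changes to 1e−9 relative.

## Differential gating and classification

One-way fixed-effects ANOVA is computed on log2 abundances across all five
groups (log2 because multiplicative measurement noise is approximately
log-normal; the scale is a declared choice).  Ratios are quotients of
arithmetic group means on the linear scale (geometric option available).
A protein is **altered** when ANOVA p < 0.05 *and* at least one
tumor/control ratio is > 1.5 or < 0.67 (strict inequalities; all four
thresholds configurable).  **Metastasis-specific** proteins are altered
proteins whose metastatic/non-metastatic ratio passes the same gate in at
least one of the three metastatic comparisons.  No multiple-testing
correction is applied by default (the ratio gate provides the specificity;
a Benjamini–Hochberg option exists).  Under the global null the altered
fraction is bounded by the p-threshold; on planted cohorts (below) the
screen reaches sensitivity ≥ 0.99 at false-discovery proportion ≈ 0.08.

**Six-pattern classification** (`patterns`).  The four tumor-group means
(non-metastatic NM, primary P, kidney K, lung L) are standardized per
protein (sample sd, ddof = 1; constant profiles become all-zero with a
warning).  Labels come from an explicit margin cascade (δ = 0.5 by
default): NM dominant → NON_METASTATIC; all of P, K, L clear NM →
METASTATIC; P dominant → PRIMARY_SITE; K and L jointly clear NM and P →
KIDNEY_LUNG; K dominant → KIDNEY; L dominant → LUNG; otherwise the argmax
group's label with the fixed tie order NM → P → K → L.  The cascade
partitions any input, is invariant to constant shifts of the z-vector, and
is deterministic — average-linkage hierarchical clustering on 1 − Pearson
distance is retained for ordering/visualization (Newick export), not for
the labels.  NON_METASTATIC proteins are excluded from the final
metastasis-specific list by pure set arithmetic.

## Survival screen and enrichment

For each marker gene the cohort is split at the median expression (ties to
the low arm, making the split deterministic — the convention of public
median-cutoff survival portals).  The two-arm log-rank test (1 df) is
computed from the observed/expected event table; the hazard direction is
sign(O − E) in the high-expression arm.  Raw p-values are reported with a
significant (p < 0.05) and a suggestive (0.05 ≤ p < 0.1) tier; no
correction for screening many genes by default.  The Kaplan–Meier
estimator backs the curves.  The implementation is verified bit-identical
to lifelines on shared inputs and its empirical type-I error at n = 200 is
4.8 % (8000 null cohorts).  A gene is *concordant* when the sign of the
log of its most extreme metastatic/non-metastatic ratio equals its hazard
direction.

Over-representation uses the one-sided Fisher exact test (hypergeometric
upper tail of the 2×2 table) with BH adjustment across sets.  The
background universe defaults to all quantified proteins — the standard
choice when the query derives from the quantified fraction, not the
genome.

## The synthetic cohort generator

`synthdata` emulates a five-group, four-replicate exosome LC–MS study (a
non-tumorigenic control plus non-metastatic, primary-site, kidney- and
lung-metastasis tumor lines): peptide base intensities log-normal
(mean 20, sd 1.5 on the ln scale, spanning ~6 orders of magnitude);
Gaussian elution peaks (σ = 6 s) sampled on a 2 s MS1 cycle over a 1200 s
gradient, so a whole peak fits the 1-minute extraction window; per-run
linear RT drift (offset up to ±60 s, slope 1 ± 0.02); per-run global
intensity bias log-uniform in [0.5, 2]; Bernoulli MS2 sampling per
precursor-run pair (default rate 0.7), so some runs lack identifications;
one multiplicative log-normal noise factor per peptide-run measurement
(default CV 0.15, bracketing the 13–18 % intra-group CVs typical of
replicate cell-culture cohorts); and a configurable fraction of *outlier*
peptides (default 1 %) whose group profile is decoupled from their
protein's.  MS2 events sit at the peak apex of the sampled run, which
makes frame centers deterministic.  Everything planted is recorded in a
`GroundTruth` object, including the exact altered / metastasis-specific
sets implied by the fold-change specification.

What the generator does **not** emulate: isotope envelopes, charge-state
coelution, chimeric spectra, m/z measurement error (peptide m/z is exact
across runs), nonlinear RT distortion, interference between co-eluting
peptides of similar mass, or biological covariance between proteins.
Passing tests therefore demonstrate correct recovery of the planted
effects under idealized peak shapes and mass accuracy — they bound
algorithmic correctness, not performance on real instrument data.

Survival cohorts use exponential event times with rate
λ₀·exp(effect · z) for standard-normal expression z, λ₀ fixed by a
60-month baseline median; censoring is uniform over a follow-up horizon
solved (Brent) so the expected censored fraction equals the requested
rate.

## Reference experiment sizes

The validation experiments (driven by `ionframe.experiments`, the test
suite and `scripts/acceptance.py`) use: 50 independent cohorts of 200
proteins × 5 peptides with 20 planted proteins at |log2 FC| ∈ [1, 2] for
the altered-screen recovery; 1000 null proteins for ANOVA calibration;
1000–3000 null survival cohorts of n = 200 for log-rank calibration; and
single cohorts for bias/drift recovery.  These sizes give sub-percent
Monte-Carlo error on the reported rates while keeping a full validation
run to a few minutes on one core.

## Numerical choices and degenerate inputs

* Strict inequalities at every gate (p, ratio, margin); boundary values do
  not pass.
* ANOVA on a protein with zero variance everywhere returns p = 1 (not
  NaN); p-values are clipped into (0, 1].
* Empty extraction windows give area 0 and apex NaN; areas are never
  missing, by construction.
* A run with no positive frame areas is a named normalization error; a
  frame set with no row observed in every run is an error.
* Warp monotonicity is enforced at construction; degenerate anchor sets
  fall back to the identity map.
* Constant z-profiles classify through the argmax fallback after an
  all-zero standardization (warned).
* All RTs are seconds, m/z in Thomson, sample ids strings, groups referenced
  by label.

## Known limitations

* BPC-based DTW can lose accuracy in the first/last ~10 % of the gradient
  where the chromatogram carries little signal; accuracy claims are made
  for the central 80 %.
* The PC-consensus outlier rule assumes one dominant peptide consensus per
  protein; proteoform mixtures with two legitimate profiles would be
  mis-flagged.
* Median-split survival screening discards dose-response information; no
  proportional-hazards model is provided.
* The mzML reader covers the centroided, single-run layout this pipeline
  consumes (64/32-bit float arrays, zlib or none); exotic mzML variants
  should be converted to the TSV dialect.
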