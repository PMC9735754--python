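# Methods

## Measurement model

Feulgen staining binds stoichiometrically to nuclear DNA, so the transmitted
intensity `I` at a pixel relates to the incident background intensity `I0`
by Beer–Lambert absorbance. We use the densitometric convention of base-10
optical density, `OD = log10(I0 / I)`, and define the integrated optical
density of a nucleus as the sum of OD over its (operator-supplied) mask.
IOD is then proportional to DNA amount. Two consequences are load-bearing
and tested as invariants: IOD is unchanged when all intensities and the
background are multiplied by the same constant (illumination does not
matter), and IOD is additive over disjoint masks. Pixels brighter than the
background (glare) are clamped to OD 0 and counted as saturation warnings
rather than failing the specimen; segmentation is out of scope — masks are
inputs, as cells are operator-designated in manual DNA-ICM practice.

## Normalization and QC

Absolute IOD units are arbitrary, so every specimen carries internal
reference cells (cytologically normal epithelial cells or lymphocytes) whose
mean IOD defines the diploid point: `c = 2 · IOD / mean(IOD_ref)`. The QC
report flags — but does not veto — specimens with fewer than 30 reference
cells, a reference coefficient of variation of 5% or more, or fewer than 300
analysis cells. Classification under a QC flag is still computed because
low-cellularity specimens occur in practice and a flagged verdict is more
useful than none; the flag is the caveat.

## Stemline detection

A DNA stemline is the modal c-value of a G0/G1 subpopulation. The detector:

1. evaluates a Gaussian kernel density estimate over the analysis cells'
   c-values on a 0.01c grid, with a fixed bandwidth of 0.1c (comparable to
   the measurement spread of a diploid peak at ~3% CV; a fixed — not
   data-driven — bandwidth keeps the mode positions stable across specimens);
2. takes local maxima with topographic prominence of at least 0.4× the
   height of a minimal admissible stemline (`min_stemline_fraction` of cells
   concentrated at a point), discarding grid-level wiggles;
3. attributes to each candidate the cells within 2.5 bandwidths of its
   position (a stemline is a narrow modal subpopulation);
4. estimates the local continuum under the candidate from flanking bands of
   equal combined width (2.5–5 bandwidths on each side) — this is where the
   S-phase plateau and scattered cells live — and keeps the candidate only
   if the cells in excess of that continuum reach both
   `min_stemline_fraction` (default 5%) of the analysis cells and
   `min_stemline_cells` (default 5). The background correction matters: with
   a realistic scattered/S-phase background, chance clusters of ~20 cells in
   a half-c window otherwise pass a raw 5% gate and would misclassify a few
   percent of euploid specimens;
5. refines each kept mode on its attributed cells (fine local grid plus the
   cell values themselves, so a cluster of identical cells yields its exact
   value), orders stemlines by cell count (ties: lower c first), and
   annotates any stemline lying within 10% (relative) of twice the position
   of a larger stemline as that line's G2/M doubling peak.

The histogram module (uniform half-open bins from 0) is for display;
detection never touches bins, avoiding bin-edge artifacts.

## Classification

ESACP-style aneuploidy, with strict boundary semantics ("deviates more than
10%" — a mode exactly at 2.2c is euploid):

- **stemline aneuploidy** — some stemline mode lies strictly outside both
  [1.8, 2.2]c and [3.6, 4.4]c, and is not the doubling peak of a stemline
  already judged euploid (an 8c peak over a euploid 4c line is G2/M, not an
  aneuploid stemline — the euploid–polyploid pattern). Membership of the 4c
  interval is euploid regardless of whether a 2c population exists: the rule
  is interval-based. The doubling peak of an *aneuploid* stemline adds
  nothing — its primary line already triggers.
- **single-cell aneuploidy** — at least one analysis cell above 9c (strict).
  Cells above 5c are counted and reported but never a reason by themselves.

The verdict is aneuploid iff at least one reason holds. Two properties are
enforced by tests: the whole result is invariant under rescaling all IODs,
and adding a >9c cell can never turn an aneuploid verdict non-aneuploid.

## Synthetic data

The generator emulates what the analysis assumes, not microscopy: reference
cells at 2c with a chosen CV; analysis cells as a mixture per stemline of a
G0/G1 point mass, a G2/M point mass at twice the position, and an S-phase
plateau uniform between them; an exact count of rare events uniform on
(9c, 12c]; and any fraction remainder as scattered background uniform on
[1.5c, 5.0c) — kept below 9c so the generator's truth label stays derivable
from its parameters by the classification rules. Noise is multiplicative
Gaussian (sd = CV × mean) truncated at zero, the standard densitometric
error model; cell-count allocation is largest-remainder, so component counts
are exact and zero-noise cases are bit-exact. Every stochastic operation
takes an explicit seed; equal specs generate identical specimens. Defaults
mirror the study conditions: 300 analysis cells, ≥30 reference cells,
measurement and reference CV 3% (the study required reference CV < 5%).

Not emulated: staining chemistry, cell overlap, debris, inflammation-related
cell loss, or the true shape of S-phase. Passing tests therefore show the
*decision logic* is right under the stated statistical structure, not that
real slides are this clean — on real material, overlapping nuclei and low
cellularity are the dominant error sources.

The nucleus-image generator renders a uniform disc whose per-pixel OD is
`c · K / area` with calibration constant K = 50 IOD units per c-unit, so the
image-to-IOD-to-c round trip is exact at zero noise and linear by
construction.

## Study cohort fixture

The packaged 602-case cohort is a **synthetic reconstruction** from the
study's printed grouped counts (cytology category × ploidy verdict margins;
dichotomized confusion totals for both tests), not deposited data. The
within-category follow-up split is not printed; the fixture documents its
allocation inline, and any allocation consistent with the margins yields
identical dichotomized metrics, AUCs and conditional OR. The file carries
its expected total and a SHA-256 of the canonicalized counts; `reproduce-study`
refuses a tampered fixture with an expected-vs-found report. The published
criteria-by-outcome table is internally inconsistent on the malignant side
(its criteria counts imply 306 aneuploid malignant cases against 288 true
positives elsewhere), so the report emits only the derivable verdict-by-outcome
cross-tabulation plus the benign-side criteria split, which is consistent.

## Diagnostics

Proportion CIs are exact Clopper–Pearson (beta quantiles). The choice is
forced by the degenerate proportions in the data: 308/308 sensitivity has a
meaningful exact lower bound (98.8%) where a Wald interval is void. A
dichotomous test has one ROC operating point; its AUC is the area of the
polygon through (0,0), (1−Sp, Se), (1,1), i.e. `(Se+Sp)/2`, identical to the
empirical rank AUC of the binary scores (tested against an independent
implementation). Its CI uses the Hanley–McNeil standard error. Two tests on
the same cases are compared with a DeLong-type chi-square on paired placement
values; for binary scores the method's exact printed statistic depends on
software conventions, so the package asserts direction and significance, not
a particular chi-square value.

## Regression

Grouped binomial logistic regression is fit by Newton/IRLS written in this
package (convergence at max coefficient change < 1e-8, cap 100 iterations;
deviance is verified non-increasing). The study design contains structural
zeros (no cytology-negative case with positive follow-up), which makes the
cytology coefficient's likelihood monotone: the fitter detects separation —
a coefficient past 15 on the log-odds scale while the deviance still falls —
stops there, and reports the affected coefficients as unbounded with a note,
never as finite numbers. Identifiable coefficients (the ploidy term) are
reported with Wald CIs and agree with the closed-form conditional odds
ratio, `OR = (a/b)/(c/d)` with `exp(log OR ± z·sqrt(1/a+1/b+1/c+1/d))`. A
zero cell makes the conditional OR undefined unless the Haldane–Anscombe
+0.5 correction is explicitly requested. A Firth (Jeffreys-penalized) fit is
available as a clearly labelled alternative for separated designs; it is a
different estimand and is never silently substituted.

## Numerical and testing choices

Display rounding is half-up at the precision of printed clinical tables (one
decimal for percentages, two for AUCs and OR bounds); internal values are
never rounded. Tests include loop-based re-implementations of stemline
classification (mode enumeration on small specimens) and odds ratios as
independent oracles, plus statsmodels GLM and scikit-learn rank-AUC as
external cross-checks. Simulation-based properties run at the study's scale:
200 generated specimens of 300 cells at 3% CV for classification recovery
(≥99% required), 100 replicates of n = 2000 grouped binomial draws for
coefficient recovery (within 3 SE in ≥95%). The full suite runs in well
under a minute on one CPU.

## Known limitations

- Stemline positions are KDE modes; systems that fit cell-cycle models
  (G1/S/G2 decomposition) may report slightly different modal values for
  skewed peaks.
- Stemlines broadened far beyond the kernel width (high c positions at
  higher measurement CV) need proportionally more cells to clear the
  background-corrected gate; at 3% CV this matters only above ~7c for
  minimal (5%) subpopulations.
- The 2.5-bandwidth attribution window can split extremely close stemline
  pairs (< 0.3c apart) or merge them into one mode, as any fixed-bandwidth
  method does.
- The binary-test AUC comparison is one defensible correlated test, not a
  reproduction of any particular software's statistic.
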