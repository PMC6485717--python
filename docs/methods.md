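# Methods

`peakcv` implements a label-free serum profiling classifier for direct-infusion
ESI mass spectra compared between two subject groups, together with the
statistics used to judge it and a synthetic-cohort generator used to test it.

## Spectral processing

Centroided spectra acquired over m/Z 400–2000 (~0.02 m/Z sampling) are
collapsed onto the integer m/Z grid: each point's intensity is added to the
bin at round(m/Z). Rounding is half-away-from-zero, fixed for
reproducibility; banker's rounding would silently move half the *.5 points.
Bins that round outside [400, 2000] are dropped; total intensity of retained
points is conserved.

Each binned spectrum is then scaled by its 10-m/Z segment sums: the grid is
split into 160 consecutive segments [400,410), …, [1990,2000] (the last
segment absorbs the closing grid point) and every intensity is divided by the
**maximum** segment sum, so the largest segment sums to exactly 1 afterwards.
This is a single global scalar per acquisition — it removes per-acquisition
intensity drift while preserving relative peak structure — and it makes
normalization idempotent and scale-invariant. A per-segment variant (each
segment divided by its own sum) is available behind `mode="per-segment"` for
users who want within-segment shape only; the global scalar is the default
because one reference amount per spectrum is the standard reading of
"scaled to the highest segment sum".

Replicate acquisitions (triplicates by default) are normalized first and
averaged second, giving each acquisition equal weight regardless of its raw
intensity; averaging first would weight replicates by their injection
efficiency, which is exactly what normalization is meant to cancel.

## Peak selection and LOOCV scoring

For a binary cohort, every integer m/Z is tested with a two-sample
unequal-variance (Welch) t-test on the per-sample mean areas,
Welch–Satterthwaite degrees of freedom, one-tailed with the tail taken in the
direction of the observed mean difference — operationally, half the
two-tailed p whenever the means differ. Peaks with p < α (default 0.05)
become rules; peaks with equal means or zero pooled variability are excluded
rather than assigned. A pooled-variance Student test is available via
`LoocvConfig(pooled=True)`.

Each selected peak carries a Peak Classification Value (PCV): the midpoint of
the two group mean areas. A sample's area strictly above the PCV classifies
to the higher-mean group; at or below (ties included) to the lower-mean
group.

Leave-one-sample-out cross-validation is strict: for every left-out sample,
peak selection *and* PCVs are recomputed on the remaining samples, and the
left-out sample's score is the percentage of rules assigning it to the
designated target group (so target % + other % = 100 by construction).
Scores are computed as 100·k/n with integer k to keep the arithmetic
identical to naive counting.

## Group-level statistics and their calibration

The two groups' per-sample scores are compared with the same one-tailed Welch
convention (`group_discrimination_p`). **This p-value is anti-conservative
under the global null and should be read jointly with the randomization
test.** Two effects stack:

1. Taking the one-tailed direction from the data doubles the nominal level
   (a peak, or the score contrast, is "significant at α" whenever its
   two-tailed p < 2α). The per-peak null selection rate is therefore ≈ 2α
   (~0.09 measured at α = 0.05), a property the test suite asserts.
2. Per-sample LOOCV scores are not independent: all samples are scored
   against rule sets built from almost the same cohort, and same-group
   samples share the rules that overfit their group's chance differences.
   Measured on null cohorts, within-group score covariance exceeds
   between-group covariance several-fold, and the group t-test rejects at
   ~0.3–0.4 when the nominal level is 0.05 — an inflation intrinsic to
   t-testing cross-validated scores, present even with plain i.i.d. data and
   no normalization.

The calibrated inference is the **label-randomization test**: group labels
are permuted uniformly over size-preserving assignments (optionally
stratified within age bins to preserve the cohort's group/age composition)
and the *identical* LOOCV + group-p analysis is rerun. Under the null the
true-label and randomized-label p-values are exchangeable — a property the
suite verifies — so a true-label p far below the randomized ones is evidence
of real structure rather than over-fitting, while the randomized p itself
lands below 0.05 in roughly a third of null runs and should not be expected
to behave like a uniform p-value.

## Diagnostic metrics

The score cutoff is placed k standard deviations from each group's score
mean (k = 2.28 by default): candidate_high = mean_target − k·SD_target,
candidate_low = mean_other + k·SD_other, drawn as the single line at their
midpoint (the two candidates nearly coincide for well-separated groups; no
published combination rule exists, so the midpoint is this package's
choice). Target samples strictly above the cutoff are true positives;
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).

Cohen's d uses the (n−1)-weighted pooled SD; power uses the noncentral t
exactly, with noncentrality d·√(n₁n₂/(n₁+n₂)) on n₁+n₂−2 df (far-tail NaNs
from scipy's noncentral t at extreme noncentrality are treated as zero
mass). Covariate association is the R² of the OLS line of score on
covariate.

## Blinded validation

`hold_out` splits a cohort into disjoint training and blinded sets (named
ids, or a seeded random draw per group). The trained model consists of the
rules selected on *all* training samples (one fixed rule set, not
per-iteration rules), the training cohort's own LOOCV score distributions,
and the SD-based cutoff derived from them. Blind samples are scored against
those frozen rules; predicted target iff score > cutoff. An explicit cutoff
override exists because published analyses sometimes draw bespoke cutoff
lines that no k·SD rule reproduces.

## Synthetic cohorts

The generator emulates the study design: two groups (defaults 21 vs 20
subjects, the scale of the main comparison), triplicate spectra on the
400–2000 grid, log-normal peak areas. Per m/Z, a baseline log-area is drawn
once (N(4, 1)); each subject adds N(0, σ) noise (σ = 0.5, ≈ 53% between-
subject CV); a configurable subset of peaks (default 200) is shifted by
Δ·σ in group B only (Δ = 1.5 default), keeping truth bookkeeping
unambiguous. Two features mimic the physics of direct-infusion serum
spectra and matter for realism:

- a per-acquisition global intensity factor (log-SD 0.3) — instrument
  response drift, the very thing segment normalization removes;
- a dominant high-abundance envelope (12 contiguous bins, e⁴ ≈ 55× larger,
  between-subject log-SD 0.1) standing in for the albumin/immunoglobulin
  charge-state envelope, which pins the maximum segment so the normalizer is
  a stable reference. Without such an envelope the max-segment estimate
  itself becomes the dominant noise source and normalization *adds* coherent
  per-sample score noise.

With these defaults the normalized per-sample score SDs land near 3–4
percentage points, comparable to the published score spreads, and at
Δ ≥ 1.5 with n ≥ 15/group the pipeline recovers sensitivity = specificity
= 1 in ≥ 90% of seeds. Replicate noise is multiplicative
(1 + 0.1·N(0,1), truncated at zero); ages are uniform on 22–62 years and
carried as a covariate. Everything is deterministic given the seed.

What the generator does **not** emulate: chemical noise and baseline drift,
isotope envelopes and charge-state correlation between bins, peak-area
correlation structure across m/Z (areas are independent given the sample
factors), bidirectional disease effects (all planted shifts point the same
way), and non-log-normal heavy tails. Passing recovery tests therefore
shows the pipeline's statistical machinery works under a faithful abstract
model of the platform, not that real sera of any particular pathology are
separable.

## Problem sizes used by the test suite and acceptance script

The suite checks oracle equivalence on 8×8×50 cohorts over 100 seeds, null
calibration on 400 full-grid cohorts at the study scale, and parameter
recovery on 100 cohorts of 15 vs 15; the acceptance script runs one full
21 vs 20 synthetic study (LOOCV, metrics, randomization, 5+5 blinded
hold-out) plus a 100-seed null calibration at 10 vs 10. These sizes keep a
full run in the minutes range on one core while leaving Monte-Carlo error
well below the asserted tolerances.

## Known limitations

- The one-tailed-by-observed-direction convention, kept for fidelity to the
  original procedure, makes per-peak selection operate at 2α and contributes
  to the anti-conservative group p discussed above; users wanting nominal
  calibration should set `two_tailed=True` and rely on the randomization
  test for inference.
- No multiple-testing correction is applied across peaks or across binary
  comparisons, by design.
- Vendor .raw files are not parsed; inputs are delimited exports or mzML.
- Multi-class (>2 group) comparisons are out of scope.
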