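# Methods

## Scope and data model

`phenopop` quantifies the split of an isogenic yeast culture into
growth-optimised ("high") and viability-optimised ("low") subpopulations
after a nutrient downshift.  Event tables are pandas DataFrames with named
channel columns (FSC-H for cell size, FSC-A for doublet gating, BL1-H for
the growth-marker fluorescence, YL1-H for propidium iodide, VL1/VL2 and
YL2 for metabolic sensors); growth curves are (time, OD600) arrays;
microscopy fields are (4, H, W) stacks in brightfield/BFP/GFP/RFP order
with an integer label mask from an external segmenter.  All channel units
are arbitrary instrument units: only ratios, ranks and mixture structure
carry meaning, so no calibration layer is provided.

## Doublet exclusion

Coincident cell pairs double the forward-scatter *area* but not its
*height*.  A robust line is fitted to log10(FSC-A) vs log10(FSC-H): the
slope is Theil–Sen (on an even-stride subsample of at most 2,000 points,
since the estimator is quadratic in n) and the intercept is the median of
`y − slope·x`, which stays centred under heavy contamination, unlike the
`median(y) − slope·median(x)` convention.  Events whose absolute residual
exceeds `k_mad × MAD` (default k = 3) are removed; zero MAD (perfectly
collinear data) removes nothing and logs a warning.  Events exactly on the
line are never removed.

## Mixture model and assignment transfer

Subpopulations are a K-component Gaussian mixture in one or two
dimensions, fitted by EM.  Two covariance families: `full`
(per-component), and `shared_spherical` (all components share one λI),
the family used for 1-D cell-size clustering behind sensor summaries —
it matches the "free proportions, shared spherical covariance" model of
mixture-model clustering taxonomies.  Numerical choices:

- initialisation: a deterministic quantile split on the first axis, plus
  4 seeded random-responsibility restarts (best log-likelihood wins);
- convergence at relative log-likelihood change < 1e-8, max 500
  iterations; the log-likelihood is asserted non-decreasing every
  iteration;
- singular covariances trigger a restart with ε·I added
  (ε = 1e-6 × mean data variance);
- components are relabelled so "low" always has the smaller size-axis
  mean; K=1 uses the closed form.

A fitted mixture is a frozen classifier: assignment computes posteriors
under *any* supplied fit, so a reference condition/timepoint (chosen by
the analyst where clustering is cleanest) transfers to all others.  Hard
assignment takes the argmax posterior; confidence mode (threshold 0.85 by
default) leaves low-confidence events unassigned, and fractions exclude
them from the denominator while reporting their share.  BIC for K ∈ {1,2}
is reported, never used to decide.

## Dip statistic and its p-value

The dip of a sample is the maximum distance between its empirical CDF
and the nearest unimodal CDF, computed by the classic iteration: fit the
greatest convex minorant left of the candidate modal interval and the
least concave majorant right of it, measure the largest discrepancy,
shrink the interval, repeat.  The kernel is numba-compiled; its floor is
1/(2n), attained by e.g. constant samples (handled by convention with
p = 1).  Correctness is established against an independent definitional
oracle (`tests/dip_reference.py`): for each candidate mode the
nearest-unimodal-CDF distance is the optimum of a linear program
(monotonicity, convexity left of the mode, concavity right, an optional
atom at the mode, and a ±d band around the empirical CDF), minimised over
modes.  The two agree to ~3e-13 over 50 varied samples, and both hit the
exact anchors (50×{0}+50×{1} → 0.25; the uniform grid → 1/(2n)).

p-values are Monte Carlo: the fraction of `n_null` seeded uniform(0,1)
samples of the same n whose dip reaches the observed one, with a
+1/(n_null+1) continuity correction.  This matches the convention of the
published dip-test tables (which are also uniform-based) and is exact at
any n.  One consequence is inherited from the test itself: the uniform is
the least favourable unimodal distribution, so for lighter-tailed
unimodal data (e.g. Gaussian) the test is strictly conservative — at
n = 500 the rejection rate under a Gaussian null is ≈ 0, not the nominal
5%.  Power is excellent where it matters: a balanced mixture separated by
4 sd at n = 5,000 is detected essentially always.  Bimodality *scores*
(the dip itself) need no null and can be computed with `n_null = 0`.

## Growth, lag and viability

Local rates are `Δln OD / Δt` per sampling interval; the maximal rate is
taken over intervals whose midpoint lies in a window (default 5–20 h)
chosen to exclude lag and stationary phases.  Optionally a 3-parameter
logistic is least-squares fitted first and rates computed on it (the
smooth analogue of the common growth-curve-fitting packages, whose model
is logistic); a failed fit falls back to raw rates with a warning.  Note
the windowed maximal local rate of a logistic is `r·(1 − OD/K)` at the
window's entry OD — it only equals the rate parameter when the culture is
still dilute inside the window.  The closed-loop tests therefore use a
dilute inoculum (od0 = 1e-3, capacity 2.0 OD600), under which the
estimator recovers the generating rate to well under 2% across
mu ∈ [0.1, 0.5] 1/h and lag ∈ [0, 8] h.

Lag is the pseudo-lag: the earliest time on a 0.5 h grid at which OD has
quadrupled (two doublings) over the starting OD, evaluated by
previous-sample hold with no interpolation, matching the discrete-interval
definition; the threshold is derived as 4×od0 (with the conventional
od0 = 0.05 this gives 0.2 OD600).  It is monotone in od0 by construction.

Viability is the fraction of events at or below a PI threshold set as the
0.995 quantile of an all-live rich-media control (the quantile is a flag;
viability is monotone in it).  Chronological lifespan summarises the
fraction per day and reports the half-life by linear interpolation of the
first crossing below 0.5, censored if never crossed.

## Microscopy scoring

Segmentation masks are consumed, never computed.  Per cell, inside its
tight bounding box in the nuclear-tag (BFP) channel: Gaussian blur
σ = 1 px, threshold at the top 15% brightest pixels of the box, one
erosion and one dilation with a 3×3 cross to delete isolated islands,
then the largest 4-connected component.  The output is invariant to
adding a constant to the patch (quantile threshold).  TF nuclear
intensity is the mean GFP over that mask; cells with an empty mask are
dropped and counted.  Mis-segmentations are filtered as the lowest-density
`floor(f·n)` cells (default f = 0.05, a flag — the kernel settings are
fixed, the cutoff is an analyst's choice) under a linear-kernel,
bandwidth-1, Euclidean KDE on the z-scored (area, mean RFP) scatter.
Subpopulation assignment reuses the flow EM at confidence 0.85.
Subpopulation TF scores are single-cell means; condition scores are
unweighted means of the available subpopulation scores; relative scores
divide by the mean of all TFs excluding the top-5 and bottom-5 at the
timepoint (single pass, requiring ≥ 12 TFs).  Differential localisation
uses the Welch unequal-variance t test (the equal-variance assumption is
never stated for such data, and Welch is the safer default), with the
difference of group means as the effect.

## Synthetic generators

Every generator is a pure function of (spec, seed) with one
`numpy.random.default_rng` per call and emits ground truth sufficient to
recompute all downstream quantities.  Component counts are exact
stratified counts (largest-remainder rounding), so truth fractions are
exact — this sharpens recovery tests.  Design of the emulation:

- *Flow*: cell size and marker are correlated lognormals (scatter and
  fluorescence channels are positive and right-skewed); defaults place
  low/high 5 log-sd apart in size and ~4.8 in marker, low weight 0.3.
  Singlets have FSC-A = 1.5·FSC-H·(1+ε), ε ~ N(0, 0.01); doublets
  multiply FSC-A by 2±10% at unchanged FSC-H.
- *Growth*: OD is flat at od0 until the lag, then logistic with the given
  rate toward capacity, plus optional additive Gaussian noise.
- *Viability*: live/dead PI intensities are lognormals (defaults 7.5
  log-sd apart — well beyond the 4 sd the recovery claims need).
- *Fields*: non-overlapping ellipses fully inside the frame; the nucleus
  is the `round(frac·area)` cell pixels nearest an off-centre point, so
  the truth nucleus count is exact.  Default nucleus fraction 0.18 of the
  cell area (≈ 0.14 of the bounding box, the scale at which a fixed
  top-15% threshold is a sensible nuclear gate — consistent with 2-D
  cross-sections of yeast nuclei).  BFP is 10× brighter in the nucleus;
  GFP is cytoplasmic level × enrichment inside it; RFP is uniform per
  cell at the subpopulation marker level.  Noise is additive Gaussian per
  channel on ideal intensities (simplest controllable SNR; no Poisson or
  PSF modelling).
- *Panels*: low weights span 0.08–0.5; growth rates are a fixed grid
  re-ordered through a Gaussian copula whose normal-score correlation
  `2·sin(π·ρ/6)` makes the population Spearman equal the designed
  coupling (exact at ±1); viability decays exponentially with a time
  constant increasing in the low weight.

What the generators deliberately do not emulate: optical PSFs, Poisson
shot noise, autofluorescence spectra, segmentation errors (masks are
perfect), plate evaporation, or RNA-seq readouts.  Passing closed-loop
tests therefore demonstrates correctness of the *computations* under the
assumed statistical structure, not robustness to every artefact of real
instruments.

## Problem sizes and reproducibility

The validation suite uses the study-scale conditions where they are
cheap (10,000–20,000 events per table, 20-condition panels, 50-cell
fields) and a moderate number of replicates (10 panel seeds, 20 fields,
100–200 dip-test replicates) as the package's own choice of simulation
size.  `scripts/acceptance.py` derives every seed from `--seed`, so runs
are exactly reproducible.

## Interfaces

Event and truth tables read/write as CSV (FCS parsing is out of scope in
this environment; cytometry exports are expected as CSV with named
channel columns); mixture fits serialise to JSON for reuse as transfer
classifiers; fields write as multi-page float TIFF with a 16-bit label
TIFF sidecar.  The package is a library: its public functions and the
acceptance script are the interface, and no shell CLI is provided since
every use is a few lines of Python over DataFrames.

## Known limitations

- The dip test's uniform Monte-Carlo null is conservative for
  lighter-tailed unimodal data (see above); dip *scores* are unaffected.
- The Wald proportion interval is degenerate at k = 0 or k = n
  (Clopper–Pearson is available behind a flag).
- Welch/BH/Spearman p-value conventions are fixed choices where several
  defensible ones exist; the exact-permutation Spearman p is limited to
  n ≤ 8.
- The ratiometric ATP convention is exposed via an `invert` flag because
  both the direct VL2/VL1 ratio and its reciprocal are used in practice;
  the package does not decide which is "the" ATP level.
- 2-D mixtures only (d ≤ 2): the phenotyping features used here are
  (size, marker) pairs; higher-dimensional gating is out of scope.
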