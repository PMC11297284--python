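# phenopop

Single-cell phenotyping of growth/viability subpopulations in budding
yeast.  When *S. cerevisiae* is shifted from rich medium to a single
nitrogen source, an isogenic culture can split into two subpopulations: a
"high" fraction of larger cells with bright growth-marker expression that
keeps growing, and a "low" fraction of small, marker-dim cells that enter
a quiescent state with extended chronological lifespan.  `phenopop`
implements the quantitative pipeline for detecting and characterising
this heterogeneity from standard single-cell readouts, plus synthetic
generators with recorded ground truth so every stage can be validated in
a closed loop.

## What it computes

**Flow cytometry** (`phenopop.flow`)
- doublet exclusion from the log FSC-H / FSC-A relation (Theil–Sen line,
  MAD residual gate),
- K-component Gaussian-mixture fits by EM, families `full` and
  `shared_spherical` (one shared λI covariance), with deterministic
  quantile-split initialisation plus seeded restarts.  A fitted
  `MixtureFit` is a transferable classifier: posteriors for any event
  table can be computed under a frozen reference fit, which is how one
  reference timepoint's clustering is generalised to a whole time course,
- posterior-based hard and confidence-thresholded assignment,
  per-replicate subpopulation fractions with SEM,
- Hartigan dip statistic for cell-size bimodality
  (dip = sup-distance between the empirical CDF and the nearest unimodal
  CDF, computed by the greatest-convex-minorant / least-concave-majorant
  iteration, numba-compiled) with seeded Monte-Carlo uniform-null
  p-values,
- cell-size CV, size-normalised fluorescence, and ratiometric metabolic
  sensor readouts (e.g. ATP as VL2-H/VL1-H).

**Growth and viability** (`phenopop.growth`)
- local specific growth rates `mu_log_i = Δln OD / Δt`, maximal rate
  within a window excluding lag and stationary phases (default 5–20 h),
  optionally on a least-squares logistic fit,
- pseudo-lag time: earliest grid time (0.5 h steps) reaching two
  doublings (fourfold OD over the starting OD),
- propidium-iodide viability against an all-live rich-media control
  threshold (0.995 control quantile), and chronological-lifespan
  summaries with interpolated half-life.

**Microscopy** (`phenopop.imaging`)
- per-cell nuclear masks from the nuclear-tag channel inside external
  segmentation bounding boxes (blur σ=1, top-15% threshold, 3×3-cross
  opening, largest component), mean nuclear TF-GFP intensity,
- KDE outlier filtering of the (size, marker) scatter (linear kernel,
  bandwidth 1), EM subpopulation assignment at confidence 0.85,
- TF score tables (subpopulation means, unweighted condition means),
  relative TF scores normalised by the mid-ranked TFs (top/bottom 5
  excluded), Welch tests for differential localisation.

**Tradeoff statistics** (`phenopop.stats`)
- Spearman correlations (e.g. bimodality score vs maximal growth rate,
  viability vs inverse lag), one-tailed Fisher exact tests by
  hypergeometric enumeration, Wald proportion CIs, Welch/paired t tests,
  Benjamini–Hochberg adjustment.

**Synthetic data** (`phenopop.synthetic`) — generators for all of the
above with exact stratified ground truth: correlated lognormal
(size, marker) mixtures with doublets, lag+logistic growth curves,
live/dead PI mixtures, multi-channel microscopy fields with label masks,
and condition panels realising a designed rank coupling between
bimodality and growth rate.

## Worked example

```python
import numpy as np
import phenopop as pp
from phenopop import synthetic as syn, growth

# 20,000 events from a 30/70 low/high mixture with 5% doublets
events = syn.simulate_flow_events(
    [syn.LOW_SUBPOP, syn.HIGH_SUBPOP], 20000, doublet_rate=0.05, seed=7)
gated = pp.exclude_doublets(events)
print(f"doublets removed: {gated.n_doublets_removed}")

X = np.column_stack([np.log(gated.events["FSC-H"]),
                     np.log(gated.events["BL1-H"])])
fit = pp.fit_gaussian_mixture(X, K=2, seed=0)
assign = pp.assign_subpopulations(fit, X, mode="confidence", threshold=0.85)
assign["replicate"] = gated.events["replicate"].to_numpy()
frac = pp.subpopulation_fractions(assign)
print(f"low-subpopulation fraction: {frac.fraction_mean:.3f}")

dip = pp.dip_test(gated.events["FSC-H"].to_numpy(), n_null=999, seed=0)
print(f"cell-size dip = {dip.dip:.4f}, p = {dip.p_value:.4f}")

curve = syn.simulate_growth_curve(od0=1e-3, lag_h=3.0, mu_max=0.35,
                                  capacity=2.0, seed=0)
gfit = growth.max_growth_rate(curve, smooth=False)
lag = growth.lag_time(curve, od0=1e-3)
print(f"mu_max = {gfit.mu_max:.3f} 1/h, lag = {lag.lag_h} h")

sample = syn.simulate_viability_events(0.7, n=10000, seed=1)
ypd = syn.simulate_viability_events(1.0, n=5000, seed=2)
v = growth.viability_fraction(sample, ypd)
print(f"viable fraction vs YPD threshold: {v.viable_fraction:.3f}")
```

Output:

```
doublets removed: 1668
low-subpopulation fraction: 0.299
cell-size dip = 0.0486, p = 0.0010
mu_max = 0.350 1/h, lag = 7.0 h
viable fraction vs YPD threshold: 0.696
```

The gate removes the 1,000 planted doublets plus a small tail of
borderline singlets; the mixture recovers the designed 0.30 low fraction;
the dip test calls the size distribution clearly bimodal; the growth
estimators return the generating rate exactly and the lag on the next
0.5 h grid point after the analytic fourfold-OD crossing (6.96 h); and
the PI threshold recovers the designed 70% viability.

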