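"""Synthetic data generators with recorded ground truth.

Every generator is a pure function of (spec, seed): the same inputs yield
byte-identical outputs, and a ground-truth table sufficient to recompute
every downstream quantity is always returned alongside the data.

The generators emulate the statistical structure of a nitrogen-downshift
phenotyping experiment in budding yeast:

* flow-cytometry event tables with two lognormal subpopulations in
  (cell size, growth-marker fluorescence) plus coincidence doublets,
* plate-reader growth curves (lag phase followed by logistic growth),
* propidium-iodide viability mixtures decaying over days in buffer,
* multi-channel microscopy fields of elliptical cells with nuclei and
  subpopulation-dependent size / marker / TF nuclear enrichment,
* condition panels with a designed rank coupling between the
  low-subpopulation weight and the maximal growth rate.

Channel units are arbitrary instrument units throughout; only ratios,
ranks and mixture structure carry meaning.  Subpopulation component counts
are drawn by exact stratified counts (largest-remainder rounding of
weight * n), not Bernoulli draws, so truth fractions are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .flow import AREA_CHANNEL, MARKER_CHANNEL, SIZE_CHANNEL

PI_CHANNEL = "YL1-H"
CHANNEL_ORDER = ("brightfield", "bfp", "gfp", "rfp")


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubpopSpec:
    """Lognormal subpopulation in (cell size, marker fluorescence).

    Sizes and fluorescence are in arbitrary forward-scatter / detector
    units.  ``size_marker_corr`` is the log-space correlation between the
    two; ``pi_shift`` is the multiplicative propidium-iodide intensity
    factor applied to dead cells; ``tf_nuclear_enrichment`` the ratio of
    nuclear to cytoplasmic TF-channel intensity in microscopy.
    """

    weight: float
    size_logmean: float
    size_logsd: float
    marker_logmean: float
    marker_logsd: float
    size_marker_corr: float = 0.0
    pi_shift: float = 20.0
    tf_nuclear_enrichment: float = 1.0

    def validate(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError("weight must be in [0, 1]")
        if self.size_logsd < 0 or self.marker_logsd < 0:
            raise ValueError("log-sds must be >= 0")
        if not (-1.0 <= self.size_marker_corr <= 1.0):
            raise ValueError("size_marker_corr must be in [-1, 1]")
        if self.tf_nuclear_enrichment < 0:
            raise ValueError("tf_nuclear_enrichment must be >= 0")


#: Default low (viability-optimised, small, marker-dim) subpopulation.
LOW_SUBPOP = SubpopSpec(weight=0.3, size_logmean=10.4, size_logsd=0.12,
                        marker_logmean=7.2, marker_logsd=0.25,
                        size_marker_corr=0.3, pi_shift=20.0,
                        tf_nuclear_enrichment=3.0)
#: Default high (growth-optimised, large, marker-bright) subpopulation.
HIGH_SUBPOP = SubpopSpec(weight=0.7, size_logmean=11.0, size_logsd=0.12,
                         marker_logmean=8.5, marker_logsd=0.25,
                         size_marker_corr=0.3, pi_shift=20.0,
                         tf_nuclear_enrichment=1.0)


@dataclass(frozen=True)
class PanelSpec:
    """A panel of nitrogen-source conditions with designed tradeoff.

    ``coupling`` is the designed rank correlation between the
    low-subpopulation weight and the maximal growth rate across conditions
    (the growth-viability tradeoff; negative couplings mean more bimodal
    conditions grow slower).  With ``rate_noise = 0`` and ``coupling`` of
    +/-1 the coupling is realised exactly.
    """

    n_conditions: int = 20
    coupling: float = -0.8
    seed: int = 0
    low_weights: tuple = ()           # default: evenly spaced 0.08..0.5
    mu_range: tuple = (0.1, 0.5)      # 1/h
    od0: float = 1e-3                 # dilute inoculum; see methods note
    capacity: float = 2.0
    lag_range_h: tuple = (0.0, 4.0)
    dt_h: float = 0.25
    t_max_h: float = 30.0
    od_noise_sd: float = 0.0
    n_events: int = 20000
    doublet_rate: float = 0.05
    viability_days: tuple = (0, 10, 20, 30)
    n_pi_events: int = 5000

    def validate(self) -> None:
        if self.n_conditions < 2:
            raise ValueError("n_conditions must be >= 2")
        if not (-1.0 <= self.coupling <= 1.0):
            raise ValueError("coupling must be in [-1, 1]")


@dataclass(frozen=True)
class FieldSpec:
    """Geometry and noise of one synthetic microscopy field."""

    image_shape: tuple = (512, 512)
    n_cells: int = 50
    radius_range_px: tuple = (6.0, 12.0)
    nucleus_area_fraction: float = 0.18
    baselines: dict = field(default_factory=lambda: {
        "brightfield": 1000.0, "bfp": 20.0, "gfp": 10.0, "rfp": 10.0})
    noise_sd: dict = field(default_factory=lambda: {
        "brightfield": 5.0, "bfp": 3.0, "gfp": 3.0, "rfp": 3.0})
    overlap_allowed: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.nucleus_area_fraction < 1.0):
            raise ValueError("nucleus_area_fraction must be in (0, 1)")
        if self.radius_range_px[0] < 2.0:
            raise ValueError("cell radii must be >= 2 px")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _stratified_counts(weights: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder rounding of weight*n to exact total n."""
    raw = weights * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _check_weights(specs) -> np.ndarray:
    w = np.array([s.weight for s in specs], dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"subpopulation weights sum to {w.sum()}, not 1")
    return w


def _subpop_labels(specs) -> list:
    """Label subpops low/high by size mean (or low/c1/c2... beyond two)."""
    order = np.argsort([s.size_logmean for s in specs], kind="stable")
    labels = [""] * len(specs)
    if len(specs) <= 2:
        names = ["low", "high"][: len(specs)]
    else:
        names = ["low"] + [f"c{i}" for i in range(1, len(specs))]
    for name, idx in zip(names, order):
        labels[idx] = name
    return labels


# --------------------------------------------------------------------------
# flow events
# --------------------------------------------------------------------------

def simulate_flow_events(specs, n_events: int, doublet_rate: float = 0.0,
                         seed: int = 0, condition: str = "synthetic",
                         timepoint_h: float = 6.0, replicate: str = "r1",
                         fsc_a_gain: float = 1.5, fsc_a_jitter: float = 0.01
                         ) -> pd.DataFrame:
    """Cytometry event table from lognormal subpopulations plus doublets.

    Singlets satisfy ``FSC-A = fsc_a_gain * FSC-H * (1 + eps)`` with small
    Gaussian ``eps``; doublets (an exact ``round(doublet_rate * n_events)``
    of the rows) have FSC-A inflated by 2 +/- 10% at unchanged FSC-H.
    Truth columns: ``truth_subpop``, ``truth_doublet``.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not (0.0 <= doublet_rate < 1.0):
        raise ValueError("doublet_rate must be in [0, 1)")
    for s in specs:
        s.validate()
    weights = _check_weights(specs)
    labels = _subpop_labels(specs)
    rng = np.random.default_rng(seed)

    counts = _stratified_counts(weights, n_events)
    size = np.empty(n_events)
    marker = np.empty(n_events)
    subpop = np.empty(n_events, dtype=object)
    pos = 0
    for spec, cnt, lab in zip(specs, counts, labels):
        if cnt == 0:
            continue
        z1 = rng.standard_normal(cnt)
        z2 = rng.standard_normal(cnt)
        rho = spec.size_marker_corr
        log_size = spec.size_logmean + spec.size_logsd * z1
        log_marker = spec.marker_logmean + spec.marker_logsd * (
            rho * z1 + np.sqrt(1.0 - rho**2) * z2)
        size[pos:pos + cnt] = np.exp(log_size)
        marker[pos:pos + cnt] = np.exp(log_marker)
        subpop[pos:pos + cnt] = lab
        pos += cnt

    perm = rng.permutation(n_events)
    size, marker, subpop = size[perm], marker[perm], subpop[perm]

    eps = fsc_a_jitter * rng.standard_normal(n_events)
    fsc_a = fsc_a_gain * size * (1.0 + eps)
    n_doublets = int(round(doublet_rate * n_events))
    is_doublet = np.zeros(n_events, dtype=bool)
    if n_doublets:
        idx = rng.choice(n_events, size=n_doublets, replace=False)
        is_doublet[idx] = True
        fsc_a[idx] *= 2.0 * (1.0 + rng.uniform(-0.1, 0.1, n_doublets))

    return pd.DataFrame({
        "event_id": np.arange(n_events),
        SIZE_CHANNEL: size,
        AREA_CHANNEL: fsc_a,
        MARKER_CHANNEL: marker,
        "condition": condition,
        "timepoint_h": timepoint_h,
        "replicate": replicate,
        "truth_subpop": subpop,
        "truth_doublet": is_doublet,
    })


# --------------------------------------------------------------------------
# growth curves
# --------------------------------------------------------------------------

@dataclass
class GrowthCurve:
    """OD600 time series (times strictly increasing, in hours)."""

    time_h: np.ndarray
    od: np.ndarray
    condition: str = "synthetic"
    replicate: str = "r1"
    blank_corrected: bool = True

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time_h.size < 2:
            raise ValueError("growth curve needs at least 2 points")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.time_h.shape != self.od.shape:
            raise ValueError("time and od must have equal length")


def logistic_od(t, od0: float, lag_h: float, mu_max: float,
                capacity: float) -> np.ndarray:
    """Lag-then-logistic OD trajectory (noise-free)."""
    t = np.asarray(t, dtype=float)
    te = np.maximum(t - lag_h, 0.0)
    return capacity * od0 / (od0 + (capacity - od0) * np.exp(-mu_max * te))


def simulate_growth_curve(od0: float, lag_h: float, mu_max: float,
                          capacity: float, dt_h: float = 0.25,
                          noise_sd: float = 0.0, seed: int = 0,
                          t_max_h: float = 30.0,
                          condition: str = "synthetic",
                          replicate: str = "r1") -> GrowthCurve:
    """Plate-reader-like growth curve: flat lag, then logistic growth."""
    if od0 <= 0:
        raise ValueError("od0 must be positive")
    if dt_h <= 0:
        raise ValueError("dt_h must be positive")
    if capacity <= od0:
        raise ValueError("capacity must exceed od0")
    t = np.arange(0.0, t_max_h + 0.5 * dt_h, dt_h)
    od = logistic_od(t, od0, lag_h, mu_max, capacity)
    if noise_sd > 0:
        od = od + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    return GrowthCurve(time_h=t, od=od, condition=condition,
                       replicate=replicate)


# --------------------------------------------------------------------------
# viability events
# --------------------------------------------------------------------------

def simulate_viability_events(viable_fraction: float,
                              live_pi=(4.6, 0.4), dead_pi=(7.6, 0.4),
                              n: int = 10000, seed: int = 0,
                              condition: str = "synthetic",
                              day: float = 0.0) -> pd.DataFrame:
    """Two-component lognormal PI-intensity mixture with truth labels.

    ``live_pi`` / ``dead_pi`` are (logmean, logsd) of the PI channel for
    membrane-intact and PI-permeable cells; the dead location must exceed
    the live one.  Counts are stratified, so the truth viable fraction is
    exact up to rounding.
    """
    if not (0.0 <= viable_fraction <= 1.0):
        raise ValueError("viable_fraction must be in [0, 1]")
    if dead_pi[0] <= live_pi[0]:
        raise ValueError("dead PI location must exceed live location")
    rng = np.random.default_rng(seed)
    counts = _stratified_counts(np.array([viable_fraction,
                                          1.0 - viable_fraction]), n)
    pi = np.concatenate([
        np.exp(live_pi[0] + live_pi[1] * rng.standard_normal(counts[0])),
        np.exp(dead_pi[0] + dead_pi[1] * rng.standard_normal(counts[1])),
    ])
    viable = np.concatenate([np.ones(counts[0], dtype=bool),
                             np.zeros(counts[1], dtype=bool)])
    perm = rng.permutation(n)
    return pd.DataFrame({
        "event_id": np.arange(n),
        PI_CHANNEL: pi[perm],
        "condition": condition,
        "day": day,
        "truth_viable": viable[perm],
    })


# --------------------------------------------------------------------------
# condition panel
# --------------------------------------------------------------------------

@dataclass
class ConditionData:
    """All raw data simulated for one panel condition."""

    name: str
    events: pd.DataFrame
    growth: GrowthCurve
    pi_courses: dict          # day -> PI event table


@dataclass
class PanelResult:
    conditions: dict          # name -> ConditionData
    truth: pd.DataFrame       # per-condition ground truth summary
    control_pi: pd.DataFrame  # all-live control events (rich-media analogue)


def simulate_condition_panel(spec: PanelSpec) -> PanelResult:
    """Panel of conditions realising a designed bimodality-growth coupling.

    Low-subpopulation weights span the panel; maximal growth rates are a
    fixed grid re-ordered through a Gaussian copula so the population rank
    correlation between weight and rate equals ``spec.coupling`` (exactly
    anti/co-monotone at +/-1).  Viability decays over days with a time
    constant increasing with the low (quiescent) weight.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_conditions

    if spec.low_weights:
        w = np.asarray(spec.low_weights, dtype=float)
        if w.size != n:
            raise ValueError("low_weights length must equal n_conditions")
    else:
        w = np.linspace(0.08, 0.5, n)

    # rank coupling via Gaussian copula: population Spearman == coupling
    rho_s = spec.coupling
    rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
    z_w = (np.argsort(np.argsort(w)) + 0.5) / n
    from scipy.stats import norm
    z = norm.ppf(z_w)
    if abs(rho_p) >= 1.0:
        latent = np.sign(rho_p) * z
    else:
        latent = rho_p * z + np.sqrt(1.0 - rho_p**2) * rng.standard_normal(n)
    mu_grid = np.linspace(spec.mu_range[0], spec.mu_range[1], n)
    mu = np.empty(n)
    mu[np.argsort(latent, kind="stable")] = mu_grid

    lags = rng.uniform(*spec.lag_range_h, size=n)
    # viability time constant grows with the quiescent (low) weight
    tau = 10.0 + 40.0 * (w - w.min()) / max(w.max() - w.min(), 1e-12)

    conditions = {}
    truth_rows = []
    for i in range(n):
        name = f"cond{i:02d}"
        low = replace(LOW_SUBPOP, weight=float(w[i]))
        high = replace(HIGH_SUBPOP, weight=float(1.0 - w[i]))
        events = simulate_flow_events(
            [low, high], spec.n_events, doublet_rate=spec.doublet_rate,
            seed=int(rng.integers(2**31)), condition=name)
        growth = simulate_growth_curve(
            spec.od0, float(lags[i]), float(mu[i]), spec.capacity,
            dt_h=spec.dt_h, noise_sd=spec.od_noise_sd,
            seed=int(rng.integers(2**31)), t_max_h=spec.t_max_h,
            condition=name)
        pi_courses = {}
        viable_by_day = {}
        for day in spec.viability_days:
            v = float(np.exp(-day / tau[i]))
            pi_courses[day] = simulate_viability_events(
                v, n=spec.n_pi_events, seed=int(rng.integers(2**31)),
                condition=name, day=day)
            viable_by_day[day] = v
        conditions[name] = ConditionData(name=name, events=events,
                                         growth=growth,
                                         pi_courses=pi_courses)
        truth_rows.append({
            "condition": name, "low_weight": w[i], "mu_max": mu[i],
            "lag_h": lags[i], "tau_days": tau[i],
            **{f"viable_day{d}": viable_by_day[d]
               for d in spec.viability_days},
        })

    control = simulate_viability_events(
        1.0, n=max(spec.n_pi_events, 1000),
        seed=int(rng.integers(2**31)), condition="YPD-control")
    return PanelResult(conditions=conditions,
                       truth=pd.DataFrame(truth_rows),
                       control_pi=control)


# --------------------------------------------------------------------------
# microscopy fields
# --------------------------------------------------------------------------

@dataclass
class FieldResult:
    """Rendered field: channels, label masks and per-cell ground truth."""

    image: np.ndarray           # (4, H, W) float, order CHANNEL_ORDER
    labels: np.ndarray          # (H, W) int32, 0 = background
    nucleus_labels: np.ndarray  # (H, W) int32, truth nucleus pixel sets
    cells: pd.DataFrame         # per-cell truth table


def simulate_microscopy_field(fieldspec: FieldSpec, subpops=None
                              ) -> FieldResult:
    """Render elliptical cells with nuclei in four channels plus masks.

    BFP is bright in the nucleus; GFP is the cytoplasmic level scaled by
    the subpopulation's ``tf_nuclear_enrichment`` inside the nucleus; RFP
    is uniform per cell at the subpopulation's marker level (rescaled to
    detector-like units).  The truth table lists per-cell area, subpop,
    nucleus pixel count and noise-free channel levels.
    """
    fieldspec.validate()
    if subpops is None:
        subpops = [LOW_SUBPOP, HIGH_SUBPOP]
    for s in subpops:
        s.validate()
    weights = _check_weights(subpops)
    labels_by_spec = _subpop_labels(subpops)
    rng = np.random.default_rng(fieldspec.seed)
    h, wpx = fieldspec.image_shape
    r_lo, r_hi = fieldspec.radius_range_px

    counts = _stratified_counts(weights, fieldspec.n_cells)
    # subpop-dependent mean radius: smaller cells for the low subpopulation
    order = np.argsort([s.size_logmean for s in subpops], kind="stable")
    r_means = np.empty(len(subpops))
    span = r_hi - r_lo
    for rank, idx in enumerate(order):
        r_means[idx] = r_lo + span * (rank + 1) / (len(subpops) + 1)

    cell_specs = []
    for i_spec, (s, cnt) in enumerate(zip(subpops, counts)):
        for _ in range(cnt):
            r = float(np.clip(r_means[i_spec] * np.exp(
                0.08 * rng.standard_normal()), r_lo, r_hi))
            ecc = rng.uniform(0.0, 0.25)
            cell_specs.append({
                "subpop": labels_by_spec[i_spec],
                "enrichment": s.tf_nuclear_enrichment,
                # marker level mapped to detector-like units
                "rfp_level": float(np.exp(
                    s.marker_logmean + s.marker_logsd * rng.standard_normal()
                ) / np.exp(HIGH_SUBPOP.marker_logmean) * 200.0),
                "r_row": r * (1.0 + ecc),
                "r_col": r * (1.0 - ecc),
                "theta": rng.uniform(0.0, np.pi),
            })
    rng.shuffle(cell_specs)

    labels = np.zeros((h, wpx), dtype=np.int32)
    nucleus_labels = np.zeros((h, wpx), dtype=np.int32)
    rows_grid, cols_grid = np.mgrid[0:h, 0:wpx]
    placed = []
    max_tries = 200
    for cid, cs in enumerate(cell_specs, start=1):
        rr, rc, th = cs["r_row"], cs["r_col"], cs["theta"]
        rmax = max(rr, rc)
        for attempt in range(max_tries):
            cy = rng.uniform(rmax + 1, h - rmax - 1)
            cx = rng.uniform(rmax + 1, wpx - rmax - 1)
            if fieldspec.overlap_allowed:
                break
            if all((cy - py)**2 + (cx - px)**2 > (rmax + pr + 1.0)**2
                   for py, px, pr in placed):
                break
        else:
            raise RuntimeError(
                f"could not place cell {cid} without overlap after "
                f"{max_tries} tries")
        placed.append((cy, cx, rmax))

        dy = rows_grid - cy
        dx = cols_grid - cx
        u = np.cos(th) * dy + np.sin(th) * dx
        v = -np.sin(th) * dy + np.cos(th) * dx
        inside = (u / rr)**2 + (v / rc)**2 <= 1.0
        labels[inside] = cid

        # nucleus: the round(frac * area) cell pixels nearest a point
        # offset slightly from the centre (compact disc, exact pixel count)
        area = int(inside.sum())
        n_nuc = max(1, int(round(fieldspec.nucleus_area_fraction * area)))
        off = 0.2 * min(rr, rc)
        ny = cy + rng.uniform(-off, off)
        nx = cx + rng.uniform(-off, off)
        cell_idx = np.flatnonzero(inside.ravel())
        d2 = ((rows_grid.ravel()[cell_idx] - ny)**2
              + (cols_grid.ravel()[cell_idx] - nx)**2)
        nuc_idx = cell_idx[np.argsort(d2, kind="stable")[:n_nuc]]
        nl = nucleus_labels.ravel()
        nl[nuc_idx] = cid
        cs.update(cell_id=cid, area_px=area, nucleus_px=n_nuc,
                  center_row=cy, center_col=cx)

    # render channels (noise-free ideals first)
    base = fieldspec.baselines
    img = np.empty((4, h, wpx), dtype=np.float64)
    img[0] = base["brightfield"]
    img[1] = base["bfp"]
    img[2] = base["gfp"]
    img[3] = base["rfp"]
    gfp_cyto = 100.0
    bfp_cell, bfp_nuc = 40.0, 400.0
    truth_rows = []
    for cs in cell_specs:
        cid = cs["cell_id"]
        cell = labels == cid
        nuc = nucleus_labels == cid
        img[0][cell] = base["brightfield"] * 0.8
        img[1][cell] = bfp_cell
        img[1][nuc] = bfp_nuc
        img[2][cell] = gfp_cyto
        img[2][nuc] = gfp_cyto * cs["enrichment"]
        img[3][cell] = cs["rfp_level"]
        truth_rows.append({
            "cell_id": cid, "subpop": cs["subpop"],
            "area_px": cs["area_px"], "nucleus_px": cs["nucleus_px"],
            "center_row": cs["center_row"], "center_col": cs["center_col"],
            "tf_nuclear_enrichment": cs["enrichment"],
            "gfp_cytoplasm": gfp_cyto,
            "gfp_nuclear": gfp_cyto * cs["enrichment"],
            "rfp_level": cs["rfp_level"],
        })

    for ci, ch in enumerate(CHANNEL_ORDER):
        sd = fieldspec.noise_sd.get(ch, 0.0)
        if sd > 0:
            img[ci] += rng.normal(0.0, sd, size=(h, wpx))

    cells = pd.DataFrame(truth_rows).sort_values("cell_id",
                                                 ignore_index=True)
    return FieldResult(image=img, labels=labels,
                       nucleus_labels=nucleus_labels, cells=cells)


def write_field_tiff(result: FieldResult, image_path, mask_path) -> None:
    """Multi-page TIFF (one page per channel) plus 16-bit label mask."""
    import tifffile

    tifffile.imwrite(image_path, result.image.astype(np.float32),
                     photometric="minisblack")
    tifffile.imwrite(mask_path, result.labels.astype(np.uint16))
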