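"""Flow-cytometry analysis: gating, subpopulation mixtures, bimodality.

Event tables are plain :class:`pandas.DataFrame` objects with named channel
columns (at minimum ``FSC-H``; ``FSC-A`` for doublet gating, ``BL1-H`` for
the growth-marker fluorescence) plus optional ``condition`` / ``timepoint_h``
/ ``replicate`` metadata and ``truth_*`` columns carried through from the
synthetic generators.

The subpopulation model is a K-component Gaussian mixture fitted by EM in
one or two dimensions.  Two covariance families are supported: ``full``
(per-component covariance) and ``shared_spherical`` (one shared lambda * I,
the model used for 1-D cell-size clustering behind metabolic-sensor
summaries).  A fitted :class:`MixtureFit` acts as a transferable classifier:
posteriors for any event table can be computed under a frozen reference fit,
which is how one reference condition/timepoint is generalised to the others.

Bimodality is scored with the Hartigan dip statistic; its p-value is the
Monte-Carlo tail frequency under seeded uniform null samples of the same
size.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import theilslopes

from ._dip import dip_stat, dip_stat_many

log = logging.getLogger(__name__)

SIZE_CHANNEL = "FSC-H"
AREA_CHANNEL = "FSC-A"
MARKER_CHANNEL = "BL1-H"
DEFAULT_K_MAD = 3.0
DEFAULT_CONFIDENCE = 0.85
DEFAULT_N_NULL = 2000
_THEILSEN_MAX_POINTS = 2000  # Theil-Sen is O(n^2); fit on a stride subsample


# --------------------------------------------------------------------------
# event-table IO
# --------------------------------------------------------------------------

def read_events_csv(path) -> pd.DataFrame:
    """Read an event table (one row per event, named channel columns)."""
    events = pd.read_csv(path)
    if "event_id" not in events.columns:
        events.insert(0, "event_id", np.arange(len(events)))
    return events


def write_events_csv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def _require_channels(events: pd.DataFrame, channels) -> None:
    missing = [c for c in channels if c not in events.columns]
    if missing:
        raise ValueError(f"event table lacks required channels {missing}")


# --------------------------------------------------------------------------
# doublet exclusion
# --------------------------------------------------------------------------

@dataclass
class DoubletResult:
    """Singlet table plus accounting of what was removed."""

    events: pd.DataFrame
    n_doublets_removed: int
    n_nonpositive_dropped: int
    slope: float
    intercept: float


def exclude_doublets(events: pd.DataFrame, k_mad: float = DEFAULT_K_MAD
                     ) -> DoubletResult:
    """Remove doublets via the FSC-H/FSC-A log-log linear relation.

    A robust (Theil-Sen) line is fitted to log10(FSC-A) versus log10(FSC-H);
    events whose absolute residual exceeds ``k_mad`` times the MAD of the
    residuals are removed.  Events with non-positive values in either channel
    are dropped first and counted separately.
    """
    if k_mad <= 0:
        raise ValueError("k_mad must be positive")
    _require_channels(events, [SIZE_CHANNEL, AREA_CHANNEL])
    h = events[SIZE_CHANNEL].to_numpy(dtype=float)
    a = events[AREA_CHANNEL].to_numpy(dtype=float)
    ok = np.isfinite(h) & np.isfinite(a) & (h > 0) & (a > 0)
    n_nonpos = int((~ok).sum())
    events = events.loc[ok]
    if len(events) < 10:
        raise ValueError("fewer than 10 events with positive FSC-H/FSC-A")

    lh = np.log10(events[SIZE_CHANNEL].to_numpy(dtype=float))
    la = np.log10(events[AREA_CHANNEL].to_numpy(dtype=float))
    if len(lh) > _THEILSEN_MAX_POINTS:
        stride = np.linspace(0, len(lh) - 1, _THEILSEN_MAX_POINTS).astype(int)
        order = np.argsort(lh, kind="stable")[stride]
        slope = float(theilslopes(la[order], lh[order])[0])
    else:
        slope = float(theilslopes(la, lh)[0])
    # median-of-residuals intercept: robust to contamination that shifts
    # median(y) (scipy's median(y) - slope*median(x) is not)
    intercept = float(np.median(la - slope * lh))

    resid = la - (intercept + slope * lh)
    center = float(np.median(resid))
    mad = float(np.median(np.abs(resid - center)))
    if mad == 0.0:
        log.warning("zero MAD in doublet gating (collinear data); "
                    "no events removed")
        keep = np.ones(len(events), dtype=bool)
    else:
        keep = np.abs(resid - center) <= k_mad * mad
    return DoubletResult(
        events=events.loc[keep],
        n_doublets_removed=int((~keep).sum()),
        n_nonpositive_dropped=n_nonpos,
        slope=float(slope),
        intercept=float(intercept),
    )


# --------------------------------------------------------------------------
# size normalisation and sensor ratios
# --------------------------------------------------------------------------

def normalize_by_size(events: pd.DataFrame,
                      fluor_channel: str = MARKER_CHANNEL,
                      size_channel: str = SIZE_CHANNEL) -> np.ndarray:
    """Per-event fluorescence divided by cell size."""
    _require_channels(events, [fluor_channel, size_channel])
    size = events[size_channel].to_numpy(dtype=float)
    bad = np.flatnonzero(~(size > 0))
    if bad.size:
        raise ValueError(
            f"non-positive size values at event rows {bad[:10].tolist()}"
            + ("..." if bad.size > 10 else "")
        )
    return events[fluor_channel].to_numpy(dtype=float) / size


def sensor_ratio(events: pd.DataFrame, numerator: str, denominator: str,
                 invert: bool = False) -> pd.Series:
    """Per-event ratiometric sensor readout (e.g. VL2-H/VL1-H for ATP).

    Events with non-positive denominator are dropped; ``invert`` returns the
    reciprocal (both published sign conventions for the FRET readout are
    thereby available).  The returned Series keeps the surviving events'
    index so it can be grouped by an assignment table.
    """
    _require_channels(events, [numerator, denominator])
    den = events[denominator].to_numpy(dtype=float)
    ok = den > 0
    if not ok.any():
        raise ValueError("all denominator values non-positive")
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("sensor_ratio dropped %d events with non-positive %s",
                    n_dropped, denominator)
    num = events[numerator].to_numpy(dtype=float)
    ratio = num[ok] / den[ok]
    if invert:
        ratio = 1.0 / ratio
    return pd.Series(ratio, index=events.index[ok], name="ratio")


def cell_size_cv(x) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) over mean."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("CV requires at least 2 values")
    mean = float(np.mean(x))
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(np.std(x, ddof=1) / mean)


# --------------------------------------------------------------------------
# Gaussian mixture EM
# --------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Fitted K-component Gaussian mixture usable as a transfer classifier.

    ``component_order`` maps the biological labels to component indices;
    "low" is always the component with the smaller mean on the first (size)
    axis.
    """

    K: int
    family: str                       # "full" | "shared_spherical"
    weights: np.ndarray               # (K,)
    means: np.ndarray                 # (K, d)
    covariances: np.ndarray           # (K, d, d)
    log_likelihood: float
    n_iter: int
    converged: bool
    component_order: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def bic(self, X: np.ndarray) -> float:
        X = np.atleast_2d(np.asarray(X, dtype=float).T).T
        n, d = X.shape
        if self.family == "shared_spherical":
            n_params = (self.K - 1) + self.K * d + 1
        else:
            n_params = (self.K - 1) + self.K * d + self.K * d * (d + 1) // 2
        ll = _log_prob(X, self.weights, self.means, self.covariances)[1]
        return float(n_params * np.log(n) - 2.0 * ll)

    def to_json(self, path=None) -> str:
        payload = {
            "K": self.K,
            "family": self.family,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),  # row-major per comp.
            "log_likelihood": self.log_likelihood,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "component_order": self.component_order,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MixtureFit":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            K=payload["K"],
            family=payload["family"],
            weights=np.asarray(payload["weights"], dtype=float),
            means=np.asarray(payload["means"], dtype=float),
            covariances=np.asarray(payload["covariances"], dtype=float),
            log_likelihood=payload["log_likelihood"],
            n_iter=payload["n_iter"],
            converged=payload["converged"],
            component_order={k: int(v)
                             for k, v in payload["component_order"].items()},
            seed=payload["seed"],
        )


def _log_prob(X, weights, means, covs):
    """Per-event log posterior numerators and total log-likelihood."""
    n, d = X.shape
    K = weights.shape[0]
    lp = np.empty((n, K))
    for k in range(K):
        diff = X - means[k]
        chol = np.linalg.cholesky(covs[k])
        sol = np.linalg.solve(chol, diff.T)
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        lp[:, k] = (np.log(weights[k])
                    - 0.5 * (d * np.log(2.0 * np.pi) + logdet + maha))
    tot = logsumexp(lp, axis=1)
    return lp, float(np.sum(tot))


def _m_step(X, resp, family, reg):
    n, d = X.shape
    K = resp.shape[1]
    nk = resp.sum(axis=0)
    weights = nk / n
    means = (resp.T @ X) / nk[:, None]
    covs = np.empty((K, d, d))
    if family == "shared_spherical":
        sq = 0.0
        for k in range(K):
            diff = X - means[k]
            sq += np.sum(resp[:, k] * np.sum(diff**2, axis=1))
        lam = sq / (n * d)
        lam = max(lam, reg)
        covs[:] = lam * np.eye(d)
    else:
        for k in range(K):
            diff = X - means[k]
            covs[k] = (resp[:, k][:, None] * diff).T @ diff / nk[k]
            covs[k] += reg * np.eye(d)
    return weights, means, covs


def _em_run(X, K, family, resp0, tol, max_iter, reg):
    n, d = X.shape
    resp = resp0
    prev_ll = -np.inf
    ll = -np.inf
    converged = False
    weights = means = covs = None
    for it in range(1, max_iter + 1):
        weights, means, covs = _m_step(X, resp, family, reg)
        lp, ll = _log_prob(X, weights, means, covs)
        if ll + 1e-9 * max(1.0, abs(ll)) < prev_ll:  # EM must not decrease
            raise FloatingPointError("log-likelihood decreased during EM")
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
            converged = True
            resp = np.exp(lp - logsumexp(lp, axis=1)[:, None])
            break
        prev_ll = ll
        resp = np.exp(lp - logsumexp(lp, axis=1)[:, None])
    return weights, means, covs, ll, it, converged


def fit_gaussian_mixture(X, K: int = 2, family: str = "full",
                         seed: int = 0, tol: float = 1e-8,
                         max_iter: int = 500, n_starts: int = 5
                         ) -> MixtureFit:
    """Fit a K-component Gaussian mixture by EM (best of ``n_starts``).

    The first start is deterministic (quantile split on the first axis);
    the remaining starts draw random component seeds.  Components are
    relabelled so that "low" is the component with the smaller mean on the
    first axis.  Singular covariances trigger a regularised restart
    (epsilon * I with epsilon = 1e-6 times the mean data variance).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if d not in (1, 2):
        raise ValueError("only 1-D and 2-D event matrices are supported")
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < 10 * K * d:
        raise ValueError(f"need at least {10 * K * d} events for K={K}, d={d}")
    if family not in ("full", "shared_spherical"):
        raise ValueError(f"unknown covariance family {family!r}")

    if K == 1:  # closed form
        mean = X.mean(axis=0, keepdims=True)
        diff = X - mean
        cov_ml = diff.T @ diff / n
        if family == "shared_spherical":
            cov = np.eye(d) * float(np.trace(cov_ml) / d)
        else:
            cov = cov_ml
        _, ll = _log_prob(X, np.array([1.0]), mean, cov[None])
        fit = MixtureFit(K=1, family=family, weights=np.array([1.0]),
                         means=mean, covariances=cov[None],
                         log_likelihood=ll, n_iter=0, converged=True,
                         seed=seed)
        fit.component_order = {"low": 0}
        return fit

    rng = np.random.default_rng(seed)
    data_var = float(np.mean(np.var(X, axis=0)))
    base_reg = 1e-6 * max(data_var, np.finfo(float).tiny)

    def quantile_resp():
        qs = np.quantile(X[:, 0], np.linspace(0, 1, K + 1)[1:-1])
        lab = np.searchsorted(qs, X[:, 0], side="right")
        resp = np.full((n, K), 0.05 / max(K - 1, 1))
        resp[np.arange(n), lab] = 0.95
        return resp

    def random_resp():
        resp = rng.random((n, K)) + 1e-3
        return resp / resp.sum(axis=1, keepdims=True)

    best = None
    n_failed = 0
    for s in range(max(1, n_starts)):
        resp0 = quantile_resp() if s == 0 else random_resp()
        for reg in (base_reg, 1e3 * base_reg):
            try:
                out = _em_run(X, K, family, resp0, tol, max_iter, reg)
                break
            except (np.linalg.LinAlgError, FloatingPointError):
                log.warning("EM start %d failed; retrying with stronger "
                            "regularisation", s)
                out = None
        if out is None:
            n_failed += 1
            continue
        if best is None or out[3] > best[3]:
            best = out
    if best is None:
        raise RuntimeError(f"all {n_starts} EM restarts failed")

    weights, means, covs, ll, n_iter, converged = best
    order = np.argsort(means[:, 0], kind="stable")
    weights, means, covs = weights[order], means[order], covs[order]
    fit = MixtureFit(K=K, family=family, weights=weights, means=means,
                     covariances=covs, log_likelihood=ll, n_iter=n_iter,
                     converged=converged, seed=seed)
    if K == 2:
        fit.component_order = {"low": 0, "high": 1}
    else:
        fit.component_order = {f"c{k}": k for k in range(K)}
        fit.component_order["low"] = 0
    return fit


def compare_k_bic(X, ks=(1, 2), family: str = "full", seed: int = 0) -> dict:
    """BIC for each candidate component count (reported, not decided)."""
    return {k: fit_gaussian_mixture(X, K=k, family=family, seed=seed).bic(X)
            for k in ks}


# --------------------------------------------------------------------------
# assignment and fractions
# --------------------------------------------------------------------------

LABEL_LOW = "low"
LABEL_HIGH = "high"
LABEL_UNASSIGNED = "unassigned"


def assign_subpopulations(fit: MixtureFit, X, mode: str = "hard",
                          threshold: float = DEFAULT_CONFIDENCE
                          ) -> pd.DataFrame:
    """Posterior-based assignment of events under a (possibly frozen) fit.

    ``fit`` may come from a different condition or timepoint than ``X``;
    classifying under a frozen reference fit is the transfer mechanism that
    generalises one reference clustering to a whole time course.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != fit.d:
        raise ValueError(
            f"event matrix has d={X.shape[1]} but fit has d={fit.d}")
    if mode not in ("hard", "confidence"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    if mode == "confidence" and not (0.5 < threshold <= 1.0):
        raise ValueError("confidence threshold must be in (0.5, 1]")

    lp, _ = _log_prob(X, fit.weights, fit.means, fit.covariances)
    post = np.exp(lp - logsumexp(lp, axis=1)[:, None])
    conf = post.max(axis=1)
    arg = post.argmax(axis=1)

    idx_to_label = {v: k for k, v in fit.component_order.items()
                    if k in (LABEL_LOW, LABEL_HIGH)}
    labels = np.array([idx_to_label.get(a, f"c{a}") for a in arg], dtype=object)
    if mode == "confidence":
        labels[conf < threshold] = LABEL_UNASSIGNED

    out = pd.DataFrame({"event_id": np.arange(X.shape[0])})
    for name, k in sorted(fit.component_order.items(), key=lambda kv: kv[1]):
        out[f"posterior_{name}"] = post[:, k]
    out["hard_label"] = labels
    out["confidence"] = conf
    return out


@dataclass
class HeterogeneitySummary:
    """Per-replicate low/high fractions with their mean and SEM."""

    per_replicate: pd.DataFrame   # replicate, frac_low, frac_high,
    #                               frac_unassigned, n_assigned
    fraction_mean: float          # mean of frac_low across replicates
    fraction_sem: float
    cv: float | None = None


def subpopulation_fractions(assignments: pd.DataFrame,
                            replicate: str | pd.Series | None = "replicate"
                            ) -> HeterogeneitySummary:
    """Low-subpopulation fraction per replicate, with mean and SEM.

    Unassigned events are excluded from the denominator but reported as a
    fraction of all events in the replicate.
    """
    df = assignments.copy()
    if replicate is None:
        df["_rep"] = "all"
    elif isinstance(replicate, str):
        if replicate not in df.columns:
            raise ValueError(f"no replicate column {replicate!r}")
        df["_rep"] = df[replicate]
    else:
        df["_rep"] = np.asarray(replicate)

    rows = []
    for rep, grp in df.groupby("_rep", sort=True):
        n_low = int((grp["hard_label"] == LABEL_LOW).sum())
        n_high = int((grp["hard_label"] == LABEL_HIGH).sum())
        n_un = int((grp["hard_label"] == LABEL_UNASSIGNED).sum())
        if n_low + n_high == 0:
            log.warning("replicate %r has zero assigned events; excluded", rep)
            continue
        rows.append({
            "replicate": rep,
            "frac_low": n_low / (n_low + n_high),
            "frac_high": n_high / (n_low + n_high),
            "frac_unassigned": n_un / len(grp),
            "n_assigned": n_low + n_high,
        })
    if not rows:
        raise ValueError("no replicate with assigned events")
    per_rep = pd.DataFrame(rows)
    fracs = per_rep["frac_low"].to_numpy()
    mean = float(fracs.mean())
    sem = float(fracs.std(ddof=1) / np.sqrt(len(fracs))) if len(fracs) > 1 \
        else float("nan")
    return HeterogeneitySummary(per_replicate=per_rep, fraction_mean=mean,
                                fraction_sem=sem)


# --------------------------------------------------------------------------
# dip test
# --------------------------------------------------------------------------

@dataclass
class BimodalityResult:
    """Dip statistic with its Monte-Carlo p-value."""

    dip: float
    p_value: float
    n: int
    n_null: int
    seed: int


def dip_test(x, n_null: int = DEFAULT_N_NULL, seed: int = 0
             ) -> BimodalityResult:
    """Hartigan dip test with seeded Monte-Carlo uniform null.

    The p-value is the continuity-corrected tail frequency
    ``(1 + #{dip_null >= dip_obs}) / (n_null + 1)`` over ``n_null`` uniform
    samples of the same size.  ``n_null = 0`` skips the null (p is NaN),
    useful when only the bimodality score is needed.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("dip test requires at least 4 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip test requires finite values")
    n = int(x.size)
    if np.all(x == x[0]):
        log.warning("constant sample: dip = 1/(2n), p = 1 by convention")
        return BimodalityResult(dip=1.0 / (2 * n), p_value=1.0, n=n,
                                n_null=n_null, seed=seed)
    obs = dip_stat(x)
    if n_null <= 0:
        return BimodalityResult(dip=obs, p_value=float("nan"), n=n,
                                n_null=0, seed=seed)
    rng = np.random.default_rng(seed)
    # chunk the null to bound memory at large n
    chunk = max(1, min(n_null, int(2e7) // n))
    n_ge = 0
    remaining = n_null
    while remaining > 0:
        m = min(chunk, remaining)
        nulls = dip_stat_many(rng.random((m, n)))
        n_ge += int(np.sum(nulls >= obs))
        remaining -= m
    p = (1.0 + n_ge) / (n_null + 1.0)
    return BimodalityResult(dip=obs, p_value=p, n=n, n_null=n_null, seed=seed)
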