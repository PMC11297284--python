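"""Transcription-factor nuclear-localisation scoring from microscopy.

Input is a multi-channel field (brightfield/BFP/GFP/RFP) plus a per-cell
label mask from an external segmenter; segmentation itself is never
computed here.  Per cell, the nucleus is found in the BFP
(nuclear-localisation tag) channel inside the cell's bounding box: Gaussian
blur (sigma = 1 px), threshold at the top 15% brightest pixels, one binary
erosion and one dilation with a 3x3 cross to remove isolated islands, then
the largest 4-connected component.  The TF nuclear intensity is the mean
GFP over that mask.  Mis-segmented cells are filtered as low-density
outliers of the (cell size, mean RFP) scatter under a linear-kernel KDE,
and cells are assigned to subpopulations by EM on the same two features
with a confidence threshold (default 0.85).

Pixel coordinates are 0-based row-major; bounding boxes are half-open
``[r0, r1) x [c0, c1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.neighbors import KernelDensity

from . import flow

log = logging.getLogger(__name__)

DEFAULT_PERCENTILE = 0.15
DEFAULT_DROP_FRACTION = 0.05
DEFAULT_CONFIDENCE = 0.85
_CROSS = ndimage.generate_binary_structure(2, 1)   # 3x3 cross


# --------------------------------------------------------------------------
# IO
# --------------------------------------------------------------------------

def read_field_tiff(image_path, mask_path):
    """Read a multi-page channel TIFF and its 16-bit label-mask TIFF."""
    import tifffile

    image = tifffile.imread(image_path).astype(np.float64)
    labels = tifffile.imread(mask_path).astype(np.int32)
    if image.ndim != 3:
        raise ValueError("expected a (channels, rows, cols) image stack")
    if image.shape[1:] != labels.shape:
        raise ValueError("image and label mask shapes disagree")
    return image, labels


# --------------------------------------------------------------------------
# nucleus segmentation and intensity
# --------------------------------------------------------------------------

def segment_nucleus(bfp_patch: np.ndarray,
                    percentile: float = DEFAULT_PERCENTILE) -> np.ndarray:
    """Nuclear mask from a BFP bounding-box patch.

    Blur (sigma = 1), keep the top ``percentile`` brightest pixels, open
    with a 3x3 cross (one erosion, one dilation), keep the largest
    4-connected component.  Returns a possibly-empty boolean mask; the
    output is invariant to adding a constant to the patch.
    """
    patch = np.asarray(bfp_patch, dtype=float)
    if patch.ndim != 2 or min(patch.shape) < 4:
        raise ValueError("patch must be 2-D and at least 4x4 px")
    if not (0.0 < percentile < 1.0):
        raise ValueError("percentile must be in (0, 1)")
    blurred = ndimage.gaussian_filter(patch, sigma=1.0)
    thresh = np.quantile(blurred, 1.0 - percentile)
    mask = blurred >= thresh
    mask = ndimage.binary_erosion(mask, structure=_CROSS)
    mask = ndimage.binary_dilation(mask, structure=_CROSS)
    if not mask.any():
        return mask
    comp, n_comp = ndimage.label(mask, structure=_CROSS)
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n_comp + 1))
        mask = comp == (1 + int(np.argmax(sizes)))
    return mask


def nuclear_intensity(gfp_patch: np.ndarray, mask: np.ndarray) -> float:
    """Mean GFP over the nuclear mask."""
    gfp_patch = np.asarray(gfp_patch, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != gfp_patch.shape:
        raise ValueError("mask and patch shapes disagree")
    if not mask.any():
        raise ValueError("empty nuclear mask")
    return float(gfp_patch[mask].mean())


# --------------------------------------------------------------------------
# per-field cell measurement
# --------------------------------------------------------------------------

@dataclass
class FieldQC:
    """Dropped-cell accounting for one field."""

    cells_in: int
    empty_mask_drops: int
    small_drops: int

    @property
    def cells_out(self) -> int:
        return self.cells_in - self.empty_mask_drops - self.small_drops


def measure_cells(image: np.ndarray, labels: np.ndarray,
                  channel_order=("brightfield", "bfp", "gfp", "rfp"),
                  percentile: float = DEFAULT_PERCENTILE,
                  min_area_px: int = 4,
                  field_id: str = "f0") -> tuple[pd.DataFrame, FieldQC]:
    """Per-cell area, mean RFP and mean nuclear GFP from one field.

    Cells with an empty post-morphology nuclear mask or area below
    ``min_area_px`` are dropped and counted in the QC record.
    """
    if image.ndim != 3 or image.shape[0] != len(channel_order):
        raise ValueError("image must be (channels, rows, cols) matching "
                         "channel_order")
    ci = {name: i for i, name in enumerate(channel_order)}
    for need in ("bfp", "gfp", "rfp"):
        if need not in ci:
            raise ValueError(f"channel_order lacks {need!r}")
    bfp, gfp, rfp = image[ci["bfp"]], image[ci["gfp"]], image[ci["rfp"]]

    objects = ndimage.find_objects(labels)
    rows = []
    empty_drops = 0
    small_drops = 0
    n_in = 0
    for cid, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        n_in += 1
        cell = labels[sl] == cid
        area = int(cell.sum())
        if area < min_area_px:
            small_drops += 1
            continue
        # tight bounding box of the segmented cell
        r0, r1 = sl[0].start, sl[0].stop
        c0, c1 = sl[1].start, sl[1].stop
        mask = segment_nucleus(bfp[r0:r1, c0:c1], percentile=percentile)
        if not mask.any():
            empty_drops += 1
            continue
        rows.append({
            "cell_id": cid,
            "field_id": field_id,
            "area_px": area,
            "bbox_r0": r0, "bbox_r1": r1, "bbox_c0": c0, "bbox_c1": c1,
            "mean_rfp": float(rfp[sl][cell].mean()),
            "nucleus_px": int(mask.sum()),
            "mean_nuclear_gfp": nuclear_intensity(gfp[r0:r1, c0:c1], mask),
        })
    if empty_drops:
        log.warning("field %s: %d cells dropped with empty nuclear mask",
                    field_id, empty_drops)
    qc = FieldQC(cells_in=n_in, empty_mask_drops=empty_drops,
                 small_drops=small_drops)
    return pd.DataFrame(rows), qc


# --------------------------------------------------------------------------
# outlier filtering and assignment
# --------------------------------------------------------------------------

def filter_outliers_kde(cells: pd.DataFrame,
                        drop_fraction: float = DEFAULT_DROP_FRACTION,
                        features=("area_px", "mean_rfp")) -> pd.DataFrame:
    """Drop the lowest-density ``floor(drop_fraction * n)`` cells.

    Density is a linear (triangular) kernel KDE with bandwidth 1 on the
    z-scored feature scatter — mis-segmentations sit far from the main
    clusters and receive near-zero density.
    """
    n = len(cells)
    if n < 20:
        raise ValueError("need at least 20 cells for outlier filtering")
    if not (0.0 <= drop_fraction < 0.5):
        raise ValueError("drop_fraction must be in [0, 0.5)")
    n_drop = int(np.floor(drop_fraction * n))
    if n_drop == 0:
        return cells
    X = cells.loc[:, features].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    kde = KernelDensity(kernel="linear", bandwidth=1.0, metric="euclidean",
                        algorithm="ball_tree").fit(X)
    density = kde.score_samples(X)
    drop_idx = np.argsort(density, kind="stable")[:n_drop]
    keep = np.ones(n, dtype=bool)
    keep[drop_idx] = False
    return cells.loc[keep]


def assign_cells(cells: pd.DataFrame, fit: flow.MixtureFit | None = None,
                 confidence: float = DEFAULT_CONFIDENCE,
                 features=("area_px", "mean_rfp"), seed: int = 0
                 ) -> tuple[pd.DataFrame, flow.MixtureFit]:
    """EM subpopulation assignment on (cell size, marker) with confidence.

    A fresh 2-component full-covariance mixture is fitted unless a frozen
    reference ``fit`` is supplied; labels below the confidence threshold
    are 'unassigned'.  Returns the cells with ``subpop``/``confidence``
    columns plus the fit used.
    """
    X = cells.loc[:, features].to_numpy(dtype=float)
    if fit is None:
        fit = flow.fit_gaussian_mixture(X, K=2, family="full", seed=seed)
    assign = flow.assign_subpopulations(fit, X, mode="confidence",
                                        threshold=confidence)
    out = cells.copy()
    out["subpop"] = assign["hard_label"].to_numpy()
    out["confidence"] = assign["confidence"].to_numpy()
    return out, fit


# --------------------------------------------------------------------------
# TF score tables
# --------------------------------------------------------------------------

def tf_score_table(cells: pd.DataFrame,
                   group_cols=("tf", "timepoint_min", "condition")
                   ) -> pd.DataFrame:
    """Subpopulation and condition TF scores from assigned single cells.

    The subpopulation score is the mean single-cell nuclear intensity; the
    condition score is the unweighted mean of the available subpopulation
    scores (cell counts do not weight it).  Groups with only unassigned
    cells yield a NaN-score row.
    """
    need = set(group_cols) | {"subpop", "mean_nuclear_gfp"}
    missing = need - set(cells.columns)
    if missing:
        raise ValueError(f"cells table lacks columns {sorted(missing)}")
    rows = []
    for key, grp in cells.groupby(list(group_cols), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        sub_scores = {}
        for subpop in (flow.LABEL_LOW, flow.LABEL_HIGH):
            sel = grp[grp["subpop"] == subpop]
            if len(sel):
                score = float(sel["mean_nuclear_gfp"].mean())
                sub_scores[subpop] = score
                rows.append(dict(zip(group_cols, key), subpop=subpop,
                                 score=score, n_cells=len(sel)))
        n_un = int((grp["subpop"] == flow.LABEL_UNASSIGNED).sum())
        if sub_scores:
            cond = float(np.mean(list(sub_scores.values())))
            rows.append(dict(zip(group_cols, key), subpop="all", score=cond,
                             n_cells=len(grp) - n_un,
                             only_one_subpop=len(sub_scores) == 1))
        else:
            log.warning("group %s has only unassigned cells", key)
            rows.append(dict(zip(group_cols, key), subpop="all",
                             score=float("nan"), n_cells=0,
                             only_one_subpop=False))
    return pd.DataFrame(rows)


def relative_tf_scores(scores: pd.Series) -> pd.Series:
    """Scores normalised by the mean of the mid-ranked TFs.

    The normaliser is the mean of all TF scores excluding the 5 largest
    and the 5 smallest at the timepoint (single pass, no re-ranking after
    exclusion); at least 12 TFs are required so the normaliser is
    non-empty.  Relative scores are invariant to rescaling all scores.
    """
    scores = scores.astype(float)
    if len(scores) < 12:
        raise ValueError("need at least 12 TFs for relative scores")
    if scores.isna().any():
        raise ValueError("scores contain NaN")
    order = np.argsort(scores.to_numpy(), kind="stable")
    mid = order[5:-5]
    normaliser = float(scores.to_numpy()[mid].mean())
    if normaliser <= 0:
        raise ValueError("non-positive normaliser")
    return scores / normaliser


def differential_localisation(group_a, group_b) -> dict:
    """Welch two-sided t test between single-cell nuclear intensities.

    Returns ``{'t', 'p', 'effect'}`` with effect = mean(a) - mean(b).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 cells per group")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        return {"t": 0.0, "p": 1.0, "effect": 0.0}
    from scipy.stats import ttest_ind

    res = ttest_ind(a, b, equal_var=False)
    return {"t": float(res.statistic), "p": float(res.pvalue),
            "effect": float(a.mean() - b.mean())}
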