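"""Fast two-marker classification from single-wavenumber SRS frames.

Four registered frames — 2850 and 2930 cm^-1 (CH2/CH3 stretches), 2222
cm^-1 (alkyne reporter of the MitoBADY mitochondrial probe) and 2100
cm^-1 (off-resonance background) — yield two per-cell markers:

* lipid-to-protein ratio ``I2850 / (I2850 + I2930)``, median over the
  cell, normalised to cell area (um^2): membrane remodelling marker;
* background-subtracted probe signal ``max(I2222 - I2100, 0)``, median
  over the cytoplasm, normalised to cytoplasm area: mitochondrial
  membrane-potential marker.

Per-marker ROC analysis (positive class = erythroid precursor = high
values) selects Youden-J thresholds, and cells are called by quadrant:
both markers above threshold -> precursor, both below ->
erythrocyte-like, mixed -> indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label

from .chemometrics import ROCResult, roc

__all__ = [
    "FrameSet",
    "ThresholdPair",
    "ratio_map",
    "probe_map",
    "segment_cells",
    "per_cell_markers",
    "calibrate_thresholds",
    "classify_quadrant",
]

CLASS_PRECURSOR = "precursor"
CLASS_ERYTHRO = "erythrocyte_like"
CLASS_INDET = "indeterminate"


@dataclass
class FrameSet:
    """Registered single-wavenumber SRS frames (same shape, non-negative)."""

    f2850: np.ndarray
    f2930: np.ndarray
    f2222: np.ndarray
    f2100: np.ndarray
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        frames = [self.f2850, self.f2930, self.f2222, self.f2100]
        shapes = {np.asarray(f).shape for f in frames}
        if len(shapes) != 1:
            raise ValueError("frames must share one shape")
        for f in frames:
            if np.any(np.asarray(f) < 0):
                raise ValueError("frame intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return np.asarray(self.f2850).shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ThresholdPair:
    """Quadrant thresholds for the two markers.

    ``provenance`` records whether the pair came from ROC calibration on
    labelled data or was supplied as fixed values (e.g. thresholds
    published for another instrument, which are instrument-specific).
    """

    mb_threshold: float
    lp_threshold: float
    provenance: str = "calibrated"       # calibrated | fixed
    roc_mb: ROCResult | None = None
    roc_lp: ROCResult | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mb_threshold) and np.isfinite(self.lp_threshold)):
            raise ValueError("thresholds must be finite")
        if self.provenance not in ("calibrated", "fixed"):
            raise ValueError("provenance must be 'calibrated' or 'fixed'")


def ratio_map(frame_2850: np.ndarray, frame_2930: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel lipid-to-protein ratio r = I2850 / (I2850 + I2930).

    Returns ``(ratio, valid)``; pixels with a zero denominator are invalid
    and carry ratio 0.  Valid ratios lie in [0, 1].
    """
    a = np.asarray(frame_2850, dtype=float)
    b = np.asarray(frame_2930, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must share one shape")
    denom = a + b
    valid = denom != 0
    ratio = np.zeros_like(a)
    np.divide(a, denom, out=ratio, where=valid)
    return ratio, valid


def probe_map(frame_2222: np.ndarray, frame_2100: np.ndarray) -> np.ndarray:
    """Background-subtracted probe image p = max(I2222 - I2100, 0).

    The off-resonance frame carries no probe band, so subtracting it
    removes the shared background; negative differences are noise and are
    clipped to zero (the probe signal is physically non-negative).
    """
    a = np.asarray(frame_2222, dtype=float)
    b = np.asarray(frame_2100, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must share one shape")
    return np.clip(a - b, 0.0, None)


def segment_cells(frameset: FrameSet, smooth_sigma: float = 1.5,
                  min_size: int = 60, nucleus_quantile: float = 25.0
                  ) -> tuple[list[dict], dict]:
    """Segment cells and their cytoplasm from the protein (2930) frame.

    Cells: Gaussian-smoothed 2930 frame, Otsu threshold, hole filling,
    connected components, minimum-size filter.  The nucleus proxy inside
    each cell is the low lipid-to-protein-ratio core (ratio below the
    ``nucleus_quantile``-th in-cell percentile, largest connected blob);
    cytoplasm = cell minus nucleus proxy.  The rule is recorded in the
    returned metadata.  Zero cells found is not an error — an empty list
    is returned.
    """
    smoothed = gaussian(np.asarray(frameset.f2930, float),
                        sigma=smooth_sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        return [], {"rule": "otsu(2930)", "note": "blank frame"}
    thr = threshold_otsu(smoothed)
    fg = smoothed > thr
    fg = ndimage.binary_fill_holes(fg)
    lab = cc_label(fg)
    sizes = np.bincount(lab.ravel())
    for small_id in np.flatnonzero(sizes < min_size):
        if small_id:
            fg[lab == small_id] = False
    lab = cc_label(fg)
    ratio, _ = ratio_map(frameset.f2850, frameset.f2930)
    ratio_s = gaussian(ratio, sigma=smooth_sigma, preserve_range=True)
    cells: list[dict] = []
    for cid in range(1, lab.max() + 1):
        cell = lab == cid
        cut = np.percentile(ratio_s[cell], nucleus_quantile)
        core = cell & (ratio_s <= cut)
        core_lab = cc_label(core)
        if core_lab.max() > 0:
            sizes = ndimage.sum_labels(np.ones_like(core_lab), core_lab,
                                       range(1, core_lab.max() + 1))
            nucleus = core_lab == (1 + int(np.argmax(sizes)))
        else:
            nucleus = np.zeros_like(cell)
        cytoplasm = cell & ~nucleus
        cells.append({"id": cid, "cell": cell, "nucleus": nucleus,
                      "cytoplasm": cytoplasm})
    meta = {
        "rule": "cells: otsu(gauss(2930)) + fill + min_size; "
                "nucleus proxy: low 2850/(2850+2930) core; "
                "cytoplasm = cell - nucleus",
        "otsu_threshold": float(thr),
        "smooth_sigma": smooth_sigma,
        "min_size": min_size,
        "nucleus_quantile": nucleus_quantile,
    }
    if not cells:
        import warnings

        warnings.warn("no cells found", stacklevel=2)
    return cells, meta


def per_cell_markers(ratio: np.ndarray, probe: np.ndarray,
                     cells: Sequence[dict], pixel_size_um: float,
                     ratio_valid: np.ndarray | None = None) -> pd.DataFrame:
    """Per-cell marker table.

    ``lp_per_area`` = median in-cell ratio / cell area (um^2);
    ``mb_per_area`` = median cytoplasmic probe signal / cytoplasm area.
    Invalid ratio pixels are excluded from the median; cells with an empty
    cytoplasm are dropped with a warning.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    px_area = pixel_size_um**2
    valid = np.ones_like(np.asarray(ratio), dtype=bool) \
        if ratio_valid is None else np.asarray(ratio_valid, bool)
    rows = []
    for cell in cells:
        cmask, cyto = cell["cell"], cell["cytoplasm"]
        if not cyto.any():
            import warnings

            warnings.warn(f"cell {cell['id']} has empty cytoplasm; dropped",
                          stacklevel=2)
            continue
        cell_area = float(cmask.sum()) * px_area
        cyto_area = float(cyto.sum()) * px_area
        rmask = cmask & valid
        lp = float(np.median(ratio[rmask])) / cell_area if rmask.any() \
            else np.nan
        mb = float(np.median(probe[cyto])) / cyto_area
        rows.append({
            "cell_id": cell["id"], "cell_area_um2": cell_area,
            "cytoplasm_area_um2": cyto_area, "lp_per_area": lp,
            "mb_per_area": mb, "call": "",
        })
    return pd.DataFrame(rows, columns=[
        "cell_id", "cell_area_um2", "cytoplasm_area_um2",
        "lp_per_area", "mb_per_area", "call",
    ])


def calibrate_thresholds(marker_table: pd.DataFrame,
                         labels: Sequence[str]) -> ThresholdPair:
    """ROC-calibrate the quadrant thresholds on a labelled cohort.

    One ROC per marker with direction "precursor = high"; thresholds at
    maximal Youden's J.  Requires both classes with n >= 5 each.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError("calibration needs both classes")
    if counts.min() < 5:
        raise ValueError("calibration needs n >= 5 per class")
    # +1 for precursor (the high class), -1 otherwise
    y = np.where(labels == CLASS_PRECURSOR, 1, -1)
    roc_lp = roc(marker_table["lp_per_area"].to_numpy(), y, "greater")
    roc_mb = roc(marker_table["mb_per_area"].to_numpy(), y, "greater")
    return ThresholdPair(
        mb_threshold=roc_mb.threshold, lp_threshold=roc_lp.threshold,
        provenance="calibrated", roc_mb=roc_mb, roc_lp=roc_lp,
    )


def classify_quadrant(marker_table: pd.DataFrame,
                      thresholds: ThresholdPair) -> pd.DataFrame:
    """Quadrant class calls: both markers above threshold -> precursor,
    both below -> erythrocyte-like, mixed quadrants -> indeterminate,
    missing marker values -> flagged unclassified."""
    out = marker_table.copy()
    calls = []
    for _, row in out.iterrows():
        lp, mb = row["lp_per_area"], row["mb_per_area"]
        if not (np.isfinite(lp) and np.isfinite(mb)):
            calls.append("unclassified")
            continue
        hi_lp = lp > thresholds.lp_threshold
        hi_mb = mb > thresholds.mb_threshold
        if hi_lp and hi_mb:
            calls.append(CLASS_PRECURSOR)
        elif not hi_lp and not hi_mb:
            calls.append(CLASS_ERYTHRO)
        else:
            calls.append(CLASS_INDET)
    out["call"] = calls
    return out
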