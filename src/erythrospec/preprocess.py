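"""Spectrum conditioning: despiking, baseline correction, normalization,
cropping, per-cell averaging.

The pipeline order is fixed — despike, baseline, crop, normalize — because
normalization before baseline removal would couple the baseline magnitude
into every downstream scale.  :class:`PreprocessConfig` enforces this by
construction (it exposes no ordering knob).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.ndimage import median_filter
from scipy.sparse.linalg import spsolve

from .core import HSImage, SpectralAxis

__all__ = [
    "PreprocessConfig",
    "remove_spikes",
    "baseline_asls",
    "baseline_polynomial",
    "baseline_correct",
    "normalize",
    "mean_cell_spectrum",
    "preprocess_spectrum",
]

# Label-free models exclude the cell-silent region; probe analyses crop to
# the alkyne window instead.
LABEL_FREE_CROP = [(600.0, 1800.0), (2800.0, 3100.0)]
PROBE_CROP = [(2150.0, 2300.0)]


@dataclass(frozen=True)
class PreprocessConfig:
    despike_window: int = 7
    despike_z: float = 8.0
    baseline_method: str = "asls"        # asls | polynomial | none
    asls_lambda: float = 1e5
    asls_p: float = 0.01
    asls_max_iter: int = 20
    poly_order: int = 3
    norm: str = "vector"                 # vector | area | none
    crop: tuple[tuple[float, float], ...] = tuple(LABEL_FREE_CROP)

    def __post_init__(self) -> None:
        if self.despike_window < 3 or self.despike_window % 2 == 0:
            raise ValueError("despike_window must be odd and >= 3")
        if not 0.0 < self.asls_p < 1.0:
            raise ValueError("asls_p must lie in (0, 1)")
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")
        if self.baseline_method not in ("asls", "polynomial", "none"):
            raise ValueError(f"unknown baseline method {self.baseline_method!r}")
        if self.norm not in ("vector", "area", "none"):
            raise ValueError(f"unknown norm mode {self.norm!r}")


def remove_spikes(spectrum: np.ndarray, window: int = 7,
                  z: float = 8.0) -> np.ndarray:
    """Replace cosmic-ray-like outliers by the local rolling median.

    A channel is flagged when its deviation from the rolling median,
    studentized by the robust (MAD) scale of all deviations, exceeds ``z``.
    When the robust scale is exactly zero (e.g. a flat spectrum with one
    delta) any non-zero deviation is a spike.
    """
    y = np.asarray(spectrum, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window >= y.size:
        raise ValueError("window must be smaller than the spectrum")
    med = median_filter(y, size=window, mode="nearest")
    resid = y - med
    scale = 1.4826 * np.median(np.abs(resid))
    if scale == 0.0:
        spikes = resid != 0.0
    else:
        spikes = np.abs(resid) > z * scale
    out = y.copy()
    out[spikes] = med[spikes]
    return out


def baseline_asls(spectrum: np.ndarray, lam: float = 1e5, p: float = 0.01,
                  max_iter: int = 20, tol: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Asymmetric least squares baseline (Whittaker smoother with
    asymmetric weights: points above the baseline get weight ``p``, points
    below get ``1 - p``).  Returns (baseline, converged)."""
    y = np.asarray(spectrum, dtype=float)
    n = y.size
    D = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    DTD = lam * (D @ D.T)
    w = np.ones(n)
    z = y.copy()
    converged = False
    for _ in range(max_iter):
        W = sparse.diags(w)
        z_new = spsolve((W + DTD).tocsc(), w * y)
        w_new = np.where(y > z_new, p, 1.0 - p)
        if np.array_equal(w_new, w) or np.max(np.abs(z_new - z)) < tol * max(
                1.0, np.max(np.abs(y))):
            z = z_new
            converged = True
            break
        z, w = z_new, w_new
    return z, converged


def baseline_polynomial(spectrum: np.ndarray, axis: SpectralAxis | np.ndarray,
                        order: int = 3) -> np.ndarray:
    wn = axis.values if isinstance(axis, SpectralAxis) else np.asarray(axis)
    y = np.asarray(spectrum, dtype=float)
    # centre the abscissa for conditioning
    span = float(np.ptp(wn))
    x = (wn - wn.mean()) / (span / 2 if span else 1.0)
    coeffs = np.polynomial.polynomial.polyfit(x, y, order)
    return np.polynomial.polynomial.polyval(x, coeffs)


def baseline_correct(
    spectrum: np.ndarray,
    config: PreprocessConfig = PreprocessConfig(),
    axis: SpectralAxis | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate and subtract a smooth baseline.

    Returns ``(corrected, baseline)`` with ``corrected + baseline`` equal
    to the input exactly.  Non-convergence of AsLS is reported via a
    ``RuntimeWarning`` carrying the residual, never an exception.
    """
    y = np.asarray(spectrum, dtype=float)
    if config.baseline_method == "none":
        baseline = np.zeros_like(y)
    elif config.baseline_method == "polynomial":
        if axis is None:
            axis = np.arange(y.size, dtype=float)
        baseline = baseline_polynomial(y, axis, config.poly_order)
    else:
        baseline, converged = baseline_asls(
            y, config.asls_lambda, config.asls_p, config.asls_max_iter)
        if not converged:
            import warnings

            resid = float(np.max(np.abs(y - baseline)))
            warnings.warn(
                f"AsLS did not converge in {config.asls_max_iter} iterations "
                f"(max |residual| = {resid:.3g})", RuntimeWarning, stacklevel=2)
    return y - baseline, baseline


def normalize(spectrum: np.ndarray, mode: str = "vector",
              axis: SpectralAxis | np.ndarray | None = None) -> np.ndarray:
    """Scale a spectrum: unit Euclidean norm, unit trapezoid area, or none."""
    y = np.asarray(spectrum, dtype=float)
    if mode == "none":
        return y.copy()
    if mode == "vector":
        nrm = float(np.linalg.norm(y))
        if nrm == 0.0:
            raise ValueError("cannot vector-normalize an all-zero spectrum")
        return y / nrm
    if mode == "area":
        x = axis.values if isinstance(axis, SpectralAxis) else (
            np.asarray(axis) if axis is not None else np.arange(y.size))
        area = float(np.trapezoid(y, x))
        if area == 0.0:
            raise ValueError("cannot area-normalize a zero-area spectrum")
        return y / area
    raise ValueError(f"unknown norm mode {mode!r}")


def mean_cell_spectrum(cube: HSImage | np.ndarray,
                       cell_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and SD over the masked pixels of a cube."""
    data = cube.data if isinstance(cube, HSImage) else np.asarray(cube)
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.shape != data.shape[:2]:
        raise ValueError("mask shape does not match cube")
    if not mask.any():
        raise ValueError("empty cell mask")
    pix = data[mask]
    return pix.mean(axis=0), pix.std(axis=0)


def preprocess_spectrum(
    spectrum: np.ndarray,
    axis: SpectralAxis,
    config: PreprocessConfig = PreprocessConfig(),
) -> tuple[np.ndarray, SpectralAxis]:
    """Full conditioning chain: despike -> baseline -> crop -> normalize."""
    y = remove_spikes(spectrum, config.despike_window, config.despike_z)
    y, _ = baseline_correct(y, config, axis)
    if config.crop:
        mask = np.zeros(len(axis), dtype=bool)
        for lo, hi in config.crop:
            mask |= axis.window(lo, hi)
        if mask.sum() < 2:
            raise ValueError("crop leaves fewer than 2 channels")
        y = y[mask]
        axis = SpectralAxis(axis.values[mask])
    y = normalize(y, config.norm, axis)
    return y, axis
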