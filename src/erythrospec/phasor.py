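"""Spectral phasor transform and phasor-plane segmentation.

The spectral phasor maps each pixel's spectrum to its first (or n-th)
normalised Fourier coefficient:

    G = sum_k I_k cos(2 pi n k / N) / sum_k I_k
    S = sum_k I_k sin(2 pi n k / N) / sum_k I_k

For non-negative spectra the point (G, S) lies inside the unit circle, is
invariant to intensity scaling, and is *linear* under spectral mixing —
the phasor of a mixture lies on the segment joining the component
phasors, at the intensity-weighted position.  Those three properties make
the phasor plane a natural space for fast unsupervised segmentation of
hyperspectral SRS stacks into subcellular regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .core import HSImage, SpectralAxis

__all__ = ["PhasorMap", "RegionSegmentation", "spectral_phasor",
           "phasor_segment"]

REGION_NAMES = ("nucleus", "cytoplasm", "intermediate")
BACKGROUND = "background"


@dataclass
class PhasorMap:
    G: np.ndarray
    S: np.ndarray
    intensity: np.ndarray
    valid_mask: np.ndarray
    harmonic: int = 1


@dataclass
class RegionSegmentation:
    """Label image over {nucleus, cytoplasm, intermediate, background}."""

    labels: np.ndarray               # integer codes
    code_to_name: dict[int, str]
    centers: np.ndarray              # cluster centers in (G, S)
    assignment_rule: dict = field(default_factory=dict)

    def mask(self, name: str) -> np.ndarray:
        codes = [c for c, n in self.code_to_name.items() if n == name]
        return np.isin(self.labels, codes)


def spectral_phasor(cube: HSImage | np.ndarray, harmonic: int = 1,
                    intensity_floor_frac: float = 0.01) -> PhasorMap:
    """Per-pixel spectral phasor coordinates of a cube.

    Pixels whose total intensity falls below ``intensity_floor_frac`` times
    the image maximum (including all-zero pixels) are flagged invalid and
    carry (G, S) = (0, 0) rather than raising.
    """
    data = cube.data if isinstance(cube, HSImage) else np.asarray(cube, float)
    n_chan = data.shape[-1]
    if n_chan < 3:
        raise ValueError("phasor needs at least 3 channels")
    if not 1 <= harmonic < n_chan / 2:
        raise ValueError("harmonic must satisfy 1 <= n < channels/2")
    k = np.arange(n_chan)
    ang = 2.0 * np.pi * harmonic * k / n_chan
    cosv, sinv = np.cos(ang), np.sin(ang)
    intensity = data.sum(axis=-1)
    floor = intensity_floor_frac * intensity.max() if intensity.size else 0.0
    valid = intensity > max(floor, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        G = np.where(valid, data @ cosv / np.where(valid, intensity, 1.0), 0.0)
        S = np.where(valid, data @ sinv / np.where(valid, intensity, 1.0), 0.0)
    return PhasorMap(G=G, S=S, intensity=intensity, valid_mask=valid,
                     harmonic=harmonic)


def _reference_signatures(axis: SpectralAxis) -> dict[str, np.ndarray]:
    """Reference spectra used to name clusters, rendered on ``axis``.

    Nucleus: nucleic acid/nucleoprotein CH profile; cytoplasm: protein CH3
    profile; intermediate: lipid CH2 profile.
    """
    from .synthetic import default_endmember_specs, build_endmember

    by_name = {s.name: s for s in default_endmember_specs()}
    return {
        "nucleus": build_endmember(by_name["nuclear"], axis),
        "cytoplasm": build_endmember(by_name["protein_cytoplasm"], axis),
        "intermediate": build_endmember(by_name["lipid_saturated"], axis),
    }


def phasor_segment(phasor_map: PhasorMap, n_clusters: int = 3, seed: int = 0,
                   image: HSImage | None = None,
                   n_init: int = 10) -> RegionSegmentation:
    """K-means segmentation of the phasor plane into cellular regions.

    Valid pixels are clustered on (G, S) with a fixed seed and ``n_init``
    restarts.  When the source ``image`` is provided, clusters are named
    by correlating their mean spectra against reference signatures
    (nucleus = nucleic-acid-like, cytoplasm = protein CH3-like,
    intermediate = lipid CH2-like) with a one-to-one greedy assignment;
    otherwise clusters keep generic ``region_i`` names.  Invalid pixels
    are the background region (code 0).
    """
    valid = phasor_map.valid_mask
    pts = np.column_stack([phasor_map.G[valid], phasor_map.S[valid]])
    if pts.shape[0] < n_clusters:
        raise ValueError("fewer valid pixels than clusters")
    if np.allclose(np.ptp(pts, axis=0), 0):
        raise ValueError("all phasor coordinates identical; nothing to split")
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    cluster_of_valid = km.fit_predict(pts)
    labels = np.zeros(valid.shape, dtype=int)
    labels[valid] = cluster_of_valid + 1          # 0 reserved for background

    code_to_name = {0: BACKGROUND}
    rule: dict = {"method": "kmeans(G,S)", "n_init": n_init, "seed": seed}
    if image is not None:
        refs = _reference_signatures(image.axis)
        flat = image.flatten()
        means = np.vstack([
            flat[labels.ravel() == c + 1].mean(axis=0)
            for c in range(n_clusters)
        ])
        ref_names = list(refs)
        corr = np.zeros((n_clusters, len(ref_names)))
        for i in range(n_clusters):
            for j, rn in enumerate(ref_names):
                corr[i, j] = np.corrcoef(means[i], refs[rn])[0, 1]
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(-corr)
        assigned = {int(r): ref_names[c] for r, c in zip(rows, cols)}
        for c in range(n_clusters):
            code_to_name[c + 1] = assigned.get(c, f"region_{c}")
        rule["naming"] = "reference-signature correlation"
    else:
        for c in range(n_clusters):
            code_to_name[c + 1] = f"region_{c}"
    return RegionSegmentation(labels=labels, code_to_name=code_to_name,
                              centers=km.cluster_centers_,
                              assignment_rule=rule)
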