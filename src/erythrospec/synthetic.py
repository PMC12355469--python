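"""Synthetic Raman/SRS data with known ground truth.

This module emulates the two cell populations the pipeline is built to
separate: erythroid precursors (K562-like) and doxorubicin-differentiated
erythrocyte-like cells.  It renders endmember spectra as sums of
Lorentzian/Gaussian bands at literature band positions, paints them onto
geometric cell phantoms, and adds a Poisson–Gaussian noise model, so that
every downstream operation (unmixing, classification, segmentation,
ratiometric markers) can be tested against exact ground truth.

The class contrast is encoded in the default abundance profiles:
erythrocyte-like cells carry more hemoglobin and glycogen, less
cytochrome c and nuclear material, a shift toward saturated lipids, a
weaker mitochondrial probe signal and a stronger smooth fluorescence
background in the cell-silent region (1800–2800 cm^-1).  Those
directions — not any absolute value — are what the generator guarantees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import comb

from .core import HSImage, SpectralAxis

__all__ = [
    "Band",
    "EndmemberSpec",
    "ClassProfile",
    "CellPhantom",
    "PhantomGeometry",
    "NoiseParams",
    "GroundTruth",
    "ENDMEMBER_NAMES",
    "CLASS_CODES",
    "default_endmember_specs",
    "default_class_profiles",
    "build_endmember",
    "build_library",
    "make_phantom",
    "simulate_hs_image",
    "simulate_cohort_spectra",
    "simulate_frames",
]

CLASS_CODES = {"precursor": 1, "erythrocyte_like": -1}

ENDMEMBER_NAMES = (
    "hemoglobin",
    "cytochrome_c",
    "glycogen",
    "lipid_saturated",
    "lipid_unsaturated",
    "nuclear",
    "protein_cytoplasm",
    "probe_MB",
    "baseline_fluorescence",
)

# Cell-silent window carrying the smooth fluorescence background term.
SILENT_WINDOW = (1800.0, 2800.0)


# ---------------------------------------------------------------------------
# Band and endmember rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Band:
    """A single vibrational band.

    Raman lines are near-Lorentzian, so that is the default shape; a
    Gaussian alternative is available per band.  ``amplitude`` is the peak
    height (the profile evaluates to ``amplitude`` exactly at ``center``).
    """

    center: float
    amplitude: float
    fwhm: float = 12.0
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        x = np.asarray(wavenumbers, dtype=float) - self.center
        hw = self.fwhm / 2.0
        if self.shape == "lorentzian":
            return self.amplitude * hw**2 / (x**2 + hw**2)
        return self.amplitude * np.exp(-4.0 * np.log(2.0) * x**2 / self.fwhm**2)


@dataclass(frozen=True)
class EndmemberSpec:
    """Named endmember: a list of bands plus an optional smooth background.

    The background term is a Bernstein-polynomial bump of the given order
    supported on ``baseline_window`` (default: the cell-silent region),
    normalised to peak height ``baseline_amplitude``.  It models the broad
    fluorescence pedestal that haem proteins and doxorubicin contribute.
    """

    name: str
    bands: tuple[Band, ...] = ()
    baseline_order: int = 0
    baseline_amplitude: float = 0.0
    baseline_window: tuple[float, float] = SILENT_WINDOW

    def __post_init__(self) -> None:
        if self.baseline_order < 0:
            raise ValueError("baseline_order must be >= 0")
        if self.baseline_amplitude < 0:
            raise ValueError("baseline_amplitude must be >= 0")
        if not self.bands and self.baseline_amplitude == 0.0:
            raise ValueError(
                f"endmember {self.name!r} is degenerate: no bands and no baseline"
            )


def _bernstein_bump(wn: np.ndarray, window: tuple[float, float],
                    order: int) -> np.ndarray:
    """Non-negative polynomial bump of given order on ``window``, peak 1.

    The peak sits toward the low-wavenumber end of the window (u = k/m with
    k = max(1, m // 3)): fluorescence pedestals rise toward the fingerprint
    side of the silent region and are nearly flat across the alkyne-probe
    readout pair (2100/2222 cm^-1), which is what makes off-resonance
    subtraction effective.
    """
    lo, hi = window
    u = np.clip((wn - lo) / (hi - lo), 0.0, 1.0)
    m = order
    k = max(1, m // 3) if m > 1 else 1
    b = comb(m, k) * u**k * (1.0 - u) ** (m - k)
    peak = comb(m, k) * (k / m) ** k * (1.0 - k / m) ** (m - k)
    out = np.where((wn >= lo) & (wn <= hi), b / peak, 0.0)
    return out


def build_endmember(spec: EndmemberSpec, axis: SpectralAxis) -> np.ndarray:
    """Render an endmember spectrum on ``axis``.

    The spectrum is the sum of all band profiles plus the smooth background
    term; it is non-negative by construction and has one value per channel.
    """
    wn = axis.values
    out = np.zeros(len(axis))
    for band in spec.bands:
        out += band.profile(wn)
    if spec.baseline_amplitude > 0:
        order = max(spec.baseline_order, 2)
        out += spec.baseline_amplitude * _bernstein_bump(
            wn, spec.baseline_window, order
        )
    return out


def build_library(specs: Sequence[EndmemberSpec],
                  axis: SpectralAxis) -> tuple[list[str], np.ndarray]:
    """Render a spectral library: returns (names, S) with S of shape (k, channels)."""
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("endmember names must be unique within a library")
    S = np.vstack([build_endmember(s, axis) for s in specs])
    return names, S


def _bands(pairs: Iterable[tuple[float, float]], fwhm: float = 12.0,
           shape: str = "lorentzian") -> tuple[Band, ...]:
    return tuple(Band(center=c, amplitude=a, fwhm=fwhm, shape=shape)
                 for c, a in pairs)


def default_endmember_specs() -> list[EndmemberSpec]:
    """The nine-component default library.

    Band positions follow standard cellular Raman assignments: hemoglobin
    (resonance-enhanced haem modes at 753, 1130, 1310, 1340, 1377, 1400,
    1555, 1585, 1610 cm^-1), cytochrome c (753, 1130, 1175, 1315, 1585 with
    pyrrole modes at 611/647 and amide I at 1653), glycogen (483–1460
    skeletal/CH modes), saturated and unsaturated lipids, nucleic
    acid/nucleoprotein, cytoplasmic protein with phenylalanine (1006/1040)
    and the CH3 stretch at 2930, the MitoBADY alkyne reporter at 2222, and a
    smooth silent-region fluorescence background.  Amplitudes are free,
    documented generator parameters.
    """
    return [
        EndmemberSpec("hemoglobin", _bands([
            (753, 0.9), (1130, 0.5), (1310, 0.6), (1340, 0.6), (1377, 0.8),
            (1400, 0.4), (1555, 0.7), (1585, 0.8), (1610, 1.0),
        ])),
        EndmemberSpec("cytochrome_c", _bands([
            (611, 0.25), (647, 0.25), (753, 1.0), (1130, 0.7), (1175, 0.3),
            (1315, 0.8), (1450, 0.3), (1585, 0.9), (1653, 0.35),
        ])),
        EndmemberSpec("glycogen", _bands([
            (483, 0.8), (579, 0.4), (856, 0.5), (941, 0.5), (1051, 0.4),
            (1084, 0.4), (1130, 0.4), (1337, 0.5), (1387, 0.4), (1460, 0.6),
            (2910, 0.5),
        ])),
        EndmemberSpec("lipid_saturated", _bands([
            (725, 0.2), (1075, 0.3), (1306, 0.7), (1440, 1.0), (1740, 0.3),
            (2850, 1.0), (2880, 0.7),
        ], fwhm=16.0)),
        EndmemberSpec("lipid_unsaturated", _bands([
            (1260, 0.6), (1660, 0.8), (3009, 0.5), (1440, 0.5), (2850, 0.7),
            (2880, 0.4),
        ], fwhm=16.0)),
        EndmemberSpec("nuclear", _bands([
            (789, 0.8), (1098, 0.5), (1340, 0.5), (1380, 0.4), (1490, 0.4),
            (1585, 0.5), (2876, 0.5), (2940, 0.8), (2980, 0.5),
        ])),
        EndmemberSpec("protein_cytoplasm", _bands([
            (1006, 1.0), (1040, 0.3), (1265, 0.5), (1450, 0.7), (1662, 0.9),
            (2850, 0.25), (2930, 1.0),
        ])),
        EndmemberSpec("probe_MB", _bands([(2222, 1.0)], fwhm=15.0)),
        EndmemberSpec("baseline_fluorescence", (), baseline_order=3,
                      baseline_amplitude=1.0),
    ]


# ---------------------------------------------------------------------------
# Class profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassProfile:
    """Per-class abundance distribution over the endmember library.

    ``abundance_mean`` maps endmember name to mean abundance (arbitrary
    concentration units); ``abundance_cv`` is the relative SD of the
    per-cell abundance draw.  ``probe_scale`` multiplies the probe_MB
    abundance and ``background_scale`` the silent-region fluorescence
    abundance, so probe uptake and background can be dialled per class
    without touching the base profile.
    """

    class_label: str
    abundance_mean: Mapping[str, float]
    abundance_cv: float = 0.15
    background_scale: float = 1.0
    probe_scale: float = 1.0
    cell_radius_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_CODES:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if any(v < 0 for v in self.abundance_mean.values()):
            raise ValueError("abundance means must be non-negative")
        if self.abundance_cv < 0 or self.background_scale < 0 \
                or self.probe_scale < 0:
            raise ValueError("scales must be non-negative")

    def effective_means(self, names: Sequence[str]) -> np.ndarray:
        """Mean abundance vector in library order with scales applied."""
        out = np.array([self.abundance_mean.get(n, 0.0) for n in names])
        for i, n in enumerate(names):
            if n == "probe_MB":
                out[i] *= self.probe_scale
            elif n == "baseline_fluorescence":
                out[i] *= self.background_scale
        return out


def default_class_profiles() -> dict[str, ClassProfile]:
    """Default contrasting profiles for the two populations.

    Directionality in the erythrocyte-like class relative to precursors:
    hemoglobin up, cytochrome c down, glycogen up, nuclear material down,
    saturated-over-unsaturated lipid shift, weaker probe, stronger
    silent-region background, larger cells.
    """
    precursor = ClassProfile(
        class_label="precursor",
        abundance_mean={
            "hemoglobin": 0.30,
            "cytochrome_c": 1.00,
            "glycogen": 0.40,
            "lipid_saturated": 0.50,
            "lipid_unsaturated": 0.55,
            "nuclear": 1.20,
            "protein_cytoplasm": 1.00,
            "probe_MB": 1.00,
            "baseline_fluorescence": 0.30,
        },
        abundance_cv=0.15,
        background_scale=1.0,
        probe_scale=1.0,
        cell_radius_scale=1.0,
    )
    erythro = ClassProfile(
        class_label="erythrocyte_like",
        abundance_mean={
            "hemoglobin": 1.50,
            "cytochrome_c": 0.55,
            "glycogen": 0.90,
            "lipid_saturated": 0.80,
            "lipid_unsaturated": 0.35,
            "nuclear": 0.55,
            "protein_cytoplasm": 0.90,
            "probe_MB": 1.00,
            "baseline_fluorescence": 0.30,
        },
        abundance_cv=0.15,
        background_scale=2.5,
        probe_scale=0.35,
        cell_radius_scale=1.3,
    )
    return {"precursor": precursor, "erythrocyte_like": erythro}


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomGeometry:
    cell_radius: tuple[float, float] = (10.0, 12.0)
    radius_scale: float = 1.0
    nucleus_frac: float = 0.45
    n_mito: tuple[int, int] = (3, 6)
    mito_radius: float = 2.0
    n_droplets: tuple[int, int] = (2, 4)
    droplet_radius: float = 1.8
    margin: int = 4
    max_attempts_per_cell: int = 300


@dataclass
class CellPhantom:
    """Binary-mask model of one cell: nucleus inside cell, organelles in
    cytoplasm, cytoplasm = cell minus nucleus."""

    mask_cell: np.ndarray
    mask_nucleus: np.ndarray
    mask_mito: np.ndarray
    mask_lipid_droplets: np.ndarray
    mask_cytoplasm: np.ndarray
    pixel_size_um: float = 0.5

    def validate(self) -> None:
        if np.any(self.mask_nucleus & ~self.mask_cell):
            raise ValueError("nucleus must be inside the cell")
        if np.any(self.mask_cytoplasm != (self.mask_cell & ~self.mask_nucleus)):
            raise ValueError("cytoplasm must equal cell minus nucleus")
        if np.any(self.mask_mito & ~self.mask_cytoplasm):
            raise ValueError("mitochondria must be inside the cytoplasm")
        if np.any(self.mask_lipid_droplets & ~self.mask_cytoplasm):
            raise ValueError("lipid droplets must be inside the cytoplasm")


def _disk(shape: tuple[int, int], cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def make_phantom(n_cells: int, image_shape: tuple[int, int] = (256, 256),
                 geometry: PhantomGeometry | None = None,
                 seed: int | np.random.Generator = 0,
                 pixel_size_um: float = 0.5) -> list[CellPhantom]:
    """Place ``n_cells`` non-overlapping cell phantoms on an image grid.

    Cells are disks with an off-centre nuclear disk, a few mitochondrial
    and lipid-droplet blobs in the cytoplasm.  Packing is by rejection
    sampling with a bounded retry budget; if the field cannot fit the
    requested count, the achieved count is returned with a warning.
    """
    geo = geometry or PhantomGeometry()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    occupied = np.zeros(image_shape, dtype=bool)
    phantoms: list[CellPhantom] = []
    h, w = image_shape
    for _ in range(n_cells):
        placed = False
        for _attempt in range(geo.max_attempts_per_cell):
            r = rng.uniform(*geo.cell_radius) * geo.radius_scale
            if 2 * (r + geo.margin) >= min(h, w):
                continue               # image too small for this radius
            cy = rng.uniform(r + geo.margin, h - r - geo.margin)
            cx = rng.uniform(r + geo.margin, w - r - geo.margin)
            cell = _disk(image_shape, cy, cx, r)
            halo = _disk(image_shape, cy, cx, r + geo.margin)
            if np.any(halo & occupied):
                continue
            nr = geo.nucleus_frac * r
            max_off = max(r - nr - 1.0, 0.0)
            ang = rng.uniform(0, 2 * np.pi)
            off = rng.uniform(0, max_off)
            nucleus = _disk(image_shape, cy + off * np.sin(ang),
                            cx + off * np.cos(ang), nr) & cell
            cytoplasm = cell & ~nucleus
            mito = np.zeros(image_shape, dtype=bool)
            for _m in range(rng.integers(geo.n_mito[0], geo.n_mito[1] + 1)):
                ma = rng.uniform(0, 2 * np.pi)
                md = rng.uniform(nr + geo.mito_radius, r - geo.mito_radius) \
                    if r - geo.mito_radius > nr + geo.mito_radius else nr + 1
                mito |= _disk(image_shape, cy + md * np.sin(ma),
                              cx + md * np.cos(ma), geo.mito_radius)
            mito &= cytoplasm
            droplets = np.zeros(image_shape, dtype=bool)
            for _d in range(rng.integers(geo.n_droplets[0], geo.n_droplets[1] + 1)):
                da = rng.uniform(0, 2 * np.pi)
                dd = rng.uniform(nr + geo.droplet_radius, r - geo.droplet_radius) \
                    if r - geo.droplet_radius > nr + geo.droplet_radius else nr + 1
                droplets |= _disk(image_shape, cy + dd * np.sin(da),
                                  cx + dd * np.cos(da), geo.droplet_radius)
            droplets &= cytoplasm
            ph = CellPhantom(cell, nucleus, mito, droplets, cytoplasm,
                             pixel_size_um)
            ph.validate()
            phantoms.append(ph)
            occupied |= cell
            placed = True
            break
        if not placed:
            warnings.warn(
                f"could only place {len(phantoms)} of {n_cells} cells",
                stacklevel=2,
            )
            break
    return phantoms


# ---------------------------------------------------------------------------
# Noise model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseParams:
    """Poisson shot noise + additive Gaussian read noise + rare spikes.

    ``shot_scale`` is the photon count per intensity unit: counts are drawn
    as Poisson(shot_scale * I) / shot_scale, so per-channel variance is
    I / shot_scale.  ``shot_scale = 0`` disables shot noise.  Spikes are
    single-channel deltas at rate ``spike_rate`` per pixel-channel with
    amplitude ``spike_amplitude`` times the cube maximum.
    """

    shot_scale: float = 0.0
    read_sigma: float = 0.0
    spike_rate: float = 0.0
    spike_amplitude: float = 50.0

    def __post_init__(self) -> None:
        if min(self.shot_scale, self.read_sigma, self.spike_rate,
               self.spike_amplitude) < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def is_noiseless(self) -> bool:
        return self.shot_scale == 0 and self.read_sigma == 0 \
            and self.spike_rate == 0


def apply_noise(clean: np.ndarray, noise: NoiseParams,
                rng: np.random.Generator) -> np.ndarray:
    if noise.is_noiseless:
        return clean.copy()
    out = clean.astype(float)
    if noise.shot_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * noise.shot_scale) \
            / noise.shot_scale
    if noise.read_sigma > 0:
        out = out + rng.normal(0.0, noise.read_sigma, size=out.shape)
    if noise.spike_rate > 0:
        n_spikes = rng.binomial(out.size, noise.spike_rate)
        if n_spikes:
            idx = rng.choice(out.size, size=n_spikes, replace=False)
            flat = out.reshape(-1)
            flat[idx] += noise.spike_amplitude * max(clean.max(), 1.0)
    return out


# ---------------------------------------------------------------------------
# Cube simulation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Noiseless factors of a simulated cube: cube == C @ S exactly."""

    C: np.ndarray                 # (y, x, k) concentration maps
    S: np.ndarray                 # (k, channels) endmember spectra
    endmember_names: list[str]
    class_label: str
    seed: int | None
    params: dict = field(default_factory=dict)


# Which phantom compartment(s) host each endmember, with relative weights.
# The probe and haem proteins retain a weak cytoplasmic presence (the probe
# is lipophilic; haem proteins are cytosolic), which is what makes per-cell
# median markers informative rather than mitochondria-only deltas.
DEFAULT_COMPARTMENT_MAP: dict[str, tuple[tuple[str, float], ...]] = {
    "hemoglobin": (("cytoplasm", 1.0),),
    "cytochrome_c": (("mito", 1.0), ("cytoplasm", 0.1)),
    "glycogen": (("cytoplasm", 1.0),),
    "lipid_saturated": (("droplets", 1.0), ("cytoplasm", 0.1)),
    "lipid_unsaturated": (("droplets", 1.0), ("cytoplasm", 0.1)),
    "nuclear": (("nucleus", 1.0),),
    "protein_cytoplasm": (("cytoplasm", 1.0),),
    "probe_MB": (("mito", 1.0), ("cytoplasm", 0.3)),
    "baseline_fluorescence": (("cell", 1.0),),
}


def _compartment_mask(ph: CellPhantom, which: str) -> np.ndarray:
    if which == "cytoplasm_clear":
        return ph.mask_cytoplasm & ~ph.mask_lipid_droplets & ~ph.mask_mito
    return {
        "cell": ph.mask_cell,
        "nucleus": ph.mask_nucleus,
        "cytoplasm": ph.mask_cytoplasm,
        "mito": ph.mask_mito,
        "droplets": ph.mask_lipid_droplets,
    }[which]


def _draw_abundances(profile: ClassProfile, names: Sequence[str],
                     rng: np.random.Generator) -> np.ndarray:
    mean = profile.effective_means(names)
    jitter = 1.0 + profile.abundance_cv * rng.standard_normal(len(names))
    return np.clip(mean * jitter, 0.0, None)


def simulate_hs_image(
    phantom: CellPhantom | Sequence[CellPhantom],
    class_profile: ClassProfile,
    endmember_specs: Sequence[EndmemberSpec] | None = None,
    axis: SpectralAxis | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
    compartment_map: Mapping[str, Sequence[tuple[str, float]]] | None = None,
) -> tuple[HSImage, GroundTruth]:
    """Simulate a hyperspectral cube over one or more cell phantoms.

    The noiseless cube is the bilinear product of per-endmember
    concentration maps (abundance drawn per cell, painted into the
    endmember's compartments with the map's relative weights) with the
    rendered library, so ground truth satisfies
    ``cube == sum_k C_k (x) S_k`` to machine precision.  Noise is
    Poisson–Gaussian with optional spikes.  Pass a custom
    ``compartment_map`` (e.g. with the disjoint ``cytoplasm_clear``
    compartment) to build cubes with guaranteed pure pixels.
    """
    specs = list(endmember_specs) if endmember_specs is not None \
        else default_endmember_specs()
    axis = axis or SpectralAxis.raman_default()
    noise = noise or NoiseParams()
    phantoms = [phantom] if isinstance(phantom, CellPhantom) else list(phantom)
    if not phantoms:
        raise ValueError("at least one phantom is required")
    cmap = dict(DEFAULT_COMPARTMENT_MAP if compartment_map is None
                else compartment_map)
    names, S = build_library(specs, axis)
    shape = phantoms[0].mask_cell.shape
    rng = np.random.default_rng(seed)
    C = np.zeros(shape + (len(names),))
    for ph in phantoms:
        ab = _draw_abundances(class_profile, names, rng)
        for k, name in enumerate(names):
            for which, weight in cmap.get(name, (("cytoplasm", 1.0),)):
                mask = _compartment_mask(ph, which)
                C[:, :, k][mask] += ab[k] * weight
    clean = C.reshape(-1, len(names)) @ S
    noisy = apply_noise(clean, noise, rng)
    cube = HSImage(
        noisy.reshape(shape + (len(axis),)), axis,
        pixel_size_um=phantoms[0].pixel_size_um,
        metadata={"class_label": class_profile.class_label, "seed": seed,
                  "modality": "raman"},
    )
    truth = GroundTruth(C=C, S=S, endmember_names=names,
                        class_label=class_profile.class_label, seed=seed,
                        params={"noise": noise, "n_cells": len(phantoms)})
    return cube, truth


# ---------------------------------------------------------------------------
# Cohort spectra
# ---------------------------------------------------------------------------

def simulate_cohort_spectra(
    n_per_class: int | Mapping[str, int] = 50,
    class_profiles: Mapping[str, ClassProfile] | None = None,
    axis: SpectralAxis | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
    endmember_specs: Sequence[EndmemberSpec] | None = None,
):
    """Simulate a labelled cohort of single-cell mean spectra.

    Each synthetic cell draws an abundance vector from its class profile
    and mixes the library linearly; read/shot noise is then applied.
    Returns a :class:`~erythrospec.chemometrics.SpectraMatrix` plus a
    DataFrame of the true abundances.
    """
    import pandas as pd

    from .chemometrics import SpectraMatrix

    profiles = class_profiles or default_class_profiles()
    axis = axis or SpectralAxis.raman_default()
    noise = noise or NoiseParams(read_sigma=0.02)
    specs = list(endmember_specs) if endmember_specs is not None \
        else default_endmember_specs()
    if isinstance(n_per_class, int):
        counts = {label: n_per_class for label in profiles}
    else:
        counts = dict(n_per_class)
    for label, n in counts.items():
        if n < 2:
            raise ValueError("need n_per_class >= 2 for every class")
    names, S = build_library(specs, axis)
    rng = np.random.default_rng(seed)
    rows, ys, ids, labels, ab_rows = [], [], [], [], []
    for label in sorted(counts):
        profile = profiles[label]
        for i in range(counts[label]):
            ab = _draw_abundances(profile, names, rng)
            spectrum = apply_noise(ab @ S, noise, rng)
            rows.append(spectrum)
            ys.append(CLASS_CODES[label])
            ids.append(f"{label}_{i:03d}")
            labels.append(label)
            ab_rows.append(ab)
    X = np.vstack(rows)
    matrix = SpectraMatrix(
        X=X, axis=axis, y=np.array(ys), sample_ids=list(ids),
        group_ids=list(ids), class_labels=list(labels),
    )
    abundances = pd.DataFrame(np.vstack(ab_rows), columns=names, index=ids)
    return matrix, abundances


# ---------------------------------------------------------------------------
# Single-wavenumber SRS frames
# ---------------------------------------------------------------------------

FRAME_WAVENUMBERS = (2100.0, 2222.0, 2850.0, 2930.0)


def simulate_frames(
    phantoms: Sequence[CellPhantom],
    class_profile: ClassProfile,
    endmember_specs: Sequence[EndmemberSpec] | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
):
    """Simulate the four single-wavenumber SRS frames the fast classifier
    uses: 2850 and 2930 cm^-1 (CH2/CH3 stretches), 2222 cm^-1 (probe band)
    and 2100 cm^-1 (off-resonance background).

    Returns a :class:`~erythrospec.markers.FrameSet` and the ground truth.
    """
    from .markers import FrameSet

    axis4 = SpectralAxis(np.array(FRAME_WAVENUMBERS))
    cube, truth = simulate_hs_image(
        phantoms, class_profile, endmember_specs, axis4,
        noise or NoiseParams(), seed,
    )
    clip = lambda a: np.clip(a, 0.0, None)  # intensities are physical
    frames = FrameSet(
        f2100=clip(cube.data[:, :, 0]), f2222=clip(cube.data[:, :, 1]),
        f2850=clip(cube.data[:, :, 2]), f2930=clip(cube.data[:, :, 3]),
        pixel_size_um=cube.pixel_size_um,
    )
    return frames, truth
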