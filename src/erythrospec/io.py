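"""Artifact readers/writers: HDF5 cubes, long-format spectra CSV, TIFF
maps, JSON thresholds, YAML run configuration.

HDF5 cube layout::

    /cube              float64, (y, x, channel)
    /wavenumbers_cm1   float64, (channel,)           strictly increasing
    attrs: pixel_size_um, modality in {raman, hsSRS, srs_frames};
           optional class_label, seed
    /ground_truth/C    optional (y, x, k)
    /ground_truth/S    optional (k, channel)

All writers are byte-deterministic for fixed inputs (HDF5 object
timestamps disabled, CSV floats pinned to 17 significant digits, JSON
keys sorted), so identical config + seed reproduce identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import HSImage, SpectralAxis
from .synthetic import GroundTruth

__all__ = [
    "read_cube",
    "write_cube",
    "read_spectra_csv",
    "write_spectra_csv",
    "write_map_tiff",
    "read_map_tiff",
    "write_thresholds_json",
    "read_thresholds_json",
    "RunConfig",
    "load_config",
]

MODALITIES = ("raman", "hsSRS", "srs_frames")

SPECTRA_COLUMNS = ["sample_id", "group_id", "class", "wavenumber_cm1",
                   "intensity"]


def write_cube(cube: HSImage, path: str | Path,
               ground_truth: GroundTruth | None = None) -> None:
    path = Path(path)
    modality = cube.metadata.get("modality", "raman")
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=cube.data.astype(np.float64),
                         track_times=False)
        f.create_dataset("wavenumbers_cm1",
                         data=cube.axis.values.astype(np.float64),
                         track_times=False)
        f.attrs["pixel_size_um"] = float(cube.pixel_size_um)
        f.attrs["modality"] = modality
        if "class_label" in cube.metadata:
            f.attrs["class_label"] = str(cube.metadata["class_label"])
        if cube.metadata.get("seed") is not None:
            f.attrs["seed"] = int(cube.metadata["seed"])
        if ground_truth is not None:
            g = f.create_group("ground_truth")
            g.create_dataset("C", data=ground_truth.C.astype(np.float64),
                             track_times=False)
            g.create_dataset("S", data=ground_truth.S.astype(np.float64),
                             track_times=False)
            g.attrs["endmember_names"] = [
                str(n) for n in ground_truth.endmember_names]


def read_cube(path: str | Path) -> tuple[HSImage, GroundTruth | None]:
    path = Path(path)
    with h5py.File(path, "r") as f:
        for key in ("cube", "wavenumbers_cm1"):
            if key not in f:
                raise ValueError(f"invalid cube file: missing /{key}")
        data = f["cube"][()]
        wn = f["wavenumbers_cm1"][()]
        if data.ndim != 3:
            raise ValueError("invalid cube file: /cube must be 3-D")
        if data.shape[2] != wn.shape[0]:
            raise ValueError(
                "invalid cube file: channel dimension does not match "
                "/wavenumbers_cm1")
        if not np.all(np.diff(wn) > 0):
            raise ValueError(
                "invalid cube file: wavenumbers must be strictly increasing")
        for attr in ("pixel_size_um", "modality"):
            if attr not in f.attrs:
                raise ValueError(f"invalid cube file: missing attr {attr!r}")
        meta: dict[str, Any] = {"modality": f.attrs["modality"]}
        if "class_label" in f.attrs:
            meta["class_label"] = str(f.attrs["class_label"])
        if "seed" in f.attrs:
            meta["seed"] = int(f.attrs["seed"])
        cube = HSImage(data, SpectralAxis(wn),
                       pixel_size_um=float(f.attrs["pixel_size_um"]),
                       metadata=meta)
        truth = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            truth = GroundTruth(
                C=g["C"][()], S=g["S"][()],
                endmember_names=[str(n) for n in g.attrs["endmember_names"]],
                class_label=meta.get("class_label", ""),
                seed=meta.get("seed"),
            )
    return cube, truth


# ---------------------------------------------------------------------------
# Spectra CSV (long format)
# ---------------------------------------------------------------------------

def write_spectra_csv(matrix, path: str | Path) -> None:
    """Write a SpectraMatrix as long-format CSV (17 significant digits)."""
    n, p = matrix.X.shape
    wn = matrix.axis.values
    classes = matrix.class_labels or [""] * n
    frame = pd.DataFrame({
        "sample_id": np.repeat(matrix.sample_ids, p),
        "group_id": np.repeat(matrix.group_ids, p),
        "class": np.repeat(classes, p),
        "wavenumber_cm1": np.tile(wn, n),
        "intensity": matrix.X.ravel(),
    })
    frame.to_csv(path, index=False, float_format="%.17g")


def read_spectra_csv(path: str | Path):
    """Read a long-format spectra CSV back into a SpectraMatrix.

    Rejects files whose samples do not share one wavenumber axis.
    """
    from .chemometrics import SpectraMatrix
    from .synthetic import CLASS_CODES

    frame = pd.read_csv(path)
    missing = [c for c in SPECTRA_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"spectra CSV missing columns {missing}")
    sample_order = list(dict.fromkeys(frame["sample_id"]))
    axes = frame.groupby("sample_id", sort=False)["wavenumber_cm1"].apply(
        lambda s: tuple(s.to_numpy()))
    if len(set(axes)) != 1:
        raise ValueError("samples have ragged wavenumber axes")
    wn = np.asarray(axes.iloc[0], dtype=float)
    X = np.empty((len(sample_order), wn.size))
    groups, classes = [], []
    for i, sid in enumerate(sample_order):
        block = frame[frame["sample_id"] == sid]
        X[i] = block["intensity"].to_numpy()
        groups.append(str(block["group_id"].iloc[0]))
        classes.append(str(block["class"].iloc[0]))
    y = np.array([CLASS_CODES.get(c, 0) for c in classes])
    return SpectraMatrix(X=X, axis=SpectralAxis(wn), y=y,
                         sample_ids=[str(s) for s in sample_order],
                         group_ids=groups, class_labels=classes)


# ---------------------------------------------------------------------------
# TIFF maps, thresholds JSON
# ---------------------------------------------------------------------------

def write_map_tiff(image: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def read_map_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_thresholds_json(thresholds, path: str | Path) -> None:
    payload = {
        "mb_threshold": float(thresholds.mb_threshold),
        "lp_threshold": float(thresholds.lp_threshold),
        "provenance": thresholds.provenance,
    }
    if thresholds.roc_mb is not None:
        payload["mb_auc"] = float(thresholds.roc_mb.auc)
    if thresholds.roc_lp is not None:
        payload["lp_auc"] = float(thresholds.roc_lp.auc)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_thresholds_json(path: str | Path):
    from .markers import ThresholdPair

    payload = json.loads(Path(path).read_text())
    return ThresholdPair(mb_threshold=payload["mb_threshold"],
                         lp_threshold=payload["lp_threshold"],
                         provenance=payload.get("provenance", "fixed"))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_KNOWN_STAGES = ("simulate", "preprocess", "decompose", "train", "phasor",
                 "classify")


@dataclass
class RunConfig:
    """Per-stage parameter blocks plus global seed/output settings.

    Unknown top-level keys and unknown stage names are rejected so that a
    typo cannot silently fall back to defaults.
    """

    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"
    stages: dict[str, dict] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.stages is None:
            self.stages = {}
        unknown = set(self.stages) - set(_KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stage blocks: {sorted(unknown)}")

    def stage(self, name: str) -> dict:
        return dict(self.stages.get(name, {}))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ValueError("config must be a mapping")
    top = {"seed", "output_dir", "log_level"}
    stages = {k: v for k, v in raw.items() if k not in top}
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", ".")),
        log_level=str(raw.get("log_level", "INFO")),
        stages=stages,
    )
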