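"""Shared fixtures: small axes, phantom fields, ground-truthed cubes."""

from __future__ import annotations

import pytest

import erythrospec as es
from erythrospec.core import SpectralAxis

# Disjoint compartment map -> cubes with guaranteed pure pixels per
# component (nucleic acid in the nucleus, protein in clear cytoplasm,
# saturated lipid in droplets).
PURE_MAP = {
    "nuclear": (("nucleus", 1.0),),
    "protein_cytoplasm": (("cytoplasm_clear", 1.0),),
    "lipid_saturated": (("droplets", 1.0),),
}

MCR_MAP = {
    "hemoglobin": (("cytoplasm_clear", 1.0),),
    "nuclear": (("nucleus", 1.0),),
    "lipid_saturated": (("droplets", 1.0),),
}


@pytest.fixture(scope="session")
def fingerprint_axis() -> SpectralAxis:
    return SpectralAxis.fingerprint()


@pytest.fixture(scope="session")
def hssrs_axis() -> SpectralAxis:
    return SpectralAxis.hssrs()


@pytest.fixture(scope="session")
def endmember_library(fingerprint_axis):
    specs = es.default_endmember_specs()
    names, S = es.build_library(specs, fingerprint_axis)
    return specs, names, S


@pytest.fixture(scope="session")
def profiles():
    return es.default_class_profiles()


def make_pure_cube(axis, image_shape=(64, 64), n_cells=4, seed=1,
                   noise=None, compartment_map=None, geometry=None):
    """Ground-truthed cube with disjoint pure-pixel components."""
    cmap = compartment_map or MCR_MAP
    specs = [s for s in es.default_endmember_specs() if s.name in cmap]
    ph = es.make_phantom(n_cells, image_shape, geometry, seed=seed)
    profile = es.default_class_profiles()["precursor"]
    return es.simulate_hs_image(ph, profile, specs, axis,
                                noise or es.NoiseParams(), seed=seed + 1,
                                compartment_map=cmap), ph


@pytest.fixture(scope="session")
def pure_cube3(fingerprint_axis):
    """Noiseless 3-component cube with pure pixels (session-cached)."""
    (cube, truth), ph = make_pure_cube(fingerprint_axis)
    return cube, truth, ph
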