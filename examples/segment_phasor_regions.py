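"""Segment a hyperspectral SRS phantom into subcellular regions via the
spectral phasor transform.

Each pixel's spectrum maps to a point (G, S) in the phasor plane;
k-means on those points separates nuclei (nucleic-acid CH profile),
cytoplasm (protein CH3) and lipid-rich intermediate regions, which are
then named by correlating cluster-mean spectra with reference signatures.
"""

import erythrospec as es
from erythrospec.core import SpectralAxis
from erythrospec.phasor import phasor_segment, spectral_phasor
from erythrospec.synthetic import PhantomGeometry

PURE = {
    "nuclear": (("nucleus", 1.0),),
    "protein_cytoplasm": (("cytoplasm_clear", 1.0),),
    "lipid_saturated": (("droplets", 1.0),),
}

axis = SpectralAxis.hssrs()          # 2800-3050 cm-1, 6 cm-1 steps
geo = PhantomGeometry(droplet_radius=2.5, n_droplets=(3, 5))
phantoms = es.make_phantom(6, (128, 128), geo, seed=3)
profile = es.default_class_profiles()["precursor"]
specs = [s for s in es.default_endmember_specs() if s.name in PURE]
cube, _ = es.simulate_hs_image(phantoms, profile, specs, axis,
                               es.NoiseParams(read_sigma=0.01), seed=4,
                               compartment_map=PURE)

pmap = spectral_phasor(cube, intensity_floor_frac=0.1)
seg = phasor_segment(pmap, n_clusters=3, seed=0, image=cube)
print(f"hsSRS stack: {cube.shape[2]} frames at 6 cm-1 steps, "
      f"{int(pmap.valid_mask.sum())} pixels above the intensity floor")
for code, name in sorted(seg.code_to_name.items()):
    n = int((seg.labels == code).sum())
    if code:
        g, s = seg.centers[code - 1]
        print(f"  region {name:13s} {n:6d} px  phasor center "
              f"G={g:+.3f} S={s:+.3f}")
    else:
        print(f"  region {name:13s} {n:6d} px")
print("distinct phasor centers per region are what make the plane "
      "separable by plain k-means.")
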