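"""Unmix a hyperspectral Raman phantom with MCR-ALS and verify recovery
against the known ground truth.

The phantom hosts three spatially distinct components (nucleic acid in
nuclei, hemoglobin in cytoplasm, saturated lipid in droplets); matched
cosine similarity and concentration-map correlation measure how well
alternating non-negative least squares recovers them.
"""

import numpy as np
from scipy.stats import pearsonr

import erythrospec as es
from erythrospec.core import SpectralAxis
from erythrospec.mcr import MCRConfig, match_components, mcr_als

CMAP = {
    "hemoglobin": (("cytoplasm_clear", 1.0),),
    "nuclear": (("nucleus", 1.0),),
    "lipid_saturated": (("droplets", 1.0),),
}

axis = SpectralAxis.fingerprint()
specs = [s for s in es.default_endmember_specs() if s.name in CMAP]
phantoms = es.make_phantom(4, (64, 64), seed=1)
profile = es.default_class_profiles()["precursor"]
clean, _ = es.simulate_hs_image(phantoms, profile, specs, axis,
                                es.NoiseParams(), seed=2,
                                compartment_map=CMAP)
sigma = float(np.sqrt(np.mean(clean.data**2))) / 20          # SNR 20
cube, truth = es.simulate_hs_image(
    phantoms, profile, specs, axis,
    es.NoiseParams(read_sigma=sigma), seed=2, compartment_map=CMAP)

result = mcr_als(cube, MCRConfig(n_components=3, tol_lof=1e-6))
perm, cosines = match_components(result.S, truth.S)
print(f"cube {cube.shape}, LOF = {result.lof_percent:.2f}% after "
      f"{result.iterations_run} iterations (converged={result.converged})")
C_true = truth.C.reshape(-1, 3)
for i, j in enumerate(perm):
    r = pearsonr(result.C[:, i], C_true[:, j])[0]
    frac = result.signal_fraction_percent[i]
    print(f"  comp {i} -> {truth.endmember_names[j]:16s} "
          f"cosine={cosines[i]:.4f}  map r={r:.4f}  "
          f"signal fraction={frac:.1f}%")
print("cosine ~1 and r ~1 mean the bilinear factors were recovered up to "
      "the inherent permutation/scale ambiguity.")
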