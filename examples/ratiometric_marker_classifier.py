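"""The fast two-marker classifier: lipid-to-protein ratio and
mitochondrial-probe signal from four single-wavenumber SRS frames.

Per cell, the markers are medians normalized to area; ROC analysis on a
labelled cohort calibrates one threshold per marker, and cells are
called by quadrant (both high -> precursor, both low -> erythrocyte-like).
"""

import pandas as pd

from erythrospec.markers import (calibrate_thresholds, classify_quadrant,
                                 per_cell_markers, probe_map, ratio_map,
                                 segment_cells)
from erythrospec.synthetic import (NoiseParams, PhantomGeometry,
                                   default_class_profiles, make_phantom,
                                   simulate_frames)

profiles = default_class_profiles()
tables, labels = [], []
for i, (label, prof) in enumerate(sorted(profiles.items())):
    geo = PhantomGeometry(radius_scale=prof.cell_radius_scale)
    phantoms = make_phantom(60, (512, 512), geo, seed=100 + i)
    frames, _ = simulate_frames(phantoms, prof,
                                noise=NoiseParams(read_sigma=0.02),
                                seed=200 + i)
    cells, _ = segment_cells(frames)
    ratio, valid = ratio_map(frames.f2850, frames.f2930)
    probe = probe_map(frames.f2222, frames.f2100)
    table = per_cell_markers(ratio, probe, cells, frames.pixel_size_um,
                             valid)
    table.insert(0, "class_true", label)
    tables.append(table)
    labels.extend([label] * len(table))

table = pd.concat(tables, ignore_index=True)
thresholds = calibrate_thresholds(table, labels)
called = classify_quadrant(table, thresholds)
accuracy = (called["call"] == called["class_true"]).mean()

print(f"{len(table)} cells segmented from two 512x512 frame sets")
print(f"lipid/protein marker: AUC={thresholds.roc_lp.auc:.3f}, "
      f"threshold={thresholds.lp_threshold:.3g} per um^2")
print(f"probe marker:         AUC={thresholds.roc_mb.auc:.3f}, "
      f"threshold={thresholds.mb_threshold:.3g} per um^2")
print(f"quadrant accuracy vs ground truth: {accuracy:.3f}")
print(called["call"].value_counts().to_string())
print("precursors sit in the upper-right quadrant (both markers high); "
      "erythrocyte-like cells in the lower-left.")
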