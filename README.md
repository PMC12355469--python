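# erythrospec

Chemometrics for detecting drug-induced erythroid differentiation from
vibrational-spectroscopy data.

Low-dose doxorubicin pushes malignant erythroid precursors (K562-type
cells) toward an erythrocyte-like phenotype: hemoglobin and glycogen
accumulate, cytochrome c and nuclear material decline, membranes shift
toward saturated lipids, cells grow, and mitochondrial membrane potential
drops (read out through the MitoBADY alkyne probe at 2222 cm⁻¹).
`erythrospec` implements the full label-free/probe-assisted analysis
chain that turns Raman and stimulated Raman scattering (SRS) measurements
of such cells into classifications:

- **`synthetic`** — a ground-truthed generator: endmember spectra as sums
  of Lorentzian/Gaussian bands at literature positions, geometric cell
  phantoms, linear mixing, Poisson–Gaussian noise, and two contrasting
  class profiles encoding the differentiation directionality.
- **`preprocess`** — despiking, AsLS/polynomial baseline correction,
  cropping, vector/area normalization, per-cell averaging.
- **`mcr`** — MCR-ALS: the bilinear decomposition `D ≈ C·Sᵀ` of a
  hyperspectral cube into non-negative concentration maps and endmember
  spectra by alternating non-negative least squares, with an optional
  sum-preserving contribution-contrast step, SIMPLISMA initialisation,
  sum-squared-signal fractions, high-intensity pixel statistics and
  permutation/scale-invariant component matching.
- **`chemometrics`** — PCA, OPLS-DA (one predictive latent variable plus
  class-orthogonal components), VIP scores, group-stratified
  cross-validation with sensitivity/specificity/MCC, group-level
  permutation testing, ROC analysis with Youden-J thresholds, and the
  Mann–Whitney test (exact for small samples).
- **`phasor`** — the spectral phasor transform
  `G = Σ Iₖcos(2πnk/N)/ΣIₖ`, `S = Σ Iₖsin(2πnk/N)/ΣIₖ` and k-means
  segmentation of the phasor plane into nucleus / cytoplasm /
  intermediate regions.
- **`markers`** — the fast two-marker classifier from four
  single-wavenumber SRS frames: lipid-to-protein ratio
  `I₂₈₅₀/(I₂₈₅₀+I₂₉₃₀)` and background-subtracted probe signal
  `max(I₂₂₂₂−I₂₁₀₀, 0)`, per-cell medians normalized to area,
  ROC-calibrated thresholds and quadrant class calls.
- **`io` / `cli`** — HDF5 cube layout, long-format spectra CSV, TIFF
  maps, thresholds JSON, YAML run config, and a thin `erythrospec`
  command chaining `simulate → preprocess → decompose → train → phasor →
  classify → report` with byte-deterministic outputs.

## Worked example

`examples/` contains one short script per capability. For instance,
unmixing a ground-truthed phantom cube
(`python examples/unmix_hyperspectral_image.py`):

```
cube (64, 64, 600), LOF = 4.98% after 53 iterations (converged=True)
  comp 0 -> lipid_saturated  cosine=1.0000  map r=0.9996  signal fraction=6.5%
  comp 1 -> nuclear          cosine=0.9992  map r=1.0000  signal fraction=62.2%
  comp 2 -> hemoglobin       cosine=0.9998  map r=0.9976  signal fraction=28.2%
```

LOF is the lack of fit (100·√(Σresid²/Σdata²)); the ~5% residual is the
injected noise (SNR 20). Each recovered component matches its true
endmember with cosine ≥ 0.999 and its concentration map correlates with
truth at r ≥ 0.998 — recovery up to MCR's inherent permutation/scale
ambiguity. The signal fractions are each component's share of the total
sum-squared signal.

The fast classifier (`python examples/ratiometric_marker_classifier.py`):

```
120 cells segmented from two 512x512 frame sets
lipid/protein marker: AUC=0.985, threshold=0.00207 per um^2
probe marker:         AUC=1.000, threshold=0.00141 per um^2
quadrant accuracy vs ground truth: 0.950
```

Both per-area markers are higher in precursors (erythrocyte-like cells
are larger and accumulate less probe), so the upper-right quadrant
collects precursors and the lower-left the differentiated cells; 95% of
cells are called correctly, the rest land in mixed quadrants and are
flagged indeterminate.

The CLI runs the same chain from the shell:

```bash
erythrospec simulate --preset two-class --out run/sim --seed 7
erythrospec preprocess --in run/sim/cohort_raman.csv --out run/cohort_pp.csv
erythrospec train --in run/cohort_pp.csv --out run/train --seed 7
erythrospec classify --frames-dir run/sim --out run/classify --seed 7
erythrospec report --run-dir run --out run/summary.json
```

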