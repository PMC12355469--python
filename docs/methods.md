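# Methods

This note documents the models implemented in `erythrospec`, the
synthetic data they are exercised on, the defaults that matter, and the
design choices made where the methodology was genuinely open.

## The scientific setting

Erythroid precursors driven toward an erythrocyte-like phenotype change
their vibrational fingerprint in characteristic directions: hemoglobin
(resonance-enhanced haem modes at 753, 1130, 1310, 1340, 1377, 1400,
1555, 1585, 1610 cm⁻¹) and glycogen rise; cytochrome c (753, 1130, 1175,
1315, 1585 cm⁻¹ plus pyrrole modes at 611/647) and nucleic-acid bands
fall as metabolism shifts away from oxidative phosphorylation and
chromatin reorganises; membranes shift toward saturated lipids; cells
enlarge; and uptake of a mitochondrial-membrane-potential-sensitive
alkyne probe (reporter band at 2222 cm⁻¹, in the cell-silent region)
drops. Differentiated populations also show a stronger fluorescence
pedestal across the silent region (1800–2800 cm⁻¹). The package
implements four analyses that read out these changes: MCR-ALS image
unmixing, OPLS-DA single-spectrum classification, spectral-phasor
segmentation, and a two-marker ratiometric classifier.

## Synthetic data generator

The generator is first-class, tested code: every analysis is validated
against cubes and cohorts whose ground truth is known exactly.

**Spectra.** An endmember is a named list of bands plus an optional
smooth background. Bands are pseudo-Voigt with pure Lorentzian default
(Raman lines are near-Lorentzian; Gaussian available per band); the peak
value equals the amplitude and FWHM defaults to 12 cm⁻¹ (16 for broad
CH-stretch lipid bands). The silent-region background is a third-order
Bernstein bump supported on 1800–2800 cm⁻¹ whose peak sits toward the
low-wavenumber end (u = 1/3 of the window), so the pedestal is nearly
flat across the probe readout pair (2100/2222 cm⁻¹) — the physical
premise that makes off-resonance subtraction effective. Rendered spectra
are non-negative by construction.

**Axes.** "Raman mode" uses 600–3100 cm⁻¹ at 2 cm⁻¹ steps; a
fingerprint-only variant (600–1798 cm⁻¹, 600 channels) serves the
unmixing experiments; "hsSRS mode" uses 2800–3050 cm⁻¹ at 6 cm⁻¹ steps,
matching frame-stepped hyperspectral SRS acquisition.

**Phantoms.** Cells are disks (radius U(10, 12) px, pixel size 0.5 µm)
with an off-centre nuclear disk (45% of the radius), 3–6 mitochondrial
blobs and 2–4 lipid droplets in the cytoplasm; placement is rejection
sampling with a 4-px margin and a bounded retry budget (a partial packing
is returned with a warning, never an exception). Masks satisfy
nucleus ⊂ cell, organelles ⊂ cytoplasm, cytoplasm = cell − nucleus.

**Mixing and noise.** A cube is the exact bilinear product of
per-endmember concentration maps (per-cell abundance drawn from the class
profile, painted into the endmember's compartments with fixed weights)
with the rendered library; noise is Poisson shot noise
(variance I/shot_scale), additive Gaussian read noise, and optional
single-channel spikes. The noiseless cube equals C·Sᵀ to machine
precision, which the tests assert.

**Class profiles.** Absolute abundances are free parameters (no
concentrations are available to copy), chosen once so that the class
contrast realises the reported directionality and held fixed:

| endmember | precursor | erythrocyte-like |
|---|---|---|
| hemoglobin | 0.30 | 1.50 |
| cytochrome c | 1.00 | 0.55 |
| glycogen | 0.40 | 0.90 |
| lipid (saturated / unsaturated) | 0.50 / 0.55 | 0.80 / 0.35 |
| nuclear | 1.20 | 0.55 |
| cytoplasmic protein | 1.00 | 0.90 |
| probe scale | 1.00 | 0.35 |
| silent-region background scale | 1.0 | 2.5 |
| cell radius scale | 1.0 | 1.3 |

Per-cell abundances jitter with CV 0.15 (truncated at zero). The probe
retains a weak cytoplasmic presence (weight 0.3 vs 1.0 in mitochondria,
reflecting its lipophilicity) — without it, a cytoplasmic median would be
blind to the probe. Cohort sizes default to 50 cells per class (60 for
the marker imaging cohorts); no counts are published, so these are the
package's own realistic choices.

**What the generator does not emulate.** Optical physics (resonance
cross-sections, laser-power effects, photodamage), instrument drift,
wavenumber miscalibration, cell-shape irregularity, intra-compartment
texture, and spatial correlation of noise. Passing tests therefore
demonstrate algorithmic correctness and recovery under the stated noise
model, not robustness to every artefact of real acquisitions.

## MCR-ALS

`D ≈ C·Sᵀ` with non-negativity on both factors. Subproblems are solved
per column by active-set NNLS on the normal equations (Bro–de Jong fast
NNLS; columns whose unconstrained solution is already feasible satisfy
the KKT conditions and skip the active-set loop; a Lawson–Hanson fallback
guards ill-conditioned columns). Rows of S are renormalised to unit L2
after every iteration with the scale absorbed into C — the package's
scale convention. Lack of fit, LOF(%) = 100·√(Σresid²/Σdata²), is
tracked per iteration; iteration stops when its relative change falls
below `tol_lof` (default 1e-6; the pre-iteration reference is the zero
model's 100%, so an enormous tolerance stops after one iteration) or at
`max_iter`. Non-convergence is reported in the result object, never
raised. With the contrast step disabled each half-update is an exact
least-squares solve, so the residual is monotone non-increasing
(asserted in tests).

Initialisation is SIMPLISMA-style purest-variable selection over
channels: purity σ/(µ+offset) with offset 5% of the largest channel
mean; after the first pick, candidates are weighted by a determinant
independence factor so duplicated channels are never re-selected. The
selected channels' intensity images form the initial concentration
estimate and the initial S is its NNLS projection onto the data.

The **contribution-contrast step** sharpens spatial contrast:
`C′ᵢ = (1−w)·Cᵢ + w·proj_dominant(Cᵢ)` per pixel, where the projection
puts the pixel's total concentration on its dominant component; pixel
sums are preserved exactly and w = 0 (the default) is the identity. The
exact operator behind published contrast-constrained MCR is not
specified in the open literature we implement from, so this sum-
preserving shrinkage is this package's documented choice.

Diagnostics: per-component sum-squared-signal fractions
100·Σ(CₖSₖᵀ)²/ΣD², high-intensity pixel percentages under absolute /
pooled-percentile / Otsu threshold rules, and Hungarian-assignment
component matching by cosine similarity. Because MCR solutions are
permutation-, scale- and rotation-ambiguous, all recovery claims use
matched cosines and concentration-map correlations, never elementwise
equality. Default k = 10 for full Raman cubes (configurable; the
ground-truth experiments use k = 3–4 with pure-pixel phantoms).

## OPLS-DA

Classes are coded +1 (precursor) / −1 (erythrocyte-like); X is
mean-centred (unit-variance scaling optional — spectra are already
vector-normalized). The predictive weight is w ∝ Xᵀy. For each of
`n_orthogonal` components the X-loading of the current predictive score
is stripped of its projection on w, giving a y-orthogonal weight whose
component is removed from X; when the confounding variation is *exactly*
y-orthogonal this loading carries no orthogonal direction, and the
implementation falls back to the dominant principal direction of the
y-filtered residual (the residual-PCA variant of the orthogonal filter).
Both constructions give orthogonal scores exactly uncorrelated with y
(asserted to 1e-8 after every fit). With `n_orthogonal = 0` the model
reduces to one-component PLS1, verified against an independent NIPALS
oracle to 1e-10. The default model uses 1 predictive + 3 orthogonal
latent variables — four LVs total.

VIP for the single predictive component is VIPⱼ = √p·|wⱼ| (w unit norm),
so mean VIP² = 1 identically; channels with VIP > 1 are flagged.

**Validation.** 7-fold group-stratified cross-validation (cells never
span folds; fold plans that would lose a class from a training set are
re-drawn up to 20 times); centering/scaling and the orthogonal filter are
re-estimated inside every training fold. Pooled confusion counts yield
sensitivity, specificity and MCC (MCC = 0 when a marginal is zero). The
permutation test permutes labels at the group level and recomputes the
cross-validated MCC, with add-one smoothing
p = (1 + #{null ≥ observed})/(n_perm + 1); default 999 draws (99 in the
timed acceptance runs). The decision threshold on the continuous
prediction is 0, the symmetric choice for ±1 coding.

## Spectral phasor

G and S are the cosine/sine first-harmonic (configurable) Fourier
coefficients of each pixel's spectrum, normalised by total intensity:
intensity-scale invariant, linear under mixing, and confined to the unit
disc for non-negative spectra — all three properties are asserted on
random spectra. Pixels below an intensity floor (default 1% of the image
maximum total intensity; segmentation phantoms use 10% so background
read-noise pixels cannot enter the clustering) are flagged invalid and
map to (0, 0). Segmentation is k-means on (G, S) of valid pixels with 10
restarts and a fixed seed; clusters are named nucleus / cytoplasm /
intermediate by correlating cluster-mean spectra against reference
signatures (nucleic-acid, protein CH3, lipid CH2 profiles) with a
one-to-one assignment, rather than by manual gating. Nucleolar
substructure detection is out of scope.

## Ratiometric markers

From four registered single-wavenumber SRS frames: ratio
r = I₂₈₅₀/(I₂₈₅₀+I₂₉₃₀) ∈ [0, 1] (zero-denominator pixels flagged
invalid), probe p = max(I₂₂₂₂−I₂₁₀₀, 0) (the off-resonance frame carries
no probe band; negative differences are noise and the signal is
physically non-negative, hence the clip). Cells are segmented from the
2930 cm⁻¹ frame (Gaussian smooth σ = 1.5, Otsu, hole filling, minimum
size 60 px); the nucleus proxy is the largest connected low-ratio core
(below the 25th in-cell ratio percentile) and cytoplasm = cell − nucleus;
the rule is recorded in the output metadata. Markers are per-cell
*medians divided by area* (µm²) — the median over the cell for the ratio,
over the cytoplasm for the probe — with invalid pixels excluded before
the median; the units-of-measure reading (median ÷ area, not median of a
per-area image) is the implemented convention.

Thresholds are calibrated by ROC per marker with the precursor class on
the high side (precursors are smaller and accumulate more probe, so both
per-area markers are precursor-high); the reported cut maximises
Youden's J with ties broken toward higher specificity and is placed
midway between adjacent unique values so a strict `>` comparison
reproduces the ROC confusion table. Quadrant calls: both markers above
threshold → precursor; both below → erythrocyte-like; mixed quadrants →
indeterminate (only two quadrants have a defined identity, so mixed
cells are not forced); missing values → unclassified. Published fixed
threshold pairs can be supplied instead of calibration but are treated
as instrument-specific.

## Preprocessing

Fixed order: despike → baseline → crop → normalize (normalizing before
baseline removal would couple the baseline scale into everything
downstream, so the config exposes no ordering knob). Despiking replaces
channels whose deviation from a rolling median (window 7) exceeds z = 8
robust (MAD) standard deviations; a zero MAD (flat spectrum plus delta)
flags any non-zero deviation. The default baseline is asymmetric least
squares (Whittaker smoother with asymmetric weights; λ = 1e5, p = 0.01,
≤ 20 iterations; non-convergence warns with the residual), chosen as the
field-standard method since no published settings are available to copy;
polynomial baselines are available. `corrected + baseline` equals the
input exactly. Label-free models crop to 600–1800 ∪ 2800–3100 cm⁻¹
(excluding the silent region); probe analyses crop to 2150–2300 cm⁻¹.
Normalization is per-spectrum, vector (unit L2) by default.

## Statistical utilities

ROC sweeps the unique values, integrates AUC by trapezoid, and equals
the normalized all-pairs Mann–Whitney statistic exactly (asserted on
every test sample). The Mann–Whitney test uses full enumeration (exact,
tie-tolerant) when n₁·n₂ ≤ 400 and the normal approximation with tie
correction otherwise, via scipy. MCC equals the Pearson correlation of
the binary truth/prediction vectors (asserted).

## Problem sizes and tolerances

The test and acceptance runs use desk-scale problems chosen as the
smallest sizes at which the properties of interest are stable: unmixing
recovery on a 64×64×600 cube (k = 3, pure pixels, SNR 20: matched
cosine ≥ 0.98, map r ≥ 0.95), cohorts of 50 cells per class for the
OPLS-DA pipeline (CV sensitivity > 0.9, specificity > 0.85), 60 cells
per class for the marker classifier (both AUCs > 0.9, quadrant accuracy
≥ 0.9), a 128×128 six-cell phantom for phasor segmentation (pixel
accuracy ≥ 0.95), permutation-test calibration over 200 null cohorts of
24 samples (empirical size at α = 0.05 within [0.01, 0.10]), and the
image-composition study on two 128×128 six-cell cubes decomposed jointly
(pooled, as replicates are pooled in practice) with per-component
thresholds from Otsu's split of pooled above-floor concentrations.
Floating-point tolerances follow the property class: machine-precision
identities (reconstruction, phasor linearity, oracle equivalences) are
asserted at 1e-9–1e-15; statistical properties use simulation bands
stated alongside each test.

## Known limitations

- The contrast-step operator and the high-intensity threshold rule are
  documented package choices; other implementations of
  contrast-constrained MCR may differ in detail.
- OPLS-DA is binary only; no multi-class extension, O2PLS, or
  shared-and-unique-structure plots.
- MCR offers no closure constraints, multi-image augmented mode, or
  uncertainty bands; rotational ambiguity is handled by invariant
  metrics, not resolved.
- The cell segmenter assumes roughly convex, non-touching cells on a
  dark background; no stitching, tracking, or nucleolus detection.
- Synthetic-data realism limits are listed in the generator section;
  conclusions about real instruments require real data.
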