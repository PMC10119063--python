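# Methods

`ramanpath` reimplements, end to end, a Raman hyperspectral-mapping (RHM)
analysis for subtyping pancreatic cancer (PC) tissue: conventional ductal
adenocarcinoma (cPDAC), intraductal papillary mucinous carcinoma (IPMC),
ampulla-of-Vater adenocarcinoma (AVAC), benign pancreatic tissue, and
stroma/empty background. No spectral data are publicly deposited for this
problem, so the package pairs every analysis step with a synthetic-data
generator whose templates encode the reported spectroscopy. This note
records the models, the parameters that matter, and the design choices made
where the design was genuinely open.

## Synthetic data model

**Spectra.** All Raman spectra live on the fingerprint axis 600–1900 cm⁻¹
at 2 cm⁻¹ steps (651 points); the FTIR preset uses 800–1800 cm⁻¹ at
4 cm⁻¹. A class/compartment template is a sum of Gaussian bands
(Lorentzian available) at literature positions: phenylalanine 1004,
CH₂/CH₃ bending 1450, amide II 1550, amide I 1650 cm⁻¹ (red-shifted to
1664 cm⁻¹ in AVAC cytoplasm, reflecting β-sheet-rich protein), the water
O–H bend at 1643 cm⁻¹ (broad, σ=45 cm⁻¹ — tissue is measured immersed in
saline), DNA phosphate stretches at 1090 and 1256 cm⁻¹, and the
methylation-sensitive CH₂/CH₃ deformation band centered at 1395 cm⁻¹
(IPMC additionally carries a discrete 1408 cm⁻¹ sub-band). Collagen stroma
has strong 856/940/1246/1450 cm⁻¹ bands relative to its amide I — the
basis of the FTIR 1450/1650 and 1406/1650 collagen markers. The nuclear
(histone) amide I sits at 1655 cm⁻¹ for every class: the class-specific
amide shift is treated as a property of the cytoplasmic proteome, so the
nuclear contrast between classes is carried by the methylation band — which
is what the nuclei PCA is designed to read.

**Calibration.** Band amplitudes and widths are not reported anywhere, so
they are generator defaults in arbitrary units (amide I ≡ 1). Two amplitude
families are calibrated rather than guessed: the β-sheet shoulder (rendered
at 1679 cm⁻¹, the center of the 1668–1690 cm⁻¹ marker window, σ=8) and the
1395 cm⁻¹ methylation band are solved per class by 1-D root finding so that
the noise-free templates reproduce the published marker ratios — β-sheet
0.23/0.18/0.16/0.10 and methylation 2.68/3.58/1.20/4.79 for
AVAC/IPMC/cPDAC/benign. AVAC needs no explicit shoulder (its 1664 cm⁻¹
amide I already fills the β window); its ratio is trimmed from above by
solving for its amide II amplitude instead. Only the orderings across
classes are contractual; the solved amplitudes are calibration, not ground
truth. `analysis/01_calibrate_templates.py` re-derives them.

**Maps.** A synthetic tissue map assigns each pixel one compartment role —
nucleus, cytoplasm, stroma, water/empty. Nuclei are random disks (radius
2.5 px), stroma is oriented elongated fibers for cPDAC/AVAC but a
homogeneous field for IPMC, water seeds at the map border. Role budgets are
filled exactly (greedy quantile assignment on smooth score fields), so
requested area fractions are met to rounding. Each pixel spectrum is its
role template plus a constant 0.25 water background (saline is everywhere),
a shared cubic polynomial baseline, and i.i.d. additive Gaussian noise
(default σ = 0.02, i.e. 2 % of the amide I amplitude — a band-SNR a
6-second-per-pixel acquisition comfortably achieves). Poisson noise and
cosmic spikes are not modeled.

**Training sets.** Classifier spectra mix each class's nucleus and
cytoplasm templates (stroma and water for the background class) with
multiplicative per-band amplitude jitter (default 5 %). By default the
mixing weight is fixed at 0.5, making the generator reproducible down to
"zero noise ⇒ identical spectra"; for models meant to predict *maps*, the
generator can instead draw the mixing weight uniformly, add random cubic
baselines, and include the water background, so pure-role map pixels are
inside the training distribution.

**What passing tests do not show.** The generator has no paraffin residue,
no instrument drift, no wavenumber miscalibration, no spatial correlation
in the noise, and classes are exactly template-shaped. Results here
demonstrate that the pipeline's machinery is correct and that the markers /
classifier respond to the encoded biology; they say nothing about
patient-tissue variability.

## Preprocessing

Baseline → Savitzky–Golay smoothing → SNV, in that order. The baseline is
an iterative modified polynomial fit (degree 3): fit, clip the working
signal at fit + (working-residual SD), refit until the fit changes by
< 1e-6 relative RMS (max 100 passes). Letting the clip level shrink with
the *working* residual makes the fit descend onto the background from above;
plain min-clipping converges to a drooped fixed point below the true
baseline and distorts band areas, which is why that variant is offered only
as the non-iterative single-polyfit mode. SG smoothing is 3rd order, 17
points; cubics are reproduced exactly at interior points. SNV uses the
sample (n−1) standard deviation over 1800–800 cm⁻¹ and crops to that
window. Second derivatives use the same SG filter with `deriv=2`, scaled
by the squared step. Resampling to the classifier's 512-point grid is
linear interpolation with endpoints preserved.

## Segmentation, unmixing, PCA

**HCA** is Ward's minimum-variance agglomeration on Euclidean distances
over preprocessed pixel spectra (scipy linkage), cut at k=7 for Raman maps
and k=5 for the FTIR preset; k is a user parameter, there is no automatic
selection. The test suite checks the linkage tree against an O(n³)
brute-force Ward oracle.

**NMF** minimizes the Frobenius reconstruction error with Lee–Seung
multiplicative updates: rank 3 by default, seeded uniform-random
initialisation, 5 restarts keeping the best objective, tol 1e-6 on the
relative error change, max 2000 iterations. SNV makes spectra dip
negative, so each spectrum is offset-shifted by its own minimum before
factorization and the shifts are recorded. Components are assigned chemical
roles by marker windows (water 1633–1653; nucleic acids 1080–1100 +
1246–1266; proteins 994–1014 + 1600–1700 cm⁻¹). A component's role score
is the *minimum* over the role's windows of the mean window intensity,
normalized by the component's overall mean — a role must show all of its
bands, which stops the broad water band from claiming the protein role
through the amide window. Roles are claimed greedily by descending score,
each component used once; leftovers are "other".

**PCA** of nuclei spectra runs on SG second derivatives (baseline
suppression), mean-centered, via SVD — equivalent to eigendecomposition of
the covariance. Loadings are oriented so the maximum-magnitude element is
positive; score signs follow. All groups are pooled into one model (a
per-group option exists). Explained-variance fractions are validated
against a brute-force covariance eigendecomposition and scikit-learn.

## Markers

Band quantities are trapezoidal integrals over closed windows with
endpoints included by linear interpolation; a peak-height mode exists
because the original ratio definition (area vs height) is not stated.
β-sheet ratio = area(1668–1690)/area(1514–1750); methylation ratio =
area(1360–1420)/area(1050–1150); FTIR collagen ratios use ±8 cm⁻¹ windows
around 1450/1406 and 1650 cm⁻¹. On SNV or derivative spectra, intensities
are min-shifted to zero over the window before integrating
(`shift_min=True`). The amide I position is the 1600–1700 cm⁻¹ argmax
refined by 3-point parabolic interpolation. Markers are usually read off
NMF component spectra (protein component for β-sheet, nucleic-acid
component for methylation) but accept any spectrum.

## The classifier

A sequential 1-D CNN consumes raw spectra — no preprocessing — as (2, 512)
tensors (row 0 intensity, row 1 wavenumber). Architecture: 18 convolution
layers in six blocks of three (kernel 7, stride 1, 'same' padding, ReLU,
max-pool 2 per block), then four dense layers 512/256/128/5 with terminal
softmax. Filter counts per block are 8/8/16/16/32/32 — the reference
architecture fixes only the layer counts and dense sizes, and these widths
keep single-CPU training fast while the synthetic classes remain easily
separable (≈348 k parameters). Initialisation is glorot-uniform, the
optimizer Adam (lr 1e-3, β₁ 0.9, β₂ 0.999), the loss categorical
cross-entropy, batch size 105, split 70/30 stratified (per-class
proportions preserved within one sample). The whole stack — im2col + GEMM
convolutions, pooling, batch norm, dense layers, Adam — is implemented in
this package on float32 numpy arrays, so a fixed seed gives bit-identical
training runs on a given platform.

Two numerical choices matter. First, each convolution is followed by
per-channel batch normalization (momentum 0.9, running stats seeded from
the first batch): a plain 18-layer ReLU stack under glorot initialisation
collapses — activations shrink by ~1/√2 per layer and the nonnegative
activations align onto a single mean direction, after which Adam cannot
recover within realistic budgets. Centering per channel removes that
collapse. Second, the wavenumber input row is scaled by a fixed constant
1e-3 inside the model (it is part of the architecture, not a data-dependent
step), so both input rows are O(1) and glorot-scaled weights see
well-conditioned inputs.

Dense-layer activations (post-ReLU, lengths 512/256/128 for the
begin/middle/end stages) can be extracted per spectrum for feature
visualisation. Prediction maps apply the trained model to every raw pixel
spectrum (argmax class + probability vector per pixel) and render with the
fixed palette: yellow stroma/empty, blue AVAC, magenta IPMC, red cPDAC,
green benign.

**Problem sizes.** The scaled-down training experiment used throughout —
1,500 spectra per class for 5 classes, 30 epochs — was chosen so the full
run (generation, tensorisation, training, evaluation) completes in minutes
on one CPU while leaving the accuracy criteria (held-out ≥ 94 %, training
≥ 99 %, held-out loss ≤ 0.17) a wide margin; at these settings the
synthetic run saturates near 100 %/100 %/≈1e-7. Tissue maps default to
48×48 pixels (the analysis drivers) and 16–24 px in smoke tests.

## Determinism

Every stochastic step (generation, layout, NMF init, shuffling, weight
init) consumes an explicit seed; the pipeline config refuses to run without
one. Repeated runs with the same config are byte-identical on the same
platform/BLAS; exact bit-reproducibility across different BLAS builds is
not claimed.

## Known limitations

- Template-shaped classes make the classification task easier than real
  histology; reported accuracies are ceilings, not estimates.
- The NMF variant and initialisation used for the original analysis are
  unknown; equivalence is asserted through recovery properties on known
  factors, not through component curves.
- ModPoly-family baselines assume the background is polynomial over the
  full window; strongly curved fluorescence backgrounds would need a
  different scheme.
- The exact convolutional hyperparameters of the reference CNN are not
  public; only the layer cardinality (18 conv + 4 dense, 512/256/128/5) and
  the training regime are matched.
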