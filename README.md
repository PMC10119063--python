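# ramanpath

Raman hyperspectral map analysis for pancreatic-cancer subtyping:
synthetic tissue-map generation, chemometric preprocessing, Ward
hierarchical clustering (HCA), NMF spectral unmixing, second-derivative PCA
of nuclei spectra, band-ratio biomarkers, and a 5-class 1-D CNN that turns
raw pixel spectra into tissue prediction maps.

## The problem

Pancreatic tumors of different origin — conventional ductal adenocarcinoma
(cPDAC), intraductal papillary mucinous carcinoma (IPMC), and
ampulla-of-Vater adenocarcinoma (AVAC) — are hard to tell apart even for
experienced pathologists, yet they differ chemically. Raman hyperspectral
mapping (one fingerprint spectrum, 1900–600 cm⁻¹, per ~1 µm tissue pixel)
exposes two quantifiable signatures:

* **β-sheet protein content** — the ratio of β-sheet amide I
  (1690–1668 cm⁻¹) to total amide I (1750–1514 cm⁻¹) band area,

  $r_\beta = \dfrac{\int_{1668}^{1690} I(\tilde\nu)\,d\tilde\nu}{\int_{1514}^{1750} I(\tilde\nu)\,d\tilde\nu}$,

  highest in AVAC, whose amide I maximum is red-shifted from 1650 to
  1664 cm⁻¹; the class ordering is AVAC > IPMC > cPDAC > benign.
* **global DNA methylation** — the ratio of the CH₂/CH₃ deformation region
  (1360–1420 cm⁻¹, where 5-methylcytosine signal grows) to the phosphate
  symmetric stretch (1050–1150 cm⁻¹), ordering
  benign > IPMC > AVAC > cPDAC.

The package implements the full workflow around these markers: maps are
segmented by Ward HCA (7 clusters), unmixed by rank-3 NMF into protein /
water / nucleic-acid components (markers are read off the components, so
the overlapping 1643 cm⁻¹ water band cannot contaminate amide I), nuclei
spectra are compared across tumors by PCA on second derivatives, and an
18-convolution / 4-dense-layer CNN classifies *raw* spectra — no
preprocessing — into five classes (stroma/empty, AVAC, IPMC, cPDAC,
benign) to paint per-pixel prediction maps.

No spectral data are deposited for this problem, so a first-class
synthetic-data module (`ramanpath.synthgen`) generates spectra, isolated
methylated/unmethylated DNA references, and spatially structured tissue
maps with known ground truth; its band amplitudes are calibrated so the
noise-free class templates reproduce the published marker ratios
(β-sheet 0.23/0.18/0.16/0.10; methylation 2.68/3.58/1.20/4.79). See
`docs/methods.md` for the model and its limits.

## Worked example

```python
from ramanpath.synthgen import SyntheticTissueSpec, generate_tissue_map
from ramanpath.unmix import nmf, assign_components
from ramanpath.markers import beta_sheet_ratio, methylation_ratio
from ramanpath.core import Spectrum

hmap = generate_tissue_map(SyntheticTissueSpec(class_name="AVAC", seed=0))
cs = assign_components(nmf(hmap, rank=3, seed=0))
protein = Spectrum(hmap.axis, cs.component_spectra[cs.component_for("proteins")])
nucleic = Spectrum(hmap.axis, cs.component_spectra[cs.component_for("nucleic_acids")])
print(f"beta-sheet ratio  {beta_sheet_ratio(protein, shift_min=True):.3f}")
print(f"methylation ratio {methylation_ratio(nucleic, shift_min=True):.3f}")
```

prints, for the 48×48 AVAC demo map:

```
beta-sheet ratio  0.093
methylation ratio 1.353
```

i.e. the protein component of the AVAC map carries more β-sheet signal
than a benign map's (0.081) and its chromatin is less methylated than
benign (3.015) but more than cPDAC (0.539) — the directions the markers
are designed to read.

The numbered drivers under `analysis/` run the whole study and write their
tables and images to `results/`:

```
01_calibrate_templates.py  re-derive the template amplitude calibration
02_generate_maps.py        one 48x48 ground-truth map per tumor class
03_hca_segmentation.py     preprocessing + 7-cluster Ward HCA maps
04_nmf_markers.py          rank-3 NMF, component assignment, marker table
05_nuclei_pca.py           second-derivative PCA of pooled nuclei spectra
06_dna_methylation.py      methylated vs unmethylated DNA reference pair
07_train_cnn.py            train the 5-class CNN (learning curves, model)
08_prediction_maps.py      per-pixel CNN prediction maps + agreement
```

Representative output of `07`/`08` (seed 0): final training accuracy
99.5 %, held-out accuracy 99.8 %; prediction maps agree with the
ground-truth class layer on 100 % (AVAC), 99.4 % (IPMC), 100 % (cPDAC) and
90.9 % (benign) of pixels — benign and IPMC nuclei, both hypermethylated,
are the closest contrast.

A `ramanpath` CLI wraps the same functionality
(`generate`, `preprocess`, `hca`, `nmf`, `pca`, `markers`, `cnn-train`,
`cnn-predict`, `cnn-features`, `run`).

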