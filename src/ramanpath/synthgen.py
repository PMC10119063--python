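"""Synthetic Raman spectra, DNA reference spectra, and tissue maps.

No spectral data accompany the study this package reproduces, so every
analysis runs on synthetic material generated here.  The generator renders
class-specific spectral templates as sums of Gaussian (optionally
Lorentzian) bands placed at the positions reported for pancreatic tissue:
phenylalanine at 1004, CH2/CH3 bending at 1450, amide I at 1650 cm^-1
(1664 cm^-1 for AVAC, whose proteins are beta-sheet rich), the water O-H
bend at 1643, DNA phosphate stretches at 1090 and 1256, and the
methylation-sensitive CH2/CH3 deformation region at 1360-1420 cm^-1 (with
the extra 1408 cm^-1 sub-band seen in IPMC chromatin).

Band amplitudes and widths are not reported anywhere, so they are generator
defaults.  The beta-sheet shoulder and methylation-band amplitudes are
calibrated so that the noise-free class templates reproduce the printed
marker ratios (beta-sheet ~0.23/0.18/0.16/0.10 for AVAC/IPMC/cPDAC/benign;
methylation ~4.79/3.58/2.68/1.20 for benign/IPMC/AVAC/cPDAC); only the
orderings are contractual, the amplitudes are calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    CLASS_CODES,
    CLASS_NAMES,
    ROLE_NAMES,
    HyperMap,
    LabeledSpectraSet,
    SpectralAxis,
    Spectrum,
    raman_axis,
)

__all__ = [
    "PeakSpec",
    "ClassTemplate",
    "RegionLayout",
    "SyntheticTissueSpec",
    "render_template",
    "render_peaks",
    "class_templates",
    "get_template",
    "generate_dna_pair",
    "generate_tissue_map",
    "generate_training_set",
    "DEFAULT_NOISE_SD",
    "DEFAULT_JITTER",
    "BETA_SHOULDER_AMP",
    "METHYL_BAND_AMP",
]

#: Default additive Gaussian noise level, in the same arbitrary intensity
#: units as the templates (template peak amplitudes are O(1)).
DEFAULT_NOISE_SD: float = 0.02

#: Default relative (multiplicative) per-peak amplitude jitter for training sets.
DEFAULT_JITTER: float = 0.05

# Calibrated beta-sheet shoulder amplitudes per class (frozen output of the
# calibration fit in analysis/01_calibrate_templates.py).  AVAC needs no
# explicit shoulder: its red-shifted 1664 cm^-1 amide I alone fills the
# beta-sheet window, and its ratio is trimmed via AMIDE_II_AMP instead.
BETA_SHOULDER_AMP: dict[str, float] = {
    "AVAC": 0.0,
    "IPMC": 0.4512,
    "cPDAC": 0.3608,
    "benign": 0.1191,
}

# Calibrated methylation-band (1395 cm^-1) amplitudes per class.
METHYL_BAND_AMP: dict[str, float] = {
    "AVAC": 0.9985,
    "IPMC": 1.6159,
    "cPDAC": 0.4444,
    "benign": 1.7885,
}

#: Amide I band centers per class (cm^-1): AVAC is red-shifted to 1664 by its
#: beta-sheet-rich proteins; the others sit at the alpha-helix position.
AMIDE_I_CENTER: dict[str, float] = {
    "AVAC": 1664.0,
    "IPMC": 1650.0,
    "cPDAC": 1650.0,
    "benign": 1650.0,
    "stroma_empty": 1660.0,
}

#: Fraction of the methylation-band amplitude assigned to the discrete
#: 1408 cm^-1 sub-band that appears in IPMC chromatin.
IPMC_1408_FRACTION: float = 0.30

#: Center/width of the rendered beta-sheet shoulder band (cm^-1).  Placed at
#: the middle of the 1668-1690 beta-sheet amide I window.
BETA_SHOULDER_CENTER: float = 1679.0
BETA_SHOULDER_SIGMA: float = 8.0

# Amide II amplitude per class.  AVAC's value is calibrated (jointly with the
# zero shoulder) because its 1664 cm^-1 amide I alone already saturates the
# beta-sheet window; see module docstring.
AMIDE_II_AMP: dict[str, float] = {
    "AVAC": 0.6393,
    "IPMC": 0.55,
    "cPDAC": 0.55,
    "benign": 0.55,
    "stroma_empty": 0.55,
}


@dataclass(frozen=True)
class PeakSpec:
    """One spectral band: center (cm^-1), amplitude, width (Gaussian sigma, cm^-1)."""

    center: float
    amplitude: float
    width: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")


@dataclass(frozen=True)
class ClassTemplate:
    """Noise-free spectral template of one class/compartment combination."""

    class_name: str
    subcellular_role: str
    peaks: tuple[PeakSpec, ...]
    amideI_center: float
    beta_amplitude: float = 0.0
    methyl_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_name!r}")
        if self.subcellular_role not in ROLE_NAMES:
            raise ValueError(f"unknown role {self.subcellular_role!r}")
        if not (1600.0 <= self.amideI_center <= 1700.0) and self.subcellular_role != "water":
            raise ValueError("amide I center must lie in [1600, 1700] cm^-1")


def render_peaks(peaks: tuple[PeakSpec, ...] | list[PeakSpec], axis: SpectralAxis) -> np.ndarray:
    """Sum of rendered band profiles on the axis grid (no baseline, no noise)."""
    wn = axis.wavenumbers
    out = np.zeros(len(axis))
    for p in peaks:
        if not (axis.lo - 1e-9 <= p.center <= axis.hi + 1e-9):
            raise ValueError(
                f"peak center {p.center} cm^-1 outside axis range [{axis.lo}, {axis.hi}]"
            )
        if p.shape == "gaussian":
            out += p.amplitude * np.exp(-0.5 * ((wn - p.center) / p.width) ** 2)
        else:  # lorentzian
            out += p.amplitude * p.width**2 / ((wn - p.center) ** 2 + p.width**2)
    return out


def render_template(template: ClassTemplate, axis: SpectralAxis | None = None) -> Spectrum:
    """Render a class template on the (default Raman) axis."""
    ax = axis or raman_axis()
    return Spectrum(ax, render_peaks(template.peaks, ax))


def _cytoplasm_peaks(class_name: str) -> tuple[PeakSpec, ...]:
    amide = AMIDE_I_CENTER[class_name]
    beta = BETA_SHOULDER_AMP[class_name]
    peaks = [
        PeakSpec(853.0, 0.30, 7.0),
        PeakSpec(880.0, 0.22, 6.0),
        PeakSpec(1004.0, 0.90, 4.0),  # Phe ring breathing
        PeakSpec(1033.0, 0.35, 4.0),
        PeakSpec(1126.0, 0.28, 7.0),
        PeakSpec(1208.0, 0.25, 7.0),
        PeakSpec(1340.0, 0.32, 9.0),
        PeakSpec(1450.0, 0.80, 10.0),  # CH2/CH3 bending
        PeakSpec(1550.0, AMIDE_II_AMP[class_name], 12.0),  # amide II
        PeakSpec(amide, 1.00, 14.0),  # amide I
    ]
    if beta > 0:
        peaks.append(
            PeakSpec(BETA_SHOULDER_CENTER, beta, BETA_SHOULDER_SIGMA)
        )  # beta-sheet shoulder
    return tuple(peaks)


#: Histone amide I position (cm^-1); conserved across classes -- the
#: class-specific amide shift is a property of the cytoplasmic proteome.
NUCLEUS_AMIDE_CENTER: float = 1655.0


def _nucleus_peaks(class_name: str) -> tuple[PeakSpec, ...]:
    amide = NUCLEUS_AMIDE_CENTER
    beta = BETA_SHOULDER_AMP[class_name]
    methyl = METHYL_BAND_AMP[class_name]
    peaks = [
        PeakSpec(785.0, 0.70, 6.0),  # DNA ring breathing / O-P-O
        PeakSpec(828.0, 0.28, 7.0),
        PeakSpec(1090.0, 0.55, 8.0),  # PO2- symmetric stretch
        PeakSpec(1256.0, 0.50, 9.0),  # PO2- asymmetric stretch
        PeakSpec(1304.0, 0.28, 8.0),
        PeakSpec(1340.0, 0.40, 9.0),
        PeakSpec(1450.0, 0.60, 10.0),
        PeakSpec(1485.0, 0.45, 8.0),  # G, A ring
        PeakSpec(1575.0, 0.42, 6.0),  # cytosine/guanine N-H
        PeakSpec(1614.0, 0.28, 7.0),
        PeakSpec(amide, 0.85, 14.0),  # histone amide I
    ]
    if methyl > 0:
        if class_name == "IPMC":
            peaks.append(PeakSpec(1395.0, methyl * (1 - IPMC_1408_FRACTION), 12.0))
            peaks.append(PeakSpec(1408.0, methyl * IPMC_1408_FRACTION, 5.0))
        else:
            peaks.append(PeakSpec(1395.0, methyl, 12.0))
    if beta > 0:
        peaks.append(PeakSpec(BETA_SHOULDER_CENTER, 0.8 * beta, BETA_SHOULDER_SIGMA))
    return tuple(peaks)


def _stroma_peaks() -> tuple[PeakSpec, ...]:
    # Collagen-dominated extracellular matrix: strong proline/hydroxyproline
    # and CH bands relative to amide I (the FTIR collagen hallmark).
    return (
        PeakSpec(856.0, 0.80, 7.0),
        PeakSpec(940.0, 0.60, 8.0),
        PeakSpec(1004.0, 0.30, 4.0),
        PeakSpec(1246.0, 0.60, 10.0),  # amide III
        PeakSpec(1270.0, 0.40, 9.0),
        PeakSpec(1406.0, 0.35, 8.0),  # CH3 bending
        PeakSpec(1450.0, 0.90, 10.0),
        PeakSpec(1550.0, 0.40, 12.0),
        PeakSpec(1660.0, 0.75, 14.0),  # collagen amide I
    )


def _water_peaks() -> tuple[PeakSpec, ...]:
    # Saline immersion medium: broad O-H bending band.
    return (PeakSpec(1643.0, 1.00, 45.0),)


def class_templates() -> dict[tuple[str, str], ClassTemplate]:
    """Registry of all (class, role) templates with calibrated defaults."""
    out: dict[tuple[str, str], ClassTemplate] = {}
    for cls in CLASS_NAMES:
        amide = AMIDE_I_CENTER[cls]
        beta = BETA_SHOULDER_AMP.get(cls, 0.0)
        methyl = METHYL_BAND_AMP.get(cls, 0.0)
        if cls != "stroma_empty":
            out[(cls, "cytoplasm")] = ClassTemplate(
                cls, "cytoplasm", _cytoplasm_peaks(cls), amide, beta, methyl
            )
            out[(cls, "nucleus")] = ClassTemplate(
                cls, "nucleus", _nucleus_peaks(cls), NUCLEUS_AMIDE_CENTER, beta, methyl
            )
        out[(cls, "stroma")] = ClassTemplate(cls, "stroma", _stroma_peaks(), 1660.0)
        out[(cls, "water")] = ClassTemplate(cls, "water", _water_peaks(), 1643.0)
    return out


def get_template(class_name: str, role: str) -> ClassTemplate:
    """One (class, role) template from the default registry."""
    registry = class_templates()
    key = (class_name, role)
    if key not in registry:
        raise KeyError(f"no template for class {class_name!r}, role {role!r}")
    return registry[key]


# ---------------------------------------------------------------------------
# Isolated-DNA reference pair
# ---------------------------------------------------------------------------

def _dna_peaks(methylation_level: float) -> tuple[PeakSpec, ...]:
    """Isolated genomic-DNA template at a given CpG methylation fraction.

    Methylation grows the 1360-1420 cm^-1 CH2/CH3 deformation signal, splits
    the phosphate symmetric stretch near 1090 cm^-1 into a doublet shifted
    slightly to higher wavenumbers (B- to A-form backbone rearrangement),
    shifts the 1256 cm^-1 asymmetric stretch likewise, and perturbs the
    cytosine bands at 1575 and 1614 cm^-1.
    """
    m = float(methylation_level)
    shift = 4.0 * m  # backbone band shift at full methylation (default, cm^-1)
    peaks = [
        PeakSpec(785.0, 0.90, 6.0),
        PeakSpec(1340.0, 0.45, 9.0),
        PeakSpec(1375.0, 0.15, 8.0),  # thymine CH3
        PeakSpec(1485.0, 0.60, 8.0),
        PeakSpec(1575.0, 0.50 - 0.15 * m, 6.0),
        PeakSpec(1614.0, 0.30 + 0.12 * m, 7.0),
        PeakSpec(1256.0 + shift, 0.65, 9.0),
    ]
    # Phosphate symmetric stretch: single band -> split doublet with methylation.
    if m > 0:
        peaks.append(PeakSpec(1090.0 - 6.0 + shift, (1 - m) * 0.8 + m * 0.45, 7.0))
        peaks.append(PeakSpec(1090.0 + 6.0 + shift, m * 0.45, 7.0))
    else:
        peaks.append(PeakSpec(1090.0, 0.80, 7.0))
    # Methylation-sensitive CH2/CH3 deformation region.
    methyl_amp = 0.10 + 1.10 * m
    peaks.append(PeakSpec(1395.0, methyl_amp, 12.0))
    return tuple(peaks)


def generate_dna_pair(
    methylation_level: float = 0.98,
    n: int = 10,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    axis: SpectralAxis | None = None,
) -> LabeledSpectraSet:
    """Replicate spectra of an unmethylated/methylated isolated-DNA pair.

    Returns ``2 n`` spectra: the first ``n`` unmethylated (label 4, reusing
    the benign code as "control") and the last ``n`` methylated at
    ``methylation_level`` (label 2, the code of the hypermethylated IPMC
    class).  The label reuse is a bookkeeping convention only.
    """
    if not (0.0 <= methylation_level <= 1.0):
        raise ValueError("methylation_level must be in [0, 1]")
    if n <= 0:
        raise ValueError("n must be positive")
    ax = axis or raman_axis()
    rng = np.random.default_rng(seed)
    unmeth = render_peaks(_dna_peaks(0.0), ax)
    meth = render_peaks(_dna_peaks(methylation_level), ax)
    spectra = np.vstack([np.tile(unmeth, (n, 1)), np.tile(meth, (n, 1))])
    if noise_sd > 0:
        spectra = spectra + rng.normal(0.0, noise_sd, spectra.shape)
    labels = np.concatenate([np.full(n, 4), np.full(n, 2)])
    return LabeledSpectraSet(ax, spectra, labels, seed=seed)


# ---------------------------------------------------------------------------
# Spatially structured tissue maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionLayout:
    """Spatial parameters of a synthetic tissue map.

    ``fractions`` gives the target area fraction of each compartment role;
    they must sum to 1.  Nuclei are placed as random disks; stroma forms
    oriented fibers for cPDAC/AVAC and a homogeneous field for IPMC;
    ``water_background`` is the water abundance mixed into every non-water
    pixel (tissue sections are measured immersed in saline).
    """

    fractions: dict[str, float] = field(
        default_factory=lambda: {
            "nucleus": 0.20,
            "cytoplasm": 0.40,
            "stroma": 0.25,
            "water": 0.15,
        }
    )
    nucleus_radius: float = 2.5
    fiber_width: float = 1.8
    fiber_length: float = 12.0
    water_background: float = 0.25

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"area fractions must sum to 1, got {total}")
        for role, frac in self.fractions.items():
            if role not in ROLE_NAMES:
                raise ValueError(f"unknown role {role!r}")
            if frac < 0:
                raise ValueError("fractions must be >= 0")


@dataclass(frozen=True)
class SyntheticTissueSpec:
    """Full recipe for one synthetic hyperspectral tissue map."""

    map_width: int = 48
    map_height: int = 48
    class_name: str = "cPDAC"
    layout: RegionLayout = field(default_factory=RegionLayout)
    baseline_coeffs: tuple[float, float, float, float] = (0.3, 0.15, -0.08, 0.04)
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.map_width <= 0 or self.map_height <= 0:
            raise ValueError("map dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.class_name not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_name!r}")
        if len(self.baseline_coeffs) != 4:
            raise ValueError("baseline_coeffs must be a cubic (4 coefficients)")


def _role_score_fields(spec: SyntheticTissueSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Smooth per-role affinity fields used to carve the map into regions."""
    h, w = spec.map_height, spec.map_width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    lay = spec.layout
    scores: dict[str, np.ndarray] = {}

    # Nuclei: union of disk bumps at random centers.
    frac_nuc = lay.fractions.get("nucleus", 0.0)
    n_nuclei = max(1, int(round(frac_nuc * h * w / (np.pi * lay.nucleus_radius**2)))) if frac_nuc > 0 else 0
    nuc = np.zeros((h, w))
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        nuc += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * lay.nucleus_radius**2))
    scores["nucleus"] = nuc

    # Stroma: oriented elongated blobs (fibrous) except for IPMC, where the
    # collagen is distributed homogeneously.
    frac_str = lay.fractions.get("stroma", 0.0)
    stroma = np.zeros((h, w))
    if frac_str > 0:
        if spec.class_name == "IPMC":
            stroma = rng.normal(0.0, 1.0, (h, w))
            # heavy smoothing -> near-homogeneous field
            from scipy.ndimage import gaussian_filter

            stroma = gaussian_filter(stroma, sigma=max(h, w) / 6.0, mode="nearest")
        else:
            n_fibers = max(1, int(round(frac_str * h * w / (lay.fiber_width * lay.fiber_length * 4))))
            for _ in range(n_fibers):
                cy, cx = rng.uniform(0, h), rng.uniform(0, w)
                theta = rng.uniform(0, np.pi)
                u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
                v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
                stroma += np.exp(
                    -(u**2) / (2 * lay.fiber_length**2) - (v**2) / (2 * lay.fiber_width**2)
                )
    scores["stroma"] = stroma

    # Water/empty space: blobs seeded at the map border.
    water = np.zeros((h, w))
    if lay.fractions.get("water", 0.0) > 0:
        n_blobs = max(2, (h + w) // 16)
        for _ in range(n_blobs):
            edge = rng.integers(0, 4)
            if edge == 0:
                cy, cx = 0.0, rng.uniform(0, w)
            elif edge == 1:
                cy, cx = float(h - 1), rng.uniform(0, w)
            elif edge == 2:
                cy, cx = rng.uniform(0, h), 0.0
            else:
                cy, cx = rng.uniform(0, h), float(w - 1)
            r = rng.uniform(0.1, 0.2) * max(h, w)
            water += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * r**2))
    scores["water"] = water
    return scores


def _assign_roles(spec: SyntheticTissueSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-pixel role indices with area fractions matched to the layout.

    Roles are assigned greedily (nucleus, stroma, water, rest cytoplasm):
    each role claims its exact pixel budget from the highest-scoring still
    unassigned pixels, so generated fractions match the requested ones to
    rounding while keeping spatial coherence from the smooth score fields.
    """
    h, w = spec.map_height, spec.map_width
    n = h * w
    lay = spec.layout
    scores = _role_score_fields(spec, rng)
    role_idx = {r: i for i, r in enumerate(ROLE_NAMES)}

    counts = {r: int(round(lay.fractions.get(r, 0.0) * n)) for r in ("nucleus", "stroma", "water")}
    labels = np.full(n, role_idx["cytoplasm"])
    assigned = np.zeros(n, dtype=bool)
    # tiny seeded dither breaks score ties deterministically
    dither = rng.uniform(0, 1e-9, n)
    for role in ("nucleus", "stroma", "water"):
        k = counts[role]
        if k <= 0:
            continue
        score = scores[role].ravel() + dither
        score[assigned] = -np.inf
        take = np.argsort(score, kind="stable")[::-1][:k]
        labels[take] = role_idx[role]
        assigned[take] = True
    if lay.fractions.get("cytoplasm", 0.0) == 0.0:
        # no cytoplasm in this tissue (e.g. pure stroma/empty maps): hand the
        # remainder to the largest requested role
        rest = ~assigned
        if rest.any():
            major = max(lay.fractions, key=lay.fractions.get)
            labels[rest] = role_idx[major]
    return labels.reshape(h, w)


def generate_tissue_map(spec: SyntheticTissueSpec, axis: SpectralAxis | None = None) -> HyperMap:
    """Generate a hyperspectral tissue map with ground-truth layers.

    Each pixel's spectrum is the abundance-weighted mixture of the class's
    role templates plus a shared cubic polynomial baseline and i.i.d.
    Gaussian noise.  Pixels are pure in their assigned role except for the
    ``water_background`` fraction of the water template mixed in everywhere.
    Returned layers: ``role_labels`` (indices into ROLE_NAMES),
    ``class_labels`` (codes 0-4: cellular pixels carry the tissue class,
    stroma/water pixels carry 0), and per-role ``abundances``.
    """
    ax = axis or raman_axis()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.map_height, spec.map_width
    role_labels = _assign_roles(spec, rng)

    registry = class_templates()
    cls = spec.class_name
    role_spectra = {}
    for role in ROLE_NAMES:
        key = (cls, role)
        role_spectra[role] = (
            render_peaks(registry[key].peaks, ax) if key in registry else np.zeros(len(ax))
        )

    # Ground-truth abundances: one-hot in the assigned role, plus the ambient
    # water background in every non-water pixel.
    wb = spec.layout.water_background
    abundances = {role: np.zeros((h, w)) for role in ROLE_NAMES}
    for i, role in enumerate(ROLE_NAMES):
        abundances[role][role_labels == i] = 1.0
    if wb > 0:
        abundances["water"] = np.clip(abundances["water"] + wb, 0.0, 1.0)

    cube = np.zeros((h, w, len(ax)))
    for role in ROLE_NAMES:
        cube += abundances[role][..., None] * role_spectra[role][None, None, :]

    # Shared cubic baseline over the normalised axis coordinate.
    t = (ax.wavenumbers - ax.wavenumbers.mean()) / (ax.hi - ax.lo)
    baseline = np.polynomial.polynomial.polyval(t, np.asarray(spec.baseline_coeffs))
    cube += baseline[None, None, :]
    if spec.noise_sd > 0:
        cube = cube + rng.normal(0.0, spec.noise_sd, cube.shape)

    cellular = np.isin(role_labels, [ROLE_NAMES.index("nucleus"), ROLE_NAMES.index("cytoplasm")])
    class_labels = np.where(cellular, CLASS_CODES[cls], CLASS_CODES["stroma_empty"])

    return HyperMap(
        axis=ax,
        cube=cube,
        role_labels=role_labels,
        class_labels=class_labels,
        abundances=abundances,
        meta={
            "class_name": cls,
            "seed": spec.seed,
            "noise_sd": spec.noise_sd,
            "baseline_coeffs": list(spec.baseline_coeffs),
        },
    )


# ---------------------------------------------------------------------------
# Labeled training sets for the CNN
# ---------------------------------------------------------------------------

def _class_role_profiles(
    class_name: str, ax: SpectralAxis
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unit-amplitude peak profiles and amplitudes for a class's two roles.

    Cellular classes mix nucleus and cytoplasm templates; the stroma/empty
    class mixes stroma and water.  Returns ``(profiles_a, amps_a,
    profiles_b, amps_b)`` with profiles of shape (n_peaks, axis length).
    """
    if class_name == "stroma_empty":
        roles = ("stroma", "water")
    else:
        roles = ("nucleus", "cytoplasm")
    registry = class_templates()
    out: list[np.ndarray] = []
    for role in roles:
        profiles, amps = [], []
        for p in registry[(class_name, role)].peaks:
            unit = render_peaks((PeakSpec(p.center, 1.0, p.width, p.shape),), ax)
            profiles.append(unit)
            amps.append(p.amplitude)
        out.extend([np.asarray(profiles), np.asarray(amps)])
    return out[0], out[1], out[2], out[3]


def generate_training_set(
    classes: list[str] | tuple[str, ...] = CLASS_NAMES,
    n_per_class: int = 100,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    jitter: float = DEFAULT_JITTER,
    axis: SpectralAxis | None = None,
    mixture_range: tuple[float, float] | None = None,
    baseline_sd: float = 0.0,
    water_background: float = 0.0,
) -> LabeledSpectraSet:
    """Labeled raw spectra for classifier training.

    Each spectrum mixes the class's nucleus and cytoplasm templates (stroma
    and water for the stroma_empty class) with every band amplitude jittered
    multiplicatively by ``1 + jitter * N(0, 1)`` (clipped at 0) and additive
    Gaussian noise of ``noise_sd``.  By default the mixing weight is fixed at
    0.5, so with ``jitter=0`` and ``noise_sd=0`` all spectra of a class are
    identical.

    To emulate the variability of real map pixels, ``mixture_range=(lo, hi)``
    draws the mixing weight uniformly per spectrum, ``baseline_sd`` adds a
    random cubic baseline (coefficients ~ N(0, baseline_sd) on the
    normalised axis), and ``water_background`` adds that fraction of the
    ambient water template to every spectrum -- matching the construction of
    :func:`generate_tissue_map` pixels.
    """
    for cls in classes:
        if cls not in CLASS_NAMES:
            raise ValueError(f"unknown class {cls!r}")
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    ax = axis or raman_axis()
    rng = np.random.default_rng(seed)
    water = render_peaks(_water_peaks(), ax)
    t = (ax.wavenumbers - ax.wavenumbers.mean()) / (ax.hi - ax.lo)
    tpow = np.vstack([t**p for p in range(4)])
    blocks, labels = [], []
    for cls in classes:
        profiles_a, amps_a, profiles_b, amps_b = _class_role_profiles(cls, ax)
        if mixture_range is None:
            u = np.full(n_per_class, 0.5)
        else:
            u = rng.uniform(mixture_range[0], mixture_range[1], n_per_class)
        parts = []
        for profiles, amps, weight in (
            (profiles_a, amps_a, u),
            (profiles_b, amps_b, 1.0 - u),
        ):
            if jitter > 0:
                factors = np.clip(
                    1.0 + jitter * rng.standard_normal((n_per_class, amps.size)),
                    0.0,
                    None,
                )
            else:
                factors = np.ones((n_per_class, amps.size))
            parts.append(weight[:, None] * ((factors * amps[None, :]) @ profiles))
        block = parts[0] + parts[1]
        if water_background > 0 and cls != "stroma_empty":
            block = block + water_background * water[None, :]
        if baseline_sd > 0:
            coeffs = rng.normal(0.0, baseline_sd, (n_per_class, 4))
            block = block + coeffs @ tpow
        if noise_sd > 0:
            block = block + rng.normal(0.0, noise_sd, block.shape)
        blocks.append(block)
        labels.append(np.full(n_per_class, CLASS_CODES[cls]))
    return LabeledSpectraSet(ax, np.vstack(blocks), np.concatenate(labels), seed=seed)
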