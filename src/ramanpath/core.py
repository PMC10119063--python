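"""Shared containers for spectra and hyperspectral maps.

A hyperspectral Raman map is a rectangular grid of pixels, each holding one
spectrum sampled on a common wavenumber axis (the "fingerprint" region,
1900-600 cm^-1 at 2 cm^-1 steps by default).  Everything downstream --
preprocessing, clustering, unmixing, PCA, marker ratios, the CNN -- operates
on these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralAxis",
    "Spectrum",
    "HyperMap",
    "LabeledSpectraSet",
    "raman_axis",
    "ftir_axis",
    "CLASS_NAMES",
    "CLASS_CODES",
    "ROLE_NAMES",
]

#: Class code convention used throughout: 0 stroma/empty, 1 AVAC, 2 IPMC,
#: 3 cPDAC, 4 benign pancreatic tissue.
CLASS_NAMES: tuple[str, ...] = ("stroma_empty", "AVAC", "IPMC", "cPDAC", "benign")
CLASS_CODES: dict[str, int] = {name: i for i, name in enumerate(CLASS_NAMES)}

#: Subcellular/compartment roles a pixel can play inside a tissue map.
ROLE_NAMES: tuple[str, ...] = ("nucleus", "cytoplasm", "stroma", "water")


@dataclass(frozen=True)
class SpectralAxis:
    """A strictly monotone, uniformly spaced wavenumber grid (cm^-1)."""

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        if wn.ndim != 1 or wn.size < 2:
            raise ValueError("axis must be a 1-D array with at least 2 points")
        steps = np.diff(wn)
        if not (np.all(steps > 0) or np.all(steps < 0)):
            raise ValueError("axis must be strictly monotone")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise ValueError("axis must be uniformly spaced")
        object.__setattr__(self, "wavenumbers", wn)

    @property
    def step(self) -> float:
        """Signed grid spacing in cm^-1."""
        return float(self.wavenumbers[1] - self.wavenumbers[0])

    @property
    def lo(self) -> float:
        return float(self.wavenumbers.min())

    @property
    def hi(self) -> float:
        return float(self.wavenumbers.max())

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return self.wavenumbers.shape == other.wavenumbers.shape and bool(
            np.array_equal(self.wavenumbers, other.wavenumbers)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((float(self.wavenumbers[0]), float(self.wavenumbers[-1]), len(self)))

    def contains(self, lo: float, hi: float) -> bool:
        """Whether the closed window [lo, hi] lies inside the axis range."""
        return lo >= self.lo - 1e-9 and hi <= self.hi + 1e-9

    def index_nearest(self, wavenumber: float) -> int:
        return int(np.argmin(np.abs(self.wavenumbers - wavenumber)))


def raman_axis() -> SpectralAxis:
    """Default fingerprint-region Raman axis: 600-1900 cm^-1, 2 cm^-1 step (651 points)."""
    return SpectralAxis(np.arange(600.0, 1900.0 + 1e-9, 2.0))


def ftir_axis() -> SpectralAxis:
    """Default processed FTIR axis: 800-1800 cm^-1, 4 cm^-1 step (251 points)."""
    return SpectralAxis(np.arange(800.0, 1800.0 + 1e-9, 4.0))


@dataclass
class Spectrum:
    """One spectrum on a shared axis."""

    axis: SpectralAxis
    intensities: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        if y.ndim != 1:
            raise ValueError("intensities must be 1-D")
        if y.size != len(self.axis):
            raise ValueError(
                f"intensities length {y.size} != axis length {len(self.axis)}"
            )
        self.intensities = y

    def copy_with(self, intensities: np.ndarray) -> "Spectrum":
        return Spectrum(self.axis, np.asarray(intensities, dtype=float))


@dataclass
class HyperMap:
    """Rectangular grid of spectra with optional ground-truth layers.

    ``cube`` has shape (height, width, n_wavenumbers); pixel (0, 0) is the
    top-left corner, row-major.  ``role_labels`` (if present) gives each pixel
    a compartment role index into :data:`ROLE_NAMES` (-1 where undefined);
    ``class_labels`` gives a per-pixel class code 0-4; ``abundances`` maps a
    role name to its per-pixel ground-truth mixing weight.
    """

    axis: SpectralAxis
    cube: np.ndarray
    role_labels: np.ndarray | None = None
    class_labels: np.ndarray | None = None
    abundances: dict[str, np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cube = np.asarray(self.cube, dtype=float)
        if cube.ndim != 3:
            raise ValueError("cube must have shape (height, width, axis length)")
        if cube.shape[2] != len(self.axis):
            raise ValueError("cube spectral dimension does not match axis")
        self.cube = cube
        for name in ("role_labels", "class_labels"):
            layer = getattr(self, name)
            if layer is not None:
                layer = np.asarray(layer)
                if layer.shape != self.shape:
                    raise ValueError(f"{name} shape {layer.shape} != map shape {self.shape}")
                setattr(self, name, layer)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.cube.shape[0], self.cube.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.cube.shape[0] * self.cube.shape[1]

    def as_matrix(self) -> np.ndarray:
        """Pixels flattened row-major to an (n_pixels, axis length) matrix."""
        return self.cube.reshape(-1, len(self.axis))

    def with_cube(self, cube: np.ndarray) -> "HyperMap":
        """Same layers and metadata over a replacement intensity cube."""
        return HyperMap(
            axis=self.axis,
            cube=cube,
            role_labels=self.role_labels,
            class_labels=self.class_labels,
            abundances=self.abundances,
            meta=dict(self.meta),
        )


@dataclass
class LabeledSpectraSet:
    """A flat set of spectra with one class code (0-4) per spectrum."""

    axis: SpectralAxis
    spectra: np.ndarray
    labels: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.spectra, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        if X.ndim != 2 or X.shape[1] != len(self.axis):
            raise ValueError("spectra must be (n, axis length)")
        if y.shape != (X.shape[0],):
            raise ValueError("one label per spectrum required")
        if y.size and (y.min() < 0 or y.max() >= len(CLASS_NAMES)):
            raise ValueError("labels must be class codes 0-4")
        self.spectra = X
        self.labels = y

    def __len__(self) -> int:
        return self.spectra.shape[0]
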