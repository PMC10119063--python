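"""Band-ratio spectral markers.

Two formula-defined markers carry the biology here:

* **beta-sheet ratio** -- integrated beta-sheet amide I (1690-1668 cm^-1)
  over integrated total amide I (1750-1514 cm^-1).  Reports the relative
  content of beta-sheet-rich protein; highest in ampulla-of-Vater
  adenocarcinoma (AVAC) tissue.
* **methylation ratio** -- integrated CH2/CH3 deformation region
  (1360-1420 cm^-1, where the 5-methylcytosine-associated signal grows) over
  the phosphate symmetric-stretch region (1050-1150 cm^-1).  Reports relative
  global DNA methylation of chromatin.

Both are usually evaluated on NMF component spectra (protein component for
the beta-sheet marker, nucleic-acid component for methylation) but accept
any spectrum.  FTIR intensity ratios (1450/1650, 1406/1650) and the amide I
peak position complete the marker set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Spectrum

__all__ = [
    "BandWindow",
    "MarkerResult",
    "band_area",
    "band_height",
    "beta_sheet_ratio",
    "methylation_ratio",
    "intensity_ratio",
    "amide_I_center",
    "compute_markers",
    "BETA_NUM_WINDOW",
    "BETA_DEN_WINDOW",
    "METHYL_NUM_WINDOW",
    "METHYL_DEN_WINDOW",
]


@dataclass(frozen=True)
class BandWindow:
    """A closed wavenumber window [lo, hi] in cm^-1."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError("window lo must be < hi")

    @property
    def width(self) -> float:
        return self.hi - self.lo


BETA_NUM_WINDOW = BandWindow(1668.0, 1690.0)
BETA_DEN_WINDOW = BandWindow(1514.0, 1750.0)
METHYL_NUM_WINDOW = BandWindow(1360.0, 1420.0)
METHYL_DEN_WINDOW = BandWindow(1050.0, 1150.0)


@dataclass(frozen=True)
class MarkerResult:
    """Marker ratios for one spectrum, with the windows that produced them."""

    beta_sheet_ratio: float
    methylation_ratio: float
    amide_I_center: float
    windows: tuple[BandWindow, ...] = (
        BETA_NUM_WINDOW,
        BETA_DEN_WINDOW,
        METHYL_NUM_WINDOW,
        METHYL_DEN_WINDOW,
    )
    source_spectrum_id: str = ""


def _window_samples(s: Spectrum, w: BandWindow) -> tuple[np.ndarray, np.ndarray]:
    """Axis/intensity samples over [lo, hi], ascending, with interpolated endpoints."""
    if not s.axis.contains(w.lo, w.hi):
        raise ValueError(
            f"window [{w.lo}, {w.hi}] outside axis range "
            f"[{s.axis.lo}, {s.axis.hi}]"
        )
    wn = s.axis.wavenumbers
    y = s.intensities
    if wn[0] > wn[-1]:
        wn, y = wn[::-1], y[::-1]
    inner = (wn > w.lo) & (wn < w.hi)
    x_parts = [np.array([w.lo]), wn[inner], np.array([w.hi])]
    y_parts = [
        np.interp([w.lo], wn, y),
        y[inner],
        np.interp([w.hi], wn, y),
    ]
    return np.concatenate(x_parts), np.concatenate(y_parts)


def band_area(s: Spectrum, w: BandWindow, *, shift_min: bool = False) -> float:
    """Trapezoidal integral of intensity over the window.

    Grid points strictly inside [lo, hi] are used and the window endpoints are
    included by linear interpolation, so the integral covers exactly the
    stated width.  With ``shift_min=True`` the intensities are first shifted
    so their minimum over the window is zero -- appropriate for spectra that
    may dip negative after SNV or differentiation.
    """
    x, y = _window_samples(s, w)
    if shift_min:
        y = y - y.min()
    return float(np.trapezoid(y, x))


def band_height(s: Spectrum, w: BandWindow, *, shift_min: bool = False) -> float:
    """Maximum intensity over the window (peak-height alternative to area)."""
    _, y = _window_samples(s, w)
    if shift_min:
        y = y - y.min()
    return float(y.max())


def _ratio(
    s: Spectrum,
    num: BandWindow,
    den: BandWindow,
    mode: str,
    shift_min: bool,
) -> float:
    measure = {"area": band_area, "height": band_height}[mode]
    denominator = measure(s, den, shift_min=shift_min)
    if denominator == 0.0:
        raise ZeroDivisionError("denominator band integrates to zero")
    return measure(s, num, shift_min=shift_min) / denominator


def beta_sheet_ratio(s: Spectrum, *, mode: str = "area", shift_min: bool = False) -> float:
    """Beta-sheet amide I (1690-1668) over total amide I (1750-1514)."""
    return _ratio(s, BETA_NUM_WINDOW, BETA_DEN_WINDOW, mode, shift_min)


def methylation_ratio(s: Spectrum, *, mode: str = "area", shift_min: bool = False) -> float:
    """CH2/CH3 deformation (1360-1420) over phosphate stretch (1050-1150)."""
    return _ratio(s, METHYL_NUM_WINDOW, METHYL_DEN_WINDOW, mode, shift_min)


def intensity_ratio(
    s: Spectrum,
    num_center: float,
    den_center: float,
    half_width: float = 8.0,
    *,
    mode: str = "area",
    shift_min: bool = False,
) -> float:
    """Ratio of band areas in symmetric windows around two band centers.

    The FTIR collagen markers are ``intensity_ratio(s, 1450, 1650)`` and
    ``intensity_ratio(s, 1406, 1650)``.
    """
    num = BandWindow(num_center - half_width, num_center + half_width)
    den = BandWindow(den_center - half_width, den_center + half_width)
    return _ratio(s, num, den, mode, shift_min)


def amide_I_center(s: Spectrum, lo: float = 1600.0, hi: float = 1700.0) -> float:
    """Wavenumber of the amide I intensity maximum in [lo, hi].

    The discrete argmax is refined by 3-point parabolic interpolation, so the
    returned position is not quantised to the axis step.
    """
    x, y = _window_samples(s, BandWindow(lo, hi))
    if np.allclose(y, y[0]):
        raise ValueError("amide I window is flat; no peak to locate")
    i = int(np.argmax(y))
    if 0 < i < len(y) - 1:
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0.0:
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -1.0, 1.0))
            return float(x[i] + delta * (x[min(i + 1, len(x) - 1)] - x[i - 1]) / 2.0)
    return float(x[i])


def compute_markers(
    s: Spectrum,
    *,
    mode: str = "area",
    shift_min: bool = False,
    spectrum_id: str = "",
) -> MarkerResult:
    """All markers for one spectrum."""
    return MarkerResult(
        beta_sheet_ratio=beta_sheet_ratio(s, mode=mode, shift_min=shift_min),
        methylation_ratio=methylation_ratio(s, mode=mode, shift_min=shift_min),
        amide_I_center=amide_I_center(s),
        source_spectrum_id=spectrum_id,
    )
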