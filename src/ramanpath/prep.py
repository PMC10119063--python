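"""Spectral preprocessing: baseline, Savitzky-Golay, SNV, derivatives, resampling.

The chemometric chain applied to every tissue spectrum before multivariate
analysis is baseline correction (3rd-order polynomial), Savitzky-Golay
smoothing (3rd order, 17 points) and Standard Normal Variate normalisation
over the 1800-800 cm^-1 biological window, in that order.  Second derivatives
(for PCA) use the same SG filter with ``deriv=2``.  All functions are pure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .core import HyperMap, SpectralAxis, Spectrum

__all__ = [
    "PreprocessConfig",
    "correct_baseline",
    "smooth_sg",
    "snv",
    "second_derivative",
    "resample",
    "preprocess",
    "preprocess_map",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the standard preprocessing chain.

    Defaults mirror common Raman practice: cubic baseline, SG(3, 17),
    SNV over 800-1800 cm^-1.
    """

    baseline_degree: int = 3
    sg_polyorder: int = 3
    sg_window: int = 17
    snv_lo: float = 800.0
    snv_hi: float = 1800.0
    baseline_iterative: bool = True

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and greater than sg_polyorder")
        if self.baseline_degree < 0:
            raise ValueError("baseline_degree must be >= 0")
        if self.snv_lo >= self.snv_hi:
            raise ValueError("snv_lo must be < snv_hi")


def _fit_polynomial(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    # Domain-scaled for conditioning; returns the fit evaluated on x.
    t = (x - x.mean()) / (x.max() - x.min())
    coeffs = np.polynomial.polynomial.polyfit(t, y, degree)
    return np.polynomial.polynomial.polyval(t, coeffs)


def correct_baseline(
    s: Spectrum,
    degree: int = 3,
    *,
    iterative: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> Spectrum:
    """Subtract a polynomial baseline of the given degree.

    The default is iterative modified polynomial fitting: fit a
    degree-``degree`` polynomial, clip the working signal to the fit plus the
    working residual standard deviation, and refit until the fit changes by
    less than ``tol`` (relative RMS) or ``max_iter`` passes.  The clip level
    shrinks as peaks are excluded, so the estimate settles onto the smooth
    background without drooping below it.  With ``iterative=False`` a single
    plain least-squares polyfit is subtracted.
    """
    y = s.intensities
    if y.size <= degree + 1:
        raise ValueError("spectrum too short for the requested baseline degree")
    x = s.axis.wavenumbers
    work = y.copy()
    fit = _fit_polynomial(x, work, degree)
    if iterative:
        scale = max(float(np.max(np.abs(y))), 1e-300)
        for _ in range(max_iter):
            # improved ModPoly: shave the working signal down to the current
            # fit plus the working residual std.  The deviation shrinks as
            # peaks are excluded, so the fit descends onto the true baseline
            # from above instead of drooping below it.
            dev = float(np.std(work - fit))
            work = np.minimum(y, fit + dev)
            new_fit = _fit_polynomial(x, work, degree)
            change = np.sqrt(np.mean((new_fit - fit) ** 2)) / scale
            fit = new_fit
            if change < tol:
                break
    return s.copy_with(y - fit)


def smooth_sg(s: Spectrum, polyorder: int = 3, window: int = 17) -> Spectrum:
    """Savitzky-Golay least-squares local-polynomial smoothing."""
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if s.intensities.size < window:
        raise ValueError("spectrum shorter than the SG window")
    return s.copy_with(savgol_filter(s.intensities, window, polyorder))


def snv(s: Spectrum, lo: float = 800.0, hi: float = 1800.0) -> Spectrum:
    """Standard Normal Variate over [lo, hi] cm^-1.

    The mean and sample (n-1) standard deviation are computed over the stated
    window and the spectrum is cropped to it; the result has mean 0 and
    standard deviation 1 over that range.
    """
    wn = s.axis.wavenumbers
    mask = (wn >= lo - 1e-9) & (wn <= hi + 1e-9)
    if mask.sum() < 2:
        raise ValueError("SNV range covers fewer than 2 axis points")
    y = s.intensities[mask]
    sd = float(np.std(y, ddof=1))
    if sd == 0.0:
        raise ValueError("SNV undefined for a constant spectrum")
    return Spectrum(SpectralAxis(wn[mask]), (y - y.mean()) / sd)


def second_derivative(s: Spectrum, polyorder: int = 3, window: int = 17) -> Spectrum:
    """SG second-derivative filter, scaled to intensity per (cm^-1)^2."""
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if s.intensities.size < window:
        raise ValueError("spectrum shorter than the SG window")
    d2 = savgol_filter(
        s.intensities, window, polyorder, deriv=2, delta=abs(s.axis.step)
    )
    return s.copy_with(d2)


def resample(s: Spectrum, n_points: int) -> Spectrum:
    """Linear interpolation onto a uniform ``n_points`` grid over the same range.

    Endpoints are preserved; used to bring spectra to the 512-point grid the
    CNN input tensors require.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    wn = s.axis.wavenumbers
    ascending = wn[0] < wn[-1]
    src_x = wn if ascending else wn[::-1]
    src_y = s.intensities if ascending else s.intensities[::-1]
    new_x = np.linspace(src_x[0], src_x[-1], n_points)
    new_y = np.interp(new_x, src_x, src_y)
    if not ascending:
        new_x, new_y = new_x[::-1], new_y[::-1]
    return Spectrum(SpectralAxis(new_x), new_y)


def preprocess(s: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Full chain: baseline -> SG smoothing -> SNV, in the stated order."""
    cfg = config or PreprocessConfig()
    out = correct_baseline(s, cfg.baseline_degree, iterative=cfg.baseline_iterative)
    out = smooth_sg(out, cfg.sg_polyorder, cfg.sg_window)
    return snv(out, cfg.snv_lo, cfg.snv_hi)


def preprocess_map(hmap: HyperMap, config: PreprocessConfig | None = None) -> HyperMap:
    """Apply :func:`preprocess` to every pixel of a map.

    The output cube lives on the cropped SNV axis; ground-truth layers and
    metadata are carried over.
    """
    cfg = config or PreprocessConfig()
    h, w = hmap.shape
    first = preprocess(Spectrum(hmap.axis, hmap.cube[0, 0]), cfg)
    out = np.empty((h, w, len(first.axis)))
    out[0, 0] = first.intensities
    for i in range(h):
        for j in range(w):
            if i == 0 and j == 0:
                continue
            out[i, j] = preprocess(Spectrum(hmap.axis, hmap.cube[i, j]), cfg).intensities
    result = HyperMap(
        axis=first.axis,
        cube=out,
        role_labels=hmap.role_labels,
        class_labels=hmap.class_labels,
        abundances=hmap.abundances,
        meta={**hmap.meta, "preprocessed": True},
    )
    return result
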