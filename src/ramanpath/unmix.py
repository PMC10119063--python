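"""NMF spectral unmixing of hyperspectral maps.

Nonnegative matrix factorization splits the pixels x wavenumbers matrix X
into abundances W (pixels x rank) and component spectra H (rank x
wavenumbers), both nonnegative, minimizing the Frobenius reconstruction
error.  On tissue maps the three main components separate intracellular
proteins (phenylalanine 1004, amide I 1700-1600, amide II 1580-1480 cm^-1),
water (the broad O-H bend at 1643 cm^-1 of the saline immersion medium) and
nucleic acids (phosphate backbone stretches at 1090 and 1256 cm^-1) --
letting protein secondary structure be read without the overlapping water
band.

The factorization uses Lee-Seung multiplicative updates with seeded uniform
random initialisation and multiple restarts keeping the best objective.
Because SNV-normalised spectra dip negative, inputs are offset-shifted
per spectrum to their minimum before factorization (the shift is recorded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import HyperMap, Spectrum

__all__ = ["ComponentSet", "nmf", "nmf_matrix", "assign_components", "ROLE_WINDOWS"]

#: Marker windows (cm^-1) used to score components for chemical assignment.
ROLE_WINDOWS: dict[str, tuple[tuple[float, float], ...]] = {
    "water": ((1633.0, 1653.0),),
    "nucleic_acids": ((1080.0, 1100.0), (1246.0, 1266.0)),
    "proteins": ((994.0, 1014.0), (1600.0, 1700.0)),
}

_EPS = 1e-12


@dataclass
class ComponentSet:
    """NMF output: abundances, component spectra, and chemical assignments."""

    abundances: np.ndarray  # (n_pixels, rank), >= 0
    component_spectra: np.ndarray  # (rank, axis length), >= 0
    axis: "np.ndarray | None" = None  # wavenumber vector of the components
    assignments: dict[int, str] = field(default_factory=dict)
    reconstruction_error: float = 0.0  # relative Frobenius
    shift: np.ndarray | None = None  # per-spectrum offsets applied before NMF
    map_shape: tuple[int, int] | None = None

    def abundance_map(self, component: int) -> np.ndarray:
        if self.map_shape is None:
            raise ValueError("component set was not computed from a map")
        return self.abundances[:, component].reshape(self.map_shape)

    def component_spectrum(self, component: int, axis_obj) -> Spectrum:
        return Spectrum(axis_obj, self.component_spectra[component])

    def component_for(self, role: str) -> int:
        for idx, r in self.assignments.items():
            if r == role:
                return idx
        raise KeyError(f"no component assigned to role {role!r}")


def _mu_nmf(
    X: np.ndarray,
    rank: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One multiplicative-update run; returns W, H and final Frobenius error."""
    n, m = X.shape
    scale = np.sqrt(X.mean() / max(rank, 1)) or 1.0
    W = rng.uniform(0.0, 1.0, (n, rank)) * scale + _EPS
    H = rng.uniform(0.0, 1.0, (rank, m)) * scale + _EPS
    norm_X = np.linalg.norm(X)
    prev = None
    for _ in range(max_iter):
        # Lee-Seung updates; each step is non-increasing in ||X - WH||_F.
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        err = np.linalg.norm(X - W @ H)
        if prev is not None and abs(prev - err) <= tol * max(norm_X, _EPS):
            prev = err
            break
        prev = err
    return W, H, float(prev if prev is not None else np.linalg.norm(X - W @ H))


def nmf_matrix(
    X: np.ndarray,
    rank: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_restarts: int = 5,
    shift: bool = True,
) -> ComponentSet:
    """NMF of an (n_spectra, n_wavenumbers) matrix.

    With ``shift=True`` each spectrum is raised by its own minimum so the
    input is nonnegative (needed after SNV); the per-spectrum offsets are
    recorded in the result.  With ``shift=False`` negative input raises.
    """
    X = np.asarray(X, dtype=float)
    if rank < 1:
        raise ValueError("rank must be >= 1")
    offsets = np.zeros(X.shape[0])
    if X.min() < 0:
        if not shift:
            raise ValueError("input has negative entries and shifting is disabled")
        offsets = np.minimum(X.min(axis=1), 0.0)
        X = X - offsets[:, None]
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    rng_master = np.random.default_rng(seed)
    for _ in range(max(1, n_restarts)):
        rng = np.random.default_rng(rng_master.integers(0, 2**31))
        W, H, err = _mu_nmf(X, rank, rng, tol, max_iter)
        if best is None or err < best[2]:
            best = (W, H, err)
    W, H, err = best
    norm_X = np.linalg.norm(X)
    return ComponentSet(
        abundances=W,
        component_spectra=H,
        reconstruction_error=err / max(norm_X, _EPS),
        shift=offsets,
    )


def nmf(
    hmap: HyperMap,
    rank: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_restarts: int = 5,
    shift: bool = True,
) -> ComponentSet:
    """NMF of all pixel spectra of a map (see :func:`nmf_matrix`)."""
    cs = nmf_matrix(
        hmap.as_matrix(), rank, seed, tol, max_iter, n_restarts, shift
    )
    cs.map_shape = hmap.shape
    cs.axis = hmap.axis.wavenumbers.copy()
    return cs


def _role_score(spectrum: np.ndarray, wn: np.ndarray, role: str) -> float:
    """Evidence that a component spectrum plays the given chemical role.

    The score is the smallest of the role's marker-window mean intensities,
    normalised by the spectrum's overall mean -- a component must show *all*
    of a role's bands (e.g. both phenylalanine and amide I for proteins), so
    the broad water band inside the amide window cannot hijack the protein
    role.  Scale-invariant in the component's intensity.
    """
    y = spectrum - spectrum.min()
    overall = max(float(y.mean()), _EPS)
    window_means = []
    for lo, hi in ROLE_WINDOWS[role]:
        mask = (wn >= lo) & (wn <= hi)
        window_means.append(float(y[mask].mean()) if mask.any() else 0.0)
    return min(window_means) / overall


def assign_components(cs: ComponentSet) -> ComponentSet:
    """Assign proteins / water / nucleic-acids roles to components.

    Each role scores every component by its normalised integrated intensity
    inside the role's marker windows; (role, component) pairs are claimed
    greedily by descending score with each component used at most once.
    Components left over are labeled ``other``.
    """
    if cs.component_spectra.shape[0] < 3:
        raise ValueError("component assignment requires rank >= 3")
    if cs.axis is None:
        raise ValueError("component set has no wavenumber axis")
    wn = np.asarray(cs.axis, dtype=float)
    rank = cs.component_spectra.shape[0]
    scored = [
        (_role_score(cs.component_spectra[i], wn, role), role, i)
        for role in ROLE_WINDOWS
        for i in range(rank)
    ]
    scored.sort(key=lambda t: -t[0])
    assignments: dict[int, str] = {}
    taken_roles: set[str] = set()
    for _, role, i in scored:
        if role in taken_roles or i in assignments:
            continue
        assignments[i] = role
        taken_roles.add(role)
    for i in range(rank):
        assignments.setdefault(i, "other")
    cs.assignments = assignments
    return cs
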