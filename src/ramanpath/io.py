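"""File formats and map rendering.

Hyperspectral maps travel as HDF5 containers with a documented layout:

* ``/axis``   -- wavenumber vector (cm^-1)
* ``/cube``   -- intensities, shape (height, width, len(axis))
* ``/role_labels``, ``/class_labels`` -- optional integer layers
* ``/abundances/<role>``              -- optional ground-truth weights
* root attribute ``meta`` -- JSON metadata (seed, generator parameters)

Flat spectra sets use CSV with the wavenumber as the first column and one
column per spectrum.  Class/cluster layers render to PNG with one image
pixel per map pixel; the default class palette follows the published
prediction-map colors (red cPDAC, blue AVAC, magenta IPMC, yellow
stroma/empty, green benign).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
from PIL import Image

from .core import HyperMap, SpectralAxis

__all__ = [
    "read_map",
    "write_map",
    "read_spectra_csv",
    "write_spectra_csv",
    "render_map_png",
    "CLASS_PALETTE",
]

#: Prediction-map palette, class code -> RGB.
CLASS_PALETTE: dict[int, tuple[int, int, int]] = {
    0: (255, 225, 25),  # stroma/empty: yellow
    1: (0, 70, 230),    # AVAC: blue
    2: (240, 20, 240),  # IPMC: magenta
    3: (230, 20, 20),   # cPDAC: red
    4: (40, 180, 60),   # benign: green
}


def write_map(path: str | Path, hmap: HyperMap) -> None:
    """Write a map container (lossless round trip of content and metadata)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("axis", data=hmap.axis.wavenumbers)
        f.create_dataset("cube", data=hmap.cube)
        if hmap.role_labels is not None:
            f.create_dataset("role_labels", data=np.asarray(hmap.role_labels, dtype=np.int64))
        if hmap.class_labels is not None:
            f.create_dataset("class_labels", data=np.asarray(hmap.class_labels, dtype=np.int64))
        if hmap.abundances:
            grp = f.create_group("abundances")
            for role, layer in hmap.abundances.items():
                grp.create_dataset(role, data=layer)
        f.attrs["meta"] = json.dumps(hmap.meta)


def read_map(path: str | Path) -> HyperMap:
    """Read a map container written by :func:`write_map`."""
    with h5py.File(path, "r") as f:
        for required in ("axis", "cube"):
            if required not in f:
                raise ValueError(f"malformed map container: missing dataset /{required}")
        axis = SpectralAxis(f["axis"][:])
        cube = f["cube"][:]
        role_labels = f["role_labels"][:] if "role_labels" in f else None
        class_labels = f["class_labels"][:] if "class_labels" in f else None
        abundances = None
        if "abundances" in f:
            abundances = {role: f["abundances"][role][:] for role in f["abundances"]}
        meta = json.loads(f.attrs.get("meta", "{}"))
    return HyperMap(
        axis=axis,
        cube=cube,
        role_labels=role_labels,
        class_labels=class_labels,
        abundances=abundances,
        meta=meta,
    )


def write_spectra_csv(path: str | Path, axis: SpectralAxis, spectra: np.ndarray) -> None:
    """CSV spectra matrix: first column wavenumber, one column per spectrum."""
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    header = "wavenumber," + ",".join(f"spectrum_{i}" for i in range(spectra.shape[0]))
    table = np.column_stack([axis.wavenumbers, spectra.T])
    np.savetxt(path, table, delimiter=",", header=header, comments="", fmt="%.10g")


def read_spectra_csv(path: str | Path) -> tuple[SpectralAxis, np.ndarray]:
    """Read a CSV spectra matrix; returns (axis, (n_spectra, n_points) array)."""
    table = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if table.shape[1] < 2:
        raise ValueError("CSV must have a wavenumber column and at least one spectrum")
    return SpectralAxis(table[:, 0]), table[:, 1:].T


def render_map_png(
    class_layer: np.ndarray,
    palette: dict[int, tuple[int, int, int]] | None = None,
    path: str | Path | None = None,
    scale: int = 1,
) -> Image.Image:
    """Render an integer class layer as a PNG image, one pixel per map pixel.

    ``scale`` magnifies by integer nearest-neighbour replication for easier
    viewing; the default 1 keeps the exact map dimensions.
    """
    pal = palette if palette is not None else CLASS_PALETTE
    layer = np.asarray(class_layer, dtype=int)
    missing = sorted(set(int(c) for c in np.unique(layer)) - set(pal))
    if missing:
        raise ValueError(f"no palette entry for class codes {missing}")
    rgb = np.zeros(layer.shape + (3,), dtype=np.uint8)
    for code, color in pal.items():
        rgb[layer == code] = color
    if scale > 1:
        rgb = np.kron(rgb, np.ones((scale, scale, 1), dtype=np.uint8))
    img = Image.fromarray(rgb)
    if path is not None:
        img.save(path)
    return img
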