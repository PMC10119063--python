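"""Generate one synthetic hyperspectral tissue map per tumor class.

Each 48 x 48 map (fingerprint axis 1900-600 cm^-1, 2 cm^-1 step) carries
ground-truth compartment roles (nuclei disks, cytoplasm, collagen stroma --
fibrous for cPDAC/AVAC, homogeneous for IPMC -- and saline), a shared cubic
baseline and additive noise.  Maps land in results/maps/<class>.h5 with
ground-truth role previews as PNG.
"""

from pathlib import Path

import numpy as np

from ramanpath.io import render_map_png, write_map
from ramanpath.synthgen import SyntheticTissueSpec, generate_tissue_map

OUT = Path(__file__).resolve().parent.parent / "results" / "maps"
OUT.mkdir(parents=True, exist_ok=True)

ROLE_PALETTE = {0: (160, 30, 160), 1: (70, 160, 70), 2: (200, 160, 60), 3: (40, 70, 180)}


def main() -> None:
    for seed, cls in enumerate(("AVAC", "IPMC", "cPDAC", "benign")):
        spec = SyntheticTissueSpec(map_width=48, map_height=48, class_name=cls, seed=seed)
        hmap = generate_tissue_map(spec)
        write_map(OUT / f"{cls}.h5", hmap)
        render_map_png(hmap.role_labels, ROLE_PALETTE, OUT / f"{cls}_roles.png")
        fracs = {
            role: float(np.mean(hmap.role_labels == i))
            for i, role in enumerate(("nucleus", "cytoplasm", "stroma", "water"))
        }
        print(f"{cls:7s} seed={seed} role fractions: "
              + ", ".join(f"{r} {f:.2f}" for r, f in fracs.items()))
    print(f"\nmaps written to {OUT}")


if __name__ == "__main__":
    main()
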