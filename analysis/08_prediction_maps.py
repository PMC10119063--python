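"""Generate per-pixel CNN prediction maps for every tissue map.

Feeds each raw map pixel spectrum to the trained CNN and renders the
predicted class image with the published palette (red cPDAC, blue AVAC,
magenta IPMC, yellow stroma/empty, green benign).  Agreement with the
ground-truth class layer is printed per map.

Run 02_generate_maps.py and 07_train_cnn.py first.
"""

from pathlib import Path

import numpy as np

from ramanpath.cnn import load_model, predict_map
from ramanpath.io import CLASS_PALETTE, read_map, render_map_png

RESULTS = Path(__file__).resolve().parent.parent / "results"
MAPS = RESULTS / "maps"
OUT = RESULTS / "prediction_maps"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    model = load_model(RESULTS / "cnn_model")
    for path in sorted(MAPS.glob("*.h5")):
        cls = path.stem
        hmap = read_map(path)
        pred = predict_map(model, hmap)
        render_map_png(pred.classes, CLASS_PALETTE, OUT / f"{cls}_prediction.png")
        np.savetxt(OUT / f"{cls}_classes.csv", pred.classes, delimiter=",", fmt="%d")
        agreement = float(np.mean(pred.classes == hmap.class_labels))
        print(f"{cls:7s} {hmap.shape[0]}x{hmap.shape[1]} map: "
              f"{100 * agreement:.1f}% of pixels match the ground-truth class layer")
    print(f"\nprediction maps in {OUT}")


if __name__ == "__main__":
    main()
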