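"""PCA of second-derivative nuclei spectra across the three tumor classes.

Nuclei pixels are taken from the ground-truth role layer of each class map
(in the full pipeline they come from the HCA cluster with the strongest
nucleic-acid bands), pooled across cPDAC, IPMC and AVAC, differentiated
twice and decomposed.  The leading component should separate cPDAC (weak
methylation band) from the hypermethylated IPMC/AVAC nuclei.

Writes results/pca_scores.csv and results/pca_loadings.csv.
Run 02_generate_maps.py first.
"""

from pathlib import Path

import numpy as np

from ramanpath.core import CLASS_CODES
from ramanpath.io import read_map, write_spectra_csv
from ramanpath.nuclei_pca import pca_second_derivative
from ramanpath.prep import preprocess_map

MAPS = Path(__file__).resolve().parent.parent / "results" / "maps"
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    spectra, groups = [], []
    axis = None
    for cls in ("cPDAC", "IPMC", "AVAC"):
        pmap = preprocess_map(read_map(MAPS / f"{cls}.h5"))
        nuclei = pmap.role_labels.ravel() == 0  # nucleus role index
        spectra.append(pmap.as_matrix()[nuclei])
        groups.append(np.full(int(nuclei.sum()), CLASS_CODES[cls]))
        axis = pmap.axis
    X = np.vstack(spectra)
    y = np.concatenate(groups)
    res = pca_second_derivative(X, axis, n_components=3, group_labels=y)

    print(f"{len(X)} nuclei spectra pooled over 3 classes")
    print("explained variance fractions:",
          ", ".join(f"PC-{i+1} {v:.1%}" for i, v in
                    enumerate(res.explained_variance_fraction)))
    for cls in ("cPDAC", "IPMC", "AVAC"):
        pc1 = res.scores[y == CLASS_CODES[cls], 0]
        print(f"  {cls:6s} PC-1 scores: mean {pc1.mean():+.4f}, sd {pc1.std():.4f}")

    np.savetxt(OUT / "pca_scores.csv",
               np.column_stack([res.scores, y]), delimiter=",",
               header="PC1,PC2,PC3,group", comments="", fmt="%.8g")
    write_spectra_csv(OUT / "pca_loadings.csv", axis, res.loadings)
    print(f"\nwrote {OUT / 'pca_scores.csv'} and {OUT / 'pca_loadings.csv'}")


if __name__ == "__main__":
    main()
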