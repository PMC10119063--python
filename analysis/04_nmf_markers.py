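"""Unmix each tissue map into 3 NMF components and read the marker ratios
off the component spectra.

Rank-3 NMF of the raw (nonnegative) maps separates intracellular proteins,
water, and nucleic acids.  The DNA-methylation ratio (1360-1420 / 1050-1150
cm^-1) evaluated on the nucleic-acid component preserves the full class
ordering benign > IPMC > AVAC > cPDAC.  The beta-sheet amide I ratio
(1690-1668 / 1750-1514 cm^-1) on the protein component is diluted by the
collagen stroma that co-loads there, so only the strongest contrast (AVAC
above benign) survives unmixing; the clean 4-class ordering lives at the
template level (see 01_calibrate_templates.py).

Writes results/marker_ratios.csv.  Run 02_generate_maps.py first.
"""

from pathlib import Path

from ramanpath.core import Spectrum
from ramanpath.io import read_map
from ramanpath.markers import amide_I_center, beta_sheet_ratio, methylation_ratio
from ramanpath.unmix import assign_components, nmf

MAPS = Path(__file__).resolve().parent.parent / "results" / "maps"
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = {}
    for path in sorted(MAPS.glob("*.h5")):
        cls = path.stem
        hmap = read_map(path)
        cs = assign_components(nmf(hmap, rank=3, seed=0))
        protein = Spectrum(hmap.axis, cs.component_spectra[cs.component_for("proteins")])
        nucleic = Spectrum(hmap.axis, cs.component_spectra[cs.component_for("nucleic_acids")])
        beta = beta_sheet_ratio(protein, shift_min=True)
        methyl = methylation_ratio(nucleic, shift_min=True)
        amide = amide_I_center(protein)
        rows[cls] = (beta, methyl, amide, cs.reconstruction_error)
        print(f"{cls:7s} beta-sheet {beta:.3f}  methylation {methyl:.3f}  "
              f"amide I {amide:.1f} cm^-1  (NMF rel. error {cs.reconstruction_error:.3f})")

    m = {c: rows[c][1] for c in rows}
    print("\nmethylation ordering benign > IPMC > AVAC > cPDAC:",
          m["benign"] > m["IPMC"] > m["AVAC"] > m["cPDAC"])
    print("beta-sheet AVAC > benign on protein components:",
          rows["AVAC"][0] > rows["benign"][0])

    with open(OUT / "marker_ratios.csv", "w") as fh:
        fh.write("class,beta_sheet_ratio,methylation_ratio,amide_I_center,nmf_rel_error\n")
        for cls, r in sorted(rows.items()):
            fh.write(f"{cls},{r[0]:.6f},{r[1]:.6f},{r[2]:.2f},{r[3]:.6f}\n")
    print(f"\nwrote {OUT / 'marker_ratios.csv'}")


if __name__ == "__main__":
    main()
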