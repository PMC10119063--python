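"""Synthetic spectrum and tissue-map generator behaviour."""

import numpy as np
import pytest

from ramanpath.core import CLASS_CODES, ROLE_NAMES, raman_axis
from ramanpath.markers import beta_sheet_ratio, methylation_ratio, amide_I_center
from ramanpath.core import Spectrum
from ramanpath.synthgen import (
    ClassTemplate,
    PeakSpec,
    RegionLayout,
    SyntheticTissueSpec,
    generate_dna_pair,
    generate_tissue_map,
    generate_training_set,
    get_template,
    render_peaks,
    render_template,
)


class TestRenderTemplate:
    def test_single_gaussian_peak_argmax_at_center(self, axis):
        out = render_peaks((PeakSpec(1004.0, 1.0, 4.0),), axis)
        assert axis.wavenumbers[np.argmax(out)] == pytest.approx(1004.0, abs=2.0)

    def test_empty_peak_list_is_zero(self, axis):
        assert np.all(render_peaks((), axis) == 0.0)

    def test_avac_amide_I_red_shifted(self, axis):
        s = render_template(get_template("AVAC", "cytoplasm"), axis)
        center = amide_I_center(s)
        assert 1660.0 <= center <= 1668.0

    def test_peak_outside_axis_raises(self, axis):
        with pytest.raises(ValueError):
            render_peaks((PeakSpec(2000.0, 1.0, 4.0),), axis)

    def test_templates_nonnegative(self, axis):
        for cls in ("AVAC", "IPMC", "cPDAC", "benign"):
            for role in ("nucleus", "cytoplasm"):
                s = render_template(get_template(cls, role), axis)
                assert np.all(s.intensities >= 0.0)

    def test_lorentzian_shape_supported(self, axis):
        g = render_peaks((PeakSpec(1200.0, 1.0, 8.0, "gaussian"),), axis)
        l = render_peaks((PeakSpec(1200.0, 1.0, 8.0, "lorentzian"),), axis)
        # Lorentzian has heavier tails at equal amplitude
        far = axis.index_nearest(1400.0)
        assert l[far] > g[far]

    def test_invalid_peak_parameters_raise(self):
        with pytest.raises(ValueError):
            PeakSpec(1000.0, -1.0, 4.0)
        with pytest.raises(ValueError):
            PeakSpec(1000.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            PeakSpec(1000.0, 1.0, 4.0, "voigt")

    def test_template_validates_amide_center(self):
        with pytest.raises(ValueError):
            ClassTemplate("AVAC", "cytoplasm", (), amideI_center=1500.0)


class TestDnaPair:
    def test_methylated_has_higher_methyl_band(self, axis):
        pair = generate_dna_pair(methylation_level=0.98, n=1, noise_sd=0.0, seed=0)
        unmeth = Spectrum(axis, pair.spectra[0])
        meth = Spectrum(axis, pair.spectra[1])
        assert methylation_ratio(meth) > methylation_ratio(unmeth)

    def test_same_seed_reproducible(self):
        a = generate_dna_pair(0.98, 5, 0.02, seed=3)
        b = generate_dna_pair(0.98, 5, 0.02, seed=3)
        assert np.array_equal(a.spectra, b.spectra)

    def test_zero_level_pair_identical_templates(self):
        pair = generate_dna_pair(0.0, 2, noise_sd=0.0, seed=0)
        assert np.array_equal(pair.spectra[0], pair.spectra[2])

    @pytest.mark.parametrize("bad", [-1, 0])
    def test_nonpositive_n_raises(self, bad):
        with pytest.raises(ValueError):
            generate_dna_pair(0.5, n=bad)

    def test_level_out_of_range_raises(self):
        with pytest.raises(ValueError):
            generate_dna_pair(1.5, n=1)

    def test_phosphate_band_shifts_up_with_methylation(self, axis):
        pair = generate_dna_pair(1.0, 1, noise_sd=0.0, seed=0)
        wn = axis.wavenumbers
        window = (wn >= 1050) & (wn <= 1150)
        unmeth_peak = wn[window][np.argmax(pair.spectra[0][window])]
        meth_peak = wn[window][np.argmax(pair.spectra[1][window])]
        assert meth_peak > unmeth_peak


class TestTissueMap:
    def test_pure_nucleus_pixel_equals_template(self, axis):
        layout = RegionLayout(
            fractions={"nucleus": 0.3, "cytoplasm": 0.7, "stroma": 0.0, "water": 0.0},
            water_background=0.0,
        )
        spec = SyntheticTissueSpec(
            map_width=12, map_height=12, class_name="cPDAC", layout=layout,
            baseline_coeffs=(0.0, 0.0, 0.0, 0.0), noise_sd=0.0, seed=0,
        )
        hmap = generate_tissue_map(spec)
        template = render_template(get_template("cPDAC", "nucleus"), axis).intensities
        i, j = np.argwhere(hmap.role_labels == ROLE_NAMES.index("nucleus"))[0]
        assert np.allclose(hmap.cube[i, j], template)

    def test_nuclei_fraction_matches_request(self):
        spec = SyntheticTissueSpec(map_width=64, map_height=64, seed=1)
        hmap = generate_tissue_map(spec)
        frac = np.mean(hmap.role_labels == ROLE_NAMES.index("nucleus"))
        assert abs(frac - 0.20) <= 0.02

    def test_same_seed_bitwise_identical(self):
        spec = SyntheticTissueSpec(map_width=16, map_height=16, seed=5)
        a = generate_tissue_map(spec)
        b = generate_tissue_map(spec)
        assert np.array_equal(a.cube, b.cube)
        assert np.array_equal(a.role_labels, b.role_labels)

    def test_class_labels_follow_roles(self):
        spec = SyntheticTissueSpec(map_width=16, map_height=16, class_name="IPMC", seed=2)
        hmap = generate_tissue_map(spec)
        cellular = np.isin(
            hmap.role_labels,
            [ROLE_NAMES.index("nucleus"), ROLE_NAMES.index("cytoplasm")],
        )
        assert np.all(hmap.class_labels[cellular] == CLASS_CODES["IPMC"])
        assert np.all(hmap.class_labels[~cellular] == CLASS_CODES["stroma_empty"])

    def test_zero_area_map_rejected(self):
        with pytest.raises(ValueError):
            SyntheticTissueSpec(map_width=0, map_height=10)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            RegionLayout(fractions={"nucleus": 0.5, "cytoplasm": 0.1,
                                    "stroma": 0.1, "water": 0.1})


class TestTrainingSet:
    def test_balanced_labels(self):
        out = generate_training_set(n_per_class=20, seed=0)
        assert len(out) == 100
        _, counts = np.unique(out.labels, return_counts=True)
        assert np.all(counts == 20)

    def test_no_noise_no_jitter_identical_within_class(self):
        out = generate_training_set(n_per_class=5, noise_sd=0.0, jitter=0.0, seed=0)
        for c in range(5):
            block = out.spectra[out.labels == c]
            assert np.allclose(block, block[0])

    def test_amide_centers_separate_avac_from_cpdac(self, axis):
        # cytoplasm-dominated spectra: the amide I shift is a property of the
        # (cytoplasmic) proteome, while histone amide I is conserved
        out = generate_training_set(
            n_per_class=30, seed=0, mixture_range=(0.05, 0.15)
        )
        means = {
            c: out.spectra[out.labels == CLASS_CODES[c]].mean(axis=0)
            for c in ("AVAC", "cPDAC")
        }
        centers = {c: amide_I_center(Spectrum(axis, m)) for c, m in means.items()}
        assert abs(centers["AVAC"] - centers["cPDAC"]) >= 10.0

    def test_unknown_class_raises(self):
        with pytest.raises(ValueError):
            generate_training_set(classes=["AVAC", "PDAC2"], n_per_class=3)

    def test_seeded_reproducibility(self):
        a = generate_training_set(n_per_class=10, seed=9)
        b = generate_training_set(n_per_class=10, seed=9)
        assert np.array_equal(a.spectra, b.spectra)


def test_noise_free_marker_orderings_across_classes(axis):
    """Class templates reproduce the published marker orderings exactly."""
    beta = {
        c: beta_sheet_ratio(render_template(get_template(c, "cytoplasm"), axis))
        for c in ("AVAC", "IPMC", "cPDAC", "benign")
    }
    methyl = {
        c: methylation_ratio(render_template(get_template(c, "nucleus"), axis))
        for c in ("AVAC", "IPMC", "cPDAC", "benign")
    }
    assert beta["AVAC"] > beta["IPMC"] > beta["cPDAC"] > beta["benign"]
    assert methyl["benign"] > methyl["IPMC"] > methyl["AVAC"] > methyl["cPDAC"]
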