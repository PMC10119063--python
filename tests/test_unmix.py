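"""NMF factor recovery, monotonicity, and chemical assignment."""

import numpy as np
import pytest

from ramanpath.core import HyperMap, SpectralAxis, raman_axis
from ramanpath.synthgen import RegionLayout, SyntheticTissueSpec, generate_tissue_map, get_template, render_template
from ramanpath.unmix import ComponentSet, _mu_nmf, assign_components, nmf, nmf_matrix


def _cosine(a, b):
    return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestFactorRecovery:
    def test_exact_rank2_factorisation_recovered(self, rng):
        W0 = rng.uniform(0.1, 1.0, (40, 2))
        H0 = rng.uniform(0.0, 1.0, (2, 25))
        X = W0 @ H0
        cs = nmf_matrix(X, rank=2, seed=0)
        assert cs.reconstruction_error <= 1e-3
        # recovered components match the generators up to permutation/scale
        sims = np.array([[_cosine(h, h0) for h0 in H0] for h in cs.component_spectra])
        order = sims.argmax(axis=1)
        assert set(order) == {0, 1}
        assert np.all(sims.max(axis=1) >= 0.99)

    def test_rank1_on_proportional_rows(self, rng):
        base = rng.uniform(0.0, 1.0, 30)
        X = np.outer(rng.uniform(0.5, 2.0, 20), base)
        cs = nmf_matrix(X, rank=1, seed=0)
        assert _cosine(cs.component_spectra[0], base) >= 0.999

    def test_same_seed_identical_factors(self, rng):
        X = rng.uniform(0.0, 1.0, (15, 10))
        a = nmf_matrix(X, rank=3, seed=2)
        b = nmf_matrix(X, rank=3, seed=2)
        assert np.array_equal(a.abundances, b.abundances)
        assert np.array_equal(a.component_spectra, b.component_spectra)

    def test_objective_nonincreasing_over_iterations(self, rng):
        X = rng.uniform(0.0, 1.0, (20, 15))
        gen = np.random.default_rng(0)
        errs = []
        W = gen.uniform(0, 1, (20, 3)) + 1e-12
        H = gen.uniform(0, 1, (3, 15)) + 1e-12
        for _ in range(50):
            H *= (W.T @ X) / (W.T @ W @ H + 1e-12)
            W *= (X @ H.T) / (W @ (H @ H.T) + 1e-12)
            errs.append(np.linalg.norm(X - W @ H))
        assert np.all(np.diff(errs) <= 1e-10)

    def test_negative_input_without_shift_raises(self):
        X = np.array([[1.0, -0.5], [0.3, 0.2]])
        with pytest.raises(ValueError):
            nmf_matrix(X, rank=1, shift=False)

    def test_shift_recorded_for_negative_input(self):
        X = np.array([[1.0, -0.5], [0.3, 0.2]])
        cs = nmf_matrix(X, rank=1, shift=True, seed=0)
        assert cs.shift[0] == pytest.approx(-0.5)
        assert cs.shift[1] == pytest.approx(0.0)

    def test_agrees_with_sklearn_on_factorable_matrix(self, rng):
        from sklearn.decomposition import NMF as SkNMF

        W0 = rng.uniform(0.1, 1.0, (30, 2))
        H0 = rng.uniform(0.0, 1.0, (2, 20))
        X = W0 @ H0
        ours = nmf_matrix(X, rank=2, seed=0)
        sk = SkNMF(n_components=2, solver="mu", init="random", random_state=0,
                   max_iter=2000, tol=1e-6).fit(X)
        sk_err = np.linalg.norm(X - sk.transform(X) @ sk.components_) / np.linalg.norm(X)
        assert ours.reconstruction_error <= max(1e-3, 2 * sk_err)


class TestTissueMapUnmixing:
    @pytest.fixture(scope="class")
    def noise_free_map(self):
        layout = RegionLayout(
            fractions={"nucleus": 0.25, "cytoplasm": 0.45, "stroma": 0.0, "water": 0.30},
            water_background=0.25,
        )
        spec = SyntheticTissueSpec(
            map_width=16, map_height=16, class_name="AVAC", layout=layout,
            baseline_coeffs=(0.0, 0.0, 0.0, 0.0), noise_sd=0.0, seed=3,
        )
        return generate_tissue_map(spec)

    def test_abundances_correlate_with_ground_truth(self, noise_free_map):
        cs = assign_components(nmf(noise_free_map, rank=3, seed=0))
        role_for = {"proteins": "cytoplasm", "nucleic_acids": "nucleus", "water": "water"}
        for role, gt_role in role_for.items():
            comp = cs.component_for(role)
            est = cs.abundances[:, comp]
            truth = noise_free_map.abundances[gt_role].ravel()
            r = np.corrcoef(est, truth)[0, 1]
            assert r >= 0.95, f"{role}: correlation {r:.3f}"

    def test_water_component_dominates_empty_pixels(self, noise_free_map):
        cs = assign_components(nmf(noise_free_map, rank=3, seed=0))
        water = cs.component_for("water")
        est = cs.abundances[:, water]
        empty = noise_free_map.role_labels.ravel() == 3  # water role index
        assert est[empty].mean() > est[~empty].mean()


def test_avac_protein_component_more_beta_rich_than_benign():
    """Beta-sheet marker on unmixed protein components preserves the
    strongest class contrast (AVAC above benign)."""
    from ramanpath.core import Spectrum
    from ramanpath.markers import beta_sheet_ratio
    from ramanpath.synthgen import SyntheticTissueSpec

    ratios = {}
    for cls in ("AVAC", "benign"):
        spec = SyntheticTissueSpec(map_width=14, map_height=14, class_name=cls, seed=6)
        hmap = generate_tissue_map(spec)
        cs = assign_components(nmf(hmap, rank=3, seed=0))
        protein = Spectrum(hmap.axis, cs.component_spectra[cs.component_for("proteins")])
        ratios[cls] = beta_sheet_ratio(protein, shift_min=True)
    assert ratios["AVAC"] > ratios["benign"]


class TestAssignment:
    def _pure_component_set(self, axis):
        H = np.vstack(
            [
                render_template(get_template("AVAC", "cytoplasm"), axis).intensities,
                render_template(get_template("AVAC", "water"), axis).intensities,
                render_template(get_template("AVAC", "nucleus"), axis).intensities,
            ]
        )
        return ComponentSet(
            abundances=np.ones((2, 3)), component_spectra=H, axis=axis.wavenumbers
        )

    def test_pure_role_templates_assigned_correctly(self, axis):
        cs = assign_components(self._pure_component_set(axis))
        assert cs.assignments[0] == "proteins"
        assert cs.assignments[1] == "water"
        assert cs.assignments[2] == "nucleic_acids"

    def test_duplicate_water_component_labeled_other(self, axis):
        water = render_template(get_template("AVAC", "water"), axis).intensities
        protein = render_template(get_template("AVAC", "cytoplasm"), axis).intensities
        nucleus = render_template(get_template("AVAC", "nucleus"), axis).intensities
        H = np.vstack([water, water, protein, nucleus])
        cs = assign_components(
            ComponentSet(abundances=np.ones((2, 4)), component_spectra=H,
                         axis=axis.wavenumbers)
        )
        assert sorted(cs.assignments.values()).count("water") == 1
        assert "other" in cs.assignments.values()

    def test_rank_below_three_rejected(self, axis):
        cs = ComponentSet(
            abundances=np.ones((2, 2)),
            component_spectra=np.ones((2, len(axis))),
            axis=axis.wavenumbers,
        )
        with pytest.raises(ValueError):
            assign_components(cs)
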