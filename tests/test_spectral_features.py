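"""Vegetation indices, FCLS unmixing, soil-free indices."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import simplex_grid_fcls
from uavagb.raster_io import plot_mean_spectrum
from uavagb.spectral_features import (
    EndmemberLibrary,
    FclsSolver,
    LibraryError,
    compute_vi,
    compute_vi_v,
    plot_vegetation_abundance,
    read_endmembers,
    unmix_fcls,
    unmix_image,
    vegetation_abundance,
    write_endmembers,
)
from uavagb.synthetic_scene import SceneConfig, generate_endmembers, generate_scene


def random_library(rng, m=4):
    """Random well-separated library with one soil entry."""
    spectra = rng.uniform(0.02, 0.9, size=(m, 6))
    is_soil = np.zeros(m, dtype=bool)
    is_soil[-1] = True
    return EndmemberLibrary(stage="SP", names=[f"E{i}" for i in range(m)],
                            spectra=spectra, is_soil=is_soil)


class TestVegetationIndices:
    # frozen values evaluated by hand from the index formulas
    @pytest.mark.parametrize("name,spectrum,expected", [
        ("NDVI", [0, 0, 0.3, 0, 0, 0.3], 0.0),          # symmetric bands
        ("NDVI", [0, 0, 0.1, 0, 0, 0.5], 0.4 / 0.6),
        ("EVI2", [0, 0, 0.1, 0, 0, 0.4], 2.5 * 0.3 / (0.4 + 0.24 + 1.0)),
        ("NDRE", [0, 0, 0, 0.2, 0, 0.45], 0.25 / 0.65),
        ("MTCI", [0, 0, 0.06, 0.2, 0, 0.45], 0.25 / 0.26),
        ("VARI", [0, 0.08, 0.06, 0, 0, 0], 0.02 / 0.14),
        ("OSAVI", [0, 0, 0.06, 0, 0, 0.45], 1.16 * 0.39 / 0.67),
    ])
    def test_formula_values(self, name, spectrum, expected):
        assert compute_vi(spectrum, name) == pytest.approx(expected, abs=1e-12)

    def test_zero_denominator_is_missing(self):
        assert np.isnan(compute_vi([0, 0, 0, 0, 0, 0], "NDVI"))

    def test_unknown_index(self):
        with pytest.raises(ValueError):
            compute_vi([0.1] * 6, "SAVI2000")

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            compute_vi([np.nan] * 6, "NDVI")


class TestFcls:
    def test_pure_endmember_vertex(self):
        lib = random_library(np.random.default_rng(0))
        res = unmix_fcls(lib.spectra[2], lib)
        expected = np.zeros(4)
        expected[2] = 1.0
        np.testing.assert_allclose(res.abundances, expected, atol=1e-9)
        assert res.residual < 1e-10

    def test_exact_interior_mixture(self):
        lib = random_library(np.random.default_rng(1))
        mixed = 0.5 * lib.spectra[0] + 0.5 * lib.spectra[1]
        res = unmix_fcls(mixed, lib)
        np.testing.assert_allclose(res.abundances, [0.5, 0.5, 0, 0],
                                   atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_noisy_mixture_matches_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        lib = random_library(rng, m=3)
        a = rng.dirichlet(np.ones(3))
        mixed = np.clip(lib.spectra.T @ a + rng.normal(0, 0.01, 6), 0, 1)
        res = unmix_fcls(mixed, lib)
        _, grid_rms = simplex_grid_fcls(lib.spectra.T, mixed, step=1e-3)
        step_bound = 2e-3 * np.linalg.norm(lib.spectra, axis=1).max() / np.sqrt(6)
        assert res.residual <= grid_rms + 1e-9
        assert grid_rms - res.residual <= step_bound

    @given(st.integers(min_value=0, max_value=200))
    def test_constraints_always_hold(self, seed):
        rng = np.random.default_rng(seed)
        lib = random_library(rng, m=rng.integers(2, 7))
        mixed = rng.uniform(0, 1, 6)
        res = unmix_fcls(mixed, lib)
        assert res.abundances.min() >= 0
        assert res.abundances.max() <= 1 + 1e-8
        assert abs(res.abundances.sum() - 1.0) <= 1e-8
        assert res.residual >= 0

    def test_duplicate_endmembers_flagged(self):
        spectra = np.vstack([[0.1, 0.2, 0.1, 0.4, 0.5, 0.5],
                             [0.1, 0.2, 0.1, 0.4, 0.5, 0.5],
                             [0.1, 0.15, 0.2, 0.22, 0.24, 0.3]])
        lib = EndmemberLibrary(stage="SP", names=["a", "b", "soil"],
                               spectra=spectra,
                               is_soil=np.array([False, False, True]))
        res = unmix_fcls(spectra[0], lib)
        assert res.nonunique
        assert abs(res.abundances.sum() - 1.0) <= 1e-8

    def test_recovery_error_nondecreasing_in_noise(self):
        """Mean abundance recovery error grows with the mixing noise."""
        ladder = [0.0, 0.002, 0.01, 0.04]
        means = []
        for sd in ladder:
            errs = []
            for seed in range(20):
                rng = np.random.default_rng(100 + seed)
                lib = random_library(rng)
                a = rng.dirichlet(np.ones(4))
                mixed = np.clip(lib.spectra.T @ a + rng.normal(0, sd, 6),
                                0, 1)
                res = unmix_fcls(mixed, lib)
                errs.append(np.abs(res.abundances - a).max())
            means.append(np.mean(errs))
        assert means[0] <= 1e-6
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))

    def test_image_solver_matches_per_pixel(self):
        rng = np.random.default_rng(7)
        lib = random_library(rng, m=5)
        X = rng.uniform(0, 1, size=(6, 40))
        solver = FclsSolver(lib)
        abd, res = solver.solve_image(X)
        for i in range(40):
            single = solver.solve(X[:, i])
            np.testing.assert_allclose(abd[:, i], single.abundances,
                                       atol=1e-10)

    def test_scene_abundance_recovery(self, noisefree_scene_tp):
        """Noise-free synthetic pixels unmix back to the generated truth."""
        scene = noisefree_scene_tp
        abd, res = unmix_image(scene["cube"], scene["lib"])
        assert np.abs(abd - scene["truth"].abundances).max() <= 1e-6
        assert np.abs(abd.sum(axis=0) - 1.0).max() <= 1e-8


class TestSoilFreeIndices:
    def test_vegetation_abundance_cases(self):
        lib = generate_endmembers("SP", 0)  # names LL, SL, LS, SS
        mk = lambda a: vegetation_abundance(
            unmix_fcls(lib.spectra.T @ np.asarray(a), lib), lib)
        assert mk([0, 0, 0.7, 0.3]) == pytest.approx(0.0, abs=1e-8)
        assert mk([1, 0, 0, 0]) == pytest.approx(1.0, abs=1e-8)
        assert mk([0.4, 0.2, 0.3, 0.1]) == pytest.approx(0.6, abs=1e-7)

    @pytest.mark.parametrize("vi,veg,expected", [
        (0.8, 1.0, 0.8), (0.8, 0.0, 0.0), (0.8, 0.5, 0.4)])
    def test_vi_v_product(self, vi, veg, expected):
        assert compute_vi_v(vi, veg) == pytest.approx(expected)

    def test_vi_v_rejects_bad_abundance(self):
        with pytest.raises(ValueError):
            compute_vi_v(0.5, 1.5)

    def test_soil_removal_improves_agb_correlation(self):
        """Pooled across stages, VI[v] tracks AGB at least as well as
        VI[plot]: the dark soil background saturates mixed-pixel NDVI, and
        the non-soil abundance restores the vegetation-amount signal."""
        vi_plot, vi_v, agb = [], [], []
        for stage in ("SP", "FP", "TP"):
            cfg = SceneConfig(seed=11, stage=stage, mixing_noise_sd=0.0)
            cube, _, _, truth, plots = generate_scene(cfg)
            lib = generate_endmembers(stage, 11)
            abd, _ = unmix_image(cube, lib)
            for p in plots:
                spec = plot_mean_spectrum(cube, p.roi)
                vi = compute_vi(spec, "NDVI")
                veg = plot_vegetation_abundance(abd, lib, p.roi)
                vi_plot.append(vi)
                vi_v.append(compute_vi_v(vi, veg))
            agb.extend(truth.agb)
        r_plot = np.corrcoef(vi_plot, agb)[0, 1]
        r_v = np.corrcoef(vi_v, agb)[0, 1]
        assert r_v >= r_plot - 1e-6


class TestLibraryIO:
    def test_round_trip(self, tmp_path):
        lib = generate_endmembers("TP", 2)
        path = tmp_path / "lib.csv"
        write_endmembers(lib, path)
        back = read_endmembers(path)
        assert back.names == lib.names
        np.testing.assert_allclose(back.spectra, lib.spectra, atol=1e-12)
        np.testing.assert_array_equal(back.is_soil, lib.is_soil)

    def test_validation(self):
        with pytest.raises(LibraryError):
            EndmemberLibrary(stage="SP", names=["a"],
                             spectra=np.full((1, 6), 0.5),
                             is_soil=np.array([True]))
        with pytest.raises(LibraryError):
            EndmemberLibrary(stage="SP", names=["a", "b"],
                             spectra=np.full((2, 6), 0.5),
                             is_soil=np.array([False, False]))
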