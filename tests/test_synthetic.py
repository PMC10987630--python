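"""Synthetic-data generator: field ACF fidelity, cubes, nuclei, cohorts."""

import numpy as np
import pytest

from cspws.errors import SizingError, ValidationError
from cspws.models import ACFModel, CohortConfig, EllipseParams, NucleusMask
from cspws.processing import compute_sigma_map
from cspws.synthetic import (
    empirical_radial_acf,
    fit_acf_slope,
    generate_cohort,
    sample_density_field,
    simulate_spectral_cube,
    synthesize_dmap,
    synthesize_nucleus_image,
    target_acf,
)


def brute_force_acf(values, max_lag):
    """O(N^2) periodic autocorrelation oracle for small grids."""
    x = values - values.mean()
    n0, n1 = x.shape
    out = np.zeros((max_lag + 1, max_lag + 1))
    for dy in range(max_lag + 1):
        for dx in range(max_lag + 1):
            out[dy, dx] = np.mean(x * np.roll(np.roll(x, dy, axis=0), dx, axis=1))
    return out / out[0, 0]


class TestDensityField:
    def test_determinism(self):
        acf = ACFModel(D=2.4)
        a = sample_density_field(acf, (256, 256), 20.0, seed=11)
        b = sample_density_field(acf, (256, 256), 20.0, seed=11)
        assert np.array_equal(a.values, b.values)
        c = sample_density_field(acf, (256, 256), 20.0, seed=12)
        assert not np.array_equal(a.values, c.values)

    def test_space_filling_limit_flat_acf(self):
        # at D = 3 the power law r^(D-3) is constant, so the log-log
        # slope over the sensitivity window vanishes
        field = sample_density_field(ACFModel(D=3.0), (1024, 1024), 20.0, seed=0)
        assert abs(fit_acf_slope(field)) < 0.15

    def test_power_law_slope_d2(self):
        slopes = [
            fit_acf_slope(sample_density_field(ACFModel(D=2.0), (1024, 1024),
                                               20.0, seed=s))
            for s in range(5)
        ]
        assert np.mean(slopes) == pytest.approx(-1.0, abs=0.1)

    def test_fft_acf_matches_brute_force(self):
        field = sample_density_field(ACFModel(D=2.2), (1024, 1024), 20.0, seed=3)
        sub = field.values[:64, :64]
        oracle = brute_force_acf(sub, max_lag=8)
        fft_acf = np.fft.ifft2(
            np.abs(np.fft.fft2(sub - sub.mean())) ** 2
        ).real / sub.size
        fft_acf /= fft_acf[0, 0]
        assert np.allclose(fft_acf[:9, :9], oracle, atol=1e-10)

    def test_zero_mean_unit_variance(self):
        field = sample_density_field(ACFModel(D=2.5), (256, 256), 20.0, seed=5)
        assert field.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert field.values.std() == pytest.approx(1.0, abs=1e-12)

    def test_grid_too_small(self):
        with pytest.raises(SizingError):
            sample_density_field(ACFModel(D=2.5), (16, 16), 20.0, seed=0)

    @pytest.mark.parametrize("bad_d", [1.0, 3.5, 0.0])
    def test_invalid_d(self, bad_d):
        with pytest.raises(ValidationError):
            ACFModel(D=bad_d)

    def test_target_acf_monotone_nonincreasing(self):
        r = np.linspace(0, 2000, 500)
        for D in (2.0, 2.5, 3.0):
            b = target_acf(r, ACFModel(D=D))
            assert b[0] == pytest.approx(1.0)
            assert np.all(np.diff(b) <= 1e-12)


class TestSpectralCube:
    def test_sigma_exact_without_noise(self, instrument, calibration):
        field = sample_density_field(ACFModel(D=2.6), (64, 64), 20.0, seed=1)
        cube = simulate_spectral_cube(field, instrument, calibration,
                                      noise_sd=0.0, seed=2)
        sigma = compute_sigma_map(cube)
        assert np.allclose(sigma.values, calibration.sigma(2.6), atol=1e-12)

    def test_sigma_ordering_follows_calibration(self, instrument, calibration):
        stds = {}
        for d in (2.2, 2.6):
            field = sample_density_field(ACFModel(D=d), (64, 64), 20.0, seed=1)
            cube = simulate_spectral_cube(field, instrument, calibration,
                                          noise_sd=0.0, seed=2)
            stds[d] = compute_sigma_map(cube).values.mean()
        assert stds[2.6] > stds[2.2]  # calibration maps higher D higher

    def test_noise_variance_additivity(self, instrument, calibration):
        field = sample_density_field(ACFModel(D=2.5), (128, 128), 20.0, seed=4)
        noise_sd = 0.01
        cube = simulate_spectral_cube(field, instrument, calibration,
                                      noise_sd=noise_sd, seed=5)
        measured = compute_sigma_map(cube, detrend_order=0).values
        expected = np.sqrt(calibration.sigma(2.5) ** 2 + noise_sd**2)
        assert np.mean(measured**2) == pytest.approx(expected**2, rel=0.02)

    def test_negative_noise_rejected(self, instrument, calibration):
        field = sample_density_field(ACFModel(D=2.5), (64, 64), 20.0, seed=0)
        with pytest.raises(ValidationError):
            simulate_spectral_cube(field, instrument, calibration, noise_sd=-1)


class TestNucleusImage:
    def test_truth_mean_and_background(self, instrument, calibration):
        nuc = synthesize_nucleus_image(2.5, 0.35, instrument, seed=3,
                                       calib=calibration)
        assert np.nanmean(nuc.d_truth) == pytest.approx(2.5)
        sigma = compute_sigma_map(nuc.cube).values
        in_std = sigma[nuc.mask.values].mean()
        out_std = sigma[~nuc.mask.values].mean()
        assert out_std < 0.1 * in_std

    def test_seed_changes_speckle_not_geometry(self, instrument, calibration):
        morph = EllipseParams(center=(47.5, 47.5), semi_axes=(20, 14))
        a = synthesize_nucleus_image(2.5, 0.35, instrument, morphology=morph,
                                     seed=1, calib=calibration)
        b = synthesize_nucleus_image(2.5, 0.35, instrument, morphology=morph,
                                     seed=2, calib=calibration)
        assert np.array_equal(a.mask.values, b.mask.values)
        assert not np.array_equal(a.cube.data, b.cube.data)

    def test_oversized_ellipse_rejected(self, instrument, calibration):
        with pytest.raises(SizingError):
            synthesize_nucleus_image(
                2.5, 0.35, instrument, seed=0, calib=calibration,
                morphology=EllipseParams(center=(10, 10), semi_axes=(60, 60)),
                shape=(64, 64),
            )


class TestSynthesizeDmap:
    def test_values_centered_on_target(self):
        dm = synthesize_dmap(2.5, jitter_sd=0.05, seed=0)
        vals = dm.values[dm.mask.values]
        assert vals.mean() == pytest.approx(2.5, abs=0.05)
        assert np.all(np.isnan(dm.values[~dm.mask.values]))

    def test_texture_coarsens_with_d(self):
        # higher D -> longer correlation length -> smoother map ->
        # smaller mean absolute difference between neighboring pixels
        def roughness(d):
            dm = synthesize_dmap(d, jitter_sd=0.06, seed=7)
            v = dm.values.copy()
            v[~dm.mask.values] = np.nan
            diff = np.abs(np.diff(v, axis=0))
            return np.nanmean(diff) / np.nanstd(v)

        assert roughness(2.2) > roughness(2.8)


class TestCohort:
    def test_paper_scale_cohort_structure(self):
        cfg = CohortConfig(seed=1)
        cohort = generate_cohort(cfg)
        assert len(cohort) == 256
        assert sum(p.n_cells for p in cohort.patients) >= 30 * 256
        sizes = {g: len(ps) for g, ps in cohort.groups().items()}
        assert sizes == {"control": 135, "DA": 13, "NDA": 15, "AA": 74,
                         "HNPCC": 9, "cancer": 10}

    def test_zero_variance_collapses_to_group_means(self):
        cfg = CohortConfig(
            group_sizes={"control": 3, "AA": 3},
            group_mean_D={"control": 2.5, "AA": 2.6},
            between_patient_sd=0.0,
            within_patient_sd=0.0,
            age_slope=0.0,
            history_d_offset={"none": 0.0, "low": 0.0, "high": 0.0},
            seed=0,
        )
        cohort = generate_cohort(cfg)
        for p in cohort.patients:
            expected = cfg.group_mean_D[p.group]
            assert np.allclose(p.cell_d_values, expected)

    def test_group_mean_ordering_of_generated_truth(self):
        cohort = generate_cohort(CohortConfig(seed=3))
        means = {g: np.mean([p.mean_d for p in ps])
                 for g, ps in cohort.groups().items()}
        order = ["control", "DA", "NDA", "AA", "HNPCC", "cancer"]
        # generous sampling slack for the small groups; the large
        # control/AA contrast must hold strictly
        assert means["AA"] > means["control"]
        assert means["cancer"] > means["control"]

    def test_determinism_identical_manifests(self, tmp_path):
        from cspws.io import file_checksum, write_cell_table, write_manifest

        for name in ("a", "b"):
            cohort = generate_cohort(CohortConfig(
                group_sizes={"control": 5, "AA": 5},
                group_mean_D={"control": 2.5, "AA": 2.6},
                seed=42,
            ))
            write_manifest(tmp_path / f"{name}.csv", cohort)
            write_cell_table(tmp_path / f"{name}_cells.csv", cohort)
        assert file_checksum(tmp_path / "a.csv") == file_checksum(tmp_path / "b.csv")
        assert file_checksum(tmp_path / "a_cells.csv") == \
            file_checksum(tmp_path / "b_cells.csv")

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValidationError):
            CohortConfig(
                group_sizes={"control": 5, "AA": 5},
                group_mean_D={"control": 2.6, "AA": 2.5},
            )

    def test_empty_groups_rejected(self):
        with pytest.raises(ValidationError):
            CohortConfig(group_sizes={})

    def test_cell_floor_enforced(self):
        with pytest.raises(ValidationError):
            CohortConfig(cells_per_patient=30)

    def test_age_slope_recovery_against_ols_oracle(self):
        cfg = CohortConfig(
            group_sizes={"control": 120},
            group_mean_D={"control": 2.5},
            between_patient_sd=0.0,
            within_patient_sd=0.0,
            age_slope=-0.008,
            history_d_offset={"none": 0.0, "low": 0.0, "high": 0.0},
            seed=9,
        )
        cohort = generate_cohort(cfg)
        ages = np.array([p.age for p in cohort.patients])
        d = np.array([p.mean_d for p in cohort.patients])
        # closed-form OLS oracle
        xc = ages - ages.mean()
        slope = float(np.sum(xc * (d - d.mean())) / np.sum(xc**2))
        assert slope == pytest.approx(-0.008, abs=1e-9)
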