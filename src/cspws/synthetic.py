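"""Ground-truth-labeled synthetic data for the packing-scaling pipeline.

The generator answers three needs, in increasing order of aggregation:

1. **Density fields** — stationary Gaussian random fields whose radial
   autocorrelation follows the mass-fractal power law ``B(r) ∝ r**(D-3)``
   inside the instrument's sensitivity window. These test the physics
   claim (the log-log ACF slope equals ``D - 3``) directly.
2. **Spectral cubes** — per-pixel interference spectra whose wavelength
   standard deviation equals the forward-model ``sigma(D, phi)``, plus
   white measurement noise. Cubes are synthesized as calibrated
   stationary fluctuation processes, not by electromagnetic simulation:
   cube-level D recovery is therefore a plumbing-and-inversion test,
   while physics realism is tested at the field-ACF level.
3. **Cohorts** — patients with diagnostic group, demographics, history
   category and per-cell nuclear D drawn from a hierarchical model
   (group mean + patient offset + cell offset + age trend).

Every operation takes an explicit seed; a cohort seed deterministically
derives per-patient and per-cell child seeds.
"""

from __future__ import annotations

import math
from functools import lru_cache as _lru_cache
from typing import NamedTuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from cspws.errors import SizingError, ValidationError
from cspws.models import (
    ACFModel,
    CalibrationTable,
    Cohort,
    CohortConfig,
    DensityField,
    DIAGNOSTIC_GROUPS,
    EllipseParams,
    HISTORY_CATEGORIES,
    InstrumentModel,
    NucleusMask,
    PatientRecord,
    SpectralCube,
)


# ---------------------------------------------------------------------------
# Density fields with prescribed power-law autocorrelation
# ---------------------------------------------------------------------------

def target_acf(r: np.ndarray, acf: ACFModel) -> np.ndarray:
    """Evaluate the model autocorrelation B(r), normalized to B(0) = 1.

    Power law ``(r / r_min)**(D - 3)`` on ``[r_min, r_max]``, flat below
    ``r_min`` (the field is unresolved there), Gaussian roll-off to zero
    beyond ``r_max`` with scale ``2 * r_max`` (the behaviour outside the
    sensitivity window is a modeling choice; the wide roll-off keeps the
    windowed function close to positive-definite).
    """
    r = np.asarray(r, dtype=float)
    exponent = acf.D - 3.0
    plateau = (acf.r_min / acf.r_max) ** exponent
    b = np.empty_like(r)
    low = r <= acf.r_min
    mid = (r > acf.r_min) & (r <= acf.r_max)
    high = r > acf.r_max
    b[low] = plateau
    b[mid] = (r[mid] / acf.r_max) ** exponent
    roll = 2.0 * acf.r_max
    b[high] = np.exp(-((r[high] - acf.r_max) ** 2) / (2.0 * roll**2))
    return b / plateau


@_lru_cache(maxsize=16)
def _acf_spectrum(acf: ACFModel, shape: tuple[int, int], pitch: float,
                  iters: int = 30) -> np.ndarray:
    """Non-negative power spectrum whose grid ACF matches the target B(r).

    The windowed power law is not exactly positive-definite, so the
    spectrum is obtained by alternating projections: clip the spectrum to
    be non-negative, transform back, re-pin B(r) to its target inside
    ``r <= r_max``, and repeat. Thirty iterations leave the realized
    log-log ACF slope within ~0.03 of ``D - 3`` on a 1024^2 grid.
    """
    ny, nx = shape
    fy = np.fft.fftfreq(ny) * ny * pitch
    fx = np.fft.fftfreq(nx) * nx * pitch
    r = np.hypot(fy[:, None], fx[None, :])
    target = target_acf(r, acf)
    fix = r <= acf.r_max
    b = target.copy()
    for _ in range(iters):
        spectrum = np.fft.fft2(b).real
        np.clip(spectrum, 0.0, None, out=spectrum)
        b = np.fft.ifft2(spectrum).real
        b[fix] = target[fix]
    spectrum = np.fft.fft2(b).real
    np.clip(spectrum, 0.0, None, out=spectrum)
    spectrum.setflags(write=False)
    return spectrum


def sample_density_field(
    acf: ACFModel,
    shape: tuple[int, int],
    pitch: float,
    seed: int,
) -> DensityField:
    """Draw a Gaussian random field realizing the target autocorrelation.

    Spectral synthesis: white Gaussian noise is colored by the square
    root of a non-negative power spectrum constructed to reproduce the
    target B(r) on the (periodic) grid. The result is stationary,
    zero-mean, unit-variance, and its radially averaged empirical ACF has
    log-log slope ``D - 3`` over ``[r_min, r_max]``.

    Parameters
    ----------
    acf
        Target autocorrelation model (validates ``1 < D <= 3``).
    shape
        Grid dimensions ``(ny, nx)``; the physical extent of each axis
        must exceed ``2 * r_max``.
    pitch
        Pixel size in nm.
    seed
        Seed for the white-noise draw; identical calls are bit-identical.
    """
    ny, nx = shape
    if min(ny, nx) * pitch <= 2.0 * acf.r_max:
        raise SizingError(
            f"grid extent {min(ny, nx) * pitch:g} nm too small to resolve "
            f"r_max = {acf.r_max:g} nm (need > 2 * r_max)"
        )
    spectrum = _acf_spectrum(acf, (ny, nx), float(pitch))

    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    field = np.fft.ifft2(np.fft.fft2(white) * np.sqrt(spectrum)).real
    field -= field.mean()
    sd = field.std()
    if sd > 0:
        field /= sd
    return DensityField(values=field, pixel_pitch=pitch, acf_truth=acf, seed=seed)


def empirical_radial_acf(
    values: np.ndarray, pitch: float, r_max: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged autocorrelation of a 2-D field (FFT, periodic).

    Returns ``(r_nm, acf)`` with the zero-lag bin normalized to 1, binned
    by integer pixel radius.
    """
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    f = np.fft.fft2(x)
    acf2d = np.fft.ifft2(f * np.conj(f)).real / x.size
    acf2d /= acf2d[0, 0]
    ny, nx = x.shape
    iy = np.fft.fftfreq(ny) * ny
    ix = np.fft.fftfreq(nx) * nx
    rpix = np.hypot(iy[:, None], ix[None, :])
    rbin = np.rint(rpix).astype(int)
    limit = int(min(ny, nx) // 2) if r_max is None else int(math.ceil(r_max / pitch))
    limit = min(limit, int(min(ny, nx) // 2))
    counts = np.bincount(rbin.ravel(), minlength=limit + 1)[: limit + 1]
    sums = np.bincount(rbin.ravel(), weights=acf2d.ravel(), minlength=limit + 1)
    prof = sums[: limit + 1] / np.maximum(counts, 1)
    r_nm = np.arange(limit + 1) * pitch
    return r_nm, prof


def fit_acf_slope(
    field: DensityField,
    r_min: float | None = None,
    r_max: float | None = None,
) -> float:
    """Least-squares log-log slope of the field's radial ACF over the window.

    For a field honoring the mass-fractal model the slope estimates
    ``D - 3``. Non-positive ACF bins are excluded from the fit.
    """
    acf = field.acf_truth
    r_min = acf.r_min if r_min is None else r_min
    r_max = acf.r_max if r_max is None else r_max
    r, prof = empirical_radial_acf(field.values, field.pixel_pitch, r_max=r_max)
    sel = (r >= r_min) & (r <= r_max) & (prof > 0)
    if sel.sum() < 3:
        raise SizingError("fewer than 3 usable ACF bins inside the fit window")
    slope = np.polyfit(np.log(r[sel]), np.log(prof[sel]), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Spectral cubes
# ---------------------------------------------------------------------------

def _detrend_projection(lambda_grid: np.ndarray, order: int) -> np.ndarray:
    """Residual-projection matrix of a degree-``order`` polynomial fit."""
    lam = np.asarray(lambda_grid, dtype=float)
    t = (lam - lam.mean()) / (lam.max() - lam.min())
    V = np.vander(t, order + 1, increasing=True)
    hat = V @ np.linalg.solve(V.T @ V, V.T)
    return np.eye(lam.size) - hat


def _fluctuation_block(
    shape_xy: tuple[int, int],
    lambda_grid: np.ndarray,
    rng: np.random.Generator,
    smooth_sigma: float = 3.0,
    detrend_order: int = 1,
) -> np.ndarray:
    """Zero-mean, detrended, unit-std spectral fluctuations per pixel.

    A white process over wavelength is smoothed (band-limited, mimicking
    the finite spectral correlation of interference fringes), projected
    onto the complement of the degree-``detrend_order`` polynomial space,
    and normalized pixelwise to unit standard deviation, so multiplying
    by the forward-model sigma gives spectra whose detrended std equals
    that sigma exactly.
    """
    L = lambda_grid.size
    raw = rng.standard_normal(shape_xy + (L,))
    raw = gaussian_filter1d(raw, sigma=smooth_sigma, axis=-1, mode="nearest")
    P = _detrend_projection(lambda_grid, detrend_order)
    raw = raw @ P.T
    sd = raw.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return raw / sd


def simulate_spectral_cube(
    field: DensityField,
    inst: InstrumentModel,
    sigma_forward: CalibrationTable,
    noise_sd: float = 0.0,
    seed: int = 0,
    d_map: np.ndarray | None = None,
) -> SpectralCube:
    """Synthesize a reference-normalized interference cube for a field.

    Each pixel's spectrum is ``1 + fluctuation`` where the fluctuation is
    a stationary process over wavelength whose (detrended) standard
    deviation equals the forward-model ``sigma`` at that pixel's local
    packing scaling, plus white measurement noise of sd ``noise_sd``.

    Parameters
    ----------
    field
        Density-field realization; its ``acf_truth.D`` is the default
        local D everywhere.
    d_map
        Optional per-pixel D override (same shape as the field).
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    local_d = np.full(field.values.shape, field.acf_truth.D) if d_map is None \
        else np.asarray(d_map, dtype=float)
    if local_d.shape != field.values.shape:
        raise ValidationError("d_map shape must match the field")
    sigma = np.asarray(sigma_forward.sigma(local_d), dtype=float)

    rng = np.random.default_rng(seed)
    fluct = _fluctuation_block(field.values.shape, inst.lambda_grid, rng)
    data = 1.0 + fluct * sigma[..., None]
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return SpectralCube(
        data=data, lambda_grid=inst.lambda_grid, pixel_pitch=field.pixel_pitch
    )


class SyntheticNucleus(NamedTuple):
    """A synthesized nucleus: cube, segmentation truth, per-pixel D truth."""

    cube: SpectralCube
    mask: NucleusMask
    d_truth: np.ndarray  # NaN outside the mask


def _ellipse_mask(shape: tuple[int, int], morph: EllipseParams) -> np.ndarray:
    cy, cx = morph.center
    ay, ax = morph.semi_axes
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dy, dx = yy - cy, xx - cx
    c, s = math.cos(morph.angle), math.sin(morph.angle)
    u = c * dy + s * dx
    v = -s * dy + c * dx
    return (u / ay) ** 2 + (v / ax) ** 2 <= 1.0


def synthesize_nucleus_image(
    D_target: float,
    phi: float,
    inst: InstrumentModel,
    morphology: EllipseParams | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (96, 96),
    calib: CalibrationTable | None = None,
    jitter_sd: float = 0.0,
    noise_sd: float = 0.0,
    background_sigma_frac: float = 0.02,
) -> SyntheticNucleus:
    """Place a constant-D (optionally jittered) elliptical nucleus on a
    clean background and synthesize its spectral cube.

    Outside the mask the fluctuation std is ``background_sigma_frac``
    times the in-mask value; the truth map is NaN there. Mask geometry is
    fully determined by ``morphology`` (seed changes only the speckle).
    """
    if morphology is None:
        morphology = EllipseParams(
            center=((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0),
            semi_axes=(shape[0] * 0.32, shape[1] * 0.24),
        )
    cy, cx = morphology.center
    ay, ax = morphology.semi_axes
    reach = max(ay, ax)
    if (cy - reach < 0 or cy + reach > shape[0] - 1
            or cx - reach < 0 or cx + reach > shape[1] - 1):
        raise SizingError("ellipse morphology exceeds the image frame")

    if calib is None:
        from cspws.processing import build_calibration

        calib = build_calibration(inst, phi)
    mask = _ellipse_mask(shape, morphology)

    rng = np.random.default_rng(seed)
    d_truth = np.full(shape, np.nan)
    d_in = np.full(int(mask.sum()), float(D_target))
    if jitter_sd > 0:
        d_in = d_in + rng.normal(0.0, jitter_sd, size=d_in.size)
        d_in = np.clip(d_in, calib.D_grid[0], calib.D_grid[-1])
    d_truth[mask] = d_in

    sigma_in = np.asarray(calib.sigma(np.where(mask, np.nan_to_num(d_truth, nan=D_target), D_target)))
    sigma_map = np.where(mask, sigma_in, background_sigma_frac * float(calib.sigma(D_target)))

    fluct = _fluctuation_block(shape, inst.lambda_grid, rng)
    data = 1.0 + fluct * sigma_map[..., None]
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    cube = SpectralCube(
        data=data, lambda_grid=inst.lambda_grid, pixel_pitch=inst.pixel_pitch
    )
    return SyntheticNucleus(cube=cube, mask=NucleusMask(values=mask), d_truth=d_truth)


def synthesize_dmap(
    D_target: float,
    shape: tuple[int, int] = (64, 64),
    morphology: EllipseParams | None = None,
    jitter_sd: float = 0.06,
    texture_corr_px: float | None = None,
    seed: int = 0,
):
    """Synthesize a recovered-looking nuclear D map directly.

    Bypasses the spectral simulation to produce what the processing stage
    would output: per-pixel D over an elliptical nucleus, equal to
    ``D_target`` plus smooth intra-nuclear heterogeneity of sd
    ``jitter_sd`` and correlation length ``texture_corr_px`` (pixels).
    When the correlation length is not given it scales with D as
    ``2 ** ((D - 2) / 0.25)`` (doubling every 0.25 in D): denser packing
    forms larger coherent packing-domain clusters, so the map's texture
    coarsens. Because downstream preprocessing min-max normalizes every
    image, this texture — not the mean level — is what a classifier can
    use.

    Returns a :class:`cspws.models.DMap` (values NaN outside the mask).
    """
    from cspws.models import DMap

    if morphology is None:
        rng0 = np.random.default_rng(seed)
        ay = shape[0] * (0.26 + 0.08 * rng0.random())
        ax = shape[1] * (0.20 + 0.08 * rng0.random())
        morphology = EllipseParams(
            center=((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0),
            semi_axes=(ay, ax),
            angle=float(rng0.uniform(0, math.pi)),
        )
    mask = _ellipse_mask(shape, morphology)
    if texture_corr_px is None:
        texture_corr_px = 2.0 ** ((D_target - 2.0) / 0.25)
    rng = np.random.default_rng(seed + 1)
    noise = rng.standard_normal(shape)
    from scipy.ndimage import gaussian_filter

    tex = gaussian_filter(noise, sigma=max(texture_corr_px, 1e-6))
    sd = tex.std()
    if sd > 0:
        tex = tex / sd * jitter_sd
    values = np.full(shape, np.nan)
    values[mask] = np.clip(D_target + tex[mask], 1.0 + 1e-6, 3.0)
    return DMap(values=values, mask=NucleusMask(values=mask))


def generate_dmap_dataset(
    n_per_class: int,
    cells_per_patient: int,
    d_by_class: tuple[float, float] = (2.35, 2.75),
    between_sd: float = 0.03,
    within_sd: float = 0.02,
    jitter_sd: float = 0.06,
    shape: tuple[int, int] = (64, 64),
    seed: int = 0,
) -> tuple[list, list[str], dict[str, int]]:
    """Per-cell D maps for classification experiments.

    Builds ``n_per_class`` patients per class; class 0 cells center on
    ``d_by_class[0]`` and class 1 on ``d_by_class[1]``, with
    between-patient and between-cell scatter. Returns
    ``(dmaps, patient_ids, labels)`` ready for
    :meth:`cspws.classifier.ClassificationDataset.from_dmaps`.
    """
    seeds = derive_child_seeds(seed, 2 * n_per_class)
    dmaps, pids, labels = [], [], {}
    for cls in (0, 1):
        for i in range(n_per_class):
            pid = f"class{cls}_p{i:03d}"
            prng = np.random.default_rng(int(seeds[cls * n_per_class + i]))
            labels[pid] = cls
            base = d_by_class[cls] + prng.normal(0.0, between_sd)
            for c in range(cells_per_patient):
                d_cell = base + prng.normal(0.0, within_sd)
                dmaps.append(
                    synthesize_dmap(
                        float(np.clip(d_cell, 2.0, 3.0)),
                        shape=shape,
                        jitter_sd=jitter_sd,
                        seed=int(prng.integers(2**31)),
                    )
                )
                pids.append(pid)
    return dmaps, pids, labels


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, bounds, size=None):
    lo, hi = bounds
    draws = rng.normal(mean, sd, size=size if size else 1)
    for _ in range(100):
        bad = (draws < lo) | (draws > hi)
        if not bad.any():
            break
        draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    np.clip(draws, lo, hi, out=draws)
    return draws if size else float(draws[0])


def derive_child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministically derive ``n`` child seeds (< 2**31) from one seed."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) % (2**31)


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort of patient records.

    Per-cell truth D is hierarchical::

        D = group_mean[g] + history_d_offset[h] + patient_offset
            + cell_offset + age_slope * (age - group_mean_age[g])

    with patient offsets ~ N(0, between_patient_sd), cell offsets
    ~ N(0, within_patient_sd), and D clipped to (1, 3]. The age trend is
    centered on each group's nominal mean age so the configured group
    means are the observed ones — cases are elevated despite being older
    on average, with age explaining only within-group variation.
    Demographics and history categories are drawn from the per-group
    models in the config. All randomness derives from ``cfg.seed``.
    """
    groups = [g for g in DIAGNOSTIC_GROUPS if g in cfg.group_sizes]
    n_total = cfg.n_patients
    patient_seeds = derive_child_seeds(cfg.seed, n_total)

    # First pass: demographics, so the cohort mean age is known before
    # cell values are drawn.
    meta = []
    idx = 0
    for g in groups:
        for j in range(cfg.group_sizes[g]):
            rng = np.random.default_rng(int(patient_seeds[idx]))
            age = _truncated_normal(
                rng, cfg.age_mean.get(g, 60.0), cfg.age_sd, cfg.age_bounds
            )
            rates = cfg.demographic_rates
            sex = "F" if rng.random() < rates["female"].get(g, 0.5) else "M"
            smoking = bool(rng.random() < rates["smoking"].get(g, 0.15))
            drinking = bool(rng.random() < rates["drinking"].get(g, 0.65))
            hp = cfg.history_probs.get(g, {"none": 1.0, "low": 0.0, "high": 0.0})
            probs = np.array([hp.get(h, 0.0) for h in HISTORY_CATEGORIES])
            probs = probs / probs.sum()
            history = HISTORY_CATEGORIES[rng.choice(len(probs), p=probs)]
            meta.append((f"P{idx:04d}", g, age, sex, smoking, drinking, history, rng))
            idx += 1

    patients = []
    for i, (pid, g, age, sex, smoking, drinking, history, rng) in enumerate(meta):
        offset = rng.normal(0.0, cfg.between_patient_sd) if cfg.between_patient_sd else 0.0
        base = (
            cfg.group_mean_D[g]
            + cfg.history_d_offset.get(history, 0.0)
            + offset
            + cfg.age_slope * (age - cfg.age_mean.get(g, 60.0))
        )
        cells = base + (
            rng.normal(0.0, cfg.within_patient_sd, size=cfg.cells_per_patient)
            if cfg.within_patient_sd
            else np.zeros(cfg.cells_per_patient)
        )
        cells = np.clip(cells, 1.0 + 1e-6, 3.0)
        patients.append(
            PatientRecord(
                patient_id=pid,
                group=g,
                age=float(age),
                sex=sex,
                smoking=smoking,
                drinking=drinking,
                history=history,
                cell_d_values=[float(c) for c in cells],
                prior_cancer=bool(history == "high" and rng.random() < 0.2),
                seed=int(patient_seeds[i]),
            )
        )
    return Cohort(patients=patients, config=cfg)
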