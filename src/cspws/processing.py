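"""Spectral-cube processing: sigma maps, calibration, D maps, aggregation.

The measured statistic is sigma — the per-pixel standard deviation over
wavelength of the reference-normalized interference spectrum. Sigma maps
to the packing scaling D through a forward model::

    sigma^2(D) = A * phi * (1 - phi)
                 * integral_{r_min}^{r_max} (r / r_min)**(D - 3) * S(r) * r dr

where ``S(r)`` is a Gaussian coherence kernel with transverse scale equal
to the instrument's transverse coherence extent (an axial factor from the
depth of field is folded into the constant), and ``A`` is an instrument
constant. The table sigma(D) is strictly increasing, so per-pixel D is
recovered by monotone interpolation of the inverse.

The calibration is self-consistent within this package: absolute D values
are defined by this forward model, which shares its functional form with
the mass-fractal autocorrelation used by the field generator, and no
external ground-truth imaging is involved.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate, ndimage, stats

from cspws.errors import CalibrationError, ValidationError
from cspws.models import (
    CalibrationTable,
    DMap,
    InstrumentModel,
    NucleusMask,
    SigmaMap,
    SpectralCube,
)
from cspws.synthetic import _detrend_projection

#: Default instrument constant of the forward model, chosen once so that
#: sigma falls in the few-percent reflectance range typical of
#: interference microscopy (sigma(D=3, phi=0.35) ~ 0.05).
DEFAULT_AMPLITUDE = 3.0e-11


def normalize_by_reference(raw: np.ndarray, reference_spectrum: np.ndarray,
                           lambda_grid: np.ndarray,
                           pixel_pitch: float = 150.0) -> SpectralCube:
    """Divide a raw cube by the blank-region reference spectrum.

    ``out(x, y, lam) = raw(x, y, lam) / reference(lam)``.
    """
    raw = np.asarray(raw, dtype=float)
    ref = np.asarray(reference_spectrum, dtype=float)
    if raw.ndim != 3:
        raise ValidationError("raw cube must be 3-D (y, x, lambda)")
    if ref.ndim != 1 or ref.size != raw.shape[2]:
        raise ValidationError(
            f"reference length {ref.size} != cube lambda axis {raw.shape[2]}"
        )
    if np.asarray(lambda_grid).size != ref.size:
        raise ValidationError("lambda_grid length != reference length")
    if np.any(ref <= 0):
        raise ValidationError("reference spectrum must be strictly positive")
    return SpectralCube(
        data=raw / ref[None, None, :],
        lambda_grid=lambda_grid,
        pixel_pitch=pixel_pitch,
    )


def compute_sigma_map(cube: SpectralCube, detrend_order: int = 1) -> SigmaMap:
    """Per-pixel standard deviation over wavelength of the detrended spectrum.

    A degree-``detrend_order`` polynomial baseline is removed from each
    pixel's spectrum before taking the (population) standard deviation;
    order 1 removes the slowly varying reflectance slope while leaving
    the interference fluctuation intact. Order 0 reduces to the plain
    standard deviation.
    """
    if cube.lambda_grid.size < 3:
        raise ValidationError("need >= 3 wavelength samples")
    data = cube.data
    if not np.all(np.isfinite(data)):
        bad = np.argwhere(~np.isfinite(data))[0]
        raise ValidationError(
            f"non-finite value in cube at pixel (y={bad[0]}, x={bad[1]}, "
            f"lambda index {bad[2]})"
        )
    if detrend_order < 0:
        raise ValidationError("detrend_order must be >= 0")
    P = _detrend_projection(cube.lambda_grid, detrend_order)
    resid = data @ P.T
    return SigmaMap(values=resid.std(axis=-1))


def segment_nuclei(
    image: np.ndarray,
    min_area: int = 200,
    max_area: int | None = None,
) -> list[NucleusMask]:
    """Automatic nucleus segmentation of a 2-D summary image.

    Otsu global threshold, hole filling, connected components, and an
    [min_area, max_area] area filter; masks are returned sorted by area,
    largest first. A blank (constant) image yields an empty list.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValidationError("summary image contains non-finite values")
    if image.max() == image.min():
        return []
    binary = image > threshold_otsu(image)
    binary = ndimage.binary_fill_holes(binary)
    labels = label(binary)
    masks = []
    for region in regionprops(labels):
        if region.area < min_area:
            continue
        if max_area is not None and region.area > max_area:
            continue
        masks.append(NucleusMask(values=labels == region.label))
    masks.sort(key=lambda m: m.area_px, reverse=True)
    return masks


def _sigma_squared_integral(D: float, inst: InstrumentModel,
                            r_min: float, r_max: float) -> float:
    """Quadrature of the coherence-weighted autocorrelation integral."""
    lt = inst.coherence_xy

    def integrand(r):
        # B normalized at r_min, so sigma grows with D (denser packing ->
        # stronger long-range correlation -> larger interference signal)
        return (r / r_min) ** (D - 3.0) * math.exp(-(r**2) / (2.0 * lt**2)) * r

    val, _ = integrate.quad(integrand, r_min, r_max, limit=200)
    axial = math.sqrt(2.0 * math.pi) * inst.depth_of_field
    return val * axial


def build_calibration(
    inst: InstrumentModel,
    phi: float,
    D_grid: np.ndarray | None = None,
    amplitude: float = DEFAULT_AMPLITUDE,
    r_min: float = 23.0,
    r_max: float = 334.0,
) -> CalibrationTable:
    """Build the strictly monotone sigma(D) forward table.

    Raises
    ------
    CalibrationError
        If sigma(D) is not strictly increasing over the grid (advises
        reviewing the grid and coherence kernel).
    """
    if not (0.0 < phi < 1.0):
        raise ValidationError("phi must be in (0, 1)")
    if amplitude <= 0:
        raise ValidationError("amplitude must be > 0")
    if D_grid is None:
        D_grid = np.linspace(2.0, 3.0, 101)
    D_grid = np.asarray(D_grid, dtype=float)
    if D_grid[0] <= 1.0 or D_grid[-1] > 3.0:
        raise ValidationError("D_grid must lie within (1, 3]")
    sig2 = np.array(
        [amplitude * phi * (1 - phi) * _sigma_squared_integral(d, inst, r_min, r_max)
         for d in D_grid]
    )
    return CalibrationTable(
        D_grid=D_grid,
        sigma_of_D=np.sqrt(sig2),
        phi=phi,
        instrument=inst.id,
        amplitude=amplitude,
    )


def effective_noise_sigma(noise_sd: float, n_lambda: int,
                          detrend_order: int = 1) -> float:
    """White measurement noise sd as it appears in a detrended sigma map.

    Detrending projects out ``detrend_order + 1`` spectral degrees of
    freedom, shrinking the white-noise variance by ``(L - p - 1) / L``.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    frac = max(n_lambda - detrend_order - 1, 0) / n_lambda
    return float(noise_sd * math.sqrt(frac))


def estimate_d_map(
    sigma: SigmaMap,
    calib: CalibrationTable,
    mask: NucleusMask,
    pixel_window: float = 458.0,
    noise_sigma: float = 0.0,
) -> DMap:
    """Invert the calibration at each in-mask pixel's sigma.

    ``noise_sigma`` is the known measurement-noise sd (as measured at a
    blank reference region, optionally corrected for detrending via
    :func:`effective_noise_sigma`); its variance is subtracted from the
    measured sigma^2 before inversion, since independent noise adds in
    variance. Out-of-mask pixels are NaN. Sigma outside the table range
    clamps to the nearest grid end and is flagged; when more than half
    of the in-mask pixels clamp, a warning-level diagnostic is recorded
    in the map's metadata.
    """
    if sigma.values.shape != mask.values.shape:
        raise ValidationError("sigma map and mask shapes differ")
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    values = np.full(sigma.values.shape, np.nan)
    clamped = np.zeros(sigma.values.shape, dtype=bool)
    m = mask.values
    sig_in = sigma.values[m]
    if noise_sigma > 0:
        sig_in = np.sqrt(np.maximum(sig_in**2 - noise_sigma**2, 0.0))
    d_in, cl_in = calib.invert(sig_in)
    values[m] = d_in
    clamped[m] = cl_in
    frac = float(cl_in.mean()) if cl_in.size else 0.0
    meta = {"clamp_fraction": frac, "calibration": calib.instrument}
    if frac > 0.5:
        meta["warning"] = (
            f"{frac:.0%} of in-mask pixels fell outside the calibrated "
            "sigma range; check phi/amplitude settings"
        )
    return DMap(values=values, mask=mask, pixel_window=pixel_window,
                clamped=clamped, metadata=meta)


def nuclear_average_d(dmap: DMap, min_area: int = 1) -> float:
    """Arithmetic mean of D over in-mask, non-clamped pixels."""
    m = dmap.mask.values & ~dmap.clamped & np.isfinite(dmap.values)
    n = int(m.sum())
    if dmap.mask.area_px < min_area:
        raise ValidationError("mask smaller than the minimum area")
    if n == 0:
        raise ValidationError("all in-mask pixels are clamped or invalid")
    return float(dmap.values[m].mean())


class PatientDStats:
    """Summary of a patient's per-cell nuclear-mean D values."""

    __slots__ = ("mean", "sd", "n", "ci_low", "ci_high", "below_floor")

    def __init__(self, mean, sd, n, ci_low, ci_high, below_floor):
        self.mean = mean
        self.sd = sd
        self.n = n
        self.ci_low = ci_low
        self.ci_high = ci_high
        self.below_floor = below_floor

    def __iter__(self):
        yield from (self.mean, self.sd, self.n, (self.ci_low, self.ci_high))


def patient_average_d(
    cell_values, confidence: float = 0.95, floor: int = 30
) -> PatientDStats:
    """Mean, sample sd and t-based confidence interval of per-cell D.

    Patients with ``n <= floor`` cells are flagged as below the study's
    inclusion floor. With a single cell the CI is undefined (infinite).
    """
    vals = np.asarray(list(cell_values), dtype=float)
    if vals.size == 0:
        raise ValidationError("cell_values must not be empty")
    n = int(vals.size)
    mean = float(vals.mean())
    if n == 1:
        return PatientDStats(mean, float("nan"), 1, -np.inf, np.inf, True)
    sd = float(vals.std(ddof=1))
    sem = sd / math.sqrt(n)
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, df=n - 1))
    half = tcrit * sem
    return PatientDStats(mean, sd, n, mean - half, mean + half, n <= floor)
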