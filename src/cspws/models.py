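"""Domain types for the chromatin packing-scaling analysis.

Conventions
-----------
* All physical lengths are in nanometres; wavelengths in nm; ages in years.
* Spectral cubes are ``(y, x, lambda)`` arrays of reference-normalized
  reflectance; masks and maps share the ``(y, x)`` shape of the cube.
* The packing scaling exponent ``D`` of the mass-fractal relation
  ``N_f ∝ r^D`` lives in ``(1, 3]``; the density autocorrelation B(r) has
  log-log slope ``D - 3`` inside the instrument's sensitivity window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from cspws.errors import CalibrationError, ValidationError

#: Diagnostic groups in order of increasing expected nuclear D.
DIAGNOSTIC_GROUPS: tuple[str, ...] = (
    "control",
    "DA",
    "NDA",
    "AA",
    "HNPCC",
    "cancer",
)

#: Colonoscopy-history risk categories.
HISTORY_CATEGORIES: tuple[str, ...] = ("none", "low", "high")


def default_lambda_grid() -> np.ndarray:
    """Acquisition wavelength grid: 500-700 nm in 2 nm steps (101 planes)."""
    return np.arange(500.0, 700.0 + 1e-9, 2.0)


@dataclass(frozen=True)
class ACFModel:
    """Target autocorrelation of the chromatin mass-density field.

    Inside the sensitivity window ``[r_min, r_max]`` the autocorrelation
    follows the mass-fractal power law ``B(r) ∝ (r / r_max)**(D - 3)``;
    below ``r_min`` it is flat and beyond ``r_max`` it rolls off smoothly
    to zero (the behaviour outside the window is a modeling choice, not a
    measurable quantity).

    Parameters
    ----------
    D
        Packing scaling exponent, dimensionless, in (1, 3].
    phi
        Chromatin volume concentration (fraction of nuclear volume).
    Nf
        Genomic size of a packing domain in monomers (carried as metadata).
    r_min, r_max
        Sensitivity window bounds in nm (defaults 23 and 334).
    Db
        Shape parameter of B(r); in this parameterization it is synonymous
        with ``D`` and defaults to it.
    """

    D: float
    phi: float = 0.35
    Nf: float = 4.0e5
    r_min: float = 23.0
    r_max: float = 334.0
    Db: float | None = None

    def __post_init__(self):
        if not (1.0 < self.D <= 3.0):
            raise ValidationError(f"D must be in (1, 3], got {self.D}")
        if not (0.0 < self.phi < 1.0):
            raise ValidationError(f"phi must be in (0, 1), got {self.phi}")
        if not (0.0 < self.r_min < self.r_max):
            raise ValidationError(
                f"need 0 < r_min < r_max, got ({self.r_min}, {self.r_max})"
            )
        if self.Db is None:
            object.__setattr__(self, "Db", self.D)


@dataclass(frozen=True)
class InstrumentModel:
    """Optical model of the interference microscope.

    Defaults follow the instrument this analysis was designed for: 0.6 NA
    illumination, 0.8 NA collection, 500-700 nm at 2 nm steps, a 458 nm
    transverse coherence extent and a ~3 um depth of field.
    """

    na_illumination: float = 0.6
    na_collection: float = 0.8
    lambda_grid: np.ndarray = field(default_factory=default_lambda_grid)
    coherence_xy: float = 458.0
    depth_of_field: float = 3000.0
    n_media: float = 1.337
    alpha: float = 0.18
    pixel_pitch: float = 150.0

    def __post_init__(self):
        lam = np.asarray(self.lambda_grid, dtype=float)
        object.__setattr__(self, "lambda_grid", lam)
        if lam.ndim != 1 or lam.size < 2 or not np.all(np.diff(lam) > 0):
            raise ValidationError("lambda_grid must be 1-D and strictly increasing")
        for name in ("coherence_xy", "depth_of_field", "pixel_pitch"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    @property
    def id(self) -> str:
        return (
            f"NA{self.na_illumination:g}/{self.na_collection:g}"
            f"-lam{self.lambda_grid[0]:g}:{self.lambda_grid[-1]:g}"
            f"-coh{self.coherence_xy:g}-dof{self.depth_of_field:g}"
        )


@dataclass
class DensityField:
    """A realization of the chromatin mass-density field rho(r).

    ``values`` is a stationary zero-mean 2-D array representing the
    projection of the density fluctuations through the depth of field;
    ``acf_truth`` records the autocorrelation model it realizes.
    """

    values: np.ndarray
    pixel_pitch: float
    acf_truth: ACFModel
    seed: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("density field must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("density field contains non-finite values")
        if self.pixel_pitch <= 0:
            raise ValidationError("pixel_pitch must be > 0")


@dataclass
class SpectralCube:
    """Reference-normalized reflectance cube ``(y, x, lambda)``."""

    data: np.ndarray
    lambda_grid: np.ndarray
    pixel_pitch: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("cube must be 3-D (y, x, lambda)")
        if self.data.shape[2] != self.lambda_grid.size:
            raise ValidationError(
                f"lambda axis length {self.data.shape[2]} != "
                f"lambda_grid length {self.lambda_grid.size}"
            )
        if self.pixel_pitch <= 0:
            raise ValidationError("pixel_pitch must be > 0")

    @property
    def shape_xy(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass
class SigmaMap:
    """Per-pixel standard deviation of the interference spectrum."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("sigma map must be 2-D")
        if np.any(self.values < 0):
            raise ValidationError("sigma must be non-negative")


@dataclass
class NucleusMask:
    """Boolean segmentation mask of a single nucleus."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValidationError("mask must be 2-D")

    @property
    def area_px(self) -> int:
        return int(self.values.sum())


@dataclass
class CalibrationTable:
    """Monotone forward map D -> sigma used for inversion.

    Built by :func:`cspws.processing.build_calibration`; ``sigma_of_D``
    must be strictly increasing over ``D_grid`` or construction fails.
    """

    D_grid: np.ndarray
    sigma_of_D: np.ndarray
    phi: float
    instrument: str = ""
    amplitude: float = 1.0

    def __post_init__(self):
        self.D_grid = np.asarray(self.D_grid, dtype=float)
        self.sigma_of_D = np.asarray(self.sigma_of_D, dtype=float)
        if self.D_grid.ndim != 1 or self.D_grid.size < 2:
            raise CalibrationError("D_grid must be 1-D with >= 2 points")
        if self.D_grid.shape != self.sigma_of_D.shape:
            raise CalibrationError("D_grid and sigma_of_D shapes differ")
        if not np.all(np.diff(self.D_grid) > 0):
            raise CalibrationError("D_grid must be strictly increasing")
        if not (self.D_grid[0] > 1.0 and self.D_grid[-1] <= 3.0):
            raise CalibrationError("D_grid must lie within (1, 3]")
        if not np.all(np.diff(self.sigma_of_D) > 0):
            raise CalibrationError(
                "sigma(D) is not strictly monotone for this instrument; "
                "review the D grid and coherence kernel"
            )

    def sigma(self, D) -> np.ndarray:
        """Forward-interpolate sigma at packing scaling D (must be in range)."""
        D = np.asarray(D, dtype=float)
        if np.any(D < self.D_grid[0] - 1e-12) or np.any(D > self.D_grid[-1] + 1e-12):
            raise CalibrationError(
                f"requested D outside calibrated range "
                f"[{self.D_grid[0]}, {self.D_grid[-1]}]"
            )
        return np.interp(D, self.D_grid, self.sigma_of_D)

    def invert(self, sigma) -> tuple[np.ndarray, np.ndarray]:
        """Monotone inverse sigma -> D.

        Values outside the table range clamp to the nearest grid end; the
        second return value flags clamped entries. No extrapolation.
        """
        sigma = np.asarray(sigma, dtype=float)
        clamped = (sigma < self.sigma_of_D[0]) | (sigma > self.sigma_of_D[-1])
        D = np.interp(sigma, self.sigma_of_D, self.D_grid)
        return D, clamped


@dataclass
class DMap:
    """Per-pixel packing scaling over a segmented nucleus.

    ``values`` is NaN outside the mask; ``clamped`` marks in-mask pixels
    whose sigma fell outside the calibration range (excluded from nuclear
    averages). ``pixel_window`` is the physical side of the coherence area
    each pixel's D integrates over.
    """

    values: np.ndarray
    mask: NucleusMask
    pixel_window: float = 458.0
    clamped: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.mask.values.shape:
            raise ValidationError("D map and mask shapes differ")
        if self.pixel_window <= 0:
            raise ValidationError("pixel_window must be > 0")
        if self.clamped is None:
            self.clamped = np.zeros_like(self.mask.values, dtype=bool)
        else:
            self.clamped = np.asarray(self.clamped, dtype=bool)

    @property
    def clamp_fraction(self) -> float:
        n = self.mask.area_px
        return float(self.clamped[self.mask.values].sum() / n) if n else 0.0


@dataclass(frozen=True)
class EllipseParams:
    """Elliptical nucleus morphology (pixel units, row/col convention)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float = 0.0  # radians, counter-clockwise


def _table1b_ages() -> dict[str, float]:
    return {
        "control": 57.4,
        "DA": 62.4,
        "NDA": 56.8,
        "AA": 64.9,
        "HNPCC": 55.0,
        "cancer": 65.8,
    }


def _table1b_rates() -> dict[str, dict[str, float]]:
    return {
        "female": {
            "control": 0.488, "DA": 0.357, "NDA": 0.45,
            "AA": 0.507, "HNPCC": 0.50, "cancer": 0.50,
        },
        "smoking": {
            "control": 0.167, "DA": 0.071, "NDA": 0.15,
            "AA": 0.178, "HNPCC": 0.15, "cancer": 0.20,
        },
        "drinking": {
            "control": 0.692, "DA": 0.643, "NDA": 0.80,
            "AA": 0.613, "HNPCC": 0.65, "cancer": 0.60,
        },
    }


def _default_history_probs() -> dict[str, dict[str, float]]:
    return {
        "control": {"none": 0.85, "low": 0.10, "high": 0.05},
        "DA": {"none": 0.60, "low": 0.30, "high": 0.10},
        "NDA": {"none": 0.50, "low": 0.35, "high": 0.15},
        "AA": {"none": 0.45, "low": 0.30, "high": 0.25},
        "HNPCC": {"none": 0.20, "low": 0.30, "high": 0.50},
        "cancer": {"none": 0.20, "low": 0.20, "high": 0.60},
    }


@dataclass
class CohortConfig:
    """Generator configuration for a synthetic screening cohort.

    Defaults reproduce the study structure the analysis assumes: the
    256-patient rectal-brushing cohort (135 control / 13 DA / 15 NDA /
    74 AA / 9 HNPCC / 10 cancer), >30 cells per patient, a monotone
    group-mean D ramp, and a small negative age slope of D (-0.008 per
    year). The absolute group means are placeholders (only ordering and
    separations are meaningful); the between-patient spread of 0.11 puts
    the AA-vs-control standardized effect near 0.8. ``history_d_offset``
    shifts a patient's D by their colonoscopy-history category,
    emulating the observed risk ladder (control < high-risk control <
    ... < high-risk advanced adenoma).
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "control": 135, "DA": 13, "NDA": 15, "AA": 74, "HNPCC": 9,
            "cancer": 10,
        }
    )
    group_mean_D: dict[str, float] = field(
        default_factory=lambda: {
            "control": 2.50, "DA": 2.53, "NDA": 2.56, "AA": 2.59,
            "HNPCC": 2.63, "cancer": 2.66,
        }
    )
    between_patient_sd: float = 0.11
    within_patient_sd: float = 0.15
    cells_per_patient: int = 31
    age_slope: float = -0.008
    age_mean: dict[str, float] = field(default_factory=_table1b_ages)
    age_sd: float = 8.0
    age_bounds: tuple[float, float] = (40.0, 90.0)
    demographic_rates: dict[str, dict[str, float]] = field(
        default_factory=_table1b_rates
    )
    history_probs: dict[str, dict[str, float]] = field(
        default_factory=_default_history_probs
    )
    history_d_offset: dict[str, float] = field(
        default_factory=lambda: {"none": 0.0, "low": 0.02, "high": 0.05}
    )
    seed: int = 0

    def __post_init__(self):
        if not self.group_sizes:
            raise ValidationError("group_sizes must not be empty")
        for g in self.group_sizes:
            if g not in DIAGNOSTIC_GROUPS:
                raise ValidationError(f"unknown diagnostic group '{g}'")
            if g not in self.group_mean_D:
                raise ValidationError(f"group '{g}' missing from group_mean_D")
        present = [g for g in DIAGNOSTIC_GROUPS if g in self.group_sizes]
        means = [self.group_mean_D[g] for g in present]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValidationError(
                "group_mean_D must increase along "
                "control < DA < NDA < AA < HNPCC < cancer"
            )
        if self.cells_per_patient <= 30:
            raise ValidationError(
                "cells_per_patient must exceed the 30-cell inclusion floor"
            )
        if self.between_patient_sd < 0 or self.within_patient_sd < 0:
            raise ValidationError("sd parameters must be >= 0")

    @property
    def n_patients(self) -> int:
        return sum(self.group_sizes.values())


@dataclass
class PatientRecord:
    """One patient: diagnosis, demographics, history, and per-cell D."""

    patient_id: str
    group: str
    age: float
    sex: str  # "F" or "M"
    smoking: bool
    drinking: bool
    history: str  # one of HISTORY_CATEGORIES
    cell_d_values: list[float] = field(default_factory=list)
    prior_cancer: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.group not in DIAGNOSTIC_GROUPS:
            raise ValidationError(f"unknown diagnostic group '{self.group}'")
        if self.history not in HISTORY_CATEGORIES:
            raise ValidationError(f"unknown history category '{self.history}'")
        if self.sex not in ("F", "M"):
            raise ValidationError("sex must be 'F' or 'M'")

    @property
    def mean_d(self) -> float:
        if not self.cell_d_values:
            raise ValidationError(f"{self.patient_id}: no cell D values")
        return float(np.mean(self.cell_d_values))

    @property
    def n_cells(self) -> int:
        return len(self.cell_d_values)


@dataclass
class Cohort:
    """A set of patient records plus the config that generated them."""

    patients: list[PatientRecord]
    config: CohortConfig | None = None

    def __post_init__(self):
        if not self.patients:
            raise ValidationError("cohort must contain at least one patient")

    def __len__(self) -> int:
        return len(self.patients)

    def groups(self) -> dict[str, list[PatientRecord]]:
        out: dict[str, list[PatientRecord]] = {}
        for p in self.patients:
            out.setdefault(p.group, []).append(p)
        return out

    def select(self, groups: Sequence[str]) -> list[PatientRecord]:
        groups = set(groups)
        return [p for p in self.patients if p.group in groups]

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "patient_id": p.patient_id,
                "group": p.group,
                "age": p.age,
                "sex": p.sex,
                "smoking": p.smoking,
                "drinking": p.drinking,
                "history": p.history,
                "prior_cancer": p.prior_cancer,
                "n_cells": p.n_cells,
                "mean_d": p.mean_d,
            }
            for p in self.patients
        ]
        return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Two-group contrast of patient-level mean D."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_diff: float  # mean(b) - mean(a); positive when case exceeds control
    p_value: float
    effect_size: float  # Cohen's d, pooled sd; sign matches mean_diff
    degenerate: bool = False

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValidationError("p_value outside [0, 1]")
        if self.n_a < 2 or self.n_b < 2:
            raise ValidationError("each group needs >= 2 patients")


@dataclass
class RocResult:
    """Split-sample ROC of a univariate score."""

    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    split_seed: int

    def __post_init__(self):
        for name in ("auc", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} outside [0, 1]")


@dataclass
class RiskModelParams:
    """Literature-derived inputs of the 5-year cumulative CRC risk model.

    None of these rates are intrinsic to this package: they come from
    surveillance literature and must be supplied by the user for any real
    analysis. The defaults are documented placeholders of plausible
    magnitude so the pipeline runs end to end.

    Attributes
    ----------
    annual_aa_to_crc
        Annual probability that an advanced adenoma progresses to CRC,
        keyed by ``(sex, stratum)`` with sex in {"F","M"} and stratum in
        {"under80", "over80"}.
    aa_r
        Cumulative probability of developing a future advanced adenoma
        over the horizon, per population category. Besides the plain
        history categories (no current lesion), the defaults carry
        ``current_aa_*`` entries for populations presenting with an
        advanced adenoma at baseline, whose recurrence risk is much
        higher and still graded by history.
    crc_m
        Cumulative probability of metachronous CRC (patients with prior
        cancer) over the horizon.
    horizon
        Model horizon in years (5).
    """

    annual_aa_to_crc: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("M", "under80"): 0.030,
            ("F", "under80"): 0.020,
            ("M", "over80"): 0.050,
            ("F", "over80"): 0.035,
        }
    )
    aa_r: dict[str, float] = field(
        default_factory=lambda: {
            "none": 0.06, "low": 0.17, "high": 0.35,
            "current_aa_none": 0.40, "current_aa_low": 0.55,
            "current_aa_high": 0.75,
        }
    )
    crc_m: float = 0.09
    horizon: float = 5.0

    def __post_init__(self):
        for k, v in self.annual_aa_to_crc.items():
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"annual_aa_to_crc[{k}] outside [0, 1]")
        for k, v in self.aa_r.items():
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"aa_r[{k}] outside [0, 1]")
        if not (0.0 <= self.crc_m <= 1.0):
            raise ValidationError("crc_m outside [0, 1]")
        if self.horizon <= 0:
            raise ValidationError("horizon must be > 0")


@dataclass
class RiskEstimate:
    """Population-level cumulative CRC risk with component breakdown."""

    population: str
    n_a: int
    n_c: int
    risk: float
    components: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_a + self.n_c < 1:
            raise ValidationError("population must contain >= 1 patient")
        if not (0.0 <= self.risk <= 1.0):
            raise ValidationError("risk outside [0, 1]")


@dataclass
class CVReport:
    """Per-fold metrics of the repeated stratified cross-validation."""

    folds: list[dict]
    k: int
    repeats: int
    seed: int
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.folds) != self.k * self.repeats:
            raise ValidationError(
                f"expected {self.k * self.repeats} folds, got {len(self.folds)}"
            )
        for f in self.folds:
            for m in ("auc", "sensitivity", "specificity"):
                if not (0.0 <= f[m] <= 1.0):
                    raise ValidationError(f"fold metric {m} outside [0, 1]")

    def _summary(self, key: str) -> tuple[float, float]:
        vals = np.array([f[key] for f in self.folds], dtype=float)
        return float(vals.mean()), float(vals.std(ddof=1))

    @property
    def auc_mean(self) -> float:
        return self._summary("auc")[0]

    @property
    def auc_sd(self) -> float:
        return self._summary("auc")[1]

    @property
    def se_mean(self) -> float:
        return self._summary("sensitivity")[0]

    @property
    def se_sd(self) -> float:
        return self._summary("sensitivity")[1]

    @property
    def sp_mean(self) -> float:
        return self._summary("specificity")[0]

    @property
    def sp_sd(self) -> float:
        return self._summary("specificity")[1]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "repeats": self.repeats,
            "seed": self.seed,
            "config": self.config,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "se_mean": self.se_mean,
            "se_sd": self.se_sd,
            "sp_mean": self.sp_mean,
            "sp_sd": self.sp_sd,
            "folds": [
                {
                    k: (list(v) if isinstance(v, (list, tuple)) else v)
                    for k, v in f.items()
                }
                for f in self.folds
            ],
        }
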