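"""Five-year cumulative colorectal-cancer risk model.

The model estimates the population-level probability of developing CRC
over a fixed horizon from surveillance-colonoscopy history::

    CRC_risk = (1 / (Na + Nc)) * [ AAr * sum_i AA_to_CRC_i  +  Nc * CRCm ]

where ``Na`` counts patients with no history or a history of adenoma,
``Nc`` counts patients with a history of cancer, ``AAr`` is the
cumulative probability of developing a future advanced adenoma (per
history category), ``AA_to_CRC_i`` is patient i's cumulative probability
of an advanced adenoma progressing to CRC (annual rate stratified by sex
and by age below/above 80, converted with ``1 - exp(-annual * t)``), and
``CRCm`` is the cumulative metachronous-CRC probability. ``AAr``
multiplies the sum, exactly as written.

The rate parameters come from surveillance literature and are config
inputs (see :class:`cspws.models.RiskModelParams`).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from cspws.errors import ValidationError
from cspws.models import Cohort, PatientRecord, RiskEstimate, RiskModelParams

#: Prior-colonoscopy finding codes and the history category they imply.
HISTORY_FINDING_MAP: dict[str, str] = {
    "none": "none",
    "hyperplastic_polyp": "none",
    "diminutive_adenoma": "low",
    "nonadvanced_adenoma": "low",
    "advanced_adenoma": "high",
    "many_adenomas": "high",
    "cancer": "high",
}

#: Category severity order used when multiple findings are present.
_SEVERITY = {"none": 0, "low": 1, "high": 2}


def cumulative_risk(annual_risk: float, time: float) -> float:
    """Convert an annual probability to a cumulative one: 1 - exp(-a*t)."""
    if annual_risk < 0 or time < 0:
        raise ValidationError("annual_risk and time must be >= 0")
    return 1.0 - math.exp(-annual_risk * time)


def assign_history_category(
    history,
    mapping: Mapping[str, str] = HISTORY_FINDING_MAP,
) -> str:
    """Map past-colonoscopy findings to {none, low, high} risk history.

    ``history`` is an iterable of finding codes (or an object with a
    ``findings`` attribute); the most severe implied category wins. An
    empty history is ``none``; an unknown code raises.
    """
    findings = getattr(history, "findings", history)
    category = "none"
    for code in findings:
        if code not in mapping:
            raise ValidationError(f"unknown finding code '{code}'")
        cat = mapping[code]
        if _SEVERITY[cat] > _SEVERITY[category]:
            category = cat
    return category


def patient_aa_to_crc(sex: str, age: float, params: RiskModelParams) -> float:
    """Cumulative AA->CRC probability for one patient's sex/age stratum."""
    stratum = "under80" if age < 80 else "over80"
    key = (sex, stratum)
    if key not in params.annual_aa_to_crc:
        raise ValidationError(f"no annual AA->CRC rate for stratum {key}")
    return cumulative_risk(params.annual_aa_to_crc[key], params.horizon)


def population_risk(
    n_a: int,
    n_c: int,
    per_patient_aa_to_crc: Sequence[float],
    params: RiskModelParams,
    history: str = "none",
    label: str = "",
) -> RiskEstimate:
    """Evaluate the population CRC-risk formula.

    Parameters
    ----------
    n_a, n_c
        Patients without / with a history of cancer.
    per_patient_aa_to_crc
        One cumulative AA->CRC probability per ``n_a`` patient.
    history
        History category selecting ``AAr`` from the params.
    """
    if n_a + n_c == 0:
        raise ValidationError("population must contain at least one patient")
    if len(per_patient_aa_to_crc) != n_a:
        raise ValidationError(
            f"expected {n_a} AA->CRC terms, got {len(per_patient_aa_to_crc)}"
        )
    if history not in params.aa_r:
        raise ValidationError(f"no AAr for history category '{history}'")
    aa_r = params.aa_r[history]
    adenoma_term = aa_r * float(np.sum(per_patient_aa_to_crc))
    cancer_term = n_c * params.crc_m
    risk = (adenoma_term + cancer_term) / (n_a + n_c)
    return RiskEstimate(
        population=label or history,
        n_a=n_a,
        n_c=n_c,
        risk=float(risk),
        components={
            "aa_r": aa_r,
            "adenoma_term": adenoma_term,
            "cancer_term": cancer_term,
            "crc_m": params.crc_m,
        },
    )


def cohort_population_risk(
    patients: Iterable[PatientRecord],
    params: RiskModelParams,
    history: str,
    label: str = "",
) -> RiskEstimate:
    """Population risk for a set of patients sharing a history category.

    Patients with a prior-cancer history contribute through the
    metachronous term (``Nc``); the rest through their sex/age-stratified
    AA->CRC term.
    """
    patients = list(patients)
    with_cancer = [p for p in patients if p.prior_cancer]
    without = [p for p in patients if not p.prior_cancer]
    terms = [patient_aa_to_crc(p.sex, p.age, params) for p in without]
    return population_risk(
        n_a=len(without),
        n_c=len(with_cancer),
        per_patient_aa_to_crc=terms,
        params=params,
        history=history,
        label=label,
    )


def cohort_group_risks(
    cohort: Cohort,
    params: RiskModelParams,
    populations: Sequence[tuple[str, Sequence[str], str]] | None = None,
) -> list[tuple[RiskEstimate, float]]:
    """Per-population risk alongside the population's mean rectal D.

    ``populations`` is a list of ``(label, diagnostic groups, history
    category[, aa_r key])``; the default follows the risk ladder the
    analysis plots — control and advanced-adenoma populations stratified
    by history, with the AA populations drawing their (much higher)
    future-AA probability from the ``current_aa_*`` parameter entries.
    """
    if populations is None:
        populations = [
            ("control_no_history", ("control",), "none", "none"),
            ("control_high_risk_history", ("control",), "high", "high"),
            ("AA_no_history", ("AA",), "none", "current_aa_none"),
            ("AA_low_risk_history", ("AA",), "low", "current_aa_low"),
            ("AA_high_risk_history", ("AA",), "high", "current_aa_high"),
        ]
    out = []
    for entry in populations:
        if len(entry) == 3:
            label, groups, history = entry
            aa_r_key = history
        else:
            label, groups, history, aa_r_key = entry
        members = [p for p in cohort.select(groups) if p.history == history]
        if not members:
            continue
        est = cohort_population_risk(members, params, aa_r_key, label=label)
        mean_d = float(np.mean([p.mean_d for p in members]))
        out.append((est, mean_d))
    return out


def risk_d_regression(
    group_mean_d: Sequence[float],
    group_risk: Sequence[float],
) -> tuple[float, float, float]:
    """OLS of population risk on population mean D.

    Returns ``(slope, intercept, r_squared)``; needs >= 3 populations
    with non-constant D.
    """
    d = np.asarray(group_mean_d, dtype=float)
    r = np.asarray(group_risk, dtype=float)
    if d.size < 3 or d.size != r.size:
        raise ValidationError("need >= 3 matched (D, risk) populations")
    if np.ptp(d) == 0:
        raise ValidationError("population mean D is constant")
    res = sps.linregress(d, r)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
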