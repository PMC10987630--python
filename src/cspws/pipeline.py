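"""Stage orchestration for the command-line pipeline.

A cohort lives in a directory::

    DIR/
      manifest.csv            patient-level table (group, demographics, mean D)
      cells.csv               per-cell ground-truth D
      patients/P0000.h5       optional imaged cells (cube + mask per cell)
      processed/cells_measured.csv    per-cell D re-estimated from images
      reports/stats.json, risk.json, cv.json

Stages are idempotent: each writes a ``<stage>.done.json`` marker holding
the config hash and seed; re-running with the same config skips the
stage unless forced or the marker's hash mismatches.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from cspws import io as cio
from cspws.errors import StageError, ValidationError
from cspws.models import (
    Cohort,
    CohortConfig,
    InstrumentModel,
    NucleusMask,
)


def _marker_path(out_dir: Path, stage: str) -> Path:
    return Path(out_dir) / f"{stage}.done.json"


def stage_done(out_dir, stage: str, cfg_hash: str) -> bool:
    p = _marker_path(Path(out_dir), stage)
    if not p.exists():
        return False
    try:
        return json.loads(p.read_text()).get("config_hash") == cfg_hash
    except json.JSONDecodeError:
        return False


def mark_stage(out_dir, stage: str, cfg_hash: str, seed: int) -> None:
    cio.write_report(
        _marker_path(Path(out_dir), stage),
        {"stage": stage, "config_hash": cfg_hash, "seed": seed},
    )


def cohort_config_from_dict(d: dict, seed: int | None = None) -> CohortConfig:
    kwargs = dict(d or {})
    if "age_bounds" in kwargs:
        kwargs["age_bounds"] = tuple(kwargs["age_bounds"])
    if seed is not None:
        kwargs["seed"] = seed
    return CohortConfig(**kwargs)


def run_simulate(
    out_dir,
    cohort_cfg: CohortConfig,
    images: dict | None = None,
) -> Cohort:
    """Generate a cohort; optionally render imaged cells per patient.

    ``images`` options: ``shape`` (pixels, default [64, 64]), ``noise_sd``
    (default 0), ``cells`` (number of cells to image per patient, default
    all), ``phi`` (default 0.35).
    """
    from cspws.processing import build_calibration
    from cspws.synthetic import generate_cohort, synthesize_nucleus_image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(cohort_cfg)
    cio.write_manifest(out_dir / "manifest.csv", cohort)
    cio.write_cell_table(out_dir / "cells.csv", cohort)

    if images:
        import h5py

        shape = tuple(images.get("shape", (64, 64)))
        noise_sd = float(images.get("noise_sd", 0.0))
        phi = float(images.get("phi", 0.35))
        inst = InstrumentModel()
        calib = build_calibration(inst, phi)
        pdir = out_dir / "patients"
        pdir.mkdir(exist_ok=True)
        for patient in cohort.patients:
            n_img = int(images.get("cells", patient.n_cells))
            with h5py.File(pdir / f"{patient.patient_id}.h5", "w") as f:
                f.attrs["lambda_grid"] = inst.lambda_grid
                f.attrs["pixel_pitch"] = inst.pixel_pitch
                f.attrs["phi"] = phi
                f.attrs["noise_sd"] = noise_sd
                for i, d_cell in enumerate(patient.cell_d_values[:n_img]):
                    d_cell = float(np.clip(d_cell, calib.D_grid[0], calib.D_grid[-1]))
                    nuc = synthesize_nucleus_image(
                        d_cell, phi, inst, shape=shape, calib=calib,
                        noise_sd=noise_sd,
                        seed=int((patient.seed + 7919 * i) % (2**31)),
                    )
                    g = f.create_group(f"cell_{i:03d}")
                    g.create_dataset("cube", data=nuc.cube.data.astype(np.float32))
                    g.create_dataset(
                        "mask", data=nuc.mask.values.astype(np.uint8)
                    )
                    g.attrs["d_truth"] = d_cell
    return cohort


def run_process(out_dir, phi: float = 0.35, detrend_order: int = 1,
                segment: bool = False) -> pd.DataFrame:
    """Re-estimate per-cell D from the imaged cubes.

    Uses the stored segmentation masks unless ``segment`` is set, in
    which case nuclei are re-segmented from the sigma map.
    """
    import h5py

    from cspws.processing import (
        build_calibration,
        compute_sigma_map,
        effective_noise_sigma,
        estimate_d_map,
        nuclear_average_d,
        segment_nuclei,
    )
    from cspws.models import SpectralCube

    out_dir = Path(out_dir)
    pdir = out_dir / "patients"
    if not pdir.exists():
        raise StageError("process", f"no imaged cells under {pdir}")
    inst = InstrumentModel()
    calib = build_calibration(inst, phi)
    rows = []
    for h5path in sorted(pdir.glob("*.h5")):
        with h5py.File(h5path, "r") as f:
            lam = np.asarray(f.attrs["lambda_grid"], dtype=float)
            pitch = float(f.attrs["pixel_pitch"])
            noise_sigma = effective_noise_sigma(
                float(f.attrs.get("noise_sd", 0.0)), lam.size, detrend_order
            )
            for name in sorted(f.keys()):
                g = f[name]
                cube = SpectralCube(
                    data=g["cube"][...].astype(float),
                    lambda_grid=lam,
                    pixel_pitch=pitch,
                )
                sigma = compute_sigma_map(cube, detrend_order=detrend_order)
                if segment:
                    masks = segment_nuclei(sigma.values, min_area=50)
                    if not masks:
                        continue
                    mask = masks[0]
                else:
                    mask = NucleusMask(values=g["mask"][...] > 0)
                dmap = estimate_d_map(sigma, calib, mask,
                                      noise_sigma=noise_sigma)
                rows.append(
                    {
                        "patient_id": h5path.stem,
                        "cell_index": int(name.split("_")[-1]),
                        "d": nuclear_average_d(dmap),
                        "d_truth": float(g.attrs.get("d_truth", np.nan)),
                        "clamp_fraction": dmap.clamp_fraction,
                    }
                )
    if not rows:
        raise StageError("process", "no cells processed")
    df = pd.DataFrame(rows)
    proc = out_dir / "processed"
    proc.mkdir(exist_ok=True)
    df.to_csv(proc / "cells_measured.csv", index=False, float_format="%.10g")
    return df


def _load_cohort(out_dir: Path, prefer_measured: bool = True) -> Cohort:
    manifest = out_dir / "manifest.csv"
    if not manifest.exists():
        raise StageError("stats", f"no manifest at {manifest}")
    measured = out_dir / "processed" / "cells_measured.csv"
    cells = measured if (prefer_measured and measured.exists()) \
        else out_dir / "cells.csv"
    return cio.read_cohort_tables(manifest, cells if cells.exists() else None)


def run_stats(out_dir, seed: int = 0, case_groups=("AA",),
              control_groups=("control",)) -> dict:
    """Cohort statistics report: contrasts, confounders, age trend, ROC."""
    from cspws.stats import (
        age_regression,
        ancova_confounders,
        compare_groups,
        univariate_roc,
    )

    out_dir = Path(out_dir)
    cohort = _load_cohort(out_dir)
    present = {p.group for p in cohort.patients}
    report: dict = {"n_patients": len(cohort)}

    comparisons = {}
    for g in sorted(present - {"control"}):
        try:
            c = comparisons[g] = dataclasses.asdict(
                compare_groups(cohort, "control", g)
            )
        except ValidationError:
            continue
    report["comparisons_vs_control"] = comparisons
    try:
        report["ancova"] = ancova_confounders(cohort).to_dict(orient="index")
    except ValidationError as exc:
        report["ancova"] = {"skipped": str(exc)}
    slope, intercept, r = age_regression(cohort)
    report["age_regression"] = {"slope": slope, "intercept": intercept, "r": r}
    try:
        roc = univariate_roc(cohort, list(case_groups), list(control_groups),
                             seed=seed)
        report["univariate_roc"] = dataclasses.asdict(roc)
    except ValidationError as exc:
        report["univariate_roc"] = {"skipped": str(exc)}
    cio.write_report(out_dir / "reports" / "stats.json", report)
    return report


def run_risk(out_dir, params=None) -> dict:
    """Population risks per (group, history) ladder + risk-vs-D regression."""
    from cspws.models import RiskModelParams
    from cspws.risk import cohort_group_risks, risk_d_regression

    out_dir = Path(out_dir)
    cohort = _load_cohort(out_dir)
    params = params or RiskModelParams()
    pairs = cohort_group_risks(cohort, params)
    report: dict = {
        "populations": [
            {
                "label": est.population,
                "n_a": est.n_a,
                "n_c": est.n_c,
                "risk": est.risk,
                "mean_d": mean_d,
            }
            for est, mean_d in pairs
        ]
    }
    if len(pairs) >= 3:
        slope, intercept, r2 = risk_d_regression(
            [m for _, m in pairs], [e.risk for e, _ in pairs]
        )
        report["regression"] = {
            "slope": slope, "intercept": intercept, "r_squared": r2
        }
    cio.write_report(out_dir / "reports" / "risk.json", report)
    return report


def run_classify(out_dir, seed: int = 0, options: dict | None = None) -> dict:
    """AI classification of imaged cells: control vs case patients."""
    import h5py

    from cspws.classifier import (
        ClassificationDataset,
        ClassifierConfig,
        RandomConvBackbone,
        extract_features,
        preprocess_dmap,
        repeated_stratified_cv,
    )
    from cspws.models import DMap
    from cspws.processing import (
        build_calibration,
        compute_sigma_map,
        effective_noise_sigma,
        estimate_d_map,
    )
    from cspws.models import SpectralCube

    options = options or {}
    out_dir = Path(out_dir)
    cohort = _load_cohort(out_dir, prefer_measured=False)
    case_groups = set(options.get("case_groups", ("AA",)))
    control_groups = set(options.get("control_groups", ("control",)))
    labels = {
        p.patient_id: 1 if p.group in case_groups else 0
        for p in cohort.patients
        if p.group in case_groups | control_groups
    }
    pdir = out_dir / "patients"
    if not pdir.exists():
        raise StageError("classify", f"no imaged cells under {pdir}")
    phi = float(options.get("phi", 0.35))
    inst = InstrumentModel()
    calib = build_calibration(inst, phi)
    backbone = RandomConvBackbone(
        out_dim=int(options.get("out_dim", 128)),
        seed=int(options.get("backbone_seed", 0)),
        channels=tuple(options.get("channels", (8, 16, 32, 32))),
    )
    size = int(options.get("input_size", 64))

    feats, pids = [], []
    for h5path in sorted(pdir.glob("*.h5")):
        pid = h5path.stem
        if pid not in labels:
            continue
        with h5py.File(h5path, "r") as f:
            lam = np.asarray(f.attrs["lambda_grid"], dtype=float)
            pitch = float(f.attrs["pixel_pitch"])
            noise_sigma = effective_noise_sigma(
                float(f.attrs.get("noise_sd", 0.0)), lam.size
            )
            for name in sorted(f.keys()):
                g = f[name]
                cube = SpectralCube(g["cube"][...].astype(float), lam, pitch)
                mask = NucleusMask(values=g["mask"][...] > 0)
                dmap = estimate_d_map(compute_sigma_map(cube), calib, mask,
                                      noise_sigma=noise_sigma)
                img = preprocess_dmap(dmap, out_size=(size, size))
                feats.append(extract_features(img, backbone))
                pids.append(pid)
    if not feats:
        raise StageError("classify", "no labeled imaged cells found")
    dataset = ClassificationDataset(np.stack(feats), np.array(pids), labels)
    config = ClassifierConfig(
        latent_dim=int(options.get("latent_dim", 40)),
        epochs=int(options.get("epochs", 50)),
    )
    report = repeated_stratified_cv(
        dataset,
        k=int(options.get("k", 4)),
        repeats=int(options.get("repeats", 5)),
        config=config,
        seed=seed,
    )
    payload = report.to_dict()
    payload["backbone"] = backbone.name
    cio.write_report(out_dir / "reports" / "cv.json", payload)
    return payload


def run_all(config: dict, force: bool = False) -> dict:
    """Execute simulate -> process -> stats -> risk -> classify.

    ``config`` keys: ``out`` (directory), ``seed``, ``cohort`` (CohortConfig
    fields), ``images``, ``processing``, ``stats``, ``risk``, ``classify``
    (per-stage options). Completed stages (matching config hash) are
    skipped unless ``force``. Returns a summary with per-stage status.
    """
    from cspws.models import RiskModelParams

    out_dir = Path(config["out"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    cfg_hash = cio.config_hash(config)
    summary: dict = {"out": str(out_dir), "seed": seed, "config_hash": cfg_hash,
                     "stages": {}}

    def _run(stage, fn):
        if not force and stage_done(out_dir, stage, cfg_hash):
            summary["stages"][stage] = "skipped"
            return
        try:
            fn()
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        mark_stage(out_dir, stage, cfg_hash, seed)
        summary["stages"][stage] = "completed"

    images = config.get("images")
    _run("simulate", lambda: run_simulate(
        out_dir, cohort_config_from_dict(config.get("cohort", {}), seed=seed),
        images=images,
    ))
    if images:
        proc = config.get("processing", {})
        _run("process", lambda: run_process(
            out_dir,
            phi=float(proc.get("phi", 0.35)),
            detrend_order=int(proc.get("detrend_order", 1)),
            segment=bool(proc.get("segment", False)),
        ))
    stats_opts = config.get("stats", {})
    _run("stats", lambda: run_stats(
        out_dir, seed=seed,
        case_groups=tuple(stats_opts.get("case_groups", ("AA",))),
        control_groups=tuple(stats_opts.get("control_groups", ("control",))),
    ))
    risk_opts = config.get("risk", {})
    params = None
    if risk_opts.get("params"):
        loaded = cio.load_yaml(risk_opts["params"])
        loaded["annual_aa_to_crc"] = {
            (k.split("/")[0], k.split("/")[1]): v
            for k, v in loaded["annual_aa_to_crc"].items()
        }
        params = RiskModelParams(**loaded)
    _run("risk", lambda: run_risk(out_dir, params=params))
    if images and config.get("classify") is not None:
        _run("classify", lambda: run_classify(
            out_dir, seed=seed, options=config.get("classify", {})
        ))
    cio.write_report(out_dir / "reports" / "pipeline.json", summary)
    return summary
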