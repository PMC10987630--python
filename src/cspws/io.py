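"""File formats: cubes (HDF5 / OME-TIFF), masks, manifests, configs, reports.

HDF5 is the default cube container (one file per patient keeps a
mini-cohort in a handful of files); OME-TIFF import/export is provided
for interoperability, with the wavelength grid carried in metadata in
both formats. Reports are written with sorted keys and repr-exact floats
so identical runs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from cspws.errors import CubeIOError
from cspws.models import Cohort, NucleusMask, SpectralCube


# ---------------------------------------------------------------------------
# Cubes
# ---------------------------------------------------------------------------

def write_cube(path, cube: SpectralCube) -> None:
    """Write a cube to ``.h5``/``.hdf5`` or ``.tif``/``.ome.tif``.

    Float32 data with the lambda grid and pixel pitch as metadata; the
    TIFF layout puts wavelength on the leading (plane) axis.
    """
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("cube", data=cube.data.astype(np.float32))
            ds.attrs["lambda_grid"] = cube.lambda_grid
            ds.attrs["pixel_pitch"] = cube.pixel_pitch
    elif suffix.endswith((".tif", ".tiff")):
        import tifffile

        meta = {
            "lambda_grid": [float(x) for x in cube.lambda_grid],
            "pixel_pitch": float(cube.pixel_pitch),
        }
        planes = np.moveaxis(cube.data.astype(np.float32), -1, 0)
        tifffile.imwrite(path, planes, description=json.dumps(meta))
    else:
        raise CubeIOError(f"unsupported cube format: {path}")


def read_cube(path) -> SpectralCube:
    """Read a cube written by :func:`write_cube` (lossless for float32)."""
    path = Path(path)
    if not path.exists():
        raise CubeIOError(f"no such cube file: {path}")
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".h5", ".hdf5")):
        import h5py

        try:
            with h5py.File(path, "r") as f:
                ds = f["cube"]
                if "lambda_grid" not in ds.attrs:
                    raise CubeIOError(f"missing lambda_grid metadata in {path}")
                return SpectralCube(
                    data=ds[...].astype(float),
                    lambda_grid=np.asarray(ds.attrs["lambda_grid"], dtype=float),
                    pixel_pitch=float(ds.attrs.get("pixel_pitch", 150.0)),
                )
        except OSError as exc:
            raise CubeIOError(f"cannot parse HDF5 cube {path}: {exc}") from exc
    if suffix.endswith((".tif", ".tiff")):
        import tifffile

        try:
            with tifffile.TiffFile(path) as tf:
                desc = tf.pages[0].description
                planes = tf.asarray()
        except Exception as exc:
            raise CubeIOError(f"cannot parse TIFF cube {path}: {exc}") from exc
        try:
            meta = json.loads(desc)
            lam = np.asarray(meta["lambda_grid"], dtype=float)
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise CubeIOError(f"missing lambda_grid metadata in {path}") from exc
        return SpectralCube(
            data=np.moveaxis(planes.astype(float), 0, -1),
            lambda_grid=lam,
            pixel_pitch=float(meta.get("pixel_pitch", 150.0)),
        )
    raise CubeIOError(f"unsupported cube format: {path}")


def write_mask(path, mask: NucleusMask) -> None:
    """Write a mask as single-channel 8-bit PNG or TIFF."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (mask.values.astype(np.uint8) * 255))


def read_mask(path) -> NucleusMask:
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise CubeIOError(f"no such mask file: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return NucleusMask(values=arr > 0)


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def write_manifest(path, cohort: Cohort) -> None:
    """Patient-level manifest CSV (UTF-8, comma, '.' decimal)."""
    df = cohort.to_frame()
    df.to_csv(Path(path), index=False, float_format="%.10g")


def write_cell_table(path, cohort: Cohort) -> None:
    """Long-format per-cell D table: patient_id, cell_index, d."""
    rows = [
        {"patient_id": p.patient_id, "cell_index": i, "d": d}
        for p in cohort.patients
        for i, d in enumerate(p.cell_d_values)
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False, float_format="%.10g")


def read_cohort_tables(manifest_path, cell_table_path=None) -> Cohort:
    """Rebuild a :class:`Cohort` from manifest (+ optional cell table)."""
    from cspws.models import PatientRecord

    df = pd.read_csv(manifest_path)
    cells: dict[str, list[float]] = {}
    if cell_table_path is not None:
        cdf = pd.read_csv(cell_table_path)
        for pid, grp in cdf.groupby("patient_id", sort=False):
            cells[str(pid)] = [float(x) for x in grp.sort_values("cell_index")["d"]]
    patients = []
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        vals = cells.get(pid, [float(row["mean_d"])])
        patients.append(
            PatientRecord(
                patient_id=pid,
                group=str(row["group"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                smoking=bool(row["smoking"]),
                drinking=bool(row["drinking"]),
                history=str(row["history"]),
                prior_cancer=bool(row.get("prior_cancer", False)),
                cell_d_values=vals,
            )
        )
    return Cohort(patients=patients)


# ---------------------------------------------------------------------------
# Configs and reports
# ---------------------------------------------------------------------------

def load_yaml(path) -> dict:
    import yaml

    with open(path) as f:
        return yaml.safe_load(f)


def dump_yaml(path, obj: dict) -> None:
    import yaml

    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=True)


def write_report(path, payload: dict) -> None:
    """Deterministic JSON report (sorted keys, repr floats, newline EOF)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        json.dump(payload, f, indent=2, sort_keys=True, default=_json_default)
        f.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def config_hash(obj: dict) -> str:
    """Stable short hash of a JSON-serializable config."""
    blob = json.dumps(obj, sort_keys=True, default=_json_default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
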