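"""Format adapters: NIfTI-1 volumes, tab-separated tables, YAML configs.

All tables are UTF-8 TSV with a header row; units are encoded in column
names (``K_per_min``, ``glucose_mM``, ``time_min``) and validated on
read.  Tables written by the pipeline carry a leading comment line with
the resolved configuration hash so outputs are traceable to their run.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .kinetics import PlasmaInputFunction
from .schedules import FrameSchedule

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_dynamic_image",
    "read_dynamic_image",
    "write_table",
    "read_table",
    "write_input_function",
    "read_input_function",
    "load_yaml",
    "save_yaml",
]


def write_nifti(path, array: np.ndarray, voxel_size: float = 1.0) -> None:
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine), str(path))


def read_nifti(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.dataobj, dtype=float), float(zooms[0])


def write_dynamic_image(path, dynamic: np.ndarray, schedule: FrameSchedule,
                        voxel_size: float = 1.0, timing_path=None) -> None:
    """4D dynamic volume plus its frame-timing sidecar TSV
    (columns start_min, end_min)."""
    if dynamic.ndim != 4 or dynamic.shape[-1] != schedule.n_frames:
        raise ValueError("dynamic image must be 4-D with one volume per frame")
    write_nifti(path, dynamic, voxel_size)
    timing_path = timing_path or Path(str(path)).with_suffix("").with_suffix(".timing.tsv")
    pd.DataFrame({"start_min": schedule.starts, "end_min": schedule.ends}).to_csv(
        timing_path, sep="\t", index=False, float_format="%.6f"
    )


def read_dynamic_image(path, timing_path=None) -> tuple[np.ndarray, FrameSchedule, float]:
    data, voxel = read_nifti(path)
    timing_path = timing_path or Path(str(path)).with_suffix("").with_suffix(".timing.tsv")
    timing = pd.read_csv(timing_path, sep="\t")
    if not {"start_min", "end_min"}.issubset(timing.columns):
        raise ValueError("timing sidecar needs columns start_min, end_min")
    if data.ndim != 4 or data.shape[-1] != len(timing):
        raise ValueError(
            f"frame-count mismatch: image has {data.shape[-1] if data.ndim == 4 else 'no'} "
            f"frames, timing file has {len(timing)} rows"
        )
    schedule = FrameSchedule(tuple(zip(timing["start_min"], timing["end_min"])))
    return data, schedule, voxel


def write_table(path, df: pd.DataFrame, config_hash: str | None = None,
                float_format: str = "%.6g") -> None:
    """TSV writer; a ``# config_hash=...`` comment line precedes the
    header when a hash is given."""
    buf = _io.StringIO()
    if config_hash:
        buf.write(f"# config_hash={config_hash}\n")
    df.to_csv(buf, sep="\t", index=False, float_format=float_format)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_table(path, required_columns: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(required_columns) - set(df.columns)
    if missing:
        raise ValueError(f"table {path} lacks required columns {sorted(missing)}")
    return df


def write_input_function(path, ipf: PlasmaInputFunction, config_hash: str | None = None) -> None:
    df = pd.DataFrame({"time_min": ipf.sample_times, "activity_kBq_per_mL": ipf.sample_values})
    write_table(path, df, config_hash=config_hash)


def read_input_function(path, cp_met: float | None = None) -> PlasmaInputFunction:
    df = read_table(path, required_columns=("time_min", "activity_kBq_per_mL"))
    return PlasmaInputFunction(
        df["time_min"].to_numpy(), df["activity_kBq_per_mL"].to_numpy(), cp_met=cp_met
    )


def load_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        out = yaml.safe_load(fh)
    return out or {}


def save_yaml(path, payload: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
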