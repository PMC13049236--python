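"""Readers and writers: NIfTI volume series, capnography text, tables.

Conventions: frame i is stamped at i * TR (no slice timing); missing-value
sentinel in maps is NaN; percentages are stored as percent (0.18 means
0.18 % BOLD/mmHg), noted in the NIfTI description field and JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .capnography import PetCO2Trace, RawCapnoTrace
from .cvr_mapping import CVRMap
from .signal_prep import InterleavedSeries, make_labels


class GridMismatchError(ValueError):
    pass


def check_grid(shape_a: tuple, shape_b: tuple, name_a: str, name_b: str) -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise GridMismatchError(
            f"grid mismatch: {name_a} has shape {tuple(shape_a)} but "
            f"{name_b} has shape {tuple(shape_b)}"
        )


# -- capnography -------------------------------------------------------------


def read_capno(path: str | Path, sampling_rate: float | None = None) -> RawCapnoTrace:
    """Delimited text: two columns (time s, CO2 mmHg) or one column + rate."""
    data = np.loadtxt(path)
    if data.ndim == 2 and data.shape[1] >= 2:
        t, v = data[:, 0], data[:, 1]
        dt = np.diff(t)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-3):
            raise ValueError("capnography time column is not uniformly sampled")
        return RawCapnoTrace(sampling_interval=float(dt[0]), values=v)
    if sampling_rate is None:
        raise ValueError("single-column capnography requires a sampling_rate")
    return RawCapnoTrace(sampling_interval=1.0 / sampling_rate, values=data.ravel())


def write_capno(trace: RawCapnoTrace, path: str | Path) -> None:
    np.savetxt(
        path,
        np.column_stack([trace.times, trace.values]),
        fmt="%.6f",
        header="time_s co2_mmhg",
    )


def write_petco2(trace: PetCO2Trace, path: str | Path, extras: dict | None = None) -> None:
    """One value per fMRI frame + JSON sidecar with rest level etc."""
    path = Path(path)
    np.savetxt(path, trace.values, fmt="%.6f")
    meta = {
        "tr": float(trace.frame_times[1] - trace.frame_times[0]),
        "n_frames": int(trace.values.size),
        "is_filtered": bool(trace.is_filtered),
        "rest_level_mmhg": float(trace.rest_level),
    }
    meta.update(extras or {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_petco2(path: str | Path) -> PetCO2Trace:
    path = Path(path)
    values = np.loadtxt(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    n = values.size
    return PetCO2Trace(
        frame_times=np.arange(n) * meta["tr"],
        values=values,
        is_filtered=meta.get("is_filtered", False),
        rest_level=meta.get("rest_level_mmhg", float("nan")),
    )


# -- 4D series ---------------------------------------------------------------


def write_series(series: InterleavedSeries, path: str | Path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(series.volumes.astype(np.float32), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, series.tr))
    img.header["descrip"] = f"{series.weighting} interleaved tag/control".encode()
    nib.save(img, path)
    order = "tag_first" if series.frame_labels[0] == "tag" else "control_first"
    sidecar = {"tr": series.tr, "weighting": series.weighting, "frame_order": order}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def read_series(path: str | Path, weighting: str | None = None) -> InterleavedSeries:
    """4D NIfTI + JSON sidecar (frame order, weighting, TR fallback)."""
    path = Path(path)
    img = nib.load(path)
    vols = np.asarray(img.dataobj, dtype=float)
    if vols.ndim != 4:
        raise ValueError(f"{path} is not a 4D series")
    sidecar = {}
    sc = _sidecar_path(path)
    if sc.exists():
        sidecar = json.loads(sc.read_text())
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr <= 0:
        tr = float(sidecar.get("tr", 0.0))
    if tr <= 0:
        raise ValueError(f"cannot determine TR for {path}")
    w = weighting or sidecar.get("weighting")
    if w is None:
        raise ValueError(f"weighting not given and absent from sidecar of {path}")
    labels = make_labels(vols.shape[-1], sidecar.get("frame_order", "tag_first"))
    return InterleavedSeries(volumes=vols, frame_labels=labels, tr=tr, weighting=w)


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(Path(path)).dataobj) > 0.5


def read_labels(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(Path(path)).dataobj).astype(int)


def write_volume(data: np.ndarray, path: str | Path, description: str = "") -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine=np.eye(4))
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, Path(path))


# -- CVR maps ----------------------------------------------------------------


def write_map(cvr_map: CVRMap, out_dir: str | Path, prefix: str = "") -> dict:
    """Write cvr_<w>, z_<w>, lag_<w> NIfTIs; returns the path dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    w = cvr_map.weighting
    paths = {}
    units = {"cvr": "% signal per mmHg PetCO2", "z": "beta/SE", "lag": "seconds"}
    for kind, data in (("cvr", cvr_map.beta), ("z", cvr_map.z), ("lag", cvr_map.lag)):
        p = out_dir / f"{prefix}{kind}_{w}.nii.gz"
        write_volume(data, p, units[kind])
        paths[kind] = p
    return paths


def read_map(out_dir: str | Path, weighting: str, prefix: str = "") -> CVRMap:
    out_dir = Path(out_dir)

    def _load(kind: str) -> np.ndarray:
        return np.asarray(
            nib.load(out_dir / f"{prefix}{kind}_{weighting}.nii.gz").dataobj,
            dtype=float,
        )

    return CVRMap(
        beta=_load("cvr"), z=_load("z"), lag=_load("lag"), weighting=weighting
    )


# -- tables ------------------------------------------------------------------


def read_roi_table(path: str | Path, label_image: np.ndarray | None = None) -> dict:
    """TSV with columns roi_id, name, venous_density -> {roi_id: density}.

    With a label image given, every nonzero label must have an entry.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"roi_id", "venous_density"}
    if not required <= set(df.columns):
        raise ValueError(f"ROI table must have columns {sorted(required)}")
    table = dict(zip(df["roi_id"].astype(int), df["venous_density"].astype(float)))
    if label_image is not None:
        ids = {int(i) for i in np.unique(label_image)} - {0}
        missing = sorted(ids - set(table))
        if missing:
            raise ValueError(f"ROI table missing ids present in label image: {missing}")
    return table


def write_roi_table(table: dict, path: str | Path, names: dict | None = None) -> None:
    rows = [
        {"roi_id": k, "name": (names or {}).get(k, f"roi{k:02d}"), "venous_density": v}
        for k, v in sorted(table.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
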