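"""File formats: NIfTI image series, CSV traces/registrations/rankings, JSON.

All artifacts round-trip: write followed by read restores the object. CSV
headers are fixed and validated on read so malformed files fail with the
offending field named.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .evaluation import EvalReport
from .selection import Ranking
from .tracking import ImageVolume, RegistrationRecord, SliceWindow, VolumeTrace

__all__ = [
    "write_image", "read_image", "write_series", "read_series",
    "write_registrations", "read_registrations",
    "write_annotation", "read_annotation",
    "write_trace", "read_trace",
    "write_ranking", "write_reports",
]

REG_COLUMNS = ["fraction", "dx_mm", "dy_mm", "dz_mm"]
TRACE_COLUMNS = ["fraction", "volume_mm3", "delta_v_pct", "qc_flag"]


def write_image(img: ImageVolume, path: str | Path) -> None:
    affine = np.diag([img.pixel_mm, img.pixel_mm, img.slice_mm, 1.0])
    affine[2, 3] = img.origin_mm
    # store as (x, y, z) per NIfTI convention
    nib.save(nib.Nifti1Image(np.ascontiguousarray(img.intensities.T), affine),
             str(path))


def read_image(path: str | Path) -> ImageVolume:
    nii = nib.load(str(path))
    zooms = nii.header.get_zooms()
    data = np.asarray(nii.dataobj).T  # back to (slice, row, col)
    return ImageVolume(intensities=data, pixel_mm=float(zooms[0]),
                       slice_mm=float(zooms[2]),
                       origin_mm=float(nii.affine[2, 3]))


def write_series(images: list[ImageVolume], directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(images, start=1):
        p = directory / f"fraction_{i:03d}.nii.gz"
        write_image(img, p)
        paths.append(p)
    return paths


def read_series(directory: str | Path) -> list[ImageVolume]:
    paths = sorted(Path(directory).glob("fraction_*.nii.gz"))
    if not paths:
        raise FileNotFoundError(f"no fraction_*.nii.gz files in {directory}")
    return [read_image(p) for p in paths]


def write_registrations(records: list[RegistrationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"fraction": r.fraction, "dx_mm": r.shift_mm[0],
          "dy_mm": r.shift_mm[1], "dz_mm": r.shift_mm[2]} for r in records]
    ).to_csv(path, index=False, float_format="%.17g")


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df[required].isna().any().any():
        bad = int(df[required].isna().any(axis=1).idxmax()) + 2  # header = line 1
        raise ValueError(f"{path}: malformed/empty field near line {bad}")


def read_registrations(path: str | Path) -> list[RegistrationRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, REG_COLUMNS, path)
    return [RegistrationRecord(fraction=int(r.fraction),
                               shift_mm=(float(r.dx_mm), float(r.dy_mm),
                                         float(r.dz_mm)))
            for r in df.itertuples()]


def write_annotation(window: SliceWindow, path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {"c1_slice_mm": window.c1_mm, "c5_slice_mm": window.c5_mm}))


def read_annotation(path: str | Path) -> SliceWindow:
    data = json.loads(Path(path).read_text())
    try:
        return SliceWindow(c1_mm=float(data["c1_slice_mm"]),
                           c5_mm=float(data["c5_slice_mm"]))
    except KeyError as exc:
        raise ValueError(f"{path}: missing annotation field {exc}") from exc


def write_trace(trace: VolumeTrace, path: str | Path) -> None:
    flags = set(trace.qc_flags)
    pd.DataFrame({
        "fraction": np.arange(1, trace.n_fractions + 1),
        "volume_mm3": trace.volumes_mm3,
        "delta_v_pct": trace.delta_v_pct,
        "qc_flag": [int(f in flags) for f in range(1, trace.n_fractions + 1)],
    }).to_csv(path, index=False, float_format="%.17g")


def read_trace(path: str | Path, patient_id: str | None = None) -> VolumeTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRACE_COLUMNS, path)
    return VolumeTrace(
        patient_id=patient_id or Path(path).stem,
        volumes_mm3=df["volume_mm3"].to_numpy(),
        delta_v_pct=df["delta_v_pct"].to_numpy(),
        qc_flags=[int(f) for f in df.loc[df["qc_flag"] == 1, "fraction"]],
    )


def write_icc_report(icc: dict[str, float], robust: list[str],
                     path: str | Path) -> None:
    pd.DataFrame({
        "feature": list(icc),
        "icc": [icc[f] for f in icc],
        "robust": [int(f in set(robust)) for f in icc],
    }).to_csv(path, index=False, float_format="%.17g")


def read_icc_report(path: str | Path) -> tuple[dict[str, float], list[str]]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["feature", "icc", "robust"], path)
    icc = dict(zip(df["feature"], df["icc"]))
    return icc, list(df.loc[df["robust"] == 1, "feature"])


def write_ranking(ranking: Ranking, path: str | Path) -> None:
    pd.DataFrame({
        "rank": np.arange(1, len(ranking.features) + 1),
        "feature": ranking.features,
        "score": ranking.scores,
        "method": ranking.method,
    }).to_csv(path, index=False)


def write_reports(reports: list[EvalReport], path: str | Path) -> None:
    payload = []
    for r in reports:
        entry = r.summary()
        entry["folds"] = [
            {k: v for k, v in fm.items() if k != "features"} | {
                "features": list(fm["features"])}
            for fm in r.fold_metrics]
        payload.append(entry)
    Path(path).write_text(json.dumps(payload, indent=1))
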