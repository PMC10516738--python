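"""Per-fraction head-and-neck body-volume tracking.

Given a longitudinal image series, the couch-shift registration records and a
planning-image annotation of the C1 and C5 spinous-process levels, this module
computes the body volume between C1 and C5 for every treatment fraction, the
percent volume change relative to fraction 1 (dV), quality-control flags for
implausible jumps between successive fractions, and the final reduction /
non-reduction label used as the adaptive-replanning surrogate endpoint.

Conventions
-----------
* Axial positions are in mm.  ``origin_mm`` is the planning-frame position of
  the start of image slice 0 before any couch shift; a couch shift moves the
  patient inside the image, so a planning-frame position ``z`` maps to image
  position ``z + dz``.
* The slice window is half-open ``[c1, c5)``; boundary slices contribute
  pro-rata thickness to the volume.
* dV is SIGNED: reductions are negative, and the classification rule is
  "mean dV over three consecutive fractions <= -10%".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "ImageVolume",
    "RegistrationRecord",
    "SliceWindow",
    "VolumeTrace",
    "ReductionLabel",
    "locate_slice_window",
    "segment_body",
    "compute_volume",
    "compute_delta_v",
    "qc_successive_jump",
    "classify_reduction",
    "min3_summary",
    "track_series",
]


class WindowOutOfRangeError(ValueError):
    """The C1-C5 window does not fit inside the scanned axial range."""


class EmptyMaskError(ValueError):
    """Thresholding produced no foreground (threshold failure)."""


@dataclass
class ImageVolume:
    """One fraction's 3-D image: intensities indexed (slice, row, col)."""

    intensities: np.ndarray
    pixel_mm: float = 1.0
    slice_mm: float = 3.0
    origin_mm: float = 0.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 3-D grid")
        if self.pixel_mm <= 0 or self.slice_mm <= 0:
            raise ValueError("voxel spacings must be positive")

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    @property
    def extent_mm(self) -> float:
        return self.n_slices * self.slice_mm


@dataclass(frozen=True)
class RegistrationRecord:
    """Couch translation (dx, dy, dz) in mm stored at image-match time."""

    fraction: int
    shift_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.shift_mm)):
            raise ValueError("registration shifts must be finite")


@dataclass(frozen=True)
class SliceWindow:
    """Planning-frame axial positions of the C1 and C5 spinous-process levels."""

    c1_mm: float
    c5_mm: float

    def __post_init__(self) -> None:
        if not self.c1_mm < self.c5_mm:
            raise ValueError("C1 must lie above C5 after orientation normalization")


@dataclass
class VolumeTrace:
    """Per-fraction volumes and signed percent changes for one patient."""

    patient_id: str
    volumes_mm3: np.ndarray
    delta_v_pct: np.ndarray = field(default=None)  # type: ignore[assignment]
    qc_flags: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.volumes_mm3 = np.asarray(self.volumes_mm3, dtype=float)
        if self.volumes_mm3.ndim != 1 or len(self.volumes_mm3) == 0:
            raise ValueError("need at least one fraction volume")
        if np.any(self.volumes_mm3 <= 0):
            raise ValueError("fraction volumes must be positive")
        if self.delta_v_pct is None:
            self.delta_v_pct = compute_delta_v(self.volumes_mm3, self.volumes_mm3[0])
        self.delta_v_pct = np.asarray(self.delta_v_pct, dtype=float)
        if len(self.delta_v_pct) != len(self.volumes_mm3):
            raise ValueError("dV series must align with the volume series")

    @property
    def n_fractions(self) -> int:
        return len(self.volumes_mm3)


@dataclass(frozen=True)
class ReductionLabel:
    """Outcome of the three-consecutive-fraction reduction rule."""

    group: str  # "reduction" | "non_reduction"
    trigger_fraction: int | None
    min3_mean: float

    def __post_init__(self) -> None:
        if self.group not in ("reduction", "non_reduction"):
            raise ValueError("group must be reduction or non_reduction")
        if (self.group == "reduction") != (self.trigger_fraction is not None):
            raise ValueError("trigger_fraction present iff group is reduction")


def locate_slice_window(window: SliceWindow, reg: RegistrationRecord,
                        img: ImageVolume) -> tuple[float, float]:
    """Map the planning-frame C1/C5 window into one fraction's image.

    Only the axial shift component moves the window.  Positions are quantized
    to 0.01 mm (sub-slice interpolation granularity); the window length is
    preserved exactly.  Raises :class:`WindowOutOfRangeError` when the shifted
    window leaves the scanned range — a lack-of-range fraction must be
    signalled, not guessed.
    """
    dz = reg.shift_mm[2]
    c1 = round((window.c1_mm + dz - img.origin_mm) * 100.0) / 100.0
    c5 = c1 + round((window.c5_mm - window.c1_mm) * 100.0) / 100.0
    if c1 < 0.0 or c5 > img.extent_mm:
        raise WindowOutOfRangeError(
            f"window [{c1:.2f}, {c5:.2f}) mm outside scanned range "
            f"[0, {img.extent_mm:.2f}) at fraction {reg.fraction}")
    return c1, c5


def _window_slices(img: ImageVolume, window_mm: tuple[float, float]
                   ) -> tuple[int, int, np.ndarray]:
    """Slice index range [k0, k1) covering the window plus pro-rata weights."""
    t = img.slice_mm
    z0, z1 = window_mm
    k0 = int(np.floor(z0 / t))
    k1 = int(np.ceil(z1 / t))
    k0 = max(k0, 0)
    k1 = min(k1, img.n_slices)
    if k1 <= k0:
        raise WindowOutOfRangeError("slice window covers no slices")
    lo = np.arange(k0, k1) * t
    weights = (np.minimum(lo + t, z1) - np.maximum(lo, z0)) / t
    return k0, k1, np.clip(weights, 0.0, 1.0)


def segment_body(img: ImageVolume, window_mm: tuple[float, float],
                 crop_box: tuple[int, int, int, int],
                 threshold: float | str = "auto") -> np.ndarray:
    """Binarize the body contour inside the crop box and slice window.

    The crop box ``(x0, x1, y0, y1)`` excludes the treatment couch and
    immobilization hardware.  Intensities are thresholded (Otsu on the cropped
    window when ``threshold="auto"``), holes are filled per axial slice, one
    3-D binary closing with an in-plane 3x3 structuring element smooths the
    contour, and only the largest connected component is kept so stray bright
    voxels cannot inflate the volume.  Internal cavities are filled so they do
    not underestimate the body volume.
    """
    x0, x1, y0, y1 = crop_box
    if not (0 <= x0 < x1 <= img.intensities.shape[2]
            and 0 <= y0 < y1 <= img.intensities.shape[1]):
        raise ValueError("crop box must lie inside the image grid")
    k0, k1, _ = _window_slices(img, window_mm)

    sub = img.intensities[k0:k1, y0:y1, x0:x1]
    if threshold == "auto":
        thr = float(threshold_otsu(sub))
    else:
        thr = float(threshold)
    binary = sub > thr
    if not binary.any():
        raise EmptyMaskError(f"no voxels above threshold {thr:.1f}")

    filled = np.empty_like(binary)
    for i in range(binary.shape[0]):
        filled[i] = ndimage.binary_fill_holes(binary[i])
    closing_structure = np.ones((1, 3, 3), dtype=bool)
    filled = ndimage.binary_closing(filled, structure=closing_structure)
    # closing can re-open thin slice-wise cavities at the border; refill
    for i in range(filled.shape[0]):
        filled[i] = ndimage.binary_fill_holes(filled[i])

    labels, n = ndimage.label(filled)
    if n == 0:
        raise EmptyMaskError("morphology removed all foreground")
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        filled = labels == keep

    mask = np.zeros(img.intensities.shape, dtype=bool)
    mask[k0:k1, y0:y1, x0:x1] = filled
    return mask


def compute_volume(mask: np.ndarray, pixel_mm: float, slice_mm: float) -> float:
    """Volume in mm**3 = voxel count x pixel_mm**2 x slice_mm."""
    mask = np.asarray(mask)
    count = int(mask.sum())
    if count == 0:
        raise EmptyMaskError("cannot compute the volume of an empty mask")
    return count * pixel_mm**2 * slice_mm


def _windowed_volume(mask: np.ndarray, img: ImageVolume,
                     window_mm: tuple[float, float]) -> float:
    """Mask volume with boundary slices weighted by their in-window fraction."""
    k0, k1, weights = _window_slices(img, window_mm)
    counts = mask[k0:k1].sum(axis=(1, 2))
    vol = float(np.dot(counts, weights)) * img.pixel_mm**2 * img.slice_mm
    if vol <= 0:
        raise EmptyMaskError("empty mask inside the slice window")
    return vol


def compute_delta_v(v_n, v_1st: float):
    """Signed percent volume change (V_n - V_1st) / V_1st * 100.

    Reductions are negative; the classification rule reads "dV < -10%".
    Accepts a scalar or an array of fraction volumes.
    """
    if v_1st <= 0:
        raise ValueError("first-fraction volume must be positive")
    return (np.asarray(v_n, dtype=float) - v_1st) / v_1st * 100.0


def qc_successive_jump(trace: VolumeTrace, jump_threshold: float = 5.0) -> list[int]:
    """Fractions (1-based) whose dV step from the previous fraction exceeds 5.

    A jump of more than 5 percentage points between successive fractions marks
    a suspect binarization (e.g. immobilization hardware leaking into the
    mask); flags are advisory and feed the re-threshold repair path.
    """
    if trace.n_fractions < 2:
        raise ValueError("successive-jump QC needs at least two fractions")
    steps = np.abs(np.diff(trace.delta_v_pct))
    return [int(i) + 2 for i in np.nonzero(steps > jump_threshold)[0]]


def classify_reduction(trace: VolumeTrace, threshold: float = -10.0,
                       window: int = 3, rule: str = "mean") -> ReductionLabel:
    """Apply the reduction / non-reduction rule to one dV trace.

    A patient is labeled ``reduction`` when some run of ``window`` consecutive
    fractions has mean dV <= ``threshold`` (averaging suppresses single-fraction
    measurement noise).  The reported trigger fraction is the middle fraction
    of the first qualifying run, so a run over fractions 24-26 reports 25.
    ``rule="all"`` switches to the stricter variant requiring every fraction in
    the run to cross the threshold individually.  ``min3_mean`` is the mean of
    the three most negative dV values regardless of group.
    """
    if rule not in ("mean", "all"):
        raise ValueError("rule must be 'mean' or 'all'")
    dv = trace.delta_v_pct
    n = len(dv)
    if n < window:
        raise ValueError(f"trace has {n} fractions; rule needs {window}")

    trigger = None
    for start in range(n - window + 1):
        run = dv[start:start + window]
        hit = run.mean() <= threshold if rule == "mean" else np.all(run <= threshold)
        if hit:
            trigger = start + window // 2 + 1  # 1-based middle fraction
            break

    min3 = float(np.mean(np.sort(dv)[:min(3, n)]))
    group = "reduction" if trigger is not None else "non_reduction"
    return ReductionLabel(group=group, trigger_fraction=trigger, min3_mean=min3)


def min3_summary(traces: list[VolumeTrace], threshold: float = -10.0,
                 window: int = 3) -> dict:
    """Cohort median and range of the per-patient min3 mean, by label group.

    The per-patient statistic is the mean of the three most negative dV values;
    the cohort summary is reported for all cases and separately for the
    reduction and non-reduction groups.
    """
    per_patient = []
    for trace in traces:
        if trace.n_fractions < 3:
            raise ValueError(f"trace {trace.patient_id} has fewer than 3 fractions")
        label = classify_reduction(trace, threshold=threshold, window=window)
        per_patient.append((label.group, label.min3_mean))

    def _stats(values: list[float]) -> dict:
        if not values:
            return {"n": 0, "median": None, "min": None, "max": None}
        arr = np.asarray(values)
        return {"n": len(arr), "median": float(np.median(arr)),
                "min": float(arr.min()), "max": float(arr.max())}

    return {
        "all": _stats([v for _, v in per_patient]),
        "reduction": _stats([v for g, v in per_patient if g == "reduction"]),
        "non_reduction": _stats([v for g, v in per_patient if g == "non_reduction"]),
    }


def _repair_candidates(img: ImageVolume, window_mm: tuple[float, float],
                       crop_box: tuple[int, int, int, int]) -> list[float]:
    """Threshold candidates for the QC repair path: Otsu, fixed fallback, +/-10%."""
    x0, x1, y0, y1 = crop_box
    k0, k1, _ = _window_slices(img, window_mm)
    sub = img.intensities[k0:k1, y0:y1, x0:x1]
    otsu = float(threshold_otsu(sub))
    lo, hi = np.percentile(sub, [1, 99])
    fallback = float(0.5 * (lo + hi))
    return [otsu, fallback, otsu * 0.9, otsu * 1.1]


def track_series(
    images: list[ImageVolume],
    records: list[RegistrationRecord],
    window: SliceWindow,
    crop_box: tuple[int, int, int, int],
    threshold: float | str = "auto",
    threshold_overrides: dict[int, float] | None = None,
    qc_jump: float = 5.0,
    patient_id: str = "patient",
    log: list | None = None,
) -> VolumeTrace:
    """Run the full per-patient tracking workflow.

    For every fraction: map the C1/C5 window through the recorded couch shift,
    segment the body, and integrate the windowed volume.  The resulting dV
    series is screened by the successive-jump QC; flagged fractions are
    re-segmented with alternative thresholds (Otsu recomputed, a fixed
    mid-intensity fallback, then +/-10% perturbations), keeping the candidate
    that best removes the jump, after which dV is recalculated for all
    fractions.  ``threshold_overrides`` forces a specific threshold at given
    fractions before QC (used to exercise the repair path).
    """
    if len(images) != len(records):
        raise ValueError("one registration record is required per image")
    overrides = threshold_overrides or {}
    events = log if log is not None else []

    windows_mm = []
    volumes = np.empty(len(images))
    for i, (img, rec) in enumerate(zip(images, records)):
        win = locate_slice_window(window, rec, img)
        windows_mm.append(win)
        thr = overrides.get(rec.fraction, threshold)
        try:
            mask = segment_body(img, win, crop_box, threshold=thr)
            volumes[i] = _windowed_volume(mask, img, win)
        except EmptyMaskError:
            # threshold failure itself triggers the re-threshold path
            for cand in _repair_candidates(img, win, crop_box):
                try:
                    mask = segment_body(img, win, crop_box, threshold=cand)
                    volumes[i] = _windowed_volume(mask, img, win)
                except EmptyMaskError:
                    continue
                events.append({"event": "re_threshold", "patient": patient_id,
                               "fraction": rec.fraction,
                               "volume_mm3": float(volumes[i])})
                break
            else:
                raise

    trace = VolumeTrace(patient_id=patient_id, volumes_mm3=volumes)
    if len(images) >= 2:
        flags = qc_successive_jump(trace, jump_threshold=qc_jump)
        for frac in flags:
            i = frac - 1
            img, win = images[i], windows_mm[i]
            best_vol, best_jump = volumes[i], _local_jump(volumes, i)
            for cand in _repair_candidates(img, win, crop_box):
                try:
                    mask = segment_body(img, win, crop_box, threshold=cand)
                    vol = _windowed_volume(mask, img, win)
                except EmptyMaskError:
                    continue
                trial = volumes.copy()
                trial[i] = vol
                jump = _local_jump(trial, i)
                if jump < best_jump:
                    best_vol, best_jump = vol, jump
            if best_vol != volumes[i]:
                events.append({"event": "re_threshold", "patient": patient_id,
                               "fraction": frac, "volume_mm3": float(best_vol)})
            volumes[i] = best_vol
        # dV recalculated for all fractions after any repair
        trace = VolumeTrace(patient_id=patient_id, volumes_mm3=volumes,
                            qc_flags=flags)
        for frac in flags:
            events.append({"event": "qc_flag", "patient": patient_id,
                           "fraction": frac})
    return trace


def _local_jump(volumes: np.ndarray, i: int) -> float:
    """Worst dV step adjacent to fraction index i (repair objective)."""
    dv = compute_delta_v(volumes, volumes[0])
    steps = []
    if i >= 1:
        steps.append(abs(dv[i] - dv[i - 1]))
    if i + 1 < len(dv):
        steps.append(abs(dv[i + 1] - dv[i]))
    return max(steps) if steps else 0.0
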