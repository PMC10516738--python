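"""Feature-level metrics: ICC robustness, GLCM texture (IMC1), DVH parameters.

Radiomic features are only trusted when they survive contour perturbation, so
robustness is scored with the two-way mixed-effects, absolute-agreement,
single-measure intraclass correlation (McGraw & Wong Case 3A) across repeated
segmentations, and features with ICC <= 0.7 are dropped before any selection.
The one texture feature implemented natively is the first informational
measure of correlation (IMC1), an entropy-based gray-level co-occurrence
statistic in [-1, 0] where values nearer -1 indicate greater textural
heterogeneity.  Dose-volume-histogram Dx% parameters summarize planned dose to
the tumor volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ICCResult",
    "icc_case3A",
    "robust_filter",
    "GLCMatrix",
    "glcm_compute",
    "imc1",
    "dose_at_volume",
]


@dataclass(frozen=True)
class ICCResult:
    """Single-measure absolute-agreement ICC with its ANOVA mean squares."""

    value: float
    ms_rows: float  # between-subject mean square
    ms_cols: float  # between-rater mean square
    ms_error: float
    degenerate: bool = False


def icc_case3A(matrix: np.ndarray) -> ICCResult:
    """Two-way mixed-effects, absolute-agreement, single-measure ICC.

    ``matrix`` holds one feature's values for n subjects (rows) under k raters
    / repeated segmentations (columns).  With MSR, MSC, MSE the subject, rater
    and residual mean squares of the two-way ANOVA without replication:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    A matrix with zero variance everywhere is degenerate: the feature carries
    no information, so 0 is returned with the degenerate flag set (and the
    robustness filter will drop it).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("rater matrix must be 2-D (subjects x raters)")
    n, k = m.shape
    if n < 2:
        raise ValueError("need at least two subjects")
    if k < 2:
        raise ValueError("need at least two raters")
    if not np.all(np.isfinite(m)):
        raise ValueError("rater matrix must be finite")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_error = ss_total - ss_rows - ss_cols

    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))

    denom = ms_rows + (k - 1) * ms_error + (k / n) * (ms_cols - ms_error)
    if np.isclose(ss_total, 0.0) or np.isclose(denom, 0.0):
        return ICCResult(0.0, ms_rows, ms_cols, ms_error, degenerate=True)
    value = (ms_rows - ms_error) / denom
    return ICCResult(float(value), float(ms_rows), float(ms_cols),
                     float(ms_error))


def robust_filter(features: list[str], icc_values: dict[str, float],
                  cutoff: float = 0.7) -> list[str]:
    """Keep only features with ICC strictly above the cutoff.

    Features whose value shifts materially under small segmentation changes
    are excluded from the selection stage altogether.  The inequality is
    strict: ICC exactly at the cutoff is not robust.
    """
    missing = [f for f in features if f not in icc_values]
    if missing:
        raise KeyError(f"no ICC value for feature(s): {missing}")
    return [f for f in features if icc_values[f] > cutoff]


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized symmetric gray-level co-occurrence probabilities."""

    P: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("GLCM must be a square matrix")
        if np.any(P < 0) or not np.isclose(P.sum(), 1.0):
            raise ValueError("GLCM entries must be non-negative and sum to 1")

    @property
    def px(self) -> np.ndarray:
        return np.asarray(self.P).sum(axis=1)

    @property
    def py(self) -> np.ndarray:
        return np.asarray(self.P).sum(axis=0)


def _entropy_bits(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float).ravel()
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def glcm_compute(image: np.ndarray, levels: int = 16,
                 offset: tuple[int, ...] = (0, 1),
                 mask: np.ndarray | None = None) -> GLCMatrix:
    """Symmetric, normalized gray-level co-occurrence matrix.

    The image (2-D or 3-D) is quantized to ``levels`` equal-width bins over
    its (masked) intensity range, then voxel pairs separated by ``offset`` are
    accumulated in both directions and the counts normalized to probabilities.
    A constant image collapses to a single level and produces the degenerate
    one-hot diagonal matrix, which downstream statistics must tolerate.
    """
    img = np.asarray(image, dtype=float)
    offset = tuple(int(o) for o in offset)
    if img.ndim not in (1, 2, 3):
        raise ValueError("image must be 1-D, 2-D or 3-D")
    if len(offset) != img.ndim:
        raise ValueError("offset dimensionality must match the image")
    if all(o == 0 for o in offset):
        raise ValueError("offset must be nonzero")
    if levels < 1:
        raise ValueError("need at least one gray level")

    roi = np.ones(img.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    lo, hi = img[roi].min(), img[roi].max()
    if hi > lo:
        q = np.minimum((img - lo) / (hi - lo) * levels, levels - 1).astype(int)
    else:
        q = np.zeros(img.shape, dtype=int)

    # slice views of the two members of every pair at the given displacement
    src = tuple(slice(max(0, -o), img.shape[d] - max(0, o))
                for d, o in enumerate(offset))
    dst = tuple(slice(max(0, o), img.shape[d] + min(0, o))
                for d, o in enumerate(offset))
    a, b = q[src].ravel(), q[dst].ravel()
    valid = roi[src].ravel() & roi[dst].ravel()
    a, b = a[valid], b[valid]
    if a.size == 0:
        raise ValueError("no voxel pairs at this offset inside the mask")

    counts = np.zeros((levels, levels), dtype=float)
    np.add.at(counts, (a, b), 1.0)
    counts += counts.T  # symmetric accumulation
    return GLCMatrix(P=counts / counts.sum())


def imc1(g: GLCMatrix) -> float:
    """First informational measure of correlation, in bits.

    IMC1 = (HXY - HXY1) / max(HX, HY) with
    HXY  = -sum p(i,j) log2 p(i,j)         (joint entropy),
    HXY1 = -sum p(i,j) log2 (px(i) py(j)),
    HX, HY the marginal entropies.  HXY1 >= HXY always, so IMC1 <= 0; an
    independent joint distribution gives exactly 0, and stronger gray-level
    dependence pushes the value toward -1.  The degenerate constant-image
    GLCM has max(HX, HY) = 0 and returns 0 by convention.
    """
    P = np.asarray(g.P)
    px, py = g.px, g.py
    hx, hy = _entropy_bits(px), _entropy_bits(py)
    denom = max(hx, hy)
    if denom == 0.0:
        return 0.0
    hxy = _entropy_bits(P)
    outer = np.outer(px, py)
    nz = P > 0
    hxy1 = float(-np.sum(P[nz] * np.log2(outer[nz])))
    return (hxy - hxy1) / denom


def dose_at_volume(doses: np.ndarray, x_percent: float) -> float:
    """Dx%: minimum dose received by the hottest x percent of an ROI's voxels.

    D2% approaches the near-maximum dose, D98% the near-minimum.  The function
    is monotone non-increasing in x.  Voxels are equal-volume samples of the
    region of interest.
    """
    d = np.asarray(doses, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("dose sample is empty")
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise ValueError("doses must be finite and non-negative")
    if not 0 < x_percent <= 100:
        raise ValueError("x must lie in (0, 100]")
    n_hot = int(np.ceil(x_percent / 100.0 * d.size))
    # minimum of the n_hot largest values = (size - n_hot)-th order statistic
    return float(np.partition(d, d.size - n_hot)[d.size - n_hot])
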