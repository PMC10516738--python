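"""Synthetic longitudinal imaging phantoms with analytically known volumes.

The phantom stands in for per-fraction cone-beam CT of the head-and-neck
region: a stack of axial ellipses (head wider than neck) that shrinks
geometrically over the treatment course, imaged on a fixed voxel grid with a
high-intensity couch slab, an internal air cavity, additive noise, and random
per-fraction couch shifts recorded exactly as applied.  Because each axial
cross-section is an ellipse, the true body volume is available in closed form
at every fraction, which gives the volume tracker an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion
from scipy.optimize import brentq
from scipy.stats import norm

from .tracking import ImageVolume, RegistrationRecord, SliceWindow

__all__ = [
    "PhantomSpec",
    "generate_phantom_series",
    "analytic_volume",
    "sample_patient_specs",
    "reduction_shrink_threshold",
    "multirater_volumes",
]

# intensity model: arbitrary units, bimodal air/tissue with a brighter couch
AIR_INTENSITY = 50.0
BODY_INTENSITY = 1050.0
COUCH_INTENSITY = 1900.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and course parameters of one shrinking body phantom.

    ``radius_a_mm``/``radius_b_mm`` give the lateral/antero-posterior
    semi-axes of the body ellipse per occupied slice; the body occupies
    ``n_body_slices`` slices starting at ``body_start_slice``.  The body at
    fraction ``f`` is the fraction-1 body with both in-plane semi-axes scaled
    by ``sqrt((1 - shrink_rate)**(f - 1))`` so its volume decays exactly
    geometrically.
    """

    radius_a_mm: tuple[float, ...] = tuple(np.linspace(40.0, 34.0, 14))
    radius_b_mm: tuple[float, ...] = tuple(np.linspace(36.0, 30.0, 14))
    n_slices: int = 18
    body_start_slice: int = 2
    slice_thickness_mm: float = 3.0
    pixel_mm: float = 1.0
    grid_ny: int = 104
    grid_nx: int = 96
    center_yx_mm: tuple[float, float] = (44.0, 48.0)
    shrink_rate: float = 0.005
    n_fractions: int = 33
    couch: bool = True
    couch_start_row: int = 94
    cavity: bool = True
    cavity_radius_mm: float = 8.0
    noise_sd: float = 20.0
    max_shift_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        radii = np.concatenate([self.radius_a_mm, self.radius_b_mm])
        if len(self.radius_a_mm) != len(self.radius_b_mm):
            raise ValueError("semi-axis profiles must have equal length")
        if len(self.radius_a_mm) == 0:
            raise ValueError("phantom body needs at least one slice")
        if np.any(radii <= 0):
            raise ValueError("all body radii must be positive")
        if not 0 <= self.shrink_rate < 1:
            raise ValueError("shrink_rate must lie in [0, 1)")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        last = self.body_start_slice + len(self.radius_a_mm)
        if self.body_start_slice < 0 or last > self.n_slices:
            raise ValueError("body slices must fit inside the grid")

    @property
    def n_body_slices(self) -> int:
        return len(self.radius_a_mm)

    @property
    def window(self) -> SliceWindow:
        """C1/C5 annotation bracketing the body, planning-frame mm."""
        t = self.slice_thickness_mm
        c1 = self.body_start_slice * t
        return SliceWindow(c1_mm=c1, c5_mm=c1 + self.n_body_slices * t)

    @property
    def crop_box(self) -> tuple[int, int, int, int]:
        """In-plane rectangle (x0, x1, y0, y1) excluding the couch slab."""
        return (2, self.grid_nx - 2, 2, min(self.grid_ny - 2, self.couch_start_row - 6))


def analytic_volume(spec: PhantomSpec, fraction: int) -> float:
    """Exact stack-of-ellipses body volume in mm**3 at a 1-based fraction.

    V_f = sum_i(pi * a_i * b_i * t) * (1 - shrink_rate)**(f - 1); the decay
    starts after fraction 1.
    """
    if not 1 <= fraction <= spec.n_fractions:
        raise ValueError(f"fraction {fraction} outside 1..{spec.n_fractions}")
    a = np.asarray(spec.radius_a_mm)
    b = np.asarray(spec.radius_b_mm)
    base = float(np.sum(np.pi * a * b) * spec.slice_thickness_mm)
    return base * (1.0 - spec.shrink_rate) ** (fraction - 1)


def _rasterize(spec: PhantomSpec, fraction: int, shift: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """Voxelize one fraction: body at the shifted position, couch, cavity, noise."""
    nz, ny, nx = spec.n_slices, spec.grid_ny, spec.grid_nx
    img = np.full((nz, ny, nx), AIR_INTENSITY, dtype=np.float32)

    scale = np.sqrt((1.0 - spec.shrink_rate) ** (fraction - 1))
    cy = spec.center_yx_mm[0] + shift[1]
    cx = spec.center_yx_mm[1] + shift[0]
    # pixel centers in mm
    ys = (np.arange(ny) + 0.5) * spec.pixel_mm
    xs = (np.arange(nx) + 0.5) * spec.pixel_mm
    yy = (ys - cy)[:, None]
    xx = (xs - cx)[None, :]

    # axial shift is pre-snapped to a whole number of slices
    dz_slices = int(round(shift[2] / spec.slice_thickness_mm))
    k0 = spec.body_start_slice + dz_slices

    for i in range(spec.n_body_slices):
        a = spec.radius_a_mm[i] * scale
        b = spec.radius_b_mm[i] * scale
        if a < spec.pixel_mm or b < spec.pixel_mm:
            raise ValueError(
                f"body vanishes at fraction {fraction}: semi-axis below one "
                f"pixel ({min(a, b):.2f} mm)")
        inside = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
        img[k0 + i][inside] = BODY_INTENSITY

    if spec.cavity:
        # air-filled ellipsoid strictly interior to the body (shrinks with it)
        r = spec.cavity_radius_mm * scale
        mid = k0 + spec.n_body_slices // 2
        zs = (np.arange(nz) + 0.5) * spec.slice_thickness_mm
        z_mid = (mid + 0.5) * spec.slice_thickness_mm
        zz = ((zs - z_mid) / r)[:, None, None] ** 2
        hole = zz + (yy / r)[None] ** 2 + (xx / r)[None] ** 2 <= 1.0
        img[hole] = AIR_INTENSITY

    if spec.couch:
        img[:, spec.couch_start_row:, :] = COUCH_INTENSITY

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)
    return img


def generate_phantom_series(
    spec: PhantomSpec,
) -> tuple[list[ImageVolume], list[RegistrationRecord], SliceWindow, list[float]]:
    """Generate one patient's per-fraction image series.

    Returns the images, the couch-shift registration records actually applied,
    the C1/C5 slice annotation in the planning frame, and the closed-form body
    volume at every fraction.  Identical spec (including seed) reproduces the
    series bit for bit.

    Couch shifts are drawn uniformly in ``[-max_shift_mm, +max_shift_mm]`` per
    axis; the axial component is snapped to the slice grid because the slab
    phantom has no sub-slice structure, and the snapped value is what the
    registration record stores.
    """
    rng = np.random.default_rng(spec.seed)
    t = spec.slice_thickness_mm
    images: list[ImageVolume] = []
    records: list[RegistrationRecord] = []
    truth: list[float] = []
    for f in range(1, spec.n_fractions + 1):
        shift = rng.uniform(-spec.max_shift_mm, spec.max_shift_mm, size=3)
        shift[2] = round(shift[2] / t) * t
        img = _rasterize(spec, f, shift, rng)
        images.append(ImageVolume(intensities=img, pixel_mm=spec.pixel_mm,
                                  slice_mm=t, origin_mm=0.0))
        records.append(RegistrationRecord(
            fraction=f, shift_mm=tuple(float(s) for s in shift)))
        truth.append(analytic_volume(spec, f))
    return images, records, spec.window, truth


def reduction_shrink_threshold(n_fractions: int = 33, window: int = 3,
                               threshold_pct: float = -10.0) -> float:
    """Per-fraction shrink rate at which a course just reaches the reduction rule.

    Volume change at fraction f is 100*((1-s)**(f-1) - 1), monotone in f, so
    the first qualifying window is the last one; solve for s where the mean of
    the final ``window`` relative volumes equals 1 + threshold/100.
    """
    if n_fractions < window:
        raise ValueError("course shorter than the classification window")
    target = 1.0 + threshold_pct / 100.0
    exps = np.arange(n_fractions - window, n_fractions)

    def gap(s: float) -> float:
        return float(np.mean((1.0 - s) ** exps)) - target

    return brentq(gap, 0.0, 0.5)


def sample_patient_specs(
    n_patients: int,
    n_fractions: int = 33,
    prevalence: float = 0.29,
    sigma_log: float = 0.5,
    seed: int = 0,
) -> tuple[list[PhantomSpec], np.ndarray]:
    """Draw a cohort of phantom specs from a latent shrink-rate model.

    Each patient gets a log-normal shrink rate ``s = s* exp(sigma*(z - z0))``
    with ``z ~ N(0,1)`` and ``z0`` the population quantile at 1 - prevalence,
    so the probability of crossing the classification threshold ``s*`` is
    exactly ``prevalence`` (the latent variable thresholded at its upper
    30th-percentile style cut).  Body size varies mildly across patients.

    Returns the specs and the latent ground-truth labels (1 = reduction).
    """
    rng = np.random.default_rng(seed)
    s_star = reduction_shrink_threshold(n_fractions=n_fractions)
    z0 = norm.ppf(1.0 - prevalence)
    z = rng.standard_normal(n_patients)
    rates = s_star * np.exp(sigma_log * (z - z0))
    labels = (z > z0).astype(int)

    base = PhantomSpec(n_fractions=n_fractions)
    specs = []
    for i in range(n_patients):
        size = rng.uniform(0.92, 1.08)
        specs.append(replace(
            base,
            radius_a_mm=tuple(np.asarray(base.radius_a_mm) * size),
            radius_b_mm=tuple(np.asarray(base.radius_b_mm) * size),
            shrink_rate=float(min(rates[i], 0.05)),
            cavity=bool(rng.random() < 0.5),
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return specs, labels


def multirater_volumes(specs: list[PhantomSpec], k_raters: int = 3) -> np.ndarray:
    """Subjects x raters volume matrix from systematic contour perturbation.

    Emulates inter-observer segmentation variability: rater 0 traces the true
    body contour, rater 1 erodes it by one in-plane voxel, rater 2 dilates by
    one, rater 3 erodes by two, and so on.  Used to feed the ICC robustness
    filter with data whose disagreement structure is known.
    """
    if k_raters < 2:
        raise ValueError("need at least two raters")
    out = np.empty((len(specs), k_raters))
    structure = np.zeros((1, 3, 3), dtype=bool)
    structure[0] = True
    for i, spec in enumerate(specs):
        rng = np.random.default_rng(spec.seed)
        img = _rasterize(replace(spec, couch=False, cavity=False, noise_sd=0.0),
                         1, np.zeros(3), rng)
        mask = img > (AIR_INTENSITY + BODY_INTENSITY) / 2
        voxel = spec.pixel_mm**2 * spec.slice_thickness_mm
        for j in range(k_raters):
            rounds = (j + 1) // 2
            if rounds == 0:
                m = mask
            elif j % 2 == 1:
                m = binary_erosion(mask, structure, iterations=rounds)
            else:
                m = binary_dilation(mask, structure, iterations=rounds)
            out[i, j] = m.sum() * voxel
    return out
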