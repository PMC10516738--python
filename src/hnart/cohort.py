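"""Synthetic patient feature tables with the study's statistical structure.

The real cohort (172 head-and-neck radiotherapy patients) is not public, so
this module generates tables with the same shape and the effect structure the
analysis assumes: clinical factors with realistic marginals, nine near-constant
dose-volume parameters (D2/D50/D98 percent for GTVp, GTVn and PTV), and one
block-correlated radiomic panel per tumor structure.  Three designated columns
carry the label signal — a GLCM IMC1-like texture feature of the primary GTV
whose group means are -0.35 (reduction) vs -0.47 (non-reduction), HPV16
positivity, and chemotherapy — while every other column is null by
construction.  A null mode removes all three effects so selector and model
pipelines can be checked against chance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["CohortSpec", "FeatureTable", "generate_feature_table", "FEATURE_SETS"]

# the seven feature-set combinations of clinical, dose and radiomic groups
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "clin": ("clinical",),
    "dose": ("dose",),
    "rad": ("rad_gtvp", "rad_gtvn"),
    "clin+dose": ("clinical", "dose"),
    "clin+rad": ("clinical", "rad_gtvp", "rad_gtvn"),
    "dose+rad": ("dose", "rad_gtvp", "rad_gtvn"),
    "clin+dose+rad": ("clinical", "dose", "rad_gtvp", "rad_gtvn"),
}

LABEL_COLUMN = "reduction"


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    ``imc1_means`` are the (reduction, non-reduction) group means of the
    informative texture column; ``hpv_rates`` / ``chemo_rates`` are the
    corresponding conditional positivity rates.  The informative effects are
    deliberately strong relative to the weak associations a small clinical
    cohort can establish, so that selector-recovery behaviour is testable.
    ``null_mode`` severs every feature-label association.
    """

    n_patients: int = 172
    target_prevalence: float = 0.29
    n_radiomic: int = 107
    imc1_means: tuple[float, float] = (-0.35, -0.47)
    imc1_sd: float = 0.09
    hpv_rates: tuple[float, float] = (0.70, 0.12)
    chemo_rates: tuple[float, float] = (0.92, 0.40)
    block_size: int = 10
    block_rho: float = 0.6
    frac_only_gtvp: float = 0.22
    frac_only_gtvn: float = 0.19
    null_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must lie in (0, 1)")
        if self.n_patients < 10:
            raise ValueError("cohort needs at least 10 patients")
        if not np.all(np.isfinite(self.imc1_means)):
            raise ValueError("effect sizes must be finite")
        if self.frac_only_gtvp + self.frac_only_gtvn >= 1:
            raise ValueError("missingness fractions must leave complete cases")


@dataclass
class FeatureTable:
    """Patients x features with per-column group tags and a binary label."""

    df: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if LABEL_COLUMN not in self.df.columns:
            raise ValueError(f"table must contain a '{LABEL_COLUMN}' column")
        untagged = set(self.df.columns) - set(self.groups) - {LABEL_COLUMN}
        if untagged:
            raise ValueError(f"columns without a group tag: {sorted(untagged)}")

    @property
    def labels(self) -> np.ndarray:
        return self.df[LABEL_COLUMN].to_numpy(dtype=int)

    def feature_names(self, feature_set: str) -> list[str]:
        wanted = FEATURE_SETS[feature_set]
        return [c for c in self.df.columns
                if c != LABEL_COLUMN and self.groups[c] in wanted]

    def to_csv(self, path: str | Path) -> None:
        """Write the table plus a sidecar JSON with the group tags."""
        path = Path(path)
        self.df.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".groups.json")
        sidecar.write_text(json.dumps(self.groups, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".groups.json")
        groups = json.loads(sidecar.read_text())
        return cls(df=df, groups=groups)


def _ar1_block(rng: np.random.Generator, n: int, width: int, rho: float) -> np.ndarray:
    """Standard-normal columns with AR(1) correlation rho along the block."""
    z = rng.standard_normal((n, width))
    out = np.empty_like(z)
    out[:, 0] = z[:, 0]
    for j in range(1, width):
        out[:, j] = rho * out[:, j - 1] + np.sqrt(1 - rho**2) * z[:, j]
    return out


def _radiomic_panel(rng: np.random.Generator, spec: CohortSpec, prefix: str,
                    y: np.ndarray, informative: bool) -> pd.DataFrame:
    """One structure's radiomic columns; IMC1-like first, noise blocks after."""
    n = spec.n_patients
    cols: dict[str, np.ndarray] = {}
    mu_red, mu_non = spec.imc1_means
    if spec.null_mode or not informative:
        mu = 0.5 * (mu_red + mu_non)
        imc = rng.normal(mu, spec.imc1_sd, size=n)
    else:
        imc = np.where(y == 1, rng.normal(mu_red, spec.imc1_sd, size=n),
                       rng.normal(mu_non, spec.imc1_sd, size=n))
    cols[f"{prefix}_glcm_imc1"] = np.clip(imc, -1.0, 0.0)

    remaining = spec.n_radiomic - 1
    idx = 2
    while remaining > 0:
        width = min(spec.block_size, remaining)
        block = _ar1_block(rng, n, width, spec.block_rho)
        for j in range(width):
            cols[f"{prefix}_tex_{idx:03d}"] = block[:, j]
            idx += 1
        remaining -= width
    return pd.DataFrame(cols)


def generate_feature_table(spec: CohortSpec,
                           labels: np.ndarray | None = None) -> FeatureTable:
    """Draw one synthetic cohort.

    Labels come from a standard-normal latent severity variable thresholded at
    its population ``1 - prevalence`` quantile, so the realized prevalence
    fluctuates binomially around the target (29% by default, echoing 50 of 172
    reduction cases).  Passing ``labels`` instead ties the informative columns
    to externally measured outcomes (e.g. tracker-derived groups), which is how
    the full pipeline couples imaging to the feature table.  Patients missing
    one tumor structure get NaN radiomic blocks, to be imputed downstream.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    if labels is None:
        z = rng.standard_normal(n)
        y = (z > norm.ppf(1.0 - spec.target_prevalence)).astype(int)
    else:
        y = np.asarray(labels, dtype=int)
        if len(y) != n:
            raise ValueError("labels length must equal n_patients")

    def bern(p_red: float, p_non: float) -> np.ndarray:
        if spec.null_mode:
            p = spec.target_prevalence * p_red + (1 - spec.target_prevalence) * p_non
            return (rng.random(n) < p).astype(int)
        p = np.where(y == 1, p_red, p_non)
        return (rng.random(n) < p).astype(int)

    site = rng.choice(4, size=n, p=[0.63, 0.19, 0.13, 0.05])
    clinical = pd.DataFrame({
        "age": np.clip(np.round(rng.normal(66, 13, n)), 28, 90),
        "sex_male": (rng.random(n) < 0.84).astype(int),
        "pathology_scc": (rng.random(n) < 0.95).astype(int),
        "site_pharynx": (site == 0).astype(int),
        "site_oral_cavity": (site == 1).astype(int),
        "site_larynx": (site == 2).astype(int),
        "site_other": (site == 3).astype(int),
        "treatment_radical": (rng.random(n) < 0.74).astype(int),
        "hpv16_positive": bern(*spec.hpv_rates),
        "chemotherapy": bern(*spec.chemo_rates),
        "weight_kg": np.clip(rng.normal(60, 11, n), 31, 95),
        "bmi": np.clip(rng.normal(22.2, 3.0, n), 14, 32),
        "total_protein": rng.normal(6.8, 0.5, n),
        "albumin": rng.normal(3.7, 0.5, n),
        "ag_ratio": rng.normal(1.3, 0.25, n),
        "hemoglobin": rng.normal(13.3, 1.6, n),
    })

    # optimizer-constrained plans: case differences in dose are small
    dose_means = {"gtvp": (71.5, 70.0, 68.0), "gtvn": (71.0, 69.8, 67.5),
                  "ptv": (72.0, 70.0, 66.5)}
    dose = pd.DataFrame({
        f"d{x}_{roi}": rng.normal(mu, 0.4, n)
        for roi, (m2, m50, m98) in dose_means.items()
        for x, mu in zip((2, 50, 98), (m2, m50, m98))
    })

    rad_p = _radiomic_panel(rng, spec, "gtvp", y, informative=True)
    rad_n = _radiomic_panel(rng, spec, "gtvn", y, informative=False)

    # structure availability: some patients have only one GTV contoured
    u = rng.random(n)
    only_p = u < spec.frac_only_gtvp
    only_n = (u >= spec.frac_only_gtvp) & (u < spec.frac_only_gtvp + spec.frac_only_gtvn)
    rad_n.loc[only_p, :] = np.nan
    rad_p.loc[only_n, :] = np.nan

    df = pd.concat([clinical, dose, rad_p, rad_n], axis=1)
    groups = {c: "clinical" for c in clinical.columns}
    groups |= {c: "dose" for c in dose.columns}
    groups |= {c: "rad_gtvp" for c in rad_p.columns}
    groups |= {c: "rad_gtvn" for c in rad_n.columns}
    df[LABEL_COLUMN] = y
    return FeatureTable(df=df, groups=groups)
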