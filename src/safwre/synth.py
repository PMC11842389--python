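"""Synthetic COPD-cohort generator.

The generator emulates a two-group cohort of elderly COPD patients screened
for mild cognitive impairment (MoCA < 26): an impaired group and a
cognitively normal group described by 20 clinical and laboratory features
plus the binary impairment label.

Two modes:

``table8``
    Labels fix the group sizes; the eight informative features (pulmonary
    function GOLD stage, course of disease, age, education level, PaCO2,
    Hcy, ET-1, 25-hydroxyvitamin D) are drawn from class-conditional
    distributions parameterized by the published group summaries
    (mean +/- SD for continuous features, per-level counts for the two
    categoricals); the remaining 12 nuisance features are class-independent.

``mechanism``
    Features are drawn first from pooled distributions, and the label comes
    from a logistic mechanism whose log-odds are linear in the eight
    informative features plus an optional nonlinear term
    (an age x PaCO2 interaction and a saturating transform of ET-1),
    scaled by ``nonlinearity_strength``.  This gives the residual stage a
    ground-truth nonlinear signal to capture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "SynthConfig",
    "FEATURE_TYPES",
    "TOP8_FEATURES",
    "CLASS_CONDITIONAL_CONTINUOUS",
    "generate_cohort",
    "generate_external_cohort",
    "split_train_test",
    "write_cohort",
    "read_cohort",
]

LABEL_COLUMN = "cognitive_impairment"

# Feature schema: name -> type, in the order the cohort columns appear.
# education_level is coded 1 = senior high school and above;
# pulmonary_function_stage is the GOLD stage 1-4.
FEATURE_TYPES: dict[str, str] = {
    "sex": "binary",
    "age": "continuous",
    "bmi": "continuous",
    "marital_status": "binary",
    "education_level": "binary",
    "smoking_history": "binary",
    "alcoholism_history": "binary",
    "family_history_copd": "binary",
    "hypertension": "binary",
    "diabetes": "binary",
    "course_of_disease": "continuous",
    "admission": "continuous",
    "multi_disease_coexistence": "binary",
    "pulmonary_function_stage": "ordinal",
    "et1": "continuous",
    "hcy": "continuous",
    "vitd25": "continuous",
    "pao2": "continuous",
    "paco2": "continuous",
    "long_term_oxygen_therapy": "binary",
}

TOP8_FEATURES = (
    "pulmonary_function_stage",
    "course_of_disease",
    "age",
    "education_level",
    "paco2",
    "hcy",
    "et1",
    "vitd25",
)

# (impaired mean, impaired sd, normal mean, normal sd) and physiologic floor
CLASS_CONDITIONAL_CONTINUOUS: dict[str, tuple[float, float, float, float, float]] = {
    "age": (69.23, 2.34, 62.38, 2.13, 60.0),
    "course_of_disease": (5.17, 1.32, 4.28, 1.08, 0.0),
    "paco2": (66.27, 5.23, 57.15, 4.28, 0.0),
    "hcy": (29.33, 3.72, 28.65, 3.22, 0.0),
    "et1": (96.27, 7.32, 77.73, 7.11, 0.0),
    "vitd25": (28.37, 3.16, 32.21, 4.07, 0.0),
}

# GOLD stage I-IV counts: impaired (9, 124, 170, 53), normal (88, 223, 157, 39)
STAGE_PROBS = {
    1: np.array([9, 124, 170, 53], dtype=float) / 356.0,
    0: np.array([88, 223, 157, 39], dtype=float) / 507.0,
}

# P(education = senior high and above): impaired 187/356, normal 404/507
EDUCATION_HIGH_PROB = {1: 187 / 356, 0: 404 / 507}

# Class-independent nuisance features: continuous (mean, sd, floor) or
# binary prevalence.  Values chosen as plausible for an elderly COPD ward.
NUISANCE_CONTINUOUS = {
    "bmi": (23.5, 3.2, 10.0),
    "admission": (2.1, 1.1, 0.0),
    "pao2": (62.0, 8.0, 30.0),
}
NUISANCE_BINARY = {
    "sex": 0.6,
    "marital_status": 0.6,
    "smoking_history": 0.55,
    "alcoholism_history": 0.3,
    "family_history_copd": 0.3,
    "hypertension": 0.45,
    "diabetes": 0.3,
    "multi_disease_coexistence": 0.5,
    "long_term_oxygen_therapy": 0.4,
}

# Linear log-odds coefficients of the mechanism mode, on standardized scale.
MECHANISM_BETA = {
    "pulmonary_function_stage": 0.9,
    "course_of_disease": 0.9,
    "age": 1.0,
    "education_level": -0.8,
    "paco2": 0.9,
    "hcy": 0.7,
    "et1": 1.0,
    "vitd25": -0.8,
}


@dataclass
class CohortTable:
    """Patients x features + binary label, with per-feature type metadata."""

    data: pd.DataFrame
    feature_types: Mapping[str, str] = field(default_factory=lambda: dict(FEATURE_TYPES))
    label_column: str = LABEL_COLUMN

    def __post_init__(self) -> None:
        missing = [c for c in self.feature_types if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort is missing feature columns: {missing}")
        if self.label_column not in self.data.columns:
            raise ValueError(f"cohort is missing label column {self.label_column!r}")
        if self.data.isna().any().any():
            raise ValueError("cohort contains missing values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.feature_types)

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def X(self) -> np.ndarray:
        return self.data[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data[self.label_column].to_numpy(dtype=int)

    def subset_features(self, names: list[str]) -> "CohortTable":
        types = {n: self.feature_types[n] for n in names}
        cols = names + [self.label_column]
        return CohortTable(self.data[cols].copy(), types, self.label_column)

    def take(self, index: np.ndarray) -> "CohortTable":
        return CohortTable(
            self.data.iloc[index].reset_index(drop=True),
            dict(self.feature_types),
            self.label_column,
        )


@dataclass
class SynthConfig:
    n_impaired: int = 356
    n_normal: int = 507
    mode: str = "table8"
    nonlinearity_strength: float = 4.0
    site_shift_sd: float = 0.0  # shift of continuous means, in within-class SDs
    seed: int = 0
    continuous_params: Mapping[str, tuple] = field(
        default_factory=lambda: dict(CLASS_CONDITIONAL_CONTINUOUS)
    )

    def __post_init__(self) -> None:
        if self.n_impaired < 2 or self.n_normal < 2:
            raise ValueError("group sizes must be >= 2")
        if self.mode not in ("table8", "mechanism"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.nonlinearity_strength < 0:
            raise ValueError("nonlinearity_strength must be >= 0")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, floor: float, size: int
) -> np.ndarray:
    """Gaussian draw with resampling below the physiologic floor."""
    out = rng.normal(mean, sd, size)
    bad = out < floor
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < floor
    return out


def _draw_nuisance(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    for name, (mean, sd, floor) in NUISANCE_CONTINUOUS.items():
        cols[name] = _truncated_normal(rng, mean, sd, floor, n)
    for name, prev in NUISANCE_BINARY.items():
        cols[name] = (rng.random(n) < prev).astype(float)
    return cols


def generate_cohort(cfg: SynthConfig) -> CohortTable:
    """Draw a synthetic cohort under the configured mode (see module docstring)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_impaired + cfg.n_normal
    shift = cfg.site_shift_sd

    if cfg.mode == "table8":
        y = np.concatenate([np.ones(cfg.n_impaired), np.zeros(cfg.n_normal)]).astype(int)
        rng.shuffle(y)
        cols: dict[str, np.ndarray] = {}
        for name, (m1, s1, m0, s0, floor) in cfg.continuous_params.items():
            vals = np.empty(n)
            for label, (m, s) in ((1, (m1, s1)), (0, (m0, s0))):
                mask = y == label
                vals[mask] = _truncated_normal(
                    rng, m + shift * s, s, floor, int(mask.sum())
                )
            cols[name] = vals
        stage = np.empty(n)
        edu = np.empty(n)
        for label in (1, 0):
            mask = y == label
            stage[mask] = rng.choice([1, 2, 3, 4], size=int(mask.sum()), p=STAGE_PROBS[label])
            edu[mask] = (rng.random(int(mask.sum())) < EDUCATION_HIGH_PROB[label]).astype(float)
        cols["pulmonary_function_stage"] = stage
        cols["education_level"] = edu
        cols.update(_draw_nuisance(rng, n))
    else:  # mechanism mode: features first, then a logistic label mechanism
        cols = {}
        prev_impaired = cfg.n_impaired / n
        for name, (m1, s1, m0, s0, floor) in cfg.continuous_params.items():
            m = prev_impaired * m1 + (1 - prev_impaired) * m0
            s = max(s1, s0) * 1.2  # pooled spread, mildly inflated
            cols[name] = _truncated_normal(rng, m + shift * s, s, floor, n)
        p_stage = prev_impaired * STAGE_PROBS[1] + (1 - prev_impaired) * STAGE_PROBS[0]
        cols["pulmonary_function_stage"] = rng.choice([1, 2, 3, 4], size=n, p=p_stage)
        p_edu = prev_impaired * EDUCATION_HIGH_PROB[1] + (1 - prev_impaired) * EDUCATION_HIGH_PROB[0]
        cols["education_level"] = (rng.random(n) < p_edu).astype(float)
        cols.update(_draw_nuisance(rng, n))

        z = {
            name: (cols[name] - cols[name].mean()) / (cols[name].std() + 1e-12)
            for name in MECHANISM_BETA
        }
        logit = sum(beta * z[name] for name, beta in MECHANISM_BETA.items())
        logit = logit + cfg.nonlinearity_strength * (
            z["age"] * z["paco2"] + np.tanh(2.0 * z["et1"])
        )
        logit = logit - logit.mean() + np.log(cfg.n_impaired / cfg.n_normal)
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    frame = pd.DataFrame({name: cols[name] for name in FEATURE_TYPES})
    frame[LABEL_COLUMN] = y
    perm = rng.permutation(n)
    frame = frame.iloc[perm].reset_index(drop=True)
    return CohortTable(frame)


def generate_external_cohort(cfg: SynthConfig | None = None) -> CohortTable:
    """External-validation cohort: same schema, smaller groups (114 impaired /
    219 normal by default), continuous means shifted by ``site_shift_sd``
    within-class SDs (default 0.25) to emulate between-site covariate shift."""
    if cfg is None:
        cfg = SynthConfig(n_impaired=114, n_normal=219, site_shift_sd=0.25, seed=1)
    return generate_cohort(cfg)


def split_train_test(
    cohort: CohortTable,
    train_fraction: float = 0.8,
    stratified: bool = True,
    seed: int = 0,
) -> tuple[CohortTable, CohortTable]:
    """Random train/test partition; train size is floor(n * fraction), so an
    863-patient cohort at 80% yields 690 training and 173 test patients.

    When stratified, per-class training counts are floor(n_c * fraction) with
    the remainder assigned to classes by largest fractional part.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = cohort.n_patients
    n_train = int(np.floor(n * train_fraction))
    rng = np.random.default_rng(seed)
    if not stratified:
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    else:
        y = cohort.y
        classes = np.unique(y)
        counts = {c: int(np.sum(y == c)) for c in classes}
        base = {c: int(np.floor(counts[c] * train_fraction)) for c in classes}
        frac = {c: counts[c] * train_fraction - base[c] for c in classes}
        short = n_train - sum(base.values())
        for c in sorted(classes, key=lambda c: -frac[c])[:short]:
            base[c] += 1
        train_parts, test_parts = [], []
        for c in classes:
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            train_parts.append(idx[: base[c]])
            test_parts.append(idx[base[c]:])
        train_idx = np.concatenate(train_parts)
        test_idx = np.concatenate(test_parts)
        rng.shuffle(train_idx)
        rng.shuffle(test_idx)
    return cohort.take(train_idx), cohort.take(test_idx)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """CSV with a header row plus a JSON sidecar recording the schema."""
    path = Path(path)
    cohort.data.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".schema.json")
    sidecar.write_text(
        json.dumps(
            {"label_column": cohort.label_column, "feature_types": dict(cohort.feature_types)},
            indent=2,
        )
    )


def read_cohort(path: str | Path) -> CohortTable:
    path = Path(path)
    frame = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".schema.json")
    if sidecar.exists():
        schema = json.loads(sidecar.read_text())
        return CohortTable(frame, schema["feature_types"], schema["label_column"])
    types = {c: FEATURE_TYPES.get(c, "continuous") for c in frame.columns if c != LABEL_COLUMN}
    return CohortTable(frame, types)
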