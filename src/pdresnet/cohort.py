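"""Synthetic wearable-gait cohorts for Parkinson's disease classification.

Emulates a per-subject feature table of 190 instrumented gait features
measured under three test conditions — timed-up-and-go (TUG, 97 features),
a spinning turn (TURN, 7) and narrow-path walking (NARROW, 86) — plus four
demographic covariates (sex, age, thigh length, lower-leg length), with a
binary diagnosis (PD / HC) and a severity subgroup for PD subjects
(early vs. moderate-to-advanced, i.e. Hoehn–Yahr > 2.5).

Gait features within a condition block are equicorrelated Gaussians built
from a shared block factor; a configurable fraction of features in each
block carries a standardized class shift (PD vs. HC), and
moderate-to-advanced subjects carry an additional shift on the same
features. Demographics are age-matched between classes by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "CohortConfigError",
    "CohortSchemaError",
    "feature_columns",
    "gait_feature_columns",
    "shifted_feature_columns",
    "generate_cohort",
    "cohort_to_csv",
    "csv_to_cohort",
]

DEMOGRAPHIC_COLUMNS = ("sex", "age", "thigh_len", "shank_len")
LABEL_COLUMNS = ("diagnosis", "severity")


class CohortConfigError(ValueError):
    """Raised when a :class:`CohortConfig` violates its invariants."""


class CohortSchemaError(ValueError):
    """Raised when a cohort CSV does not match the expected schema."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic gait cohort.

    Defaults reproduce the reference cohort: 296 PD (230 early + 66
    moderate-to-advanced) and 161 healthy controls, with 97 + 7 + 86 gait
    features and 4 demographic features (194 columns in total).

    Parameters
    ----------
    effect_size
        Standardized mean shift (in units of ``noise_sd``) between PD and
        HC on the shifted fraction of gait features.
    subgroup_effect
        Additional shift applied to moderate-to-advanced PD subjects.
    correlation
        Equicorrelation within each condition block, in [0, 1).
    noise_sd
        Marginal standard deviation of every gait feature (> 0).
    shift_fraction
        Fraction of features per block that carries the class shift.
    """

    n_pd: int = 296
    n_hc: int = 161
    n_early: int = 230
    n_modadv: int = 66
    n_tug: int = 97
    n_turn: int = 7
    n_narrow: int = 86
    n_demo: int = 4
    effect_size: float = 1.0
    subgroup_effect: float = 0.75
    correlation: float = 0.3
    noise_sd: float = 1.0
    shift_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        problems = []
        for name in ("n_pd", "n_hc", "n_early", "n_modadv",
                     "n_tug", "n_turn", "n_narrow"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_early + self.n_modadv != self.n_pd:
            problems.append(
                f"n_early + n_modadv must equal n_pd "
                f"({self.n_early} + {self.n_modadv} != {self.n_pd})")
        if self.n_demo != len(DEMOGRAPHIC_COLUMNS):
            problems.append(
                f"n_demo must be {len(DEMOGRAPHIC_COLUMNS)} "
                f"(sex, age, thigh_len, shank_len), got {self.n_demo}")
        if not 0.0 <= self.correlation < 1.0:
            problems.append(f"correlation must be in [0, 1), got {self.correlation}")
        if not self.noise_sd > 0:
            problems.append(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0.0 <= self.shift_fraction <= 1.0:
            problems.append(f"shift_fraction must be in [0, 1], got {self.shift_fraction}")
        if problems:
            raise CohortConfigError("; ".join(problems))

    @property
    def n_features(self) -> int:
        return self.n_tug + self.n_turn + self.n_narrow + self.n_demo

    @property
    def n_subjects(self) -> int:
        return self.n_pd + self.n_hc


def _block_columns(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i + 1:03d}" for i in range(n)]


def gait_feature_columns(config: CohortConfig | None = None) -> list[str]:
    """Names of the per-condition gait feature columns, in block order."""
    config = config or CohortConfig()
    return (_block_columns("tug", config.n_tug)
            + _block_columns("turn", config.n_turn)
            + _block_columns("nar", config.n_narrow))


def feature_columns(config: CohortConfig | None = None) -> list[str]:
    """All feature column names: gait blocks then demographics."""
    config = config or CohortConfig()
    return gait_feature_columns(config) + list(DEMOGRAPHIC_COLUMNS)


def shifted_feature_columns(config: CohortConfig | None = None) -> list[str]:
    """Gait features carrying the PD-vs-HC mean shift for this config.

    The selection is a deterministic function of the config seed, so it can
    be recovered independently of :func:`generate_cohort`.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5F1F]))
    shifted: list[str] = []
    for prefix, n in (("tug", config.n_tug), ("turn", config.n_turn),
                      ("nar", config.n_narrow)):
        k = int(round(config.shift_fraction * n))
        cols = _block_columns(prefix, n)
        idx = np.sort(rng.choice(n, size=k, replace=False)) if k else []
        shifted.extend(cols[i] for i in idx)
    return shifted


def _gait_block(rng: np.random.Generator, n_rows: int, n_feat: int,
                rho: float, sd: float) -> np.ndarray:
    """Equicorrelated Gaussian block: shared factor + independent residual."""
    z = rng.standard_normal((n_rows, 1))
    eps = rng.standard_normal((n_rows, n_feat))
    return sd * (math.sqrt(rho) * z + math.sqrt(1.0 - rho) * eps)


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate a synthetic per-subject gait feature table.

    Returns a DataFrame with one row per subject: ``subject_id``, the 194
    feature columns (TUG, TURN, NARROW blocks then demographics),
    ``diagnosis`` in {PD, HC} and ``severity`` in
    {none, early, moderate_advanced} (``none`` iff HC). Identical seeds
    yield bit-identical tables.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    diagnosis = np.array(["PD"] * config.n_pd + ["HC"] * config.n_hc)
    severity = np.array(["early"] * config.n_early
                        + ["moderate_advanced"] * config.n_modadv
                        + ["none"] * config.n_hc)
    is_pd = diagnosis == "PD"
    is_modadv = severity == "moderate_advanced"

    shifted = set(shifted_feature_columns(config))
    data: dict[str, np.ndarray] = {}
    for prefix, n_feat in (("tug", config.n_tug), ("turn", config.n_turn),
                           ("nar", config.n_narrow)):
        cols = _block_columns(prefix, n_feat)
        block = _gait_block(rng, n, n_feat, config.correlation, config.noise_sd)
        for j, col in enumerate(cols):
            if col in shifted:
                block[is_pd, j] += config.effect_size * config.noise_sd
                block[is_modadv, j] += config.subgroup_effect * config.noise_sd
        for j, col in enumerate(cols):
            data[col] = block[:, j]

    # Demographics: age-matched between classes, so no class shift here.
    data["sex"] = rng.integers(0, 2, size=n).astype(float)
    data["age"] = rng.normal(65.0, 8.0, size=n)
    data["thigh_len"] = rng.normal(45.0, 3.0, size=n)
    data["shank_len"] = rng.normal(38.0, 3.0, size=n)

    table = pd.DataFrame(data)
    table.insert(0, "subject_id", [f"S{i + 1:04d}" for i in range(n)])
    table["diagnosis"] = diagnosis
    table["severity"] = severity
    return table


def cohort_to_csv(table: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV (full float precision, row order kept)."""
    table.to_csv(path, index=False)


def csv_to_cohort(path, config: CohortConfig | None = None) -> pd.DataFrame:
    """Read a cohort CSV, validating and realigning columns by name.

    The header may list columns in any order; the returned table is in
    canonical order. A missing or superfluous column raises
    :class:`CohortSchemaError` naming the offending column.
    """
    config = config or CohortConfig()
    try:
        raw = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise CohortSchemaError(f"could not parse cohort CSV {path!r}: {exc}") from exc

    expected = ["subject_id"] + feature_columns(config) + list(LABEL_COLUMNS)
    have = set(raw.columns)
    for col in expected:
        if col not in have:
            raise CohortSchemaError(f"missing column {col!r} in {path!r}")
    extra = [c for c in raw.columns if c not in set(expected)]
    if extra:
        raise CohortSchemaError(
            f"unexpected column(s) {extra!r} in {path!r} "
            f"(expected {len(expected)} columns)")

    table = raw[expected].copy()
    bad_diag = set(table["diagnosis"].unique()) - {"PD", "HC"}
    if bad_diag:
        raise CohortSchemaError(f"invalid diagnosis value(s) {sorted(bad_diag)}")
    bad_sev = set(table["severity"].unique()) - {"none", "early", "moderate_advanced"}
    if bad_sev:
        raise CohortSchemaError(f"invalid severity value(s) {sorted(bad_sev)}")
    feats = table[feature_columns(config)]
    if feats.isna().any().any():
        col = feats.columns[feats.isna().any()][0]
        raise CohortSchemaError(f"missing values in column {col!r}")
    return table
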