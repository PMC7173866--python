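"""Design preparation: complete-case filtering, standardization and
construction of the prognostic/predictive design matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS, CONTINUOUS_COVARIATES

#: Coefficient labels in the order used throughout the package.
PROGNOSTIC_LABELS = ("Intercept", "General Health", "Age", "Sex", "HbA1c")
PREDICTIVE_LABELS = (
    "Treatment",
    "General Health x Treatment",
    "Age x Treatment",
    "Sex x Treatment",
    "HbA1c x Treatment",
)
ALL_LABELS = PROGNOSTIC_LABELS + PREDICTIVE_LABELS


@dataclass(frozen=True)
class StandardizationParams:
    """Center/scale per continuous covariate, estimated on the analysis
    sample (n-1 denominator).  Used to map grids and new subjects onto
    the scale the model was fit on."""

    center: dict
    scale: dict

    def __post_init__(self):
        for name, s in self.scale.items():
            if not s > 0:
                raise ValueError(f"scale for {name!r} must be > 0")

    def transform(self, name: str, values):
        """Standardize raw values of covariate ``name``."""
        if name not in self.center:
            raise KeyError(f"no standardization stored for covariate {name!r}")
        return (np.asarray(values, dtype=float) - self.center[name]) / self.scale[name]

    def inverse(self, name: str, values):
        """Map standardized values of covariate ``name`` back to raw units."""
        return np.asarray(values, dtype=float) * self.scale[name] + self.center[name]


@dataclass(frozen=True)
class DesignMatrices:
    """Model design built from a complete-case cohort.

    ``X`` (prognostic) and ``Z`` (predictive) are identical n x 5
    matrices with columns (1, GH, age, sex, HbA1c) on the standardized
    scale; the treatment main effect is carried by Z's constant column.
    """

    X: np.ndarray
    Z: np.ndarray
    t: np.ndarray
    y: np.ndarray
    std: StandardizationParams
    column_labels: tuple = ALL_LABELS

    def __post_init__(self):
        X, Z = np.asarray(self.X), np.asarray(self.Z)
        if X.shape != Z.shape or X.ndim != 2 or X.shape[1] != 5:
            raise ValueError("X and Z must be matching (n, 5) matrices")
        if np.isnan(X).any() or np.isnan(Z).any():
            raise ValueError("design matrices contain missing values")
        if X.shape[0] and not (
            np.all(X[:, 0] == 1.0) and np.all(Z[:, 0] == 1.0)
        ):
            raise ValueError("first column of X and Z must be all ones")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def regressors(self) -> np.ndarray:
        """Stacked n x 10 regressor matrix [X, t*Z]."""
        return np.hstack([self.X, self.t[:, None] * self.Z])


def complete_cases(cohort: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows with any missing field; returns (filtered, removed count).

    Row order is preserved.  Raises if the cohort is empty or no
    complete rows remain.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    kept = cohort.dropna(axis=0, how="any", subset=list(COHORT_COLUMNS))
    removed = len(cohort) - len(kept)
    if len(kept) == 0:
        raise ValueError("no complete cases remain after filtering")
    return kept.reset_index(drop=True), removed


def standardize(cohort: pd.DataFrame) -> tuple[pd.DataFrame, StandardizationParams]:
    """Standardize the continuous covariates of a complete-case cohort.

    Each of sf36_gh, age and hba1c is centred at its sample mean and
    scaled by its sample standard deviation (n-1 denominator); sex,
    treatment and event are untouched.
    """
    if cohort[list(COHORT_COLUMNS)].isna().any().any():
        raise ValueError("standardize requires complete cases")
    center, scale = {}, {}
    out = cohort.copy()
    for name in CONTINUOUS_COVARIATES:
        col = cohort[name].to_numpy(dtype=float)
        mu = col.mean()
        sd = col.std(ddof=1)
        if not sd > 0:
            raise ValueError(f"covariate {name!r} is constant; cannot standardize")
        center[name], scale[name] = float(mu), float(sd)
        out[name] = (col - mu) / sd
    return out, StandardizationParams(center=center, scale=scale)


def build_design(cohort: pd.DataFrame) -> DesignMatrices:
    """Build :class:`DesignMatrices` from a complete-case cohort.

    The same four covariates act as both prognostic and predictive
    terms, so X and Z share columns; Z's leading constant column makes
    the first predictive coefficient the treatment main effect.
    """
    std_cohort, std = standardize(cohort)
    n = len(std_cohort)
    X = np.column_stack(
        [
            np.ones(n),
            std_cohort["sf36_gh"].to_numpy(dtype=float),
            std_cohort["age"].to_numpy(dtype=float),
            std_cohort["sex"].to_numpy(dtype=float),
            std_cohort["hba1c"].to_numpy(dtype=float),
        ]
    )
    return DesignMatrices(
        X=X,
        Z=X.copy(),
        t=std_cohort["treatment"].to_numpy(dtype=float),
        y=std_cohort["event"].to_numpy(dtype=float),
        std=std,
    )
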