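"""Synthetic trial cohort generation with known ground truth.

Cohorts mimic a lifestyle-intervention trial with four baseline
covariates (SF-36 general health, age, sex, HbA1c), a 1:1 randomised
binary treatment and a binary composite cardiovascular endpoint.  Events
are generated from a logistic model on within-sample standardized
covariates, so the generating coefficients live on the same scale as the
coefficients later estimated by :mod:`credsub.model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

#: Covariate columns a cohort table must carry, in canonical order.
COVARIATE_COLUMNS = ("age", "sex", "sf36_gh", "hba1c")
#: Full cohort column set.
COHORT_COLUMNS = COVARIATE_COLUMNS + ("treatment", "event")
#: Continuous covariates, in the order they appear in design matrices.
CONTINUOUS_COVARIATES = ("sf36_gh", "age", "hba1c")

#: Default prognostic coefficients (intercept, GH, age, sex, HbA1c),
#: log-odds units on the standardized scale.
DEFAULT_BETA = (-2.41, -0.07, 0.43, 0.82, 0.39)
#: Default predictive coefficients (treatment main effect, GH x t,
#: age x t, sex x t, HbA1c x t), log-odds units.
DEFAULT_GAMMA = (-0.22, -0.19, -0.01, -0.07, 0.32)


@dataclass(frozen=True)
class TruthParams:
    """Generating coefficients of the event model, standardized scale.

    ``beta`` holds the prognostic effects ordered (intercept, general
    health, age, sex, HbA1c); ``gamma`` the predictive effects ordered
    (treatment main effect, then the four treatment interactions in the
    same covariate order).
    """

    beta: tuple[float, ...] = DEFAULT_BETA
    gamma: tuple[float, ...] = DEFAULT_GAMMA

    def __post_init__(self):
        beta = tuple(float(v) for v in self.beta)
        gamma = tuple(float(v) for v in self.gamma)
        if len(beta) != 5 or len(gamma) != 5:
            raise ValueError("beta and gamma must each have length 5")
        if not all(np.isfinite(beta + gamma)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "gamma", gamma)

    @property
    def beta_array(self) -> np.ndarray:
        return np.asarray(self.beta, dtype=float)

    @property
    def gamma_array(self) -> np.ndarray:
        return np.asarray(self.gamma, dtype=float)


@dataclass(frozen=True)
class CohortGenConfig:
    """Configuration of the synthetic cohort generator.

    Defaults reproduce the marginal baseline moments of the emulated
    trial's entire sample: age 58.9 (6.8) years, 41% male, HbA1c
    7.3 (1.2) %, SF-36 general health 47.2 (8.9), 1:1 allocation.
    Covariates are drawn independently unless ``continuous_corr`` gives
    a correlation matrix for (sf36_gh, age, hba1c).
    """

    n_subjects: int = 4893
    age_mean: float = 58.9
    age_sd: float = 6.8
    male_prob: float = 0.41
    hba1c_mean: float = 7.3
    hba1c_sd: float = 1.2
    sf36_mean: float = 47.2
    sf36_sd: float = 8.9
    allocation_prob: float = 0.5
    truth: TruthParams = field(default_factory=TruthParams)
    seed: int = 0
    continuous_corr: tuple | None = None

    def __post_init__(self):
        if int(self.n_subjects) <= 0:
            raise ValueError("n_subjects must be a positive integer")
        for name in ("age_sd", "hba1c_sd", "sf36_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("male_prob", "allocation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.continuous_corr is not None:
            c = np.asarray(self.continuous_corr, dtype=float)
            if c.shape != (3, 3) or not np.allclose(c, c.T):
                raise ValueError("continuous_corr must be a symmetric 3x3 matrix")


def _standardize_columns(values: np.ndarray) -> np.ndarray:
    return (values - values.mean()) / values.std(ddof=1)


def generate_cohort(config: CohortGenConfig) -> pd.DataFrame:
    """Generate a trial-like cohort under ``config``.

    Covariates are drawn from the configured marginal distributions,
    treatment is Bernoulli(``allocation_prob``) and the event indicator
    is Bernoulli(logit^-1(x'beta + t * z'gamma)) with x = z the
    (1, GH, age, sex, HbA1c) vector on the scale obtained by
    standardizing the continuous covariates within the generated sample.

    Returns a DataFrame with columns ``age, sex, sf36_gh, hba1c,
    treatment, event``; fixed ``config.seed`` reproduces it exactly.
    """
    n = int(config.n_subjects)
    rng = np.random.default_rng(config.seed)

    means = np.array([config.sf36_mean, config.age_mean, config.hba1c_mean])
    sds = np.array([config.sf36_sd, config.age_sd, config.hba1c_sd])
    if config.continuous_corr is None:
        cont = rng.normal(means, sds, size=(n, 3))
    else:
        corr = np.asarray(config.continuous_corr, dtype=float)
        cov = corr * np.outer(sds, sds)
        cont = rng.multivariate_normal(means, cov, size=n)
    sf36, age, hba1c = cont[:, 0], cont[:, 1], cont[:, 2]
    sex = (rng.random(n) < config.male_prob).astype(float)
    treatment = (rng.random(n) < config.allocation_prob).astype(float)

    x = np.column_stack(
        [
            np.ones(n),
            _standardize_columns(sf36),
            _standardize_columns(age),
            sex,
            _standardize_columns(hba1c),
        ]
    )
    eta = x @ config.truth.beta_array + treatment * (x @ config.truth.gamma_array)
    event = (rng.random(n) < expit(eta)).astype(float)

    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "sf36_gh": sf36,
            "hba1c": hba1c,
            "treatment": treatment,
            "event": event,
        }
    )


def inject_missingness(
    cohort: pd.DataFrame, n_incomplete: int, seed: int
) -> pd.DataFrame:
    """Return a copy in which exactly ``n_incomplete`` rows have at least
    one baseline covariate set to NaN.

    Rows and the missing covariate within each row are chosen uniformly
    at random; treatment and event are never blanked.
    """
    n_incomplete = int(n_incomplete)
    n = len(cohort)
    if not 0 <= n_incomplete <= n:
        raise ValueError(f"n_incomplete must lie in [0, {n}], got {n_incomplete}")
    out = cohort.copy()
    if n_incomplete == 0:
        return out
    rng = np.random.default_rng(seed)
    rows = rng.choice(n, size=n_incomplete, replace=False)
    cols = rng.integers(0, len(COVARIATE_COLUMNS), size=n_incomplete)
    for r, c in zip(rows, cols):
        out.iloc[int(r), out.columns.get_loc(COVARIATE_COLUMNS[c])] = np.nan
    return out


def true_benefit_mask(
    truth: TruthParams, points: np.ndarray, threshold: float = 0.0
) -> np.ndarray:
    """Boolean mask of grid points truly benefiting under ``truth``.

    ``points`` is an (m, 5) array of predictive vectors
    (1, GH, age, sex, HbA1c) on the standardized scale.  A point
    benefits when the benefit-positive effect ``-(z' gamma)`` strictly
    exceeds ``threshold``.  Prognostic coefficients play no role.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 5:
        raise ValueError("points must be an (m, 5) array")
    return -(points @ truth.gamma_array) > threshold


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as headered CSV; missing values become empty fields."""
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks required columns: {missing}")
    return df[list(COHORT_COLUMNS)].astype(float)


def with_truth(config: CohortGenConfig, truth: TruthParams) -> CohortGenConfig:
    """Convenience: copy of ``config`` with a different generating truth."""
    return replace(config, truth=truth)
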