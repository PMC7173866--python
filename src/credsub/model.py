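"""Bayesian logistic regression with a heterogeneity-sceptical prior.

The model is Y_i | eta_i ~ Bernoulli(logit^-1(eta_i)) with
eta_i = x_i' beta + t_i z_i' gamma, independent mean-zero normal priors
with a vague variance on the prognostic block (default 1000) and a
conservative variance on the predictive block (default 1).

The default sampler is a blocked Gibbs sampler based on Pólya-Gamma
data augmentation, which gives conjugate multivariate-normal coefficient
updates; a random-walk Metropolis sampler is available behind the same
interface as a fallback and cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from . import _pg
from .design import ALL_LABELS, DesignMatrices

_N_COEF = 10


@dataclass(frozen=True)
class PriorSpec:
    """Independent mean-zero normal priors for the two coefficient blocks."""

    prognostic_variance: float = 1000.0
    predictive_variance: float = 1.0

    def __post_init__(self):
        if self.prognostic_variance <= 0 or self.predictive_variance <= 0:
            raise ValueError("prior variances must be > 0")

    def variances(self) -> np.ndarray:
        """Length-10 vector of prior variances, beta block then gamma block."""
        return np.concatenate(
            [
                np.full(5, float(self.prognostic_variance)),
                np.full(5, float(self.predictive_variance)),
            ]
        )


@dataclass(frozen=True)
class MCMCConfig:
    iterations: int = 10_000
    burn_in: int = 1_000
    seed: int = 0
    init: str = "zero"

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.init != "zero":
            raise ValueError("only 'zero' initialization is supported")


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained MCMC draws of the 10 coefficients.

    Columns are ordered (beta_0..beta_4, gamma_0..gamma_4) matching
    :data:`credsub.design.ALL_LABELS`.
    """

    draws: np.ndarray
    labels: tuple = ALL_LABELS

    def __post_init__(self):
        d = np.asarray(self.draws)
        if d.ndim != 2 or d.shape[1] != _N_COEF:
            raise ValueError(f"draws must be (k, {_N_COEF})")
        if not np.isfinite(d).all():
            raise ValueError("draws contain non-finite values")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    @property
    def beta(self) -> np.ndarray:
        """(k, 5) prognostic block."""
        return self.draws[:, :5]

    @property
    def gamma(self) -> np.ndarray:
        """(k, 5) predictive block (treatment main effect first)."""
        return self.draws[:, 5:]

    def linear_predictor(self, x, z, t) -> np.ndarray:
        """eta per draw for a single design row (x, z, t)."""
        return self.beta @ np.asarray(x, float) + float(t) * (
            self.gamma @ np.asarray(z, float)
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(self.draws, columns=list(self.labels)).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PosteriorDraws":
        df = pd.read_csv(path)
        return cls(draws=df.to_numpy(dtype=float), labels=tuple(df.columns))


def _validate_design(dm: DesignMatrices) -> np.ndarray:
    reg = dm.regressors()
    if not np.isfinite(reg).all() or not np.isfinite(dm.y).all():
        raise ValueError("design contains non-finite values")
    if dm.n and not np.isin(dm.y, (0.0, 1.0)).all():
        raise ValueError("y must be binary")
    return reg


def _gibbs(reg, y, prior_var, cfg) -> np.ndarray:
    n, d = reg.shape
    master = np.random.default_rng(cfg.seed)
    _pg.seed(int(master.integers(2**31 - 1)))
    rng = np.random.default_rng(master.integers(2**63 - 1))

    b_inv = np.diag(1.0 / prior_var)
    kappa = y - 0.5
    xk = reg.T @ kappa
    theta = np.zeros(d)
    omega = np.empty(n)
    total = cfg.burn_in + cfg.iterations
    out = np.empty((cfg.iterations, d))
    for it in range(total):
        eta = reg @ theta
        _pg.draw(eta, out=omega)
        prec = reg.T @ (reg * omega[:, None]) + b_inv
        chol = linalg.cho_factor(prec, lower=True)
        mean = linalg.cho_solve(chol, xk)
        # theta ~ N(mean, prec^-1): solve L' u = xi with prec = L L'
        xi = rng.standard_normal(d)
        theta = mean + linalg.solve_triangular(chol[0].T, xi, lower=False)
        if it >= cfg.burn_in:
            out[it - cfg.burn_in] = theta
    return out


def _log_post(theta, reg, y, prior_var):
    eta = reg @ theta
    llik = y @ eta - np.logaddexp(0.0, eta).sum()
    return llik - 0.5 * np.sum(theta**2 / prior_var)


def _metropolis(reg, y, prior_var, cfg) -> np.ndarray:
    # Adaptive-scale random-walk fallback; adaptation stops after burn-in.
    d = reg.shape[1]
    rng = np.random.default_rng(cfg.seed)
    step = 0.1 * np.sqrt(np.minimum(prior_var, 1.0 + 4.0 / max(reg.shape[0], 1)))
    theta = np.zeros(d)
    lp = _log_post(theta, reg, y, prior_var)
    total = cfg.burn_in + cfg.iterations
    out = np.empty((cfg.iterations, d))
    accepted = 0
    for it in range(total):
        prop = theta + step * rng.standard_normal(d)
        lp_prop = _log_post(prop, reg, y, prior_var)
        if np.log(rng.random()) < lp_prop - lp:
            theta, lp = prop, lp_prop
            accepted += 1
        if it < cfg.burn_in and (it + 1) % 100 == 0:
            rate = accepted / (it + 1)
            step *= np.exp(0.5 * (rate - 0.25))
        if it >= cfg.burn_in:
            out[it - cfg.burn_in] = theta
    return out


def sample_posterior(
    dm: DesignMatrices,
    prior: PriorSpec | None = None,
    cfg: MCMCConfig | None = None,
    method: str = "gibbs",
) -> PosteriorDraws:
    """Sample the posterior of the 10 coefficients.

    Parameters
    ----------
    dm : DesignMatrices
        Complete-case, standardized design.  With zero rows the
        posterior equals the prior and draws are taken from it directly
        through the same update (the data terms vanish).
    prior, cfg : PriorSpec, MCMCConfig
        Priors and chain settings; defaults follow the package's
        standard analysis (variances 1000/1, 10,000 retained draws after
        1,000 burn-in).
    method : {"gibbs", "metropolis"}
        "gibbs" is the Pólya-Gamma augmented Gibbs sampler (default);
        "metropolis" a random-walk fallback with the same interface.

    Returns exactly ``cfg.iterations`` retained draws; a fixed
    ``cfg.seed`` reproduces them bit-for-bit.
    """
    prior = prior or PriorSpec()
    cfg = cfg or MCMCConfig()
    reg = _validate_design(dm)
    prior_var = prior.variances()
    if method == "gibbs":
        draws = _gibbs(reg, dm.y, prior_var, cfg)
    elif method == "metropolis":
        draws = _metropolis(reg, dm.y, prior_var, cfg)
    else:
        raise ValueError(f"unknown sampler method {method!r}")
    if not np.isfinite(draws).all():
        raise RuntimeError("sampler produced non-finite draws")
    return PosteriorDraws(draws=draws, labels=dm.column_labels)


def posterior_summary(draws: PosteriorDraws, level: float = 0.95) -> pd.DataFrame:
    """Per-coefficient posterior mean, sd, equal-tailed credible bounds
    and a significance flag (bounds exclude zero).

    Returns a DataFrame indexed by coefficient label with columns
    ``mean, sd, lower, upper, significant``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if draws.n_draws < 2:
        raise ValueError("need at least 2 draws to summarize")
    d = draws.draws
    alpha = 1.0 - level
    lower = np.quantile(d, alpha / 2.0, axis=0)
    upper = np.quantile(d, 1.0 - alpha / 2.0, axis=0)
    return pd.DataFrame(
        {
            "mean": d.mean(axis=0),
            "sd": d.std(axis=0, ddof=1),
            "lower": lower,
            "upper": upper,
            "significant": (lower > 0.0) | (upper < 0.0),
        },
        index=list(draws.labels),
    )


def _autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = x - x.mean()
    denom = x @ x
    n = x.shape[0]
    acf = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        acf[lag] = (x[: n - lag] @ x[lag:]) / denom
    return acf


def _ess_ips(x: np.ndarray) -> float:
    # Effective sample size via Geyer's initial positive sequence rule.
    n = x.shape[0]
    acf = _autocorr(x, max_lag=min(n - 2, 2000))
    pair_sums = []
    for k in range(0, (len(acf) - 1) // 2):
        g = acf[2 * k] + acf[2 * k + 1]
        if g <= 0.0:
            break
        pair_sums.append(g)
    tau = max(-1.0 + 2.0 * sum(pair_sums), 1e-12)
    return float(min(n / tau, n))


@dataclass(frozen=True)
class DiagnosticsReport:
    """Autocorrelation (lags 0..50) and effective sample size per coefficient."""

    autocorrelation: pd.DataFrame  # index: lag, columns: labels
    ess: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.autocorrelation.T
        out.columns = [f"acf_lag{k}" for k in out.columns]
        out.insert(0, "ess", self.ess)
        return out


def diagnostics(draws: PosteriorDraws, max_lag: int = 50) -> DiagnosticsReport:
    """Chain diagnostics: sample autocorrelation to ``max_lag`` and ESS
    from the initial-positive-sequence rule.

    Raises for chains shorter than 10 draws or constant in any column.
    """
    d = draws.draws
    if d.shape[0] < 10:
        raise ValueError("need at least 10 draws for diagnostics")
    acfs = {}
    ess = {}
    for j, label in enumerate(draws.labels):
        col = d[:, j]
        if np.ptp(col) == 0.0:
            raise ValueError(f"chain for {label!r} is constant; autocorrelation undefined")
        acfs[label] = _autocorr(col, min(max_lag, d.shape[0] - 1))
        ess[label] = _ess_ips(col)
    acf_df = pd.DataFrame(acfs)
    acf_df.index.name = "lag"
    return DiagnosticsReport(autocorrelation=acf_df, ess=pd.Series(ess))
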