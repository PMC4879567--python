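"""Core containers for the univariate linear Gaussian state-space model.

The model is the textbook AR(1)-plus-noise state-space model

    x_t = rho * x_{t-1} + eta_t,      eta_t ~ N(0, sigma_eta^2)   (process)
    y_t = x_t + eps_t,                eps_t ~ N(0, sigma_eps^2)   (observation)

observed at regular time steps t = 1..n.  ``sigma_eta`` is the process
(biological) stochasticity, ``sigma_eps`` the measurement error.  The initial
state x_0 is either known exactly or given a Gaussian prior N(mu, sigma0^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class InvalidConfigError(ValueError):
    """Raised for invalid model or simulation configuration."""


class DegenerateLikelihoodError(ValueError):
    """Raised when the likelihood degenerates to a point mass inconsistent
    with the data (e.g. both variances zero but observations off the
    deterministic path)."""


@dataclass(frozen=True)
class GaussianPrior:
    """Gaussian prior N(mu, sigma0^2) for the initial state x_0."""

    mu: float = 0.0
    sigma0: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma0 > 0:
            raise InvalidConfigError("x0 prior requires sigma0 > 0")


@dataclass(frozen=True)
class SSMParams:
    """Parameter vector theta = (sigma_eps, rho, sigma_eta) plus the
    initial-state specification.

    Parameters
    ----------
    rho : autoregression coefficient of the latent state (dimensionless).
    sigma_eta : standard deviation of the process innovations (state units).
    sigma_eps : standard deviation of the observation noise (state units).
    x0 : initial state value, used when ``x0_prior`` is None (known x_0).
    x0_prior : optional Gaussian prior on x_0; None means x_0 is known.
    """

    rho: float
    sigma_eta: float
    sigma_eps: float
    x0: float = 0.0
    x0_prior: GaussianPrior | None = None

    def __post_init__(self) -> None:
        if self.sigma_eta < 0 or self.sigma_eps < 0:
            raise InvalidConfigError("standard deviations must be >= 0")
        if not np.isfinite(self.rho):
            raise InvalidConfigError("rho must be finite")

    @property
    def theta(self) -> tuple[float, float, float]:
        """Estimation-order parameter tuple (sigma_eps, rho, sigma_eta)."""
        return (self.sigma_eps, self.rho, self.sigma_eta)

    def replace(self, **kwargs) -> "SSMParams":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


@dataclass
class TimeSeries:
    """Observations y_1..y_n at unit time steps, NaN marking missing values.

    ``x_true`` carries the simulated latent states when the series was
    produced by the simulator; it is absent (None) for real data.
    """

    y: np.ndarray
    x_true: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1 or self.y.size == 0:
            raise InvalidConfigError("y must be a non-empty 1-D array")
        if self.x_true is not None:
            self.x_true = np.asarray(self.x_true, dtype=float)
            if self.x_true.shape != self.y.shape:
                raise InvalidConfigError("x_true must match y in length")
            if np.isnan(self.x_true).any():
                raise InvalidConfigError("x_true may not contain missing values")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing observations."""
        return ~np.isnan(self.y)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())
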