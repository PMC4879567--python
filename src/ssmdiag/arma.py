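"""ARMA(1,1) observational equivalence and parameter redundancy.

The stationary AR(1)-plus-noise state-space model is observationally
equivalent to an ARMA(1,1): with w_t = y_t - rho * y_{t-1}, the process w_t
is MA(1), so y_t follows an ARMA(1,1) with AR coefficient phi = rho.  When
the measurement error dominates the process stochasticity the MA root nearly
cancels the AR root (theta -> -phi), i.e. the model is observationally close
to white noise and the parameters are redundant — the structural explanation
for the estimability failures at high error-to-stochasticity ratios.  When
measurement error is negligible, theta -> 0 and the model behaves as a pure
AR(1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import InvalidConfigError, SSMParams

__all__ = ["ARMAParams", "ssm_autocovariance", "ssm_to_arma", "redundancy_index"]


class NonStationaryError(InvalidConfigError):
    """Raised when |rho| >= 1 and a stationary quantity is requested."""


@dataclass(frozen=True)
class ARMAParams:
    """Invertible ARMA(1,1) parameters: y_t = phi y_{t-1} + e_t + theta_ma e_{t-1}."""

    phi: float
    theta_ma: float
    sigma_e: float

    def __post_init__(self) -> None:
        if abs(self.theta_ma) > 1.0 + 1e-12:
            raise InvalidConfigError("theta_ma must satisfy |theta| <= 1 (invertible)")
        if self.sigma_e < 0:
            raise InvalidConfigError("sigma_e must be >= 0")


def _check_stationary(params: SSMParams) -> None:
    if abs(params.rho) >= 1.0:
        raise NonStationaryError("|rho| must be < 1 for the stationary model")


def ssm_autocovariance(params: SSMParams, max_lag: int) -> np.ndarray:
    """Stationary autocovariance of the observations y at lags 0..max_lag.

    gamma(0) = sigma_eta^2 / (1 - rho^2) + sigma_eps^2 and
    gamma(k) = rho^k * sigma_eta^2 / (1 - rho^2) for k >= 1.
    """
    _check_stationary(params)
    if max_lag < 0:
        raise InvalidConfigError("max_lag must be >= 0")
    var_x = params.sigma_eta ** 2 / (1.0 - params.rho ** 2)
    gamma = var_x * params.rho ** np.arange(max_lag + 1)
    gamma[0] += params.sigma_eps ** 2
    return gamma


def ssm_to_arma(params: SSMParams) -> ARMAParams:
    """Map the stationary state-space model to its ARMA(1,1) equivalent.

    phi = rho; (theta, sigma_e) solve the MA(1) moment equations of
    w_t = y_t - rho y_{t-1}:

        (1 + theta^2) sigma_e^2 = sigma_eta^2 + (1 + rho^2) sigma_eps^2
        theta sigma_e^2         = -rho sigma_eps^2

    with the invertible root |theta| <= 1, so the mapped ARMA reproduces the
    state-space autocovariance function exactly.
    """
    _check_stationary(params)
    var_eta = params.sigma_eta ** 2
    var_eps = params.sigma_eps ** 2
    c0 = var_eta + (1.0 + params.rho ** 2) * var_eps
    c1 = -params.rho * var_eps
    if c0 == 0.0:
        return ARMAParams(phi=params.rho, theta_ma=0.0, sigma_e=0.0)
    if c1 == 0.0:
        return ARMAParams(phi=params.rho, theta_ma=0.0, sigma_e=math.sqrt(c0))
    r = c1 / c0  # |r| <= 1/2 by AM-GM, so the root below is real
    # stable form of the invertible root (no cancellation as r -> 0)
    theta = 2.0 * r / (1.0 + math.sqrt(1.0 - 4.0 * r * r))
    sigma_e = math.sqrt(c0 / (1.0 + theta * theta))
    return ARMAParams(phi=params.rho, theta_ma=theta, sigma_e=sigma_e)


def redundancy_index(params: SSMParams) -> float:
    """|phi + theta| of the mapped ARMA(1,1): 0 means exact AR/MA root
    cancellation (observationally white noise; full parameter redundancy).

    The index decreases toward 0 as the measurement-error-to-process ratio
    sigma_eps/sigma_eta grows at fixed rho, and equals |rho| when
    sigma_eps = 0.
    """
    arma = ssm_to_arma(params)
    return abs(arma.phi + arma.theta_ma)
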