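"""Continuous-discrete Kalman filtering and forecasting of flow states.

Between measurements the mean and covariance of the linear system
``dx = F x dt + B u dt + G dw`` propagate continuously,

    d/dt xhat  = F xhat + B u,
    d/dt Sigma = F Sigma + Sigma F' + G Q G',

and at each (possibly irregularly spaced) observation instant t_n the
discrete measurement ``z(t_n) = H x(t_n) + v(t_n)``, cov(v) = R_obs, is
assimilated through the Kalman gain

    K = Sigma H' (H Sigma H' + R_obs)^-1.

Both propagation steps are exact for piecewise-constant input (matrix
exponential for the mean, Van Loan discretization for the covariance), and
the measurement update uses the Joseph form internally so the covariance
stays symmetric positive semidefinite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from sklearn.base import BaseEstimator

from .dynamics import StateTrajectory, as_input_function, _check_times
from .network import LinearDynamics

__all__ = [
    "ObservationModel",
    "ObservationSeries",
    "FilterState",
    "FilterResult",
    "KalmanFilter",
    "time_update",
    "measurement_update",
    "run_filter",
    "forecast",
]


@dataclass(frozen=True)
class ObservationModel:
    """Linear observation map ``z = H x + v`` with noise covariance R_obs."""

    H: np.ndarray
    R_obs: np.ndarray

    def __post_init__(self) -> None:
        H = np.atleast_2d(np.asarray(self.H, dtype=float))
        R = np.atleast_2d(np.asarray(self.R_obs, dtype=float))
        object.__setattr__(self, "H", H)
        object.__setattr__(self, "R_obs", R)
        p = H.shape[0]
        if R.shape != (p, p):
            raise ValueError("R_obs must be p x p with p = rows of H")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("R_obs must be symmetric")
        if np.any(np.linalg.eigvalsh((R + R.T) / 2) <= 0):
            raise ValueError("R_obs must be positive definite")

    @property
    def p(self) -> int:
        return self.H.shape[0]


@dataclass(frozen=True)
class ObservationSeries:
    """Time-stamped observation vectors at strictly increasing instants."""

    times: np.ndarray
    values: np.ndarray  # (T, p)
    channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if times.ndim != 1 or values.shape[0] != len(times):
            raise ValueError("values must align with times")
        if len(times) and np.any(np.diff(times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if len(times) and not np.all(np.isfinite(values)):
            raise ValueError("observations must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.channels and len(self.channels) != values.shape[1]:
            raise ValueError("channels must match the value dimension")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class FilterState:
    """State estimate and covariance at one instant."""

    time: float
    xhat: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self) -> None:
        xhat = np.asarray(self.xhat, dtype=float).ravel()
        Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        object.__setattr__(self, "xhat", xhat)
        object.__setattr__(self, "Sigma", Sigma)
        n = len(xhat)
        if Sigma.shape != (n, n):
            raise ValueError("Sigma must be n x n")
        if not np.allclose(Sigma, Sigma.T, atol=1e-8):
            raise ValueError("Sigma must be symmetric")

    @property
    def n(self) -> int:
        return len(self.xhat)


def _symmetrize(S: np.ndarray) -> np.ndarray:
    return (S + S.T) / 2.0


def _van_loan(A: np.ndarray, GQGt: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact discretization (Phi, Qd) of the Lyapunov propagation over dt."""
    n = A.shape[0]
    M = np.zeros((2 * n, 2 * n))
    M[:n, :n] = -A
    M[:n, n:] = GQGt
    M[n:, n:] = A.T
    E = expm(M * dt)
    Phi = E[n:, n:].T
    Qd = Phi @ E[:n, n:]
    return Phi, _symmetrize(Qd)


def time_update(fs: FilterState, dyn: LinearDynamics, u, tau: float) -> FilterState:
    """Propagate mean and covariance from fs.time to tau (no measurements).

    Exact for input held constant at u(fs.time) over the interval.
    """
    dt = float(tau) - fs.time
    if dt < 0:
        raise ValueError(f"target time {tau} precedes filter time {fs.time}")
    if dt == 0:
        return fs
    F = dyn.A
    GQGt = dyn.G @ dyn.Q @ dyn.G.T
    Phi, Qd = _van_loan(F, GQGt, dt)
    u_fn = as_input_function(u, dyn.n_inputs)
    b = dyn.B @ u_fn(fs.time) if dyn.n_inputs else np.zeros(dyn.n)
    # Gamma = int_0^dt expm(F s) ds via the same block-exponential trick
    n = dyn.n
    M = np.zeros((2 * n, 2 * n))
    M[:n, :n] = F
    M[:n, n:] = np.eye(n)
    Gamma = expm(M * dt)[:n, n:]
    xhat = Phi @ fs.xhat + Gamma @ b
    Sigma = _symmetrize(Phi @ fs.Sigma @ Phi.T + Qd)
    return FilterState(float(tau), xhat, Sigma)


def measurement_update(
    fs: FilterState, om: ObservationModel, z: Sequence[float]
) -> tuple[FilterState, np.ndarray]:
    """Assimilate one observation at fs.time; returns (posterior, innovation).

    Joseph-form covariance update (algebraically equal to (I - K H) Sigma).
    """
    z = np.asarray(z, dtype=float).ravel()
    H, R = om.H, om.R_obs
    if H.shape[1] != fs.n:
        raise ValueError("observation model dimension mismatch")
    if len(z) != om.p:
        raise ValueError("observation vector dimension mismatch")
    S = _symmetrize(H @ fs.Sigma @ H.T + R)
    try:
        K = np.linalg.solve(S, H @ fs.Sigma).T
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"singular innovation covariance: {err}") from err
    innovation = z - H @ fs.xhat
    xhat = fs.xhat + K @ innovation
    IKH = np.eye(fs.n) - K @ H
    Sigma = _symmetrize(IKH @ fs.Sigma @ IKH.T + K @ R @ K.T)
    return FilterState(fs.time, xhat, Sigma), innovation


@dataclass(frozen=True)
class FilterResult:
    """Posterior filter states, innovations and gains at the observation instants."""

    states: tuple[FilterState, ...]
    priors: tuple[FilterState, ...]
    innovations: np.ndarray  # (T, p)
    final: FilterState

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.states])

    @property
    def means(self) -> np.ndarray:
        return np.array([s.xhat for s in self.states]) if self.states else np.zeros((0, self.final.n))

    def to_trajectory(self) -> StateTrajectory:
        return StateTrajectory(self.times, self.means)


def run_filter(
    dyn: LinearDynamics,
    om: ObservationModel,
    series: ObservationSeries,
    init: FilterState,
    u=None,
) -> FilterResult:
    """Alternate time updates to each t_n with measurement updates at t_n."""
    if len(series) and init.time > series.times[0]:
        raise ValueError("filter initial time is after the first observation")
    fs = init
    states: list[FilterState] = []
    priors: list[FilterState] = []
    innovations = np.zeros((len(series), om.p))
    for i, t in enumerate(series.times):
        prior = time_update(fs, dyn, u, t)
        fs, innovations[i] = measurement_update(prior, om, series.values[i])
        priors.append(prior)
        states.append(fs)
    return FilterResult(tuple(states), tuple(priors), innovations, fs)


def forecast(
    fs: FilterState, dyn: LinearDynamics, u, horizon: float, dt: float = 1.0
) -> tuple[FilterState, ...]:
    """Propagate without measurements over ``horizon`` minutes, reporting every ``dt``.

    Returns the state at fs.time and at each step out to fs.time + horizon.
    """
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    out = [fs]
    if horizon == 0:
        return tuple(out)
    grid = np.arange(dt, horizon + dt / 2, dt)
    grid = grid[grid <= horizon + 1e-12]
    if len(grid) == 0 or grid[-1] < horizon - 1e-12:
        grid = np.append(grid, horizon)
    cur = fs
    for h in grid:
        cur = time_update(cur, dyn, u, fs.time + h)
        out.append(cur)
    return tuple(out)


class KalmanFilter(BaseEstimator):
    """Continuous-discrete Kalman filter with an estimator-style interface.

    Parameters
    ----------
    dyn : LinearDynamics
        The (possibly augmented) linear system to filter.
    observation_model : ObservationModel
        Observation map and noise covariance.
    x0 : array, optional
        Initial mean.  Default: pseudo-inverse lift of the first observation.
    sigma0 : float, default 10.0
        Initial covariance is ``sigma0**2 * I``.
    u : input signal, optional
        Exogenous input (constant vector or callable of time).

    Attributes
    ----------
    result_ : FilterResult
    states_ : tuple of FilterState
    innovations_ : ndarray (T, p)
    final_state_ : FilterState
    """

    def __init__(self, dyn=None, observation_model=None, x0=None, sigma0=10.0, u=None):
        self.dyn = dyn
        self.observation_model = observation_model
        self.x0 = x0
        self.sigma0 = sigma0
        self.u = u

    def _initial_state(self, series: ObservationSeries) -> FilterState:
        om = self.observation_model
        Sigma0 = self.sigma0**2 * np.eye(self.dyn.n)
        t0 = series.times[0] if len(series) else 0.0
        if self.x0 is not None:
            return FilterState(t0, np.asarray(self.x0, dtype=float), Sigma0)
        if not len(series):
            return FilterState(t0, np.zeros(self.dyn.n), Sigma0)
        x0 = np.linalg.pinv(om.H) @ series.values[0]
        return FilterState(t0, x0, Sigma0)

    def fit(self, series: ObservationSeries, y=None) -> "KalmanFilter":
        """Run the filter over the observation series."""
        if self.dyn is None or self.observation_model is None:
            raise ValueError("dyn and observation_model are required")
        init = self._initial_state(series)
        self.result_ = run_filter(self.dyn, self.observation_model, series, init, self.u)
        self.states_ = self.result_.states
        self.innovations_ = self.result_.innovations
        self.final_state_ = self.result_.final
        return self

    def predict(self, horizon: float, dt: float = 1.0) -> tuple[FilterState, ...]:
        """Forecast from the last filtered state (no further measurements)."""
        if not hasattr(self, "final_state_"):
            raise ValueError("fit the filter before forecasting")
        return forecast(self.final_state_, self.dyn, self.u, horizon, dt)
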