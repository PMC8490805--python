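"""Second-stage recursive estimation of rate-parameter perturbations.

Stage 1 (the Kalman filter plus the sensitivity integrator) produces a
filtered state eta_hat and the sensitivity matrix Psi(t) whose columns are
psi_j = d eta / d k_j evaluated at the nominal rates.  The discrepancy
between the filtered state and the nominal model state,

    y(t) = eta_hat(t) - eta_model(t)  ~  Psi(t) @ dk,

is regressed on Psi by exponentially forgetting recursive least squares:

    d dk_hat / dt = P Psi' e,     e = y - Psi dk_hat,
    d P / dt      = a P - P Psi' Psi P,

with forgetting rate ``a`` (per minute).  The inverse gain is the
exponentially weighted Fisher information

    R(t) = int_0^t exp(-a (t - s)) Psi(s)' Psi(s) ds,
    d R / dt = -a R + Psi' Psi,

so P(t) R(t) = I when both are initialized consistently.  Discretely, both P
and R advance with the same trapezoidal information increment, which makes
that duality exact step by step.

``TwoStageRateEstimator`` orchestrates the full loop: per observation epoch
it integrates the nominal model and sensitivities, runs the filter, forms the
residual, and performs one RLS/Fisher step; optionally the nominal rates are
refreshed to k_bar + dk_hat each cycle so the linearization tracks the
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .dynamics import integrate_sensitivities, integrate_state
from .kalman import (
    FilterState,
    ObservationModel,
    ObservationSeries,
    measurement_update,
    time_update,
)
from .network import FlowNetwork, RateParameters, build_system_matrices

__all__ = [
    "EstimatorState",
    "EstimatorConfig",
    "TwoStageResult",
    "TwoStageRateEstimator",
    "residual_signal",
    "rls_step",
    "fisher_step",
    "two_stage_estimate",
]


@dataclass(frozen=True)
class EstimatorState:
    """RLS state: perturbation estimate, gain, Fisher information, forgetting rate.

    The underscore-prefixed fields remember the previous regressor/residual so
    that the trapezoidal steps of :func:`rls_step` and :func:`fisher_step`
    integrate the same information increment independently of call order.
    """

    time: float
    dk_hat: np.ndarray  # (r,)
    P: np.ndarray  # (r, r) symmetric PD
    fisher: np.ndarray  # (r, r) symmetric PSD
    a: float
    y: np.ndarray | None = None
    _psi_prev_gain: np.ndarray | None = None
    _e_prev: np.ndarray | None = None
    _psi_prev_fisher: np.ndarray | None = None

    def __post_init__(self) -> None:
        dk = np.asarray(self.dk_hat, dtype=float).ravel()
        P = np.atleast_2d(np.asarray(self.P, dtype=float))
        R = np.atleast_2d(np.asarray(self.fisher, dtype=float))
        object.__setattr__(self, "dk_hat", dk)
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "fisher", R)
        r = len(dk)
        if P.shape != (r, r) or R.shape != (r, r):
            raise ValueError("P and fisher must be r x r")
        if self.a < 0:
            raise ValueError("forgetting rate must be nonnegative")
        if not np.allclose(P, P.T, atol=1e-8):
            raise ValueError("P must be symmetric")
        np.linalg.cholesky(P + 1e-14 * np.trace(P) * np.eye(r))  # PD check

    @property
    def r(self) -> int:
        return len(self.dk_hat)

    @classmethod
    def initial(cls, r: int, a: float, p0: float = 1e4) -> "EstimatorState":
        """Matched initialization: P(0) = p0 I, FisherInfo(0) = P(0)^-1."""
        return cls(0.0, np.zeros(r), p0 * np.eye(r), (1.0 / p0) * np.eye(r), a)


def residual_signal(eta_hat: Sequence[float], eta_model: Sequence[float]) -> np.ndarray:
    """Discrepancy y = eta_hat - eta_model between filtered and nominal states."""
    eta_hat = np.asarray(eta_hat, dtype=float).ravel()
    eta_model = np.asarray(eta_model, dtype=float).ravel()
    if eta_hat.shape != eta_model.shape:
        raise ValueError("state estimate and model state have different dimensions")
    return eta_hat - eta_model


def _info_increment(
    psi_prev: np.ndarray | None, psi: np.ndarray, lam: float, dt: float
) -> np.ndarray:
    """Trapezoidal increment of int exp(-a(t+dt-s)) Psi(s)'Psi(s) ds over one step."""
    r = psi.shape[1]
    prev = np.zeros((r, r)) if psi_prev is None else psi_prev.T @ psi_prev
    return 0.5 * dt * (lam * prev + psi.T @ psi)


def rls_step(
    es: EstimatorState, psi: np.ndarray, y: Sequence[float], dt: float
) -> EstimatorState:
    """One forgetting-RLS step over ``dt`` with regressor ``psi`` (N x r).

    Discretizes the gradient-flow dynamics with forgetting factor
    lambda = exp(-a dt): the inverse gain advances by
    ``P^-1 <- lambda P^-1 + trapezoid(Psi'Psi)`` and the estimate by the
    trapezoidal drive P Psi' e.  Converges to the continuous dynamics as
    dt -> 0.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    if psi.shape[1] != es.r:
        raise ValueError(f"psi must have r={es.r} columns")
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != psi.shape[0]:
        raise ValueError("residual dimension must match psi rows")
    lam = float(np.exp(-es.a * dt))
    incr = _info_increment(es._psi_prev_gain, psi, lam, dt)
    Pinv = np.linalg.inv(es.P)
    Pinv_new = lam * Pinv + incr
    try:
        P_new = np.linalg.inv(Pinv_new)
        np.linalg.cholesky((P_new + P_new.T) / 2)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "gain matrix lost positive-definiteness (degenerate regressors)"
        ) from err
    P_new = (P_new + P_new.T) / 2
    e_new = y - psi @ es.dk_hat
    prev_drive = (
        np.zeros(es.r)
        if es._psi_prev_gain is None or es._e_prev is None
        else es._psi_prev_gain.T @ es._e_prev
    )
    # trapezoid of P(s) Psi(s)' e(s): old P with old regressor, new with new
    drive = 0.5 * dt * (es.P @ prev_drive + P_new @ (psi.T @ e_new))
    dk_new = es.dk_hat + drive
    return replace(
        es,
        time=es.time + dt,
        dk_hat=dk_new,
        P=P_new,
        y=y,
        _psi_prev_gain=psi,
        _e_prev=y - psi @ dk_new,
    )


def fisher_step(es: EstimatorState, psi: np.ndarray, dt: float) -> EstimatorState:
    """Advance the Fisher information by dR/dt = -a R + Psi' Psi over ``dt``.

    Exact exponential decay of the -aR part; trapezoidal quadrature of the
    Psi'Psi inflow (matching :func:`rls_step`'s inverse-gain increment).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    if psi.shape[1] != es.r:
        raise ValueError(f"psi must have r={es.r} columns")
    lam = float(np.exp(-es.a * dt))
    R_new = lam * es.fisher + _info_increment(es._psi_prev_fisher, psi, lam, dt)
    return replace(es, fisher=(R_new + R_new.T) / 2, _psi_prev_fisher=psi)


@dataclass(frozen=True)
class EstimatorConfig:
    """Tunables of the two-stage loop.

    a : forgetting rate (1/min); p0 : initial gain scale P(0) = p0 I;
    sigma0 : initial filter standard deviation; refresh : re-linearize around
    k_bar + dk_hat every ``cadence`` epochs; burn_in_epochs : epochs ignored
    by convergence diagnostics; q_process / r_obs defaults used when no
    explicit noise model is supplied.
    """

    a: float = 0.1
    p0: float = 1e4
    sigma0: float = 10.0
    refresh: bool = True
    burn_in_epochs: int = 10
    cadence: int = 1
    rank_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.cadence < 1:
            raise ValueError("cadence must be >= 1")
        if self.p0 <= 0 or self.sigma0 <= 0:
            raise ValueError("p0 and sigma0 must be positive")


@dataclass(frozen=True)
class TwoStageResult:
    """Trajectories produced by the two-stage loop."""

    times: np.ndarray
    dk_hat: np.ndarray  # (T, r)
    k_hat: np.ndarray  # (T, r)
    filter_states: tuple[FilterState, ...]
    estimator_state: EstimatorState
    innovations: np.ndarray
    residuals: np.ndarray  # (T, N) stage-2 regression residual signals y
    identifiable: bool
    rate_names: tuple[str, ...] = ()

    @property
    def k_final(self) -> np.ndarray:
        return self.k_hat[-1]


class TwoStageRateEstimator(BaseEstimator):
    """Joint state filtering and rate-perturbation estimation.

    Parameters
    ----------
    network : FlowNetwork
        Compiled flow network.
    k_nominal : RateParameters
        Nominal rates k_bar the perturbation is measured against.
    observation_model : ObservationModel
        Observation map over the plain state (p x N) and its noise covariance.
    u : input signal, optional
    a, p0, sigma0, refresh, burn_in_epochs, cadence : see EstimatorConfig.
    process_noise : float, default 1e-2
        Diagonal process-noise intensity used in the filter's dynamics.

    Attributes
    ----------
    result_ : TwoStageResult
    k_hat_ : ndarray (r,) -- final rate estimate k_bar + dk_hat
    dk_hat_ : ndarray (r,)
    P_ : ndarray (r, r)
    fisher_ : ndarray (r, r)
    """

    def __init__(
        self,
        network=None,
        k_nominal=None,
        observation_model=None,
        u=None,
        a=0.1,
        p0=1e4,
        sigma0=10.0,
        refresh=True,
        burn_in_epochs=10,
        cadence=1,
        process_noise=1e-2,
    ):
        self.network = network
        self.k_nominal = k_nominal
        self.observation_model = observation_model
        self.u = u
        self.a = a
        self.p0 = p0
        self.sigma0 = sigma0
        self.refresh = refresh
        self.burn_in_epochs = burn_in_epochs
        self.cadence = cadence
        self.process_noise = process_noise

    def _config(self) -> EstimatorConfig:
        return EstimatorConfig(
            a=self.a,
            p0=self.p0,
            sigma0=self.sigma0,
            refresh=self.refresh,
            burn_in_epochs=self.burn_in_epochs,
            cadence=self.cadence,
        )

    def fit(self, series: ObservationSeries, y=None) -> "TwoStageRateEstimator":
        """Run the two-stage loop over the observation series."""
        net, kbar, om = self.network, self.k_nominal, self.observation_model
        if net is None or kbar is None or om is None:
            raise ValueError("network, k_nominal and observation_model are required")
        if len(series) < 2:
            raise ValueError("need at least two observation epochs")
        cfg = self._config()
        n, r = net.n_species, net.n_rules
        Q = self.process_noise * np.eye(n)

        times = series.times
        # filter initialization: pseudo-inverse lift of the first observation
        x0 = np.linalg.pinv(om.H) @ series.values[0]
        fs = FilterState(times[0], x0, cfg.sigma0**2 * np.eye(n))
        fs, innov0 = measurement_update(fs, om, series.values[0])

        es = EstimatorState.initial(r, cfg.a, cfg.p0)
        es = replace(es, time=times[0])
        dk_frozen = np.zeros(r)
        k_curr = kbar.values.copy()

        # model reference: starts at the filtered state, re-anchored on refresh
        anchor_time = times[0]
        anchor_state = fs.xhat.copy()

        T = len(times)
        dk_traj = np.zeros((T, r))
        k_traj = np.zeros((T, r))
        resids = np.zeros((T, n))
        innovations = np.zeros((T, om.p))
        innovations[0] = innov0
        k_traj[0] = k_curr
        filter_states = [fs]

        dyn = build_system_matrices(net, kbar.with_values(k_curr), Q=Q)
        seg_times = [anchor_time]
        for i in range(1, T):
            t = times[i]
            prior = time_update(fs, dyn, self.u, t)
            fs, innovations[i] = measurement_update(prior, om, series.values[i])
            filter_states.append(fs)

            # nominal model + sensitivities from the current anchor
            seg_times.append(t)
            grid = np.asarray(seg_times)
            model = integrate_state(dyn, anchor_state, self.u, grid)
            sens = integrate_sensitivities(
                net, kbar.with_values(k_curr), model, self.u, grid
            )
            psi_t = sens.psi[-1]  # (N, r)
            y_t = residual_signal(fs.xhat, model.states[-1])
            resids[i] = y_t
            target = y_t + psi_t @ dk_frozen
            dt = t - times[i - 1]
            es = rls_step(es, psi_t, target, dt)
            es = fisher_step(es, psi_t, dt)

            if cfg.refresh and i % cfg.cadence == 0:
                k_curr = np.clip(kbar.values + es.dk_hat, 0.0, None)
                dk_frozen = es.dk_hat.copy()
                anchor_time = t
                anchor_state = fs.xhat.copy()
                seg_times = [anchor_time]
                dyn = build_system_matrices(net, kbar.with_values(k_curr), Q=Q)

            dk_traj[i] = es.dk_hat
            k_traj[i] = np.clip(kbar.values + es.dk_hat, 0.0, None)

        burn = min(cfg.burn_in_epochs, T - 1)
        eigs = np.linalg.eigvalsh(es.fisher)
        identifiable = bool(eigs.min() > cfg.rank_tol) if T - 1 > burn else False

        self.result_ = TwoStageResult(
            times=times,
            dk_hat=dk_traj,
            k_hat=k_traj,
            filter_states=tuple(filter_states),
            estimator_state=es,
            innovations=innovations,
            residuals=resids,
            identifiable=identifiable,
            rate_names=net.rate_names,
        )
        self.dk_hat_ = es.dk_hat.copy()
        self.k_hat_ = self.result_.k_final.copy()
        self.P_ = es.P.copy()
        self.fisher_ = es.fisher.copy()
        return self


def two_stage_estimate(
    net: FlowNetwork,
    k_nominal: RateParameters,
    series: ObservationSeries,
    om: ObservationModel,
    cfg: EstimatorConfig | None = None,
    u=None,
    process_noise: float = 1e-2,
) -> TwoStageResult:
    """Functional wrapper around :class:`TwoStageRateEstimator`."""
    cfg = cfg or EstimatorConfig()
    est = TwoStageRateEstimator(
        network=net,
        k_nominal=k_nominal,
        observation_model=om,
        u=u,
        a=cfg.a,
        p0=cfg.p0,
        sigma0=cfg.sigma0,
        refresh=cfg.refresh,
        burn_in_epochs=cfg.burn_in_epochs,
        cadence=cfg.cadence,
        process_noise=process_noise,
    )
    est.fit(series)
    return est.result_
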