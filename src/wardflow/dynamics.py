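"""Deterministic integration of flow states and parameter sensitivities.

The state ODE ``d/dt eta = A(k) eta + B(k) u`` is integrated exactly on a
grid with piecewise-constant input, using per-step matrix exponentials.  The
sensitivity functions ``psi_j(t) = d eta / d k_j`` obey the companion linear
ODE

    d/dt psi_j = A(kbar) psi_j + (dA/dk_j) eta + (dB/dk_j) u,  psi_j(0) = 0,

and all r of them are integrated jointly as one block upper-triangular linear
system.  ``build_augmented_system`` assembles the 2N filtering system over
x = [psi_j; eta] used for joint sensitivity/state estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import expm

from .network import (
    FlowNetwork,
    LinearDynamics,
    RateParameters,
    build_system_matrices,
    rate_jacobians,
)

__all__ = [
    "StateTrajectory",
    "SensitivityTrajectory",
    "AugmentedDynamics",
    "integrate_state",
    "integrate_sensitivities",
    "build_augmented_system",
    "as_input_function",
]

InputSignal = Callable[[float], np.ndarray]


def as_input_function(u, m: int) -> InputSignal:
    """Normalize an input specification to a callable t -> R^m.

    Accepts None (zero input), a constant vector/scalar, or a callable.
    Values are interpreted as piecewise-constant between grid points: the
    integrators evaluate the signal at the left endpoint of each step.
    """
    if m == 0:
        return lambda t: np.zeros(0)
    if u is None:
        return lambda t: np.zeros(m)
    if callable(u):
        return lambda t: np.broadcast_to(np.asarray(u(t), dtype=float), (m,))
    const = np.broadcast_to(np.asarray(u, dtype=float), (m,)).copy()
    return lambda t: const


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 1:
        raise ValueError("times must be a nonempty 1-d grid")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return times


@dataclass(frozen=True)
class StateTrajectory:
    """Node counts eta(t) on a time grid (minutes)."""

    times: np.ndarray
    states: np.ndarray  # (T, N)
    params: RateParameters | None = None

    def __post_init__(self) -> None:
        times = _check_times(self.times)
        states = np.asarray(self.states, dtype=float)
        if states.shape[0] != len(times):
            raise ValueError("states must align with times")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)

    @property
    def n(self) -> int:
        return self.states.shape[1]


@dataclass(frozen=True)
class SensitivityTrajectory:
    """Per-time N x r sensitivity matrices Psi(t), columns psi_j = d eta/d k_j."""

    times: np.ndarray
    psi: np.ndarray  # (T, N, r)

    def __post_init__(self) -> None:
        times = _check_times(self.times)
        psi = np.asarray(self.psi, dtype=float)
        if psi.ndim != 3 or psi.shape[0] != len(times):
            raise ValueError("psi must be (T, N, r) aligned with times")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "psi", psi)


class AugmentedDynamics(LinearDynamics):
    """2N-dimensional system over x = [psi_j; eta] for one parameter index.

    Block upper-triangular: A_aug = [[A, dA/dk_j], [0, A]], with input matrix
    [[dB/dk_j], [B]].  Expanding the top block row reproduces the sensitivity
    ODE exactly.
    """


def _step_pair(A: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """(Phi, Gamma) with Phi = expm(A dt), Gamma = int_0^dt expm(A s) ds."""
    n = A.shape[0]
    M = np.zeros((2 * n, 2 * n))
    M[:n, :n] = A
    M[:n, n:] = np.eye(n)
    E = expm(M * dt)
    return E[:n, :n], E[:n, n:]


class _StepCache:
    """Cache exact-step matrices keyed by dt (grids are usually uniform)."""

    def __init__(self, A: np.ndarray):
        self.A = A
        self._cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def __call__(self, dt: float) -> tuple[np.ndarray, np.ndarray]:
        key = round(float(dt), 12)
        if key not in self._cache:
            self._cache[key] = _step_pair(self.A, dt)
        return self._cache[key]


def integrate_state(
    dyn: LinearDynamics,
    eta0: Sequence[float],
    u,
    times: Sequence[float],
) -> StateTrajectory:
    """Exactly integrate ``d/dt eta = A eta + B u`` on ``times``.

    ``u`` is piecewise-constant between grid points (left-endpoint value).
    """
    times = _check_times(np.asarray(times))
    eta0 = np.asarray(eta0, dtype=float)
    if eta0.shape != (dyn.n,):
        raise ValueError(f"eta0 must have dimension {dyn.n}")
    u_fn = as_input_function(u, dyn.n_inputs)
    steps = _StepCache(dyn.A)
    out = np.empty((len(times), dyn.n))
    out[0] = eta0
    x = eta0.copy()
    for i in range(len(times) - 1):
        dt = times[i + 1] - times[i]
        Phi, Gamma = steps(dt)
        b = dyn.B @ u_fn(times[i]) if dyn.n_inputs else np.zeros(dyn.n)
        x = Phi @ x + Gamma @ b
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"nonfinite state at t={times[i + 1]}")
        out[i + 1] = x
    return StateTrajectory(times, out)


def integrate_sensitivities(
    net: FlowNetwork,
    kbar: RateParameters,
    eta: StateTrajectory,
    u,
    times: Sequence[float] | None = None,
) -> SensitivityTrajectory:
    """Jointly integrate all r sensitivity functions psi_j on eta's grid.

    The stacked vector z = [psi_1; ...; psi_r; eta] obeys a single linear ODE
    with A(kbar) on every diagonal block and dA/dk_j coupling eta into psi_j;
    it is stepped exactly by matrix exponential, so the returned Psi matches
    the state integrator's discretization.
    """
    if times is None:
        times = eta.times
    times = _check_times(np.asarray(times))
    if len(times) != len(eta.times) or not np.allclose(times, eta.times):
        raise ValueError("sensitivity grid must match the state trajectory grid")
    dyn = build_system_matrices(net, kbar)
    jac = rate_jacobians(net, kbar)
    n, r, m = net.n_species, net.n_rules, dyn.n_inputs

    big = np.zeros(((r + 1) * n, (r + 1) * n))
    bigB = np.zeros(((r + 1) * n, max(m, 1)))
    for j in range(r):
        sl = slice(j * n, (j + 1) * n)
        big[sl, sl] = dyn.A
        big[sl, r * n:] = jac[j][0]
        if m:
            bigB[sl, :m] = jac[j][1]
    big[r * n:, r * n:] = dyn.A
    if m:
        bigB[r * n:, :m] = dyn.B

    u_fn = as_input_function(u, m)
    steps = _StepCache(big)
    z = np.zeros((r + 1) * n)
    z[r * n:] = eta.states[0]
    psi = np.zeros((len(times), n, r))
    for i in range(len(times) - 1):
        dt = times[i + 1] - times[i]
        Phi, Gamma = steps(dt)
        b = bigB[:, :m] @ u_fn(times[i]) if m else np.zeros((r + 1) * n)
        z = Phi @ z + Gamma @ b
        psi[i + 1] = z[: r * n].reshape(r, n).T
    return SensitivityTrajectory(times, psi)


def build_augmented_system(
    net: FlowNetwork,
    kbar: RateParameters,
    j: int,
    G: np.ndarray | None = None,
    Q: np.ndarray | None = None,
) -> AugmentedDynamics:
    """Assemble the 2N system over [psi_j; eta] for parameter index ``j`` (0-based)."""
    if not 0 <= j < net.n_rules:
        raise IndexError(f"parameter index {j} out of range for r={net.n_rules}")
    dyn = build_system_matrices(net, kbar)
    dAj, dBj = rate_jacobians(net, kbar)[j]
    n = net.n_species
    A_aug = np.block([[dyn.A, dAj], [np.zeros((n, n)), dyn.A]])
    B_aug = np.vstack([dBj, dyn.B])
    if G is None:
        # process noise enters on the state rows only
        G = np.vstack([np.zeros((n, n)), np.eye(n)])
    if Q is None:
        Q = 1e-2 * np.eye(np.atleast_2d(G).shape[1])
    labels = tuple(f"psi_{net.rate_names[j]}:{sp}" for sp in net.species) + net.species
    return AugmentedDynamics(A_aug, B_aug, G, Q, labels, net.input_channels)
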