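# wardflow

Estimation and short-horizon forecasting of patient flow through hospital
wards and transport stages, for operations analysts and modellers who need a
live picture of where patients (or porter orders) are piling up and which
process rates have drifted away from their nominal values.

## What it does

A flow network is written as transfer rules over labelled nodes, e.g.

```
0 -> WAIT @ k0 [u_arrivals]     # admissions feed the waiting node
WAIT -> TRANSIT @ k1            # dispatch into transport
TRANSIT -> 0 @ k2               # completion / discharge
```

Each non-source rule is first-order mass action with a single unit-coefficient
driver node, so the network compiles to the linear model

    d/dt eta(t) = A(k) eta(t) + B(k) u(t),

where eta is the vector of node counts, u the exogenous inputs and
k = (k_1, ..., k_r) the per-minute rate constants. Both matrices are linear in
k, and the sensitivity functions psi_j = d eta / d k_j obey the companion ODE

    d/dt psi_j = A psi_j + (dA/dk_j) eta + (dB/dk_j) u,  psi_j(0) = 0.

Estimation is a two-stage scheme:

1. **State stage.** A continuous-discrete Kalman filter propagates mean and
   covariance of the stochastic flow model between irregularly spaced,
   time-stamped node-count observations z(t_n) = H x(t_n) + v(t_n) and
   assimilates each one (Joseph-form update, Van Loan discretization).
   The same machinery forecasts the flow beyond the last observation, and the
   block-augmented system over [psi_j; eta] supports joint
   sensitivity/state filtering.
2. **Parameter stage.** The discrepancy y(t) between the filtered state and
   the nominal-model state is, to first order, Psi(t) dk. Recursive least
   squares with exponential forgetting a integrates

       d dk_hat/dt = P Psi' e,   e = y - Psi dk_hat,
       d P/dt      = a P - P Psi' Psi P,

   whose inverse gain is the exponentially weighted Fisher information
   R(t) = int_0^t exp(-a(t-s)) Psi'Psi ds (dR/dt = -aR + Psi'Psi). The
   nominal rates are refreshed to k_bar + dk_hat each cycle so the
   linearization tracks the estimate.

A synthetic-data module supplies validation inputs: exact Gaussian sample
paths of the linear stochastic model, and a seeded discrete-event simulation
of a hospital porter workflow (orders arrive by an inhomogeneous Poisson
process with morning/afternoon demand peaks, queue for one of 80 porters, and
pass through searching / walking / migrating stages whose lognormal durations
are moment-matched to observed statistics: 5.37/10.66, 4.00/3.56 and
9.025/7.13 minutes).

## Worked example

Recover a 10% drift of all three rates of the tandem network above from 480
one-minute observations of the two node counts (low observation noise,
square-wave admissions input):

```python
import numpy as np
import wardflow as wf

net = wf.parse_rule_file(
    "0 -> WAIT @ k0 [u_arrivals]\nWAIT -> TRANSIT @ k1\nTRANSIT -> 0 @ k2\n"
)
kbar = wf.RateParameters.from_dict(net, {"k0": 1.0, "k1": 0.2, "k2": 0.1})
ktrue = kbar.with_values(1.10 * kbar.values)

u = lambda t: np.array([4.0 if (int(t) // 60) % 2 == 0 else 8.0])
times = np.arange(0.0, 481.0, 1.0)
om = wf.ObservationModel(np.eye(2), 0.05**2 * np.eye(2))
dyn_true = wf.build_system_matrices(net, ktrue, Q=1e-4 * np.eye(2))
_, series = wf.simulate_linear_sde(dyn_true, np.zeros(2), u, times, om, seed=42)

res = wf.two_stage_estimate(
    net, kbar, series, om,
    wf.EstimatorConfig(a=0.01, burn_in_epochs=60),
    u=u, process_noise=1e-4,
)
for name, est in zip(net.rate_names, res.k_final):
    print(name, round(est, 4))
```

prints

```
k0 1.1168
k1 0.2286
k2 0.111
```

i.e. each rate is recovered within 5% of its true value (1.100, 0.220, 0.110)
starting from nominals that were 10% off. `res` also carries the full
dk_hat/k_hat trajectories, the filtered states, the innovation sequence, the
terminal gain matrix P and Fisher information, and an identifiability flag
(smallest Fisher eigenvalue past burn-in).

The same pipeline is scriptable from the shell: `wardflow simulate`,
`calibrate`, `filter`, `estimate` and `forecast` read a YAML config (network
file, rates, observation model, estimator settings, seed) and exchange plain
CSV; see `wardflow --help`.

`TwoStageRateEstimator` and `KalmanFilter` are scikit-learn-style estimators
(`fit`, `get_params`/`set_params`, trailing-underscore fitted attributes) for
use in parameter sweeps and pipelines; the module-level functions above are
thin wrappers over them.

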