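# Methods

## Flow model

A network is a set of transfer rules over labelled nodes. Rule j consumes
`a_ij` units of node i and produces `b_ij` units, at a rate governed by the
constant `k_j` (per minute). In linear mode every non-source rule must have
exactly one input node with coefficient 1 (its *driver* d(j)), and its flow
rate is first-order mass action, v_j = k_j * eta_{d(j)}. This is the only
reading under which the compiled model

    d/dt eta = A(k) eta + B(k) u

is genuinely linear; rules with several input nodes or non-unit driver
coefficients are rejected rather than silently linearized. Source rules
(empty input side) are driven by a named exogenous channel and enter through
B with entry k_j * b_ij; sink rules remove items at k_j * eta_{d(j)}.
Stoichiometric coefficients are nonnegative integers, rates nonnegative
reals, and rates are treated as constant in time. Consequences used by the
tests: A and B are linear and homogeneous in k; for unit-conserving networks
(every rule has equal input and output unit totals) the columns of A sum to
zero, so the total count is an exact invariant.

The per-parameter derivatives dA/dk_j, dB/dk_j are the unit-rate
contributions of rule j and are constant in k.

## Integration

State and sensitivity ODEs are stepped exactly: per grid interval the
transition matrix is a matrix exponential and the (piecewise-constant,
left-endpoint) input enters through the block-exponential integral
`int_0^dt expm(A s) ds`. All r sensitivities are integrated jointly as one
(r+1)N block upper-triangular linear system, so Psi is consistent with the
state integrator's discretization to machine precision. The 2N augmented
system over x = [psi_j; eta] -- A on both diagonal blocks, dA/dk_j in the
upper-right, zero lower-left -- reproduces the sensitivity ODE exactly when
expanded and is what the filter propagates in joint sensitivity/state use.
Per-parameter augmentation (r separate 2N systems) is used instead of one
(r+1)N stochastic system because the psi_j do not couple and the covariance
bookkeeping stays simple.

Process noise is modelled entirely at the filter level (intensity Q on the
state rows through the injection map G, default identity); the deterministic
integrators carry no noise term. Q defaults to 1e-2 * I per minute and is a
config knob: nothing in the rule file determines how uncertain the rates
are, so the noise intensity expresses the modeller's trust in the nominal
model.

## Continuous-discrete Kalman filter

Between observations the mean propagates by d xhat/dt = F xhat + B u and the
covariance by the Lyapunov equation d Sigma/dt = F Sigma + Sigma F' + G Q G',
discretized exactly (Van Loan). F is the system matrix of whatever
LinearDynamics is supplied -- the plain A(k) in state-only use, the augmented
block matrix in joint use. At each observation the standard update with gain
K = Sigma H'(H Sigma H' + R_obs)^-1 is applied; the covariance uses the
Joseph form internally (algebraically equal to (I - KH) Sigma, but PSD-safe),
and the innovation sequence is recorded. Observation spacing may be
irregular.

Initialization is not dictated by the model; the default is a pseudo-inverse
lift of the first observation, xhat(0) = pinv(H) z(0), with Sigma(0) =
sigma0^2 I (sigma0 default 10 counts). This is a deliberate package choice,
exposed in config.

## Recursive rate estimation

The stage-2 regression target is y(t) = eta_hat(t) - eta_model(t), the
discrepancy between the filtered state and the nominal-model state evaluated
at the same instant; to first order y = Psi dk. The forgetting-RLS dynamics
and the Fisher-information ODE (see README) are discretized with one shared
rule: per step of length dt, with lambda = exp(-a dt), the information
quantity advances by

    lambda * (previous) + dt/2 * (lambda * Psi_prev' Psi_prev + Psi' Psi),

i.e. exact exponential decay plus trapezoidal quadrature of the Psi'Psi
inflow. P^-1 and R follow the same recursion, so with matched initialization
(P(0)^-1 = R(0)) the duality P(t) R(t) = I holds to machine precision at
every step -- this is the checkable form of the claimed correspondence
between the recursive estimator and Fisher information. The estimate drive
P Psi' e is also trapezoidal (Heun-style, explicit residual at the right
endpoint). Each step function keeps its own previous-regressor slot inside
EstimatorState so rls_step and fisher_step remain consistent regardless of
call order. Since R(0) = 0 makes P(0) undefined, P(0) = p0 * I with p0 = 1e4
by default.

The loss these dynamics minimize is the exponentially weighted integral of
the squared residual norm; the forgetting rate a (per minute, default 0.1;
the validation scenarios use 0.01 to retain transient information) trades
tracking speed against variance. With a > 0 and persistent excitation the
Fisher information stays bounded; with a = 0 it accumulates monotonically.

### The two-stage loop

Per observation epoch: (stage 1) the nominal model state and the sensitivity
matrix are integrated at the current nominal rates and the filter is advanced
to the epoch and updated; (stage 2) the residual y is formed and one
RLS/Fisher step taken. In refresh mode (default) the nominal rates are reset
to k_bar + dk_hat every `cadence` epochs, and the model/sensitivity
integration re-anchors at the filtered state with Psi reset to zero; the
regression target is y + Psi dk_frozen so dk_hat always measures the total
perturbation from k_bar. The fixed point of this loop is the true rate
vector: when the current rates match the truth the expected residual
vanishes, so Kalman-gain shrinkage of y affects convergence speed but not the
limit. Estimated rates are clipped at zero (rates are nonnegative); no other
constraints are applied. A no-refresh mode (fixed linearization at k_bar,
globally integrated model and sensitivities) exists for linear-theory tests
such as the duality checks. Identifiability is flagged from the smallest
Fisher eigenvalue after a configurable burn-in.

The "entropy fluctuation tensor" sometimes invoked for observation
uncertainty is exposed simply as the configurable noise intensity Q (the
inverse of an information matrix on the rate coefficients); no further
structure is assumed.

## Synthetic generators

`simulate_linear_sde` draws exact Gaussian sample paths (matrix-exponential
mean, Van Loan step covariance, eigenvalue square root for sampling) plus
discrete observations with covariance R_obs; with the noise set to zero it
reproduces the deterministic integrator, and given a seed it is bit
reproducible. This is the well-specified regime: when the filter and
estimator pass their tests on these paths, it shows correctness of the
algorithms under the model's own assumptions, not robustness to model error.

`simulate_porter_day` is a discrete-event simulation (heap-based event loop)
of porter dispatch. Orders arrive by an inhomogeneous Poisson process whose
piecewise-constant daily profile integrates to the configured volume
(default 1,000 orders/day): a small overnight trickle (weight 0.15), a
daytime base 07:00-22:00, and 3x base during the two demand peaks
10:00-12:00 and 14:00-17:00. Orders queue for one of 80 porters (higher
priority first -- classes very urgent / urgent / normal with weights
0.05/0.25/0.70 -- FCFS within a class, no preemption), and the assigned
porter is held through three stage durations drawn independently per order:
searching, walking, migrating. The stage distributions default to lognormal,
moment-matched to the observed means/SDs (searching 5.37/10.66, walking
4.00/3.56, migrating 9.025/7.13 minutes); lognormal is the default because a
searching SD nearly twice its mean rules out symmetric families, and gamma
and deterministic variants are available. Completion reporting time is
treated as zero. The 20-minute completion target and the peak windows are
part of the frozen preset.

What the DES does *not* capture: geography and lift capacity (absorbed, if at
all, into the walking/migrating distributions), time-of-day dependence of the
*service* stages (stage durations are iid all day, so congestion enters only
through queueing for porters), dispatcher behaviour beyond priority-FCFS, and
any correlation between stages of one order.

A consequence worth stating plainly: with independent stage durations
moment-matched to those statistics, the probability that searching + walking
+ migrating alone exceeds 20 minutes is about 0.31 (the stage total has mean
18.4 and SD ~13 minutes, so the target sits only ~0.12 SD above the mean).
Queueing can only add to completion times, so under this generator the
peak-window fraction of orders missing the 20-minute target has a floor of
about 31% regardless of the arrival profile or porter count; the calibration
run reports the honest computed value (~31% at the stated operating point)
rather than the ~20% sometimes quoted for peak-hour shortfalls, which is not
reachable by any independent-stage model matched to these moments.

## Problem sizes and numerics

The validation scenarios use the three-rule tandem network (2 nodes, 3
rates), 480 one-minute observation epochs, a 10% rate perturbation, process
noise 1e-4 and observation SD 0.05 counts, with a square-wave admissions
input (4 vs 8 per minute, alternating hourly) -- steady flows leave the
all-rates-proportional direction unidentifiable, so the input is deliberately
persistently exciting. Service-time calibration uses 200,000 draws per stage;
the DES calibration accumulates >= 50,000 peak-window orders (~90 simulated
days). Covariances are symmetrized after every update and checked against an
eigenvalue floor of -1e-10; the RLS gain is refused (with a clear error) if
it loses positive definiteness; matrix exponentials are cached per step size,
so uniform grids cost one decomposition each.

## Known limitations

Flow rates are linear only; saturating or state-dependent capacities are out
of scope (the DES exhibits them, the ODE model does not -- that gap is
precisely what the perturbation estimator is meant to absorb locally).
Rates are constant in time within a run; slow drift is tracked only through
the forgetting factor. The estimator returns point estimates with P as a
relative (not calibrated) uncertainty measure. No smoothing, nonlinear
filtering, or adaptive noise estimation.
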