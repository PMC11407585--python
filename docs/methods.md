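# Methods

## The event model

A single gene copy cycles through four stochastic events. The active phase
is a run of `E_P` events — each `E_P` ends with one polymerase entering
productive elongation, releasing exactly one transcript — extended with
probability `p1` after each completion. When the run ends, the inactive
phase begins: `E_S1` (scaffold disassembly), an optional geometric run of
`E_S3` (nucleosome-governed denial of promoter access, continuation
probability `p2` checked after `E_S1` and after every `E_S3`), then `E_S2`
(PIC assembly), after which a new burst starts with probability `p1`,
otherwise another inactive cycle follows. Mature mRNA decays independently
with exponential lifetime `tau_m` (each molecule is assigned a lifetime at
synthesis — statistically identical to a first-order degradation channel,
and easier to verify). All times are minutes; `tau_m` defaults to 5 min.

Event durations default to exponential distributions. Gamma and
delayed-exponential families are supported because the downstream results
depend only weakly on the shape as long as it is unimodal, and because a
refractory period at the start of the inactive phase is naturally modelled
as a hard offset on `E_S1`. `p1 = 0` (no bursting) and `p2 = 0` (no `E_S3`)
are legal degenerate inputs; `p = 1` is rejected (infinite expectations).
A single-exponential inactive block of mean `tau_S`
(`BurstParams.from_inactive_mean`) is the reduced parameterization used for
most closed-form work; the general composition is
`tau_S = tau_S1 + tau_S2 + p2 tau_S3/(1-p2)`.

The chromatin-opening and terminal silencing events that bracket the whole
expression episode are deliberately not simulated as timed events: they are
initial-condition devices only (see Transient response), since no kinetics
are attached to them anywhere in the model.

## Exact steady state

Completed `E_P` events form a renewal process: one inter-synthesis interval
is an `E_P` duration plus, with probability `1-p1`, a complete inactive
phase (a Geometric(`p1`) number of cycles). Filtering the renewal point
process through exponential survival gives the stationary moments exactly:

    <m>      = b f tau_m
    sigma^2  = <m> + <m> * uhat(1/tau_m) - <m>^2,   uhat = fhat/(1 - fhat)

where `fhat(s)` is the Laplace transform of the interval. Every supported
duration family has a closed-form transform, so the variance is exact for
arbitrary event shapes, including the refractory offset — this is what the
constraint scan uses. For the single-exponential inactive block the result
reduces algebraically to

    sigma^2 = <m> + <m>^2 [(c+d) s - c d] / (c + d + c d)
    F       = 1 + [d(b-1) - b c d/(c+d)] / (c + d + c d)

with `c = tau_A/tau_m`, `d = tau_I/tau_m`, `s = tau_S/tau_m`. Both compact
forms are exposed (`variance_closed_form`, `fano_closed_form`) and tested to
agree with the renewal expression to 1e-10; for multi-component inactive
phases they are a means-only approximation while `variance_and_fano`
remains exact.

Consequences verified in the test suite: the Poisson limit `F -> 1` as
`tau_S -> 0`; the instantaneous-burst limit `F -> b` as `tau_P -> 0`
(cross-checked against a truncated master equation); the fixed-`tau_P`
bounds `<m> < tau_m/tau_P` and `F < 1 + tau_m/tau_P`; and a small
*sub-Poissonian* dip (`F` slightly below 1) just before the always-active
limit, because one-transcript-per-`E_P` synthesis is more regular than a
Poisson process. Due to that dip, the slope `dF/d<m>` along the
`tau_S`-regulated path (`fano_slope`, implemented as the exact analytic
derivative and validated against centered finite differences) approaches
`+tau_P/tau_m`, not zero, at the very end of the path; it is negative over
essentially the whole observable range.

The burst height `h ~ tau_m(1-e^-c)(1-e^-d)/[tau_P(1-e^-(c+d))]` for
`tau_P < tau_m` (else `h ~ 1`) is an approximation: it is tested against
simulated per-burst maxima at 15% tolerance and no continuity is claimed at
the regime boundary.

`fano_lower_bound` evaluates `F` at the corner (`tau_S0`, `p10`) of the
admissible region with `tau_P` eliminated through the mean. The corner is
the constrained minimum in the high-expression regime; at the margin of the
validity condition (`<m>` just above `tau_m/(2 tau_S0)`) an interior point
can undercut it by a few percent, so the grid-minimization agreement test
starts at `<m> = 10` for `tau_S0 = 1, tau_m = 5`.

## Regulation

Regulator occupancy `O(R) = R^n_H/(R^n_H + K_d^n_H)` rescales exactly one
elementary *rate* per basic mode. Because binding accelerates (or blocks) a
reaction, interpolation is linear in the rate, never in the duration:
`1/tau(O) = (1-O)/tau_U + O/tau_B` for duration modes, and
`J(O) = (1-O) J_U + O J_B` with `p = J+/(J+ + J-)` for the flow modes
(MIE/MFA scale the flow favouring the change; MIA/MFC suppress the opposing
flow; the endpoint `p_B = eps p_U` fixes the scale factor, e.g.
`lam = eps(1-p_U)/(1-eps p_U)` for MIE). Under this convention a single
mode with `n_H = 1` yields an exactly Mobius mean rate
`v(R) = v_max (beta + R)/(Omega + R)` whose half-response point satisfies
`Omega = beta F_v`; the closed forms (duration modes: `beta = eps K_d`;
MIE/MFA: `beta = K_d/lam`; MIA/MFC: `beta = K_d`) match a numeric half-max
search to machine precision, which is the test that pins the convention
down. Linear-in-duration interpolation is *not* equivalent: it yields
`beta = K_d` for duration modes and `Omega > K_d`, contradicting the
closed-form table; this is why the package rejects it. For `n_H != 1` the
same forms hold in `R^n_H` with exponent `n = n_H` exactly; combined modes
fall back to a numeric half-max search plus a fitted exponent.

Valid mode combinations touch disjoint parameters (at most one of
{MIE, MIA} and one of {MFC, MFA}): 143 of the 255 non-empty subsets.

Specificity compares cognate binding (`K_d`) against non-target binding
(`nontarget_fold * K_d`, default 100); its maximum approaches the fold
change `F_v` as the fold grows (tested at 10% for fold 100, 1% for 1e4).
Dose-response log-sensitivities `S_b = dln b/dln <m>` and `S_f` are
analytic chain-rule derivatives along the occupancy path; `m = b f tau_m`
makes `S_b + S_f = 1` hold to rounding. The burst frequency peaks exactly
where `tau_A = tau_I`.

## Transient response

With exponential events the inactive phase is a 3-phase (S1, S3, S2)
phase-type distribution; its first two moments are exact matrix
expressions, and the analytic curves use the Gamma distribution matched to
them (`f_I ~ Gamma(alpha_I, theta_I)`); the exact phase-type density is
available as a cross-check (`inactive_density="exact"`). The active phase
is exactly exponential with mean `tau_A` (a geometric sum of exponentials).
The renewal series

    P_A(t) = f_I_init * sum_i (f_A * f_I)^{*i} * exp(-t/tau_A)
    <m>(t) = (1/tau_P) exp(-t/tau_m) * P_A(t)

is evaluated by trapezoidal grid convolution, truncating once a term's
grid mass drops below 1e-8. Equivalently (exactly, by commutativity and
`exp(-t/tau_A) = tau_A f_A`), `P_A = tau_A sum_i f_first * (f_I*f_A)^{*i}`
with `f_first = f_A * f_I_init` the first-burst duration; this second entry
point accepts a Gamma-matched `f_first` directly. Note a structural
constraint: any legal `f_first` is a convolution with `f_A`, hence bounded
by `1/tau_A` and with `CV_first < 1` whenever its mean exceeds `tau_A`;
Gamma inputs violating this (shape <= 1) produce a spurious density spike
at zero and are outside the model.

Default grid: `dt = min(tau_A, theta_I, tau_m)/50`, horizon
`10 max(T, tau_m)`; a `check_resolution` flag re-runs at `dt/2` and raises
if `t_re` shifts by more than 1%. Peaks are flagged as overshoots only
beyond 0.5% above steady state, to suppress grid noise.

Per-mode initial conditions encode where the silent gene was parked:

* MEE (`tau_P` silenced): in `E_P`, paused polymerase poised to fire —
  activation at t = 0 (`P_A(0) = 1`, `<m>(0) = 0`);
* MFI: in `E_S2`; MEA: in `E_S1` (the full inactive phase, `f_I_init =
  f_I`); MCC, MFA, MFC: in `E_S3` (hence MCC and MFA respond identically);
* MIE, MIA (`p1` silenced): the gene cycles through the inactive chain
  indefinitely, so the initial phase is the stationary time-weighted mix —
  equivalently `f_I_init` is the equilibrium residual of `f_I`. All initial
  conditions are exact phase-type distributions; no extra approximation
  enters beyond the Gamma `f_I` in the series.

Overshoot thresholds: with `alpha_P = 1/CV_first^2`,
`alpha_m = (tau_m+tau_first)^2/(tau_m^2 + tau_first^2 CV_first^2)`,
`delta_P = 0`, `delta_m = tau_m`,

    h_x = [alpha_x/(delta_x + tau_first)] (alpha_x-1)^(alpha_x-1)
          e^-(alpha_x-1) / Gamma(alpha_x),

`h_x T > 1` is a *sufficient* condition for overshoot (it bounds the peak
using the first renewal term only). On the exact curves, overshoot persists
down to `h T ~ 0.65`; the tests therefore assert sufficiency plus its
contrapositive (no non-overshooting point above the threshold band), not a
two-sided boundary match.

Response times: `t_GA` and `t_re` are the first crossings of half the
stationary `P_A` and `<m>` (linear interpolation between grid points);
`t_re < tau_m ln 2` marks the production-limited regime in which
synchronized early bursts outrun the degradation clock.

### Scenario diagram

`classify_scenario` places an inactive-phase composition
(`x = tau_S2/tau_S1`, `y = tau_S3/tau_S1`, `p2`) into one of four regions
bounded by `y = 1/(x+1)`, `y = 1` and `y = (1+sqrt(1+4x(1-p2)/p2))/2`, each
associated with a canonical `t_re` ordering of the six activating modes
(MEE always fastest, MFI second; MCC and MFA always tied). The `y = 1`
boundary — where MEA and MCC/MFA trade places — is exact: their initial
means differ by exactly `tau_S3 - tau_S1`. The other two closed-form
boundaries involve MIE, whose crossings they only approximate: a
moment-matching derivation that drops the `E_S2` cross term in the
inactive-cycle variance places the MEA/MIE crossing at the third boundary,
whereas the exact crossing satisfies `r y(y-1-x) = x` in the mean
(`r = p2/(1-p2)`) and, with distribution shapes included, sits somewhat
above even that (the higher-variance MIE initial condition crosses
half-steady-state first when the means tie). Likewise the exact MIE vs
MCC/MFA crossing lies at roughly half the reference `1/(x+1)` height. The
package keeps the closed-form boundaries in `classify_scenario` (they are
the field's reference diagram) and computes orderings honestly via
`compare_modes`; the property tests assert the MIE-free orderings exactly
at region interiors, all four canonical orderings across the plane, and
document the displaced MIE crossings. A practical consequence: of the four
reference compositions (15,2,4), (10,20,6), (3,10,15), (5,20,8), the last
two fall on the same side of the exact MEA/MIE crossing and produce the
same ordering, so the orderings realized over those particular four sets
number three, not four — the four distinct scenarios appear only once the
compositions straddle the exact crossings. This is the package's computed
result, triple-checked against phase-level Monte Carlo and raw event-level
simulation with an explicit silent-state burn-in.

## Constraint scan

Bursting parameter sets are sampled with the burst period log-uniform in
[1, 1000] min (or, with `duration_interpretation="active"`, the active
phase itself), the transcription rate `1/tau_P` log-uniform in [0.1, 100]
per min, a uniform active fraction with rejection of `tau_A >= tau_I`, and
`p1 = 1 - tau_P/tau_A` (rejecting infeasible sets). The refractory period
(1/5/10 min) enters the exact renewal variance as a delayed-exponential
offset on the inactive block, and its main effect on the scan is through
feasibility: it removes the fast-cycling sets that would otherwise reach
high expression at low noise, raising the lower Fano envelope.

The telegraph comparator uses the same rate mapping (`k_on = 1/tau_I`,
`k_off = 1/tau_A`, `k_syn = 1/tau_P`) but samples its three rates
*independently* within the same ranges. This is the point of the
comparison: at matched parameter sets the telegraph lower envelope is
algebraically tied to the event model's
(`F_tel - 1 = m d^2/(c+d+cd)` vs `F_evt - 1 = d(m d - 1)/(c+d+cd)`), so a
coupled comparator would reproduce the same rising floor; only the absence
of the event-structure correlations (`b = tau_A/tau_P` forced, `tau_A <
tau_I`) lets high expression coexist with near-Poisson noise. A
`coupled_telegraph=True` flag restores the matched-set variant for
inspection.

## Mean-Fano fitting

`mf_curve` traces the (mean, Fano) trajectory of a regulation path using
the exact stationary formulas; `fit_mf_data` minimizes summed squared
orthogonal-projection distances in (log m, log F) space (dense occupancy
grid plus point-to-segment refinement) with a bounded Nelder-Mead simplex,
10 seeded multi-starts and a final polish restart. Because the regulation
path is a straight line in (odds `p1`, `1/tau_S`) coordinates, the curve
*as a point set* does not identify where the unstimulated baseline and the
saturated endpoint sit on it; the loss therefore also anchors the lowest-
and highest-expression data points to the occupancy-0/1 curve ends. The
synthetic-data generator samples occupancies stratified-uniformly with both
endpoints included (the unstimulated and saturated conditions are observed
in a dose-response experiment) and applies independent mean-one log-normal
noise (CV `noise_cv`) to the mean and Fano of each point.

Identifiability, measured by the self-consistency study in the test suite
(5-parameter frequency/size trajectory, n = 30 points, 5% noise, 20 seeds):
`tau_P` and the bound-state parameters are recovered to ~1% median error,
the baseline `p1U` to ~4%, but the baseline `tau_SU` only to ~11% — the
baseline end of the curve is informed by a single anchored point, and error
propagation through the (p1U, tau_SU) pair amplifies its 5% noise to ~12%
(sd of `ln tau_SU`), so this is at the information limit of those
conditions rather than an optimizer artifact. Noise-free round trips
recover all parameters to better than 0.1%.

## Problem sizes and tolerances

The default test suite uses ensembles of 1e4 trajectories (51 parameter
sets for the simulation-vs-formula check, with a 2-of-153 multiplicity
allowance at 3 Monte-Carlo SEs), 1e5 draws for duration-moment checks, 1e4
bursts for distributional chi-square/KS checks (p > 0.01 at fixed seeds), a
20x20 overshoot grid, 1e4-set constraint scans, and 20-seed fitting
studies; everything completes in a few minutes on one core. Convolution
grids resolve the shortest timescale with 50 points and truncate renewal
series at 1e-8 residual mass; closed-form identities are asserted at
1e-9..1e-12.

## Known limitations

* Intrinsic noise only: no extrinsic parameter variability, cell-cycle or
  multi-allele effects, and a one-step mRNA maturation/degradation channel.
* The analytic transient machinery requires exponential event durations
  (the phase-type construction); gamma/delayed events are supported in the
  steady-state formulas and simulators.
* The Gamma approximation of `f_I` is a two-moment match; mode orderings
  within ~1% of each other should be resolved with the exact phase-type
  density or the simulators.
* The compact Fano forms assume a single-exponential inactive block;
  `variance_and_fano` is exact in general and should be preferred.
* Dose-response curves assume a single regulator at thermodynamic
  occupancy with fast binding kinetics relative to the burst cycle.
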