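"""Transient response to a step rise in regulator concentration.

After stimulus onset the gene alternates between active phases (exponential,
mean ``tau_A``) and inactive phases, starting with a first inactive interval
drawn from ``f_I_init`` whose form encodes *where in the burst cycle the gene
was silenced* — and therefore which regulatory mode silenced it.  The mean
activation probability and copy number follow the renewal series

    P_A(t) = f_I_init * sum_i (f_A * f_I)^{*i} * exp(-t/tau_A),
    <m>(t) = (1/tau_P) exp(-t/tau_m) * P_A(t),

evaluated here by discretized convolution.  With exponential events the
inactive phase is exactly a 3-phase (E_S1, E_S3, E_S2) phase-type
distribution; ``f_I`` is approximated by a moment-matched Gamma (the exact
phase-type density is available as a cross-check), and per-mode initial
conditions are phase-type distributions started from the phase in which the
silent gene was parked:

* MEE — in E_P (paused Pol II poised to fire): activation at t = 0;
* MFI — in E_S2; MEA — in E_S1 (the full inactive phase); MCC/MFA/MFC — in
  E_S3; MIE/MIA — the stationary phase mix of the endlessly cycling
  (p1 = 0) inactive chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.signal import fftconvolve
from scipy.stats import gamma as gamma_dist

from .core import BurstParams, InvalidParameterError, derive_quantities

__all__ = [
    "GammaDist",
    "ExpDist",
    "PointMass",
    "PhaseType",
    "PhaseDistributions",
    "TransientCurves",
    "ScenarioClass",
    "GridResolutionError",
    "inactive_phase_type",
    "mode_initial_phase",
    "gamma_match",
    "phase_distributions",
    "transient_curves",
    "overshoot_criterion",
    "response_times",
    "classify_scenario",
    "compare_modes",
    "ordering_string",
    "TRANSIENT_MODES",
]

TRANSIENT_MODES = ("MEE", "MFI", "MIE", "MEA", "MFA", "MCC")


class GridResolutionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# duration distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GammaDist:
    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def var(self) -> float:
        return self.shape * self.scale**2

    @property
    def cv2(self) -> float:
        return 1.0 / self.shape

    def sample(self, rng, size=None):
        return rng.gamma(self.shape, self.scale, size)

    def grid_density(self, t: np.ndarray, dt: float) -> np.ndarray:
        if self.shape >= 1.0:
            return gamma_dist.pdf(t, self.shape, scale=self.scale)
        # integrable singularity at 0: use cell averages
        edges_hi = t + dt / 2.0
        edges_lo = np.clip(t - dt / 2.0, 0.0, None)
        cdf_hi = gamma_dist.cdf(edges_hi, self.shape, scale=self.scale)
        cdf_lo = gamma_dist.cdf(edges_lo, self.shape, scale=self.scale)
        return (cdf_hi - cdf_lo) / dt


def ExpDist(mean: float) -> GammaDist:
    """Exponential distribution as a shape-1 Gamma."""
    return GammaDist(1.0, mean)


@dataclass(frozen=True)
class PointMass:
    t0: float = 0.0

    @property
    def mean(self) -> float:
        return self.t0

    @property
    def var(self) -> float:
        return 0.0

    def sample(self, rng, size=None):
        return np.full(size, self.t0) if size is not None else self.t0


class PhaseType:
    """Absorption time of a transient continuous-time Markov chain.

    ``pi`` is the initial phase distribution, ``Q`` the sub-generator over
    transient phases; the absorption (exit) rates are ``-Q @ 1``.
    """

    def __init__(self, pi: np.ndarray, Q: np.ndarray, labels=None):
        self.pi = np.asarray(pi, dtype=float)
        self.Q = np.asarray(Q, dtype=float)
        self.labels = labels
        self._Minv = np.linalg.inv(-self.Q)
        self.exit = -self.Q.sum(axis=1)

    @property
    def mean(self) -> float:
        return float(self.pi @ self._Minv.sum(axis=1))

    @property
    def var(self) -> float:
        m1 = self._Minv.sum(axis=1)
        m2 = 2.0 * self._Minv @ m1
        return float(self.pi @ m2 - (self.pi @ m1) ** 2)

    def with_pi(self, pi) -> "PhaseType":
        return PhaseType(pi, self.Q, self.labels)

    def grid_density(self, t: np.ndarray, dt: float) -> np.ndarray:
        E = expm(self.Q * dt)
        out = np.empty(t.size)
        v = self.pi.copy()
        for k in range(t.size):
            out[k] = v @ self.exit
            v = v @ E
        return out

    def sample(self, rng, size=None):
        n = int(np.prod(size)) if size is not None else 1
        rates = -np.diag(self.Q)
        P = self.Q / rates[:, None]
        np.fill_diagonal(P, 0.0)
        P = np.column_stack([P, self.exit / rates])  # last column = absorb
        cum = np.cumsum(P, axis=1)
        state = rng.choice(self.pi.size, size=n, p=self.pi)
        t = np.zeros(n)
        active = np.ones(n, dtype=bool)
        while active.any():
            idx = np.flatnonzero(active)
            s = state[idx]
            t[idx] += rng.exponential(1.0 / rates[s])
            nxt = (rng.random(idx.size)[:, None] < cum[s]).argmax(axis=1)
            absorbed = nxt == self.pi.size
            active[idx[absorbed]] = False
            state[idx[~absorbed]] = nxt[~absorbed]
        if size is None:
            return float(t[0])
        return t.reshape(size)


# ---------------------------------------------------------------------------
# phase-type construction from burst parameters
# ---------------------------------------------------------------------------


def _require_exponential(params: BurstParams) -> None:
    if not params.all_exponential:
        raise InvalidParameterError(
            "analytic transient machinery requires exponential event durations"
        )


def _phase_layout(params: BurstParams):
    labels = ["S1"]
    if params.p2 > 0 and params.tau_S3 > 0:
        labels.append("S3")
    if params.tau_S2 > 0:
        labels.append("S2")
    return labels


def inactive_phase_type(params: BurstParams) -> PhaseType:
    """Exact phase-type representation of the inactive-phase duration.

    Phases are the inactive events present in the flow; absorption is entry
    into E_P.  Requires ``p1 > 0`` and exponential event durations.
    """
    _require_exponential(params)
    if params.p1 == 0.0:
        raise InvalidParameterError("inactive phase is infinite for p1 = 0")
    labels = _phase_layout(params)
    ix = {s: i for i, s in enumerate(labels)}
    n = len(labels)
    p1, p2 = params.p1, params.p2
    has_S3 = "S3" in ix
    has_S2 = "S2" in ix
    Q = np.zeros((n, n))

    def land_after_s_branch(row: int, rate: float, weight: float) -> None:
        # weight*rate of flow leaving toward "E_S2 or checkpoint"
        if has_S2:
            Q[row, ix["S2"]] += weight * rate
        else:
            # immediate checkpoint: back to S1 w.p. (1-p1), absorb w.p. p1
            Q[row, ix["S1"]] += weight * rate * (1.0 - p1)

    taus = {"S1": params.tau_S1, "S3": params.tau_S3, "S2": params.tau_S2}
    for s in labels:
        r = 1.0 / taus[s]
        Q[ix[s], ix[s]] = -r
        if s in ("S1", "S3"):
            if has_S3:
                Q[ix[s], ix["S3"]] += p2 * r
                land_after_s_branch(ix[s], r, 1.0 - p2)
            else:
                land_after_s_branch(ix[s], r, 1.0)
        else:  # S2 -> checkpoint
            Q[ix[s], ix["S1"]] += (1.0 - p1) * r
    pi = np.zeros(n)
    pi[ix["S1"]] = 1.0
    return PhaseType(pi, Q, labels)


def mode_initial_phase(params: BurstParams, mode: str):
    """Distribution of the time from stimulus onset to the first activation.

    ``params`` are the post-stimulus (final) parameters; the mode determines
    the phase in which the silent gene was parked before the stimulus.
    """
    if mode == "MEE":
        return PointMass(0.0)
    ph = inactive_phase_type(params)
    ix = {s: i for i, s in enumerate(ph.labels)}
    pi = np.zeros(len(ph.labels))
    if mode == "MEA":
        pi[ix["S1"]] = 1.0
    elif mode == "MFI":
        if "S2" not in ix:
            raise InvalidParameterError("MFI initial condition requires tau_S2 > 0")
        pi[ix["S2"]] = 1.0
    elif mode in ("MCC", "MFA", "MFC"):
        if "S3" not in ix:
            raise InvalidParameterError(f"{mode} initial condition requires an E_S3 loop")
        pi[ix["S3"]] = 1.0
    elif mode in ("MIE", "MIA"):
        # stationary occupancy of the endlessly cycling (p1 = 0) inactive chain
        w = {"S1": params.tau_S1}
        if "S3" in ix:
            w["S3"] = params.tau_S3 * params.p2 / (1.0 - params.p2)
        if "S2" in ix:
            w["S2"] = params.tau_S2
        tot = sum(w.values())
        for s, v in w.items():
            pi[ix[s]] = v / tot
    else:
        raise InvalidParameterError(f"unknown transient mode {mode!r}")
    return ph.with_pi(pi)


# ---------------------------------------------------------------------------
# moment matching and analytic curves
# ---------------------------------------------------------------------------


@dataclass
class PhaseDistributions:
    f_A: GammaDist
    f_I: GammaDist
    f_I_exact: PhaseType | None
    f_I_init: object | None
    f_first: GammaDist | None
    tau_A: float
    tau_I: float
    T: float
    tau_first: float | None
    cv_first: float | None

    @property
    def alpha_I(self) -> float:
        return self.f_I.shape

    @property
    def theta_I(self) -> float:
        return self.f_I.scale


def gamma_match(params: BurstParams, f_I_init=None) -> PhaseDistributions:
    """Gamma moment-matching of the inactive phase and the first burst.

    The inactive phase (a geometric compound of inactive cycles) is matched
    by its exact first two phase-type moments; ``f_first = f_A * f_I_init``
    is matched likewise when an initial distribution is supplied.
    """
    der = derive_quantities(params)
    ph = inactive_phase_type(params)
    mu, var = ph.mean, ph.var
    f_I = GammaDist(mu**2 / var, var / mu)
    f_A = ExpDist(der.tau_A)
    tau_first = cv_first = f_first = None
    if f_I_init is not None:
        tau_first = der.tau_A + float(f_I_init.mean)
        var_first = der.tau_A**2 + float(f_I_init.var)
        cv_first = math.sqrt(var_first) / tau_first
        f_first = GammaDist(tau_first**2 / var_first, var_first / tau_first)
    return PhaseDistributions(
        f_A=f_A,
        f_I=f_I,
        f_I_exact=ph,
        f_I_init=f_I_init,
        f_first=f_first,
        tau_A=der.tau_A,
        tau_I=mu,
        T=der.tau_A + mu,
        tau_first=tau_first,
        cv_first=cv_first,
    )


def phase_distributions(
    tau_A: float, f_I: GammaDist, f_first: GammaDist | None = None, f_I_init=None
) -> PhaseDistributions:
    """Assemble phase distributions from explicitly given components.

    Either ``f_I_init`` (the first inactive interval) or ``f_first`` (the
    Gamma-matched first-burst duration) may drive the transient curves; when
    only ``f_I_init`` is given, ``f_first`` is moment-matched from
    ``f_A * f_I_init``.
    """
    if f_first is None and f_I_init is not None:
        tau_first = tau_A + float(f_I_init.mean)
        var_first = tau_A**2 + float(f_I_init.var)
        f_first = GammaDist(tau_first**2 / var_first, var_first / tau_first)
    tau_first = f_first.mean if f_first is not None else None
    cv_first = math.sqrt(f_first.cv2) if f_first is not None else None
    return PhaseDistributions(
        f_A=ExpDist(tau_A),
        f_I=f_I,
        f_I_exact=None,
        f_I_init=f_I_init,
        f_first=f_first,
        tau_A=tau_A,
        tau_I=f_I.mean,
        T=tau_A + f_I.mean,
        tau_first=tau_first,
        cv_first=cv_first,
    )


@dataclass
class TransientCurves:
    t_grid: np.ndarray
    P_A: np.ndarray
    m_mean: np.ndarray
    P_AP: float
    P_Ass: float
    m_peak: float
    m_ss: float
    H_P: float
    H_m: float
    t_GA: float
    t_re: float
    overshoot_P: bool
    overshoot_m: bool


def _conv(a: np.ndarray, b: np.ndarray, dt: float) -> np.ndarray:
    """Trapezoidal convolution (a * b)(t) on a uniform grid starting at 0."""
    n = a.size
    full = fftconvolve(a, b)[:n]
    return dt * full - 0.5 * dt * (a[0] * b + b[0] * a)


def _first_crossing(t: np.ndarray, y: np.ndarray, target: float) -> float:
    above = y >= target
    if not above.any():
        raise GridResolutionError(
            "curve does not reach its half-steady-state value; extend the grid"
        )
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    frac = (target - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def transient_curves(
    pdists: PhaseDistributions,
    tau_P: float,
    tau_m: float,
    t_grid=None,
    series_tol: float = 1e-8,
    inactive_density: str = "gamma",
    overshoot_tol: float = 5e-3,
    check_resolution: bool = False,
) -> TransientCurves:
    """Evaluate the renewal-series transient curves P_A(t) and <m>(t).

    The series is accumulated by forward convolution and truncated once a
    term's remaining mass on the grid drops below ``series_tol``.
    ``inactive_density`` selects the Gamma approximation (default, the
    analytic route) or the exact phase-type density (cross-check).
    A peak is flagged as an overshoot only when it exceeds the steady state
    by more than ``overshoot_tol`` (relative), avoiding grid-noise false
    positives.
    """
    tau_A, T = pdists.tau_A, pdists.T
    if t_grid is None:
        theta = pdists.theta_I
        dt = min(tau_A, theta, tau_m) / 50.0
        horizon = 10.0 * max(T, tau_m)
        t_grid = np.arange(0.0, horizon + dt, dt)
    t = np.asarray(t_grid, dtype=float)
    dt = float(t[1] - t[0])
    if not np.allclose(np.diff(t), dt, rtol=1e-8):
        raise InvalidParameterError("t_grid must be uniform")

    fA_d = np.exp(-t / tau_A) / tau_A
    if inactive_density == "gamma":
        fI_d = pdists.f_I.grid_density(t, dt)
    elif inactive_density == "exact":
        fI_d = pdists.f_I_exact.grid_density(t, dt)
    else:
        raise InvalidParameterError("inactive_density must be 'gamma' or 'exact'")
    g = _conv(fA_d, fI_d, dt)
    S_A = np.exp(-t / tau_A)

    init = pdists.f_I_init
    if init is not None:
        # P_A = f_I_init * sum_i (f_A*f_I)^i * exp(-t/tau_A)
        delta_init = isinstance(init, PointMass) and init.t0 == 0.0
        if delta_init:
            acc = g.copy()
            term = g
            extra = S_A
        else:
            if isinstance(init, PointMass):
                term = np.zeros_like(t)
                k = int(round(init.t0 / dt))
                term[min(k, t.size - 1)] = 1.0 / dt
            else:
                term = init.grid_density(t, dt)
            acc = term.copy()
            extra = 0.0
        for _ in range(100_000):
            term = _conv(term, g, dt)
            if dt * term.sum() < series_tol:
                break
            acc += term
        P_A = extra + _conv(acc, S_A, dt)
    elif pdists.f_first is not None:
        # equivalent first-burst form: P_A = tau_A * sum_i f_first * (f_I*f_A)^i
        term = pdists.f_first.grid_density(t, dt)
        acc = term.copy()
        for _ in range(100_000):
            term = _conv(term, g, dt)
            if dt * term.sum() < series_tol:
                break
            acc += term
        P_A = tau_A * acc
    else:
        raise InvalidParameterError("transient curves require f_I_init or f_first")
    m = _conv(P_A, np.exp(-t / tau_m), dt) / tau_P

    P_Ass = tau_A / T
    m_ss = P_Ass * tau_m / tau_P
    P_AP = float(P_A.max())
    m_peak = float(m.max())
    H_P = max(0.0, (P_AP - P_Ass) / P_Ass)
    H_m = max(0.0, (m_peak - m_ss) / m_ss)
    curves = TransientCurves(
        t_grid=t,
        P_A=P_A,
        m_mean=m,
        P_AP=P_AP,
        P_Ass=P_Ass,
        m_peak=m_peak,
        m_ss=m_ss,
        H_P=H_P,
        H_m=H_m,
        t_GA=_first_crossing(t, P_A, P_Ass / 2.0),
        t_re=_first_crossing(t, m, m_ss / 2.0),
        overshoot_P=H_P > overshoot_tol,
        overshoot_m=H_m > overshoot_tol,
    )
    if check_resolution:
        fine = transient_curves(
            pdists, tau_P, tau_m,
            np.arange(0.0, t[-1] + dt / 2.0, dt / 2.0),
            series_tol, inactive_density, overshoot_tol, False,
        )
        if abs(fine.t_re - curves.t_re) > 0.01 * max(curves.t_re, dt):
            raise GridResolutionError("t_re changed by >1% under grid refinement")
    return curves


def overshoot_criterion(
    tau_first: float, cv_first: float, T: float, tau_m: float
) -> tuple[float, float, bool, bool]:
    """Analytic overshoot thresholds h_P and h_m with predictions h_x T > 1.

    ``h_x = [alpha_x/(delta_x + tau_first)] (alpha_x-1)^(alpha_x-1)
    / Gamma(alpha_x) * e^-(alpha_x-1)`` with ``alpha_P = 1/CV_first^2``,
    ``alpha_m = (tau_m+tau_first)^2/(tau_m^2 + tau_first^2 CV_first^2)``,
    ``delta_P = 0`` and ``delta_m = tau_m``.  ``alpha_x <= 1`` predicts no
    overshoot.
    """
    if min(tau_first, cv_first, T, tau_m) <= 0:
        raise InvalidParameterError("all overshoot-criterion inputs must be positive")

    def h(alpha: float, delta: float) -> float:
        if alpha <= 1.0:
            return 0.0
        log_val = (
            (alpha - 1.0) * math.log(alpha - 1.0)
            - math.lgamma(alpha)
            - (alpha - 1.0)
        )
        return alpha / (delta + tau_first) * math.exp(log_val)

    alpha_P = 1.0 / cv_first**2
    alpha_m = (tau_m + tau_first) ** 2 / (tau_m**2 + (tau_first * cv_first) ** 2)
    h_P = h(alpha_P, 0.0)
    h_m = h(alpha_m, tau_m)
    return h_P, h_m, h_P * T > 1.0, h_m * T > 1.0


def response_times(curves: TransientCurves, tau_m: float):
    """(t_GA, t_re, regime): regime is production- or degradation-limited.

    ``t_re < tau_m ln 2`` indicates the rise of <m> is governed by correlated
    mRNA production (production-limited); otherwise degradation sets the
    timescale.
    """
    regime = (
        "production-limited"
        if curves.t_re < tau_m * math.log(2.0)
        else "degradation-limited"
    )
    return curves.t_GA, curves.t_re, regime


# ---------------------------------------------------------------------------
# scenario classification (inactive-phase composition phase diagram)
# ---------------------------------------------------------------------------

REGION_ORDERINGS = {
    1: "MEE < MFI < MCC,MFA < MIE < MEA",
    2: "MEE < MFI < MIE < MCC,MFA < MEA",
    3: "MEE < MFI < MIE < MEA < MCC,MFA",
    4: "MEE < MFI < MEA < MIE < MCC,MFA",
}


@dataclass
class ScenarioClass:
    region: int | None
    x: float
    y: float
    p2: float
    ordering: str | None


def classify_scenario(
    tau_S1: float, tau_S2: float, tau_S3: float, p2: float
) -> ScenarioClass:
    """Locate the inactive-phase composition in the response-scenario diagram.

    With ``x = tau_S2/tau_S1`` and ``y = tau_S3/tau_S1`` the region boundaries
    are ``y = 1/(x+1)``, ``y = 1`` and
    ``y = (1 + sqrt(1 + 4x(1-p2)/p2))/2``; a point exactly on a boundary gets
    ``region=None``.
    """
    if min(tau_S1, tau_S2, tau_S3) <= 0:
        raise InvalidParameterError("durations must be positive")
    if not 0.0 < p2 < 1.0:
        raise InvalidParameterError("p2 must lie in (0, 1)")
    x = tau_S2 / tau_S1
    y = tau_S3 / tau_S1
    b1 = 1.0 / (x + 1.0)
    b3 = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * x * (1.0 - p2) / p2))
    if y in (b1, 1.0, b3):
        return ScenarioClass(None, x, y, p2, None)
    if y < b1:
        region = 1
    elif y < 1.0:
        region = 2
    elif y < b3:
        region = 3
    else:
        region = 4
    return ScenarioClass(region, x, y, p2, REGION_ORDERINGS[region])


def compare_modes(
    params: BurstParams,
    modes=TRANSIENT_MODES,
    t_grid=None,
    tie_frac: float = 0.01,
) -> pd.DataFrame:
    """Transient response from the silent state under each regulatory mode.

    All modes share the same final parameters (hence identical steady state);
    they differ only in the phase the silent gene occupied, i.e. in
    ``f_I_init``.  Returns one row per mode sorted by the half-response time
    ``t_re``.
    """
    rows = []
    for mode in modes:
        init = mode_initial_phase(params, mode)
        pdists = gamma_match(params, f_I_init=init)
        cv = transient_curves(pdists, params.tau_P, params.tau_m, t_grid=t_grid)
        rows.append(
            {
                "mode": mode,
                "t_re": cv.t_re,
                "t_GA": cv.t_GA,
                "m_ss": cv.m_ss,
                "H_P": cv.H_P,
                "H_m": cv.H_m,
                "overshoot_P": cv.overshoot_P,
                "overshoot_m": cv.overshoot_m,
                "tau_first": pdists.tau_first,
                "cv_first": pdists.cv_first,
                "T": pdists.T,
            }
        )
    df = pd.DataFrame(rows).sort_values("t_re", kind="stable").reset_index(drop=True)
    df.attrs["tie_frac"] = tie_frac
    return df


def ordering_string(df: pd.DataFrame, tie_frac: float = 0.01) -> str:
    """Canonical ordering of modes by t_re, grouping ties within tie_frac*T."""
    T = float(df["T"].iloc[0])
    sub = df.sort_values("t_re", kind="stable")
    groups: list[list[str]] = []
    last = None
    for _, row in sub.iterrows():
        if last is not None and row["t_re"] - last <= tie_frac * T:
            groups[-1].append(row["mode"])
        else:
            groups.append([row["mode"]])
        last = row["t_re"]
    return " < ".join(",".join(sorted(g)) for g in groups)
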