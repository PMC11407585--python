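"""Regulator concentration -> bursting parameters: modes, sensitivity, specificity.

A regulator binding its cognate site (occupancy ``O = R^n_H/(R^n_H+K_d^n_H)``)
modulates exactly one elementary rate per basic mode:

========  =================  =========================================
mode      parameter          mechanism
========  =================  =========================================
MEE       tau_P              accelerates E_P (Pol II release)
MEA       tau_S1             accelerates E_S1 (scaffold disassembly)
MFI       tau_S2             accelerates E_S2 (PIC assembly)
MCC       tau_S3             accelerates E_S3 (nucleosome clearance)
MIE       p1 (via J1+)       boosts the flow into repeated E_P
MIA       p1 (via J1-)       suppresses the flow out of the burst
MFC       p2 (via J2+)       suppresses the flow into repeated E_S3
MFA       p2 (via J2-)       boosts the flow out of the E_S3 loop
========  =================  =========================================

Because regulators act on *rates*, interpolation is linear in the rate (flow):
``1/tau(O) = (1-O)/tau_U + O/tau_B`` for durations and
``J(O) = (1-O) J_U + O J_B`` with ``p = J+/(J+ + J-)`` for the repetition
probabilities.  For a single basic mode with ``n_H = 1`` the resulting mean
transcription rate is exactly a Hill-type (Mobius) function of ``[R]``,
``v(R) = v_max (beta + R)/(Omega + R)``, whose half-response point satisfies
``Omega = beta * F_v`` with fold change ``F_v = v_max/v_min``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .core import BurstParams, InvalidParameterError, compose_tau_s, derive_quantities
from .steady_state import mean_mrna

__all__ = [
    "BASIC_MODES",
    "RegulatoryMode",
    "RegulatoryFunctionParams",
    "DoseResponse",
    "SpecificityCurve",
    "InvalidModeError",
    "FitFailureError",
    "occupancy",
    "apply_modes",
    "interpolate_params",
    "regulatory_function",
    "fit_hill_exponent",
    "specificity_curve",
    "dose_response",
    "is_valid_combination",
]

# mode -> (regulated parameter, kind)
BASIC_MODES: Mapping[str, tuple[str, str]] = {
    "MEE": ("tau_P", "duration"),
    "MEA": ("tau_S1", "duration"),
    "MFI": ("tau_S2", "duration"),
    "MCC": ("tau_S3", "duration"),
    "MIE": ("p1", "flow+"),
    "MIA": ("p1", "flow-"),
    "MFC": ("p2", "flow+"),
    "MFA": ("p2", "flow-"),
}


class InvalidModeError(InvalidParameterError):
    pass


class FitFailureError(RuntimeError):
    pass


def is_valid_combination(names: Sequence[str]) -> bool:
    """A combination is valid when the basic modes touch disjoint parameters."""
    names = list(names)
    if not names or any(n not in BASIC_MODES for n in names):
        return False
    touched = [BASIC_MODES[n][0] for n in names]
    return len(touched) == len(set(touched))


@dataclass(frozen=True)
class RegulatoryMode:
    """A combination of basic modes with efficacies, K_d, and Hill coefficient.

    ``efficacies[name]`` is the factor by which full occupancy multiplies the
    targeted parameter: ``tau_XB = eps tau_XU`` (eps in (0,1]) for duration
    modes, ``p1B = eps p1U`` (eps >= 1) for MIE/MIA, ``p2B = eps p2U``
    (eps in (0,1]) for MFC/MFA.
    """

    efficacies: Mapping[str, float]
    K_d: float = 1.0
    n_H: float = 1.0

    def __post_init__(self) -> None:
        if not self.efficacies:
            raise InvalidModeError("at least one basic mode required")
        if not is_valid_combination(list(self.efficacies)):
            raise InvalidModeError(
                f"invalid mode combination {sorted(self.efficacies)!r} "
                "(unknown mode or overlapping parameters)"
            )
        for name, eps in self.efficacies.items():
            kind = BASIC_MODES[name][1]
            if kind == "duration" or name in ("MFC", "MFA"):
                if not 0.0 < eps <= 1.0:
                    raise InvalidModeError(f"{name} requires efficacy in (0, 1]")
            else:  # MIE / MIA
                if eps < 1.0:
                    raise InvalidModeError(f"{name} requires efficacy >= 1")
        if self.K_d <= 0:
            raise InvalidModeError("K_d must be positive")
        if self.n_H <= 0:
            raise InvalidModeError("Hill coefficient must be positive")

    @property
    def basic_modes(self) -> tuple[str, ...]:
        return tuple(sorted(self.efficacies))


def occupancy(R, K_d: float, n_H: float = 1.0):
    """Regulator occupancy R^n_H / (R^n_H + K_d^n_H); monotone in R, in [0, 1]."""
    if K_d <= 0 or n_H <= 0:
        raise InvalidParameterError("K_d and n_H must be positive")
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise InvalidParameterError("concentration must be nonnegative")
    x = (R / K_d) ** n_H
    out = x / (x + 1.0)
    return out if out.shape else float(out)


# -- parameter maps ---------------------------------------------------------


def _duration_map(tau_U: float, eps: float, O):
    """Rate-linear interpolation: tau(O) = eps tau_U / (eps + (1-eps) O)."""
    O = np.asarray(O, dtype=float)
    den = eps + (1.0 - eps) * O
    val = tau_U * eps / den
    dval = -tau_U * eps * (1.0 - eps) / den**2
    return val, dval


def _flow_map(p_U: float, eps: float, route: str, O):
    """Flow-linear interpolation of a repetition probability.

    ``route='flow+'`` scales the flow favouring repetition by
    ``g(O) = 1 + (lam-1) O`` with ``lam`` fixed by the endpoint
    ``p_B = eps p_U``; ``route='flow-'`` scales the opposing flow.
    """
    O = np.asarray(O, dtype=float)
    q_U = 1.0 - p_U
    if eps * p_U >= 1.0:
        raise InvalidModeError("efficacy would push the probability to 1")
    if route == "flow+":
        lam = eps * q_U / (1.0 - eps * p_U)
        g = 1.0 + (lam - 1.0) * O
        den = g * p_U + q_U
        val = g * p_U / den
        dval = (lam - 1.0) * p_U * q_U / den**2
    else:
        lam = (1.0 - eps * p_U) / (eps * q_U)
        g = 1.0 + (lam - 1.0) * O
        den = p_U + g * q_U
        val = p_U / den
        dval = -(lam - 1.0) * p_U * q_U / den**2
    return val, dval


def _param_paths(mode: RegulatoryMode, baseline: BurstParams, O):
    """Values and O-derivatives of every bursting parameter along the mode."""
    O = np.asarray(O, dtype=float)
    vals = {k: np.broadcast_to(v, O.shape).astype(float)
            for k, v in baseline.to_dict().items()}
    derivs = {k: np.zeros(O.shape) for k in vals}
    for name, eps in mode.efficacies.items():
        pname, kind = BASIC_MODES[name]
        if kind == "duration":
            tau_U = getattr(baseline, pname)
            if tau_U <= 0:
                raise InvalidModeError(f"{name} targets {pname} which is zero")
            vals[pname], derivs[pname] = _duration_map(tau_U, eps, O)
        else:
            p_U = getattr(baseline, pname)
            if p_U <= 0:
                raise InvalidModeError(f"{name} targets {pname} which is zero")
            vals[pname], derivs[pname] = _flow_map(p_U, eps, kind, O)
    return vals, derivs


def apply_modes(
    mode: RegulatoryMode,
    O: float,
    baseline: BurstParams,
    endpoint: BurstParams | None = None,
) -> BurstParams:
    """Bursting parameters at occupancy ``O``; O=0 gives the baseline, O=1 the
    fully bound endpoint.

    If ``endpoint`` is supplied it is checked for consistency with the mode's
    efficacies.
    """
    if not 0.0 <= O <= 1.0:
        raise InvalidParameterError("occupancy must lie in [0, 1]")
    if endpoint is not None:
        full, _ = _param_paths(mode, baseline, np.asarray(1.0))
        for k, v in full.items():
            if not math.isclose(float(v), getattr(endpoint, k), rel_tol=1e-9, abs_tol=1e-12):
                raise InvalidModeError(
                    f"endpoint field {k}={getattr(endpoint, k)} inconsistent "
                    f"with mode (expected {float(v)})"
                )
    vals, _ = _param_paths(mode, baseline, np.asarray(float(O)))
    return BurstParams(**{k: float(v) for k, v in vals.items()})


def interpolate_params(
    baseline: BurstParams, endpoint: BurstParams, O
) -> dict[str, np.ndarray]:
    """Generic rate/flow-linear interpolation between two parameter sets.

    Durations interpolate harmonically (rates add); probabilities via the
    flow favouring the change (odds scale linearly).  Used by the mean-Fano
    curve machinery where endpoints, not efficacies, are given.
    """
    O = np.asarray(O, dtype=float)
    out: dict[str, np.ndarray] = {}
    for k, vU in baseline.to_dict().items():
        vB = getattr(endpoint, k)
        if math.isclose(vU, vB, rel_tol=1e-12, abs_tol=1e-15):
            out[k] = np.broadcast_to(vU, O.shape).astype(float)
        elif k.startswith("tau"):
            if vU <= 0 or vB <= 0:
                raise InvalidParameterError(f"cannot interpolate {k} through zero")
            out[k] = 1.0 / ((1.0 - O) / vU + O / vB)
        else:  # probability: linear odds (flow favouring the change)
            lam = (vB * (1.0 - vU)) / (vU * (1.0 - vB))
            g = 1.0 + (lam - 1.0) * O
            out[k] = g * vU / (g * vU + 1.0 - vU)
    return out


# -- gene-regulatory function ----------------------------------------------


@dataclass(frozen=True)
class RegulatoryFunctionParams:
    v_min: float
    v_max: float
    beta: float
    omega: float
    n: float
    F_v: float
    sensitivity: float  # K_d / omega


def _rate_at_O(mode: RegulatoryMode, baseline: BurstParams, O: float) -> float:
    return mean_mrna(apply_modes(mode, O, baseline)) / baseline.tau_m


def regulatory_function(
    mode: RegulatoryMode,
    baseline: BurstParams,
    numeric: bool = False,
    n_grid: int = 400,
) -> RegulatoryFunctionParams:
    """Hill-form description of the mean transcription rate v([R]).

    For a single basic mode the closed forms hold exactly (with exponent
    ``n = n_H``): ``beta`` as listed in the mode table and
    ``Omega = beta F_v``.  Combined modes (or ``numeric=True``) fall back to a
    numeric half-response search plus a fitted exponent.
    """
    v_min = _rate_at_O(mode, baseline, 0.0)
    v_max = _rate_at_O(mode, baseline, 1.0)
    F_v = v_max / v_min
    single = len(mode.efficacies) == 1
    if single and not numeric:
        (name, eps), = mode.efficacies.items()
        kind = BASIC_MODES[name][1]
        Kp = mode.K_d**mode.n_H
        if kind == "duration":
            beta_p = eps * Kp
        elif name == "MIE":
            p = baseline.p1
            lam = eps * (1.0 - p) / (1.0 - eps * p)
            beta_p = Kp / lam
        elif name == "MFA":
            p = baseline.p2
            lam = (1.0 - eps * p) / (eps * (1.0 - p))
            beta_p = Kp / lam
        else:  # MIA, MFC: the scaled flow opposes the numerator
            beta_p = Kp
        omega_p = beta_p * F_v
        beta = beta_p ** (1.0 / mode.n_H)
        omega = omega_p ** (1.0 / mode.n_H)
        n = mode.n_H
    else:
        R_grid = mode.K_d * np.geomspace(1e-5, 1e5, n_grid)
        O_grid = occupancy(R_grid, mode.K_d, mode.n_H)
        v = np.array([_rate_at_O(mode, baseline, o) for o in O_grid])
        target = 0.5 * (v_min + v_max)

        def g(logR):
            o = occupancy(math.exp(logR), mode.K_d, mode.n_H)
            return _rate_at_O(mode, baseline, o) - target

        idx = np.nonzero(np.diff(np.sign(v - target)))[0]
        if idx.size == 0:
            omega = math.nan
        else:
            i = idx[0]
            omega = math.exp(
                brentq(g, math.log(R_grid[i]), math.log(R_grid[i + 1]), xtol=1e-12)
            )
        n = fit_hill_exponent(R_grid, v, v_min, v_max, omega)
        beta = omega * abs(F_v) ** (-1.0 / n) if F_v > 0 else math.nan
    return RegulatoryFunctionParams(
        v_min=v_min,
        v_max=v_max,
        beta=beta,
        omega=omega,
        n=n,
        F_v=F_v,
        sensitivity=mode.K_d / omega,
    )


def fit_hill_exponent(R_grid, v_values, v_min, v_max, omega) -> float:
    """Least-squares exponent of v = v_max (beta^n + R^n)/(Omega^n + R^n).

    ``beta`` is eliminated through ``beta = Omega (v_min/v_max)^(1/n)``; the
    residual is summed over log concentrations.
    """
    R = np.asarray(R_grid, dtype=float)
    v = np.asarray(v_values, dtype=float)
    dv = np.diff(v)
    if not (np.all(dv >= -1e-12 * abs(v).max()) or np.all(dv <= 1e-12 * abs(v).max())):
        raise FitFailureError("dose-response values are not monotone")

    def loss(log_n):
        n = math.exp(log_n)
        bn = (omega**n) * (v_min / v_max)
        model = v_max * (bn + R**n) / (omega**n + R**n)
        return float(np.sum((np.log(model) - np.log(v)) ** 2))

    res = minimize_scalar(loss, bounds=(math.log(0.05), math.log(20.0)), method="bounded",
                          options={"xatol": 1e-10})
    return float(math.exp(res.x))


# -- specificity ------------------------------------------------------------


@dataclass
class SpecificityCurve:
    R_grid: np.ndarray
    S: np.ndarray
    S_m: float
    R_at_Sm: float


def specificity_curve(
    mode: RegulatoryMode,
    baseline: BurstParams,
    nontarget_fold: float = 100.0,
    R_grid=None,
) -> SpecificityCurve:
    """Specificity S([R]): cognate-driven over nontarget-driven expression.

    Nontarget sites bind with dissociation constant ``nontarget_fold * K_d``.
    S is unimodal for nonzero basal expression; its maximum approaches the
    fold change ``F_v`` as the fold grows.
    """
    if nontarget_fold <= 1.0:
        raise InvalidParameterError("nontarget_fold must exceed 1")
    if R_grid is None:
        R_grid = mode.K_d * np.geomspace(1e-4, 1e4, 257)
    R_grid = np.asarray(R_grid, dtype=float)

    def v_at(R, kd):
        return _rate_at_O(mode, baseline, occupancy(R, kd, mode.n_H))

    kd_nt = nontarget_fold * mode.K_d
    S = np.array([v_at(R, mode.K_d) / v_at(R, kd_nt) for R in R_grid])
    i = int(np.argmax(S))
    lo = R_grid[max(i - 1, 0)]
    hi = R_grid[min(i + 1, R_grid.size - 1)]
    res = minimize_scalar(
        lambda x: -v_at(math.exp(x), mode.K_d) / v_at(math.exp(x), kd_nt),
        bounds=(math.log(lo), math.log(hi)),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return SpecificityCurve(
        R_grid=R_grid, S=S, S_m=float(-res.fun), R_at_Sm=float(math.exp(res.x))
    )


# -- dose response ----------------------------------------------------------


@dataclass
class DoseResponse:
    R_grid: np.ndarray
    O: np.ndarray
    m: np.ndarray
    b: np.ndarray
    f: np.ndarray
    tau_A: np.ndarray
    tau_I: np.ndarray
    S_b: np.ndarray
    S_f: np.ndarray
    omega_m: float
    omega_b: float
    omega_f: float


def _mbf_and_slopes(mode: RegulatoryMode, baseline: BurstParams, O):
    vals, dv = _param_paths(mode, baseline, O)
    tau_P, p1, p2 = vals["tau_P"], vals["p1"], vals["p2"]
    tau_S = compose_tau_s_vec(vals)
    # d tau_S / dO through components
    dtau_S = (
        dv["tau_S1"]
        + dv["tau_S2"]
        + dv["tau_S3"] * p2 / (1.0 - p2)
        + dv["p2"] * vals["tau_S3"] / (1.0 - p2) ** 2
    )
    q = (1.0 - p1) / p1
    D = tau_P + q * tau_S  # tau_m / m
    m = baseline.tau_m / D
    dD = dv["tau_P"] + q * dtau_S - dv["p1"] * tau_S / p1**2
    dm = -baseline.tau_m * dD / D**2
    b = 1.0 / (1.0 - p1)
    db = dv["p1"] / (1.0 - p1) ** 2
    tau_A = tau_P * b
    tau_I = tau_S / p1
    T = tau_A + tau_I
    dT = (
        dv["tau_P"] / (1.0 - p1)
        + dv["p1"] * (tau_P / (1.0 - p1) ** 2 - tau_S / p1**2)
        + dtau_S / p1
    )
    f = 1.0 / T
    df = -dT / T**2
    return m, dm, b, db, f, df, tau_A, tau_I


def compose_tau_s_vec(vals: Mapping[str, np.ndarray]) -> np.ndarray:
    return (
        vals["tau_S1"]
        + vals["tau_S2"]
        + vals["p2"] * vals["tau_S3"] / (1.0 - vals["p2"])
    )


def _half_max_crossing(R_grid, curve):
    """First concentration where the curve reaches half of its maximum."""
    target = 0.5 * np.max(curve)
    above = curve >= target
    if above[0] or not above.any():
        return math.nan
    i = int(np.argmax(above))  # first index above
    x0, x1 = np.log(R_grid[i - 1]), np.log(R_grid[i])
    y0, y1 = curve[i - 1], curve[i]
    return float(np.exp(x0 + (target - y0) * (x1 - x0) / (y1 - y0)))


def dose_response(
    mode: RegulatoryMode,
    baseline: BurstParams,
    endpoint: BurstParams | None = None,
    R_grid=None,
) -> DoseResponse:
    """Mean, burst size, and burst frequency versus regulator concentration.

    The log-sensitivities ``S_b = dln b/dln m`` and ``S_f = dln f/dln m`` are
    computed by analytic chain-rule differentiation along the occupancy path;
    the identity ``m = b f tau_m`` makes ``S_b + S_f = 1`` pointwise.
    ``omega_x`` are the concentrations at which each curve first reaches half
    its maximum.
    """
    if endpoint is not None:
        apply_modes(mode, 1.0, baseline, endpoint)  # consistency check
    if R_grid is None:
        R_grid = mode.K_d * np.geomspace(1e-4, 1e4, 801)
    R_grid = np.asarray(R_grid, dtype=float)
    O = occupancy(R_grid, mode.K_d, mode.n_H)
    m, dm, b, db, f, df, tau_A, tau_I = _mbf_and_slopes(mode, baseline, O)
    with np.errstate(divide="ignore", invalid="ignore"):
        S_b = (db / b) / (dm / m)
        S_f = (df / f) / (dm / m)
    return DoseResponse(
        R_grid=R_grid,
        O=O,
        m=m,
        b=b,
        f=f,
        tau_A=tau_A,
        tau_I=tau_I,
        S_b=S_b,
        S_f=S_f,
        omega_m=_half_max_crossing(R_grid, m),
        omega_b=_half_max_crossing(R_grid, b),
        omega_f=_half_max_crossing(R_grid, f),
    )
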