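"""Closed-form steady-state statistics of the event-based bursting model.

The completed ``E_P`` events form a renewal point process: each inter-synthesis
interval is one ``E_P`` duration plus, with probability ``1 - p1``, a full
inactive phase (a geometric number of (``E_S1`` → ``E_S3``* → ``E_S2``)
cycles).  Filtering that point process through first-order degradation gives
the exact stationary copy-number moments

    <m>   = b f tau_m,
    sigma^2 = <m> + <m> * uhat(1/tau_m) - <m>^2,

where ``uhat(s) = fhat(s) / (1 - fhat(s))`` is the Laplace transform of the
renewal density and ``fhat`` that of the inter-synthesis interval.  Because
every event family used here (exponential, gamma, delayed-exponential) has a
closed-form Laplace transform, the variance is exact for arbitrary event
shapes, including a refractory offset on ``E_S1``.

When the inactive cycle is a single exponential block of mean ``tau_S`` the
general result reduces to the compact textbook forms (with ``b = 1/(1-p1)``,
``c = tau_A/tau_m``, ``d = tau_I/tau_m``, ``s = tau_S/tau_m``):

    sigma^2 = <m> + <m>^2 [ (c+d) s - c d ] / (c + d + c d),
    F       = 1 + [ d (b-1) - b c d / (c+d) ] / (c + d + c d),

which are exposed separately as :func:`variance_closed_form` and
:func:`fano_closed_form` and tested to agree with the renewal result.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .core import (
    BurstParams,
    InvalidParameterError,
    derive_quantities,
)

__all__ = [
    "InfeasibleMeanError",
    "mean_mrna",
    "interval_laplace",
    "variance_and_fano",
    "variance_closed_form",
    "fano_closed_form",
    "fano_slope",
    "burst_height",
    "expression_bounds",
    "fano_lower_bound",
    "telegraph_mean_fano",
    "mean_fano_exponential_vec",
    "constraint_scan",
]


class InfeasibleMeanError(InvalidParameterError):
    """The requested mean expression is unreachable for the given bounds."""


def mean_mrna(params: BurstParams) -> float:
    """Steady-state mean copy number  <m> = tau_m / (tau_P + (1-p1)/p1 * tau_S)."""
    return derive_quantities(params).m_mean


def interval_laplace(params: BurstParams, s):
    """Laplace transform of the interval between consecutive mRNA syntheses.

    The interval is ``E_P`` plus, with probability ``1-p1``, an inactive phase
    consisting of a Geometric(p1) number of inactive cycles; each cycle is
    ``E_S1`` then a Geometric run of ``E_S3`` (continuation ``p2``) then
    ``E_S2``.
    """
    p1, p2 = params.p1, params.p2
    L_P = params.model_for("E_P").laplace(s)
    L_C = params.model_for("E_S1").laplace(s)
    if params.tau_S2 > 0:
        L_C = L_C * params.model_for("E_S2").laplace(s)
    if p2 > 0 and params.tau_S3 > 0:
        L_S3 = params.model_for("E_S3").laplace(s)
        L_C = L_C * (1.0 - p2) / (1.0 - p2 * L_S3)
    if p1 == 0.0:
        return 0.0 * np.asarray(s)  # inactive phase never ends
    I_hat = p1 * L_C / (1.0 - (1.0 - p1) * L_C)
    return L_P * (p1 + (1.0 - p1) * I_hat)


def variance_and_fano(params: BurstParams) -> tuple[float, float]:
    """Exact stationary (variance, Fano factor) of the mRNA copy number.

    Returns ``(0.0, nan)`` when ``p1 = 0`` (no expression, Fano undefined).
    """
    m = mean_mrna(params)
    if m == 0.0:
        return 0.0, math.nan
    fhat = float(interval_laplace(params, 1.0 / params.tau_m))
    uhat = fhat / (1.0 - fhat)
    var = m + m * uhat - m * m
    return var, var / m


def variance_closed_form(params: BurstParams) -> float:
    """The compact variance expression in terms of (tau_A, tau_I, tau_S, tau_m).

    Exact when all events are exponential and the inactive cycle is a single
    block; an approximation (means only) for multi-component inactive phases.
    """
    q = derive_quantities(params)
    if q.m_mean == 0.0:
        return 0.0
    c, d = q.c, q.d
    s = q.tau_S / params.tau_m
    m = q.m_mean
    return m + m * m * ((c + d) * s - c * d) / (c + d + c * d)


def fano_closed_form(b, c, d):
    """The Fano factor in terms of burst size and dimensionless phase durations.

    ``F = 1 + [d(b-1) - b c d/(c+d)] / (c + d + c d)``; accepts arrays.
    """
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    out = 1.0 + (d * (b - 1.0) - b * c * d / (c + d)) / (c + d + c * d)
    return out if out.shape else float(out)


def fano_slope(params: BurstParams) -> float:
    """Exact derivative dF/d<m> along the tau_S-regulated path (tau_P, p1 fixed).

    Along that path ``b`` and ``c`` are constant while ``d`` varies with
    ``<m> = b/(c+d)``.  At large ``<m>`` the slope is negative (noise falls
    toward the Poisson floor as the inactive phase shrinks).
    """
    q = derive_quantities(params)
    if q.m_mean == 0.0:
        raise InvalidParameterError("fano slope undefined at zero expression")
    b, c, d = q.b, q.c, q.d
    N = d * (b - 1.0) - b * c * d / (c + d)
    D = c + d + c * d
    dN = (b - 1.0) - b * c**2 / (c + d) ** 2
    dD = 1.0 + c
    dF_dd = (dN * D - N * dD) / D**2
    dd_dm = -((c + d) ** 2) / b
    return dF_dd * dd_dm


def burst_height(params: BurstParams) -> float:
    """Mean height of burst profiles.

    ``h ~ tau_m (1-e^-c)(1-e^-d) / [tau_P (1-e^-(c+d))]`` for ``tau_P < tau_m``
    and ``h ~ 1`` otherwise.  This is a stated approximation; no continuity is
    guaranteed at ``tau_P = tau_m``.
    """
    if params.tau_P >= params.tau_m:
        return 1.0
    q = derive_quantities(params)
    c, d = q.c, q.d
    num = params.tau_m * (-np.expm1(-c)) * (-np.expm1(-d))
    den = params.tau_P * (-np.expm1(-(c + d)))
    return float(num / den)


def expression_bounds(tau_P: float, tau_m: float) -> tuple[float, float]:
    """Upper bounds at fixed tau_P:  <m> < tau_m/tau_P  and  F < 1 + tau_m/tau_P."""
    if tau_P <= 0 or tau_m <= 0:
        raise InvalidParameterError("times must be positive")
    return tau_m / tau_P, 1.0 + tau_m / tau_P


def fano_lower_bound(
    m_mean: float, tau_S0: float, p10: float, tau_m: float = 5.0
) -> float:
    """Minimum Fano factor at fixed mean expression.

    With ``tau_S >= tau_S0`` and ``p1 <= p10``, the constrained minimum of F at
    fixed ``<m>`` sits at the corner ``(tau_S0, p10)`` in the high-expression
    regime (``<m> > tau_m/(2 tau_S0)``); ``tau_P`` is eliminated through the
    mean-expression identity.
    """
    if not (0.0 < p10 < 1.0):
        raise InvalidParameterError("p10 must lie in (0, 1)")
    if tau_S0 <= 0 or tau_m <= 0 or m_mean <= 0:
        raise InvalidParameterError("tau_S0, tau_m, m_mean must be positive")
    tau_P = tau_m / m_mean - (1.0 - p10) / p10 * tau_S0
    if tau_P <= 0:
        raise InfeasibleMeanError(
            f"mean {m_mean} unreachable with tau_S0={tau_S0}, p10={p10}"
        )
    params = BurstParams.from_inactive_mean(tau_P, tau_S0, p10, tau_m)
    return variance_and_fano(params)[1]


def telegraph_mean_fano(k_on, k_off, k_syn, tau_m):
    """Stationary (mean, Fano) of the two-state telegraph model.

    mean = k_syn tau_m k_on/(k_on+k_off);
    F = 1 + k_syn k_off / [(k_on+k_off)(k_on+k_off+1/tau_m)].
    Accepts arrays.
    """
    k_on = np.asarray(k_on, dtype=float)
    k_off = np.asarray(k_off, dtype=float)
    k_syn = np.asarray(k_syn, dtype=float)
    mean = k_syn * tau_m * k_on / (k_on + k_off)
    fano = 1.0 + k_syn * k_off / ((k_on + k_off) * (k_on + k_off + 1.0 / tau_m))
    return mean, fano


def mean_fano_exponential_vec(tau_P, tau_S1, tau_S2, tau_S3, p1, p2, tau_m):
    """Vectorized exact (mean, Fano) for all-exponential event durations.

    Broadcasts over parameter arrays; degenerate components (``tau_S2`` or
    ``tau_S3`` equal to zero) are handled.
    """
    tau_P, tau_S1, tau_S2, tau_S3, p1, p2 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float)
          for a in (tau_P, tau_S1, tau_S2, tau_S3, p1, p2))
    )
    s = 1.0 / tau_m
    L_P = 1.0 / (1.0 + s * tau_P)
    L_C = 1.0 / (1.0 + s * tau_S1)
    L_C = L_C * np.where(tau_S2 > 0, 1.0 / (1.0 + s * tau_S2), 1.0)
    s3 = (p2 > 0) & (tau_S3 > 0)
    L_S3 = 1.0 / (1.0 + s * tau_S3)
    L_C = L_C * np.where(s3, (1.0 - p2) / (1.0 - p2 * L_S3), 1.0)
    I_hat = p1 * L_C / (1.0 - (1.0 - p1) * L_C)
    fhat = L_P * (p1 + (1.0 - p1) * I_hat)
    uhat = fhat / (1.0 - fhat)
    tau_S = tau_S1 + tau_S2 + p2 * tau_S3 / (1.0 - p2)
    m = tau_m / (tau_P + (1.0 - p1) / p1 * tau_S)
    return m, 1.0 + uhat - m


# ---------------------------------------------------------------------------
# genome-scale constraint scan
# ---------------------------------------------------------------------------


def _event_fano_vec(tau_P, tau_S, p1, delta, tau_m):
    """Vectorized exact (mean, Fano) for a single delayed-exponential inactive block."""
    s = 1.0 / tau_m
    L_P = 1.0 / (1.0 + s * tau_P)
    L_C = np.exp(-s * delta) / (1.0 + s * (tau_S - delta))
    I_hat = p1 * L_C / (1.0 - (1.0 - p1) * L_C)
    fhat = L_P * (p1 + (1.0 - p1) * I_hat)
    uhat = fhat / (1.0 - fhat)
    m = tau_m / (tau_P + (1.0 - p1) / p1 * tau_S)
    fano = 1.0 + uhat - m
    return m, fano


def _log_uniform(rng, lo, hi, size):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def constraint_scan(
    n_sets: int,
    burst_duration_range: tuple[float, float] = (1.0, 1000.0),
    rate_range: tuple[float, float] = (0.1, 100.0),
    refractory: float = 1.0,
    tau_m: float = 5.0,
    seed: int | None = None,
    duration_interpretation: str = "period",
    coupled_telegraph: bool = False,
) -> pd.DataFrame:
    """Random scan of bursting parameters and the matched telegraph comparator.

    Event-model sets are sampled with the burst period (or, with
    ``duration_interpretation='active'``, the active-phase duration)
    log-uniform in ``burst_duration_range``, the transcription rate
    ``1/tau_P`` log-uniform in ``rate_range``, and ``tau_A < tau_I`` enforced
    by rejection; the refractory period enters as a hard offset on the
    inactive cycle.  The Fano factor is evaluated exactly through the renewal
    formula, so the refractory offset affects the noise, not only the means.

    The telegraph comparator uses the same rate mapping
    (``k_on = 1/tau_I``, ``k_off = 1/tau_A``, ``k_syn = 1/tau_P``) but — being
    free of the event-structure correlations — samples its three rates
    independently within the same ranges, with no refractory.  With
    ``coupled_telegraph=True`` it instead reuses the event-model parameter
    sets verbatim.
    """
    if n_sets < 1:
        raise InvalidParameterError("n_sets must be >= 1")
    if duration_interpretation not in ("period", "active"):
        raise InvalidParameterError("duration_interpretation must be 'period' or 'active'")
    rng = np.random.default_rng(seed)
    lo, hi = burst_duration_range

    # --- event model: rejection sampling ---------------------------------
    cols = {k: [] for k in ("tau_A", "tau_I", "tau_P", "p1", "tau_S")}
    n_acc, n_tried = 0, 0
    while n_acc < n_sets:
        batch = max(4 * (n_sets - n_acc), 1024)
        n_tried += batch
        if duration_interpretation == "period":
            T = _log_uniform(rng, lo, hi, batch)
            u = rng.uniform(0.0, 1.0, batch)
            tau_A, tau_I = u * T, (1.0 - u) * T
        else:
            tau_A = _log_uniform(rng, lo, hi, batch)
            tau_I = _log_uniform(rng, lo, hi, batch)
        tau_P = 1.0 / _log_uniform(rng, *rate_range, size=batch)
        p1 = 1.0 - tau_P / tau_A
        tau_S = p1 * tau_I
        ok = (tau_A < tau_I) & (tau_P < tau_A) & (tau_S > refractory)
        for k, v in zip(cols, (tau_A, tau_I, tau_P, p1, tau_S)):
            cols[k].append(v[ok])
        n_acc += int(ok.sum())
        if n_tried > 2000 * n_sets + 10_000 and n_acc == 0:
            raise InvalidParameterError("empty feasible region for the scan ranges")
    ev = {k: np.concatenate(v)[:n_sets] for k, v in cols.items()}
    m_ev, F_ev = _event_fano_vec(
        ev["tau_P"], ev["tau_S"], ev["p1"], refractory, tau_m
    )

    # --- telegraph comparator --------------------------------------------
    if coupled_telegraph:
        tg_A, tg_I, tg_P = ev["tau_A"], ev["tau_I"], ev["tau_P"]
    else:
        tg_A = _log_uniform(rng, lo, hi, n_sets)
        tg_I = _log_uniform(rng, lo, hi, n_sets)
        tg_P = 1.0 / _log_uniform(rng, *rate_range, size=n_sets)
    m_tg, F_tg = telegraph_mean_fano(1.0 / tg_I, 1.0 / tg_A, 1.0 / tg_P, tau_m)

    n = n_sets
    df = pd.DataFrame(
        {
            "model": ["event"] * n + ["telegraph"] * n,
            "set_id": list(range(n)) * 2,
            "m_mean": np.concatenate([m_ev, m_tg]),
            "fano": np.concatenate([F_ev, F_tg]),
            "tau_A": np.concatenate([ev["tau_A"], tg_A]),
            "tau_I": np.concatenate([ev["tau_I"], tg_I]),
            "tau_P": np.concatenate([ev["tau_P"], tg_P]),
            "p1": np.concatenate([ev["p1"], np.full(n, np.nan)]),
            "refractory": np.concatenate(
                [np.full(n, float(refractory)), np.zeros(n)]
            ),
        }
    )
    return df


def envelope_rise(df: pd.DataFrame, model: str) -> float:
    """Lower-decile Fano in the top mean-expression quartile minus that in the bottom.

    A positive value indicates the rising noise floor ("higher expression is
    accompanied by increased burstiness").
    """
    sub = df[df["model"] == model]
    q1, q3 = sub["m_mean"].quantile([0.25, 0.75])
    low = sub[sub["m_mean"] <= q1]["fano"].quantile(0.10)
    high = sub[sub["m_mean"] >= q3]["fano"].quantile(0.10)
    return float(high - low)


__all__.append("envelope_rise")
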