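"""Event-driven stochastic simulation of transcriptional bursting.

Two complementary simulators are provided:

* :func:`simulate_trajectory` — a faithful single-trajectory event loop over
  the flow E_S1 -> (E_S3*) -> E_S2 -> {E_P...} with full event records; used
  for burst-statistics extraction and distributional checks.
* :func:`ensemble_moments` — a vectorized ensemble simulator exploiting the
  renewal structure of synthesis times (each inter-synthesis interval is one
  E_P duration plus, with probability 1-p1, an inactive phase), used for
  moment estimates over thousands of trajectories.

Degradation assigns each molecule an independent exponential lifetime with
mean ``tau_m`` — statistically identical to a first-order Gillespie channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BurstParams, InvalidParameterError, derive_quantities

__all__ = [
    "EventRecord",
    "Trajectory",
    "BurstSummary",
    "PhaseRenewalResult",
    "simulate_trajectory",
    "burst_statistics",
    "sample_inactive_phase",
    "ensemble_counts",
    "ensemble_moments",
    "simulate_phase_renewal",
    "simulate_telegraph",
]


@dataclass(frozen=True)
class EventRecord:
    event_kind: str
    start: float
    duration: float
    produced_mrna: int


@dataclass
class Trajectory:
    events: list
    synthesis_times: np.ndarray
    degradation_times: np.ndarray
    seed: int | None
    params: BurstParams
    t_end: float
    init: str

    def count_at(self, times):
        """mRNA copy number at the given times (vectorized)."""
        t = np.asarray(times, dtype=float)
        births = np.sort(self.synthesis_times)
        deaths = np.sort(self.degradation_times)
        n = np.searchsorted(births, t, side="right") - np.searchsorted(
            deaths, t, side="right"
        )
        return n


@dataclass
class BurstSummary:
    burst_sizes: np.ndarray
    active_durations: np.ndarray
    inactive_durations: np.ndarray
    n_bursts: int

    @property
    def mean_burst_size(self) -> float:
        return float(np.mean(self.burst_sizes)) if self.n_bursts else math.nan

    @property
    def mean_active(self) -> float:
        return float(np.mean(self.active_durations)) if self.n_bursts else math.nan

    @property
    def mean_inactive(self) -> float:
        if len(self.inactive_durations) == 0:
            return math.nan
        return float(np.mean(self.inactive_durations))

    @property
    def empty(self) -> bool:
        return self.n_bursts == 0


def simulate_trajectory(
    params: BurstParams,
    t_end: float,
    seed: int | None = None,
    init="inactive-start",
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Simulate one trajectory of the event flow with full event records.

    ``init`` is ``"inactive-start"`` (default; the gene begins a fresh
    inactive cycle at E_S1), ``"burst-start"`` (the gene begins in E_P), or a
    tuple ``("silent", dist)`` where ``dist.sample(rng)`` draws the time of
    first activation (the gene then enters E_P).

    One mRNA is produced at the completion of each E_P; each molecule receives
    an independent exponential lifetime with mean ``tau_m``.  Events with a
    zero-mean duration (degenerate components) are skipped, not recorded.
    """
    if t_end <= 0:
        raise InvalidParameterError("t_end must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    p1, p2 = params.p1, params.p2
    has_S2 = params.tau_S2 > 0
    has_S3 = params.tau_S3 > 0 and p2 > 0
    kinds = ["E_P", "E_S1"] + (["E_S2"] if has_S2 else []) + (["E_S3"] if has_S3 else [])
    models = {k: params.model_for(k) for k in kinds}

    events: list[EventRecord] = []
    synth: list[float] = []
    t = 0.0
    if init == "inactive-start":
        state = "E_S1"
    elif init == "burst-start":
        state = "E_P"
    elif isinstance(init, tuple) and len(init) == 2 and init[0] == "silent":
        t = float(init[1].sample(rng))
        state = "E_P"
    else:
        raise InvalidParameterError(f"invalid init spec {init!r}")

    def after_inactive_entry() -> str:
        # branch taken after E_S1 and after each E_S3
        if has_S3 and rng.random() < p2:
            return "E_S3"
        return "E_S2" if has_S2 else "_checkpoint"

    while t < t_end:
        if state == "_checkpoint":
            state = "E_P" if rng.random() < p1 else "E_S1"
            continue
        dur = float(models[state].sample(rng))
        events.append(
            EventRecord(state, t, dur, 1 if state == "E_P" else 0)
        )
        t += dur
        if state == "E_P":
            if t <= t_end:
                synth.append(t)
            state = "E_P" if rng.random() < p1 else "E_S1"
        elif state in ("E_S1", "E_S3"):
            state = after_inactive_entry()
        else:  # E_S2
            state = "_checkpoint"

    synth_arr = np.asarray(synth, dtype=float)
    lifetimes = rng.exponential(params.tau_m, synth_arr.size)
    return Trajectory(
        events=events,
        synthesis_times=synth_arr,
        degradation_times=synth_arr + lifetimes,
        seed=seed,
        params=params,
        t_end=t_end,
        init=str(init),
    )


def burst_statistics(traj: Trajectory) -> BurstSummary:
    """Per-burst statistics: sizes, active/inactive phase durations.

    A burst is a maximal run of consecutive E_P events; only runs terminated
    by a following inactive event are counted (incomplete trailing phases are
    discarded), and inactive phases are counted only when flanked by bursts.
    """
    kinds = [e.event_kind for e in traj.events]
    runs = []  # (is_active, start_idx, end_idx)
    i = 0
    while i < len(kinds):
        j = i
        active = kinds[i] == "E_P"
        while j < len(kinds) and (kinds[j] == "E_P") == active:
            j += 1
        runs.append((active, i, j))
        i = j

    sizes, act_dur, inact_dur = [], [], []
    for r, (active, i, j) in enumerate(runs):
        dur = sum(e.duration for e in traj.events[i:j])
        if active and r < len(runs) - 1:
            sizes.append(j - i)
            act_dur.append(dur)
        elif not active and 0 < r < len(runs) - 1:
            inact_dur.append(dur)
    return BurstSummary(
        burst_sizes=np.asarray(sizes, dtype=float),
        active_durations=np.asarray(act_dur, dtype=float),
        inactive_durations=np.asarray(inact_dur, dtype=float),
        n_bursts=len(sizes),
    )


# ---------------------------------------------------------------------------
# vectorized ensemble machinery
# ---------------------------------------------------------------------------


def _segment_sum(values: np.ndarray, counts: np.ndarray) -> np.ndarray:
    cs = np.concatenate([[0.0], np.cumsum(values)])
    ends = np.cumsum(counts)
    starts = ends - counts
    return cs[ends] - cs[starts]


def sample_inactive_phase(
    params: BurstParams, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized draws of complete inactive-phase durations.

    Each phase comprises a Geometric(p1) number of cycles; each cycle is one
    E_S1 draw, a Geometric run of E_S3 draws (continuation p2), and one E_S2
    draw.
    """
    if params.p1 == 0.0:
        raise InvalidParameterError("inactive phase is infinite for p1 = 0")
    n_cyc = rng.geometric(params.p1, size)
    total = int(n_cyc.sum())
    cyc = params.model_for("E_S1").sample(rng, total)
    if params.tau_S2 > 0:
        cyc = cyc + params.model_for("E_S2").sample(rng, total)
    if params.p2 > 0 and params.tau_S3 > 0:
        k3 = rng.geometric(1.0 - params.p2, total) - 1
        n3 = int(k3.sum())
        if n3:
            draws3 = params.model_for("E_S3").sample(rng, n3)
            cyc = cyc + _segment_sum(draws3, k3)
    return _segment_sum(cyc, n_cyc)


def _synthesis_intervals(
    params: BurstParams, n_traj: int, n_cols: int, rng, first_col: str
) -> np.ndarray:
    ep = params.model_for("E_P").sample(rng, (n_traj, n_cols))
    gap = rng.random((n_traj, n_cols)) >= params.p1
    if first_col == "inactive":
        gap[:, 0] = True
    elif first_col == "burst":
        gap[:, 0] = False
    idx = np.flatnonzero(gap)
    if idx.size:
        phases = sample_inactive_phase(params, idx.size, rng)
        flat = np.zeros(n_traj * n_cols)
        flat[idx] = phases
        ep = ep + flat.reshape(n_traj, n_cols)
    return ep


def ensemble_counts(
    params: BurstParams,
    t_points,
    n_traj: int,
    seed: int | None = None,
    init: str = "inactive-start",
    _max_block: int = 40_000_000,
) -> np.ndarray:
    """mRNA copy numbers of ``n_traj`` trajectories at each time point.

    Returns an array of shape ``(len(t_points), n_traj)``.  Exploits the
    renewal structure of synthesis times; trajectories are simulated in
    chunks to bound memory.
    """
    if n_traj < 1:
        raise InvalidParameterError("n_traj must be >= 1")
    t_points = np.atleast_1d(np.asarray(t_points, dtype=float))
    if np.any(np.diff(t_points) < 0):
        raise InvalidParameterError("t_points must be increasing")
    rng = np.random.default_rng(seed)
    der = derive_quantities(params)
    if der.f == 0.0:
        return np.zeros((t_points.size, n_traj), dtype=int)
    t_max = float(t_points[-1])
    nu = der.b * der.f  # synthesis rate
    n_exp = nu * t_max
    n_cols = int(n_exp + 6.0 * math.sqrt(n_exp + 1.0) + 30)
    chunk = max(1, min(n_traj, _max_block // max(n_cols, 1)))
    out = np.empty((t_points.size, n_traj), dtype=np.int64)
    done = 0
    if init not in ("inactive-start", "burst-start"):
        raise InvalidParameterError(f"invalid init spec {init!r}")
    first_col = "inactive" if init == "inactive-start" else "burst"
    while done < n_traj:
        n = min(chunk, n_traj - done)
        first = _synthesis_intervals(params, n, n_cols, rng, first_col)
        births = np.cumsum(first, axis=1)
        while births[:, -1].min() <= t_max:
            extra = _synthesis_intervals(params, n, n_cols // 2 + 8, rng, "renewal")
            births = np.concatenate(
                [births, births[:, -1:] + np.cumsum(extra, axis=1)], axis=1
            )
        deaths = births + rng.exponential(params.tau_m, births.shape)
        for k, t in enumerate(t_points):
            out[k, done : done + n] = ((births <= t) & (deaths > t)).sum(axis=1)
        done += n
    return out


def ensemble_moments(
    params: BurstParams,
    n_traj: int,
    t_grid,
    seed: int | None = None,
    init: str = "inactive-start",
) -> pd.DataFrame:
    """Ensemble (mean, variance, Fano) of the copy number on a time grid."""
    counts = ensemble_counts(params, t_grid, n_traj, seed, init)
    mean = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fano = np.where(mean > 0, var / mean, np.nan)
    return pd.DataFrame(
        {"time": np.atleast_1d(t_grid), "mean": mean, "var": var, "fano": fano}
    )


# ---------------------------------------------------------------------------
# phase-level renewal simulation (transient response, telegraph comparator)
# ---------------------------------------------------------------------------


@dataclass
class PhaseRenewalResult:
    t_grid: np.ndarray
    P_A: np.ndarray
    m_mean: np.ndarray
    m_var: np.ndarray
    fano: np.ndarray
    n_traj: int
    seed: int | None = None


def simulate_phase_renewal(
    f_A,
    f_I,
    f_I_init,
    tau_P: float,
    tau_m: float,
    t_grid,
    n_traj: int = 10_000,
    seed: int | None = None,
) -> PhaseRenewalResult:
    """Monte-Carlo estimate of P_A(t) and the mean copy number.

    The gene starts silent; the first inactive interval is drawn from
    ``f_I_init``, after which active (``f_A``) and inactive (``f_I``)
    intervals alternate.  While active, transcripts are produced at rate
    ``1/tau_P``; each decays with an exponential lifetime ``tau_m``.  The
    distribution arguments are any objects exposing ``sample(rng, size)`` and
    ``mean`` (e.g. :class:`~burstevents.core.EventDurationModel` or the
    transient-module distributions).
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if t_grid[-1] <= 0:
        raise InvalidParameterError("t_end must be positive")
    rng = np.random.default_rng(seed)
    t_end = float(t_grid[-1])
    mean_cycle = float(f_A.mean) + float(f_I.mean)
    n_cyc = int(t_end / mean_cycle * 1.3 + 12)

    i0 = np.asarray(f_I_init.sample(rng, n_traj), dtype=float)
    A = np.asarray(f_A.sample(rng, (n_traj, n_cyc)), dtype=float)
    I = np.asarray(f_I.sample(rng, (n_traj, n_cyc)), dtype=float)
    while True:
        cyc = np.cumsum(A + I, axis=1)
        a_start = i0[:, None] + np.concatenate(
            [np.zeros((n_traj, 1)), cyc[:, :-1]], axis=1
        )
        if (a_start[:, -1] + A[:, -1]).min() > t_end:
            break
        extra = max(4, n_cyc // 2)
        A = np.concatenate([A, f_A.sample(rng, (n_traj, extra))], axis=1)
        I = np.concatenate([I, f_I.sample(rng, (n_traj, extra))], axis=1)
        n_cyc += extra
    a_end = a_start + A

    # synthesis events: Poisson(rate 1/tau_P) on each active interval,
    # truncated at the observation horizon (later births can never be seen)
    A_eff = np.clip(t_end - a_start, 0.0, A)
    n_syn = rng.poisson(A_eff / tau_P)
    tot = int(n_syn.sum())
    flat_start = np.repeat(a_start.ravel(), n_syn.ravel())
    flat_len = np.repeat(A_eff.ravel(), n_syn.ravel())
    births = flat_start + rng.uniform(0.0, 1.0, tot) * flat_len
    deaths = births + rng.exponential(tau_m, tot)
    traj_id = np.repeat(
        np.repeat(np.arange(n_traj), n_cyc), n_syn.ravel()
    )

    P_A = np.empty(t_grid.size)
    m_mean = np.empty(t_grid.size)
    m_var = np.empty(t_grid.size)
    for k, t in enumerate(t_grid):
        P_A[k] = ((a_start <= t) & (t < a_end)).any(axis=1).mean()
        alive = (births <= t) & (deaths > t)
        per_traj = np.bincount(traj_id[alive], minlength=n_traj)
        m_mean[k] = per_traj.mean()
        m_var[k] = per_traj.var(ddof=1) if n_traj > 1 else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        fano = np.where(m_mean > 0, m_var / m_mean, np.nan)
    return PhaseRenewalResult(t_grid, P_A, m_mean, m_var, fano, n_traj, seed)


def simulate_telegraph(
    k_on: float,
    k_off: float,
    k_syn: float,
    tau_m: float,
    t_grid,
    n_traj: int = 10_000,
    seed: int | None = None,
) -> PhaseRenewalResult:
    """Ensemble simulation of the two-state telegraph model.

    Exponential ON (mean ``1/k_off``) and OFF (mean ``1/k_on``) dwell times
    with Poisson synthesis at rate ``k_syn`` while ON; the gene starts at the
    beginning of an OFF period.  At times well beyond relaxation the mean
    approaches ``k_syn tau_m k_on/(k_on+k_off)``.
    """
    if min(k_on, k_off, k_syn) <= 0:
        raise InvalidParameterError("telegraph rates must be positive")
    from .core import EventDurationModel

    f_on = EventDurationModel("exponential", 1.0 / k_off)
    f_off = EventDurationModel("exponential", 1.0 / k_on)
    return simulate_phase_renewal(
        f_on, f_off, f_off, 1.0 / k_syn, tau_m, t_grid, n_traj, seed
    )
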