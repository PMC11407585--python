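"""Mean-Fano curve families and parameter-trajectory fitting.

As a regulator's occupancy sweeps from 0 to 1, a gene traces a curve in the
(mean, Fano) plane whose shape betrays which bursting parameters are being
regulated (tau_P-only and tau_S-only regulation bound the family).  This
module generates those curves from a (baseline, endpoint) parameter pair and
fits the trajectory parameters to observed (mean, Fano) scatter by minimizing
squared orthogonal distances in (log m, log F) space with a multi-start
simplex search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core import BurstParams, InvalidParameterError
from .regulation import interpolate_params
from .steady_state import mean_fano_exponential_vec

__all__ = [
    "MFDataset",
    "FitSpec",
    "FitResult",
    "mf_curve",
    "mf_curve_from_spec",
    "fit_mf_data",
    "synth_mf_dataset",
    "default_o_grid",
]

_PAIR_KEYS = ("tau_PU", "tau_PB", "p1U", "p1B", "tau_SU", "tau_SB")


@dataclass
class MFDataset:
    m_mean: np.ndarray
    fano: np.ndarray
    weight: np.ndarray | None = None
    provenance: str = "user"

    def __post_init__(self) -> None:
        self.m_mean = np.asarray(self.m_mean, dtype=float)
        self.fano = np.asarray(self.fano, dtype=float)
        if np.any(self.m_mean <= 0) or np.any(self.fano <= 0):
            raise InvalidParameterError("mean and Fano values must be positive")
        if self.weight is not None:
            self.weight = np.asarray(self.weight, dtype=float)

    def __len__(self) -> int:
        return self.m_mean.size

    def to_frame(self) -> pd.DataFrame:
        d = {"m_mean": self.m_mean, "fano": self.fano}
        if self.weight is not None:
            d["weight"] = self.weight
        return pd.DataFrame(d)


def default_o_grid(n: int = 400) -> np.ndarray:
    """Occupancy grid concentrated where dose-response curves bend."""
    r = np.geomspace(1e-4, 1e4, n - 2)
    return np.concatenate([[0.0], r / (1.0 + r), [1.0]])


def mf_curve(
    baseline: BurstParams, endpoint: BurstParams, O_grid=None
) -> tuple[np.ndarray, np.ndarray]:
    """(mean, Fano) along the regulation path from baseline to endpoint.

    Durations interpolate rate-linearly and probabilities flow-linearly in
    the occupancy; the statistics are the exact renewal results for
    exponential events.
    """
    if O_grid is None:
        O_grid = default_o_grid()
    O_grid = np.asarray(O_grid, dtype=float)
    vals = interpolate_params(baseline, endpoint, O_grid)
    return mean_fano_exponential_vec(
        vals["tau_P"], vals["tau_S1"], vals["tau_S2"], vals["tau_S3"],
        vals["p1"], vals["p2"], baseline.tau_m,
    )


@dataclass(frozen=True)
class FitSpec:
    """Which trajectory parameters are free in a mean-Fano fit.

    ``free`` names a subset of ``tau_PU, tau_PB, p1U, p1B, tau_SU, tau_SB``
    (``tau_P`` is shorthand for an unregulated, shared tau_PU = tau_PB;
    similarly ``p1`` and ``tau_S``); ``fixed`` supplies the remaining values
    and ``tau_m``.  The inactive phase is a single exponential block
    (direct-tau_S parameterization).
    """

    free: tuple[str, ...]
    fixed: dict = field(default_factory=dict)
    tau_m: float = 5.0

    def expand(self, theta: dict) -> dict:
        full = dict(self.fixed)
        full.update(theta)
        for short in ("tau_P", "p1", "tau_S"):
            if short in full:
                full[short + "U"] = full[short + "B"] = full.pop(short)
        missing = [k for k in _PAIR_KEYS if k not in full]
        if missing:
            raise InvalidParameterError(f"fit spec incomplete: missing {missing}")
        return full

    def pair(self, theta: dict) -> tuple[BurstParams, BurstParams]:
        full = self.expand(theta)
        base = BurstParams.from_inactive_mean(
            full["tau_PU"], full["tau_SU"], full["p1U"], self.tau_m
        )
        end = BurstParams.from_inactive_mean(
            full["tau_PB"], full["tau_SB"], full["p1B"], self.tau_m
        )
        return base, end

    def curve(self, theta: dict, O_grid=None):
        base, end = self.pair(theta)
        return mf_curve(base, end, O_grid)


@dataclass
class FitResult:
    spec: FitSpec
    params: dict
    loss: float
    converged: bool
    n_restarts: int


def _ortho_distance2(px, py, cx, cy):
    """Squared distance from points to the polyline (cx, cy), vectorized."""
    d2 = (px[:, None] - cx[None, :]) ** 2 + (py[:, None] - cy[None, :]) ** 2
    j = np.argmin(d2, axis=1)
    best = d2[np.arange(px.size), j]
    # refine on the two segments adjacent to the nearest vertex
    for off in (-1, 0):
        a = np.clip(j + off, 0, cx.size - 2)
        ax, ay = cx[a], cy[a]
        bx, by = cx[a + 1], cy[a + 1]
        vx, vy = bx - ax, by - ay
        den = vx**2 + vy**2
        t = np.where(den > 0, ((px - ax) * vx + (py - ay) * vy) / np.where(den > 0, den, 1.0), 0.0)
        t = np.clip(t, 0.0, 1.0)
        seg = (px - (ax + t * vx)) ** 2 + (py - (ay + t * vy)) ** 2
        best = np.minimum(best, seg)
    return best


_DEFAULT_BOUNDS = {
    "tau_PU": (1e-3, 1e3),
    "tau_PB": (1e-3, 1e3),
    "tau_SU": (1e-2, 1e4),
    "tau_SB": (1e-2, 1e4),
    "p1U": (1e-3, 0.9999),
    "p1B": (1e-3, 0.9999),
    "tau_P": (1e-3, 1e3),
    "tau_S": (1e-2, 1e4),
    "p1": (1e-3, 0.9999),
}


def _to_internal(name, v, lo, hi):
    if name.startswith("p1"):
        return math.log(v / (1.0 - v))
    return math.log(v)


def _from_internal(name, z, lo, hi):
    z = min(max(z, -50.0), 50.0)
    if name.startswith("p1"):
        v = 1.0 / (1.0 + math.exp(-z))
    else:
        v = math.exp(z)
    return min(max(v, lo), hi)


def fit_mf_data(
    data: MFDataset,
    spec: FitSpec,
    bounds: dict | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    n_curve: int = 400,
    anchor_endpoints: bool = True,
) -> FitResult:
    """Fit trajectory parameters to (mean, Fano) data.

    Minimizes the summed squared orthogonal-projection residuals between the
    data points and the parametric curve in (log m, log F) space using a
    bounded Nelder-Mead simplex with ``n_restarts`` seeded multi-starts.

    Because the regulation path is a straight line in (odds(p1), 1/tau_S)
    coordinates, the curve *as a set* does not identify where the baseline
    and the fully-bound endpoint sit on it; with ``anchor_endpoints`` (the
    default) the lowest- and highest-expression data points are additionally
    matched to the curve's occupancy-0 and occupancy-1 ends, identifying the
    trajectory end to end.
    """
    if len(data) < max(4, len(spec.free)):
        raise InvalidParameterError(
            "need at least max(4, n_free) data points for a trajectory fit"
        )
    bounds = {**_DEFAULT_BOUNDS, **(bounds or {})}
    rng = np.random.default_rng(seed)
    px = np.log(data.m_mean)
    py = np.log(data.fano)
    w = data.weight if data.weight is not None else np.ones(px.size)
    w = w / w.sum()
    O_grid = default_o_grid(n_curve)
    names = spec.free

    def loss_z(z):
        theta = {
            n: _from_internal(n, zi, *bounds[n]) for n, zi in zip(names, z)
        }
        try:
            m, F = spec.curve(theta, O_grid)
        except (InvalidParameterError, FloatingPointError):
            return 1e9
        ok = np.isfinite(m) & np.isfinite(F) & (m > 0) & (F > 0)
        if ok.sum() < 4:
            return 1e9
        cx, cy = np.log(m[ok]), np.log(F[ok])
        d2 = _ortho_distance2(px, py, cx, cy)
        total = float(np.sum(w * d2))
        if anchor_endpoints:
            # pin the lowest/highest-expression data points to the curve's
            # occupancy-0/1 ends; without this the baseline can slide along
            # the (odds, rate)-linear path
            i_lo, i_hi = int(np.argmin(px)), int(np.argmax(px))
            total += float(
                w[i_lo] * ((px[i_lo] - cx[0]) ** 2 + (py[i_lo] - cy[0]) ** 2)
                + w[i_hi] * ((px[i_hi] - cx[-1]) ** 2 + (py[i_hi] - cy[-1]) ** 2)
            )
        return total

    starts = []
    for k in range(n_restarts):
        z0 = []
        for n in names:
            lo, hi = bounds[n]
            if k == 0 and n in spec.fixed:
                v = spec.fixed[n]
            else:
                if n.startswith("p1"):
                    v = rng.uniform(0.05, 0.995)
                else:
                    v = math.exp(rng.uniform(math.log(lo * 10), math.log(hi / 10)))
            z0.append(_to_internal(n, v, lo, hi))
        starts.append(np.array(z0))

    best = None
    with np.errstate(all="ignore"):
        for z0 in starts:
            res = minimize(
                loss_z, z0, method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-12},
            )
            if best is None or res.fun < best.fun:
                best = res
        # polish: restart the simplex from the incumbent (a fresh simplex
        # escapes the shrunken one that multi-start NM often stalls in)
        for _ in range(2):
            res = minimize(
                loss_z, best.x, method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-13},
            )
            if res.fun < best.fun:
                best = res
    theta = {n: _from_internal(n, zi, *bounds[n]) for n, zi in zip(names, best.x)}
    full = spec.expand(theta)
    return FitResult(
        spec=spec,
        params={**{k: full[k] for k in _PAIR_KEYS}, **theta},
        loss=float(best.fun),
        converged=bool(best.success or best.fun < 1e-10),
        n_restarts=n_restarts,
    )


def synth_mf_dataset(
    spec: FitSpec,
    true_params: dict,
    n_points: int,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> MFDataset:
    """Synthetic (mean, Fano) dataset along a known regulation trajectory.

    Occupancies are stratified-uniform on [0, 1] and include both endpoints
    (the unstimulated and saturated conditions), so the trajectory is
    identified end to end; multiplicative log-normal noise with coefficient
    of variation ``noise_cv`` (mean 1) is applied independently to the mean
    and the Fano factor.
    """
    if noise_cv < 0:
        raise InvalidParameterError("noise_cv must be nonnegative")
    if n_points < 4:
        raise InvalidParameterError("need at least 4 points")
    rng = np.random.default_rng(seed)
    k = n_points - 2
    O = np.concatenate([[0.0, 1.0], (np.arange(k) + rng.uniform(0, 1, k)) / k])
    m, F = spec.curve(true_params, np.sort(O))
    if noise_cv > 0:
        sig = math.sqrt(math.log(1.0 + noise_cv**2))
        m = m * rng.lognormal(-0.5 * sig**2, sig, n_points)
        F = F * rng.lognormal(-0.5 * sig**2, sig, n_points)
    return MFDataset(m_mean=m, fano=F, provenance="synthetic")
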