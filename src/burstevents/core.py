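"""Domain types and parameter algebra for the event-based bursting model.

A transcriptional burst cycle is a sequence of four stochastic events:
``E_P`` (one mRNA released into productive elongation per completed event),
``E_S1`` (scaffold disassembly), ``E_S2`` (PIC assembly) and ``E_S3``
(nucleosome-governed delay of promoter access).  Two probabilities order the
events: after each ``E_P`` another ``E_P`` follows with probability ``p1``
(otherwise the inactive phase starts with ``E_S1``); after ``E_S1`` and after
each ``E_S3``, another ``E_S3`` occurs with probability ``p2`` (otherwise
``E_S2`` follows).  After ``E_S2`` a burst starts with probability ``p1``,
otherwise a new inactive cycle begins.  Mature mRNA decays as a first-order
Poisson process with mean lifetime ``tau_m``.

All times are in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "EVENT_KINDS",
    "EventDurationModel",
    "BurstParams",
    "DerivedQuantities",
    "InvalidParameterError",
    "compose_tau_s",
    "derive_quantities",
    "sample_duration",
]

EVENT_KINDS = ("E_P", "E_S1", "E_S2", "E_S3")

_FAMILIES = ("exponential", "gamma", "delayed-exponential")


class InvalidParameterError(ValueError):
    """Raised when a kinetic parameter violates its domain."""


@dataclass(frozen=True)
class EventDurationModel:
    """Duration distribution of a single event.

    Parameters
    ----------
    family:
        ``exponential`` (the default basis of the model), ``gamma``
        (unimodal alternative, ``cv**2 = 1/shape``) or
        ``delayed-exponential`` (a hard refractory offset ``delay`` followed
        by an exponential tail; used to model the refractory period of
        ``E_S1``).
    mean:
        Mean duration in minutes (includes the delay, if any).
    cv:
        Coefficient of variation.  Forced to 1 for the exponential family and
        to ``1 - delay/mean`` for the delayed-exponential family.
    delay:
        Refractory offset in minutes, only meaningful for
        ``delayed-exponential``; must satisfy ``0 <= delay < mean``.
    """

    family: str = "exponential"
    mean: float = 1.0
    cv: float = 1.0
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise InvalidParameterError(f"unknown duration family {self.family!r}")
        if not (self.mean > 0 and np.isfinite(self.mean)):
            raise InvalidParameterError("event mean duration must be positive")
        if self.family == "exponential":
            object.__setattr__(self, "cv", 1.0)
            object.__setattr__(self, "delay", 0.0)
        elif self.family == "gamma":
            if not self.cv > 0:
                raise InvalidParameterError("gamma cv must be positive")
            object.__setattr__(self, "delay", 0.0)
        else:  # delayed-exponential
            if not 0.0 <= self.delay < self.mean:
                raise InvalidParameterError(
                    "delayed-exponential requires 0 <= delay < mean"
                )
            object.__setattr__(self, "cv", 1.0 - self.delay / self.mean)

    # -- moments -----------------------------------------------------------
    @property
    def variance(self) -> float:
        if self.family == "gamma":
            return (self.cv * self.mean) ** 2
        if self.family == "delayed-exponential":
            return (self.mean - self.delay) ** 2
        return self.mean**2

    @property
    def gamma_shape(self) -> float:
        if self.family != "gamma":
            raise InvalidParameterError("gamma_shape only defined for gamma family")
        return 1.0 / self.cv**2

    @property
    def gamma_scale(self) -> float:
        return self.mean / self.gamma_shape

    # -- Laplace transform -------------------------------------------------
    def laplace(self, s):
        """Laplace transform E[exp(-s T)] of the duration; ``s`` may be an array."""
        s = np.asarray(s, dtype=float)
        if self.family == "exponential":
            out = 1.0 / (1.0 + s * self.mean)
        elif self.family == "gamma":
            k = self.gamma_shape
            out = (1.0 + s * self.gamma_scale) ** (-k)
        else:
            tail = self.mean - self.delay
            out = np.exp(-s * self.delay) / (1.0 + s * tail)
        return out if out.shape else float(out)

    # -- sampling ----------------------------------------------------------
    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "exponential":
            return rng.exponential(self.mean, size)
        if self.family == "gamma":
            return rng.gamma(self.gamma_shape, self.gamma_scale, size)
        return self.delay + rng.exponential(self.mean - self.delay, size)


def sample_duration(model: EventDurationModel, rng: np.random.Generator, size=None):
    """Draw event duration(s) from ``model`` using the seeded generator ``rng``."""
    return model.sample(rng, size)


def compose_tau_s(tau_S1: float, tau_S2: float, tau_S3: float, p2: float) -> float:
    """Mean duration of one inactive cycle, tau_S = tau_S1 + tau_S2 + p2*tau_S3/(1-p2).

    The geometric repetition of ``E_S3`` (continuation probability ``p2``)
    contributes ``p2/(1-p2)`` occurrences on average.
    """
    if not 0.0 <= p2 < 1.0:
        raise InvalidParameterError("p2 must lie in [0, 1)")
    if tau_S1 <= 0 or tau_S2 < 0 or tau_S3 < 0:
        raise InvalidParameterError("inactive-event durations must be nonnegative (tau_S1 > 0)")
    return tau_S1 + tau_S2 + p2 * tau_S3 / (1.0 - p2)


@dataclass(frozen=True)
class BurstParams:
    """The six bursting parameters plus the mRNA lifetime.

    ``tau_S2``/``tau_S3`` may be zero, which removes the corresponding event;
    that degenerate form (with ``p2 = 0``) is how a directly specified
    single-exponential inactive block ``tau_S`` is represented (see
    :meth:`from_inactive_mean`).  ``p1 = 1`` or ``p2 = 1`` would give infinite
    expected phase durations and are rejected; ``p1 = 0`` (no bursting) and
    ``p2 = 0`` (no ``E_S3``) are allowed degenerate inputs.
    """

    tau_P: float
    tau_S1: float
    tau_S2: float = 0.0
    tau_S3: float = 0.0
    p1: float = 0.5
    p2: float = 0.0
    tau_m: float = 5.0
    duration_models: Mapping[str, EventDurationModel] | None = field(default=None)

    def __post_init__(self) -> None:
        for name in ("tau_P", "tau_S1", "tau_m"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise InvalidParameterError(f"{name} must be positive and finite")
        for name in ("tau_S2", "tau_S3"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be nonnegative")
        for name in ("p1", "p2"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1)")
        if self.duration_models:
            for kind, model in self.duration_models.items():
                if kind not in EVENT_KINDS:
                    raise InvalidParameterError(f"unknown event kind {kind!r}")
                tau = {
                    "E_P": self.tau_P,
                    "E_S1": self.tau_S1,
                    "E_S2": self.tau_S2,
                    "E_S3": self.tau_S3,
                }[kind]
                if not math.isclose(model.mean, tau, rel_tol=1e-9, abs_tol=1e-12):
                    raise InvalidParameterError(
                        f"duration model mean for {kind} ({model.mean}) does not "
                        f"match the corresponding tau field ({tau})"
                    )

    @classmethod
    def from_inactive_mean(
        cls,
        tau_P: float,
        tau_S: float,
        p1: float,
        tau_m: float = 5.0,
        duration_models: Mapping[str, EventDurationModel] | None = None,
    ) -> "BurstParams":
        """Parameterize the inactive cycle as one exponential block of mean ``tau_S``."""
        return cls(
            tau_P=tau_P,
            tau_S1=tau_S,
            tau_S2=0.0,
            tau_S3=0.0,
            p1=p1,
            p2=0.0,
            tau_m=tau_m,
            duration_models=duration_models,
        )

    # -- duration-model access --------------------------------------------
    def model_for(self, kind: str) -> EventDurationModel:
        """Duration model for one event kind (exponential with the tau field by default)."""
        if self.duration_models and kind in self.duration_models:
            return self.duration_models[kind]
        tau = {
            "E_P": self.tau_P,
            "E_S1": self.tau_S1,
            "E_S2": self.tau_S2,
            "E_S3": self.tau_S3,
        }[kind]
        return EventDurationModel("exponential", tau)

    @property
    def tau_S(self) -> float:
        return compose_tau_s(self.tau_S1, self.tau_S2, self.tau_S3, self.p2)

    @property
    def all_exponential(self) -> bool:
        if not self.duration_models:
            return True
        return all(m.family == "exponential" for m in self.duration_models.values())

    def to_dict(self) -> dict:
        return {
            "tau_P": self.tau_P,
            "tau_S1": self.tau_S1,
            "tau_S2": self.tau_S2,
            "tau_S3": self.tau_S3,
            "p1": self.p1,
            "p2": self.p2,
            "tau_m": self.tau_m,
        }


@dataclass(frozen=True)
class DerivedQuantities:
    """Burst-level quantities implied by the event parameters.

    ``tau_A = tau_P/(1-p1)`` (mean active phase), ``tau_I = tau_S/p1`` (mean
    inactive phase), ``T = tau_A + tau_I`` (burst period), ``b = 1/(1-p1)``
    (mean burst size), ``f = 1/T`` (burst frequency), and the steady-state
    mean ``m_mean = b*f*tau_m``.  ``c`` and ``d`` are the dimensionless phase
    durations ``tau_A/tau_m`` and ``tau_I/tau_m`` that govern the Fano factor.
    """

    tau_S: float
    tau_A: float
    tau_I: float
    T: float
    b: float
    f: float
    m_mean: float
    c: float
    d: float

    @property
    def infinite_period(self) -> bool:
        return not np.isfinite(self.T)


def derive_quantities(params: BurstParams) -> DerivedQuantities:
    """Map event parameters to burst-level quantities.

    For ``p1 = 0`` the gene never bursts: the period is infinite and the
    steady-state mean is zero.
    """
    tau_S = params.tau_S
    tau_A = params.tau_P / (1.0 - params.p1)
    if params.p1 == 0.0:
        tau_I = math.inf
        T = math.inf
        f = 0.0
        m_mean = 0.0
    else:
        tau_I = tau_S / params.p1
        T = tau_A + tau_I
        f = 1.0 / T
        m_mean = params.tau_m / (
            params.tau_P + (1.0 - params.p1) / params.p1 * tau_S
        )
    b = 1.0 / (1.0 - params.p1)
    return DerivedQuantities(
        tau_S=tau_S,
        tau_A=tau_A,
        tau_I=tau_I,
        T=T,
        b=b,
        f=f,
        m_mean=m_mean,
        c=tau_A / params.tau_m,
        d=tau_I / params.tau_m,
    )
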