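"""Independent oracles used by the test suite.

These deliberately avoid the package's own analytic machinery: truncated
master-equation stationary solvers for the telegraph and bursty birth-death
models, Monte-Carlo standard errors, and a brute-force constrained minimizer
for the Fano lower bound.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import spsolve


def telegraph_master_equation(k_on, k_off, k_syn, tau_m, n_max=400):
    """Stationary (mean, Fano) of the telegraph model from the master equation.

    State (g, n): gene off/on, n transcripts; synthesis at rate k_syn while
    on, degradation at rate n/tau_m.  Solved by direct sparse linear algebra
    on a truncated ladder.
    """
    delta = 1.0 / tau_m
    N = n_max + 1
    dim = 2 * N

    def idx(g, n):
        return g * N + n

    # A[i, j] = rate j -> i; diagonal = -outflow.  Solve A p = 0 with
    # normalization replacing one row.
    A = lil_matrix((dim, dim))
    for g in (0, 1):
        for n in range(N):
            j = idx(g, n)
            out = n * delta + (k_on if g == 0 else k_off)
            if g == 1 and n < N - 1:
                out += k_syn
            A[j, j] -= out
            if n > 0:
                A[idx(g, n - 1), j] += n * delta
            A[idx(1 - g, n), j] += k_on if g == 0 else k_off
            if g == 1 and n < N - 1:
                A[idx(1, n + 1), j] += k_syn
    A = A.tolil()
    A[dim - 1, :] = 1.0
    rhs = np.zeros(dim)
    rhs[dim - 1] = 1.0
    p = spsolve(A.tocsr(), rhs)
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    n_vals = np.tile(np.arange(N), 2)
    mean = float((p * n_vals).sum())
    var = float((p * n_vals**2).sum() - mean**2)
    return mean, var / mean


def bursty_birth_death_master_equation(freq, b_mean, tau_m, n_max=600):
    """Stationary (mean, Fano) for instantaneous geometric bursts.

    Bursts arrive at rate ``freq``; each adds G ~ Geometric(1/b_mean) on
    {1, 2, ...} transcripts; each transcript decays at rate 1/tau_m.  This is
    the tau_P -> 0 limit of the event model with an exponential inactive
    phase.
    """
    delta = 1.0 / tau_m
    q = 1.0 - 1.0 / b_mean  # geometric continuation probability
    N = n_max + 1
    A = lil_matrix((N, N))
    for n in range(N):
        A[n, n] -= n * delta + freq
        if n > 0:
            A[n - 1, n] += n * delta
        # burst of size k>=1 from state n
        for k in range(1, N - n):
            A[n + k, n] += freq * (1.0 - q) * q ** (k - 1)
        # overflow mass truncated
    A = A.tolil()
    A[N - 1, :] = 1.0
    rhs = np.zeros(N)
    rhs[N - 1] = 1.0
    p = spsolve(A.tocsr(), rhs)
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    n_vals = np.arange(N)
    mean = float((p * n_vals).sum())
    var = float((p * n_vals**2).sum() - mean**2)
    return mean, var / mean


def mc_standard_errors(counts: np.ndarray):
    """(SE of mean, SE of variance, SE of Fano) for a sample of counts.

    Variance SE from the fourth central moment; Fano SE by the delta method
    including the mean-variance covariance (third moment).
    """
    c = np.asarray(counts, dtype=float)
    n = c.size
    m = c.mean()
    s2 = c.var(ddof=1)
    mu = c - m
    m3 = float(np.mean(mu**3))
    m4 = float(np.mean(mu**4))
    se_mean = float(np.sqrt(s2 / n))
    var_s2 = max((m4 - s2**2 * (n - 3) / (n - 1)) / n, 0.0)
    se_var = float(np.sqrt(var_s2))
    F = s2 / m
    var_F = max((var_s2 - 2 * F * m3 / n + F * F * s2 / n) / m**2, 0.0)
    return se_mean, se_var, float(np.sqrt(var_F))


def fano_min_grid(m_mean, tau_S0, p10, tau_m, n_grid=100):
    """Brute-force minimum Fano over tau_S >= tau_S0, p1 <= p10 at fixed mean."""
    from burstevents.core import BurstParams
    from burstevents.steady_state import variance_and_fano

    best = np.inf
    for p1 in np.linspace(0.2, p10, n_grid):
        for tau_S in np.geomspace(tau_S0, 500.0, n_grid):
            tau_P = tau_m / m_mean - (1.0 - p1) / p1 * tau_S
            if tau_P <= 0:
                continue
            F = variance_and_fano(
                BurstParams.from_inactive_mean(tau_P, tau_S, p1, tau_m)
            )[1]
            best = min(best, F)
    return best
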