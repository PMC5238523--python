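"""The Tracy-Widom (beta = 1, GOE) distribution of the largest eigenvalue.

Computed from the Hastings-McLeod solution q of Painleve II,

    q'' = s q + 2 q^3,      q(s) ~ Ai(s)  as s -> +inf,

via the classical determinantal representations

    F2(s) = exp(-int_s^inf (x - s) q(x)^2 dx),
    F1(s) = sqrt(F2(s)) * exp(-0.5 * int_s^inf q(x) dx).

The ODE is integrated once (downwards from s0 = 8 with Airy initial data,
carrying the integrals as extra state) and the log survival function is
tabulated on a dense grid.  Far in the right tail, where 1 - F1 underflows
any direct evaluation, the asymptotic expansion

    log(1 - F1(s)) ~ -(2/3) s^(3/2) - (3/4) log s - log(4 sqrt(pi))

is used instead, so p-value thresholds as extreme as 1e-100 remain meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.special import airy

__all__ = ["tw1_logsf", "tw1_sf"]

_S0 = 8.0
_SMIN = -10.0
_CROSSOVER = 6.0  # switch to the asymptotic tail above this point
_grid = None
_logsf_grid = None


def _build_table():
    global _grid, _logsf_grid
    ai0, aip0, _, _ = airy(_S0)
    int_ai = quad(lambda x: airy(x)[0], _S0, np.inf)[0]
    int_ai2 = quad(lambda x: airy(x)[0] ** 2, _S0, np.inf)[0]
    int_xai2 = quad(lambda x: x * airy(x)[0] ** 2, _S0, np.inf)[0]

    def rhs(s, v):
        q, qp, _, _, _ = v
        return [qp, s * q + 2.0 * q**3, -q, -q * q, -s * q * q]

    sol = solve_ivp(
        rhs,
        (_S0, _SMIN),
        [ai0, aip0, int_ai, int_ai2, int_xai2],
        rtol=1e-11,
        atol=1e-13,
        dense_output=True,
        method="RK45",
    )
    s = np.arange(_SMIN, _S0, 0.005)
    q, qp, I, J, K = sol.sol(s)
    log_f2 = -(K - s * J)
    log_f1 = 0.5 * log_f2 - 0.5 * I
    f1 = np.exp(log_f1)
    with np.errstate(divide="ignore"):
        logsf = np.where(f1 < 1.0, np.log1p(-np.minimum(f1, 1.0 - 1e-300)), -np.inf)
    _grid, _logsf_grid = s, logsf


def _tail_logsf(s):
    return -(2.0 / 3.0) * s**1.5 - 0.75 * np.log(s) - np.log(4.0 * np.sqrt(np.pi))


def tw1_logsf(x):
    """log of the survival function P(TW1 > x); vectorized."""
    if _grid is None:
        _build_table()
    x = np.asarray(x, dtype=float)
    out = np.empty(x.shape)
    tail = x >= _CROSSOVER
    out[tail] = _tail_logsf(x[tail])
    body = ~tail
    xv = np.clip(x[body], _SMIN, _CROSSOVER)
    out[body] = np.interp(xv, _grid, _logsf_grid)
    # below the tabulated range the SF is 1 to double precision
    out[x <= _SMIN] = 0.0
    return out if out.shape else float(out)


def tw1_sf(x):
    """Survival function P(TW1 > x) (underflows to 0 beyond ~ 1e-308)."""
    return np.exp(tw1_logsf(x))
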