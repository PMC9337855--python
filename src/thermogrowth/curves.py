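"""Growth-curve primitives: exponential and power-law size functions.

Rosette growth is modelled by the ODE dM/dt = r * M**beta.  With beta = 1
growth is exponential, M(t) = M0 * exp(r * t); with beta < 1 the relative
growth rate declines as the plant gets bigger and the ODE integrates to

    M(t) = (M0**(1 - beta) + r * t * (1 - beta)) ** (1 / (1 - beta)).

``beta`` is unitless; ``r`` has units area**(1-beta) / day (1/day in the
exponential case); ``M0`` is the size at the start of the temperature
treatment (the model clock's t = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# below this |1 - beta| the power-law formula is numerically degenerate and
# the exponential limit is used instead
_BETA_ONE_TOL = 1e-8


@dataclass(frozen=True)
class GrowthParams:
    """Parameter triple (M0, r, beta) of a power-law growth curve."""

    M0: float
    r: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not self.M0 > 0:
            raise ValueError(f"M0 must be positive, got {self.M0}")
        if not np.isfinite(self.r):
            raise ValueError(f"r must be finite, got {self.r}")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError(f"beta must lie in (0, 1], got {self.beta}")


def exponential_size(t, M0: float, r: float):
    """Size under exponential growth, M0 * exp(r * t)."""
    t = np.asarray(t, dtype=float)
    return M0 * np.exp(r * t)


def powerlaw_size(t, M0: float, r: float, beta: float):
    """Size under power-law growth at time(s) ``t`` (days from treatment start).

    Dispatches to :func:`exponential_size` when beta is within 1e-8 of 1.
    Raises ``ValueError`` when the base M0**(1-beta) + r*t*(1-beta) is not
    positive for some requested t (the curve is undefined there).
    """
    t = np.asarray(t, dtype=float)
    a = 1.0 - beta
    if abs(a) < _BETA_ONE_TOL:
        return exponential_size(t, M0, r)
    base = M0**a + r * t * a
    if np.any(base <= 0):
        bad = np.atleast_1d(t)[np.atleast_1d(base) <= 0]
        raise ValueError(
            f"power-law curve undefined (nonpositive base) at t={bad.min():g}"
            f" for M0={M0:g}, r={r:g}, beta={beta:g}"
        )
    return base ** (1.0 / a)


def growth_curve(t, params: GrowthParams):
    """Evaluate the growth curve described by ``params``."""
    return powerlaw_size(t, params.M0, params.r, params.beta)


def powerlaw_gradient(t, logM0: float, r: float, beta: float):
    """Curve values and partial derivatives wrt (log M0, r, beta).

    The M0 coordinate is log-scale (keeps M0 positive inside optimizers).
    Returns ``(f, J)`` with ``J`` of shape (len(t), 3).  Falls back to the
    exponential branch (where df/dbeta is still computed from the power-law
    limit: 0.5 * r^2 t^2 f + ... is not needed; the exponential model simply
    has no beta column — callers slice it off).
    """
    t = np.asarray(t, dtype=float)
    a = 1.0 - beta
    if abs(a) < _BETA_ONE_TOL:
        f = np.exp(logM0 + r * t)
        J = np.empty((t.size, 3))
        J[:, 0] = f
        J[:, 1] = t * f
        # limit of the power-law derivative as beta -> 1
        J[:, 2] = f * (0.5 * (r * t) ** 2 + logM0 * r * t)
        return f, J
    eaL = np.exp(a * logM0)  # M0**(1-beta)
    u = eaL + r * t * a
    if np.any(u <= 0):
        raise ValueError("nonpositive power-law base inside gradient")
    f = u ** (1.0 / a)
    logu = np.log(u)
    J = np.empty((t.size, 3))
    J[:, 0] = f / u * eaL
    J[:, 1] = t * f / u
    # d/dbeta with a = 1-beta: f * [ (-logM0*eaL - r*t)/(a*u) + log(u)/a^2 ]
    J[:, 2] = f * ((-logM0 * eaL - r * t) / (a * u) + logu / a**2)
    return f, J


def exponential_gradient(t, logM0: float, r: float):
    """Exponential curve values and partials wrt (log M0, r)."""
    t = np.asarray(t, dtype=float)
    f = np.exp(logM0 + r * t)
    J = np.stack([f, t * f], axis=1)
    return f, J


def exponential_gradient_vec(t, logM0, r):
    """Elementwise exponential curve and partials for per-observation params.

    Returns ``(f, J, valid)`` with J of shape (n, 2); always valid.
    """
    t = np.asarray(t, dtype=float)
    f = np.exp(logM0 + r * t)
    J = np.stack([f, t * f], axis=1)
    return f, J, np.ones(t.size, dtype=bool)


def powerlaw_gradient_vec(t, logM0, r, beta):
    """Elementwise power-law curve and partials for per-observation params.

    All arguments broadcast elementwise.  For |1 - beta| < 1e-4 a first-order
    expansion around the exponential limit is used (the exact formulas lose
    precision to cancellation there), so beta may equal 1 exactly and the
    curve degenerates smoothly into the exponential.  Where the base
    M0**(1-beta) + r*t*(1-beta) is nonpositive the observation is flagged
    invalid and evaluated at a clipped base so the outputs stay finite.

    Returns ``(f, J, valid)`` with J of shape (n, 3) holding partials wrt
    (log M0, r, beta).
    """
    t = np.asarray(t, dtype=float)
    logM0 = np.broadcast_to(np.asarray(logM0, float), t.shape).astype(float)
    r = np.broadcast_to(np.asarray(r, float), t.shape).astype(float)
    beta = np.broadcast_to(np.asarray(beta, float), t.shape).astype(float)
    a = 1.0 - beta
    near1 = np.abs(a) < 1e-4
    a_safe = np.where(near1, 1.0, a)  # placeholder, masked out below

    eaL = np.exp(a_safe * logM0)
    u = eaL + r * t * a_safe
    valid = (u > 0) | near1
    u = np.where(u > 0, u, 1e-12)
    f_pl = u ** (1.0 / a_safe)
    logu = np.log(u)
    JL_pl = f_pl / u * eaL
    Jr_pl = t * f_pl / u
    Jb_pl = f_pl * ((-logM0 * eaL - r * t) / (a_safe * u) + logu / a_safe**2)

    # expansion around beta = 1: log f = (L + r t) - a*(L*r*t + (r t)^2/2)
    rt = r * t
    g = logM0 * rt + 0.5 * rt**2
    f_ex = np.exp(logM0 + rt - a * g)
    JL_ex = f_ex * (1.0 - a * rt)
    Jr_ex = f_ex * (t - a * t * (logM0 + rt))
    Jb_ex = f_ex * g

    f = np.where(near1, f_ex, f_pl)
    J = np.empty((t.size, 3))
    J[:, 0] = np.where(near1, JL_ex, JL_pl)
    J[:, 1] = np.where(near1, Jr_ex, Jr_pl)
    J[:, 2] = np.where(near1, Jb_ex, Jb_pl)
    return f, J, valid
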