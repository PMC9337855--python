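"""Hierarchical (mixed-effects) growth-curve fitting.

Two fitting stages mirror how the growth analysis is organised:

* stage 1 — a plain nonlinear mixed model per candidate curve family
  (exponential or power-law): global fixed (log M0, r[, beta]) plus per-plant
  random effects on every parameter with unstructured covariance and i.i.d.
  Gaussian residuals.  Used to choose between the two families by AIC/LRT.
* stage 2 — the power-law model with accession fixed effects on M0,
  accession x temperature fixed effects on the growth rate, a single shared
  beta, per-plant random effects on (log M0, r, beta), and continuous-AR1
  residual correlation corr(e_i, e_j) = phi**|t_i - t_j| within plants.

Estimation is an alternating scheme: (i) penalized nonlinear least squares
for fixed effects and random-effect modes given the variance parameters,
(ii) Laplace-approximation updates of the random-effect covariance, residual
variance and phi — iterated to a relative log-likelihood tolerance of 1e-6
(at most 200 outer iterations, with up to 3 jittered restarts).  Fixed and
random effects for M0 act on the log scale, which keeps M0 positive.
Reported log-likelihoods are maximum-likelihood (not REML), so
likelihood-ratio tests across the nested curve families are valid.

All per-plant computations are vectorized over a single stacked observation
vector: CAR1 whitening is a bidiagonal transform that never crosses plant
boundaries (the boundary lag is treated as infinite), and per-plant
Gauss-Newton systems are assembled with segmented reductions and solved as
batched q x q systems.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats

from .curves import exponential_gradient_vec, powerlaw_gradient_vec
from .series import PlantSeries, selfstart

__all__ = [
    "ModelFit",
    "ConvergenceError",
    "fit_stage1",
    "fit_stage2",
    "select_growth_model",
    "compare_models",
    "comparison_table",
    "accession_estimates",
    "plant_estimates",
    "temperature_response",
]

_BETA_LO, _BETA_HI = 0.02, 1.0  # usable range of the power-law exponent
_PHI_HI = 0.98


class ConvergenceError(RuntimeError):
    """Raised when the alternating scheme fails after all restarts."""

    def __init__(self, message: str, best_loglik: float = np.nan):
        super().__init__(message)
        self.best_loglik = best_loglik


@dataclass
class ModelFit:
    """A converged hierarchical growth-model fit."""

    model_kind: str  # "exponential" | "powerlaw"
    fixed_effects: pd.Series
    re_cov: np.ndarray
    phi: float | None
    sigma2: float
    loglik: float
    k: int
    n_obs: int
    aic: float = field(init=False)
    bic: float = field(init=False)
    # bookkeeping for downstream extraction
    plants: pd.DataFrame | None = None
    accessions: list[str] | None = None
    temperatures: list[str] | None = None
    n_outer: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        self.aic = 2 * self.k - 2 * self.loglik
        self.bic = self.k * np.log(self.n_obs) - 2 * self.loglik
        C = np.asarray(self.re_cov)
        if not np.allclose(C, C.T, atol=1e-8):
            raise ValueError("re_cov must be symmetric")
        if np.linalg.eigvalsh(C).min() < -1e-8 * max(np.trace(C), 1.0):
            raise ValueError("re_cov must be positive semi-definite")


# ---------------------------------------------------------------------------
# stacked observation container

class _Stack:
    """All plants' observations concatenated, with segment bookkeeping."""

    def __init__(self, series_set, designs, q, p, model_kind, intercepts=None):
        self.q = q
        self.p = p
        self.model_kind = model_kind
        # fixed-effect index of the global intercept of each curve parameter;
        # used to recenter random-effect means (removes the flat ridge between
        # the intercepts and the RE mean)
        self.intercepts = intercepts if intercepts is not None else tuple(range(q))
        self.meta = [(s.plant_id, s.accession, s.experiment, s.temperature) for s in series_set]
        self.t = np.concatenate([s.times for s in series_set])
        self.y = np.concatenate([s.areas for s in series_set])
        n = np.array([len(s) for s in series_set])
        self.n = n
        self.P = len(series_set)
        self.N = int(n.sum())
        self.starts = np.concatenate([[0], np.cumsum(n)[:-1]])
        self.obs_plant = np.repeat(np.arange(self.P), n)
        # lag across a plant boundary is infinite -> zero CAR1 correlation
        dt = np.diff(self.t)
        boundary = np.diff(self.obs_plant) != 0
        dt[boundary] = np.inf
        self.dt = dt
        # design: per-plant fixed-effect indices feeding each curve parameter
        rows, cols, streams = [], [], []
        S = [sparse.lil_matrix((self.P, p)) for _ in range(q)]
        for i, (idx_L, idx_r, idx_beta) in enumerate(designs):
            for m, idx in enumerate((idx_L, idx_r, idx_beta)[:q]):
                for j in idx:
                    S[m][i, j] = 1.0
                    obs = np.arange(self.starts[i], self.starts[i] + n[i])
                    rows.append(obs)
                    cols.append(np.full(n[i], j))
                    streams.append(np.full(n[i], m))
        self.S = [m.tocsr() for m in S]
        self.entry_obs = np.concatenate(rows)
        self.entry_col = np.concatenate(cols).astype(np.intp)
        self.entry_stream = np.concatenate(streams).astype(np.intp)

    # -- segmented reductions ------------------------------------------------
    def seg_sum(self, x):
        return np.add.reduceat(x, self.starts, axis=0)

    def seg_outer(self, Z):
        prod = Z[:, :, None] * Z[:, None, :]
        return np.add.reduceat(prod, self.starts, axis=0)

    # -- CAR1 whitening ------------------------------------------------------
    def whiten(self, x, phi):
        if phi <= 0.0:
            return x
        rho = phi**self.dt
        s = np.sqrt(1.0 - rho**2)
        out = np.empty_like(x, dtype=float)
        out[0] = x[0]
        if x.ndim == 1:
            out[1:] = (x[1:] - rho * x[:-1]) / s
        else:
            out[1:] = (x[1:] - rho[:, None] * x[:-1]) / s[:, None]
        return out

    def logdet_corr(self, phi):
        if phi <= 0.0:
            return 0.0
        rho2 = (phi**self.dt) ** 2
        return float(np.sum(np.log1p(-rho2[np.isfinite(self.dt)])))

    # -- curve evaluation ----------------------------------------------------
    def plant_params(self, mu, b):
        th = np.stack([Sm @ mu for Sm in self.S], axis=1) + b
        if self.q == 3:
            th[:, 2] = np.clip(th[:, 2], _BETA_LO, _BETA_HI)
        return th

    def curve(self, mu, b):
        th = self.plant_params(mu, b)[self.obs_plant]
        if self.model_kind == "exponential":
            return exponential_gradient_vec(self.t, th[:, 0], th[:, 1])
        return powerlaw_gradient_vec(self.t, th[:, 0], th[:, 1], th[:, 2])

    def plant_invalid(self, valid):
        return self.seg_sum((~valid).astype(float)) > 0


# ---------------------------------------------------------------------------
# alternating estimation

def _mode_objective(stack, mu, b, Psi_inv, sigma2, phi):
    f, _, valid = stack.curve(mu, b)
    rw = stack.whiten(stack.y - f, phi)
    obj = stack.seg_sum(rw * rw) / sigma2 + np.einsum("ij,jk,ik->i", b, Psi_inv, b)
    return np.where(stack.plant_invalid(valid), np.inf, obj)


def _update_modes(stack, mu, b, Psi_inv, sigma2, phi, n_iter=2):
    q = stack.q
    for _ in range(n_iter):
        f, J, valid = stack.curve(mu, b)
        rw = stack.whiten(stack.y - f, phi)
        Zw = stack.whiten(J, phi)
        A = stack.seg_outer(Zw)
        lhs = A / sigma2 + Psi_inv[None, :, :]
        g = stack.seg_sum(Zw * rw[:, None]) / sigma2 - b @ Psi_inv
        try:
            step = np.linalg.solve(lhs, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            lhs += 1e-8 * np.eye(q)[None]
            step = np.linalg.solve(lhs, g[:, :, None])[:, :, 0]
        obj0 = stack.seg_sum(rw * rw) / sigma2 + np.einsum("ij,jk,ik->i", b, Psi_inv, b)
        obj0 = np.where(stack.plant_invalid(valid), np.inf, obj0)
        b0 = b.copy()
        b_cur = b0.copy()
        accepted = np.zeros(stack.P, dtype=bool)
        lam = np.ones(stack.P)
        for _ in range(8):
            cand = b0 + lam[:, None] * step
            b_eval = np.where(accepted[:, None], b_cur, cand)
            obj = _mode_objective(stack, mu, b_eval, Psi_inv, sigma2, phi)
            improve = ~accepted & (
                (obj <= obj0 + 1e-12) | (np.isfinite(obj) & ~np.isfinite(obj0))
            )
            b_cur[improve] = cand[improve]
            accepted |= improve
            if accepted.all():
                break
            lam[~accepted] *= 0.5
        b = b_cur
    return b


def _fixed_sse(stack, mu, b, phi):
    f, _, valid = stack.curve(mu, b)
    if np.any(~valid):
        return np.inf
    rw = stack.whiten(stack.y - f, phi)
    return float(rw @ rw)


def _update_fixed(stack, mu, b, sigma2, phi, n_iter=2, ridge=1e-10):
    p = stack.p
    for _ in range(n_iter):
        f, J, _ = stack.curve(mu, b)
        rw = stack.whiten(stack.y - f, phi)
        Zw = stack.whiten(J, phi)
        data = Zw[stack.entry_obs, stack.entry_stream]
        Js = sparse.coo_matrix(
            (data, (stack.entry_obs, stack.entry_col)), shape=(stack.N, p)
        ).tocsr()
        M = (Js.T @ Js).toarray()
        v = Js.T @ rw
        M[np.diag_indices_from(M)] += ridge * (1.0 + np.trace(M) / p)
        try:
            step = np.linalg.solve(M, v)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(M, v, rcond=None)[0]
        s0 = _fixed_sse(stack, mu, b, phi)
        lam = 1.0
        for _ in range(8):
            if _fixed_sse(stack, mu + lam * step, b, phi) <= s0 + 1e-12:
                mu = mu + lam * step
                break
            lam *= 0.5
    return mu


def _marginal_loglik(stack, mu, b, Psi, sigma2, phi):
    """Laplace/linearized marginal log-likelihood at the current modes."""
    q = stack.q
    try:
        Lp = np.linalg.cholesky(Psi + 1e-12 * max(np.trace(Psi), 1e-300) * np.eye(q))
    except np.linalg.LinAlgError:
        return -np.inf
    f, J, valid = stack.curve(mu, b)
    if np.any(~valid):
        return -np.inf
    rw = stack.whiten(stack.y - f, phi)
    Zw = stack.whiten(J, phi)
    w = rw + np.einsum("nq,nq->n", Zw, b[stack.obs_plant])
    B = Zw @ Lp
    G = stack.seg_outer(B)  # (P, q, q)
    Cap = np.eye(q)[None, :, :] + G / sigma2
    try:
        Lc = np.linalg.cholesky(Cap)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet_cap = 2.0 * np.sum(np.log(np.diagonal(Lc, axis1=1, axis2=2)), axis=1)
    rhs = stack.seg_sum(B * w[:, None]) / sigma2
    u = np.linalg.solve(Lc, rhs[:, :, None])[:, :, 0]
    quad = stack.seg_sum(w * w) / sigma2 - np.sum(u * u, axis=1)
    ll = -0.5 * (
        stack.N * np.log(2 * np.pi)
        + stack.N * np.log(sigma2)
        + np.sum(logdet_cap)
        + stack.logdet_corr(phi)
        + np.sum(quad)
    )
    return float(ll)


def _em_update(stack, mu, b, Psi, sigma2, phi):
    """One Laplace/EM step for (Psi, sigma2) at the current modes."""
    q = stack.q
    Psi_inv = np.linalg.pinv(Psi)
    f, J, _ = stack.curve(mu, b)
    rw = stack.whiten(stack.y - f, phi)
    Zw = stack.whiten(J, phi)
    A = stack.seg_outer(Zw)
    C = np.linalg.inv(A / sigma2 + Psi_inv[None, :, :])
    S = (np.einsum("ij,ik->jk", b, b) + C.sum(axis=0)) / stack.P
    rss = float(rw @ rw) + float(np.sum(C * A))
    Psi_new = 0.5 * (S + S.T)
    w, U = np.linalg.eigh(Psi_new)
    w = np.clip(w, 1e-12 * max(w.max(), 1e-12), None)
    return (U * w) @ U.T, max(rss / stack.N, 1e-12)  # floor guards noiseless data


def _optimize_phi(stack, mu, b, Psi, sigma2, phi):
    res = optimize.minimize_scalar(
        lambda ph: -_marginal_loglik(stack, mu, b, Psi, sigma2, ph),
        bounds=(0.0, _PHI_HI),
        method="bounded",
        options={"maxiter": 15, "xatol": 1e-3},
    )
    return float(res.x)


def _run_fit(stack, mu, b, Psi, sigma2, phi, use_car1, max_outer=200, tol=1e-6, warmup=5):
    """Alternate penalized NLS and Laplace variance updates to convergence.

    phi is held at its starting value for the first ``warmup`` outer
    iterations so the curve parameters settle before residual correlation is
    estimated (joint early updates can push phi to its bound).
    """
    ll_prev = -np.inf
    Psi_inv = np.linalg.pinv(Psi)
    n_outer = 0
    converged = False
    best = None  # (ll, mu, b, Psi, sigma2, phi): the scheme is not monotone
    for it in range(max_outer):
        n_outer = it + 1
        for _ in range(2):
            b = _update_modes(stack, mu, b, Psi_inv, sigma2, phi)
            # shift the RE mean into the global intercepts (gauge fixing)
            bbar = b.mean(axis=0)
            for m, j in enumerate(stack.intercepts[: stack.q]):
                mu[j] += bbar[m]
            b = b - bbar
            mu = _update_fixed(stack, mu, b, sigma2, phi)
            if stack.model_kind == "powerlaw":
                jb = stack.intercepts[2]
                mu[jb] = float(np.clip(mu[jb], _BETA_LO, _BETA_HI))
        Psi, sigma2 = _em_update(stack, mu, b, Psi, sigma2, phi)
        Psi_inv = np.linalg.pinv(Psi)
        if use_car1 and it >= warmup:
            phi = _optimize_phi(stack, mu, b, Psi, sigma2, phi)
        ll = _marginal_loglik(stack, mu, b, Psi, sigma2, phi)
        if not np.isfinite(ll):
            raise ConvergenceError("log-likelihood became non-finite", ll_prev)
        if best is None or ll > best[0]:
            best = (ll, mu.copy(), b.copy(), Psi.copy(), sigma2, phi)
        if it > warmup and abs(ll - ll_prev) <= tol * (abs(ll) + 1.0):
            ll_prev = ll
            converged = True
            break
        ll_prev = ll
    ll, mu, b, Psi, sigma2, phi = best
    if use_car1:
        phi2 = _optimize_phi(stack, mu, b, Psi, sigma2, phi)
        b2 = _update_modes(stack, mu, b.copy(), np.linalg.pinv(Psi), sigma2, phi2)
        ll2 = _marginal_loglik(stack, mu, b2, Psi, sigma2, phi2)
        if ll2 > ll:
            ll, b, phi = ll2, b2, phi2
    return mu, b, Psi, sigma2, phi, ll, n_outer, converged


def _fit_with_restarts(stack, mu0, Psi0, sigma2_0, phi0, use_car1, max_outer, tol, seed, b0=None):
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for attempt in range(4):  # initial try + 3 jittered restarts
        jitter = 0.0 if attempt == 0 else 0.05 * attempt
        mu = mu0 * (1 + jitter * rng.standard_normal(mu0.size))
        b = np.zeros((stack.P, stack.q)) if b0 is None else b0.copy()
        try:
            return _run_fit(
                stack, mu, b, Psi0.copy(), sigma2_0, phi0, use_car1,
                max_outer=max_outer, tol=tol,
            )
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as err:
            last_err = err
    raise ConvergenceError(
        f"hierarchical fit failed after 3 restarts: {last_err}",
        best_loglik=getattr(last_err, "best_loglik", np.nan),
    )


# ---------------------------------------------------------------------------
# model assembly

def _require_cleaned(series_set):
    usable = [s for s in series_set if s.usable and len(s) >= 4]
    if len(usable) < 2:
        raise ValueError("need at least 2 usable (cleaned, >=4 points) plants")
    return usable


def _selfstart_table(series_set, model_kind) -> np.ndarray:
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in series_set:
            rows.append(selfstart(s, model_kind))
    return np.asarray(rows, float)


def _consistent_starts(series_set, model_kind):
    """Per-plant (log M0, r, beta) starts that share a single beta.

    Per-plant self-starts profile their own beta, but (log M0, r) estimated
    at different betas live on incompatible scales, so cell means of such
    values are useless as starting points.  This re-estimates every plant's
    (log M0, r) by linearized OLS at the *median* self-start beta.
    """
    raw = _selfstart_table(series_set, model_kind)
    if model_kind == "exponential":
        return raw[:, :2], 1.0
    beta0 = float(np.clip(np.median(raw[:, 2]), 0.1, _BETA_HI))
    a = 1.0 - beta0
    out = np.empty_like(raw)
    out[:, 2] = raw[:, 2]
    for i, s in enumerate(series_set):
        X = np.stack([np.ones_like(s.times), s.times], axis=1)
        coef, *_ = np.linalg.lstsq(X, s.areas**a, rcond=None)
        c0, c1 = coef
        if c0 > 0:
            out[i, 0] = np.log(c0) / a
            out[i, 1] = c1 / a
        else:  # pathological plant: fall back to its own self-start
            out[i, :2] = raw[i, :2]
    return out, beta0


def _init_cov(dev: np.ndarray) -> np.ndarray:
    q = dev.shape[1]
    C = np.cov(dev, rowvar=False) if dev.shape[0] > q else np.eye(q) * 1e-2
    C = np.atleast_2d(C)
    w, U = np.linalg.eigh(0.5 * (C + C.T))
    w = np.clip(w, max(1e-6 * (w.max() if w.size else 1.0), 1e-10), None)
    return (U * w) @ U.T


def _init_sigma2(stack, mu) -> float:
    f, _, valid = stack.curve(mu, np.zeros((stack.P, stack.q)))
    r = np.where(valid, stack.y - f, 0.0)
    return max(float(r @ r) / max(int(valid.sum()), 1), 1e-8)


def _plant_frame(stack, b) -> pd.DataFrame:
    out = pd.DataFrame(
        stack.meta, columns=["plant_id", "accession", "experiment", "temperature"]
    )
    for j, name in enumerate(["b_logM0", "b_r", "b_beta"][: stack.q]):
        out[name] = b[:, j]
    return out


def fit_stage1(
    series_set: list[PlantSeries],
    model_kind: str,
    max_outer: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    init: dict | None = None,
) -> ModelFit:
    """Stage-1 nonlinear mixed model: global curve + per-plant random effects.

    ``model_kind`` is "exponential" (q=2 random effects, k = 2+3+1 = 6
    parameters) or "powerlaw" (q=3, k = 3+6+1 = 10).  Residuals are i.i.d.
    Gaussian — no CAR1 at this stage.  ``init`` may carry starting values
    (keys mu, b, Psi, sigma2), e.g. to warm-start the power-law fit from a
    converged exponential fit along the nesting (beta = 1).
    """
    if model_kind not in ("exponential", "powerlaw"):
        raise ValueError(f"unknown model_kind {model_kind!r}")
    series_set = _require_cleaned(series_set)
    q = 2 if model_kind == "exponential" else 3
    start, beta0 = _consistent_starts(series_set, model_kind)
    start = start[:, :q]

    designs = [([0], [1], [2] if q == 3 else []) for _ in series_set]
    stack = _Stack(series_set, designs, q=q, p=q, model_kind=model_kind)
    mu0 = np.median(start, axis=0)
    if q == 3:
        mu0[2] = beta0
    Psi0 = _init_cov(start - mu0)
    sigma2_0 = _init_sigma2(stack, mu0)
    # start the RE modes at the per-plant deviations from the global start
    b0 = start - mu0
    if q == 3:
        b0[:, 2] = 0.0
    if init is not None:
        mu0 = np.asarray(init.get("mu", mu0), float)
        b0 = np.asarray(init.get("b", b0), float)
        Psi0 = np.asarray(init.get("Psi", Psi0), float)
        sigma2_0 = float(init.get("sigma2", sigma2_0))

    mu, b, Psi, sigma2, phi, ll, n_outer, conv = _fit_with_restarts(
        stack, mu0, Psi0, sigma2_0, phi0=0.0, use_car1=False,
        max_outer=max_outer, tol=tol, seed=seed, b0=b0,
    )
    names = ["logM0", "r"] + (["beta"] if q == 3 else [])
    k = q + q * (q + 1) // 2 + 1
    return ModelFit(
        model_kind=model_kind,
        fixed_effects=pd.Series(mu, index=names),
        re_cov=Psi,
        phi=None,
        sigma2=sigma2,
        loglik=ll,
        k=k,
        n_obs=stack.N,
        plants=_plant_frame(stack, b),
        n_outer=n_outer,
        converged=conv,
    )


def _temp_value(label: str) -> float:
    m = re.search(r"-?\d+(\.\d+)?", str(label))
    return float(m.group()) if m else np.nan


def _stage2_design(series_set):
    accessions = sorted({s.accession for s in series_set})
    # warmest treatment first: it is the fixed-effect baseline
    temps = sorted({s.temperature for s in series_set}, key=_temp_value, reverse=True)
    A = len(accessions)
    acc_pos = {a: i for i, a in enumerate(accessions)}
    two_temp = len(temps) == 2
    r_base = A
    t_off = r_base + A  # temperature main effect
    beta_idx = r_base + (2 * A if two_temp else A)
    p = beta_idx + 1
    return accessions, temps, acc_pos, r_base, t_off, beta_idx, p, two_temp


def fit_stage2(
    series_set: list[PlantSeries],
    car1: bool = True,
    max_outer: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
) -> ModelFit:
    """Stage-2 power-law NLMM with the full fixed-effect structure.

    Fixed effects: accession on log M0; accession, temperature and their
    interaction on r (reference coding: first accession and the warmer
    treatment as baseline); a single shared beta.  Per-plant random effects
    on (log M0, r, beta) with unstructured covariance; CAR1 residual
    correlation within plants unless ``car1=False``.
    """
    series_set = _require_cleaned(series_set)
    accs, temps, acc_pos, r_base, t_off, beta_idx, p, two_temp = _stage2_design(series_set)
    if len(accs) < 2:
        raise ValueError("stage 2 requires at least 2 accessions")
    if not two_temp:
        warnings.warn("single temperature level: fitting without temperature terms", stacklevel=2)

    start, beta0 = _consistent_starts(series_set, "powerlaw")
    designs = []
    for s in series_set:
        a = acc_pos[s.accession]
        idx_L = [0] + ([a] if a > 0 else [])
        idx_r = [r_base] + ([r_base + a] if a > 0 else [])
        if two_temp and s.temperature == temps[1]:
            idx_r.append(t_off)
            if a > 0:
                idx_r.append(t_off + a)
        designs.append((idx_L, idx_r, [beta_idx]))
    stack = _Stack(
        series_set, designs, q=3, p=p, model_kind="powerlaw",
        intercepts=(0, r_base, beta_idx),
    )

    mu0 = _stage2_start(series_set, start, accs, temps, acc_pos, r_base, t_off, beta_idx, p, two_temp)
    mu0[beta_idx] = beta0
    # RE covariance initialised from within-cell spread of the self-starts
    df = pd.DataFrame(start, columns=["L", "r", "beta"])
    df["key"] = [(s.accession, s.temperature) for s in series_set]
    dev = df.groupby("key")[["L", "r", "beta"]].transform(lambda x: x - x.mean()).to_numpy()
    Psi0 = _init_cov(dev)
    sigma2_0 = _init_sigma2(stack, mu0)
    # start the RE modes at per-plant deviations from the design prediction
    pred = np.stack([Sm @ mu0 for Sm in stack.S], axis=1)
    b0 = start - pred
    b0[:, 2] = 0.0

    mu, b, Psi, sigma2, phi, ll, n_outer, conv = _fit_with_restarts(
        stack, mu0, Psi0, sigma2_0, phi0=0.3 if car1 else 0.0, use_car1=car1,
        max_outer=max_outer, tol=tol, seed=seed, b0=b0,
    )

    names = ["logM0:(Intercept)"] + [f"logM0:{a}" for a in accs[1:]]
    names += ["r:(Intercept)"] + [f"r:{a}" for a in accs[1:]]
    if two_temp:
        names += [f"r:temp{temps[1]}"] + [f"r:{a}:temp{temps[1]}" for a in accs[1:]]
    names += ["beta"]
    k = p + 6 + 1 + (1 if car1 else 0)
    return ModelFit(
        model_kind="powerlaw",
        fixed_effects=pd.Series(mu, index=names),
        re_cov=Psi,
        phi=float(phi) if car1 else None,
        sigma2=sigma2,
        loglik=ll,
        k=k,
        n_obs=stack.N,
        plants=_plant_frame(stack, b),
        accessions=accs,
        temperatures=temps,
        n_outer=n_outer,
        converged=conv,
    )


def _stage2_start(series_set, start, accs, temps, acc_pos, r_base, t_off, beta_idx, p, two_temp):
    df = pd.DataFrame(
        {
            "acc": [s.accession for s in series_set],
            "temp": [s.temperature for s in series_set],
            "L": start[:, 0],
            "r": start[:, 1],
            "beta": start[:, 2],
        }
    )
    mu0 = np.zeros(p)
    Lm = df.groupby("acc")["L"].mean()
    mu0[0] = Lm[accs[0]]
    for a in accs[1:]:
        mu0[acc_pos[a]] = Lm.get(a, Lm.mean()) - mu0[0]
    rm = df.groupby(["acc", "temp"])["r"].mean()

    def cell(a, t):
        try:
            return rm.loc[(a, t)]
        except KeyError:
            return rm.mean()

    mu0[r_base] = cell(accs[0], temps[0])
    for a in accs[1:]:
        mu0[r_base + acc_pos[a]] = cell(a, temps[0]) - mu0[r_base]
    if two_temp:
        mu0[t_off] = cell(accs[0], temps[1]) - mu0[r_base]
        for a in accs[1:]:
            mu0[t_off + acc_pos[a]] = (
                cell(a, temps[1]) - mu0[r_base] - mu0[r_base + acc_pos[a]] - mu0[t_off]
            )
    mu0[beta_idx] = float(np.clip(df["beta"].median(), 0.1, _BETA_HI))
    return mu0


def select_growth_model(
    series_set: list[PlantSeries],
    max_outer: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
):
    """Fit both stage-1 curve families and compare them.

    Because the exponential is the power-law at beta = 1, a power-law fit
    that lands below the exponential likelihood has merely failed to
    converge; it is then refit warm-started from the exponential solution.

    Returns ``(fit_exp, fit_pl, comparison)``.
    """
    fit_exp = fit_stage1(series_set, "exponential", max_outer, tol, seed)
    fit_pl = fit_stage1(series_set, "powerlaw", max_outer, tol, seed)
    if fit_pl.loglik < fit_exp.loglik:
        Psi = np.zeros((3, 3))
        Psi[:2, :2] = fit_exp.re_cov
        Psi[2, 2] = 1e-6
        b = np.zeros((len(fit_exp.plants), 3))
        b[:, :2] = fit_exp.plants[["b_logM0", "b_r"]].to_numpy()
        init = {
            "mu": np.r_[fit_exp.fixed_effects.to_numpy(), 1.0],
            "b": b,
            "Psi": Psi,
            "sigma2": fit_exp.sigma2,
        }
        refit = fit_stage1(series_set, "powerlaw", max_outer, tol, seed, init=init)
        if refit.loglik > fit_pl.loglik:
            fit_pl = refit
    # symmetric check: when the power-law sits at beta ~ 1 the two families
    # coincide, so a large likelihood gap means the exponential fit stalled
    if fit_pl.fixed_effects["beta"] > 0.99 and fit_pl.loglik - fit_exp.loglik > 1.0:
        init = {
            "mu": fit_pl.fixed_effects.to_numpy()[:2],
            "b": fit_pl.plants[["b_logM0", "b_r"]].to_numpy(),
            "Psi": fit_pl.re_cov[:2, :2],
            "sigma2": fit_pl.sigma2,
        }
        refit = fit_stage1(series_set, "exponential", max_outer, tol, seed, init=init)
        if refit.loglik > fit_exp.loglik:
            fit_exp = refit
    return fit_exp, fit_pl, compare_models(fit_exp, fit_pl)


# ---------------------------------------------------------------------------
# extraction and comparison

def compare_models(fit_exp: ModelFit, fit_pl: ModelFit) -> dict:
    """AIC/BIC/likelihood-ratio comparison of the nested curve families."""
    if fit_pl.k <= fit_exp.k:
        raise ValueError("power-law fit must have more parameters than exponential (nesting)")
    if fit_pl.n_obs != fit_exp.n_obs:
        raise ValueError("fits compare different data (n_obs mismatch)")
    lratio = 2.0 * (fit_pl.loglik - fit_exp.loglik)
    df_diff = fit_pl.k - fit_exp.k
    p = float(stats.chi2.sf(max(lratio, 0.0), df_diff)) if lratio > 0 else 1.0
    return {
        "delta_aic": fit_pl.aic - fit_exp.aic,
        "delta_bic": fit_pl.bic - fit_exp.bic,
        "l_ratio": lratio,
        "df_diff": df_diff,
        "p_value": p,
        "preferred": "powerlaw" if fit_pl.aic < fit_exp.aic else "exponential",
    }


def comparison_table(fit_exp: ModelFit, fit_pl: ModelFit) -> pd.DataFrame:
    """Model-comparison table (model, df, AIC, BIC, logLik, L.ratio, p)."""
    cmp = compare_models(fit_exp, fit_pl)
    return pd.DataFrame(
        {
            "model": ["exponential", "powerlaw"],
            "df": [fit_exp.k, fit_pl.k],
            "AIC": [fit_exp.aic, fit_pl.aic],
            "BIC": [fit_exp.bic, fit_pl.bic],
            "logLik": [fit_exp.loglik, fit_pl.loglik],
            "L.ratio": [np.nan, cmp["l_ratio"]],
            "p": [np.nan, cmp["p_value"]],
        }
    )


def temperature_response(r6, r16):
    """Growth-rate temperature response: the increase from 6C to 16C.

    Defined as the plain difference r16 - r6; an ordered two-level contrast
    slope is this difference times a positive constant (1/sqrt(2)), so all
    correlations downstream are unchanged.
    """
    return np.asarray(r16, float) - np.asarray(r6, float)


def accession_estimates(fit: ModelFit) -> pd.DataFrame:
    """Per-accession (M0, r16, r6, response) from stage-2 fixed effects only."""
    if fit.accessions is None:
        raise ValueError("accession_estimates requires a stage-2 fit")
    fe = fit.fixed_effects
    accs, temps = fit.accessions, fit.temperatures
    two_temp = len(temps) == 2
    rows = []
    for a in accs:
        L = fe["logM0:(Intercept)"] + (fe.get(f"logM0:{a}", 0.0) if a != accs[0] else 0.0)
        r_warm = fe["r:(Intercept)"] + (fe.get(f"r:{a}", 0.0) if a != accs[0] else 0.0)
        if two_temp:
            r_cold = (
                r_warm
                + fe[f"r:temp{temps[1]}"]
                + (fe.get(f"r:{a}:temp{temps[1]}", 0.0) if a != accs[0] else 0.0)
            )
        else:
            r_cold = np.nan
        rows.append({"accession": a, "M0": float(np.exp(L)), "r16": r_warm, "r6": r_cold})
    out = pd.DataFrame(rows)
    out["response"] = temperature_response(out["r6"], out["r16"])
    return out


def plant_estimates(fit: ModelFit) -> pd.DataFrame:
    """Per-plant (M0, r, beta) combining fixed effects and RE modes."""
    if fit.plants is None:
        raise ValueError("fit carries no plant-level modes")
    fe = fit.fixed_effects
    out = fit.plants.copy()
    if fit.accessions is None:  # stage 1: global fixed effects
        out["M0"] = np.exp(fe["logM0"] + out["b_logM0"])
        out["r"] = fe["r"] + out["b_r"]
        out["beta"] = fe.get("beta", 1.0) + (out["b_beta"] if "b_beta" in out else 0.0)
        return out
    accs, temps = fit.accessions, fit.temperatures
    ref = accs[0]
    L = fe["logM0:(Intercept)"] + np.array(
        [fe.get(f"logM0:{a}", 0.0) if a != ref else 0.0 for a in out["accession"]]
    )
    r = fe["r:(Intercept)"] + np.array(
        [fe.get(f"r:{a}", 0.0) if a != ref else 0.0 for a in out["accession"]]
    )
    if len(temps) == 2:
        cold = (out["temperature"] == temps[1]).to_numpy()
        inter = np.array(
            [fe.get(f"r:{a}:temp{temps[1]}", 0.0) if a != ref else 0.0 for a in out["accession"]]
        )
        r = r + np.where(cold, fe[f"r:temp{temps[1]}"] + inter, 0.0)
    out["M0"] = np.exp(L + out["b_logM0"])
    out["r"] = r + out["b_r"]
    out["beta"] = fe["beta"] + out["b_beta"]
    return out
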