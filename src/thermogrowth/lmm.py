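"""Linear mixed model with one genetic variance component.

The model is y = X b + g + e with g ~ N(0, sg2 * K) and e ~ N(0, se2 * I).
Writing V = se2 * (delta * K + I) with delta = sg2/se2 and rotating by the
eigenvectors of K diagonalizes V, so the likelihood profile over delta is a
cheap 1-D optimization — the classic spectral trick used by EMMA-style
association scans.  Both ML and REML criteria are supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class LmmFit:
    """A fitted single-component LMM on the rotated spectrum."""

    beta: np.ndarray
    se: np.ndarray
    sigma_g2: float
    sigma_e2: float
    delta: float  # variance ratio sg2/se2
    loglik: float
    reml: bool
    n: int

    @property
    def h2(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)

    def wald_p(self, j: int = -1) -> float:
        """Two-sided Wald p-value for coefficient j (t with n - p df)."""
        dfree = self.n - self.beta.size
        tstat = self.beta[j] / self.se[j]
        return float(2.0 * stats.t.sf(abs(tstat), dfree))


def _profile(delta, lam, yr, Xr, reml):
    """Profiled -2 log-likelihood over the variance ratio delta.

    lam are the eigenvalues of K; yr, Xr the rotated response and design.
    Returns (neg2ll, beta, XtVX_inv, s2) with s2 the profiled se2.
    """
    n, p = Xr.shape
    w = 1.0 / (delta * lam + 1.0)
    XtWX = Xr.T @ (Xr * w[:, None])
    XtWy = Xr.T @ (yr * w)
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(XtWX, XtWy, rcond=None)[0]
    r = yr - Xr @ beta
    q = float(r @ (r * w))
    logdet_v = float(-np.sum(np.log(w)))
    if reml:
        dof = n - p
        s2 = q / dof
        sign, logdet_x = np.linalg.slogdet(XtWX)
        neg2 = dof * np.log(2 * np.pi * s2) + dof + logdet_v + logdet_x
    else:
        s2 = q / n
        neg2 = n * np.log(2 * np.pi * s2) + n + logdet_v
    return neg2, beta, XtWX, s2


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    eigvals: np.ndarray,
    eigvecs: np.ndarray,
    reml: bool = False,
    delta_bounds: tuple[float, float] = (1e-6, 1e6),
) -> LmmFit:
    """Fit y = X b + g + e, g ~ N(0, sg2 K), via the eigensystem of K.

    ``eigvals``/``eigvecs`` come from the (symmetric PSD) kinship; tiny
    negative eigenvalues are clipped to zero.  The variance ratio is profiled
    on a log grid and polished with Brent's method.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.size:
        X = X.T
    lam = np.clip(np.asarray(eigvals, float), 0.0, None)
    U = np.asarray(eigvecs, float)
    yr = U.T @ y
    Xr = U.T @ X

    grid = np.logspace(np.log10(delta_bounds[0]), np.log10(delta_bounds[1]), 25)
    vals = [_profile(d, lam, yr, Xr, reml)[0] for d in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda ld: _profile(np.exp(ld), lam, yr, Xr, reml)[0],
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    delta = float(np.exp(res.x))
    # compare against the boundary delta -> 0 (no genetic variance)
    neg2_0, beta0, XtWX0, s2_0 = _profile(0.0, lam, yr, Xr, reml)
    neg2, beta, XtWX, s2 = _profile(delta, lam, yr, Xr, reml)
    if neg2_0 <= neg2:
        delta, neg2, beta, XtWX, s2 = 0.0, neg2_0, beta0, XtWX0, s2_0
    cov = s2 * np.linalg.inv(XtWX)
    return LmmFit(
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        sigma_g2=delta * s2,
        sigma_e2=s2,
        delta=delta,
        loglik=-0.5 * neg2,
        reml=reml,
        n=y.size,
    )
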