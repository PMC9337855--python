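"""Kinship, heritability, and structure-corrected climate correlations.

Covers the accession-level quantitative genetics around the growth
phenotypes: the centered genomic relatedness matrix, broad-sense
heritability from replicate plants, Pearson and kinship-corrected
trait-climate correlations, and the variance partition of initial size into
winter-temperature and seed-size contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .lmm import fit_lmm


@dataclass
class KinshipMatrix:
    """Centered genomic relatedness with a cached eigendecomposition.

    K = (1/p) sum_s (g_s - mean(g_s)) (g_s - mean(g_s))^T over p SNPs, so
    every row sums to zero and K is PSD by construction.
    """

    K: np.ndarray
    ids: list[str]
    eigvals: np.ndarray = field(init=False)
    eigvecs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        K = np.asarray(self.K, float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("K must be square")
        if len(self.ids) != K.shape[0]:
            raise ValueError("ids length must match K")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("K must be symmetric")
        w, U = np.linalg.eigh(K)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError(f"kinship not PSD: min eigenvalue {w.min():g}")
        order = np.argsort(w)[::-1]  # descending
        self.K = K
        self.eigvals = w[order]
        self.eigvecs = U[:, order]

    @property
    def n(self) -> int:
        return self.K.shape[0]


def kinship_centered(G, ids=None) -> KinshipMatrix:
    """Centered relatedness matrix from an accessions x SNPs allele matrix.

    Accepts a DataFrame (index = accession ids) or an array plus ``ids``.
    Missing entries (NaN) are mean-imputed per SNP.  Raises if every SNP is
    monomorphic.
    """
    if isinstance(G, pd.DataFrame):
        ids = list(G.index)
        X = G.to_numpy(dtype=float)
    else:
        X = np.asarray(G, dtype=float)
        ids = list(ids) if ids is not None else [str(i) for i in range(X.shape[0])]
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("genotype matrix must be 2-D with >= 1 SNP")
    col_mean = np.nanmean(X, axis=0)
    if np.isnan(col_mean).any():
        raise ValueError("SNP with all calls missing")
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X = np.where(nan_mask, np.broadcast_to(col_mean, X.shape), X)
    Xc = X - col_mean
    if not np.any(Xc.std(axis=0) > 0):
        raise ValueError("all SNPs monomorphic; kinship undefined")
    K = (Xc @ Xc.T) / X.shape[1]
    return KinshipMatrix(K=K, ids=ids)


@dataclass(frozen=True)
class H2Result:
    """Broad-sense heritability: Vg / (Vg + Ve)."""

    Vg: float
    Ve: float

    @property
    def H2(self) -> float:
        tot = self.Vg + self.Ve
        return self.Vg / tot if tot > 0 else 0.0


@dataclass(frozen=True)
class CorrResult:
    """A trait-variable association, raw and structure-corrected."""

    trait: str
    variable: str
    n: int
    pearson_r: float
    p_pearson: float
    corrected_beta: float | None = None
    p_corrected: float | None = None


# ---------------------------------------------------------------------------
# correlations

def pearson_correlations(traits: pd.DataFrame, climate: pd.DataFrame) -> list[CorrResult]:
    """Pairwise-complete Pearson correlations of every trait-variable pair.

    Both tables must be indexed by accession.  Pairs with zero variance or
    fewer than 3 complete observations are reported with NaN.
    """
    traits, climate = traits.align(climate, join="inner", axis=0)
    out = []
    for t in traits.columns:
        for v in climate.columns:
            x = traits[t].to_numpy(float)
            y = climate[v].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                out.append(CorrResult(t, v, n, np.nan, np.nan))
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            out.append(CorrResult(t, v, n, float(r), float(p)))
    return out


def standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def kinship_corrected_correlation(
    y, x, kin: KinshipMatrix, trait: str = "y", variable: str = "x"
) -> CorrResult:
    """Trait-variable association with a kinship random effect.

    Both variables are standardized, so the fixed-effect coefficient of the
    mixed model y = beta * x + g + e (g ~ N(0, sg2 K)) is comparable to a
    Pearson correlation.  The ML fit uses the cached eigensystem of K; the
    p-value is a Wald test on beta.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    ok = np.isfinite(y) & np.isfinite(x)
    if ok.sum() < 3:
        raise ValueError("need >= 3 complete pairs")
    if ok.all():
        lam, U = kin.eigvals, kin.eigvecs
    else:
        sub = kin.K[np.ix_(ok, ok)]
        w, V = np.linalg.eigh(sub)
        lam, U = np.clip(w[::-1], 0, None), V[:, ::-1]
    ys = standardize(y[ok])
    xs = standardize(x[ok])
    r, p_raw = stats.pearsonr(ys, xs)
    X = np.stack([np.ones(ys.size), xs], axis=1)
    fit = fit_lmm(ys, X, lam, U, reml=False)
    return CorrResult(
        trait=trait,
        variable=variable,
        n=int(ok.sum()),
        pearson_r=float(r),
        p_pearson=float(p_raw),
        corrected_beta=float(fit.beta[1]),
        p_corrected=fit.wald_p(1),
    )


# ---------------------------------------------------------------------------
# broad-sense heritability

def _h2_reml_neg2(delta, y, Xf, codes, m_per, n, p):
    """-2 REML log-likelihood of y = Xf b + accession + e at variance ratio delta.

    Uses the block structure of H = I + delta * Z Z' (accession blocks), so
    H^{-1} = I - c_a J within accession a with c_a = delta / (1 + delta*m_a).
    """
    c = delta / (1.0 + delta * m_per)

    def hinv_quad(A, B):
        # A' H^{-1} B via group sums
        sa = np.stack([np.bincount(codes, weights=A[:, j]) for j in range(A.shape[1])], 1)
        sb = np.stack([np.bincount(codes, weights=B[:, j]) for j in range(B.shape[1])], 1)
        return A.T @ B - sa.T @ (sb * c[:, None])

    XtHX = hinv_quad(Xf, Xf)
    XtHy = hinv_quad(Xf, y[:, None])[:, 0]
    beta = np.linalg.solve(XtHX, XtHy)
    r = y - Xf @ beta
    sr = np.bincount(codes, weights=r)
    q = float(r @ r - (sr * c) @ sr)
    logdet_h = float(np.sum(np.log1p(delta * m_per)))
    dof = n - p
    s2 = q / dof
    sign, logdet_x = np.linalg.slogdet(XtHX)
    return dof * np.log(2 * np.pi * s2) + dof + logdet_h + logdet_x, s2


def heritability(
    plant_params: pd.DataFrame,
    trait: str,
    temperature: str | None = None,
) -> H2Result:
    """Broad-sense heritability of a plant-level growth parameter.

    Fits trait ~ experiment (fixed) + accession (random) by REML on the
    per-plant parameter estimates and returns Vg/(Vg+Ve).  Growth-rate
    heritabilities are computed within one temperature (pass
    ``temperature``); initial-size heritability uses all plants.
    """
    df = plant_params
    if temperature is not None:
        df = df[df["temperature"].astype(str) == str(temperature)]
    df = df.dropna(subset=[trait])
    counts = df.groupby("accession")[trait].size()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 accessions with >= 2 plants each")
    y = df[trait].to_numpy(float)
    acc = pd.Categorical(df["accession"])
    codes = acc.codes
    m_per = np.bincount(codes).astype(float)
    Xf = pd.get_dummies(df["experiment"], drop_first=True, dtype=float)
    Xf.insert(0, "(Intercept)", 1.0)
    Xf = Xf.to_numpy()
    n, p = Xf.shape

    def obj(logd):
        return _h2_reml_neg2(np.exp(logd), y, Xf, codes, m_per, n, p)[0]

    grid = np.linspace(np.log(1e-6), np.log(1e4), 25)
    vals = [obj(g) for g in grid]
    i = int(np.argmin(vals))
    res = optimize.minimize_scalar(
        obj,
        bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
        method="bounded",
        options={"xatol": 1e-10},
    )
    delta = float(np.exp(res.x))
    neg2_0, s2_0 = _h2_reml_neg2(1e-12, y, Xf, codes, m_per, n, p)
    neg2, s2 = _h2_reml_neg2(delta, y, Xf, codes, m_per, n, p)
    if neg2_0 <= neg2:
        warnings.warn("accession variance at boundary; H2 = 0", stacklevel=2)
        return H2Result(Vg=0.0, Ve=s2_0)
    return H2Result(Vg=delta * s2, Ve=s2)


# ---------------------------------------------------------------------------
# seed-size variance partition

def variance_partition(
    m0: np.ndarray, winter_temp: np.ndarray, seed_size: np.ndarray
) -> dict:
    """Partition initial-size variance between winter temperature and seed size.

    Fits the joint linear model of M0 on both standardized predictors and
    attributes to predictor j the fraction var(beta_j x_j)/var(M0).  The
    seed-size-corrected winter-temperature association p-value comes from a
    mixed model in which seed size enters as a one-column random effect.
    Complete cases only.
    """
    m0 = np.asarray(m0, float)
    wt = np.asarray(winter_temp, float)
    ss = np.asarray(seed_size, float)
    ok = np.isfinite(m0) & np.isfinite(wt) & np.isfinite(ss)
    if ok.sum() < 4:
        raise ValueError("need >= 4 complete cases")
    y = m0[ok]
    x1 = standardize(wt[ok])
    x2 = standardize(ss[ok])
    r12 = float(np.corrcoef(x1, x2)[0, 1])
    if abs(r12) > 0.99:
        raise ValueError(f"winter temperature and seed size collinear (r={r12:.3f})")
    X = np.stack([np.ones(y.size), x1, x2], axis=1)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    var_y = y.var()
    frac_wt = float(beta[1] ** 2 / var_y)  # var(beta*x) with x standardized
    frac_ss = float(beta[2] ** 2 / var_y)
    resid = y - X @ beta
    r2 = 1.0 - resid.var() / var_y

    # corrected p: seed size as a one-column random effect (K = x2 x2')
    Kss = np.outer(x2, x2)
    w, U = np.linalg.eigh(Kss)
    fit = fit_lmm(
        standardize(y), np.stack([np.ones(y.size), x1], 1), np.clip(w[::-1], 0, None),
        U[:, ::-1], reml=False,
    )
    return {
        "n": int(ok.sum()),
        "frac_winter_temp": frac_wt,
        "frac_seed_size": frac_ss,
        "r2_joint": float(r2),
        "beta_winter_temp": float(beta[1]),
        "beta_seed_size": float(beta[2]),
        "p_winter_temp_corrected": fit.wald_p(1),
    }
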