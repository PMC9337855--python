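"""Linear-mixed-model association scan with relatedness correction.

Single-trait GWAS for inbred panels ({0,1} allele coding): the null model
y = mu + g + e with g ~ N(0, sg2 K) is fitted once by REML on the kinship
eigensystem; every SNP is then tested by generalized least squares in the
rotated coordinates with the variance ratio held fixed (the EMMAX
approximation).  Exact per-SNP ratio optimization is available behind a
flag.  Includes the MAF filter, Bonferroni threshold, and QQ-plot data with
a pointwise beta-order-statistic null band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import fit_lmm
from .quantgen import KinshipMatrix

#: SNPs with more than this fraction of missing calls are dropped
MAX_MISSING = 0.20


@dataclass
class GwasResult:
    """Per-SNP association results plus the null-model variance ratio."""

    table: pd.DataFrame  # id, chrom, pos, maf, beta, se, p
    lambda_hat: float  # genetic/residual variance ratio of the null model
    n: int
    n_tests: int

    def bonferroni(self, alpha: float = 0.05) -> float:
        return bonferroni_threshold(self.n_tests, alpha)


def maf_filter(G: pd.DataFrame, threshold: float = 0.10):
    """Keep SNPs with minor-allele frequency strictly above ``threshold``.

    Frequencies are computed on non-missing {0,1} calls.  Returns the
    filtered matrix and a report dict.  Raises if nothing survives.
    """
    X = G.to_numpy(dtype=float)
    freq = np.nanmean(X, axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    miss = np.mean(np.isnan(X), axis=0)
    keep = (maf > threshold) & (miss <= MAX_MISSING)
    if not keep.any():
        raise ValueError(f"no SNP passes MAF > {threshold}")
    report = {
        "n_input": X.shape[1],
        "n_kept": int(keep.sum()),
        "n_maf_removed": int((~(maf > threshold)).sum()),
        "n_missing_removed": int((miss > MAX_MISSING).sum()),
        "threshold": threshold,
    }
    return G.loc[:, keep], report


def _parse_positions(snp_ids, positions=None):
    if positions is not None:
        return positions
    chrom, pos = [], []
    for s in snp_ids:
        parts = str(s).replace("_", ":").split(":")
        if len(parts) >= 2 and parts[-1].isdigit():
            chrom.append(parts[0])
            pos.append(int(parts[-1]))
        else:
            chrom.append("1")
            pos.append(len(pos) + 1)
    return pd.DataFrame({"chrom": chrom, "pos": pos}, index=snp_ids)


def lmm_scan(
    y: np.ndarray,
    G: pd.DataFrame,
    kin: KinshipMatrix,
    exact: bool = False,
    positions: pd.DataFrame | None = None,
) -> GwasResult:
    """Association scan of trait ``y`` against every SNP column of ``G``.

    ``y``, rows of ``G`` and ``kin`` must be aligned.  Missing calls are
    mean-imputed (SNPs with > 20% missing should be removed by
    :func:`maf_filter` first).  With ``exact=True`` the variance ratio is
    re-optimized per SNP instead of being held at the null-model value.
    """
    y = np.asarray(y, float)
    if y.std() == 0:
        raise ValueError("constant phenotype")
    X = G.to_numpy(dtype=float)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X = np.where(nan_mask, np.broadcast_to(np.nanmean(X, axis=0), X.shape), X)
    n, m = X.shape
    lam, U = kin.eigvals, kin.eigvecs

    null = fit_lmm(y, np.ones((n, 1)), lam, U, reml=True)
    delta = null.delta
    freq = X.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)

    yr = U.T @ y
    onesr = U.T @ np.ones(n)
    Gr = U.T @ X
    if exact:
        beta = np.empty(m)
        se = np.empty(m)
        pvals = np.empty(m)
        for j in range(m):
            fit = fit_lmm(y, np.stack([np.ones(n), X[:, j]], 1), lam, U, reml=True)
            beta[j], se[j] = fit.beta[1], fit.se[1]
            pvals[j] = fit.wald_p(1)
    else:
        w = 1.0 / (delta * np.clip(lam, 0, None) + 1.0)
        # per-SNP 2x2 GLS with design [1, g] in rotated coordinates
        a11 = float(onesr @ (w * onesr))
        a12 = (onesr * w) @ Gr
        a22 = np.einsum("ij,ij->j", Gr * w[:, None], Gr)
        b1 = float((onesr * w) @ yr)
        b2 = (Gr * w[:, None]).T @ yr
        det = a11 * a22 - a12**2
        degenerate = det <= 1e-12 * np.maximum(a11 * a22, 1e-300)
        det_safe = np.where(degenerate, 1.0, det)
        beta = (a11 * b2 - a12 * b1) / det_safe
        alpha = (a22 * b1 - a12 * b2) / det_safe
        yty = float(yr @ (w * yr))
        rss = yty - 2 * (alpha * b1 + beta * b2) + (
            alpha**2 * a11 + 2 * alpha * beta * a12 + beta**2 * a22
        )
        dof = n - 2
        s2 = np.maximum(rss, 0.0) / dof
        var_beta = s2 * a11 / det_safe
        se = np.sqrt(var_beta)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
        beta = np.where(degenerate, 0.0, beta)
        se = np.where(degenerate, np.nan, se)
        pvals = np.where(degenerate, 1.0, pvals)

    posinfo = _parse_positions(G.columns, positions)
    table = pd.DataFrame(
        {
            "id": list(G.columns),
            "chrom": posinfo["chrom"].to_numpy(),
            "pos": posinfo["pos"].to_numpy(),
            "maf": maf,
            "beta": beta,
            "se": se,
            "p": np.clip(pvals, np.nextafter(0, 1), 1.0),
        }
    )
    return GwasResult(table=table, lambda_hat=delta, n=n, n_tests=m)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Bonferroni-corrected genome-wide threshold on the -log10 p scale."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(-np.log10(alpha / n_tests))


def qq_data(p_values: np.ndarray, band: float = 0.95) -> pd.DataFrame:
    """Observed vs expected -log10(p) quantiles with a pointwise null band.

    Expected quantiles are i/(n+1); the band is the central ``band`` interval
    of the i-th order statistic of n uniforms, Beta(i, n-i+1).
    """
    p = np.sort(np.asarray(p_values, float))
    n = p.size
    if n < 10:
        raise ValueError("need >= 10 p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    i = np.arange(1, n + 1)
    expected = i / (n + 1.0)
    tail = (1.0 - band) / 2.0
    lo = stats.beta.ppf(tail, i, n - i + 1)
    hi = stats.beta.ppf(1.0 - tail, i, n - i + 1)
    return pd.DataFrame(
        {
            "expected": -np.log10(expected),
            "observed": -np.log10(p),
            "band_lower": -np.log10(hi),
            "band_upper": -np.log10(lo),
        }
    )
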