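"""Test for polygenic adaptive differentiation along kinship PCs.

A trait that evolved neutrally in a structured population has the same
expected variance along every axis of genetic differentiation, after scaling
by the corresponding kinship eigenvalue.  Selection along an axis inflates
the trait's projection on it.  The test standardizes the trait's projections
on the top kinship PCs by a neutral variance estimated from the lower "tail"
PCs and compares each squared standardized projection to an F(1, n_tail)
distribution.

The kinship is first conditioned on the trait mean by restricting to the
(n-1)-dimensional complement of the 1-vector: K_c = T K T' with T an
orthonormal basis of that complement (Helmert rows).  This is the
conditional-MVN construction of the neutral null; using an orthonormal basis
makes the statistics exactly invariant to accession ordering, which a
drop-one-accession variant of the same conditioning is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantgen import KinshipMatrix


@dataclass
class ConditionalEigen:
    """Eigensystem of the mean-conditioned kinship (n-1 axes)."""

    eigvals: np.ndarray  # descending
    eigvecs: np.ndarray  # columns orthonormal
    transform: np.ndarray  # (n-1) x n center-and-drop matrix


@dataclass
class QpcResult:
    """Per-PC adaptive-differentiation statistics and the neutral variance."""

    trait: str
    c: np.ndarray  # standardized projections c_m = u_m' z_c / sqrt(lambda_m)
    eigvals: np.ndarray
    F: np.ndarray  # tested PCs only
    p: np.ndarray
    va_tail: float
    tested: np.ndarray  # 1-based PC indices
    tail: np.ndarray


def conditional_eigen(
    kin: KinshipMatrix | np.ndarray, centering: str = "conditional"
) -> ConditionalEigen:
    """Eigendecomposition of the kinship conditioned on the population mean.

    ``centering="conditional"`` (default) projects onto an orthonormal basis
    of the complement of the 1-vector (Helmert rows), yielding an
    (n-1)-dimensional full-rank system whose statistics do not depend on
    accession order.  ``centering="simple"`` double-centers K instead and
    keeps the top n-1 eigenpairs of the centered n x n matrix.
    """
    from scipy.linalg import helmert

    K = kin.K if isinstance(kin, KinshipMatrix) else np.asarray(kin, float)
    n = K.shape[0]
    if n < 20:
        raise ValueError("conditional eigensystem needs >= 20 accessions")
    if centering == "conditional":
        T = helmert(n)  # (n-1) x n, orthonormal rows, each orthogonal to 1
    elif centering == "simple":
        C = np.eye(n) - np.ones((n, n)) / n
        T = C[:-1]  # rank n-1; spectrum of T K T' depends on basis choice
    else:
        raise ValueError(f"unknown centering {centering!r}")
    Kc = T @ K @ T.T
    w, U = np.linalg.eigh(0.5 * (Kc + Kc.T))
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError(f"conditional kinship not PSD: min eigenvalue {w.min():g}")
    order = np.argsort(w)[::-1]
    return ConditionalEigen(eigvals=w[order], eigvecs=U[:, order], transform=T)


def qpc_test(
    z: np.ndarray,
    kin: KinshipMatrix | ConditionalEigen,
    n_tested: int = 10,
    trait: str = "trait",
) -> QpcResult:
    """Adaptive-differentiation test of trait ``z`` along the top kinship PCs.

    c_m = u_m' z_c / sqrt(lambda_m) on the conditional system; the neutral
    additive variance Va is the mean of c_m^2 over the tail PCs
    (m = n_tested+1 ... n-1); F_m = c_m^2 / Va is compared to F(1, |tail|).
    """
    ce = kin if isinstance(kin, ConditionalEigen) else conditional_eigen(kin)
    z = np.asarray(z, float)
    n = ce.transform.shape[1]
    if z.size != n:
        raise ValueError("trait vector does not match kinship dimension")
    if not n_tested < (n - 1) / 2:
        raise ValueError("n_tested must be < (n-1)/2")
    lam = ce.eigvals
    # guard near-null dimensions (rank-deficient kinship estimates)
    usable = lam > 1e-10 * lam[0]
    zc = ce.transform @ z
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(usable, (ce.eigvecs.T @ zc) / np.sqrt(lam), np.nan)
    tail_idx = np.arange(n_tested, lam.size)[usable[n_tested:]]
    if tail_idx.size < 2:
        raise ValueError("tail too small after dropping null eigenvalues")
    va_tail = float(np.mean(c[tail_idx] ** 2))
    head = float(np.nanmax(c[:n_tested] ** 2)) if n_tested else 0.0
    if va_tail <= 0 or va_tail < 1e-12 * head:
        raise ValueError("degenerate trait: zero variance along tail PCs")
    F = c[:n_tested] ** 2 / va_tail
    p = stats.f.sf(F, 1, tail_idx.size)
    return QpcResult(
        trait=trait,
        c=c,
        eigvals=lam,
        F=F,
        p=p,
        va_tail=va_tail,
        tested=np.arange(1, n_tested + 1),
        tail=tail_idx + 1,
    )


def neutral_envelope(
    qpc: QpcResult, pc_index: int, scores: np.ndarray, confidence: float = 0.90
) -> pd.DataFrame:
    """Neutral band for trait vs PC-score scatter plots.

    Under neutrality the regression slope of the (centered) trait on the
    unit-norm PC ``u_m`` is N(0, Va * lambda_m), so the fitted line at score
    s stays within +/- z_{(1+conf)/2} * sqrt(Va * lambda_m) * |s| / ||s||
    with the stated confidence.  Returns (pc_score, fitted, lower, upper).
    """
    if not 0.0 <= confidence < 1.0:
        raise ValueError("confidence must be in [0, 1)")
    m = pc_index - 1
    scores = np.asarray(scores, float)
    zcrit = stats.norm.ppf(0.5 + confidence / 2.0)
    norm = np.linalg.norm(scores)
    half = zcrit * np.sqrt(qpc.va_tail * qpc.eigvals[m]) * np.abs(scores) / norm
    slope = qpc.c[m] * np.sqrt(qpc.eigvals[m])  # u_m' z_c
    return pd.DataFrame(
        {"pc_score": scores, "fitted": slope * scores / norm, "lower": -half, "upper": half}
    )


def qpc_screen(
    traits: pd.DataFrame,
    kin: KinshipMatrix,
    n_tested: int = 10,
    subset: list[str] | None = None,
    centering: str = "conditional",
) -> tuple[dict[str, QpcResult], pd.DataFrame]:
    """Run the differentiation test for every trait column.

    ``traits`` is indexed by accession and aligned with the kinship ids.
    With ``subset`` the kinship and traits are restricted to those
    accessions first (robustness reruns).  Returns per-trait results and a
    flat summary table (trait, pc, lambda, c, F, p, significant).
    """
    ids = list(kin.ids)
    if subset is not None:
        keep = [i for i, a in enumerate(ids) if a in set(subset)]
        if len(keep) < 2 * n_tested:
            raise ValueError("subset smaller than twice the number of tested PCs")
        sub_ids = [ids[i] for i in keep]
        kin = KinshipMatrix(K=kin.K[np.ix_(keep, keep)], ids=sub_ids)
        ids = sub_ids
    traits = traits.loc[ids]
    ce = conditional_eigen(kin, centering=centering)
    results: dict[str, QpcResult] = {}
    rows = []
    for col in traits.columns:
        res = qpc_test(traits[col].to_numpy(float), ce, n_tested=n_tested, trait=col)
        results[col] = res
        for j in range(n_tested):
            rows.append(
                {
                    "trait": col,
                    "pc": j + 1,
                    "lambda": res.eigvals[j],
                    "c": res.c[j],
                    "F": res.F[j],
                    "p": res.p[j],
                    "significant": res.p[j] < 0.05,
                }
            )
    return results, pd.DataFrame(rows)
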