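"""Genomic kinship and the two-step family-based association test.

The association strategy is the GRAMMAR/FASTA design: fit the polygenic
mixed model

    y = X b + g + e,   g ~ N(0, 2K sigma2_g),   e ~ N(0, I sigma2_e)

once per cohort (null model, no SNP term), then score-test every variant
against the mixed-model-adjusted trait.  With the eigendecomposition
2K = U diag(d) U' cached from the null fit, each per-variant test is a pair
of O(n^2) rotations, and a whole scan is a single matrix product.

The per-variant statistic is the exact GLS estimate

    beta = c' V^-1 y* / c' V^-1 c,    se = (c' V^-1 c)^{-1/2},

where V = 2K sigma2_g + I sigma2_e at the null-model variance estimates,
y* = y - X b_gls, and c is the coded genotype residualized on the
covariates under the V^-1 inner product.  p-values are two-sided normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import optimize, stats

from .types import GenotypeMatrix, KinshipMatrix, PolygenicFit, ValidationError

__all__ = [
    "estimate_kinship",
    "fit_polygenic",
    "profile_reml_loglik",
    "score_test",
    "score_test_batch",
    "ScoreTestResult",
    "write_kinship",
    "read_kinship",
]


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def estimate_kinship(genotypes: GenotypeMatrix) -> KinshipMatrix:
    """Genomic kinship from dosages.

    Off-diagonals are the allele-frequency-weighted average
    mean_v (g_i - 2p)(g_j - 2p) / (4 p (1-p)); the diagonal is set to
    0.5 (1 + f_i) with f_i the usual variant-averaged inbreeding estimate,
    so that 2K has the duplicate-pair covariance convention.  Monomorphic
    variants carry no information and are skipped.
    """
    X = genotypes.dosage
    n = genotypes.n_samples
    if n < 2:
        raise ValidationError("kinship needs at least 2 samples")
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValidationError("all variants are monomorphic")
    Xp = X[:, poly]
    p = p[poly]
    m = Xp.shape[1]
    het = 2.0 * p * (1.0 - p)
    Z = (Xp - 2.0 * p) / np.sqrt(2.0 * het)   # scaled so Z Z' / m has 4p(1-p)/2...
    # K_ij = mean_v (g_i-2p)(g_j-2p)/(4 p q) = (Z Z')_ij / m with Z scaled by
    # 1/sqrt(2 * 2 p q)
    K = (Z @ Z.T) / m
    f_hat = (Xp * Xp - (1.0 + 2.0 * p) * Xp + 2.0 * p * p).sum(axis=1)
    f_hat = f_hat / het.sum()
    np.fill_diagonal(K, 0.5 * (1.0 + f_hat))
    K = 0.5 * (K + K.T)
    return KinshipMatrix(list(genotypes.samples), K)


def write_kinship(kinship: KinshipMatrix, path: str) -> None:
    import pandas as pd

    df = pd.DataFrame(kinship.K, index=kinship.samples, columns=kinship.samples)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_kinship(path: str) -> KinshipMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return KinshipMatrix([str(s) for s in df.columns], df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# polygenic REML fit
# ---------------------------------------------------------------------------

def _eigendecompose(kinship: KinshipMatrix, psd: str = "clip",
                    psd_tol: float = 1e-8):
    """Eigendecompose 2K.

    A genomic kinship matrix estimated from a finite SNP panel (with the
    diagonal fixed to 0.5(1+f)) is often very slightly indefinite.  The
    default policy truncates negative eigenvalues at zero (the usual
    treatment of empirical relationship matrices); ``psd='raise'`` demands a
    PSD input and errors otherwise.
    """
    d, U = np.linalg.eigh(2.0 * kinship.K)
    if psd == "raise" and d.min() < -psd_tol:
        raise ValidationError(
            f"2K is not positive semi-definite (min eigenvalue {d.min():.3e}); "
            "add a small ridge to the kinship diagonal or use psd='clip'"
        )
    return np.clip(d, 0.0, None), U


def _reml_pieces(h2: float, yt: np.ndarray, Xt: np.ndarray, d: np.ndarray):
    n, pdim = Xt.shape
    w = h2 * d + (1.0 - h2)
    Xw = Xt / w[:, None]
    A = Xt.T @ Xw
    rhs = Xw.T @ yt
    beta = np.linalg.solve(A, rhs)
    resid = yt - Xt @ beta
    rss = float(resid @ (resid / w))
    sigma2 = rss / (n - pdim)
    sign, logdetA = np.linalg.slogdet(A)
    ll = -0.5 * (
        (n - pdim) * (np.log(2.0 * np.pi * sigma2) + 1.0)
        + np.log(w).sum()
        + logdetA
    )
    return ll, beta, sigma2


def profile_reml_loglik(
    h2: float, y: np.ndarray, X: np.ndarray, kinship: KinshipMatrix
) -> float:
    """Restricted log-likelihood profiled over the total variance, at h2."""
    d, U = _eigendecompose(kinship)
    ll, _, _ = _reml_pieces(h2, U.T @ y, U.T @ X, d)
    return ll


def fit_polygenic(
    y: np.ndarray,
    covariates: np.ndarray,
    kinship: KinshipMatrix,
    h2_fixed: Optional[float] = None,
    tol: float = 1e-8,
    psd: str = "clip",
) -> PolygenicFit:
    """REML fit of the null polygenic model via one eigendecomposition of 2K.

    The restricted likelihood is profiled over the total variance and
    maximized over h2 = sigma2_g / (sigma2_g + sigma2_e) on (0, 1) by Brent
    search.  ``h2_fixed`` skips the search (useful to force e.g. sigma2_g = 0).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(covariates, dtype=float)
    n = len(y)
    if X.shape[0] != n or len(kinship.samples) != n:
        raise ValidationError("y, covariates and kinship dimensions disagree")
    d, U = _eigendecompose(kinship, psd=psd)
    yt, Xt = U.T @ y, U.T @ X

    identifiable = bool(np.ptp(d) > 1e-8)
    if h2_fixed is not None:
        h2 = float(h2_fixed)
    elif not identifiable:
        # V is proportional to I for every h2; components are not separable
        h2 = 0.0
    else:
        lo, hi = 1e-9, 1.0 - 1e-6
        res = optimize.minimize_scalar(
            lambda h: -_reml_pieces(h, yt, Xt, d)[0],
            bounds=(lo, hi), method="bounded",
            options={"xatol": tol},
        )
        if not res.success:
            grid = np.linspace(lo, hi, 50)
            trace = [(h, _reml_pieces(h, yt, Xt, d)[0]) for h in grid]
            raise ValidationError(
                f"REML search failed to converge; likelihood trace: {trace}"
            )
        h2 = float(res.x)
        # the bounded search can sit at an interior point when the optimum is
        # at the h2 -> 0 boundary; compare explicitly
        if _reml_pieces(lo, yt, Xt, d)[0] >= _reml_pieces(h2, yt, Xt, d)[0]:
            h2 = lo
    ll, beta, sigma2 = _reml_pieces(h2, yt, Xt, d)
    fit = PolygenicFit(
        samples=list(kinship.samples),
        sigma2_g=h2 * sigma2,
        sigma2_e=(1.0 - h2) * sigma2,
        fixed_effects=beta,
        residuals=y - X @ beta,
        loglik=ll,
        eigvecs=U,
        eigvals=d,
        X=X,
        identifiable=identifiable,
    )
    return fit


# ---------------------------------------------------------------------------
# score test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreTestResult:
    beta: float
    se: float
    p: Optional[float]
    testable: bool = True


def _rotated_cache(fit: PolygenicFit):
    cache = getattr(fit, "_rot_cache", None)
    if cache is None:
        w = fit.v_weights()
        Xt = fit.eigvecs.T @ fit.X
        rt = fit.eigvecs.T @ fit.residuals
        Xw = Xt / w[:, None]
        A = Xt.T @ Xw
        Ainv = np.linalg.inv(A)
        cache = (w, Xt, Xw, Ainv, rt / w)
        fit._rot_cache = cache
    return cache


def score_test(coded_genotype: np.ndarray, fit: PolygenicFit) -> ScoreTestResult:
    """Exact-GLS single-variant test against the null polygenic fit."""
    g = np.asarray(coded_genotype, dtype=float)
    if g.shape != (fit.n,):
        raise ValidationError("coded genotype length does not match the fit")
    res = score_test_batch(g[:, None], fit)
    return res[0]


def score_test_batch(coded: np.ndarray, fit: PolygenicFit) -> list:
    """Vectorized score tests for an n x m matrix of coded genotypes."""
    w, Xt, Xw, Ainv, rw = _rotated_cache(fit)
    Gt = fit.eigvecs.T @ np.asarray(coded, dtype=float)
    B = Xw.T @ Gt                         # p x m
    Ct = Gt - Xt @ (Ainv @ B)             # residualized, rotated
    den = np.einsum("ij,ij->j", Ct, Ct / w[:, None])
    num = Ct.T @ rw
    cnorm = np.einsum("ij,ij->j", Ct, Ct)
    gnorm = np.einsum("ij,ij->j", Gt, Gt)
    out = []
    for j in range(coded.shape[1]):
        if cnorm[j] <= 1e-10 * (gnorm[j] + 1.0):
            out.append(ScoreTestResult(np.nan, np.nan, None, testable=False))
            continue
        beta = num[j] / den[j]
        se = 1.0 / np.sqrt(den[j])
        z = beta / se
        p = float(min(1.0, max(2.0 * stats.norm.sf(abs(z)), 5e-324)))
        out.append(ScoreTestResult(float(beta), float(se), p))
    return out
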