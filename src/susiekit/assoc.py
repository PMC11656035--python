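"""Per-variant logistic regression, LD matrices and positive-definite repair.

Summary statistics are held in a pandas DataFrame with PLINK-style columns
``SNP, CHR, BP, A1, A2, BETA, SE, Z, P, MAF`` (A1 is the counted/effect
allele). The LD matrix is the Pearson correlation of dosage columns over the
same individuals used for association (in-sample LD); when it is not
positive definite it is repaired by flooring eigenvalues at ``eps`` and
rescaling back to unit diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .synthetic import GenotypeMatrix, PhenotypeVector

SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "Z", "P", "MAF"]

#: |beta| beyond which a logistic fit is treated as (quasi-)separated
SEPARATION_BETA = 15.0


class EmptyLocusError(ValueError):
    """No variants survive filtering at a locus."""


class MonomorphicVariantError(ValueError):
    """A genotype column has zero variance."""


@dataclass
class LDMatrix:
    """Symmetric unit-diagonal variant correlation matrix.

    ``repaired`` records whether an eigenvalue-flooring repair (floor
    ``eps``) was applied to make the matrix positive definite.
    """

    r: np.ndarray
    variant_ids: np.ndarray | None = None
    repaired: bool = False
    eps: float = field(default=1e-4)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("LD matrix must be square")
        if self.variant_ids is not None:
            self.variant_ids = np.asarray(self.variant_ids, dtype=object)
            if len(self.variant_ids) != self.r.shape[0]:
                raise ValueError("variant_ids length does not match matrix")

    @property
    def p(self) -> int:
        return self.r.shape[0]

    def validate(self, atol: float = 1e-12) -> None:
        if not np.allclose(self.r, self.r.T, atol=atol, rtol=0):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=atol, rtol=0):
            raise ValueError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1 + atol):
            raise ValueError("LD entries exceed 1 in magnitude")

    def subset(self, idx: np.ndarray) -> "LDMatrix":
        ids = None if self.variant_ids is None else self.variant_ids[idx]
        return LDMatrix(
            r=self.r[np.ix_(idx, idx)], variant_ids=ids, repaired=self.repaired, eps=self.eps
        )


def _as_dosage_array(genotypes) -> np.ndarray:
    if isinstance(genotypes, GenotypeMatrix):
        return np.asarray(genotypes.dosages, dtype=float)
    return np.asarray(genotypes, dtype=float)


def _as_labels(phenotype) -> np.ndarray:
    if isinstance(phenotype, PhenotypeVector):
        return np.asarray(phenotype.y, dtype=float)
    return np.asarray(phenotype, dtype=float)


def _newton_no_covariates(
    g: np.ndarray, y: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched Newton-Raphson for per-variant intercept+dosage logistic fits.

    All variants are updated simultaneously with closed-form 2x2 solves.
    Returns (beta, se, converged-and-sane mask).
    """
    n, p = g.shape
    b0 = np.full(p, logit(np.clip(y.mean(), 1e-12, 1 - 1e-12)))
    b1 = np.zeros(p)
    ok = np.ones(p, dtype=bool)
    active = np.ones(p, dtype=bool)
    se = np.full(p, np.nan)
    for _ in range(max_iter):
        if not active.any():
            break
        ga = g[:, active]
        eta = b0[active][None, :] + ga * b1[active][None, :]
        mu = expit(eta)
        resid = y[:, None] - mu
        g0 = resid.sum(axis=0)
        g1 = (ga * resid).sum(axis=0)
        w = mu * (1.0 - mu)
        s00 = w.sum(axis=0)
        s01 = (w * ga).sum(axis=0)
        s11 = (w * ga * ga).sum(axis=0)
        det = s00 * s11 - s01 * s01
        bad = det <= 1e-12
        det = np.where(bad, 1.0, det)
        db0 = (s11 * g0 - s01 * g1) / det
        db1 = (s00 * g1 - s01 * g0) / det
        ia = np.flatnonzero(active)
        b0[ia] += np.where(bad, 0.0, db0)
        b1[ia] += np.where(bad, 0.0, db1)
        se[ia] = np.sqrt(np.maximum(s00 / det, 0.0))
        done = np.maximum(np.abs(g0), np.abs(g1)) < tol
        sep = (np.abs(b1[ia]) > SEPARATION_BETA) | bad
        ok[ia[sep]] = False
        active[ia[done | sep]] = False
    ok &= ~active  # never converged
    ok &= np.isfinite(se) & (se > 0)
    return b1, se, ok


def _newton_with_covariates(
    g: np.ndarray, y: np.ndarray, covar: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, p = g.shape
    # drop covariate columns that are constant or duplicated (rank deficiency)
    x0 = np.column_stack([np.ones(n), covar])
    q, r, piv = _qr_rank(x0)
    if q.shape[1] < x0.shape[1]:
        warnings.warn(
            "rank-deficient covariate design: dropping redundant columns",
            stacklevel=3,
        )
    base = q  # orthonormal basis of the intercept+covariate column space
    beta = np.full(p, np.nan)
    se = np.full(p, np.nan)
    ok = np.zeros(p, dtype=bool)
    for j in range(p):
        x = np.column_stack([base, g[:, j]])
        k = x.shape[1]
        coef = np.zeros(k)
        good = False
        for _ in range(max_iter):
            eta = x @ coef
            mu = expit(eta)
            grad = x.T @ (y - mu)
            w = mu * (1.0 - mu)
            hess = (x * w[:, None]).T @ x
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                break
            coef += step
            if np.abs(coef[-1]) > SEPARATION_BETA:
                break
            if np.max(np.abs(grad)) < tol:
                good = True
                break
        if good:
            eta = x @ coef
            w = expit(eta) * (1.0 - expit(eta))
            hess = (x * w[:, None]).T @ x
            try:
                cov = np.linalg.inv(hess)
            except np.linalg.LinAlgError:
                continue
            beta[j] = coef[-1]
            se[j] = np.sqrt(cov[-1, -1])
            ok[j] = np.isfinite(se[j]) and se[j] > 0
    return beta, se, ok


def _qr_rank(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-pivoted rank-revealing reduction; returns orthonormal basis."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(diag.max(), 1.0)
    return q[:, keep], r[keep], keep


def logistic_gwas(
    genotypes,
    phenotype,
    covariates: np.ndarray | None = None,
    chrom: str = "1",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Per-variant logistic regression (Wald tests), one variant at a time.

    Each variant's Bernoulli log-likelihood with linear predictor
    ``intercept + dosage (+ covariates)`` is maximised by Newton-Raphson to
    gradient norm < ``tol``; BETA/SE are the dosage coefficient and its
    observed-information standard error, P the two-sided normal tail of
    Z = BETA/SE. Variants that fail to converge or show separation
    (|beta| > 15) are excluded with a warning. Monomorphic columns are
    excluded likewise.
    """
    g = _as_dosage_array(genotypes)
    y = _as_labels(phenotype)
    if y.ndim != 1 or g.shape[0] != y.size:
        raise ValueError("genotype rows and phenotype length disagree")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need at least one case and one control")

    n, p = g.shape
    poly = g.std(axis=0) > 0
    beta = np.full(p, np.nan)
    se = np.full(p, np.nan)
    ok = np.zeros(p, dtype=bool)
    if poly.any():
        gp = g[:, poly]
        if covariates is None or np.size(covariates) == 0:
            b, s, conv = _newton_no_covariates(gp, y, max_iter, tol)
        else:
            covar = np.asarray(covariates, dtype=float)
            if covar.ndim == 1:
                covar = covar[:, None]
            b, s, conv = _newton_with_covariates(gp, y, covar, max_iter, tol)
        beta[poly], se[poly], ok[poly] = b, s, conv

    excluded = np.flatnonzero(~ok)
    if excluded.size:
        warnings.warn(
            f"excluded {excluded.size} variant(s) (monomorphic, separated or "
            "non-converged)",
            stacklevel=2,
        )

    if isinstance(genotypes, GenotypeMatrix):
        ids = genotypes.variant_ids
        pos = genotypes.positions
    else:
        ids = np.array([f"snp{j + 1}" for j in range(p)], dtype=object)
        pos = np.arange(1, p + 1, dtype=np.int64)
    freq = g.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)

    z = beta / se
    df = pd.DataFrame(
        {
            "SNP": ids,
            "CHR": chrom,
            "BP": pos,
            "A1": "A",
            "A2": "G",
            "BETA": beta,
            "SE": se,
            "Z": z,
            "P": 2.0 * norm.sf(np.abs(z)),
            "MAF": maf,
        }
    )
    df = df.loc[ok].reset_index(drop=True)
    df.attrs["excluded"] = ids[excluded].tolist()
    return df


def filter_variants(
    sumstats: pd.DataFrame, maf_min: float = 1e-4, ld: LDMatrix | None = None
):
    """Keep variants with MAF strictly greater than ``maf_min``.

    Row order is preserved; when an aligned LD matrix is supplied its rows
    and columns are subset in lockstep and the pair is returned.
    """
    if "MAF" not in sumstats.columns:
        raise ValueError("summary statistics lack a MAF column")
    keep = np.flatnonzero(sumstats["MAF"].to_numpy() > maf_min)
    out = sumstats.iloc[keep].reset_index(drop=True)
    out.attrs = dict(sumstats.attrs)
    if ld is None:
        return out
    if ld.p != len(sumstats):
        raise ValueError("LD matrix is not aligned with the summary statistics")
    return out, ld.subset(keep)


def compute_ld(genotypes) -> LDMatrix:
    """In-sample LD: Pearson correlation of dosage columns."""
    g = _as_dosage_array(genotypes)
    sd = g.std(axis=0)
    if np.any(sd == 0):
        if isinstance(genotypes, GenotypeMatrix):
            bad = genotypes.variant_ids[sd == 0].tolist()
        else:
            bad = np.flatnonzero(sd == 0).tolist()
        raise MonomorphicVariantError(f"monomorphic variant(s): {bad}")
    r = np.corrcoef(g, rowvar=False)
    r = np.atleast_2d(r)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    ids = genotypes.variant_ids if isinstance(genotypes, GenotypeMatrix) else None
    return LDMatrix(r=r, variant_ids=ids)


def repair_psd(ld: LDMatrix | np.ndarray, eps: float = 1e-4) -> LDMatrix:
    """Force a correlation matrix to be positive definite.

    Eigenvalues below ``eps`` are raised to ``eps``, the matrix is
    reconstructed and rescaled to unit diagonal. Inputs whose smallest
    eigenvalue is already >= ``eps`` are returned unchanged (idempotent).
    """
    if isinstance(ld, LDMatrix):
        r, ids = ld.r, ld.variant_ids
    else:
        r, ids = np.asarray(ld, dtype=float), None
    if not np.allclose(r, r.T, atol=1e-8, rtol=0):
        raise ValueError("matrix is asymmetric beyond 1e-8")
    r = (r + r.T) / 2.0
    vals, vecs = np.linalg.eigh(r)
    if vals[0] >= eps:
        return LDMatrix(r=r, variant_ids=ids, repaired=False, eps=eps)
    fixed = (vecs * np.maximum(vals, eps)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    fixed = (fixed + fixed.T) / 2.0
    np.fill_diagonal(fixed, 1.0)
    return LDMatrix(r=fixed, variant_ids=ids, repaired=True, eps=eps)
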