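"""Sum-of-single-effects regression on z-scores with an LD matrix.

The model writes the standardized effect vector as a sum of L "single
effect" vectors, each having exactly one nonzero coordinate. Each single
effect regression (SER) has a conjugate form on residualized z-scores:
with prior variance s0 on the (standardized) effect,

    lbf_j = -0.5 * log(1 + s0) + 0.5 * z_j^2 * s0 / (1 + s0)
    alpha_j  propto  prior_weight_j * exp(lbf_j)
    mu1_j = z_j * s0 / (1 + s0),   posterior variance = s0 / (1 + s0)

The L effects are fitted by iterative Bayesian stepwise selection: each
sweep residualizes the z-scores against the other effects through the LD
matrix R and refits one SER, optionally re-estimating its prior variance on
a grid that includes 0 so superfluous effects switch off. The variational
objective (an evidence lower bound) is tracked per sweep and is
non-decreasing because each SER update is an exact coordinate maximisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .assoc import LDMatrix


def default_sigma0_grid() -> np.ndarray:
    """Prior-variance grid: 0 plus 15 log-spaced values in [1e-3, 1e2]
    (z-score units), wide enough for GWAS-scale standardized effects."""
    return np.concatenate([[0.0], np.logspace(-3, 2, 15)])


@dataclass
class SusieFit:
    """Fitted sum-of-single-effects model.

    ``alpha`` (L x p) are per-effect inclusion probabilities, ``mu1`` /
    ``mu2`` the posterior first/second moments of each effect conditional on
    inclusion, ``sigma0_sq`` the per-effect prior variances (0 = effect
    switched off), ``elbo_trace`` the per-sweep objective values.
    """

    alpha: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray
    sigma0_sq: np.ndarray
    elbo_trace: np.ndarray
    converged: bool
    n_iter: int
    prior_weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def L(self) -> int:
        return self.alpha.shape[0]

    @property
    def p(self) -> int:
        return self.alpha.shape[1]


@dataclass
class PIPVector:
    """Marginal posterior inclusion probabilities, one per variant."""

    pip: np.ndarray

    def __post_init__(self) -> None:
        self.pip = np.asarray(self.pip, dtype=float)
        if np.any((self.pip < 0) | (self.pip > 1)):
            raise ValueError("PIPs must lie in [0, 1]")


def ser_fit(
    z_resid: np.ndarray,
    sigma0_sq: float,
    prior_weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Single effect regression on residualized z-scores.

    Returns (alpha, mu1, mu2, log_bf) where log_bf is the log Bayes factor
    of the SER model against the null, log sum_j w_j exp(lbf_j).
    """
    z = np.asarray(z_resid, dtype=float)
    w = np.asarray(prior_weights, dtype=float)
    if sigma0_sq < 0:
        raise ValueError("prior variance must be nonnegative")
    if z.shape != w.shape:
        raise ValueError("z_resid and prior_weights shapes disagree")
    s0 = float(sigma0_sq)
    shrink = s0 / (1.0 + s0)
    lbf = -0.5 * np.log1p(s0) + 0.5 * z * z * shrink
    with np.errstate(divide="ignore"):
        logw = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)), -np.inf)
    log_bf = float(logsumexp(lbf + logw))
    shifted = lbf + logw
    shifted = shifted - shifted.max()
    alpha = np.exp(shifted)
    alpha /= alpha.sum()
    mu1 = shrink * z
    mu2 = shrink + mu1 * mu1
    return alpha, mu1, mu2, log_bf


def estimate_sigma0(
    z_resid: np.ndarray,
    prior_weights: np.ndarray,
    grid: np.ndarray | None = None,
) -> float:
    """Pick the prior variance maximising the SER log Bayes factor on a grid.

    Zero is always included so null effects can switch off; ties favour the
    smaller variance.
    """
    g = default_sigma0_grid() if grid is None else np.asarray(grid, dtype=float)
    if g.size == 0:
        raise ValueError("grid must be nonempty")
    g = np.unique(np.concatenate([[0.0], g]))  # sorted, 0 included
    lbfs = np.array([ser_fit(z_resid, s0, prior_weights)[3] for s0 in g])
    return float(g[int(np.argmax(lbfs))])


def _elbo(
    z: np.ndarray,
    R: np.ndarray,
    alpha: np.ndarray,
    mu1: np.ndarray,
    mu2: np.ndarray,
    sigma0_sq: np.ndarray,
    prior_weights: np.ndarray,
) -> float:
    """Variational objective (constants independent of the fit dropped).

    Expected residual sum of squares uses the sufficient-statistic identity
    with X'X = R and unit diagonal; the KL term of each SER posterior
    against its prior is available in closed form.
    """
    bbar = alpha * mu1  # L x p
    btot = bbar.sum(axis=0)
    Rb = R @ btot
    erss = (
        float(z.size)
        - 2.0 * float(btot @ z)
        + float(btot @ Rb)
        - float(np.einsum("lp,pq,lq->", bbar, R, bbar))
        + float((alpha * mu2).sum())
    )
    kl = 0.0
    logw = np.where(prior_weights > 0, np.log(np.where(prior_weights > 0, prior_weights, 1.0)), np.inf)
    for l in range(alpha.shape[0]):
        s0 = sigma0_sq[l]
        if s0 <= 0:
            continue
        a = alpha[l]
        tau2 = s0 / (1.0 + s0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = np.where(a > 0, a * (np.log(np.where(a > 0, a, 1.0)) - logw), 0.0)
        kl_norm = 0.5 * (np.log1p(s0) + (tau2 + mu1[l] ** 2) / s0 - 1.0)
        kl += float(ent.sum() + (a * kl_norm).sum())
    return -0.5 * erss - kl


def fit_susie_rss(
    z: np.ndarray,
    ld: LDMatrix | np.ndarray,
    L: int = 10,
    *,
    prior_weights: np.ndarray | None = None,
    sigma0_sq: float = 1.0,
    estimate_prior: bool = True,
    sigma0_grid: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-3,
) -> SusieFit:
    """Fit the sum-of-single-effects model to z-scores and an LD matrix.

    Effects are updated in order 1..L within each sweep; convergence is
    declared when the maximum absolute change in PIP between sweeps falls
    below ``tol``. The LD matrix must be positive definite (repair it
    first if necessary).
    """
    z = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(z)):
        raise ValueError("z contains non-finite values")
    R = ld.r if isinstance(ld, LDMatrix) else np.asarray(ld, dtype=float)
    p = z.size
    if R.shape != (p, p):
        raise ValueError(f"LD matrix shape {R.shape} does not match p={p}")
    if not 1 <= L <= p:
        raise ValueError("require 1 <= L <= p")
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        raise ValueError(
            "LD matrix is not positive definite; apply repair_psd first"
        ) from None

    w = np.full(p, 1.0 / p) if prior_weights is None else np.asarray(prior_weights, float)
    w = w / w.sum()

    alpha = np.tile(w, (L, 1))
    mu1 = np.zeros((L, p))
    mu2 = np.zeros((L, p))
    s0 = np.full(L, float(sigma0_sq))
    if estimate_prior:
        s0[:] = 0.0
    Rb = R @ (alpha * mu1).sum(axis=0)

    pip_prev = np.zeros(p)
    elbo_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for l in range(L):
            bl = alpha[l] * mu1[l]
            Rb_minus = Rb - R @ bl
            z_resid = z - Rb_minus
            if estimate_prior:
                s0[l] = estimate_sigma0(z_resid, w, sigma0_grid)
            a, m1, m2, _ = ser_fit(z_resid, s0[l], w)
            alpha[l], mu1[l], mu2[l] = a, m1, m2
            Rb = Rb_minus + R @ (a * m1)
        elbo_trace.append(_elbo(z, R, alpha, mu1, mu2, s0, w))
        pip = compute_pip_arrays(alpha, s0)
        if np.max(np.abs(pip - pip_prev)) < tol:
            converged = True
            break
        pip_prev = pip

    return SusieFit(
        alpha=alpha,
        mu1=mu1,
        mu2=mu2,
        sigma0_sq=s0,
        elbo_trace=np.asarray(elbo_trace),
        converged=converged,
        n_iter=it,
        prior_weights=w,
    )


def compute_pip_arrays(alpha: np.ndarray, sigma0_sq: np.ndarray) -> np.ndarray:
    """PIP_j = 1 - prod_l (1 - alpha_lj) over effects with sigma0_sq > 0."""
    live = sigma0_sq > 0
    if not live.any():
        return np.zeros(alpha.shape[1])
    return 1.0 - np.prod(1.0 - alpha[live], axis=0)


def compute_pip(fit: SusieFit) -> PIPVector:
    """Marginal inclusion probabilities of a fitted model (null effects
    excluded from the product)."""
    return PIPVector(pip=compute_pip_arrays(fit.alpha, fit.sigma0_sq))
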