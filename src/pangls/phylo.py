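"""Phylogenetic covariance, Pagel-λ GLS, and phylogenetic-signal tests.

The Brownian-motion covariance of a rooted tree assigns each pair of tips
the branch-length distance from the root to their most recent common
ancestor; the diagonal holds root-to-tip path lengths.  Pagel's λ rescales
the off-diagonal (shared history) part of that matrix, interpolating between
complete independence (λ = 0) and full Brownian covariance (λ = 1).

GLS fitting uses the maximum-likelihood variance estimate in the reported
log-likelihood, so models with λ free, λ = 0 and λ = 1 are comparable on a
single AIC scale; reported standard errors use the usual small-sample
divisor n − p.  A REML objective is available behind a flag for comparison
with `nlme::gls` defaults, but ML is the package default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .io import DataValidationError, Phylogeny

logger = logging.getLogger(__name__)

#: absolute log-likelihood tolerance below which a λ profile is called flat
FLAT_PROFILE_TOL = 1e-7


class NumericalError(RuntimeError):
    """A fit could not be computed (singular design, degenerate likelihood)."""


@dataclass
class GLSFit:
    """Generalized least-squares fit y = Xβ + ε, ε ~ N(0, σ²V)."""

    beta: np.ndarray
    se: np.ndarray
    sigma2_ml: float
    sigma2_adj: float
    loglik: float
    n: int
    n_coef: int
    residuals: np.ndarray            # raw residuals y − Xβ̂
    whitened_residuals: np.ndarray   # L⁻¹(y − Xβ̂), decorrelated under the model

    @property
    def n_params(self) -> int:
        """Free parameters counted for AIC: coefficients plus σ²."""
        return self.n_coef + 1


@dataclass
class ProfiledLambda:
    lam: float
    loglik: float
    fit: GLSFit
    profile_flat: bool = False


@dataclass
class SignalTestResult:
    """Result of a phylogenetic-signal test (Pagel's λ LRT or Blomberg's K)."""

    statistic_name: str
    estimate: float
    p_value: float
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Covariance construction
# ---------------------------------------------------------------------------


def phylo_covariance(phylogeny: Phylogeny) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance matrix of a rooted tree.

    Returns the tree's tip labels (in tree order) and the matrix V with
    V[i, j] = root-to-MRCA path length for tips i, j.  The root's own stem
    edge, if present, is excluded.
    """
    tree = phylogeny.tree
    labels = phylogeny.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))

    # Shared history starts at the MRCA of the tips: walk past any basal
    # unifurcation chain (e.g. a stem left by pruning an outgroup) so the
    # stem length does not leak into every entry of V.
    origin = tree.seed_node
    while len(origin.child_nodes()) == 1:
        origin = origin.child_nodes()[0]
    depth: dict[int, float] = {id(origin): 0.0}
    skipped = {id(a) for a in origin.ancestor_iter()}
    for node in tree.preorder_node_iter():
        if id(node) in depth or id(node) in skipped:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + node.edge.length

    # Postorder: the MRCA of two tips in different child subtrees is this node.
    tips_below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            V[i, i] = depth[id(node)]
            tips_below[id(node)] = [i]
        else:
            groups = [tips_below.pop(id(c)) for c in node.child_nodes()]
            d = depth.get(id(node), 0.0)  # basal unifurcations have one group
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            V[i, j] = V[j, i] = d
            tips_below[id(node)] = [i for g in groups for i in g]
    return labels, V


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Scale the off-diagonal of V by λ ∈ [0, 1], leaving the diagonal."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    out = V * lam
    np.fill_diagonal(out, np.diag(V))
    return out


def _cholesky_with_jitter(V: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor; on failure retry once with a tiny ridge."""
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        jitter = 1e-10 * float(np.mean(np.diag(V)))
        logger.warning("covariance factorization failed; adding jitter %.3g", jitter)
        try:
            return linalg.cholesky(V + jitter * np.eye(V.shape[0]), lower=True)
        except linalg.LinAlgError as exc:
            raise NumericalError("covariance matrix is not positive definite") from exc


# ---------------------------------------------------------------------------
# GLS
# ---------------------------------------------------------------------------


def gls_fit(y: np.ndarray, X: np.ndarray, V: np.ndarray,
            reml: bool = False) -> GLSFit:
    """Fit y = Xβ + ε with ε ~ N(0, σ²V) by whitening.

    β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y; σ̂²_ML = rᵀV⁻¹r/n; the log-likelihood profiles σ²
    out at its ML (or REML) value.  SEs use σ̂²_adj with divisor n − p.
    With V = I the fit reduces exactly to OLS.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n, p = X.shape
    if n <= p:
        raise NumericalError(f"need n > p, got n={n}, p={p}")
    L = _cholesky_with_jitter(V)
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < p:
        raise NumericalError("design matrix is singular")
    rw = yw - Xw @ beta
    rss = float(rw @ rw)
    sigma2_ml = rss / n
    # an (almost) perfect fit has no likelihood maximum in sigma^2
    degenerate_below = 1e-12 * float(np.var(yw)) if np.var(yw) > 0 else 0.0
    if sigma2_ml <= degenerate_below or not np.isfinite(sigma2_ml):
        raise NumericalError("degenerate likelihood: residual variance is zero")
    sigma2_adj = rss / (n - p)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    if reml:
        XtX = Xw.T @ Xw
        sign, logdet_xtx = np.linalg.slogdet(XtX)
        sigma2_reml = rss / (n - p)
        loglik = -0.5 * ((n - p) * math.log(2 * math.pi * sigma2_reml)
                         + logdetV + logdet_xtx + (n - p))
    else:
        loglik = -0.5 * (n * math.log(2 * math.pi * sigma2_ml) + logdetV + n)
    XtVinvX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(sigma2_adj * np.diag(XtVinvX_inv))
    return GLSFit(beta=beta, se=se, sigma2_ml=sigma2_ml, sigma2_adj=sigma2_adj,
                  loglik=loglik, n=n, n_coef=p,
                  residuals=y - X @ beta, whitened_residuals=rw)


def profile_lambda(y: np.ndarray, X: np.ndarray, V: np.ndarray,
                   reml: bool = False, xatol: float = 1e-6) -> ProfiledLambda:
    """Maximize the GLS likelihood over λ ∈ [0, 1] (bounded scalar search).

    The endpoints are always evaluated; a profile flat to within
    ``FLAT_PROFILE_TOL`` reports λ̂ = 0 with ``profile_flat=True`` (parsimony
    tie-break — a star tree otherwise returns an arbitrary λ).
    """

    def negll(lam: float) -> float:
        return -gls_fit(y, X, lambda_transform(V, lam), reml=reml).loglik

    res = optimize.minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": xatol})
    candidates = [(0.0, -negll(0.0)), (1.0, -negll(1.0)),
                  (float(res.x), -float(res.fun))]
    lam_hat, ll_hat = max(candidates, key=lambda t: t[1])
    ll0 = candidates[0][1]
    flat = (ll_hat - ll0) < FLAT_PROFILE_TOL
    if flat:
        lam_hat, ll_hat = 0.0, ll0
    fit = gls_fit(y, X, lambda_transform(V, lam_hat), reml=reml)
    return ProfiledLambda(lam=lam_hat, loglik=fit.loglik, fit=fit,
                          profile_flat=flat)


# ---------------------------------------------------------------------------
# Signal tests
# ---------------------------------------------------------------------------


def pagel_lambda_test(y: np.ndarray, V: np.ndarray,
                      reml: bool = False) -> SignalTestResult:
    """Likelihood-ratio test of Pagel's λ for an intercept-only model.

    LRT = 2(lnL(λ̂) − lnL(λ=0)) against the upper tail of χ²₁.  At λ̂ = 0 the
    models coincide and p = 1.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] < 4:
        raise DataValidationError("signal tests need at least 4 tips")
    if np.allclose(y, y[0]):
        raise DataValidationError("trait is constant; signal test undefined")
    X = np.ones((y.shape[0], 1))
    prof = profile_lambda(y, X, V, reml=reml)
    ll0 = gls_fit(y, X, lambda_transform(V, 0.0), reml=reml).loglik
    lrt = max(0.0, 2.0 * (prof.loglik - ll0))
    p = 1.0 if prof.lam == 0.0 else float(stats.chi2.sf(lrt, df=1))
    return SignalTestResult(
        statistic_name="pagel_lambda", estimate=prof.lam, p_value=p,
        extras={"lrt": lrt, "loglik_hat": prof.loglik, "loglik_0": ll0,
                "profile_flat": prof.profile_flat},
    )


def _blomberg_k_stats(Y: np.ndarray, Vinv: np.ndarray, trV: float,
                      n: int) -> np.ndarray:
    """Vectorized K for each column of Y (n × m)."""
    ones = np.ones(n)
    Vinv1 = Vinv @ ones
    denom = float(ones @ Vinv1)
    abar = (Vinv1 @ Y) / denom                     # phylogenetic mean per column
    R = Y - abar[np.newaxis, :]
    mse0 = np.einsum("ij,ij->j", R, R) / (n - 1)
    mse = np.einsum("ij,ij->j", R, Vinv @ R) / (n - 1)
    expected = (trV - n / denom) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(y: np.ndarray, V: np.ndarray, n_perm: int = 999,
               seed: int | None = None) -> SignalTestResult:
    """Blomberg's K with a tip-permutation test.

    K compares the observed ratio of tip variance to phylogenetically
    corrected variance against its Brownian-motion expectation; K ≈ 1 under
    BM, K → 0 with no signal.  p = (1 + #{K_perm ≥ K_obs}) / (n_perm + 1).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if np.allclose(y, y[0]):
        raise DataValidationError("trait is constant; K undefined")
    if n_perm < 99:
        raise ValueError("need n_perm >= 99")
    L = _cholesky_with_jitter(V)
    Vinv = linalg.cho_solve((L, True), np.eye(n))
    trV = float(np.trace(V))
    k_obs = float(_blomberg_k_stats(y[:, None], Vinv, trV, n)[0])
    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm))
    for j in range(n_perm):
        perms[:, j] = y[rng.permutation(n)]
    k_perm = _blomberg_k_stats(perms, Vinv, trV, n)
    p = (1.0 + float(np.sum(k_perm >= k_obs))) / (n_perm + 1.0)
    return SignalTestResult(statistic_name="blomberg_K", estimate=k_obs,
                            p_value=p, extras={"n_perm": n_perm})
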