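"""Single-kernel linear mixed model solver (EMMA/GEMMA device).

Model: y = X b + u + e with u ~ N(0, Ks * sigma_s2) and e ~ N(0, sigma_e2 * I).
Writing delta = sigma_e2 / sigma_s2, the covariance is sigma_s2 * H with
H = Ks + delta * I.  A one-time spectral decomposition Ks = U S U^T rotates
the problem so that, for any delta, H is diagonal, making the profile ML and
REML log-likelihoods over delta cheap to evaluate on a grid.  The optimum is
located by a log-spaced grid search followed by Brent refinement; the
fixed effects are the GLS estimate at the optimal delta and sigma_s2 has a
closed-form profile estimate.

Profile log-likelihoods (r = y - X beta_GLS, q = r^T H^{-1} r):

  ML:    sigma_s2 = q / n,        lF = -1/2 [ n log(2 pi sigma_s2) + log|H| + n ]
  REML:  sigma_s2 = q / (n - p),
         lR = lF + 1/2 [ p log(2 pi sigma_s2) + log|X^T X| - log|X^T H^-1 X| ]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from blocklmm.kernels import GramMatrix

DELTA_MIN = 1e-5
DELTA_MAX = 1e5
_GRID_SIZE = 100
_SIGMA_FLOOR = 1e-12


@dataclass
class SingleKernelFit:
    """Result of a single-kernel LMM fit.

    delta is the residual-to-genetic variance ratio sigma_e2/sigma_s2; lF
    and lR are the full and restricted log-likelihoods evaluated at the
    returned estimates.  ``boundary`` flags delta pinned at the search
    bounds [1e-5, 1e5].
    """

    beta_hat: np.ndarray
    sigma_s2: float
    sigma_e2: float
    delta: float
    lF: float
    lR: float
    boundary: bool = False


def _as_matrix(Ks) -> np.ndarray:
    return Ks.values if isinstance(Ks, GramMatrix) else np.asarray(Ks, dtype=float)


def eigendecompose(Ks) -> tuple[np.ndarray, np.ndarray]:
    """Spectral decomposition Ks = U diag(s) U^T, eigenvalues clipped at 0."""
    s, U = np.linalg.eigh(_as_matrix(Ks))
    return np.clip(s, 0.0, None), U


def _grid_profile(s, yt, Xt, deltas, reml):
    """Profile log-likelihood, GLS beta and profile sigma_s2 at each delta.

    All arguments are in the rotated (eigen) basis; vectorized over deltas.
    """
    n, p = Xt.shape
    d = s[None, :] + deltas[:, None]  # (D, n) eigenvalues of H
    w = 1.0 / d
    XtW = Xt[None, :, :] * w[:, :, None]
    A = np.einsum("dnp,nq->dpq", XtW, Xt)
    b = np.einsum("dnp,n->dp", XtW, yt)
    beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
    r = yt[None, :] - beta @ Xt.T
    q = np.einsum("dn,dn->d", r * w, r)
    logdetH = np.log(d).sum(axis=1)
    if reml:
        sigma2 = np.maximum(q / (n - p), _SIGMA_FLOOR)
        _, logdetA = np.linalg.slogdet(A)
        _, logdetXX = np.linalg.slogdet(Xt.T @ Xt)
        ll = -0.5 * (
            (n - p) * np.log(2.0 * np.pi * sigma2)
            + logdetH
            + logdetA
            - logdetXX
            + q / sigma2
        )
    else:
        sigma2 = np.maximum(q / n, _SIGMA_FLOOR)
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdetH + q / sigma2)
    return ll, beta, sigma2


def fit_single_kernel(
    y: np.ndarray,
    X: np.ndarray,
    Ks,
    criterion: str = "REML",
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> SingleKernelFit:
    """Fit the single-kernel LMM by profile ML or REML over delta in [1e-5, 1e5].

    ``eig`` may carry a precomputed ``eigendecompose(Ks)`` so repeated fits
    against the same kernel skip the decomposition.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if criterion not in ("ML", "REML"):
        raise ValueError("criterion must be 'ML' or 'REML'")
    if not np.isfinite(y).all():
        raise ValueError("non-finite phenotype values")
    if y.size != n:
        raise ValueError("y and X dimension mismatch")
    if n <= p:
        raise ValueError("need n > p")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix X is rank deficient")
    reml = criterion == "REML"
    s, U = eig if eig is not None else eigendecompose(Ks)
    yt = U.T @ y
    Xt = U.T @ X

    deltas = np.logspace(np.log10(DELTA_MIN), np.log10(DELTA_MAX), _GRID_SIZE)
    ll, _, _ = _grid_profile(s, yt, Xt, deltas, reml)
    i = int(np.argmax(ll))

    def neg_ll(log10_delta: float) -> float:
        v, _, _ = _grid_profile(s, yt, Xt, np.array([10.0**log10_delta]), reml)
        return -v[0]

    lo = np.log10(deltas[max(i - 1, 0)])
    hi = np.log10(deltas[min(i + 1, _GRID_SIZE - 1)])
    boundary = i in (0, _GRID_SIZE - 1)
    if lo < hi:
        res = minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        delta = float(10.0 ** res.x)
        # keep the grid optimum if Brent's endpoint handling lost it
        if -res.fun < ll[i]:
            delta = float(deltas[i])
    else:
        delta = float(deltas[i])
    boundary = boundary and not (DELTA_MIN < delta < DELTA_MAX)

    _, beta_all, sigma_all = _grid_profile(s, yt, Xt, np.array([delta]), reml)
    beta = beta_all[0]
    sigma_s2 = float(max(sigma_all[0], _SIGMA_FLOOR))
    lF = _eval_full(s, yt, Xt, beta, sigma_s2, delta)
    lR = _eval_restricted(s, yt, Xt, sigma_s2, delta)
    return SingleKernelFit(
        beta_hat=beta,
        sigma_s2=sigma_s2,
        sigma_e2=float(delta * sigma_s2),
        delta=delta,
        lF=float(lF),
        lR=float(lR),
        boundary=boundary,
    )


def _eval_full(s, yt, Xt, beta, sigma_s2, delta):
    n = yt.size
    d = s + delta
    r = yt - Xt @ beta
    q = np.sum(r * r / d)
    return -0.5 * (n * np.log(2.0 * np.pi * sigma_s2) + np.log(d).sum() + q / sigma_s2)


def _eval_restricted(s, yt, Xt, sigma_s2, delta):
    n, p = Xt.shape
    d = s + delta
    w = 1.0 / d
    A = Xt.T @ (w[:, None] * Xt)
    beta = np.linalg.solve(A, Xt.T @ (w * yt))
    lF = _eval_full(s, yt, Xt, beta, sigma_s2, delta)
    _, logdetA = np.linalg.slogdet(A)
    _, logdetXX = np.linalg.slogdet(Xt.T @ Xt)
    return lF + 0.5 * (p * np.log(2.0 * np.pi * sigma_s2) + logdetXX - logdetA)


def full_loglik(y, X, Ks, beta, sigma_s2, delta) -> float:
    """Full log-likelihood of the single-kernel LMM at the given parameters.

    lF = 1/2 [ -n log(2 pi sigma_s2) - log|H| - (y-Xb)^T H^-1 (y-Xb) / sigma_s2 ]
    with H = Ks + delta I.
    """
    if sigma_s2 <= 0:
        raise ValueError("sigma_s2 must be positive")
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.asarray(beta, dtype=float).ravel()
    n = y.size
    H = _as_matrix(Ks) + delta * np.eye(n)
    sign, logdetH = np.linalg.slogdet(H)
    if sign <= 0:
        raise ValueError("H is singular")
    r = y - X @ beta
    q = r @ np.linalg.solve(H, r)
    return float(-0.5 * (n * np.log(2.0 * np.pi * sigma_s2) + logdetH + q / sigma_s2))


def restricted_loglik(y, X, Ks, sigma_s2, delta) -> float:
    """Restricted log-likelihood: lF at the GLS beta plus the REML correction.

    lR = lF(beta_GLS) + 1/2 [ p log(2 pi sigma_s2) + log|X^T X| - log|X^T H^-1 X| ].
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    H = _as_matrix(Ks) + delta * np.eye(n)
    Hinv_X = np.linalg.solve(H, X)
    A = X.T @ Hinv_X
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        raise ValueError("X^T H^-1 X is singular")
    beta = np.linalg.solve(A, Hinv_X.T @ y)
    lF = full_loglik(y, X, Ks, beta, sigma_s2, delta)
    _, logdetXX = np.linalg.slogdet(X.T @ X)
    return float(lF + 0.5 * (p * np.log(2.0 * np.pi * sigma_s2) + logdetXX - logdetA))
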