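"""Smoothed SNP variant frequency per chromosome: a binomial generalized
additive model on the logit scale.

At marker position x with v variant reads out of n, the model is

    v ~ Binomial(n, p(x)),   logit p(x) = eta(x) = B(x) beta

with B a cubic B-spline basis (quantile-placed interior knots) and beta
estimated by penalised iteratively re-weighted least squares (P-IRLS),
maximising the binomial log-likelihood minus a difference penalty
``lambda * beta' P beta``.  The penalty is dominated by second-order
differences; a weak first-order component is added so that the infinite-
smoothing limit is the constant overall pooled frequency rather than an
arbitrary linear trend.  The smoothing parameter is selected by minimising
AIC (deviance + 2 * effective degrees of freedom) over a log-spaced grid.

The coefficient covariance is the inverse penalised information
``(B' W B + lambda P)^-1``, which feeds the Monte-Carlo simultaneous-band
machinery downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.special import expit, logit

from .genome import ConfigurationError

ETA_CAP = 15.0  # |logit| cap when reporting frequencies, avoids p == 0 or 1
_FIRST_ORDER_RIDGE = 1e-3  # relative weight of the first-difference penalty


@dataclass
class SmoothBasis:
    """Cubic B-spline basis over one chromosome.

    Parameters
    ----------
    knots : int
        Number of interior knots (quantile-placed over marker positions).
    grid_bp : int
        Regular evaluation-grid spacing in bp; markers are always included.
    """

    knots: int = 20
    grid_bp: int = 1000
    degree: int = 3

    def __post_init__(self) -> None:
        if self.knots < 3:
            raise ConfigurationError("need at least 3 interior knots")

    def knot_vector(self, positions: np.ndarray, lo: float, hi: float) -> np.ndarray:
        qs = np.linspace(0, 1, self.knots + 2)[1:-1]
        interior = np.quantile(positions.astype(float), qs)
        interior = interior[(interior > lo) & (interior < hi)]
        interior = np.unique(interior)
        k = self.degree
        return np.concatenate([np.full(k + 1, lo), interior, np.full(k + 1, hi)])

    def design(self, t: np.ndarray, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), t[0], t[-1])
        return BSpline.design_matrix(x, t, self.degree, extrapolate=False).toarray()

    def evaluation_grid(self, positions: np.ndarray, lo: float, hi: float) -> np.ndarray:
        regular = np.arange(lo, hi + 1, self.grid_bp, dtype=float)
        return np.unique(np.concatenate([positions.astype(float), regular]))


def difference_penalty(n_coef: int) -> np.ndarray:
    """Second-order difference penalty with a weak first-order ridge.

    Null space is the constant vector only: infinitely strong smoothing
    collapses the fit to the overall pooled logit frequency.
    """
    d2 = np.diff(np.eye(n_coef), n=2, axis=0)
    d1 = np.diff(np.eye(n_coef), n=1, axis=0)
    return d2.T @ d2 + _FIRST_ORDER_RIDGE * (d1.T @ d1)


@dataclass
class FrequencyFit:
    """Fitted smooth for one (pool, chromosome) pair."""

    pool_id: str
    chrom: str
    knot_vector: np.ndarray
    coef: np.ndarray
    cov: np.ndarray  # inverse penalised information
    lam: float
    basis: SmoothBasis
    grid: np.ndarray  # bp positions (markers + regular grid)
    grid_design: np.ndarray  # B evaluated on the grid
    eta: np.ndarray  # fitted logit on the grid (uncapped)
    se: np.ndarray  # pointwise SE on the grid
    edf: float
    deviance: float
    # linearised smoother: fitted curve ~ influence @ (marker-level logit
    # signal); maps marker-level noise (e.g. finite-pool composition) onto
    # the grid for the simultaneous-inference machinery
    marker_positions: np.ndarray | None = None
    influence: np.ndarray | None = None

    @property
    def p_hat(self) -> np.ndarray:
        """Fitted variant frequency on the grid, with the logit capped."""
        return expit(np.clip(self.eta, -ETA_CAP, ETA_CAP))


def _binomial_deviance(v, n, mu):
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(v > 0, v * np.log(v / (n * mu)), 0.0)
        t2 = np.where(n - v > 0, (n - v) * np.log((n - v) / (n * (1 - mu))), 0.0)
    return 2.0 * float(np.sum(t1 + t2))


def _pirls(X, v, n, P, lam, max_iter=50, tol=1e-8):
    """Penalised IRLS for the binomial-logit spline; returns (beta, H, dev, edf)."""
    eta = logit((v + 0.5) / (n + 1.0))
    beta = None
    dev_trace = []
    for _ in range(max_iter):
        # clip the working predictor: keeps weights bounded away from zero
        # when cells saturate (v == 0 or v == n)
        eta = np.clip(eta, -ETA_CAP, ETA_CAP)
        mu = expit(eta)
        w = n * mu * (1 - mu)
        z = eta + (v - n * mu) / w
        XtW = X.T * w
        H = XtW @ X + lam * P
        beta_new = np.linalg.solve(H, XtW @ z)
        eta_new = X @ beta_new
        dev = _binomial_deviance(v, n, expit(eta_new))
        dev_trace.append(dev)
        if beta is not None and np.max(np.abs(beta_new - beta)) < tol * (
            1 + np.max(np.abs(beta))
        ):
            beta = beta_new
            eta = eta_new
            break
        # saturated cells push coefficients along the unpenalised constant
        # direction indefinitely; once the deviance is flat the fit is done
        if len(dev_trace) >= 3 and abs(dev_trace[-1] - dev_trace[-2]) < 1e-9 * (
            1.0 + dev_trace[-1]
        ):
            beta, eta = beta_new, eta_new
            break
        beta, eta = beta_new, eta_new
    else:
        if len(dev_trace) >= 2 and abs(dev_trace[-1] - dev_trace[-2]) > 1e-3 * (
            1 + abs(dev_trace[-1])
        ):
            raise RuntimeError(
                f"P-IRLS did not converge; deviance trace: {dev_trace[-5:]}"
            )
    mu = expit(np.clip(eta, -ETA_CAP, ETA_CAP))
    w = n * mu * (1 - mu)
    XtW = X.T * w
    info = XtW @ X
    H = info + lam * P
    Hinv = np.linalg.inv(H)
    edf = float(np.trace(Hinv @ info))
    dev = _binomial_deviance(v, n, mu)
    return beta, Hinv, dev, edf


DEFAULT_LAMBDA_GRID = np.logspace(-4, 8, 13)


def fit_pool_chromosome(
    positions: np.ndarray,
    variant_count: np.ndarray,
    total_count: np.ndarray,
    basis: SmoothBasis = SmoothBasis(),
    *,
    pool_id: str = "pool",
    chrom: str = "chr",
    chrom_length: float | None = None,
    lam: float | None = None,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
) -> FrequencyFit:
    """Fit the smoothed logit-frequency curve for one pool on one chromosome.

    Markers with ``total_count == 0`` carry zero information and are dropped
    from the likelihood (they remain on the evaluation grid).  ``lam=None``
    selects the smoothing parameter by AIC over ``lambda_grid``.
    """
    positions = np.asarray(positions, dtype=float)
    v = np.asarray(variant_count, dtype=float)
    n = np.asarray(total_count, dtype=float)
    informative = n > 0
    x, v_f, n_f = positions[informative], v[informative], n[informative]
    n_coef = basis.knots + basis.degree + 1
    if x.size < basis.knots + 2:
        raise ConfigurationError(
            f"{x.size} informative markers on {chrom} but {basis.knots} knots; "
            "reduce the number of knots"
        )
    lo = 1.0
    hi = float(chrom_length) if chrom_length is not None else float(positions[-1])
    t = basis.knot_vector(x, lo, hi)
    X = basis.design(t, x)
    P = difference_penalty(X.shape[1])

    if lam is None:
        best = None
        for lam_try in lambda_grid:
            beta, Hinv, dev, edf = _pirls(X, v_f, n_f, P, lam_try)
            aic = dev + 2.0 * edf
            if best is None or aic < best[0]:
                best = (aic, lam_try, beta, Hinv, dev, edf)
        _, lam, beta, Hinv, dev, edf = best
    else:
        beta, Hinv, dev, edf = _pirls(X, v_f, n_f, P, lam)

    grid = basis.evaluation_grid(positions, lo, hi)
    B = basis.design(t, grid)
    eta = B @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, Hinv, B), 0.0))
    mu = expit(np.clip(X @ beta, -ETA_CAP, ETA_CAP))
    w = n_f * mu * (1 - mu)
    influence = B @ Hinv @ (X.T * w)
    return FrequencyFit(
        pool_id=pool_id,
        chrom=chrom,
        knot_vector=t,
        coef=beta,
        cov=Hinv,
        lam=float(lam),
        basis=basis,
        grid=grid,
        grid_design=B,
        eta=eta,
        se=se,
        edf=edf,
        deviance=dev,
        marker_positions=x,
        influence=influence,
    )


def predict(fit: FrequencyFit, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the fitted logit curve and its pointwise SE at new positions."""
    positions = np.asarray(positions, dtype=float)
    t = fit.knot_vector
    if np.any(positions < t[0]) or np.any(positions > t[-1]):
        raise ConfigurationError("positions outside the fitted chromosome")
    B = fit.basis.design(t, positions)
    eta = B @ fit.coef
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, fit.cov, B), 0.0))
    return eta, se


def fit_profile_frame(fit: FrequencyFit):
    """Fitted profile as a DataFrame (chrom, pos, eta, se, p_hat)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": fit.chrom,
            "pos": fit.grid.astype(np.int64),
            "eta": fit.eta,
            "se": fit.se,
            "p_hat": fit.p_hat,
        }
    )
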