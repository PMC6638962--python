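"""Null-model fitting for genome-wide environment interaction scans.

The null model regresses the phenotype on covariates and environment main
effects only -- no genetic terms.  Everything downstream (per-locus score
statistics, the scan-free l_approx diagnostic) consumes the *working
quantities* of this fit: the weights ``omega``, the working residuals ``u``,
the complement-of-leverage diagonal ``(Q_Ztilde)_ii`` and the projected
residuals ``(Q_Ztilde u)_i``.

Two families are supported:

* ``gaussian`` (identity link): ordinary least squares; ``omega = 1``,
  ``u = y``.
* ``binomial`` (logit link): logistic maximum likelihood via iteratively
  reweighted least squares; ``omega_i = mu_i (1 - mu_i)``,
  ``u_i = (y_i - mu_i) / omega_i``.

Projections onto the weighted null design are computed from a thin QR
factorization of ``Omega^{1/2} Z`` -- the cross-product matrix ``Z'Z`` is
never formed explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger("gweistat")

#: IRLS convergence tolerance on the max absolute score component.
IRLS_TOL = 1e-10
#: IRLS iteration cap.
IRLS_MAXIT = 100
#: Fitted probabilities closer than this to 0/1 trigger a separation error.
SEPARATION_EPS = 1e-10
#: Relative singular-value cutoff declaring the null design rank deficient.
RANK_TOL = 1e-10


class RankDeficientError(ValueError):
    """Null design matrix is numerically rank deficient."""


class ConvergenceError(RuntimeError):
    """Logistic null fit failed to converge or is quasi-separated."""


@dataclass(frozen=True)
class ModelFamily:
    """Distribution family of the phenotype; the link is implied."""

    family: Literal["gaussian", "binomial"]

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def link(self) -> str:
        return "identity" if self.family == "gaussian" else "logit"


GAUSSIAN = ModelFamily("gaussian")
BINOMIAL = ModelFamily("binomial")


@dataclass
class DesignBundle:
    """Phenotype, null design and tested-multiplier design for one analysis.

    Attributes
    ----------
    y : (n,) phenotype vector; in {0, 1} for the binomial family.
    Z : (n, q) null design: intercept, covariates, environment main effects.
    X : (n, p) tested-multiplier matrix; first column all ones.  For the
        joint 2df GxE test with one environment variable, ``X = [1, E]``.
        For the marginal association test, ``X = [1]``.
    """

    y: np.ndarray
    Z: np.ndarray
    X: np.ndarray
    family: ModelFamily = GAUSSIAN
    z_names: Sequence[str] = field(default_factory=list)
    x_names: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.shape[0]
        if self.Z.shape[0] != n or self.X.shape[0] != n:
            raise ValueError("y, Z and X must share the sample dimension")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first column of X must be all ones")
        if n < self.Z.shape[1] + 2:
            raise ValueError("need n >= q + 2 samples")
        if self.family.family == "binomial":
            vals = np.unique(self.y)
            if not np.all(np.isin(vals, [0.0, 1.0])):
                raise ValueError("binomial phenotype must be coded 0/1")
            if vals.size < 2:
                raise ValueError("binomial phenotype has a single class")
        if not self.z_names:
            self.z_names = [f"z{j}" for j in range(self.Z.shape[1])]
        if not self.x_names:
            self.x_names = [f"x{j}" for j in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class NullFit:
    """Working quantities of the fitted null model.

    ``q_diag`` holds ``(Q_Ztilde)_ii = 1 - leverage_i``.  ``u_tilde`` is the
    weighted working residual ``Omega^{1/2} u = Omega^{-1/2} (y - mu)`` (the
    Pearson residual; equal to ``u`` itself in the gaussian family), and
    ``q_u`` holds its projection ``(Q_Ztilde u_tilde)_i`` -- the residual
    from regressing ``u_tilde`` on the weighted null design
    ``Ztilde = Omega^{1/2} Z``.  On this scale the per-locus score vector
    ``Wtilde' Q u_tilde`` equals the classical score ``W'(y - mu)`` at the
    null MLE, and each component has unit variance under a correct null.
    """

    family: ModelFamily
    gamma_hat: np.ndarray
    omega: np.ndarray
    u: np.ndarray
    u_tilde: np.ndarray
    q_diag: np.ndarray
    q_u: np.ndarray
    qmat: np.ndarray  # thin-QR orthonormal basis of Omega^{1/2} Z
    rss_null: float | None
    converged: bool
    n: int
    q: int

    def project_complement(self, v: np.ndarray) -> np.ndarray:
        """Apply ``Q_Ztilde = I - Q Q^T`` to columns of ``v``."""
        v = np.asarray(v, dtype=float)
        return v - self.qmat @ (self.qmat.T @ v)


def build_design(Z: np.ndarray, add_intercept: bool = True) -> np.ndarray:
    """Prepend an intercept column unless one (any constant column) exists."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.ndim == 1:
        Z = Z[:, None]
    has_const = any(np.ptp(Z[:, j]) == 0 and Z[0, j] != 0 for j in range(Z.shape[1]))
    if add_intercept and not has_const:
        Z = np.column_stack([np.ones(Z.shape[0]), Z])
    return Z


def _check_rank(Z: np.ndarray, names: Sequence[str]) -> None:
    sv = np.linalg.svd(Z, compute_uv=False)
    if sv[-1] <= RANK_TOL * sv[0]:
        # identify columns whose removal restores conditioning
        bad = []
        for j in range(Z.shape[1]):
            sub = np.delete(Z, j, axis=1)
            s = np.linalg.svd(sub, compute_uv=False)
            if s[-1] > RANK_TOL * s[0]:
                bad.append(names[j] if j < len(names) else f"col{j}")
        raise RankDeficientError(
            "null design Z is rank deficient; collinear columns: "
            + (", ".join(bad) if bad else "(unidentified)")
        )


def fit_null(bundle: DesignBundle) -> NullFit:
    """Fit the null model and return its working quantities.

    Gaussian: least squares, ``omega = 1``, ``u = y``; ``rss_null`` is the
    squared norm of the residual ``||Q_Z y||^2``.  Binomial: logistic MLE by
    IRLS started at ``gamma = 0``, converged when the largest score component
    falls below ``IRLS_TOL``.
    """
    y, Z = bundle.y, bundle.Z
    n, q = bundle.n, bundle.q
    _check_rank(Z, bundle.z_names)

    if bundle.family.family == "gaussian":
        gamma, *_ = np.linalg.lstsq(Z, y, rcond=None)
        omega = np.ones(n)
        u = y.copy()
        converged = True
    else:
        gamma = np.zeros(q)
        converged = False
        for _ in range(IRLS_MAXIT):
            eta = Z @ gamma
            mu = 1.0 / (1.0 + np.exp(-eta))
            score = Z.T @ (y - mu)
            if np.max(np.abs(score)) < IRLS_TOL:
                converged = True
                break
            w = np.maximum(mu * (1.0 - mu), 1e-300)  # floor avoids 0/0 drift
            # Newton step via weighted least squares on the working response
            sw = np.sqrt(w)
            Zw = Z * sw[:, None]
            rhs = sw * (eta + (y - mu) / w)
            gamma, *_ = np.linalg.lstsq(Zw, rhs, rcond=None)
        eta = Z @ gamma
        mu = 1.0 / (1.0 + np.exp(-eta))
        if not converged:
            raise ConvergenceError(
                "logistic null fit did not converge in "
                f"{IRLS_MAXIT} IRLS iterations; review covariates"
            )
        if np.any(mu < SEPARATION_EPS) or np.any(mu > 1.0 - SEPARATION_EPS):
            raise ConvergenceError(
                "fitted probabilities at 0/1 boundary (quasi-separation); "
                "review covariates"
            )
        omega = mu * (1.0 - mu)
        u = (y - mu) / omega

    sw = np.sqrt(omega)
    Qmat, _ = np.linalg.qr(Z * sw[:, None])
    lev = np.einsum("ij,ij->i", Qmat, Qmat)
    q_diag = 1.0 - lev
    u_tilde = sw * u
    q_u = u_tilde - Qmat @ (Qmat.T @ u_tilde)
    rss = float(q_u @ q_u) if bundle.family.family == "gaussian" else None
    return NullFit(
        family=bundle.family,
        gamma_hat=np.asarray(gamma, dtype=float),
        omega=omega,
        u=u,
        u_tilde=u_tilde,
        q_diag=q_diag,
        q_u=q_u,
        qmat=Qmat,
        rss_null=rss,
        converged=converged,
        n=n,
        q=q,
    )


def dichotomize_at_mean(y: np.ndarray) -> np.ndarray:
    """Binary indicator of the phenotype exceeding its mean.

    Turns a quantitative phenotype into a case/control phenotype for the
    logistic-family analyses.
    """
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype cannot be dichotomized")
    b = (y > y.mean()).astype(float)
    if b.min() == b.max():  # pathological: all mass on one side of the mean
        raise ValueError("dichotomization produced a single class")
    return b


def drop_missing(
    y: np.ndarray, Z: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Complete-case deletion across phenotype, covariates and multipliers."""
    y = np.asarray(y, dtype=float).ravel()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    keep = np.isfinite(y) & np.isfinite(Z).all(axis=1) & np.isfinite(X).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d samples with missing phenotype/covariates", n_dropped)
    return y[keep], Z[keep], X[keep], n_dropped
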