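"""Per-locus score statistics and genome-wide scan summaries.

For locus ``l`` with dosage vector ``g_l`` and multiplier design ``X`` (first
column all ones), the tested block is ``W_l = G_l X`` with
``G_l = diag(g_l)``.  The joint GxE score statistic is the quadratic form

    t_l = u' {Q(G_l Xt)} {(G_l Xt)' Q (G_l Xt)}^{-1} {Q(G_l Xt)}' u,

where ``Xt = Omega^{1/2} X`` and ``Q`` projects onto the orthogonal
complement of the weighted null design.  Under a correctly specified null,
``t_l`` is asymptotically chi-squared with ``p = ncol(X)`` degrees of
freedom.  With ``X`` a single all-ones column this reduces to the marginal
association statistic.

For the gaussian family the raw quadratic form is rescaled to

    T_l = t_l / {(||Q_Z y||^2 - t_l) / n},

which restores the chi-squared scale of the F/t statistic.  The genome-wide
summary is ``l_mean = mean(statistic) / p`` (``T`` for gaussian, raw ``t``
for binomial), which is close to one when the null model is well specified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .null_model import DesignBundle, NullFit

#: Condition-number threshold above which a locus's p x p information
#: block is declared numerically singular and the locus skipped.
SINGULAR_COND = 1e12


@dataclass
class TestedDesign:
    """Tested block for one locus: dosage ``g`` times multiplier matrix ``X``."""

    __test__ = False  # name starts with "Test" but this is not a test case

    g: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.g.shape[0] != self.X.shape[0]:
            raise ValueError("g and X must share the sample dimension")

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class ScanResult:
    """Genome-wide scan output: per-locus statistics and scaled means."""

    t: np.ndarray
    T: np.ndarray | None
    p_df: int
    t_mean: float
    l_mean: float
    lambda_median: float
    lambda_mean: float
    n_skipped: int

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.t)


def _stat_from_projected(V: np.ndarray, u: np.ndarray) -> float:
    """Quadratic form c' (V'V)^{-1} c with c = V'u; NaN when V'V is singular."""
    S = V.T @ V
    c = V.T @ u
    if S.shape == (1, 1):
        if S[0, 0] <= 0.0:
            return np.nan
        return float(c[0] ** 2 / S[0, 0])
    # condition check on the p x p information block
    ev = np.linalg.eigvalsh(S)
    if ev[0] <= 0.0 or ev[-1] / ev[0] > SINGULAR_COND:
        return np.nan
    sol = np.linalg.solve(S, c)
    return float(c @ sol)


def joint_gxe_stat(design: TestedDesign, fit: NullFit) -> float:
    """Joint GxE score statistic for one locus; NaN flags a skipped locus.

    Monomorphic dosages or any locus whose projected tested block is rank
    deficient return NaN rather than raising, so genome scans proceed.
    """
    if design.g.shape[0] != fit.n:
        raise ValueError("design and fit disagree on sample count")
    gw = design.g * np.sqrt(fit.omega)
    W = gw[:, None] * design.X  # G_l Xtilde
    V = fit.project_complement(W)
    return _stat_from_projected(V, fit.u_tilde)


def marginal_stat(g: np.ndarray, fit: NullFit) -> float:
    """Marginal (1df) association score statistic; NaN flags a skipped locus."""
    g = np.asarray(g, dtype=float).ravel()
    gt = g * np.sqrt(fit.omega)
    v = fit.project_complement(gt)
    denom = float(v @ v)
    if denom <= 0.0 or denom <= 1e-12 * float(gt @ gt):
        return np.nan  # g lies (numerically) in the span of Z
    return float((v @ fit.u_tilde) ** 2 / denom)


def gaussian_rescale(t: np.ndarray | float, rss_null: float, n: int):
    """Rescale raw gaussian quadratic forms onto the chi-squared scale."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr[np.isfinite(t_arr)] >= rss_null):
        raise ValueError("statistic exceeds the null residual sum of squares")
    out = t_arr / ((rss_null - t_arr) / n)
    return float(out) if np.isscalar(t) else out


def _chi2_median(df: int) -> float:
    from scipy.stats import chi2

    return float(chi2.median(df))


def genomic_lambdas(stats: np.ndarray, df: int) -> tuple[float, float]:
    """Genomic-control inflation factors (median-based, mean-based)."""
    s = stats[np.isfinite(stats)]
    lam_med = float(np.median(s) / _chi2_median(df))
    lam_mean = float(np.mean(s) / df)
    return lam_med, lam_mean


def genome_scan(
    G: np.ndarray,
    bundle: DesignBundle,
    fit: NullFit,
    mode: Literal["joint", "marginal"] = "joint",
    engine: Literal["vectorized", "loop"] = "vectorized",
) -> ScanResult:
    """Score-test every locus of ``G`` (n x L) against the shared null fit.

    Per-locus missing dosages are mean-imputed within the locus so the single
    null fit remains valid for every test.  Degenerate loci (monomorphic, or
    numerically singular information block) are skipped and excluded from
    the means.  The vectorized and locus-by-locus engines agree to 1e-10.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if G.shape[0] != fit.n:
        raise ValueError("genotype matrix and null fit disagree on n")
    L = G.shape[1]
    if np.isnan(G).any():
        G = G.copy()
        for j in range(L):
            col = G[:, j]
            m = np.isnan(col)
            if m.any():
                col[m] = np.nanmean(col) if not m.all() else 0.0
    X = np.ones((fit.n, 1)) if mode == "marginal" else bundle.X
    p = X.shape[1]

    if engine == "loop":
        t = np.array(
            [
                joint_gxe_stat(TestedDesign(G[:, j], X), fit)
                if mode == "joint"
                else marginal_stat(G[:, j], fit)
                for j in range(L)
            ]
        )
    else:
        t = _scan_vectorized(G, X, fit)

    valid = np.isfinite(t)
    n_skipped = int((~valid).sum())
    if not valid.any():
        raise ValueError("all loci skipped in genome scan")
    t_mean = float(np.mean(t[valid]))
    T = None
    if fit.family.family == "gaussian":
        T = np.where(valid, gaussian_rescale(np.where(valid, t, 0.0), fit.rss_null, fit.n), np.nan)
        stat_for_summary = T
    else:
        stat_for_summary = t
    summary_mean = float(np.mean(stat_for_summary[valid]))
    l_mean = summary_mean / p
    lam_med, lam_mean = genomic_lambdas(stat_for_summary, p)
    return ScanResult(
        t=t,
        T=T,
        p_df=p,
        t_mean=t_mean,
        l_mean=l_mean,
        lambda_median=lam_med,
        lambda_mean=lam_mean,
        n_skipped=n_skipped,
    )


def _scan_vectorized(G: np.ndarray, X: np.ndarray, fit: NullFit) -> np.ndarray:
    """All-loci quadratic forms via batched projection and p x p solves."""
    n, L = G.shape
    p = X.shape[1]
    sw = np.sqrt(fit.omega)
    # projected columns of G_l Xtilde for every locus: (p, n, L)
    V = np.empty((p, n, L))
    for k in range(p):
        Wk = (sw * X[:, k])[:, None] * G
        V[k] = fit.project_complement(Wk)
    S = np.einsum("anl,bnl->lab", V, V)  # (L, p, p)
    c = np.einsum("anl,n->la", V, fit.u_tilde)  # (L, p)
    ev = np.linalg.eigvalsh(S)
    bad = (ev[:, 0] <= 0.0) | (ev[:, -1] > SINGULAR_COND * np.maximum(ev[:, 0], 0.0))
    S_safe = S.copy()
    S_safe[bad] = np.eye(p)
    sol = np.linalg.solve(S_safe, c[:, :, None])[:, :, 0]
    t = np.einsum("la,la->l", c, sol)
    t[bad] = np.nan
    return t
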