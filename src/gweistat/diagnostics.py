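"""Companion diagnostics: genomic control, Cook's distance, QQ data.

Genomic control estimates the inflation factor lambda from genome-wide
chi-squared statistics -- by the median (robust to a handful of true
signals) or by the mean -- and rescales the statistics so the adjusted
median (or mean) matches the theoretical null.  Cook's distance flags
influential samples in the gaussian null fit; the flagging rule is
``D_i > mean(D) + k * sd(D)`` with ``k = 4`` by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

#: Default multiplier k in the Cook's-distance flag mean(D) + k * sd(D).
COOKS_SD_MULTIPLIER = 4.0


@dataclass
class GCResult:
    lambda_median: float
    lambda_mean: float
    df: int
    adjusted: np.ndarray  # statistics divided by the median-based lambda


def genomic_lambda(t: np.ndarray, df: int, method: str = "median") -> float:
    """Genomic-control inflation factor from genome-wide statistics."""
    t = np.asarray(t, dtype=float)
    t = t[np.isfinite(t)]
    if t.size == 0:
        raise ValueError("no finite statistics")
    if method == "median":
        return float(np.median(t) / chi2.median(df))
    if method == "mean":
        return float(np.mean(t) / df)
    raise ValueError(f"unknown method {method!r}")


def gc_adjust(t: np.ndarray, df: int) -> GCResult:
    """Estimate lambda both ways and divide by the median-based estimate."""
    lam_med = genomic_lambda(t, df, "median")
    lam_mean = genomic_lambda(t, df, "mean")
    return GCResult(
        lambda_median=lam_med,
        lambda_mean=lam_mean,
        df=df,
        adjusted=np.asarray(t, dtype=float) / lam_med,
    )


def cooks_flags(
    y: np.ndarray,
    Z: np.ndarray,
    sd_multiplier: float = COOKS_SD_MULTIPLIER,
) -> tuple[np.ndarray, np.ndarray]:
    """Cook's distances of the least-squares fit of y on Z, plus flags.

    Returns ``(D, flags)`` where ``flags[i]`` is True when
    ``D[i] > mean(D) + sd_multiplier * sd(D)``.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import OLSInfluence

    y = np.asarray(y, dtype=float).ravel()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n, q = Z.shape
    if n <= q:
        raise ValueError("need more samples than null-design columns")
    res = sm.OLS(y, Z).fit()
    D = OLSInfluence(res).cooks_distance[0]
    if not np.all(np.isfinite(D)):
        raise ValueError("Cook's distance undefined (saturated fit)")
    thresh = D.mean() + sd_multiplier * D.std(ddof=1)
    return D, D > thresh


def qq_points(t: np.ndarray, df: int) -> np.ndarray:
    """Expected-vs-observed chi-squared quantiles for a QQ plot.

    Returns an array with columns (expected statistic, observed statistic,
    expected -log10 p, observed -log10 p); expected quantiles are taken at
    probabilities ``(i - 0.5) / L``.
    """
    t = np.asarray(t, dtype=float)
    t = np.sort(t[np.isfinite(t)])
    L = t.size
    probs = (np.arange(1, L + 1) - 0.5) / L
    expected = chi2.ppf(probs, df)
    exp_logp = -np.log10(chi2.sf(expected, df))
    obs_logp = -np.log10(np.maximum(chi2.sf(t, df), 1e-300))
    return np.column_stack([expected, t, exp_logp, obs_logp])
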