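"""Group-level statistics: MANOVA on PCA scores and demographic tests.

``manova_pca`` answers the control-consistency question (are PCOS and
healthy plasma spectra distinguishable?) with a one-way MANOVA on
PCA-reduced spectra, using Wilks' Λ converted to an F statistic through
Rao's approximation (Pillai's trace is available as an alternative).
``t_test_from_summary`` and ``pearson_chi2`` reproduce the demographic
comparisons computable from printed cohort tables: a two-sample t-test from
summary statistics (Welch by default) and Pearson's χ² of independence
without continuity correction, with optional dropping of empty categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classify_eval import fit_pca

__all__ = [
    "GroupTestResult",
    "manova_pca",
    "wilks_lambda_f",
    "t_test_from_summary",
    "pearson_chi2",
]


@dataclass
class GroupTestResult:
    statistic: float
    kind: str  # "Wilks-lambda-F" | "Pillai-F" | "t" | "chi-squared"
    df: tuple[float, ...]
    p_value: float
    extra: dict | None = None


def wilks_lambda_f(groups: list[np.ndarray]) -> GroupTestResult:
    """One-way MANOVA via Wilks' Λ with Rao's F approximation.

    ``groups`` is a list of (n_i × p) score matrices. Λ = det(W)/det(W+B)
    with W the pooled within-group and B the between-group SSCP matrices.
    """
    g = len(groups)
    p = groups[0].shape[1]
    N = sum(x.shape[0] for x in groups)
    grand = np.vstack(groups).mean(axis=0)

    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for x in groups:
        c = x - x.mean(axis=0)
        W += c.T @ c
        d = (x.mean(axis=0) - grand)[:, None]
        B += x.shape[0] * (d @ d.T)

    T = W + B
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        raise ValueError(
            "singular SSCP matrix: too many retained components for the "
            "available within-group degrees of freedom"
        )
    lam = float(np.exp(logdet_w - logdet_t))

    dfh = g - 1
    denom = p**2 + dfh**2 - 5
    t = np.sqrt((p**2 * dfh**2 - 4) / denom) if denom > 0 and p**2 * dfh**2 > 4 else 1.0
    df1 = p * dfh
    m = N - 1 - (p + g) / 2
    df2 = m * t - df1 / 2 + 1
    lam_t = lam ** (1 / t)
    F = (1 - lam_t) / lam_t * df2 / df1
    pval = float(stats.f.sf(F, df1, df2))
    return GroupTestResult(
        statistic=float(F),
        kind="Wilks-lambda-F",
        df=(float(df1), float(df2)),
        p_value=pval,
        extra={"wilks_lambda": lam},
    )


def _pillai_f(groups: list[np.ndarray]) -> GroupTestResult:
    g = len(groups)
    p = groups[0].shape[1]
    N = sum(x.shape[0] for x in groups)
    grand = np.vstack(groups).mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for x in groups:
        c = x - x.mean(axis=0)
        W += c.T @ c
        d = (x.mean(axis=0) - grand)[:, None]
        B += x.shape[0] * (d @ d.T)
    V = float(np.trace(B @ np.linalg.inv(B + W)))
    s = min(p, g - 1)
    m = (abs(p - g + 1) - 1) / 2
    n = (N - g - p - 1) / 2
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n + s + 1)
    F = (2 * n + s + 1) / (2 * m + s + 1) * V / (s - V)
    return GroupTestResult(
        statistic=float(F),
        kind="Pillai-F",
        df=(float(df1), float(df2)),
        p_value=float(stats.f.sf(F, df1, df2)),
        extra={"pillai_trace": V},
    )


def manova_pca(
    Xa: np.ndarray,
    Xb: np.ndarray,
    variance_target: float = 0.95,
    statistic: str = "wilks",
) -> GroupTestResult:
    """MANOVA on pooled-PCA scores of two spectra groups.

    PCA is fitted on the pooled rows retaining ``variance_target`` cumulative
    variance; the retained scores enter a one-way MANOVA. Raises when the
    retained dimensionality exhausts the pooled within-group degrees of
    freedom.
    """
    Xa = np.asarray(Xa, dtype=float)
    Xb = np.asarray(Xb, dtype=float)
    if Xa.shape[0] == 0 or Xb.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    N = Xa.shape[0] + Xb.shape[0]

    pca = fit_pca(np.vstack([Xa, Xb]), variance_target)
    k = pca.n_components
    if k >= N - 2:
        raise ValueError(
            f"{k} retained components >= pooled within-group df {N - 2}; "
            "reduce variance_target"
        )
    Sa, Sb = pca.transform(Xa), pca.transform(Xb)
    if statistic == "wilks":
        res = wilks_lambda_f([Sa, Sb])
    elif statistic == "pillai":
        res = _pillai_f([Sa, Sb])
    else:
        raise ValueError("statistic must be 'wilks' or 'pillai'")
    res.extra = {**(res.extra or {}), "n_components": k}
    return res


def t_test_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "welch",
) -> GroupTestResult:
    """Two-sided two-sample t-test from summary statistics.

    ``variant="welch"`` uses Welch–Satterthwaite degrees of freedom;
    ``"pooled"`` assumes equal variances. Degenerate zero-SD inputs follow
    the convention p = 1 for equal means, p = 0 otherwise.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be >= 0")
    if sd1 == 0 and sd2 == 0:
        equal = mean1 == mean2
        return GroupTestResult(
            statistic=0.0 if equal else np.inf,
            kind="t",
            df=(float(n1 + n2 - 2),),
            p_value=1.0 if equal else 0.0,
        )
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = n1 + n2 - 2.0
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return GroupTestResult(statistic=float(t), kind="t", df=(float(df),),
                           p_value=float(p))


def pearson_chi2(table, drop_empty: bool = True) -> GroupTestResult:
    """Pearson χ² test of independence, no continuity correction.

    With ``drop_empty`` all-zero rows/columns (empty categories) are removed
    before computing df = (r−1)(c−1). Raises on zero marginals or a table
    smaller than 2×2 after dropping.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if drop_empty:
        t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns after dropping")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return GroupTestResult(statistic=float(chi2), kind="chi-squared",
                           df=(float(df),), p_value=float(p))
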