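"""Statistical primitives shared by the stratified analyses.

Thin, contract-enforcing wrappers over scipy/statsmodels: two-sample
Kolmogorov-Smirnov, Benjamini-Hochberg step-up adjustment, Pearson
correlation, quadratic trend fits, and Pearson chi-square on contingency
tables (no continuity correction, matching the direct formula).
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def ks_two_sample(a, b, exact: bool = False) -> tuple[float, float]:
    """Two-sided two-sample KS test: D = sup |ECDF_a - ECDF_b| and p-value.

    The asymptotic p-value is the default; `exact=True` switches to the
    exact small-sample computation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = sps.ks_2samp(a, b, method="exact" if exact else "asymp")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = multipletests(p, method="fdr_bh")[1]
    return [float(x) for x in adjusted]


def pearson_corr(x, y) -> tuple[float, float]:
    """Product-moment correlation with its t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def quadratic_trend(x, y) -> tuple[tuple[float, float, float], float]:
    """Least-squares fit y = a + b*x + c*x**2; returns ((a, b, c), p_c).

    p_c is the two-sided t-test p-value on the curvature term c. A rank-
    deficient design (e.g. all x equal) is rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need >= 4 points for a quadratic fit")
    design = sm.add_constant(np.column_stack([x, x**2]))
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("degenerate design: x values do not support a quadratic")
    fit = sm.OLS(y, design).fit()
    a, b, c = fit.params
    scale = max(1.0, float(np.abs(y).max()))
    if fit.ssr <= 1e-24 * scale**2 * y.size:  # exact fit: the t-test degenerates
        p_c = 1.0 if abs(c) <= 1e-10 * scale else 0.0
    else:
        p_c = float(fit.pvalues[2])
    return (float(a), float(b), float(c)), p_c


def chi2_contingency(table) -> tuple[float, float, int]:
    """Pearson chi-square on an r x c count table: (statistic, p, dof).

    No Yates continuity correction, so the statistic equals the direct
    sum over cells of (observed - expected)^2 / expected.
    """
    table = np.asarray(table, dtype=float)
    if table.min() < 0:
        raise ValueError("counts must be non-negative")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)
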