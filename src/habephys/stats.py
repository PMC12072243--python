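"""Group-level statistics: two-sample KS, chi-squared with adjusted
standardized (Haberman) residuals, correlations and paired/group tests.

All tests are two-sided.  The adjusted-residual formula is authored
here; KS, correlations, t/Wilcoxon/ANOVA and the Holm-Sidak adjustment
delegate to scipy/statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests


@dataclass
class ResidualReport:
    expected: np.ndarray        # E_ij = R_i C_j / N
    residuals: np.ndarray       # adjusted standardized residuals r_ij
    p_values: np.ndarray        # per-cell two-sided normal p
    marks: np.ndarray           # "up" / "down" / "" at alpha
    alpha: float


def _validate_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need a 2-D table with >= 2 rows and columns")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    return t


def chi_squared_with_residuals(table, alpha: float = 0.05,
                               correction: bool = False):
    """Pearson chi-squared plus per-cell adjusted standardized residuals.

    r_ij = (O_ij - E_ij) / sqrt(E_ij (1 - R_i/N)(1 - C_j/N)), with a
    two-sided normal p per cell and increase/decrease marks at ``alpha``.
    """
    O = _validate_table(table)
    N = O.sum()
    R = O.sum(axis=1, keepdims=True)
    C = O.sum(axis=0, keepdims=True)
    E = R @ C / N
    if (E <= 0).any():
        raise ValueError("zero expected count; merge sparse categories")
    chi2, p, dof, _ = sstats.chi2_contingency(O, correction=correction)
    denom = np.sqrt(E * (1.0 - R / N) * (1.0 - C / N))
    r = (O - E) / denom
    cell_p = 2.0 * sstats.norm.sf(np.abs(r))
    marks = np.full(O.shape, "", dtype=object)
    marks[(cell_p < alpha) & (r > 0)] = "up"
    marks[(cell_p < alpha) & (r < 0)] = "down"
    report = ResidualReport(expected=E, residuals=r, p_values=cell_p,
                            marks=marks, alpha=alpha)
    return float(chi2), int(dof), float(p), report


def ks_two_sample(x, y):
    """Two-sample Kolmogorov-Smirnov (D, p); exact p for small samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    method = "exact" if x.size * y.size <= 10_000 else "asymp"
    res = sstats.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def correlations(x, y, method: str = "pearson"):
    """Pearson r or Spearman rho (midrank ties) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    if method == "pearson":
        res = sstats.pearsonr(x, y)
    elif method == "spearman":
        res = sstats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def paired_t(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("paired test needs equal-length samples, n >= 2")
    d = x - y
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    res = sstats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("paired test needs equal-length samples, n >= 2")
    if np.allclose(x - y, 0.0):
        return 0.0, 1.0
    res = sstats.wilcoxon(x, y)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(x, y):
    res = sstats.mannwhitneyu(np.asarray(x, float), np.asarray(y, float),
                              alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def one_way_anova(*groups):
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    res = sstats.f_oneway(*[np.asarray(g, float) for g in groups])
    return float(res.statistic), float(res.pvalue)


def holm_sidak(p_values, alpha: float = 0.05):
    """Holm-Sidak step-down adjustment; returns (reject, adjusted_p)."""
    p = np.asarray(p_values, dtype=float)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm-sidak")
    return reject, p_adj
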