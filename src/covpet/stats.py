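"""The study-style statistical battery for group comparisons and correlations.

Parametric tests are used when their assumptions hold, nonparametric
otherwise: the "auto" mode formalizes the usual reporting convention
("normal distribution with equal variances") as Shapiro-Wilk normality on
every group plus Levene's homoscedasticity test, both at alpha = 0.05.
Forced modes are available to reproduce a specific published choice.

Included tests:

* two-group: pooled-variance two-sample t or Mann-Whitney U (exact for
  combined n <= 20 without ties, tie-corrected normal approximation
  otherwise),
* paired: two-sided paired t,
* three-group: one-way ANOVA with Bonferroni pairwise t post hoc, or
  Kruskal-Wallis with Dunn's rank post hoc (Bonferroni-adjusted),
* 2x2 Pearson chi-square *without* continuity correction,
* Pearson / Spearman correlation,
* Steiger's Z for comparing two dependent correlations sharing one
  variable (r(x,y) vs r(x,z) given r(y,z)).

Most tests delegate to scipy; Dunn's post hoc and Steiger's Z are
implemented here because no installed package provides them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_GATE = 0.05


@dataclass
class TestResult:
    """One hypothesis test outcome."""

    name: str
    statistic: float
    p: float
    n: tuple[int, ...]
    posthoc: pd.DataFrame | None = None
    details: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0 <= self.p <= 1:
            raise ValueError("p value outside [0, 1]")


def _as_arrays(*groups) -> list[np.ndarray]:
    return [np.asarray(g, dtype=np.float64) for g in groups]


def _gate_parametric(groups: list[np.ndarray]) -> tuple[bool, dict]:
    """True when every group passes Shapiro-Wilk and Levene passes, at 0.05."""
    detail: dict = {}
    normal = True
    for i, g in enumerate(groups):
        if np.ptp(g) == 0:
            normal = False
            detail[f"shapiro_p_{i}"] = 0.0
            continue
        p = float(sps.shapiro(g).pvalue)
        detail[f"shapiro_p_{i}"] = p
        normal &= p > ALPHA_GATE
    lev_p = float(sps.levene(*groups).pvalue) if all(np.ptp(g) > 0 for g in groups) else 0.0
    detail["levene_p"] = lev_p
    return normal and lev_p > ALPHA_GATE, detail


def compare_two(a, b, mode: str = "auto") -> TestResult:
    """Two-group comparison: pooled-variance t or Mann-Whitney U.

    ``mode``: "auto" (assumption-gated), "t", or "mw".
    """
    a, b = _as_arrays(a, b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    details: dict = {}
    if mode == "auto":
        parametric, details = _gate_parametric([a, b])
        mode = "t" if parametric else "mw"
        details["selected"] = mode
    if mode == "t":
        res = sps.ttest_ind(a, b, equal_var=True)
        return TestResult("two-sample t", float(res.statistic), float(res.pvalue),
                          (len(a), len(b)), details=details)
    if mode == "mw":
        pooled = np.concatenate([a, b])
        if np.ptp(pooled) == 0:
            return TestResult("Mann-Whitney U", len(a) * len(b) / 2.0, 1.0,
                              (len(a), len(b)), details=details,
                              flags=["degenerate: identical constant groups"])
        ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(pooled) <= 20 and not ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        details["method"] = method
        return TestResult("Mann-Whitney U", float(res.statistic), float(res.pvalue),
                          (len(a), len(b)), details=details)
    raise ValueError(f"unknown mode {mode!r}")


def paired_compare(pre, post) -> TestResult:
    """Two-sided paired t test on pre - post differences."""
    pre, post = _as_arrays(pre, post)
    if len(pre) != len(post):
        raise ValueError("paired samples must have equal length")
    if len(pre) < 3:
        raise ValueError("need at least 3 pairs")
    diff = pre - post
    if np.ptp(diff) == 0:
        stat = 0.0 if diff[0] == 0 else np.inf * np.sign(diff[0])
        return TestResult("paired t", float(stat), 1.0 if diff[0] == 0 else 0.0,
                          (len(pre),), flags=["degenerate: zero-variance differences"])
    res = sps.ttest_rel(pre, post)
    return TestResult("paired t", float(res.statistic), float(res.pvalue),
                      (len(pre),), details={"df": int(len(pre) - 1)})


def _dunn_posthoc(groups: list[np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests, Bonferroni-adjusted."""
    all_vals = np.concatenate(groups)
    ranks = sps.rankdata(all_vals)
    n_total = len(all_vals)
    # tie correction term for the rank variance
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    mean_ranks, sizes, offset = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[offset:offset + len(g)].mean())
        sizes.append(len(g))
        offset += len(g)
    n_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie_term)
                         * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"pair": f"{i}-{j}", "z": z, "p_raw": p,
                         "p_adj": min(1.0, p * n_pairs)})
    return pd.DataFrame(rows)


def _bonferroni_t_posthoc(groups: list[np.ndarray]) -> pd.DataFrame:
    n_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            res = sps.ttest_ind(groups[i], groups[j], equal_var=True)
            rows.append({"pair": f"{i}-{j}", "t": float(res.statistic),
                         "p_raw": float(res.pvalue),
                         "p_adj": min(1.0, float(res.pvalue) * n_pairs)})
    return pd.DataFrame(rows)


def compare_three(groups, mode: str = "auto") -> TestResult:
    """Three-group comparison with post hoc pairwise tests.

    ``mode``: "auto", "anova" (+ Bonferroni pairwise t), or
    "kw" (Kruskal-Wallis + Dunn's test, Bonferroni-adjusted).
    """
    groups = _as_arrays(*groups)
    if len(groups) != 3:
        raise ValueError("expected exactly 3 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    details: dict = {}
    if mode == "auto":
        parametric, details = _gate_parametric(groups)
        mode = "anova" if parametric else "kw"
        details["selected"] = mode
    sizes = tuple(len(g) for g in groups)
    if mode == "anova":
        res = sps.f_oneway(*groups)
        return TestResult("one-way ANOVA", float(res.statistic), float(res.pvalue),
                          sizes, posthoc=_bonferroni_t_posthoc(groups), details=details)
    if mode == "kw":
        if np.ptp(np.concatenate(groups)) == 0:
            return TestResult("Kruskal-Wallis", 0.0, 1.0, sizes,
                              flags=["degenerate: identical constant groups"])
        res = sps.kruskal(*groups)
        return TestResult("Kruskal-Wallis", float(res.statistic), float(res.pvalue),
                          sizes, posthoc=_dunn_posthoc(groups), details=details)
    raise ValueError(f"unknown mode {mode!r}")


def chi_square_2x2(table) -> TestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0) or not np.all(table == np.floor(table)):
        raise ValueError("table entries must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all row and column margins must be positive")
    res = sps.chi2_contingency(table, correction=False)
    return TestResult("Pearson chi-square", float(res.statistic), float(res.pvalue),
                      (int(table[0].sum()), int(table[1].sum())),
                      details={"df": int(res.dof)})


def correlate(x, y, method: str = "pearson") -> TestResult:
    """Pearson r or Spearman rho (midrank ties), two-sided p."""
    x, y = _as_arrays(x, y)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if method == "pearson":
        res = sps.pearsonr(x, y)
        return TestResult("Pearson r", float(res.statistic), float(res.pvalue), (len(x),))
    if method == "spearman":
        res = sps.spearmanr(x, y)
        return TestResult("Spearman rho", float(res.statistic), float(res.pvalue), (len(x),))
    raise ValueError(f"unknown method {method!r}")


def steiger_z(r_xy, r_xz, r_yz, n):
    """Steiger's Z for H0: rho(x,y) = rho(x,z) with x shared (vectorized).

    Uses the pooled-correlation variant: with Fisher transforms
    z1 = atanh(r_xy), z2 = atanh(r_xz) and rbar = (r_xy + r_xz)/2,

        psi  = r_yz (1 - 2 rbar^2) - rbar^2 (1 - 2 rbar^2 - r_yz^2) / 2
        c    = psi / (1 - rbar^2)^2
        Z    = (z1 - z2) sqrt((n - 3) / (2 - 2 c))

    Z is antisymmetric in (r_xy, r_xz) and referred to the standard normal.
    """
    r_xy, r_xz, r_yz = (np.asarray(r, dtype=np.float64) for r in (r_xy, r_xz, r_yz))
    if np.any(np.abs(r_xy) >= 1) or np.any(np.abs(r_xz) >= 1) or np.any(np.abs(r_yz) >= 1):
        raise ValueError("correlations must satisfy |r| < 1")
    n = np.asarray(n)
    if np.any(n < 4):
        raise ValueError("need n >= 4")
    z1 = np.arctanh(r_xy)
    z2 = np.arctanh(r_xz)
    rbar = (r_xy + r_xz) / 2.0
    psi = r_yz * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (1.0 - 2.0 * rbar**2 - r_yz**2)
    c = psi / (1.0 - rbar**2) ** 2
    return (z1 - z2) * np.sqrt((n - 3.0) / (2.0 - 2.0 * c))


def compare_dependent_correlations(r_xy: float, r_xz: float, r_yz: float, n: int) -> TestResult:
    """Two-sided Steiger Z test for two dependent correlations sharing x."""
    z = float(steiger_z(r_xy, r_xz, r_yz, n))
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult("Steiger Z (dependent correlations)", z, p, (int(n),),
                      details={"r_xy": r_xy, "r_xz": r_xz, "r_yz": r_yz})
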