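"""Two-group statistics: Welch's t, summary-statistic ANOVA and chi-square
(demographics-table style), Kolmogorov-Smirnov normality screening,
Benjamini-Hochberg FDR, and the edge/node/global network comparison drivers.

Sign convention: group contrasts are computed as HS - LS, so a negative t
means the LS-like group is higher (matching how temporal/frontotemporal
deficits of the HS group appear as negative t-values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class SummaryStats:
    """Mean, SD and n of a scalar trait in one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("need n >= 2")


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test (two-sided).

    Returns (t, p, df) with Welch-Satterthwaite degrees of freedom. The
    contrast is mean(a) - mean(b). Two degenerate equal samples give t = 0,
    p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0, float(a.size + b.size - 2)
        raise ValueError("zero variance in both samples with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue), float(res.df)


def anova_f_from_summary(g1: SummaryStats, g2: SummaryStats) -> tuple[float, tuple[int, int]]:
    """Two-group one-way ANOVA F from (mean, sd, n) summaries.

    Equals the squared pooled-variance t statistic; df = (1, n1 + n2 - 2).
    """
    n1, n2 = g1.n, g2.n
    if n1 + n2 <= 3:
        raise ValueError("need n1 + n2 > 3")
    ss_within = (n1 - 1) * g1.sd**2 + (n2 - 1) * g2.sd**2
    ms_within = ss_within / (n1 + n2 - 2)
    grand = (n1 * g1.mean + n2 * g2.mean) / (n1 + n2)
    ss_between = n1 * (g1.mean - grand) ** 2 + n2 * (g2.mean - grand) ** 2
    if ms_within == 0:
        raise ValueError("zero within-group variance")
    return float(ss_between / ms_within), (1, n1 + n2 - 2)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, 1 df, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or table.min() < 0:
        raise ValueError("need a 2x2 table of non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in the 2x2 table")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def ks_normality(sample) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a normal with the sample's
    own mean and SD (Lilliefors-style standardization; the tabulated p is
    therefore conservative)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("need n >= 4")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance sample has no normality test")
    z = (x - x.mean()) / sd
    stat, p = sps.kstest(z, "norm")
    return float(stat), float(p)


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q_values, significance mask)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0), np.zeros(0, dtype=bool)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, qvals < q


# ---------------------------------------------------------------------------
# Network comparison drivers
# ---------------------------------------------------------------------------

def _group_arrays(values: np.ndarray, groups: np.ndarray, hs_label, ls_label):
    hs = values[groups == hs_label]
    ls = values[groups == ls_label]
    if len(hs) < 2 or len(ls) < 2:
        raise ValueError("need >= 2 subjects per group")
    return hs, ls


def compare_edges(
    plv_stack: np.ndarray,
    groups: np.ndarray,
    labels: tuple[str, ...],
    hs_label: str = "HS-like",
    ls_label: str = "LS-like",
    q: float = 0.05,
) -> pd.DataFrame:
    """Edge-level Welch t (HS - LS) on a (subjects, ch, ch) PLV stack with BH
    FDR across all edges of the family. Returns a long-format table."""
    n_ch = plv_stack.shape[1]
    iu, ju = np.triu_indices(n_ch, k=1)
    rows = []
    for i, j in zip(iu, ju):
        vals = plv_stack[:, i, j]
        hs, ls = _group_arrays(vals, groups, hs_label, ls_label)
        if hs.var(ddof=1) == 0 and ls.var(ddof=1) == 0:
            t, p = 0.0, 1.0
        else:
            t, p, _ = welch_t(hs, ls)
        rows.append((labels[i], labels[j], t, p))
    df = pd.DataFrame(rows, columns=["channel_i", "channel_j", "t_value", "p_value"])
    df["q_value"], df["significant"] = fdr_bh(df["p_value"].to_numpy(), q=q)
    return df


def compare_node_metrics(
    metric_stack: np.ndarray,
    groups: np.ndarray,
    labels: tuple[str, ...],
    hs_label: str = "HS-like",
    ls_label: str = "LS-like",
    alpha: float = 0.05,
    strong_alpha: float = 0.001,
    fdr: bool = False,
    check_normality: bool = True,
) -> pd.DataFrame:
    """Per-channel Welch t (HS - LS) on a (subjects, ch) node-metric stack.

    Reported at the uncorrected ``alpha`` by default (an FDR mode is
    available); ``strong`` flags the stricter ``strong_alpha`` subset used
    for headline tables. Normality rejections are warned about but do not
    gate the t-tests.
    """
    rows = []
    for c in range(metric_stack.shape[1]):
        vals = metric_stack[:, c]
        hs, ls = _group_arrays(vals, groups, hs_label, ls_label)
        if hs.var(ddof=1) == 0 and ls.var(ddof=1) == 0:
            t, p = 0.0, 1.0
        else:
            t, p, _ = welch_t(hs, ls)
        if check_normality and np.concatenate([hs, ls]).std(ddof=1) > 0:
            try:
                _, pn = ks_normality(np.concatenate([hs, ls]))
                if pn < 0.05:
                    warnings.warn(
                        f"normality rejected for channel {labels[c]} (KS p={pn:.3g})",
                        stacklevel=2,
                    )
            except ValueError:
                pass
        rows.append((labels[c], t, p))
    df = pd.DataFrame(rows, columns=["channel", "t_value", "p_value"])
    if fdr:
        df["q_value"], df["significant"] = fdr_bh(df["p_value"].to_numpy(), q=alpha)
    else:
        df["significant"] = df["p_value"] < alpha
    df["strong"] = df["p_value"] < strong_alpha
    return df


def compare_global(
    ge_stack: np.ndarray,
    groups: np.ndarray,
    densities,
    hs_label: str = "HS-like",
    ls_label: str = "LS-like",
) -> pd.DataFrame:
    """Welch t (HS - LS) of global efficiency per density level on a
    (subjects, densities) stack."""
    rows = []
    for d_idx, d in enumerate(densities):
        hs, ls = _group_arrays(ge_stack[:, d_idx], groups, hs_label, ls_label)
        if hs.var(ddof=1) == 0 and ls.var(ddof=1) == 0:
            t, p = 0.0, 1.0
        else:
            t, p, _ = welch_t(hs, ls)
        rows.append((float(d), t, p, hs.mean(), hs.std(ddof=1), ls.mean(), ls.std(ddof=1)))
    return pd.DataFrame(
        rows,
        columns=["density", "t_value", "p_value", "hs_mean", "hs_sd", "ls_mean", "ls_sd"],
    )
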