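"""Group comparisons between PSD and non-PSD cohorts.

Continuous quantities are compared with a two-sample t-test when both
groups pass the Shapiro–Wilk normality check, otherwise with the
Kruskal–Wallis rank test. Demographic categorical fields use Fisher's exact
test. Edge-wise connectivity comparisons run one test per unordered channel
pair (91 for 14 channels) at an uncorrected threshold by default;
Benjamini–Hochberg FDR is available behind a flag. Metric-vs-HAMD
associations use Spearman correlation on the two groups pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_ALPHA = 0.05
NORMALITY_ALPHA = 0.05


@dataclass
class ComparisonRecord:
    """Outcome of one two-group comparison."""

    name: str
    test: str                  # t_two_tail | t_one_tail | kruskal_wallis | fisher_exact | spearman
    statistic: float
    p: float
    direction: str | None = None   # "A>B" | "B>A" for one-tailed records
    normality_p: tuple[float, float] | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {"name": self.name, "test": self.test, "statistic": self.statistic,
             "p": self.p, "direction": self.direction, "flags": ";".join(self.flags)}
        if self.normality_p is not None:
            d["normality_p_a"], d["normality_p_b"] = self.normality_p
        return d


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro–Wilk p-value; constant samples count as non-normal."""
    if np.ptp(x) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def compare_groups(
    values_a,
    values_b,
    tails: str = "two",
    alpha: float = DEFAULT_ALPHA,
    name: str = "",
    equal_var: bool = True,
) -> ComparisonRecord:
    """Two-group comparison with a normality-gated choice of test.

    Both groups normal by Shapiro–Wilk → two-sample t-test, one- or
    two-tailed per ``tails`` ("one" tests the direction of the observed
    sample means and reports it). Otherwise → Kruskal–Wallis; a one-tailed
    request under non-normality is reported two-sided with a flag.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per group")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    flags: list[str] = []
    direction = "A>B" if a.mean() > b.mean() else "B>A"
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return ComparisonRecord(name, "degenerate", 0.0, 1.0, None, (0.0, 0.0), ["constant identical samples"])
    pa, pb = _shapiro_p(a), _shapiro_p(b)
    normal = pa >= NORMALITY_ALPHA and pb >= NORMALITY_ALPHA
    if normal:
        t, p_two = sps.ttest_ind(a, b, equal_var=equal_var)
        if tails == "one":
            return ComparisonRecord(name, "t_one_tail", float(t), float(p_two) / 2, direction, (pa, pb), flags)
        return ComparisonRecord(name, "t_two_tail", float(t), float(p_two), None, (pa, pb), flags)
    try:
        h, p = sps.kruskal(a, b)
    except ValueError:  # all values identical across both groups
        return ComparisonRecord(name, "degenerate", 0.0, 1.0, None, (pa, pb), ["identical ranks"])
    if tails == "one":
        flags.append("one-tail requested under non-normality; two-sided rank test reported")
    return ComparisonRecord(name, "kruskal_wallis", float(h), float(p), None, (pa, pb), flags)


def benjamini_hochberg(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """BH step-up procedure; returns a boolean rejection mask."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    out = np.zeros(m, dtype=bool)
    if passed.any():
        out[order[: np.max(np.nonzero(passed)) + 1]] = True
    return out


def compare_connectivity_edges(
    group_a: np.ndarray,
    group_b: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    tails: str = "two",
    fdr: bool = False,
) -> pd.DataFrame:
    """Entry-by-entry comparison of Fisher-z connectivity between two groups.

    ``group_a``/``group_b`` are stacks of symmetric z matrices,
    ``(n_subjects, n, n)``. Returns one row per unordered channel pair with
    1-based channel labels, the chosen test, p-value and significance at
    ``alpha`` (uncorrected unless ``fdr=True``).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("groups must share the channel count")
    n = a.shape[1]
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            rec = compare_groups(a[:, i, j], b[:, i, j], tails=tails, alpha=alpha,
                                 name=f"edge_ch{i + 1:02d}-ch{j + 1:02d}")
            rows.append({"ch_i": i + 1, "ch_j": j + 1, **rec.to_dict()})
    df = pd.DataFrame(rows)
    if fdr:
        df["significant"] = benjamini_hochberg(df["p"].to_numpy(), alpha)
    else:
        df["significant"] = df["p"] < alpha
    return df


def compare_metric_aucs(
    table: pd.DataFrame,
    labels: pd.Series,
    alpha: float = DEFAULT_ALPHA,
    tails: str = "two",
    fdr: bool = False,
) -> pd.DataFrame:
    """Column-wise group comparison of metric-AUC features.

    ``table`` is subjects × features; ``labels`` holds the group of each row.
    NaN entries (metrics undefined for a subject) are dropped per column.
    """
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    ga, gb = sorted(groups)
    rows = []
    for col in table.columns:
        va = table.loc[labels == ga, col].dropna().to_numpy()
        vb = table.loc[labels == gb, col].dropna().to_numpy()
        if len(va) < 3 or len(vb) < 3:
            rows.append({"metric": col, "test": "skipped", "statistic": np.nan,
                         "p": np.nan, "direction": None, "flags": "too few defined values"})
            continue
        rec = compare_groups(va, vb, tails=tails, alpha=alpha, name=str(col))
        rows.append({"metric": col, **{k: v for k, v in rec.to_dict().items() if k != "name"}})
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    df["significant"] = False
    if fdr and ok.any():
        df.loc[ok, "significant"] = benjamini_hochberg(df.loc[ok, "p"].to_numpy(), alpha)
    else:
        df.loc[ok, "significant"] = df.loc[ok, "p"] < alpha
    return df


def compare_demographics(
    table: pd.DataFrame,
    group_col: str = "group",
    categorical: tuple[str, ...] = (),
    continuous: tuple[str, ...] = (),
) -> list[ComparisonRecord]:
    """Demographics: two-tailed t-test for measurements, Fisher's exact for categories.

    Categorical fields with more than two levels are collapsed to the most
    frequent level vs the rest, with a warning.
    """
    if table.empty:
        raise ValueError("empty demographics table")
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    ga, gb = groups
    records = []
    for col in categorical:
        sub = table[[group_col, col]].dropna()
        levels = sub[col].value_counts().index.tolist()
        if len(levels) < 2:
            records.append(ComparisonRecord(col, "fisher_exact", np.nan, 1.0,
                                            flags=["single category level; collapsed"]))
            continue
        if len(levels) > 2:
            warnings.warn(f"{col}: >2 levels; collapsing to {levels[0]!r} vs rest", RuntimeWarning)
            sub = sub.assign(**{col: np.where(sub[col] == levels[0], levels[0], "other")})
            levels = [levels[0], "other"]
        tab = np.array([
            [(sub[(sub[group_col] == g) & (sub[col] == lv)]).shape[0] for lv in levels[:2]]
            for g in (ga, gb)
        ])
        odds, p = sps.fisher_exact(tab, alternative="two-sided")
        records.append(ComparisonRecord(col, "fisher_exact", float(odds), float(p)))
    for col in continuous:
        va = table.loc[table[group_col] == ga, col].dropna().to_numpy(dtype=float)
        vb = table.loc[table[group_col] == gb, col].dropna().to_numpy(dtype=float)
        records.append(compare_groups(va, vb, tails="two", name=col))
    return records


def spearman_vs_hamd(metric_values, hamd_scores, name: str = "") -> ComparisonRecord:
    """Spearman correlation between a metric and HAMD, both groups pooled.

    Midrank ties; two-sided p. A constant metric yields a missing (NaN) rho.
    """
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(hamd_scores, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need >= 5 paired observations")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 5 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return ComparisonRecord(name, "spearman", float("nan"), float("nan"),
                                flags=["constant input; rho undefined"])
    rho, p = sps.spearmanr(x, y)
    return ComparisonRecord(name, "spearman", float(rho), float(p))
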