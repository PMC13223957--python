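"""Statistical layer: BH false-discovery-rate adjustment, per-size two-group
tests, paired Wilcoxon, Mann-Whitney, and a two-way mixed ANOVA contract.

The Benjamini-Hochberg adjustment is authored from the step-up definition:
sort the m raw p-values ascending, set q_(i) = min_{j >= i} min(1, m p_(j)/j),
and return the q's in input order.  The family for per-size comparisons is
the size set of one group-pair comparison (one table row), not the pooled
table.  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Star notation: * p<0.05, ** p<0.01, *** p<0.001, 'ns' otherwise."""
    if np.isnan(p):
        return "na"
    for level, stars in STAR_LEVELS:
        if p < level:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up BH-adjusted p-values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a nonempty 1-D p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = q_sorted
    return out


# ---------------------------------------------------------------------------
# two-group tests
# ---------------------------------------------------------------------------

def welch_t(a, b) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value.

    Zero-variance edge cases follow the zero-difference convention: equal
    constant groups give p = 1, distinct constant groups p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    import warnings
    with warnings.catch_warnings():
        # near-constant groups trip scipy's catastrophic-cancellation warning
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def mann_whitney(a, b) -> float:
    """Two-sided Mann-Whitney U p-value; exact for small tie-free samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not ties and max(a.size, b.size) <= 25) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


@dataclass
class WilcoxonResult:
    p_value: float
    n_effective: int
    degenerate: bool


def paired_wilcoxon(pre, post) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test on per-fish values.

    Zero differences are dropped (Wilcoxon's original convention).  Exact
    null distribution for n <= 25 tie-free differences, normal approximation
    with continuity correction otherwise.  All-zero differences yield a
    degenerate flag with p = NaN rather than an exception.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired samples must have equal length")
    d = post - pre
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonResult(p_value=float("nan"), n_effective=0,
                              degenerate=True)
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method,
                       correction=(method == "approx"))
    return WilcoxonResult(p_value=float(res.pvalue), n_effective=int(d.size),
                          degenerate=False)


# ---------------------------------------------------------------------------
# per-size comparison tables
# ---------------------------------------------------------------------------

@dataclass
class GroupComparisonTable:
    """One row of a comparison table: a pair of conditions tested per size,
    BH-adjusted within that size family."""

    comparison: str
    table: pd.DataFrame  # index: size_deg; columns: raw_p, adj_p, n_a, n_b, test, stars


def per_size_tests(group_a: pd.DataFrame | dict,
                   group_b: pd.DataFrame | dict,
                   test: str = "t",
                   comparison: str = "",
                   alpha: float = 0.05) -> GroupComparisonTable:
    """Per-size two-group tests with BH adjustment within the size family.

    ``group_a``/``group_b`` map sizes to per-larva index values (a mapping
    or a DataFrame whose columns are sizes).  Sizes with fewer than two
    non-missing observations in either group are reported NA and excluded
    from the BH family size m.
    """
    if test not in {"t", "mann_whitney"}:
        raise ValueError("test must be 't' or 'mann_whitney'")
    a_cols = _as_columns(group_a)
    b_cols = _as_columns(group_b)
    sizes = sorted(set(a_cols) & set(b_cols))
    if not sizes:
        raise DesignError("groups share no sizes")
    raw, ns = {}, {}
    for size in sizes:
        a = np.asarray(a_cols[size], dtype=float)
        b = np.asarray(b_cols[size], dtype=float)
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        ns[size] = (a.size, b.size)
        if a.size < 2 or b.size < 2:
            raw[size] = float("nan")
        elif test == "t":
            raw[size] = welch_t(a, b)
        else:
            raw[size] = mann_whitney(a, b)
    tested = [s for s in sizes if not np.isnan(raw[s])]
    adj = dict(zip(tested, benjamini_hochberg([raw[s] for s in tested]))) \
        if tested else {}
    table = pd.DataFrame({
        "raw_p": [raw[s] for s in sizes],
        "adj_p": [adj.get(s, float("nan")) for s in sizes],
        "n_a": [ns[s][0] for s in sizes],
        "n_b": [ns[s][1] for s in sizes],
        "test": test,
        "stars": [significance_stars(adj.get(s, float("nan")))
                  for s in sizes],
    }, index=pd.Index(sizes, name="size_deg"))
    return GroupComparisonTable(comparison=comparison, table=table)


def _as_columns(group) -> dict[float, np.ndarray]:
    if isinstance(group, pd.DataFrame):
        return {float(c): group[c].to_numpy(dtype=float)
                for c in group.columns}
    return {float(k): np.asarray(v, dtype=float) for k, v in group.items()}


# ---------------------------------------------------------------------------
# mixed ANOVA contract
# ---------------------------------------------------------------------------

def mixed_anova(data: pd.DataFrame, dv: str, within: str, between: str,
                subject: str) -> pd.DataFrame:
    """Two-way mixed-effects ANOVA: one within factor, one between factor.

    Returns a table with effect name, F and p for the between main effect,
    the within main effect and their interaction.  A constant response is a
    well-defined degenerate design and reports F = 0, p = 1 for all effects.
    """
    for factor in (within, between):
        if data[factor].nunique() < 2:
            raise DesignError(f"factor {factor!r} has fewer than two levels")
    effects = [between, within, "Interaction"]
    if data[dv].nunique() == 1:
        return pd.DataFrame({"effect": effects, "F": 0.0, "p": 1.0})
    import pingouin as pg
    aov = pg.mixed_anova(data=data, dv=dv, within=within, between=between,
                         subject=subject)
    aov = aov.set_index("Source")
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    rows = []
    for effect in effects:
        rows.append({"effect": effect,
                     "F": float(aov.loc[effect, "F"]),
                     "p": float(aov.loc[effect, p_col])})
    return pd.DataFrame(rows)


def tukey_hsd(data: pd.DataFrame, dv: str, factor: str) -> pd.DataFrame:
    """Tukey HSD pairwise contrasts on one declared factor."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    res = pairwise_tukeyhsd(endog=data[dv].to_numpy(dtype=float),
                            groups=data[factor].astype(str).to_numpy())
    frame = pd.DataFrame(res.summary().data[1:],
                         columns=res.summary().data[0])
    return frame
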