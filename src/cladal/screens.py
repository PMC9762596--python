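"""Nonparametric per-taxon differential-abundance screens.

Genus-level (or any-rank) screens on relative abundances: a two-sided
Wilcoxon rank-sum test between age groups, and a Kruskal-Wallis test
across diet groups within each age stratum (week-6 samples only), each
followed by Benjamini-Hochberg correction across taxa.

The Wilcoxon path is exact (full enumeration of the rank-sum null)
when both groups have at most 10 observations and there are no ties;
otherwise the tie-corrected normal approximation is used.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .nb import bh_adjust
from .tree import ValidationError

EXACT_MAX_N = 10


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) statistic and p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    exact = (len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N
             and not _has_ties(pooled))
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
    )
    return float(res.statistic), float(res.pvalue)


def wilcoxon_screen(rel_abund: pd.DataFrame, groups: pd.Series,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Per-taxon rank-sum screen between two groups of samples.

    Parameters
    ----------
    rel_abund : samples x taxa relative-abundance DataFrame
    groups : binary labels indexed by sample id

    Returns one row per taxon: statistic, p, BH q, and group medians.
    """
    groups = groups.loc[rel_abund.index].astype(str)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {levels}")
    ga, gb = levels
    a_idx = groups[groups == ga].index
    b_idx = groups[groups == gb].index
    if len(a_idx) == 0 or len(b_idx) == 0:
        raise ValidationError("both groups must be non-empty")
    rows = []
    for taxon in rel_abund.columns:
        xa = rel_abund.loc[a_idx, taxon].to_numpy()
        xb = rel_abund.loc[b_idx, taxon].to_numpy()
        stat, p = rank_sum_test(xa, xb)
        rows.append({
            "taxon": taxon, "statistic": stat, "p": p,
            f"median_{ga}": float(np.median(xa)),
            f"median_{gb}": float(np.median(xb)),
        })
    out = pd.DataFrame(rows).set_index("taxon")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


def kruskal_screen(rel_abund: pd.DataFrame, groups: pd.Series,
                   strata: pd.Series, alpha: float = 0.05
                   ) -> tuple[dict[str, pd.DataFrame], dict[str, str]]:
    """Per-taxon Kruskal-Wallis screen across groups within each stratum.

    ``groups`` (diet) and ``strata`` (age) are indexed by sample id;
    the caller subsets samples (e.g. to week 6) before the screen.
    BH runs across taxa within each stratum.  Strata with a single
    group level are skipped with a reason.
    """
    groups = groups.loc[rel_abund.index].astype(str)
    strata = strata.loc[rel_abund.index].astype(str)
    screens: dict[str, pd.DataFrame] = {}
    skipped: dict[str, str] = {}
    for stratum in sorted(strata.unique()):
        s_idx = strata[strata == stratum].index
        g = groups.loc[s_idx]
        levels = sorted(g.unique())
        if len(levels) < 2:
            skipped[stratum] = f"single group level ({levels})"
            continue
        rows = []
        for taxon in rel_abund.columns:
            samples = [rel_abund.loc[g[g == lev].index, taxon].to_numpy()
                       for lev in levels]
            try:
                with np.errstate(invalid="ignore"):
                    import warnings as _warnings
                    with _warnings.catch_warnings():
                        _warnings.simplefilter("ignore", RuntimeWarning)
                        stat, p = stats.kruskal(*samples)
            except ValueError:
                stat, p = np.nan, 1.0
            if not np.isfinite(p):  # all values identical: no evidence
                stat, p = np.nan, 1.0
            rows.append({"taxon": taxon, "statistic": float(stat), "p": float(p)})
        out = pd.DataFrame(rows).set_index("taxon")
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] < alpha
        screens[stratum] = out
    return screens, skipped
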