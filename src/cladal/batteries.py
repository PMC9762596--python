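"""Per-clade regression batteries: age, diet, and IL-6.

Each battery fits one negative-binomial regression per clade and
applies Benjamini-Hochberg FDR correction across the clades of the
battery family, followed by the intercept-sign exclusion: a clade whose
fitted model has a negative intercept is removed from the significant
set (counts are bounded below by zero, so a negative fitted baseline
signals a degenerate fit), but stays in the BH family.

The three batteries mirror the study design:

* age      — NB GLM ``Abundance ~ Age`` on all week-0 and week-6 fecal
             samples, one BH family across all clades;
* diet     — NB GLMM ``Abundance ~ Diet + (1 | Host)``, one model family
             per age x study cell (young/old x supplementation/deficiency),
             diet coded control (ZA) = 0, zinc-modified arm = 1;
* il6      — NB GLM ``Abundance ~ IL-6`` on week-6 samples only, one
             family per age group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clades import CladeMatrix
from .nb import NBGLM, NBGLMM, DegenerateDataError, bh_adjust
from .tables import SampleMetadata
from .tree import ValidationError

RESULT_COLUMNS = [
    "clade_id", "battery", "family", "slope", "se", "p", "q",
    "intercept", "theta", "sigma_b", "converged", "n_obs",
    "excluded_reason", "significant",
]

MIN_NONZERO = 3  # clades nonzero in fewer subset samples are unidentifiable


class BatteryResult:
    """Fitted battery: one row per clade per family, plus skipped families."""

    def __init__(self, battery: str, table: pd.DataFrame, skipped: dict | None = None):
        self.battery = battery
        self.table = table
        self.skipped = skipped or {}

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def counts(self) -> pd.DataFrame:
        """Tested / significant / excluded tallies per family."""
        rows = []
        for fam, sub in self.table.groupby("family", sort=True):
            rows.append({
                "family": fam,
                "tested": int(sub["p"].notna().sum()),
                "significant": int(sub["significant"].sum()),
                "negative_intercept": int((sub["excluded_reason"] == "negative_intercept").sum()),
                "degenerate": int((sub["excluded_reason"] == "degenerate").sum()),
                "nonconverged": int((sub["excluded_reason"] == "nonconverged").sum()),
            })
        return pd.DataFrame(rows)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<BatteryResult {self.battery}: {len(self.table)} rows, "
                f"{int(self.table['significant'].sum())} significant>")


def filter_significant(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Mark significant clades: q < alpha, converged, intercept >= 0.

    Exclusion happens after BH (clades leave the significant set, not
    the BH family) and every exclusion is recorded with its reason.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    out = table.copy()
    passed_q = out["q"].notna() & (out["q"] < alpha)
    neg_int = passed_q & out["converged"] & (out["intercept"] < 0)
    nonconv = passed_q & ~out["converged"].astype(bool)
    out.loc[neg_int & (out["excluded_reason"] == ""), "excluded_reason"] = "negative_intercept"
    out.loc[nonconv & (out["excluded_reason"] == ""), "excluded_reason"] = "nonconverged"
    out["significant"] = (
        passed_q & out["converged"].astype(bool) & (out["intercept"] >= 0)
    )
    return out


def _empty_row(cid, battery, family, n_obs, reason):
    return {
        "clade_id": cid, "battery": battery, "family": family,
        "slope": np.nan, "se": np.nan, "p": np.nan, "q": np.nan,
        "intercept": np.nan, "theta": np.nan, "sigma_b": np.nan,
        "converged": False, "n_obs": n_obs,
        "excluded_reason": reason, "significant": False,
    }


def _fit_family_glm(ctu_sub: pd.DataFrame, x: np.ndarray, battery: str,
                    family: str) -> list[dict]:
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    rows = []
    for cid in ctu_sub.columns:
        y = ctu_sub[cid].to_numpy()
        if np.count_nonzero(y) < MIN_NONZERO:
            rows.append(_empty_row(cid, battery, family, n, "degenerate"))
            continue
        try:
            res = NBGLM(y, X, exog_names=["Intercept", battery]).fit()
        except (DegenerateDataError, ValueError):
            rows.append(_empty_row(cid, battery, family, n, "degenerate"))
            continue
        rows.append({
            "clade_id": cid, "battery": battery, "family": family,
            "slope": res.params[1], "se": res.bse[1],
            "p": res.pvalues[1], "q": np.nan,
            "intercept": res.params[0], "theta": res.theta,
            "sigma_b": np.nan, "converged": res.converged, "n_obs": n,
            "excluded_reason": "" if res.converged else "nonconverged",
            "significant": False,
        })
    return rows


def _fit_family_glmm(ctu_sub: pd.DataFrame, x: np.ndarray, groups: np.ndarray,
                     battery: str, family: str, n_quad: int) -> list[dict]:
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    rows = []
    for cid in ctu_sub.columns:
        y = ctu_sub[cid].to_numpy()
        if np.count_nonzero(y) < MIN_NONZERO:
            rows.append(_empty_row(cid, battery, family, n, "degenerate"))
            continue
        try:
            res = NBGLMM(y, X, groups, exog_names=["Intercept", battery],
                         n_quad=n_quad).fit()
        except (DegenerateDataError, ValueError):
            rows.append(_empty_row(cid, battery, family, n, "degenerate"))
            continue
        se = res.bse[1]
        ok = res.converged and np.isfinite(se) and se > 0
        rows.append({
            "clade_id": cid, "battery": battery, "family": family,
            "slope": res.params[1], "se": se,
            "p": res.pvalues[1] if ok else np.nan, "q": np.nan,
            "intercept": res.params[0], "theta": res.theta,
            "sigma_b": res.sigma_b, "converged": ok, "n_obs": n,
            "excluded_reason": "" if ok else "nonconverged",
            "significant": False,
        })
    return rows


def _bh_within_family(rows: list[dict]) -> None:
    p = np.array([r["p"] for r in rows], dtype=float)
    mask = np.isfinite(p)
    if mask.any():
        q = np.full(len(p), np.nan)
        q[mask] = bh_adjust(p[mask])
        for r, qi in zip(rows, q):
            r["q"] = qi


def _finish(battery, rows, skipped, alpha) -> BatteryResult:
    if rows:
        table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        table = filter_significant(table, alpha=alpha)
    else:
        table = pd.DataFrame(columns=RESULT_COLUMNS)
    return BatteryResult(battery, table, skipped)


def run_age_battery(ctu: CladeMatrix, meta: SampleMetadata,
                    alpha: float = 0.05) -> BatteryResult:
    """NB GLM per clade on all samples; age coded young = 0, old = 1."""
    meta.check_covers(ctu.sample_ids)
    md = meta.data.loc[ctu.sample_ids]
    x = (md["age"].astype(str) == "old").to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValidationError("age battery needs both young and old samples")
    rows = _fit_family_glm(ctu.abundances, x, "age", "all")
    _bh_within_family(rows)
    return _finish("age", rows, {}, alpha)


DIET_FAMILIES = (
    ("young", "ZAM1", "ZS"),
    ("old", "ZAM1", "ZS"),
    ("young", "ZAM2", "ZD"),
    ("old", "ZAM2", "ZD"),
)


def run_diet_battery(ctu: CladeMatrix, meta: SampleMetadata,
                     alpha: float = 0.05, n_quad: int = 7) -> BatteryResult:
    """Four NB GLMM families (age x study), host random intercept.

    Diet is coded control (ZA) = 0, zinc-modified arm = 1; both
    timepoints enter and the host intercept absorbs per-mouse
    baselines, so discoveries reflect within-study diet contrasts.
    """
    meta.check_covers(ctu.sample_ids)
    md = meta.data.loc[ctu.sample_ids]
    rows: list[dict] = []
    skipped: dict[str, str] = {}
    for age, study, treat in DIET_FAMILIES:
        fam = f"{age}_{study}"
        sel = (
            (md["age"].astype(str) == age)
            & (md["study"].astype(str) == study)
            & (md["diet"].astype(str).isin(["ZA", treat]))
        )
        sub = md[sel]
        hosts_per_arm = sub.groupby("diet", observed=True)["host_id"].nunique()
        if (hosts_per_arm.reindex(["ZA", treat]).fillna(0) < 2).any():
            skipped[fam] = "fewer than 2 hosts per diet arm"
            continue
        x = (sub["diet"].astype(str) == treat).to_numpy(dtype=float)
        groups = sub["host_id"].to_numpy()
        fam_rows = _fit_family_glmm(
            ctu.abundances.loc[sub.index], x, groups, "diet", fam, n_quad
        )
        _bh_within_family(fam_rows)
        rows.extend(fam_rows)
    return _finish("diet", rows, skipped, alpha)


def run_il6_battery(ctu: CladeMatrix, meta: SampleMetadata,
                    alpha: float = 0.05) -> BatteryResult:
    """NB GLM of week-6 abundance on LPS-induced IL-6, per age group."""
    meta.check_covers(ctu.sample_ids)
    md = meta.data.loc[ctu.sample_ids]
    rows: list[dict] = []
    skipped: dict[str, str] = {}
    for age in ("young", "old"):
        sel = (
            (md["age"].astype(str) == age)
            & (md["timepoint"].astype(str) == "wk6")
            & md["il6"].notna()
        )
        sub = md[sel]
        if len(sub) < MIN_NONZERO:
            skipped[age] = "too few week-6 samples with IL-6"
            continue
        x = sub["il6"].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            skipped[age] = "IL-6 constant within the group"
            continue
        fam_rows = _fit_family_glm(ctu.abundances.loc[sub.index], x, "il6", age)
        _bh_within_family(fam_rows)
        rows.extend(fam_rows)
    return _finish("il6", rows, skipped, alpha)


def combined_significant(results) -> pd.DataFrame:
    """Union of significant clades across batteries, one row per hit."""
    frames = [r.significant.assign(battery=r.battery) for r in results]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return pd.concat(frames, ignore_index=True)[RESULT_COLUMNS]
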