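"""Longitudinal statistics for the cohort marker table.

Group (between-subject) × day (within-subject) repeated-measures ANOVA,
Tukey HSD group contrasts per day, Pearson correlation with a least-squares
line, percent-difference effect sizes, and a mean ± SE longitudinal summary.

All quantities are computed from explicit sums of squares and closed-form
formulas rather than delegated to an opaque fitter, so each term can be
verified independently (library implementations serve as cross-checks in
the test suite, never as the implementation).  Multiple testing across the
three markers is deliberately not adjusted; this matches the original
analysis convention and is recorded in the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, MetricError

MARKERS = ("surface_rr", "normalized_area", "volumetric_rr")


# ---- containers ------------------------------------------------------------

@dataclass
class EffectRow:
    ss: float
    df: int
    ms: float
    F: float
    p: float


@dataclass
class AnovaResult:
    """Mixed two-factor repeated-measures ANOVA decomposition."""

    response: str
    effects: Dict[str, EffectRow]          # group, day, group:day
    errors: Dict[str, EffectRow]           # subjects_within_group, day_x_subjects
    ss_total: float
    gg_epsilon: float
    p_gg: Dict[str, float]                 # sphericity-corrected within-subject p
    note: str = ""
    metadata: dict = field(default_factory=lambda: {
        "multiple_testing": "no adjustment across markers (by design)",
        "headline_p": "uncorrected; Greenhouse-Geisser reported alongside"})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, e in {**self.effects, **self.errors}.items():
            rows.append({"effect": name, "ss": e.ss, "df": e.df, "ms": e.ms,
                         "F": e.F, "p": e.p, "p_gg": self.p_gg.get(name, np.nan)})
        return pd.DataFrame(rows)


@dataclass
class TukeyContrast:
    day: int
    group_a: str
    group_b: str
    mean_diff: float
    q: float
    p_adj: float
    significant: bool


@dataclass
class PearsonResult:
    r: float
    r_squared: float
    p: float
    slope: float
    intercept: float
    n: int


# ---- table validation ------------------------------------------------------

def validate_table(table: pd.DataFrame, response: str) -> pd.DataFrame:
    for col in ("subject", "group", "day", response):
        if col not in table.columns:
            raise DesignError(f"cohort table lacks column {col!r}")
    df = table.dropna(subset=[response]).copy()
    if df.empty:
        raise DesignError(f"no observations for response {response!r}")
    dup = df.duplicated(subset=["subject", "day"])
    if dup.any():
        raise DesignError(
            f"duplicate (subject, day) rows: {df.loc[dup, ['subject', 'day']].values.tolist()}")
    return df


# ---- repeated-measures ANOVA ----------------------------------------------

def _greenhouse_geisser_epsilon(wide: pd.DataFrame, groups: pd.Series) -> float:
    """Box/GG epsilon from the pooled within-group covariance of the days."""
    d = wide.shape[1]
    if d < 2:
        return 1.0
    pooled = np.zeros((d, d))
    dof = 0
    for g, sub in wide.groupby(groups):
        x = sub.to_numpy(float)
        if len(x) > 1:
            pooled += (len(x) - 1) * np.cov(x, rowvar=False)
            dof += len(x) - 1
    if dof == 0:
        return 1.0
    S = pooled / dof
    # double-centre S; epsilon = (sum lambda)^2 / ((d-1) sum lambda^2)
    J = np.eye(d) - np.ones((d, d)) / d
    Sc = J @ S @ J
    tr = np.trace(Sc)
    tr2 = np.trace(Sc @ Sc)
    if tr2 <= 0:
        return 1.0
    eps = tr**2 / ((d - 1) * tr2)
    return float(min(1.0, max(eps, 1.0 / (d - 1))))


def _f_p(ss_eff: float, df_eff: int, ss_err: float, df_err: int):
    ms_eff = ss_eff / df_eff if df_eff else np.nan
    ms_err = ss_err / df_err if df_err else np.nan
    if not np.isfinite(ms_err) or ms_err <= 0:
        # no-variance case: F undefined when the effect is also null
        if ss_eff <= 1e-300:
            return ms_eff, ms_err, np.nan, np.nan
        return ms_eff, ms_err, np.inf, 0.0
    F = ms_eff / ms_err
    return ms_eff, ms_err, F, float(sps.f.sf(F, df_eff, df_err))


def repeated_anova(table: pd.DataFrame, response: str) -> AnovaResult:
    """Two-factor mixed ANOVA: group between subjects, day within subjects.

    Requires a balanced design (every subject observed at every day, >= 2
    subjects per group); raises :class:`DesignError` listing missing cells.
    """
    df = validate_table(table, response)
    days = sorted(df["day"].unique())
    subjects = df[["subject", "group"]].drop_duplicates()
    if subjects["group"].nunique() < 2:
        raise DesignError("need at least two groups")
    if (subjects.groupby("group").size() < 2).any():
        raise DesignError("need >= 2 subjects per group")

    wide = df.pivot(index="subject", columns="day", values=response)
    missing = [(s, d) for s in wide.index for d in days if pd.isna(wide.loc[s, d])]
    if missing:
        raise DesignError(f"unbalanced design; missing (subject, day) cells: {missing}")
    groups = subjects.set_index("subject")["group"]
    wide = wide.loc[groups.index, days]

    y = wide.to_numpy(float)                      # subjects x days
    g = groups.to_numpy()
    n_subj, n_day = y.shape
    group_names = sorted(set(g))
    n_group = len(group_names)
    grand = y.mean()

    ss_total = float(((y - grand) ** 2).sum())
    subj_means = y.mean(axis=1)
    ss_subjects = float(n_day * ((subj_means - grand) ** 2).sum())
    group_means = {gn: y[g == gn].mean() for gn in group_names}
    counts = {gn: int((g == gn).sum()) for gn in group_names}
    ss_group = float(n_day * sum(
        counts[gn] * (group_means[gn] - grand) ** 2 for gn in group_names))
    ss_subj_within = ss_subjects - ss_group
    day_means = y.mean(axis=0)
    ss_day = float(n_subj * ((day_means - grand) ** 2).sum())
    ss_gd = 0.0
    for gn in group_names:
        cell = y[g == gn].mean(axis=0)
        ss_gd += counts[gn] * ((cell - group_means[gn] - day_means + grand) ** 2).sum()
    ss_gd = float(ss_gd)
    ss_err_within = ss_total - ss_subjects - ss_day - ss_gd

    df_group = n_group - 1
    df_sw = n_subj - n_group
    df_day = n_day - 1
    df_gd = df_group * df_day
    df_err = df_sw * df_day

    ms_g, ms_sw, F_g, p_g = _f_p(ss_group, df_group, ss_subj_within, df_sw)
    ms_d, ms_e, F_d, p_d = _f_p(ss_day, df_day, ss_err_within, df_err)
    ms_gd, _, F_gd, p_gd = _f_p(ss_gd, df_gd, ss_err_within, df_err)

    eps = _greenhouse_geisser_epsilon(wide, groups)
    p_gg = {}
    for name, F, dfe in (("day", F_d, df_day), ("group:day", F_gd, df_gd)):
        if np.isfinite(F):
            p_gg[name] = float(sps.f.sf(F, eps * dfe, eps * df_err))
        else:
            p_gg[name] = 0.0 if F == np.inf else np.nan

    note = ""
    if ss_total <= 1e-300:
        note = "no-variance case: all responses identical"

    return AnovaResult(
        response=response,
        effects={
            "group": EffectRow(ss_group, df_group, ms_g, F_g, p_g),
            "day": EffectRow(ss_day, df_day, ms_d, F_d, p_d),
            "group:day": EffectRow(ss_gd, df_gd, ms_gd, F_gd, p_gd),
        },
        errors={
            "subjects_within_group": EffectRow(
                ss_subj_within, df_sw, ss_subj_within / df_sw if df_sw else np.nan,
                np.nan, np.nan),
            "day_x_subjects_within_group": EffectRow(
                ss_err_within, df_err, ms_e, np.nan, np.nan),
        },
        ss_total=ss_total, gg_epsilon=eps, p_gg=p_gg, note=note)


# ---- Tukey HSD post hoc ----------------------------------------------------

def tukey_posthoc(table: pd.DataFrame, response: str, alpha: float = 0.05
                  ) -> List[TukeyContrast]:
    """Pairwise group contrasts per day with Tukey HSD adjustment."""
    df = validate_table(table, response)
    if df["group"].nunique() < 2:
        raise DesignError("Tukey contrasts need >= 2 groups")
    out: List[TukeyContrast] = []
    for day, sub in df.groupby("day"):
        gnames = sorted(sub["group"].unique())
        k = len(gnames)
        if k < 2:
            continue
        cells = {gn: sub.loc[sub["group"] == gn, response].to_numpy(float)
                 for gn in gnames}
        df_err = sum(len(v) - 1 for v in cells.values())
        if df_err <= 0:
            continue
        mse = sum(((v - v.mean()) ** 2).sum() for v in cells.values()) / df_err
        for i in range(k):
            for j in range(i + 1, k):
                a, bv = cells[gnames[i]], cells[gnames[j]]
                diff = float(a.mean() - bv.mean())
                se = np.sqrt(mse / 2.0 * (1.0 / len(a) + 1.0 / len(bv)))
                if se == 0:
                    q = 0.0 if diff == 0 else np.inf
                    p = 1.0 if diff == 0 else 0.0
                else:
                    q = abs(diff) / se
                    p = float(sps.studentized_range.sf(q, k, df_err))
                out.append(TukeyContrast(
                    day=int(day), group_a=gnames[i], group_b=gnames[j],
                    mean_diff=diff, q=float(q), p_adj=float(np.clip(p, 0, 1)),
                    significant=bool(p < alpha)))
    return out


# ---- Pearson correlation ---------------------------------------------------

def pearson(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Product-moment correlation with the least-squares line and t-test p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise MetricError("x and y must be equal-length 1D vectors")
    n = len(x)
    if n < 3:
        raise MetricError("correlation needs at least 3 points")
    sx = x - x.mean()
    sy = y - y.mean()
    ssx = (sx**2).sum()
    ssy = (sy**2).sum()
    if ssx == 0 or ssy == 0:
        raise MetricError("correlation undefined for constant input")
    sxy = (sx * sy).sum()
    r = float(sxy / np.sqrt(ssx * ssy))
    r = float(np.clip(r, -1.0, 1.0))
    slope = float(sxy / ssx)
    intercept = float(y.mean() - slope * x.mean())
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), n - 2))
    return PearsonResult(r=r, r_squared=r * r, p=p, slope=slope,
                         intercept=intercept, n=n)


def percent_difference(a: float, b: float) -> float:
    """100 (a − b)/a: positive when the comparand b is lower than reference a."""
    if a == 0:
        raise MetricError("percent difference undefined for zero reference")
    return 100.0 * (a - b) / a


# ---- longitudinal summary (Table-2 style) ----------------------------------

def summarize_cohort(table: pd.DataFrame,
                     markers: Sequence[str] = MARKERS,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-marker mean ± SE by group and day, with Tukey significance flags.

    SE is SD/sqrt(n); with a single subject in a cell the SE is reported as
    missing.  A cell is flagged significant when the Tukey contrast against
    the other group at that day rejects at ``alpha``.
    """
    rows = []
    for marker in markers:
        if marker not in table.columns or table[marker].dropna().empty:
            continue
        df = validate_table(table, marker)
        try:
            contrasts = tukey_posthoc(df, marker, alpha=alpha)
        except DesignError:
            contrasts = []
        sig_days = {c.day for c in contrasts if c.significant}
        for (group, day), cell in df.groupby(["group", "day"]):
            vals = cell[marker].to_numpy(float)
            n = len(vals)
            se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            rows.append({
                "marker": marker, "group": group, "day": int(day), "n": n,
                "mean": float(vals.mean()), "se": se,
                "significant": bool(day in sig_days)})
    return pd.DataFrame(rows).sort_values(
        ["marker", "day", "group"]).reset_index(drop=True)
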