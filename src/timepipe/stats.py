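"""Cohort comparison: Pearson chi-squared tests with BH adjustment.

Per-patient event counts are summed within each outcome group to form a
2 x 2 contingency per feature (events vs non-events), tested with the
Pearson chi-squared statistic (no continuity correction) and adjusted
across the feature family by Benjamini-Hochberg. A patient-level
Mann-Whitney rank comparison of per-patient rates is reported alongside as
a sensitivity check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import CohortError, ParameterError


def chi_squared_test(contingency) -> tuple[float, int, float]:
    """Pearson chi-squared on a contingency table of counts.

    Returns (statistic, degrees of freedom, p). Expected counts come from
    the row/column margins; no continuity correction.
    """
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ParameterError("contingency must be at least 2 x 2")
    if (table < 0).any():
        raise ParameterError("counts must be nonnegative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ParameterError("degenerate table: a margin is zero")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ParameterError("p-values must lie in [0, 1]")
    if method != "BH":
        raise ParameterError(f"unsupported adjustment method {method!r}")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(
    feature_counts: pd.DataFrame,
    patients: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare per-patient event counts between the two outcome groups.

    ``feature_counts`` is tidy: patient_id, feature, events, total (events
    <= total; total is the patient's denominator for that feature family,
    e.g. its neighborhood count). Counts are summed within each group to a
    2 x 2 table per feature. Features with a zero margin (e.g. no events in
    either group) are kept with statistic 0, p = 1 and flagged
    ``degenerate`` so the BH family is stable.

    Returns one row per feature: contingency cells, statistic, df, p,
    p_adj, direction (group with the higher event rate), p_rank
    (Mann-Whitney on per-patient rates), significant (p_adj < alpha).
    """
    required = {"patient_id", "feature", "events", "total"}
    if not required.issubset(feature_counts.columns):
        raise ParameterError(f"feature_counts needs columns {sorted(required)}")
    groups = sorted(patients["outcome"].unique())
    if len(groups) != 2:
        raise CohortError(f"expected exactly 2 outcome groups, got {groups}")
    by_patient = feature_counts.merge(
        patients[["patient_id", "outcome"]], on="patient_id", how="left"
    )
    if by_patient["outcome"].isna().any():
        missing = by_patient.loc[by_patient["outcome"].isna(), "patient_id"].unique()
        raise CohortError(f"patients missing from patient table: {sorted(missing)}")
    g0, g1 = groups
    rows = []
    for feature, sub in by_patient.groupby("feature", sort=True):
        agg = sub.groupby("outcome")[["events", "total"]].sum()
        e0, t0 = (agg.loc[g0] if g0 in agg.index else pd.Series({"events": 0, "total": 0}))[
            ["events", "total"]
        ]
        e1, t1 = (agg.loc[g1] if g1 in agg.index else pd.Series({"events": 0, "total": 0}))[
            ["events", "total"]
        ]
        table = np.array([[e0, t0 - e0], [e1, t1 - e1]], dtype=float)
        degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
        if degenerate:
            stat, df, p = 0.0, 1, 1.0
        else:
            stat, df, p = chi_squared_test(table)
        r0 = e0 / t0 if t0 else 0.0
        r1 = e1 / t1 if t1 else 0.0
        direction = g0 if r0 > r1 else (g1 if r1 > r0 else "tie")
        rates = {
            g: (sub.loc[sub["outcome"] == g, "events"] /
                sub.loc[sub["outcome"] == g, "total"].replace(0, np.nan)).dropna()
            for g in groups
        }
        if len(rates[g0]) and len(rates[g1]) and not degenerate:
            p_rank = float(
                sps.mannwhitneyu(rates[g0], rates[g1], alternative="two-sided").pvalue
            )
        else:
            p_rank = 1.0
        rows.append(
            {
                "feature": feature,
                "events_a": int(e0),
                "total_a": int(t0),
                "events_b": int(e1),
                "total_b": int(t1),
                "statistic": stat,
                "df": df,
                "p": p,
                "direction": direction,
                "p_rank": p_rank,
                "degenerate": bool(degenerate),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = adjust_pvalues(out["p"].to_numpy())
        out["significant"] = out["p_adj"] < alpha
    else:
        out["p_adj"] = []
        out["significant"] = []
    out.attrs["groups"] = (g0, g1)
    return out
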