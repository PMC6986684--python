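"""Lineage- and cultivar-level copy-number statistics.

One-way ANOVA per paralog across lineages, Tukey HSD post hoc pairwise
comparisons, and paired t-tests for cultivars sequenced twice.  The F and t
statistics are computed from sums of squares directly; only the reference
distributions (F, studentized range, t) come from scipy.

Lineage ANOVAs exclude samples labelled "unassigned": the comparison of
interest is among the three named lineages.  No correction is applied across
per-paralog tests by default; Benjamini-Hochberg can be switched on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .depth import CopyNumberTable
from .errors import DegenerateInputError, InvalidInputError


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    median: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    groups: tuple[GroupSummary, ...]


def _validated_groups(
    values_by_group: Mapping[str, Sequence[float]],
) -> dict[str, np.ndarray]:
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise InvalidInputError("need at least 2 groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise InvalidInputError(f"group '{label}' has fewer than 2 observations")
    ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    if ssw <= 0:
        raise DegenerateInputError("total within-group variance is zero")
    return groups


def one_way_anova(values_by_group: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA from sums of squares.

    F = MSB / MSW with df (k - 1, n - k); p from the F distribution.  Requires
    >= 2 groups, each with >= 2 observations, and nonzero pooled within-group
    variance.
    """
    groups = _validated_groups(values_by_group)
    all_values = np.concatenate(list(groups.values()))
    grand_mean = all_values.mean()
    k = len(groups)
    n = len(all_values)
    ssb = sum(len(v) * (v.mean() - grand_mean) ** 2 for v in groups.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_between = k - 1
    df_within = n - k
    F = (ssb / df_between) / (ssw / df_within)
    p = float(sps.f.sf(F, df_between, df_within))
    summaries = tuple(
        GroupSummary(label=l, n=len(v), mean=float(v.mean()), median=float(np.median(v)))
        for l, v in groups.items()
    )
    return AnovaResult(
        F=float(F),
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        groups=summaries,
    )


def tukey_posthoc(values_by_group: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons after a one-way ANOVA.

    Adjusted p-values come from the studentized-range distribution with the
    pooled within-group variance (the Tukey-Kramer form for unequal group
    sizes).  One row per unordered group pair.
    """
    groups = _validated_groups(values_by_group)
    labels = list(groups)
    k = len(groups)
    n = sum(len(v) for v in groups.values())
    df_within = n - k
    msw = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df_within
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[labels[i]], groups[labels[j]]
            diff = gi.mean() - gj.mean()
            se = np.sqrt(msw / 2.0 * (1.0 / len(gi) + 1.0 / len(gj)))
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, df_within))
            rows.append(
                {
                    "group_i": labels[i],
                    "group_j": labels[j],
                    "mean_difference": float(diff),
                    "p_adjusted": min(p_adj, 1.0),
                }
            )
    return pd.DataFrame(rows)


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Paired t-test on the element-wise differences; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InvalidInputError("paired samples must have equal length")
    if len(x) < 2:
        raise InvalidInputError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("differences have zero variance")
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return float(t), n - 1, p


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def lineage_anova_tables(
    cn_table: CopyNumberTable,
    min_group_size: int = 2,
    bh_correct: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-paralog lineage ANOVA and Tukey post hoc tables.

    Samples with lineage "unassigned" are dropped.  Groups smaller than
    ``min_group_size`` are excluded from that paralog's test; paralogs left
    with fewer than two usable groups, or with degenerate variance, are
    reported with NaN statistics rather than aborting the batch.
    """
    meta = cn_table.samples.set_index("sample_id")
    anova_rows, posthoc_frames = [], []
    for paralog in cn_table.paralogs:
        values_by_group: dict[str, list[float]] = {}
        for sid, cn in cn_table.values[paralog].items():
            lineage = meta.loc[sid, "lineage"]
            if lineage == "unassigned":
                continue
            values_by_group.setdefault(lineage, []).append(float(cn))
        values_by_group = {
            k: v for k, v in values_by_group.items() if len(v) >= min_group_size
        }
        row: dict = {"paralog": paralog}
        try:
            res = one_way_anova(values_by_group)
        except (InvalidInputError, DegenerateInputError) as exc:
            row.update(F=np.nan, df_between=np.nan, df_within=np.nan,
                       p_value=np.nan, note=str(exc))
            anova_rows.append(row)
            continue
        row.update(
            F=res.F,
            df_between=res.df_between,
            df_within=res.df_within,
            p_value=res.p_value,
            note="",
        )
        for g in res.groups:
            row[f"mean_{g.label}"] = g.mean
            row[f"median_{g.label}"] = g.median
            row[f"n_{g.label}"] = g.n
        anova_rows.append(row)
        ph = tukey_posthoc(values_by_group)
        ph.insert(0, "paralog", paralog)
        posthoc_frames.append(ph)
    anova = pd.DataFrame(anova_rows)
    if bh_correct and anova["p_value"].notna().any():
        mask = anova["p_value"].notna()
        anova.loc[mask, "p_adjusted_bh"] = benjamini_hochberg(
            anova.loc[mask, "p_value"].to_numpy()
        )
    posthoc = (
        pd.concat(posthoc_frames, ignore_index=True)
        if posthoc_frames
        else pd.DataFrame(columns=["paralog", "group_i", "group_j",
                                   "mean_difference", "p_adjusted"])
    )
    return anova, posthoc


def replicate_cultivar_tests(cn_table: CopyNumberTable) -> pd.DataFrame:
    """Within-cultivar CN comparisons for cultivars sequenced more than once.

    Cultivars with exactly two libraries are compared with a paired t-test
    across paralogs; cultivars with more than two use a one-way ANOVA with
    libraries as groups and paralogs as observations.
    """
    meta = cn_table.samples
    rows = []
    for cultivar, grp in meta.groupby("cultivar"):
        sids = list(grp["sample_id"])
        if len(sids) < 2:
            continue
        profiles = [cn_table.values.loc[sid].to_numpy() for sid in sids]
        if len(sids) == 2:
            try:
                t, df, p = paired_t(profiles[0], profiles[1])
                rows.append({"cultivar": cultivar, "test": "paired_t",
                             "statistic": t, "df": df, "p_value": p, "note": ""})
            except DegenerateInputError as exc:
                rows.append({"cultivar": cultivar, "test": "paired_t",
                             "statistic": np.nan, "df": np.nan,
                             "p_value": np.nan, "note": str(exc)})
        else:
            try:
                res = one_way_anova({sid: prof for sid, prof in zip(sids, profiles)})
                rows.append({"cultivar": cultivar, "test": "anova",
                             "statistic": res.F, "df": res.df_within,
                             "p_value": res.p_value, "note": ""})
            except (InvalidInputError, DegenerateInputError) as exc:
                rows.append({"cultivar": cultivar, "test": "anova",
                             "statistic": np.nan, "df": np.nan,
                             "p_value": np.nan, "note": str(exc)})
    return pd.DataFrame(
        rows, columns=["cultivar", "test", "statistic", "df", "p_value", "note"]
    )
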