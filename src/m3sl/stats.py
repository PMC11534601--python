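"""Group statistics over per-subject metrics.

One-way ANOVA compares metric means across the levels of a factor (model
variant, clinical stage, or scanner); where the factor has more than two
levels, post-hoc pairwise two-sample t-tests with pooled variance are
corrected by the Holm-Bonferroni step-down procedure at alpha = 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import StatsError


@dataclass
class PairwiseTest:
    group_a: str
    group_b: str
    t: float
    raw_p: float
    corrected_p: float
    significant: bool


@dataclass
class StatsReport:
    factor: str
    metric: str = ""
    anova_F: float = float("nan")
    anova_dfs: tuple = (0, 0)
    anova_p: float = float("nan")
    pairwise: List[PairwiseTest] = field(default_factory=list)
    note: str = ""


def _check_groups(groups: Dict[str, Sequence[float]]) -> Dict[str, np.ndarray]:
    if len(groups) < 2:
        raise StatsError(f"need >= 2 groups, got {len(groups)}")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray([v for v in vals if np.isfinite(v)], dtype=np.float64)
        if arr.size < 2:
            raise StatsError(f"group {name!r} has n={arr.size} < 2 finite values")
        out[name] = arr
    return out


def one_way_anova(groups: Dict[str, Sequence[float]]) -> StatsReport:
    """Standard between/within variance decomposition.

    Returns F with (k-1, N-k) degrees of freedom and its p-value.  Groups
    with identical means give F = 0, p = 1.
    """
    g = _check_groups(groups)
    arrays = list(g.values())
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    F, p = sps.f_oneway(*arrays)
    if not np.isfinite(F):  # zero within-group variance edge case
        means = [a.mean() for a in arrays]
        if np.ptp(means) == 0:
            F, p = 0.0, 1.0
    return StatsReport(
        factor="", anova_F=float(F), anova_dfs=(k - 1, n_total - k), anova_p=float(p)
    )


def pooled_t(a: np.ndarray, b: np.ndarray):
    """Two-sample t-test with pooled variance (equal-variance assumption)."""
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def holm_correct(raw_p: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values."""
    _, corrected, _, _ = multipletests(raw_p, alpha=0.05, method="holm")
    return corrected


def posthoc_holm(
    groups: Dict[str, Sequence[float]], alpha: float = 0.05
) -> List[PairwiseTest]:
    """All pairwise pooled-variance t-tests, Holm-corrected as one family."""
    g = _check_groups(groups)
    pairs = list(combinations(sorted(g), 2))
    raw = []
    ts = []
    for a, b in pairs:
        t, p = pooled_t(g[a], g[b])
        ts.append(t)
        raw.append(p if np.isfinite(p) else 1.0)
    corrected = holm_correct(raw)
    return [
        PairwiseTest(
            group_a=a,
            group_b=b,
            t=ts[i],
            raw_p=raw[i],
            corrected_p=float(corrected[i]),
            significant=bool(corrected[i] < alpha),
        )
        for i, (a, b) in enumerate(pairs)
    ]


def group_report(
    reports,  # List[MetricReport] or DataFrame
    factor: str,
    metrics: Sequence[str] = ("f_measure", "iou", "hd95"),
    alpha: float = 0.05,
) -> List[StatsReport]:
    """ANOVA + Holm post-hoc per metric, subjects grouped by ``factor``.

    ``factor`` is one of the MetricReport categorical fields ("variant",
    "stage", "scanner").  A single-level factor yields a report with the
    ANOVA skipped and an explanatory note.  NaN metric values (e.g.
    undefined HD95) are dropped per group.
    """
    import pandas as pd

    if not isinstance(reports, pd.DataFrame):
        from .metrics import reports_to_frame

        df = reports_to_frame(reports)
    else:
        df = reports
    if factor not in df.columns:
        raise StatsError(f"factor {factor!r} not present in reports")
    levels = [l for l in df[factor].unique() if l != ""]
    out: List[StatsReport] = []
    for metric in metrics:
        if len(levels) < 2:
            out.append(
                StatsReport(
                    factor=factor,
                    metric=metric,
                    note=f"factor {factor!r} has a single level; ANOVA skipped",
                )
            )
            continue
        groups = {
            str(lv): df.loc[df[factor] == lv, metric].to_numpy() for lv in levels
        }
        rep = one_way_anova(groups)
        rep.factor = factor
        rep.metric = metric
        rep.pairwise = posthoc_holm(groups, alpha=alpha)
        out.append(rep)
    return out


def stats_to_frame(reports: List[StatsReport]):
    """Pairwise tables of several StatsReports as one tidy DataFrame."""
    import pandas as pd

    rows = []
    for r in reports:
        if not r.pairwise:
            rows.append(
                {
                    "factor": r.factor, "metric": r.metric, "group_a": "", "group_b": "",
                    "anova_F": r.anova_F, "anova_p": r.anova_p, "t": np.nan,
                    "raw_p": np.nan, "corrected_p": np.nan, "significant": False,
                    "note": r.note,
                }
            )
        for pw in r.pairwise:
            rows.append(
                {
                    "factor": r.factor, "metric": r.metric, "group_a": pw.group_a,
                    "group_b": pw.group_b, "anova_F": r.anova_F, "anova_p": r.anova_p,
                    "t": pw.t, "raw_p": pw.raw_p, "corrected_p": pw.corrected_p,
                    "significant": pw.significant, "note": r.note,
                }
            )
    return pd.DataFrame(rows)
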