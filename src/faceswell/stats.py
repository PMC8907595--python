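"""Group statistics: mean ± SD summaries, one-way ANOVA, Student's t.

The statistical surface of a small longitudinal cohort study: per-group
per-day mean ± SD (sample SD, n−1 denominator), one-way ANOVA across
arms, two-sample Student's t tests (pooled variance by default, Welch
behind a flag), significance flagged at P < 0.05, and the
progressive-calibration deviation summary (per-rat CV at each stage).

F and t statistics are computed from the explicit sums-of-squares /
pooled-variance formulas with scipy supplying only the F and t
distributions; the test suite cross-checks them against
scipy.stats.f_oneway / ttest_ind.  No multiple-testing correction is
applied by default (per-timepoint testing); Holm is available via
``adjust="holm"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import FaceswellError
from .study import STAGE_COLUMNS

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize",
    "anova_oneway",
    "ttest_two_sample",
    "pairwise_day_tests",
    "deviation_report",
    "DeviationReport",
    "build_report",
    "plot_group_curves",
]

ALPHA = 0.05


class StatsDomainError(FaceswellError):
    """Degenerate input to a statistical routine."""


@dataclass(frozen=True)
class GroupSummary:
    group: str
    day: int
    n: int
    mean: float
    sd: float
    cv: float


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, df, p, and the P < 0.05 flag."""

    label: str
    statistic: float
    df: tuple[float, ...] | float
    p_value: float
    significant: bool
    degenerate: bool = False


def _stage_column(stage: str) -> str:
    try:
        return STAGE_COLUMNS[stage]
    except KeyError:
        raise StatsDomainError(
            f"unknown stage {stage!r}; expected one of {sorted(STAGE_COLUMNS)}"
        ) from None


def summarize(table: pd.DataFrame, stage: str = "final") -> pd.DataFrame:
    """Per-group per-day n / mean / sample SD / CV of the stage area.

    Row-permutation invariant; a single observation gets SD = 0.
    """
    col = _stage_column(stage)
    if table.empty:
        raise StatsDomainError("empty table")
    g = table.groupby(["group", "day"], sort=True)[col]
    out = g.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
    out = out.reset_index()
    out["cv"] = out["sd"] / out["mean"]
    out.insert(2, "stage", stage)
    return out


def anova_oneway(groups: Sequence[Sequence[float]], label: str = "anova") -> TestResult:
    """Classic one-way fixed-effects ANOVA from sums of squares.

    F = (SS_between / (k−1)) / (SS_within / (N−k)).  Conventions for
    degenerate inputs: zero between- and within-group variance → F = 0,
    p = 1; zero within- with non-zero between-group variance → p = 0
    with the degeneracy flag set.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise StatsDomainError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise StatsDomainError("every ANOVA group needs n >= 2")
    all_x = np.concatenate(arrs)
    grand = all_x.mean()
    k, n_total = len(arrs), all_x.size
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df = (float(k - 1), float(n_total - k))
    if ss_within == 0.0:
        if ss_between == 0.0:
            return TestResult(label, 0.0, df, 1.0, False, degenerate=True)
        return TestResult(label, math.inf, df, 0.0, True, degenerate=True)
    f = (ss_between / df[0]) / (ss_within / df[1])
    p = float(sps.f.sf(f, df[0], df[1]))
    return TestResult(label, float(f), df, p, p < ALPHA)


def ttest_two_sample(
    a: Sequence[float],
    b: Sequence[float],
    label: str = "t-test",
    *,
    welch: bool = False,
) -> TestResult:
    """Two-sided two-sample t test, pooled variance (Student) by default.

    Zero pooled variance: equal means → t = 0, p = 1; different means →
    p = 0 with the degeneracy flag.  ``welch=True`` drops the
    equal-variance assumption (Welch–Satterthwaite df).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise StatsDomainError("both samples need n >= 2")
    na, nb = x.size, y.size
    va, vb = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0.0:
            dfw = float(na + nb - 2)
            return _degenerate_t(label, diff, dfw)
        dfw = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        t = diff / math.sqrt(se2)
        df: float = float(dfw)
    else:
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        if se2 == 0.0:
            return _degenerate_t(label, diff, df)
        t = diff / math.sqrt(se2)
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(label, float(t), df, p, p < ALPHA)


def _degenerate_t(label: str, diff: float, df: float) -> TestResult:
    if diff == 0.0:
        return TestResult(label, 0.0, df, 1.0, False, degenerate=True)
    return TestResult(label, math.copysign(math.inf, diff), df, 0.0, True, degenerate=True)


def pairwise_day_tests(
    table: pd.DataFrame,
    stage: str = "final",
    *,
    welch: bool = False,
    adjust: str = "none",
) -> pd.DataFrame:
    """Per-day ANOVA across arms plus all pairwise t tests.

    ``adjust="holm"`` applies a Holm step-down correction to the
    pairwise p-values within each day (off by default, matching
    uncorrected per-timepoint testing).
    """
    if adjust not in ("none", "holm"):
        raise StatsDomainError("adjust must be 'none' or 'holm'")
    col = _stage_column(stage)
    rows = []
    for day, sub in table.groupby("day", sort=True):
        samples = {
            g: v[col].to_numpy()
            for g, v in sub.groupby("group")
            if len(v) >= 2
        }
        names = sorted(samples)
        if len(names) >= 2:
            res = anova_oneway([samples[g] for g in names], label="anova:" + "/".join(names))
            rows.append(_test_row(day, stage, res))
        pair_results = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                ga, gb = names[i], names[j]
                pair_results.append(
                    ttest_two_sample(
                        samples[ga], samples[gb], label=f"t:{ga}-vs-{gb}", welch=welch
                    )
                )
        if adjust == "holm" and pair_results:
            from statsmodels.stats.multitest import multipletests

            reject, p_adj, _, _ = multipletests(
                [r.p_value for r in pair_results], alpha=ALPHA, method="holm"
            )
            pair_results = [
                TestResult(r.label, r.statistic, r.df, float(p), bool(rej), r.degenerate)
                for r, p, rej in zip(pair_results, p_adj, reject)
            ]
        rows.extend(_test_row(day, stage, r) for r in pair_results)
    return pd.DataFrame(
        rows,
        columns=["day", "stage", "comparison", "statistic", "df", "p_value", "significant"],
    )


def _test_row(day, stage, r: TestResult) -> dict:
    df = r.df if isinstance(r.df, float) else "/".join(f"{d:g}" for d in r.df)
    return {
        "day": day,
        "stage": stage,
        "comparison": r.label,
        "statistic": r.statistic,
        "df": df,
        "p_value": r.p_value,
        "significant": r.significant,
    }


@dataclass
class DeviationReport:
    """Per-rat CV at each calibration stage plus the group means."""

    per_rat: pd.DataFrame
    mean_cv: pd.Series
    monotone_decreasing: bool


def deviation_report(
    repeats: pd.DataFrame,
    stages: Sequence[str] = ("raw", "le", "rot", "final"),
) -> DeviationReport:
    """CV of repeated captures of static heads, stage by stage.

    ``repeats`` holds >= 2 rows per rat_id with the stage area columns
    (as produced by :func:`faceswell.study.repeat_capture`).  The report
    flags whether the mean CV decreases monotonically along the
    calibration order — the signature of each stage removing its
    nuisance factor.
    """
    cols = [_stage_column(s) for s in stages]
    counts = repeats.groupby("rat_id").size()
    if counts.empty or (counts < 2).any():
        raise StatsDomainError("need at least 2 repeats per rat")
    cv = repeats.groupby("rat_id")[cols].agg(lambda v: v.std(ddof=1) / v.mean())
    cv.columns = list(stages)
    mean_cv = cv.mean(axis=0)
    mono = bool((mean_cv.diff().dropna() < 0).all())
    return DeviationReport(per_rat=cv.reset_index(), mean_cv=mean_cv, monotone_decreasing=mono)


def build_report(
    table: pd.DataFrame,
    stages: Sequence[str] = ("raw", "le", "rot", "final"),
    *,
    welch: bool = False,
    adjust: str = "none",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(summaries, tests) over all requested stages, tidy long format."""
    summaries = pd.concat([summarize(table, s) for s in stages], ignore_index=True)
    tests = pd.concat(
        [pairwise_day_tests(table, s, welch=welch, adjust=adjust) for s in stages],
        ignore_index=True,
    )
    return summaries, tests


def plot_group_curves(
    table: pd.DataFrame,
    path,
    stages: Sequence[str] = ("raw", "final"),
):
    """Group mean ± SD versus study day, one panel per calibration stage."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(stages), figsize=(5.0 * len(stages), 3.6), squeeze=False)
    for ax, stage in zip(axes[0], stages):
        summ = summarize(table, stage)
        for group, sub in summ.groupby("group"):
            ax.errorbar(
                sub["day"], sub["mean"], yerr=sub["sd"], marker="o", capsize=3, label=group
            )
        ax.set_xlabel("study day")
        ax.set_ylabel(f"S ({stage}) [px²]")
        ax.set_title(f"stage: {stage}")
    axes[0][0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
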