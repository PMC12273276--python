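"""Survival and stage-progression endpoints.

Kaplan–Meier product-limit curves and log-rank tests are delegated to
lifelines; this module adds the cohort conventions: patient-centric units
(multi-lesion patients resolved to their worst, highest-β class), median
follow-up as the plain median of follow-up times with a reverse-KM option,
and the class x progression contingency analysis with a CNS (stage IVM1D)
breakdown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .subtypes import CLASS_ORDER

logger = logging.getLogger(__name__)


def _check_times(times: np.ndarray, events: np.ndarray) -> None:
    if np.any(times < 0):
        raise ValueError("negative survival times")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event flags must be 0/1")


@dataclass
class SurvivalCurve:
    group: str
    table: pd.DataFrame  # columns: time, at_risk, events, survival

    @property
    def median(self) -> float:
        below = self.table.loc[self.table["survival"] <= 0.5, "time"]
        return float(below.iloc[0]) if len(below) else float("nan")


def km_estimate(times, events, group_labels=None) -> dict[str, SurvivalCurve]:
    """Product-limit survival curve per group (events precede censorings at ties)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    _check_times(times, events)
    if group_labels is None:
        group_labels = np.array(["all"] * len(times))
    group_labels = np.asarray(group_labels)
    out: dict[str, SurvivalCurve] = {}
    for g in pd.unique(group_labels):
        m = group_labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m])
        ev = kmf.event_table
        tab = pd.DataFrame({
            "time": ev.index.to_numpy(dtype=float),
            "at_risk": ev["at_risk"].to_numpy(dtype=int),
            "events": ev["observed"].to_numpy(dtype=int),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(dtype=float),
        })
        out[str(g)] = SurvivalCurve(group=str(g), table=tab.reset_index(drop=True))
    return out


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


def logrank_test(times, events, groups) -> LogRankResult:
    """k-sample log-rank test (observed-minus-expected chi-square, df = k − 1)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    _check_times(times, events)
    if len(pd.unique(groups)) < 2:
        raise ValueError("need at least 2 groups")
    res = multivariate_logrank_test(times, groups, events)
    df = len(pd.unique(groups)) - 1
    return LogRankResult(statistic=float(res.test_statistic), df=df,
                         p=float(res.p_value))


def median_followup(times, events=None, reverse_km: bool = False) -> dict:
    """Median follow-up with range.

    Default is the plain median of all follow-up times; ``reverse_km``
    instead uses the reverse Kaplan–Meier estimator (censorings treated as
    events), which requires the event flags.
    """
    times = np.asarray(times, dtype=float)
    if len(times) == 0:
        raise ValueError("need at least one subject")
    if reverse_km:
        if events is None:
            raise ValueError("reverse-KM follow-up needs event flags")
        kmf = KaplanMeierFitter()
        kmf.fit(times, 1 - np.asarray(events, dtype=int))
        med = float(kmf.median_survival_time_)
    else:
        med = float(np.median(times))
    return {"median": med, "min": float(times.min()), "max": float(times.max())}


@dataclass
class ProgressionTable:
    counts: pd.DataFrame  # class x {progressed, not_progressed}
    statistic: float
    df: int
    p: float
    pct_progressed_by_class: pd.Series
    #: share of each class among all non-progressing patients (sums to 100)
    pct_of_nonprogressors: pd.Series
    cns_counts: pd.Series | None
    degenerate: bool = False


def _class_rank(label: str) -> int:
    return CLASS_ORDER.index(label) if label in CLASS_ORDER else -1


def resolve_patient_class(sheet: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Patient-level table with one class per patient (worst = highest β)."""
    df = sheet.set_index("sample_id").join(labels.rename("class"), how="inner")
    multi = df.groupby("patient_id")["class"].nunique()
    n_multi = int((multi > 1).sum())
    if n_multi:
        logger.warning("%d patients with lesions in different classes; "
                       "worst (highest-β) class used", n_multi)
    df = df.sort_values("class", key=lambda s: s.map(_class_rank))
    return df.groupby("patient_id").last()


def progression_analysis(sheet: pd.DataFrame, labels: pd.Series) -> ProgressionTable:
    """Class x stage-progression contingency analysis (patient-centric).

    The progression flag comes from the sheet (column ``progression``);
    chi-square is Pearson without continuity correction.  When a
    ``final_stage`` column is present, progression to CNS metastases is
    tallied as final stage IVM1D.
    """
    pat = resolve_patient_class(sheet, labels)
    if "progression" not in pat.columns:
        raise ValueError("sample sheet lacks a 'progression' column")
    prog = pat["progression"].astype(bool)
    classes_present = [c for c in CLASS_ORDER if c in set(pat["class"])]
    if not classes_present:
        classes_present = sorted(set(pat["class"]))
    counts = pd.DataFrame(0, index=classes_present,
                          columns=["progressed", "not_progressed"])
    for c in classes_present:
        m = pat["class"] == c
        counts.loc[c, "progressed"] = int((m & prog).sum())
        counts.loc[c, "not_progressed"] = int((m & ~prog).sum())
    degenerate = (counts.sum(axis=0) == 0).any()
    if degenerate:
        logger.warning("degenerate progression table (empty margin); "
                       "chi-square not computed")
        chi2, dof, p = float("nan"), 0, float("nan")
    else:
        chi2, p, dof, expected = stats.chi2_contingency(counts.to_numpy(),
                                                        correction=False)
        if (expected < 5).any():
            logger.warning("progression chi-square: expected counts < 5")
    totals = counts.sum(axis=1)
    pct_prog = 100.0 * counts["progressed"] / totals.replace(0, np.nan)
    non_prog_total = counts["not_progressed"].sum()
    pct_nonprog = 100.0 * counts["not_progressed"] / max(non_prog_total, 1)
    cns = None
    if "final_stage" in pat.columns:
        is_cns = pat["final_stage"].astype(str).str.upper() == "IVM1D"
        cns = pat.loc[is_cns, "class"].value_counts().reindex(
            classes_present, fill_value=0)
    return ProgressionTable(
        counts=counts, statistic=float(chi2), df=int(dof), p=float(p),
        pct_progressed_by_class=pct_prog.rename("pct_progressed"),
        pct_of_nonprogressors=pct_nonprog.rename("pct_of_nonprogressors"),
        cns_counts=cns, degenerate=bool(degenerate),
    )


def plot_km(curves: dict[str, SurvivalCurve], ax=None):
    """Step plot of per-group survival curves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for g, curve in curves.items():
        t = np.concatenate([[0.0], curve.table["time"].to_numpy()])
        s = np.concatenate([[1.0], curve.table["survival"].to_numpy()])
        ax.step(t, s, where="post", label=g)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax
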