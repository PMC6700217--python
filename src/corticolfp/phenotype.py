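"""Drinking-phenotype labeling and group statistics.

Subjects are labeled high- or low-drinker (HD/LD) by a median split of
their mean consumption (g/kg) over the last three training sessions; a
value at or above the median is HD, which puts the median subject in HD
and yields the 7/6 split for a 13-subject cohort. Group comparisons use a
pooled-variance two-sample t test, and the stimulation response uses a
2x2 mixed (split-plot) ANOVA: phase (training vs. stimulation) within
subjects, group (HD vs. LD) between subjects, with partial eta squared
effect sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypeLabels",
    "TTestResult",
    "AnovaResult",
    "average_last_sessions",
    "median_split",
    "two_sample_t",
    "mixed_anova_2x2",
]

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeLabels:
    """HD/LD assignment per subject plus the split value used."""

    labels: Dict[str, str]
    split_value: float

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {"HD", "LD"}
        if bad:
            raise ValueError(f"labels must be 'HD' or 'LD', got {bad}")

    def group(self, subject_id: str) -> str:
        return self.labels[subject_id]

    def subjects(self, group: str) -> Tuple[str, ...]:
        return tuple(s for s, g in self.labels.items() if g == group)

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, name="group")


@dataclass
class TTestResult:
    t: float
    df: int
    p: float


@dataclass
class AnovaResult:
    """Split-plot ANOVA table: one row per effect (group, time, interaction)."""

    effects: Dict[str, Dict[str, float]]  # effect -> {F, df1, df2, p, partial_eta_sq}

    def __post_init__(self) -> None:
        for name, row in self.effects.items():
            if row["F"] < 0:
                raise ValueError(f"negative F for {name}")
            if not 0 <= row["p"] <= 1:
                raise ValueError(f"p outside [0, 1] for {name}")
            if not 0 <= row["partial_eta_sq"] <= 1:
                raise ValueError(f"partial eta squared outside [0, 1] for {name}")

    def __getitem__(self, effect: str) -> Dict[str, float]:
        return self.effects[effect]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"effect": k, **v}
                for k, v in self.effects.items()
            ]
        ).set_index("effect")


def average_last_sessions(
    table: pd.DataFrame, k: int = 3, session_type: str = "training"
) -> Dict[str, float]:
    """Mean g/kg over each subject's final ``k`` sessions of a given type.

    Sessions are ordered by ``session_index``. A subject with fewer than
    ``k`` sessions is an error naming that subject.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    sub = table
    if "session_type" in table.columns and session_type is not None:
        sub = table[table["session_type"] == session_type]
    out: Dict[str, float] = {}
    for subject, grp in sub.groupby("subject_id", sort=False):
        grp = grp.sort_values("session_index")
        if len(grp) < k:
            raise ValueError(
                f"subject {subject!r} has only {len(grp)} "
                f"{session_type} sessions; need {k}"
            )
        out[str(subject)] = float(grp["g_per_kg"].tail(k).mean())
    return out


def median_split(values: Mapping[str, float]) -> PhenotypeLabels:
    """Label subjects HD when their value is at or above the cohort median.

    For odd n the median subject lands in HD (13 subjects -> 7 HD, 6 LD).
    Exact ties at the median are all assigned HD; a degenerate split
    (one empty group) is logged.
    """
    if len(values) < 2:
        raise ValueError("median split needs at least 2 subjects")
    med = float(np.median(list(values.values())))
    labels = {s: ("HD" if v >= med else "LD") for s, v in values.items()}
    groups = set(labels.values())
    if len(groups) < 2:
        logger.warning(
            "median split is degenerate (ties at the median): all subjects "
            "assigned %s",
            groups.pop(),
        )
    return PhenotypeLabels(labels=labels, split_value=med)


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Pooled-variance (Student) two-sample t test, two-sided.

    ``df = n_a + n_b - 2`` (11 for a 7 vs 6 comparison). With zero pooled
    variance: equal means give t = 0, p = 1; unequal means give an
    infinite t with p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = a.mean() - b.mean()
    if se == 0.0:
        if diff == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0)
        return TTestResult(t=float(np.sign(diff)) * np.inf, df=df, p=0.0)
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p))


def mixed_anova_2x2(
    pre_values: Mapping[str, float],
    stim_values: Mapping[str, float],
    labels: PhenotypeLabels,
) -> AnovaResult:
    """2 (phase, within) x 2 (group, between) mixed ANOVA.

    Sums of squares follow the standard split-plot decomposition with
    observed (weighted) cell sizes: between-subjects variation splits
    into group and subjects-within-group; within-subjects variation
    splits into time, time x group, and time x subjects-within-group.
    Each effect is tested on (1, n - 2) df; partial eta squared is
    SS_effect / (SS_effect + SS_error-for-that-effect). With two within
    levels the interaction F equals the squared pooled t on per-subject
    difference scores.
    """
    subjects = list(pre_values)
    if set(stim_values) != set(subjects) or set(labels.labels) != set(subjects):
        raise ValueError("pre, stim and labels must cover the same subjects")
    groups = {g: [s for s in subjects if labels.group(s) == g] for g in ("HD", "LD")}
    for g, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects")
    n = len(subjects)

    y = {}  # (group, subject, time) -> value
    for s in subjects:
        g = labels.group(s)
        y[(g, s, 0)] = float(pre_values[s])
        y[(g, s, 1)] = float(stim_values[s])
    all_vals = np.array(list(y.values()))
    gm = all_vals.mean()

    subj_mean = {s: (y[(labels.group(s), s, 0)] + y[(labels.group(s), s, 1)]) / 2.0 for s in subjects}
    grp_mean = {g: np.mean([subj_mean[s] for s in groups[g]]) for g in groups}
    time_mean = {j: np.mean([y[(labels.group(s), s, j)] for s in subjects]) for j in (0, 1)}
    cell_mean = {
        (g, j): np.mean([y[(g, s, j)] for s in groups[g]]) for g in groups for j in (0, 1)
    }

    ss_group = 2.0 * sum(len(groups[g]) * (grp_mean[g] - gm) ** 2 for g in groups)
    ss_subj = 2.0 * sum(
        (subj_mean[s] - grp_mean[g]) ** 2 for g in groups for s in groups[g]
    )
    ss_time = n * sum((time_mean[j] - gm) ** 2 for j in (0, 1))
    ss_inter = sum(
        len(groups[g]) * (cell_mean[(g, j)] - grp_mean[g] - time_mean[j] + gm) ** 2
        for g in groups
        for j in (0, 1)
    )
    ss_err_within = sum(
        (y[(g, s, j)] - cell_mean[(g, j)] - subj_mean[s] + grp_mean[g]) ** 2
        for g in groups
        for s in groups[g]
        for j in (0, 1)
    )

    df_den = n - 2

    def _row(ss_effect: float, ss_error: float) -> Dict[str, float]:
        ms_e = ss_error / df_den
        if ms_e == 0.0:
            f = 0.0 if ss_effect == 0.0 else np.inf
        else:
            f = ss_effect / ms_e
        p = float(stats.f.sf(f, 1, df_den)) if np.isfinite(f) else 0.0
        denom = ss_effect + ss_error
        pes = ss_effect / denom if denom > 0 else 0.0
        return {
            "F": float(f),
            "df1": 1.0,
            "df2": float(df_den),
            "p": p,
            "partial_eta_sq": float(pes),
        }

    return AnovaResult(
        effects={
            "group": _row(ss_group, ss_subj),
            "time": _row(ss_time, ss_err_within),
            "time*group": _row(ss_inter, ss_err_within),
        }
    )
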