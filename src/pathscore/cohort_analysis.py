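"""Cohort-level statistics on activity scores.

Implements the study-style comparisons: per-group summary statistics
(median, quartiles by linear interpolation, range), one-way fixed-effects
ANOVA with Tukey's HSD correction for all pairwise comparisons
(Tukey–Kramer for unequal group sizes), per-patient longitudinal
trajectories, and a paired one-sided test for a score increase between two
timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

#: conventional significance threshold, reported alongside results
SIGNIFICANCE_LEVEL = 0.05

QUARTILE_CONVENTION = "linear interpolation between order statistics"


@dataclass(frozen=True)
class GroupSummary:
    n: int
    median: float
    q1: float
    q3: float
    minimum: float
    maximum: float
    quartile_convention: str = QUARTILE_CONVENTION


@dataclass
class GroupComparisonResult:
    """Omnibus + pairwise comparison of k groups of scores."""

    groups: dict[str, GroupSummary]
    f_statistic: float
    p_value: float
    pairwise_p: dict[tuple[str, str], float]
    alpha: float = SIGNIFICANCE_LEVEL

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, p in self.pairwise_p.items() if p < self.alpha]


@dataclass(frozen=True)
class Trajectory:
    patient_id: str
    points: tuple[tuple[str, float], ...]
    delta_sign: int  # sign of (last score − first score)


@dataclass
class TrajectorySet:
    trajectories: dict[str, Trajectory]
    timepoint_order: tuple[str, ...]

    def delta_signs(self) -> pd.Series:
        return pd.Series(
            {pid: t.delta_sign for pid, t in self.trajectories.items()},
            name="delta_sign",
        )


def summarize_group(scores: Sequence[float]) -> GroupSummary:
    """Median, quartiles, and range of one group of scores."""
    x = np.asarray(list(scores), dtype=float)
    if x.size == 0:
        raise ValidationError("cannot summarize an empty group")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75], method="linear")
    return GroupSummary(
        n=int(x.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        minimum=float(x.min()),
        maximum=float(x.max()),
    )


def compare_groups(
    groups: Mapping[str, Sequence[float]], *, alpha: float = SIGNIFICANCE_LEVEL
) -> GroupComparisonResult:
    """One-way ANOVA with Tukey HSD adjusted pairwise p values.

    Classical (equal-variance) fixed-effects ANOVA; the Tukey step uses the
    studentized-range distribution with pooled within-group variance and
    the Tukey–Kramer harmonic-mean adjustment for unequal group sizes.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValidationError("need at least two groups")
    arrays = []
    for lab in labels:
        x = np.asarray(list(groups[lab]), dtype=float)
        if x.size < 2:
            raise ValidationError(f"group {lab!r} has fewer than 2 observations")
        arrays.append(x)

    grand = np.concatenate(arrays)
    if np.allclose(grand, grand[0]):
        # all observations identical: no variation to attribute anywhere
        f_stat, p_val = 0.0, 1.0
        pairwise = {
            (labels[i], labels[j]): 1.0
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        }
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
        tukey = stats.tukey_hsd(*arrays)
        pairwise = {
            (labels[i], labels[j]): float(
                np.clip(tukey.pvalue[i, j], 0.0, 1.0)
            )
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        }
    return GroupComparisonResult(
        groups={lab: summarize_group(arr) for lab, arr in zip(labels, arrays)},
        f_statistic=float(f_stat),
        p_value=float(p_val),
        pairwise_p=pairwise,
        alpha=alpha,
    )


def longitudinal_trajectories(
    scores: pd.DataFrame, timepoint_order: Sequence[str]
) -> TrajectorySet:
    """Order each patient's scores by the study's declared timepoint order.

    ``scores`` needs columns ``patient_id``, ``timepoint``, ``score``.
    Missing intermediate timepoints are allowed (ragged panels happen);
    duplicate (patient, timepoint) pairs are an error.  ``delta_sign`` is
    the sign of last-minus-first score, so "a consistent increase across
    patients" is assertable as all signs positive.
    """
    order = list(timepoint_order)
    if len(set(order)) != len(order):
        raise ValidationError("duplicate labels in timepoint_order")
    required = {"patient_id", "timepoint", "score"}
    if not required.issubset(scores.columns):
        raise ValidationError(f"scores table needs columns {sorted(required)}")
    unknown = sorted(set(scores["timepoint"]) - set(order))
    if unknown:
        raise ValidationError(f"timepoints not in declared order: {unknown}")
    dup = scores.duplicated(subset=["patient_id", "timepoint"])
    if dup.any():
        pairs = scores.loc[dup, ["patient_id", "timepoint"]].values.tolist()
        raise ValidationError(f"duplicate (patient, timepoint) pairs: {pairs}")

    rank = {tp: i for i, tp in enumerate(order)}
    trajectories = {}
    for pid, sub in scores.groupby("patient_id", sort=True):
        sub = sub.sort_values("timepoint", key=lambda s: s.map(rank))
        points = tuple(
            (str(tp), float(sc)) for tp, sc in zip(sub["timepoint"], sub["score"])
        )
        delta = points[-1][1] - points[0][1]
        trajectories[str(pid)] = Trajectory(
            patient_id=str(pid),
            points=points,
            delta_sign=int(np.sign(delta)),
        )
    return TrajectorySet(trajectories=trajectories, timepoint_order=tuple(order))


def paired_increase_test(
    baseline: Sequence[float],
    followup: Sequence[float],
    *,
    method: str = "permutation",
    n_resamples: int = 2000,
    seed: int | None = 0,
) -> tuple[float, float]:
    """One-sided paired test that follow-up scores exceed baseline scores.

    ``method="permutation"`` (default) runs a sign-flip permutation test on
    the mean paired difference — exact-level under the exchangeable null
    and robust to the strongly bimodal score differences binary latent
    states produce.  ``method="ttest"`` is the classical paired t test.
    Returns (statistic, one-sided p value).
    """
    b = np.asarray(list(baseline), dtype=float)
    f = np.asarray(list(followup), dtype=float)
    if b.shape != f.shape or b.size < 2:
        raise ValidationError("need ≥2 matched baseline/followup pairs")
    if method == "ttest":
        res = stats.ttest_rel(f, b, alternative="greater")
        return float(res.statistic), float(res.pvalue)
    if method != "permutation":
        raise ValidationError(f"unknown method {method!r}")
    diff = f - b
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    res = stats.permutation_test(
        (diff,),
        lambda d, axis=-1: np.mean(d, axis=axis),
        permutation_type="samples",
        alternative="greater",
        n_resamples=n_resamples,
        rng=np.random.default_rng(seed),
    )
    return float(res.statistic), float(res.pvalue)
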