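"""Four-way classification of contingent schedules: FR, HS, CC, OT.

A subject's 21-entry contingent schedule is assigned exactly one label by
rules applied in strict order:

1. **Free rider (FR)** — the maximum planned contribution never exceeds a
   small fraction of the endowment (20% -> 4 tokens by default; 10% and
   30% are robustness cutoffs).
2. **Hump-shaped (HS)** — some split of the schedule into a leading and a
   trailing segment (leading length 3..18) shows a significantly positive
   Spearman correlation with others' average on the leading segment and a
   significantly negative one on the trailing segment, both at the 1%
   level: cooperation rises, then falls.
3. **Conditional cooperator (CC)** — the full 21-entry schedule has a
   significantly positive Spearman correlation at the 1% level.
4. **Other (OT)** — everything else, including unconditional cooperators
   (constant schedules have undefined correlation and can never reach CC
   or HS).

Segment correlations use exact permutation p-values for segments of eight
or fewer entries (see :mod:`coopgene.spearman`); in particular a
three-entry segment can never be significant at 1% (the smallest exact
two-sided p is 2/6), so the shortest splits never fire spuriously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pgg import ContingentSchedule, SCHEDULE_LEN, round_half_up
from .spearman import SpearmanResult, spearman_with_p

LABELS = ("CC", "HS", "FR", "OT")

__all__ = [
    "LABELS",
    "ClassifierConfig",
    "SplitDiagnostic",
    "StrategyCall",
    "CohortDistribution",
    "classify",
    "classify_cohort",
    "average_profile",
    "calls_to_frame",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable knobs of the classification algorithm.

    fr_fraction : fraction of the endowment defining the FR ceiling
        (ceiling = round-half-up(fr_fraction * tokens); 0.20 -> 4 tokens).
    alpha : significance level for all Spearman tests (1%).
    min_segment : shortest segment allowed on either side of a split.
    two_sided : use two-sided p-values with a sign requirement (default);
        when False, directional one-sided tails are used instead.
    """

    fr_fraction: float = 0.20
    alpha: float = 0.01
    min_segment: int = 3
    two_sided: bool = True
    tokens: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.fr_fraction < 1:
            raise ValueError("fr_fraction must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_segment < 2:
            raise ValueError("min_segment must be >= 2")

    @property
    def fr_ceiling_tokens(self) -> int:
        return round_half_up(self.fr_fraction * self.tokens)


@dataclass(frozen=True)
class SplitDiagnostic:
    """Spearman diagnostics for one split of the schedule.

    ``split_index`` k means the leading segment covers others' averages
    0..k-1 and the trailing segment k..20.  Correlations on a constant
    segment are undefined (rho/p = nan, defined flag False).
    """

    split_index: int
    rho_first: float
    p_first: float
    first_defined: bool
    rho_second: float
    p_second: float
    second_defined: bool
    hump_flag: bool


@dataclass(frozen=True)
class StrategyCall:
    """Classification label plus the full diagnostic trace."""

    label: str
    fr_ceiling_tokens: int
    full_rho: float
    full_p: float
    full_defined: bool
    splits: tuple[SplitDiagnostic, ...] = field(repr=False)

    @property
    def hump_splits(self) -> tuple[int, ...]:
        return tuple(s.split_index for s in self.splits if s.hump_flag)


def _segment_test(x, y, sign: int, config: ClassifierConfig) -> SpearmanResult:
    if config.two_sided:
        return spearman_with_p(x, y, alternative="two-sided")
    return spearman_with_p(x, y, alternative="greater" if sign > 0 else "less")


def classify(
    schedule: ContingentSchedule | Sequence[int],
    config: ClassifierConfig = ClassifierConfig(),
) -> StrategyCall:
    """Classify one contingent schedule, always returning a full trace."""
    if not isinstance(schedule, ContingentSchedule):
        schedule = ContingentSchedule(tuple(schedule))
    y = schedule.as_array()
    x = np.arange(SCHEDULE_LEN)

    full = _segment_test(x, y, +1, config)

    splits = []
    lo, hi = config.min_segment, SCHEDULE_LEN - config.min_segment
    for k in range(lo, hi + 1):
        first = _segment_test(x[:k], y[:k], +1, config)
        second = _segment_test(x[k:], y[k:], -1, config)
        hump = first.significant(config.alpha, +1) and second.significant(
            config.alpha, -1
        )
        splits.append(
            SplitDiagnostic(
                split_index=k,
                rho_first=first.rho,
                p_first=first.p,
                first_defined=first.defined,
                rho_second=second.rho,
                p_second=second.p,
                second_defined=second.defined,
                hump_flag=hump,
            )
        )

    if int(y.max()) <= config.fr_ceiling_tokens:
        label = "FR"
    elif any(s.hump_flag for s in splits):
        label = "HS"
    elif full.significant(config.alpha, +1):
        label = "CC"
    else:
        label = "OT"

    return StrategyCall(
        label=label,
        fr_ceiling_tokens=config.fr_ceiling_tokens,
        full_rho=full.rho,
        full_p=full.p,
        full_defined=full.defined,
        splits=tuple(splits),
    )


@dataclass(frozen=True)
class CohortDistribution:
    """Per-subject calls plus the label distribution of a cohort."""

    calls: tuple[StrategyCall, ...]
    counts: dict[str, int]
    percentages: dict[str, float]

    @property
    def n(self) -> int:
        return len(self.calls)


def classify_cohort(
    schedules: Iterable[ContingentSchedule | Sequence[int]],
    config: ClassifierConfig = ClassifierConfig(),
) -> CohortDistribution:
    """Classify every schedule and tabulate the label distribution.

    Percentages are over all classified subjects, reported to two decimals.
    """
    calls = tuple(classify(s, config) for s in schedules)
    if not calls:
        raise ValueError("cannot classify an empty cohort")
    counts = {lab: 0 for lab in LABELS}
    for c in calls:
        counts[c.label] += 1
    n = len(calls)
    percentages = {lab: round(100.0 * counts[lab] / n, 2) for lab in LABELS}
    return CohortDistribution(calls=calls, counts=counts, percentages=percentages)


def average_profile(
    calls: Sequence[StrategyCall],
    schedules: Sequence[ContingentSchedule | Sequence[int]],
    labels: Sequence[str] = LABELS,
) -> dict[str, np.ndarray]:
    """Entrywise mean schedule per label; labels with no subjects are absent
    from the result rather than reported as zeros."""
    if len(calls) != len(schedules):
        raise ValueError("calls and schedules must align")
    arrays: dict[str, list[np.ndarray]] = {lab: [] for lab in labels}
    for call, sched in zip(calls, schedules):
        if call.label in arrays:
            if not isinstance(sched, ContingentSchedule):
                sched = ContingentSchedule(tuple(sched))
            arrays[call.label].append(sched.as_array())
    return {
        lab: np.mean(group, axis=0) for lab, group in arrays.items() if group
    }


def calls_to_frame(ids: Sequence, calls: Sequence[StrategyCall]) -> pd.DataFrame:
    """Flatten calls into one row per subject for TSV export.

    The "best split" columns show the first qualifying hump split when one
    exists, otherwise NaN.
    """
    rows = []
    for sid, call in zip(ids, calls):
        best = next((s for s in call.splits if s.hump_flag), None)
        rows.append(
            {
                "id": sid,
                "label": call.label,
                "fr_ceiling": call.fr_ceiling_tokens,
                "full_rho": call.full_rho,
                "full_p": call.full_p,
                "best_split": best.split_index if best else np.nan,
                "best_split_rho_first": best.rho_first if best else np.nan,
                "best_split_p_first": best.p_first if best else np.nan,
                "best_split_rho_second": best.rho_second if best else np.nan,
                "best_split_p_second": best.p_second if best else np.nan,
            }
        )
    return pd.DataFrame(rows)
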