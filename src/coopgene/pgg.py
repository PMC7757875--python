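"""Four-player linear public-goods game with strategy-method elicitation.

Each of four group members holds an endowment of 20 tokens (worth 250 CLP
each).  Tokens contributed to the common pot are doubled and split equally,
so every member receives back half of the total contribution:

    payoff_i = (tokens - g_i + 0.5 * sum_j g_j) * token_value

The marginal private return of a contributed token (0.5) is below the
marginal return of a kept token (1), so free riding dominates for a selfish
payoff maximizer, while the group as a whole earns most at full
contribution -- the defining tension of a social dilemma.

The strategy method elicits two decisions per subject: an *uninformed*
contribution (chosen with no information about the group) and a 21-entry
*contingent schedule* giving the planned contribution for every possible
rounded average contribution (0..20) of the other three members.  A group
is resolved by averaging three members' uninformed contributions and
letting the fourth member's schedule respond; either decision may determine
earnings, which makes both incentive compatible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

GROUP_SIZE = 4
SCHEDULE_LEN = 21

__all__ = [
    "GROUP_SIZE",
    "SCHEDULE_LEN",
    "Endowment",
    "ContingentSchedule",
    "Decision",
    "GroupOutcome",
    "payoff",
    "resolve_group",
    "marginal_gain_check",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero upward (8.5 -> 9).

    Python's built-in ``round`` uses banker's rounding; the experimental
    software convention is everyday half-up rounding, which only differs on
    exact .5 averages.
    """
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class Endowment:
    """Game constants: endowment size, token value, and per-member return.

    ``multiplier_return`` is the fraction of the group pot each member
    receives (0.5 here: contributions doubled, split among four).  The
    social-dilemma condition 1/group_size < multiplier_return < 1 must
    hold, otherwise contributing is either dominant or strictly wasteful.
    """

    tokens: int = 20
    token_value: int = 250
    multiplier_return: float = 0.5

    def __post_init__(self) -> None:
        if self.tokens <= 0:
            raise ValueError("tokens must be positive")
        if self.token_value <= 0:
            raise ValueError("token_value must be positive")
        if not (1.0 / GROUP_SIZE < self.multiplier_return < 1.0):
            raise ValueError(
                "multiplier_return must lie strictly between "
                f"1/{GROUP_SIZE} and 1 for a social dilemma, got "
                f"{self.multiplier_return}"
            )


@dataclass(frozen=True)
class ContingentSchedule:
    """A 21-entry contingent plan: entries[x] is the planned own contribution
    when the rounded average contribution of the others is x tokens."""

    entries: tuple[int, ...]

    def __post_init__(self) -> None:
        entries = tuple(int(e) for e in self.entries)
        if len(entries) != SCHEDULE_LEN:
            raise ValueError(
                f"schedule must have {SCHEDULE_LEN} entries, got {len(entries)}"
            )
        if any(e < 0 or e > 20 for e in entries):
            raise ValueError("schedule entries must lie in [0, 20]")
        object.__setattr__(self, "entries", entries)

    def __getitem__(self, idx: int) -> int:
        return self.entries[idx]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.entries, dtype=int)


@dataclass(frozen=True)
class Decision:
    """One subject's pair of strategy-method decisions."""

    uninformed: int
    schedule: ContingentSchedule

    def __post_init__(self) -> None:
        if not 0 <= int(self.uninformed) <= 20:
            raise ValueError("uninformed contribution must lie in [0, 20]")
        object.__setattr__(self, "uninformed", int(self.uninformed))


@dataclass(frozen=True)
class GroupOutcome:
    """Resolved four-player group: realized contributions and CLP payoffs."""

    contributions: tuple[int, int, int, int]
    responder_index: int
    others_average: int
    payoffs_clp: tuple[Fraction, Fraction, Fraction, Fraction] = field(repr=False)


def payoff(
    own_contribution: int,
    group_contributions: Sequence[int],
    endowment: Endowment = Endowment(),
) -> Fraction:
    """CLP payoff of one member given all four realized contributions.

    The sum runs over the whole group including the member themself.
    Returned as an exact Fraction (a multiple of half a token value) so the
    group accounting identity holds without float drift; with the default
    250-CLP token every payoff is an integer multiple of 125 CLP.
    """
    group = [int(g) for g in group_contributions]
    if len(group) != GROUP_SIZE:
        raise ValueError(f"need exactly {GROUP_SIZE} group contributions")
    own = int(own_contribution)
    if own not in group:
        raise ValueError("own_contribution must be one of group_contributions")
    for i, g in enumerate(group):
        if not 0 <= g <= endowment.tokens:
            raise ValueError(
                f"contribution of member {i} ({g}) outside [0, {endowment.tokens}]"
            )
    ret = Fraction(endowment.multiplier_return).limit_denominator(10**6)
    value = (endowment.tokens - own + ret * sum(group)) * endowment.token_value
    return Fraction(value)


def resolve_group(
    decisions: Sequence[Decision],
    responder_index: int,
    endowment: Endowment = Endowment(),
    rounding=round_half_up,
) -> GroupOutcome:
    """Resolve a four-player group with one schedule-bound responder.

    The three non-responders contribute their uninformed amounts; their
    average, rounded to an integer (half-up by default, configurable), is
    looked up in the responder's contingent schedule.
    """
    if len(decisions) != GROUP_SIZE:
        raise ValueError(f"need exactly {GROUP_SIZE} decisions")
    if responder_index not in range(GROUP_SIZE):
        raise ValueError("responder_index must be in {0,1,2,3}")
    others = [
        d.uninformed for i, d in enumerate(decisions) if i != responder_index
    ]
    others_average = rounding(sum(others) / len(others))
    contributions = [d.uninformed for d in decisions]
    contributions[responder_index] = decisions[responder_index].schedule[
        others_average
    ]
    payoffs = tuple(payoff(g, contributions, endowment) for g in contributions)
    return GroupOutcome(
        contributions=tuple(contributions),
        responder_index=responder_index,
        others_average=others_average,
        payoffs_clp=payoffs,
    )


def marginal_gain_check(endowment: Endowment = Endowment()) -> tuple[float, float]:
    """Marginal gain of contributing one token vs keeping it: (return, 1).

    Asserts the free-riding dominance condition gain_contribute < gain_keep,
    which the Endowment invariant already enforces.
    """
    gains = (endowment.multiplier_return, 1.0)
    assert gains[0] < gains[1]
    return gains


def play_session(
    decisions: Sequence[Decision],
    rng: np.random.Generator,
    endowment: Endowment = Endowment(),
) -> list[GroupOutcome]:
    """Randomly partition subjects into groups of four and resolve each with
    a uniformly drawn responder.  Seeded wrapper around :func:`resolve_group`.
    """
    n = len(decisions)
    if n % GROUP_SIZE != 0:
        raise ValueError("number of subjects must be a multiple of four")
    order = rng.permutation(n)
    outcomes = []
    for start in range(0, n, GROUP_SIZE):
        members = [decisions[i] for i in order[start : start + GROUP_SIZE]]
        responder = int(rng.integers(GROUP_SIZE))
        outcomes.append(resolve_group(members, responder, endowment))
    return outcomes
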