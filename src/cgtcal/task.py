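"""Children's Gambling Task (CGT) engine.

The CGT is a two-deck adaptation of the Iowa Gambling Task for
preschoolers: one deck (SAFE) pays a superior average number of stickers
per card, the other (RISKY) offers larger single-card gains but an
inferior average. A session is 6 practice trials (net +4 stickers to
fund future losses), then 60 scored turns broken into 6 blocks of 10,
with a video intervention point between blocks 3 and 4. After blocks
1, 2, 4 and 5 the child estimates whether the next 10 cards will pay
MORE, about the SAME, or LESS than the previous block (or DONT_KNOW).

The sticker balance is floored at zero: a child can never hold a
negative number of stickers, so realized per-turn deltas are truncated
whenever a loss exceeds the current balance.

This module encodes those rules: deck schedules, sticker bookkeeping
with the zero floor, block structure, the practice phase, and estimate
occasions. All indexing is 1-based (turns 1-60, blocks 1-6,
occasions 1-4).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import (
    InvalidCategoryError,
    InvalidResponseError,
    MalformedBlockError,
    ScheduleExhaustedError,
)

# --------------------------------------------------------------------------
# Labels
# --------------------------------------------------------------------------

SAFE = "SAFE"
RISKY = "RISKY"
DECKS = (SAFE, RISKY)

MORE = "MORE"
SAME = "SAME"
LESS = "LESS"
DONT_KNOW = "DONT_KNOW"
CATEGORIES = (MORE, SAME, LESS, DONT_KNOW)

#: Block after which the video intervention point falls (between 3 and 4).
INTERVENTION_AFTER_BLOCK = 3

# Default card cycles. The net values (gain minus loss per card) are
# configuration, not doctrine: SAFE averages +0.6 stickers/card, RISKY
# mixes +2 gains with -4/-6 losses for an average of -0.8, preserving
# the superior-vs-inferior deck structure in integer sticker units.
DEFAULT_SAFE_CYCLE = (1, 1, 0, 1, 0, 1, 1, 0, 1, 0)
DEFAULT_RISKY_CYCLE = (2, 2, -4, 2, -6, 2, 2, -4, 2, -6)

# Six practice trials whose realized sum from a zero balance is exactly
# +4 stickers (running balance 1,2,1,2,3,4 — never negative).
DEFAULT_PRACTICE_CYCLE = (1, 1, -1, 1, 1, 1)


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DeckSchedule:
    """Ordered card values for one deck.

    Parameters
    ----------
    deck_id:
        ``"SAFE"`` or ``"RISKY"``.
    card_values:
        Ordered integer net sticker values (gain minus loss per card).
    cycle:
        Reuse the list cyclically when exhausted (default True).
    """

    deck_id: str
    card_values: tuple[int, ...]
    cycle: bool = True

    def __post_init__(self):
        if self.deck_id not in DECKS:
            raise ValueError(f"deck_id must be one of {DECKS}, got {self.deck_id!r}")
        if len(self.card_values) == 0:
            raise ValueError("card_values must be non-empty")
        values = tuple(int(v) for v in self.card_values)
        if any(v != float(orig) for v, orig in zip(values, self.card_values)):
            raise ValueError("card values must be integers")
        object.__setattr__(self, "card_values", values)
        mean = sum(values) / len(values)
        if self.deck_id == SAFE and mean <= 0:
            raise ValueError(f"SAFE deck must have positive mean payoff, got {mean}")
        if self.deck_id == RISKY and mean >= 0:
            raise ValueError(f"RISKY deck must have negative mean payoff, got {mean}")


def default_safe_schedule() -> DeckSchedule:
    return DeckSchedule(SAFE, DEFAULT_SAFE_CYCLE, cycle=True)


def default_risky_schedule() -> DeckSchedule:
    return DeckSchedule(RISKY, DEFAULT_RISKY_CYCLE, cycle=True)


@dataclass(frozen=True)
class GameConfig:
    """Structural parameters of one CGT session.

    Defaults reproduce the study protocol: 6 blocks of 10 turns, 6
    practice trials netting +4 stickers, and performance estimates
    elicited after blocks 1, 2, 4 and 5. ``card_order_seed``, when set,
    applies a deterministic seeded permutation to each deck's card
    cycle (modelling the randomized deck setup); ``None`` keeps the
    listed order.
    """

    n_blocks: int = 6
    turns_per_block: int = 10
    n_practice: int = 6
    practice_net_gain: int = 4
    practice_values: tuple[int, ...] = DEFAULT_PRACTICE_CYCLE
    estimate_occasions: tuple[int, ...] = (1, 2, 4, 5)
    safe_schedule: DeckSchedule = field(default_factory=default_safe_schedule)
    risky_schedule: DeckSchedule = field(default_factory=default_risky_schedule)
    card_order_seed: int | None = None

    def __post_init__(self):
        if self.n_blocks < 1 or self.turns_per_block < 1:
            raise ValueError("n_blocks and turns_per_block must be positive")
        occ = tuple(int(o) for o in self.estimate_occasions)
        if any(b <= a for a, b in zip(occ, occ[1:])):
            raise ValueError("estimate_occasions must be strictly increasing")
        if occ and (occ[0] < 1 or occ[-1] >= self.n_blocks):
            raise ValueError(
                "estimate_occasions must lie in [1, n_blocks): each estimate "
                "predicts the block after the one it follows"
            )
        object.__setattr__(self, "estimate_occasions", occ)
        if len(self.practice_values) != self.n_practice:
            raise ValueError("practice_values length must equal n_practice")

    @property
    def n_turns(self) -> int:
        return self.n_blocks * self.turns_per_block

    def effective_schedule(self, deck: str) -> DeckSchedule:
        """Deck schedule with the card-order permutation applied, if any."""
        sched = self.safe_schedule if deck == SAFE else self.risky_schedule
        if self.card_order_seed is None:
            return sched
        rng = np.random.default_rng(
            (self.card_order_seed, 0 if deck == SAFE else 1)
        )
        perm = rng.permutation(len(sched.card_values))
        return replace(sched, card_values=tuple(sched.card_values[i] for i in perm))


@dataclass(frozen=True)
class TurnRecord:
    """One card draw: what was chosen, what the card said, what stuck."""

    turn_index: int
    block_index: int
    deck: str
    raw_value: int
    realized_delta: int
    balance_after: int

    def __post_init__(self):
        if self.balance_after < 0:
            raise ValueError("balance_after must be non-negative")


@dataclass(frozen=True)
class BlockSummary:
    """Per 10-turn block aggregate used by the calibration measures."""

    block_index: int
    n_safe: int
    relative_safe: float
    block_payoff: int
    balance_end: int


@dataclass(frozen=True)
class EstimateRecord:
    """One performance-estimate elicitation.

    ``reference_block`` is the block the child just finished;
    ``target_block`` (= reference + 1) is the block the estimate
    predicts.
    """

    occasion: int
    category: str
    reference_block: int
    target_block: int

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise InvalidCategoryError(
                f"unknown estimate category {self.category!r}; expected one of {CATEGORIES}"
            )
        if self.target_block != self.reference_block + 1:
            raise ValueError("target_block must equal reference_block + 1")


@dataclass
class SessionState:
    """Mutable per-session bookkeeping: balance, draw counters, turn index."""

    balance: int = 0
    draw_counts: dict = field(default_factory=lambda: {SAFE: 0, RISKY: 0})
    turn_index: int = 0

    def check(self):
        assert self.balance >= 0, "balance must never go negative"
        assert sum(self.draw_counts.values()) == self.turn_index


@dataclass
class ParticipantSession:
    """One complete simulated or ingested session plus covariates.

    ``arm`` is 1 for the intervention group, 0 for controls. ``female``
    and ``age_group`` are binary indicators (age_group = 1 for children
    aged 5y0m, i.e. 60 months, or older).
    """

    participant_id: str
    arm: int
    female: int
    age_months: int
    age_group: int
    start_balance: int
    turns: list[TurnRecord]
    blocks: list[BlockSummary]
    estimates: list[EstimateRecord]
    intervention_after_block: int = INTERVENTION_AFTER_BLOCK

    @property
    def final_balance(self) -> int:
        return self.turns[-1].balance_after if self.turns else self.start_balance

    def block_payoff(self, block_index: int) -> int:
        for b in self.blocks:
            if b.block_index == block_index:
                return b.block_payoff
        from .errors import IncompleteSessionError

        raise IncompleteSessionError(
            f"participant {self.participant_id}: no payoff for block {block_index}"
        )


class Cohort:
    """An ordered collection of :class:`ParticipantSession`."""

    def __init__(self, sessions: Sequence[ParticipantSession]):
        self.sessions = list(sessions)

    def __len__(self):
        return len(self.sessions)

    def __iter__(self):
        return iter(self.sessions)

    def __getitem__(self, i):
        return self.sessions[i]


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def realized_delta(balance_before: int, raw_value: int) -> tuple[int, int]:
    """Apply one card to a sticker balance under the zero floor.

    Returns ``(realized, balance_after)`` with
    ``balance_after = max(0, balance_before + raw_value)`` and
    ``realized = balance_after - balance_before``. The realized delta
    equals the raw card value unless the floor binds, in which case it
    is truncated to ``-balance_before``.
    """
    if balance_before < 0:
        raise ValueError("balance_before must be non-negative")
    balance_after = max(0, balance_before + raw_value)
    return balance_after - balance_before, balance_after


def draw_card(schedule: DeckSchedule, draw_count: int) -> int:
    """Value of the next card from ``schedule`` after ``draw_count`` prior draws."""
    if draw_count < 0:
        raise ValueError("draw_count must be non-negative")
    n = len(schedule.card_values)
    if schedule.cycle:
        return schedule.card_values[draw_count % n]
    if draw_count >= n:
        raise ScheduleExhaustedError(
            f"{schedule.deck_id} schedule of length {n} exhausted at draw {draw_count}"
        )
    return schedule.card_values[draw_count]


def play_block(
    state: SessionState,
    choices: Sequence[str],
    config: GameConfig,
    turns_out: list[TurnRecord] | None = None,
) -> BlockSummary:
    """Play one block of deck choices, mutating ``state``.

    ``choices`` must contain exactly ``config.turns_per_block`` deck
    labels. TurnRecords are appended to ``turns_out`` when given.
    """
    if len(choices) != config.turns_per_block:
        raise MalformedBlockError(
            f"block requires exactly {config.turns_per_block} choices, got {len(choices)}"
        )
    block_index = state.turn_index // config.turns_per_block + 1
    balance_start = state.balance
    n_safe = 0
    block_payoff = 0
    for deck in choices:
        if deck not in DECKS:
            raise InvalidResponseError(f"invalid deck label {deck!r}")
        sched = config.effective_schedule(deck)
        raw = draw_card(sched, state.draw_counts[deck])
        realized, after = realized_delta(state.balance, raw)
        state.draw_counts[deck] += 1
        state.turn_index += 1
        state.balance = after
        if deck == SAFE:
            n_safe += 1
        block_payoff += realized
        if turns_out is not None:
            turns_out.append(
                TurnRecord(
                    turn_index=state.turn_index,
                    block_index=block_index,
                    deck=deck,
                    raw_value=raw,
                    realized_delta=realized,
                    balance_after=after,
                )
            )
    state.check()
    assert state.balance == balance_start + block_payoff
    return BlockSummary(
        block_index=block_index,
        n_safe=n_safe,
        relative_safe=n_safe / config.turns_per_block,
        block_payoff=block_payoff,
        balance_end=state.balance,
    )


def run_practice(config: GameConfig) -> int:
    """Run the practice phase; returns the starting balance for the game.

    The practice script is constructed so its realized sum from a zero
    balance equals ``practice_net_gain`` (default +4 stickers, the
    buffer the child wins 'to pay for potential future losses').
    """
    balance = 0
    for raw in config.practice_values:
        _, balance = realized_delta(balance, raw)
    if balance != config.practice_net_gain:
        raise ValueError(
            f"practice schedule realizes {balance} stickers, expected "
            f"practice_net_gain={config.practice_net_gain}"
        )
    return balance


ChoiceSource = Callable[[int, int, SessionState], str]
EstimateSource = Callable[[int, int], str]


def run_session(
    choice_source: ChoiceSource,
    estimate_source: EstimateSource,
    config: GameConfig | None = None,
    participant_id: str = "P000",
    arm: int = 0,
    female: int = 0,
    age_months: int = 54,
    age_group: int | None = None,
) -> ParticipantSession:
    """Run one full session: practice, 60 turns in 6 blocks, estimates.

    ``choice_source(turn_index, block_index, state)`` must return a deck
    label for each of the 60 turns; ``estimate_source(occasion,
    reference_block)`` must return an estimate category at each of the
    4 estimate occasions. The intervention point (video between blocks
    3 and 4) is recorded on the session; it has no mechanical effect on
    the engine.
    """
    if config is None:
        config = GameConfig()
    if age_group is None:
        age_group = int(age_months >= 60)
    start_balance = run_practice(config)
    state = SessionState(balance=start_balance)
    turns: list[TurnRecord] = []
    blocks: list[BlockSummary] = []
    estimates: list[EstimateRecord] = []
    occasion = 0
    for block_index in range(1, config.n_blocks + 1):
        choices = [
            choice_source(state.turn_index + k + 1, block_index, state)
            for k in range(config.turns_per_block)
        ]
        blocks.append(play_block(state, choices, config, turns_out=turns))
        if block_index in config.estimate_occasions:
            occasion += 1
            category = estimate_source(occasion, block_index)
            if category not in CATEGORIES:
                raise InvalidResponseError(
                    f"estimate provider returned invalid category {category!r}"
                )
            estimates.append(
                EstimateRecord(
                    occasion=occasion,
                    category=category,
                    reference_block=block_index,
                    target_block=block_index + 1,
                )
            )
    session = ParticipantSession(
        participant_id=participant_id,
        arm=arm,
        female=female,
        age_months=age_months,
        age_group=age_group,
        start_balance=start_balance,
        turns=turns,
        blocks=blocks,
        estimates=estimates,
    )
    # conservation: final balance = practice gain + sum of realized deltas
    assert session.final_balance == start_balance + sum(
        t.realized_delta for t in turns
    )
    return session


# --------------------------------------------------------------------------
# CSV dialect (long format, RFC-4180, UTF-8, header mandatory)
# --------------------------------------------------------------------------

TURN_COLUMNS = [
    "participant_id",
    "arm",
    "female",
    "age_months",
    "age_group",
    "block",
    "turn",
    "deck",
    "raw_value",
    "realized_delta",
    "balance_after",
]
ESTIMATE_COLUMNS = ["participant_id", "occasion", "category"]
COVARIATE_COLUMNS = [
    "participant_id",
    "arm",
    "female",
    "age_months",
    "age_group",
    "start_balance",
]


def write_turns_csv(cohort: Cohort, path) -> None:
    """Write per-turn long-format CSV for a cohort."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(TURN_COLUMNS)
        for s in cohort:
            for t in s.turns:
                w.writerow(
                    [
                        s.participant_id,
                        s.arm,
                        s.female,
                        s.age_months,
                        s.age_group,
                        t.block_index,
                        t.turn_index,
                        t.deck,
                        t.raw_value,
                        t.realized_delta,
                        t.balance_after,
                    ]
                )


def write_estimates_csv(cohort: Cohort, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(ESTIMATE_COLUMNS)
        for s in cohort:
            for e in s.estimates:
                w.writerow([s.participant_id, e.occasion, e.category])


def write_covariates_csv(cohort: Cohort, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(COVARIATE_COLUMNS)
        for s in cohort:
            w.writerow(
                [s.participant_id, s.arm, s.female, s.age_months, s.age_group, s.start_balance]
            )
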