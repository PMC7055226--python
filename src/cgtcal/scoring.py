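"""Confidence-calibration scoring and model-table assembly.

Each estimate occasion is scored against the realized payoff change
``delta = payoff(target block) - payoff(reference block)``, both on the
floored sticker scale the child actually observes:

* **Overconfidence** (binary): 1 when the child predicted MORE but the
  change was negative, or predicted SAME but lost more than one
  sticker; otherwise 0. DONT_KNOW acknowledges the uncertainty and is
  always scored 0 — a deliberately conservative coding.
* **Miscalibration** (trinary, -1/0/+1): +1 under the overconfidence
  conditions; -1 (underconfidence) when the child predicted LESS but
  actually won more, or predicted SAME but won more than one sticker.

SAME is taken as a +/- 1 sticker band, so |delta| <= 1 counts as
calibrated. Boundary cases score 0: MORE with delta == 0 is not
overconfident ("negative" is strict) and LESS with delta == 0 is not
underconfident ("won more" is strict).

The module also assembles the three model-ready long tables: 6 rows
per participant for relative safe-card selection and block payoffs,
4 rows per participant for the calibration scores.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .errors import (
    IncompleteCovariatesError,
    IncompleteSessionError,
    InvalidCategoryError,
    UndefinedCorrelationError,
)
from .task import CATEGORIES, DONT_KNOW, LESS, MORE, SAME, Cohort, ParticipantSession


@dataclass(frozen=True)
class CalibrationScore:
    """Scored estimate occasion.

    ``delta`` is the realized sticker change between the target and
    reference blocks; invariant: ``overconfidence == max(0,
    miscalibration)``.
    """

    occasion: int
    delta: int
    overconfidence: int
    miscalibration: int

    def __post_init__(self):
        assert self.overconfidence == max(0, self.miscalibration)


def _check_category(category: str) -> None:
    if category not in CATEGORIES:
        raise InvalidCategoryError(
            f"unknown estimate category {category!r}; expected one of {CATEGORIES}"
        )


def score_overconfidence(category: str, delta: int) -> int:
    """Binary overconfidence score for one estimate.

    1 iff (MORE and delta < 0) or (SAME and delta < -1); else 0.
    """
    _check_category(category)
    if category == MORE and delta < 0:
        return 1
    if category == SAME and delta < -1:
        return 1
    return 0


def score_miscalibration(category: str, delta: int) -> int:
    """Trinary miscalibration score: -1 underconfident, 0 calibrated, +1 overconfident."""
    _check_category(category)
    if score_overconfidence(category, delta) == 1:
        return 1
    if category == LESS and delta > 0:
        return -1
    if category == SAME and delta > 1:
        return -1
    return 0


def score_session(session: ParticipantSession) -> list[CalibrationScore]:
    """Score every estimate occasion of a session against realized payoffs."""
    scores = []
    for est in session.estimates:
        delta = session.block_payoff(est.target_block) - session.block_payoff(
            est.reference_block
        )
        scores.append(
            CalibrationScore(
                occasion=est.occasion,
                delta=delta,
                overconfidence=score_overconfidence(est.category, delta),
                miscalibration=score_miscalibration(est.category, delta),
            )
        )
    return scores


def correlate_measures(overconfidence, miscalibration) -> float:
    """Pearson r between the two calibration scores over all participant x occasion pairs."""
    x = pd.Series(overconfidence, dtype=float)
    y = pd.Series(miscalibration, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired inputs must have equal length")
    if len(x) < 2 or x.nunique() < 2 or y.nunique() < 2:
        raise UndefinedCorrelationError(
            "Pearson r requires >= 2 paired, non-constant observations"
        )
    return float(stats.pearsonr(x, y).statistic)


_COVARIATES = ("arm", "female", "age_group")


def build_model_tables(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Assemble the three model-ready long tables.

    Returns a dict with keys ``relative_safe`` (one row per participant
    x block, outcome ``relative_safe``), ``payoffs`` (per participant x
    block, outcome ``payoff``) and ``overconfidence`` (per participant
    x estimate occasion, outcomes ``overconfidence`` and
    ``miscalibration`` plus the realized ``delta``). All tables carry
    participant_id, intervention, female, age_group, and a 1-based
    ``time`` index (block for the block-level tables, occasion for the
    calibration table).
    """
    safe_rows, payoff_rows, over_rows = [], [], []
    for s in cohort:
        for cov in _COVARIATES:
            if getattr(s, cov, None) is None:
                raise IncompleteCovariatesError(
                    f"participant {s.participant_id}: missing covariate {cov!r}"
                )
        base = {
            "participant_id": s.participant_id,
            "intervention": s.arm,
            "female": s.female,
            "age_group": s.age_group,
        }
        if len(s.blocks) < max((e.target_block for e in s.estimates), default=0):
            raise IncompleteSessionError(
                f"participant {s.participant_id}: estimates reference missing blocks"
            )
        for b in s.blocks:
            safe_rows.append({**base, "time": b.block_index, "relative_safe": b.relative_safe})
            payoff_rows.append({**base, "time": b.block_index, "payoff": b.block_payoff})
        for sc in score_session(s):
            over_rows.append(
                {
                    **base,
                    "time": sc.occasion,
                    "delta": sc.delta,
                    "overconfidence": sc.overconfidence,
                    "miscalibration": sc.miscalibration,
                }
            )
    return {
        "relative_safe": pd.DataFrame(safe_rows),
        "payoffs": pd.DataFrame(payoff_rows),
        "overconfidence": pd.DataFrame(over_rows),
    }


def write_model_tables(tables: dict[str, pd.DataFrame], directory) -> dict[str, str]:
    """Write each model table as CSV under ``directory``; returns the paths."""
    import os

    paths = {}
    for name, df in tables.items():
        path = os.path.join(directory, f"table_{name}.csv")
        df.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)
        paths[name] = path
    return paths
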