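"""Cognitive-score bookkeeping over the treatment period.

Each participant carries two assessments (an MMSE-like and an ADAS-like
instrument) at the start and end of a non-pharmacological treatment (NPT)
period, and one MEG recording somewhere in between.  The score at the
recording day is not observed, so it is estimated with a piecewise-linear
model: scores are assumed flat between the initial assessment and the first
treatment day, and to change linearly across the treatment period.

Derived quantities:

* **outcome** (Score Change): last minus initial score,
* **estimated score**: the linear model evaluated at the MEG day,
* **estimated score change**: last minus estimated score — the part of the
  outcome that accrues after the recording,
* NPT covariates: period length A (days), session count B, and session
  frequency C = B / A (sessions per day).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ParticipantTimeline",
    "ScoreDerivatives",
    "outcome",
    "estimated_score",
    "estimated_score_change",
    "npt_covariates",
    "derive_scores",
]


@dataclass(frozen=True)
class ParticipantTimeline:
    """Calendar anchors and score pair for one participant and instrument.

    Days are integer offsets from an arbitrary epoch; every derived quantity
    is invariant to a global shift.  ``instrument`` is ``"mmse"``-like
    (0–30, higher is better) or ``"adas"``-like (nonnegative, higher is
    worse).
    """

    participant_id: str
    instrument: str
    initial_score: float
    last_score: float
    day_initial_assessment: int
    day_first_npt: int
    day_meg: int
    day_last_assessment: int
    n_sessions: int

    def __post_init__(self) -> None:
        if not self.day_initial_assessment <= self.day_first_npt:
            raise ValueError("initial assessment must not follow the first NPT day")
        if not self.day_first_npt < self.day_last_assessment:
            raise ValueError("NPT period must have positive length")
        if self.day_meg < self.day_initial_assessment:
            raise ValueError("MEG day precedes the initial assessment")
        if self.n_sessions < 0:
            raise ValueError("n_sessions must be >= 0")
        if self.instrument == "mmse" and not 0 <= self.initial_score <= 30:
            raise ValueError("MMSE-like scores must lie in [0, 30]")
        if self.instrument == "mmse" and not 0 <= self.last_score <= 30:
            raise ValueError("MMSE-like scores must lie in [0, 30]")
        if self.instrument == "adas" and (self.initial_score < 0 or self.last_score < 0):
            raise ValueError("ADAS-like scores must be >= 0")


@dataclass(frozen=True)
class ScoreDerivatives:
    outcome: float
    estimated_score: float
    estimated_score_change: float
    npt_period_days: int
    npt_frequency: float


def outcome(t: ParticipantTimeline) -> float:
    """Score Change: last minus initial (positive means the score rose)."""
    return t.last_score - t.initial_score


def estimated_score(t: ParticipantTimeline) -> float:
    """Score at the MEG day under the piecewise-linear model.

    Flat before the first treatment day (a recording taken before treatment
    starts is assigned the initial score), then linear from initial to last
    across the treatment period.  A recording after the last assessment is
    capped at that day with a warning.
    """
    if t.day_meg <= t.day_first_npt:
        return t.initial_score
    day = t.day_meg
    if day > t.day_last_assessment:
        warnings.warn(
            f"{t.participant_id}: MEG day {day} after last assessment "
            f"{t.day_last_assessment}; capped",
            stacklevel=2,
        )
        day = t.day_last_assessment
    period = t.day_last_assessment - t.day_first_npt
    frac = (day - t.day_first_npt) / period
    return t.initial_score + (t.last_score - t.initial_score) * frac


def estimated_score_change(t: ParticipantTimeline) -> float:
    """Last minus estimated score: the outcome accrued after the recording."""
    return t.last_score - estimated_score(t)


def npt_covariates(t: ParticipantTimeline) -> tuple[int, int, float]:
    """(A, B, C): period days, session count, and sessions per day B/A."""
    period = t.day_last_assessment - t.day_first_npt
    if period <= 0:
        raise ValueError("NPT period must be positive")
    if t.n_sessions < 0:
        raise ValueError("n_sessions must be >= 0")
    return period, t.n_sessions, t.n_sessions / period


def derivatives(t: ParticipantTimeline) -> ScoreDerivatives:
    est = estimated_score(t)
    period, _, freq = npt_covariates(t)
    return ScoreDerivatives(
        outcome=outcome(t),
        estimated_score=est,
        estimated_score_change=t.last_score - est,
        npt_period_days=period,
        npt_frequency=freq,
    )


_TABLE_COLUMNS = {
    "participant_id": "participant_id",
    "instrument": "instrument",
    "initial_score": "initial_score",
    "last_score": "last_score",
    "day_initial": "day_initial_assessment",
    "day_first_npt": "day_first_npt",
    "day_meg": "day_meg",
    "day_last": "day_last_assessment",
    "n_sessions": "n_sessions",
}


def derive_scores(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append the derived score columns to a long-format cohort table.

    Expects the columns ``participant_id, instrument, initial_score,
    last_score, day_initial, day_first_npt, day_meg, day_last, n_sessions``;
    adds ``outcome, estimated_score, estimated_score_change,
    npt_period_days, npt_frequency``.
    """
    missing = set(_TABLE_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    out = cohort.copy()
    derived = []
    for _, row in cohort.iterrows():
        t = ParticipantTimeline(**{arg: row[col] for col, arg in _TABLE_COLUMNS.items()})
        derived.append(derivatives(t))
    out["outcome"] = [d.outcome for d in derived]
    out["estimated_score"] = [d.estimated_score for d in derived]
    out["estimated_score_change"] = [d.estimated_score_change for d in derived]
    out["npt_period_days"] = [d.npt_period_days for d in derived]
    out["npt_frequency"] = [d.npt_frequency for d in derived]
    return out
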