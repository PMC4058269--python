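"""Per-subject, per-session dependent variables of the PDT.

An event log is reduced to one row per subject × session carrying:

* ``pref_LLL`` — %LLL choices over total completed choices (gambling
  proneness);
* ``trials_per_min`` / ``pellets_per_min`` — throughput over the nominal
  session duration;
* ``persistence`` — mean inadequate pokes per trial toward the LLL hole
  (perseveration / cognitive inflexibility);
* ``restlessness`` — mean inadequate pokes per trial toward the SS hole
  (uncertainty intolerance / motor impulsivity);
* ``experienced_p`` / ``experienced_odds`` — the subject's realized delivery
  rate, experienced p = 100 * successful LLL / total LLL, and the
  corresponding odds, (100 / experienced p) − 1. Because delivery is drawn
  independently per trial, the experienced schedule fluctuates around the set
  one; the slope analysis regresses preference on *experienced* odds to
  normalize against this subjective impact of uncertainty.

Sessions with no LLL choice, or whose LLL choices were never rewarded, have
undefined experienced odds; they are reported as missing (with a warning) and
the downstream fit excludes them rather than inventing a capped value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, fields
from pathlib import Path
from typing import Optional, Sequence, Union

import math

import numpy as np
import pandas as pd

from .cohort import TrialRecord
from .protocol import ProtocolConfig

__all__ = [
    "SessionMetrics",
    "session_metrics",
    "experienced_probability",
    "experienced_odds",
    "cohort_metrics",
    "write_metrics",
    "read_metrics",
]

METRICS_COLUMNS = (
    "subject_id",
    "species",
    "session_index",
    "p_set",
    "n_trials",
    "pref_LLL",
    "trials_per_min",
    "pellets_per_min",
    "persistence",
    "restlessness",
    "experienced_p",
    "experienced_odds",
)


@dataclass(frozen=True)
class SessionMetrics:
    """Dependent variables of one subject × session; None marks missing."""

    subject_id: Optional[str]
    species: Optional[str]
    session_index: Optional[int]
    p_set: Optional[float]
    n_trials: int
    pref_LLL: Optional[float]
    trials_per_min: float
    pellets_per_min: float
    persistence: Optional[float]
    restlessness: Optional[float]
    experienced_p: Optional[float]
    experienced_odds: Optional[float]


def experienced_probability(successful_LLL: int, total_LLL: int) -> Optional[float]:
    """Realized delivery percentage: 100 * successful LLL / total LLL.

    Returns None when the subject made no LLL choice in the session.
    """
    if successful_LLL < 0 or total_LLL < 0:
        raise ValueError("counts must be non-negative")
    if successful_LLL > total_LLL:
        raise ValueError(
            f"successful LLL trials ({successful_LLL}) cannot exceed total ({total_LLL})"
        )
    if total_LLL == 0:
        return None
    return 100.0 * successful_LLL / total_LLL


def experienced_odds(experienced_p: Optional[float]) -> Optional[float]:
    """Odds implied by a realized delivery percentage: (100 / p) − 1.

    An experienced p of zero (LLL chosen, never rewarded) has no finite odds;
    it yields None with a warning, and such sessions drop out of the
    preference–odds fit.
    """
    if experienced_p is None:
        return None
    if not (0 <= experienced_p <= 100):
        raise ValueError(f"experienced p must lie in [0, 100], got {experienced_p}")
    if experienced_p == 0:
        warnings.warn(
            "experienced p = 0 (no successful LLL delivery): experienced odds "
            "undefined, session excluded from the preference-odds fit",
            stacklevel=2,
        )
        return None
    return 100.0 / experienced_p - 1.0


def session_metrics(
    records: Sequence[TrialRecord],
    protocol: ProtocolConfig,
    *,
    subject_id: Optional[str] = None,
    species: Optional[str] = None,
    session_index: Optional[int] = None,
    p_set: Optional[float] = None,
) -> SessionMetrics:
    """Reduce the trials of one subject-session to its dependent variables.

    All records must share subject, session and set probability. The keyword
    identifiers are only needed for an empty record list (a legal zero-trial
    session, which reports zero rates and missing per-trial fields).
    """
    if records:
        keys = {(r.subject_id, r.session_index, r.p_set) for r in records}
        if len(keys) != 1:
            raise ValueError(
                f"records span multiple subject-sessions: {sorted(keys)}"
            )
        r0 = records[0]
        subject_id, species = r0.subject_id, r0.species
        session_index, p_set = r0.session_index, r0.p_set

    n = len(records)
    minutes = protocol.session_minutes
    if n == 0:
        return SessionMetrics(
            subject_id=subject_id,
            species=species,
            session_index=session_index,
            p_set=p_set,
            n_trials=0,
            pref_LLL=None,
            trials_per_min=0.0,
            pellets_per_min=0.0,
            persistence=None,
            restlessness=None,
            experienced_p=None,
            experienced_odds=None,
        )

    n_lll = sum(1 for r in records if r.choice == "LLL")
    n_lll_delivered = sum(1 for r in records if r.choice == "LLL" and r.delivered)
    exp_p = experienced_probability(n_lll_delivered, n_lll)
    with warnings.catch_warnings():
        # downstream consumers are warned once per cohort, not per session
        warnings.simplefilter("ignore")
        exp_odds = experienced_odds(exp_p)
    return SessionMetrics(
        subject_id=subject_id,
        species=species,
        session_index=session_index,
        p_set=p_set,
        n_trials=n,
        pref_LLL=100.0 * n_lll / n,
        trials_per_min=n / minutes,
        pellets_per_min=sum(r.pellets for r in records) / minutes,
        persistence=sum(r.inadequate_LLL for r in records) / n,
        restlessness=sum(r.inadequate_SS for r in records) / n,
        experienced_p=exp_p,
        experienced_odds=exp_odds,
    )


def cohort_metrics(
    event_log: Sequence[TrialRecord], protocol: ProtocolConfig
) -> pd.DataFrame:
    """Session-metrics table for a whole event log.

    One row per (subject, session) present in the log, sorted by subject then
    session, with columns mirroring :class:`SessionMetrics` (missing values
    as NaN).
    """
    groups: dict[tuple[str, int], list[TrialRecord]] = {}
    for r in event_log:
        groups.setdefault((r.subject_id, r.session_index), []).append(r)
    rows = [
        asdict(session_metrics(groups[key], protocol))
        for key in sorted(groups)
    ]
    df = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    return df.astype({"session_index": "int64", "n_trials": "int64"}) if len(df) else df


def write_metrics(metrics: pd.DataFrame, destination: Union[str, Path]) -> None:
    """Write a metrics table as CSV; missing values serialize as empty cells."""
    metrics.to_csv(destination, index=False)


def read_metrics(source: Union[str, Path]) -> pd.DataFrame:
    """Read a metrics table written by :func:`write_metrics`."""
    df = pd.read_csv(source)
    missing = set(METRICS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{source}: metrics table missing columns {sorted(missing)}")
    return df
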