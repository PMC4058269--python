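"""Synthetic cohorts: trial-level simulation of PDT sessions.

No public trial-level dataset exists for this task, so the pipeline is
validated on simulated subjects whose behaviour carries the statistical
structure the analysis assumes:

* choice: each completed trial is an LLL choice with probability
  ``clamp(a + b * log10(odds + 1), 0, 100) / 100``, where ``odds`` are the
  *set* odds of the session — preference declines linearly in log-odds, with
  subject-specific intercept ``a`` (baseline %LLL at certainty) and slope
  ``b`` (% per log10-odds unit; shallow for "gambler"-like temperaments,
  steep for "non-gambler"-like ones);
* delivery: LLL trials deliver with probability ``p_set``, independently per
  trial (SS always delivers); pellets are uniform on the configured range;
* throughput: trial counts are Poisson with rate
  ``rate_lambda * (1 + rate_compensation_c * log10(odds + 1))`` per minute,
  so ``rate_compensation_c > 0`` emulates subjects that compensate for reward
  rarefaction by completing more trials;
* frustration: inadequate (timeout-window) pokes are Poisson per trial —
  ``persistence_rho`` toward the LLL hole and ``restlessness_rho`` toward the
  SS hole on omission trials, ``background_rho`` toward each hole otherwise.

Everything is reproducible from an integer seed; per-subject, per-session
substreams are derived from the master seed so a cohort simulation is stable
under reordering of other subjects.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .protocol import ProtocolConfig, set_odds

__all__ = [
    "AgentParams",
    "TrialRecord",
    "expected_preference",
    "simulate_session",
    "simulate_cohort",
    "write_event_log",
    "read_event_log",
    "demo_cohort",
]

EVENT_LOG_COLUMNS = (
    "subject_id",
    "species",
    "session_index",
    "p_set",
    "choice",
    "delivered",
    "pellets",
    "inadequate_SS",
    "inadequate_LLL",
)


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one synthetic subject.

    ``intercept_a`` is the baseline %LLL preference at zero odds (certainty)
    and ``slope_b`` the change in %LLL per unit log10(odds + 1); a strongly
    negative slope produces the sharp shift to SS that defines the
    non-gambler phenotype. ``rate_lambda`` is the base trial rate (trials per
    minute); ``rate_compensation_c`` inflates it with rarefaction. The three
    ``*_rho`` parameters are mean inadequate-poke counts per trial in the
    post-choice timeout window (see module docstring).
    """

    subject_id: str
    species: str
    intercept_a: float
    slope_b: float
    rate_lambda: float
    rate_compensation_c: float = 0.0
    persistence_rho: float = 0.0
    restlessness_rho: float = 0.0
    background_rho: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.intercept_a <= 100):
            raise ValueError(f"intercept_a must lie in [0, 100], got {self.intercept_a}")
        for name in (
            "rate_lambda",
            "rate_compensation_c",
            "persistence_rho",
            "restlessness_rho",
            "background_rho",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class TrialRecord:
    """One completed trial of a PDT session."""

    subject_id: str
    species: str
    session_index: int
    p_set: float
    choice: str  # "SS" or "LLL"
    delivered: bool
    pellets: int
    inadequate_SS: int
    inadequate_LLL: int

    def __post_init__(self) -> None:
        if self.choice not in ("SS", "LLL"):
            raise ValueError(f"choice must be 'SS' or 'LLL', got {self.choice!r}")
        if self.choice == "SS" and not self.delivered:
            raise ValueError("SS choices always deliver")
        if self.choice == "LLL" and not self.delivered and self.pellets != 0:
            raise ValueError("omitted LLL trials deliver zero pellets")
        if self.pellets < 0 or self.inadequate_SS < 0 or self.inadequate_LLL < 0:
            raise ValueError("counts must be non-negative")


def expected_preference(agent: AgentParams, p_set: float) -> float:
    """Generative %LLL preference of ``agent`` at set probability ``p_set``."""
    x = math.log10(set_odds(p_set) + 1.0)
    return min(100.0, max(0.0, agent.intercept_a + agent.slope_b * x))


def _session_rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_session(
    agent: AgentParams,
    protocol: ProtocolConfig,
    session_index: int,
    p_set: float,
    seed: Union[int, np.random.Generator],
) -> list[TrialRecord]:
    """Simulate one session of ``agent`` under ``protocol`` at ``p_set``.

    The trial count is Poisson (free-operant responding); an empty session is
    legal and returns an empty list. Fully reproducible given ``seed``.
    """
    if not any(
        math.isclose(p_set, q, abs_tol=1e-9) for q in protocol.schedule.p_levels
    ):
        raise ValueError(
            f"p_set={p_set} is not a level of the protocol schedule "
            f"{protocol.schedule.p_levels}"
        )
    rng = _session_rng(seed)
    x = math.log10(set_odds(p_set) + 1.0)
    rate = agent.rate_lambda * (1.0 + agent.rate_compensation_c * x)
    n = int(rng.poisson(rate * protocol.session_minutes))
    if n == 0:
        return []

    pref = expected_preference(agent, p_set) / 100.0
    is_lll = rng.random(n) < pref
    delivered = np.where(is_lll, rng.random(n) < p_set, True)

    reward = protocol.reward
    small = rng.integers(reward.small_min, reward.small_max + 1, size=n)
    large = rng.integers(reward.large_min, reward.large_max + 1, size=n)
    pellets = np.where(is_lll, np.where(delivered, large, 0), small)

    omission = is_lll & ~delivered
    inad_lll = np.where(
        omission,
        rng.poisson(agent.persistence_rho, size=n),
        rng.poisson(agent.background_rho, size=n),
    )
    inad_ss = np.where(
        omission,
        rng.poisson(agent.restlessness_rho, size=n),
        rng.poisson(agent.background_rho, size=n),
    )

    return [
        TrialRecord(
            subject_id=agent.subject_id,
            species=agent.species,
            session_index=session_index,
            p_set=p_set,
            choice="LLL" if is_lll[i] else "SS",
            delivered=bool(delivered[i]),
            pellets=int(pellets[i]),
            inadequate_SS=int(inad_ss[i]),
            inadequate_LLL=int(inad_lll[i]),
        )
        for i in range(n)
    ]


def simulate_cohort(
    agents: Sequence[AgentParams],
    protocol: ProtocolConfig,
    seed: int,
) -> list[TrialRecord]:
    """Simulate every scheduled session for every agent.

    Session indices enumerate the protocol schedule in order (replicate
    sessions included). Each (subject, session) pair draws from its own
    substream derived deterministically from the master ``seed``.
    """
    ids = [a.subject_id for a in agents]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject_id(s): {dupes}")
    records: list[TrialRecord] = []
    for ai, agent in enumerate(agents):
        for si, (session_index, p_set) in enumerate(protocol.schedule.session_plan()):
            child = np.random.default_rng(np.random.SeedSequence([seed, ai, si]))
            records.extend(
                simulate_session(agent, protocol, session_index, p_set, child)
            )
    return records


# -- presets ------------------------------------------------------------------

_DEMO_RATES = {"rat": 2.4, "marmoset": 8.0}  # trials per minute


def demo_cohort(
    species: str = "rat",
    n_gambler: int = 6,
    n_non_gambler: int = 6,
) -> list[AgentParams]:
    """Demonstration cohort with two well-separated temperaments.

    Gambler-like agents keep a near-flat preference for the large reward and
    persist at the LLL hole after omissions; non-gambler-like agents shift
    steeply toward SS, show omission-induced restlessness instead, and (for
    marmosets) compensate for reward rarefaction by completing more trials.
    """
    if species not in _DEMO_RATES:
        raise ValueError(f"no demo presets for species {species!r}")
    lam = _DEMO_RATES[species]
    ng_compensation = 1.2 if species == "marmoset" else 0.2
    agents = [
        AgentParams(
            subject_id=f"{species}_g{i + 1:02d}",
            species=species,
            intercept_a=95.0,
            slope_b=-15.0,
            rate_lambda=lam,
            rate_compensation_c=0.0,
            persistence_rho=1.5,
            restlessness_rho=0.3,
            background_rho=0.2,
        )
        for i in range(n_gambler)
    ]
    agents += [
        AgentParams(
            subject_id=f"{species}_n{i + 1:02d}",
            species=species,
            intercept_a=95.0,
            slope_b=-90.0,
            rate_lambda=lam,
            rate_compensation_c=ng_compensation,
            persistence_rho=0.3,
            restlessness_rho=1.5,
            background_rho=0.2,
        )
        for i in range(n_non_gambler)
    ]
    return agents


# -- event-log I/O ------------------------------------------------------------


def write_event_log(
    records: Iterable[TrialRecord], destination: Union[str, Path]
) -> None:
    """Write trial records as a CSV event log (UTF-8, header row)."""
    with open(destination, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_LOG_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.subject_id,
                    r.species,
                    r.session_index,
                    f"{r.p_set:g}",
                    r.choice,
                    int(r.delivered),
                    r.pellets,
                    r.inadequate_SS,
                    r.inadequate_LLL,
                ]
            )


class EventLogError(ValueError):
    """Malformed event log: bad header or an invariant-violating row."""


def read_event_log(source: Union[str, Path]) -> list[TrialRecord]:
    """Read and validate a CSV event log.

    Every row is checked against the trial invariants (SS choices always
    deliver; omitted LLL trials carry zero pellets; counts non-negative);
    violations raise :class:`EventLogError` naming the offending row.
    """
    records: list[TrialRecord] = []
    with open(source, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise EventLogError(f"{source}: empty file, expected header row") from None
        if tuple(header) != EVENT_LOG_COLUMNS:
            raise EventLogError(
                f"{source}: bad header {header}; expected {list(EVENT_LOG_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(EVENT_LOG_COLUMNS):
                raise EventLogError(
                    f"{source}, row {lineno}: expected {len(EVENT_LOG_COLUMNS)} "
                    f"fields, got {len(row)}"
                )
            d = dict(zip(EVENT_LOG_COLUMNS, row))
            if d["delivered"] not in ("0", "1"):
                raise EventLogError(
                    f"{source}, row {lineno}: delivered must be 0 or 1, "
                    f"got {d['delivered']!r}"
                )
            try:
                record = TrialRecord(
                    subject_id=d["subject_id"],
                    species=d["species"],
                    session_index=int(d["session_index"]),
                    p_set=float(d["p_set"]),
                    choice=d["choice"],
                    delivered=d["delivered"] == "1",
                    pellets=int(d["pellets"]),
                    inadequate_SS=int(d["inadequate_SS"]),
                    inadequate_LLL=int(d["inadequate_LLL"]),
                )
            except ValueError as exc:
                raise EventLogError(f"{source}, row {lineno}: {exc}") from None
            records.append(record)
    return records
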