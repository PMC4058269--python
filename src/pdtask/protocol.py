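"""Task structure of the probabilistic-delivery task (PDT).

The PDT confronts a freely responding subject with two poke holes. One
("Small & Sure", SS) delivers a small food reward with certainty; the other
("Large & Luck-Linked", LLL) delivers a large reward only with a
session-specific probability ``p``. Across testing sessions ``p`` is rarefied
from certainty (100%) down to very low values, and the subject's willingness
to keep choosing LLL past the point where it stops paying off indexes
gambling proneness.

This module encodes the fixed parameters of the task — reward magnitudes, the
probability rarefaction schedule, session length and post-choice timeout —
together with their analytic consequences:

* ``set_odds``: odds against delivery at a set probability, odds = 1/p − 1,
  i.e. the mean number of omitted deliveries before a successful one.
* ``indifferent_point``: the probability at which the expected payoff of the
  large-uncertain option equals the small-certain one (the reciprocal of the
  reward-size ratio). Below it, repeatedly choosing SS is the economically
  optimal strategy.

Species presets (``default_protocol``) capture the rat and common-marmoset
variants of the task: 25-min sessions with a 15-s timeout and one session per
probability level for rats; 5-min sessions with a 6-s timeout and three
replicate sessions per level for marmosets. Both use 1–2 pellets (SS) versus
5–6 pellets (LLL) and the seven-level schedule
100% → 50% → 33% → 25% → 20% → 17% → 14%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence, TextIO, Union

import yaml

__all__ = [
    "RewardSpec",
    "ProbabilitySchedule",
    "ProtocolConfig",
    "default_protocol",
    "set_odds",
    "indifferent_point",
    "indifference_zone",
    "load_protocol",
    "save_protocol",
]

#: The standard testing-phase probability progression, in session order.
DEFAULT_P_LEVELS: tuple[float, ...] = (1.0, 0.50, 0.33, 0.25, 0.20, 0.17, 0.14)

SPECIES_PRESETS = ("rat", "marmoset")


@dataclass(frozen=True)
class RewardSpec:
    """Reward magnitudes for the two options, in pellet counts.

    ``small_min``–``small_max`` is the SS pellet range, ``large_min``–
    ``large_max`` the LLL range. ``nominal_ratio_min``/``nominal_ratio_max``
    are the declared large:small fold-ratios used for indifference-point
    arithmetic (3- to 5-fold for the default 1–2 vs 5–6 pellet task); the
    extreme ratios implied by the actual pellet ranges are available via
    :meth:`actual_ratios`.
    """

    small_min: int = 1
    small_max: int = 2
    large_min: int = 5
    large_max: int = 6
    nominal_ratio_min: float = 3.0
    nominal_ratio_max: float = 5.0

    def __post_init__(self) -> None:
        counts = (self.small_min, self.small_max, self.large_min, self.large_max)
        if not all(isinstance(c, int) and c > 0 for c in counts):
            raise ValueError(f"pellet counts must be positive integers, got {counts}")
        if not (self.small_min <= self.small_max < self.large_min <= self.large_max):
            raise ValueError(
                "reward ranges must satisfy small_min <= small_max < large_min <= large_max, "
                f"got {counts}"
            )
        if self.mean_ratio() <= 1:
            raise ValueError("mean large:small reward ratio must exceed 1")
        if not (0 < self.nominal_ratio_min <= self.nominal_ratio_max):
            raise ValueError("nominal fold-ratios must be positive and ordered")

    def mean_ratio(self) -> float:
        """Ratio of mean large to mean small reward."""
        return (self.large_min + self.large_max) / (self.small_min + self.small_max)

    def actual_ratios(self) -> tuple[float, float]:
        """Extreme fold-ratios implied by the pellet ranges themselves.

        The minimum pairs the smallest large reward with the largest small
        reward; the maximum pairs the extremes the other way (2.5 and 6.0 for
        the default 1–2 vs 5–6 task).
        """
        return (self.large_min / self.small_max, self.large_max / self.small_min)


@dataclass(frozen=True)
class ProbabilitySchedule:
    """Ordered rarefaction schedule: (set probability, replicate sessions) pairs.

    Probabilities are fractions in (0, 1], strictly decreasing across levels.
    """

    levels: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("schedule must contain at least one level")
        object.__setattr__(
            self,
            "levels",
            tuple((float(p), int(k)) for p, k in self.levels),
        )
        for p, k in self.levels:
            if not (0 < p <= 1):
                raise ValueError(f"set probability {p} outside (0, 1]")
            if k < 1:
                raise ValueError(f"sessions_per_level must be >= 1, got {k}")
        ps = [p for p, _ in self.levels]
        if any(b >= a for a, b in zip(ps, ps[1:])):
            raise ValueError(f"probability levels must be strictly decreasing, got {ps}")

    @property
    def p_levels(self) -> tuple[float, ...]:
        return tuple(p for p, _ in self.levels)

    @property
    def n_sessions(self) -> int:
        return sum(k for _, k in self.levels)

    def session_plan(self) -> Iterator[tuple[int, float]]:
        """Yield (session_index, p_set) pairs, 1-based, replicates in order."""
        idx = 0
        for p, k in self.levels:
            for _ in range(k):
                idx += 1
                yield idx, p


@dataclass(frozen=True)
class ProtocolConfig:
    """Complete parameterization of one PDT variant.

    ``inclusion_session_levels`` are the set-probability levels whose sessions
    feed the inclusion filter (the sessions before the indifferent point, by
    default p = 1.0 and 0.5); a subject must average strictly more than
    ``inclusion_threshold`` % LLL preference over them to enter the analysis.
    """

    species_label: str
    session_minutes: float
    timeout_seconds: float
    reward: RewardSpec = field(default_factory=RewardSpec)
    schedule: ProbabilitySchedule = field(
        default_factory=lambda: ProbabilitySchedule(tuple((p, 1) for p in DEFAULT_P_LEVELS))
    )
    inclusion_threshold: float = 60.0
    inclusion_session_levels: tuple[float, ...] = (1.0, 0.5)

    def __post_init__(self) -> None:
        if self.session_minutes <= 0:
            raise ValueError("session_minutes must be positive")
        if self.timeout_seconds < 0:
            raise ValueError("timeout_seconds must be non-negative")
        object.__setattr__(
            self, "inclusion_session_levels", tuple(float(p) for p in self.inclusion_session_levels)
        )
        missing = [
            p
            for p in self.inclusion_session_levels
            if not any(math.isclose(p, q, abs_tol=1e-9) for q in self.schedule.p_levels)
        ]
        if missing:
            raise ValueError(
                f"inclusion levels {missing} are not part of the schedule {self.schedule.p_levels}"
            )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schedule"] = [list(level) for level in self.schedule.levels]
        d["inclusion_session_levels"] = list(self.inclusion_session_levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        d = dict(d)
        d["reward"] = RewardSpec(**d["reward"])
        d["schedule"] = ProbabilitySchedule(tuple(tuple(level) for level in d["schedule"]))
        d["inclusion_session_levels"] = tuple(d["inclusion_session_levels"])
        return cls(**d)


def default_protocol(species_label: str) -> ProtocolConfig:
    """Return the species preset for the task.

    ``"rat"``: 25-min sessions, 15-s timeout, one session per probability
    level (7 testing sessions). ``"marmoset"``: 5-min sessions, 6-s timeout,
    three consecutive sessions per level (21 testing sessions). Both share the
    1–2 vs 5–6 pellet rewards and the seven-level rarefaction schedule.
    """
    if species_label == "rat":
        return ProtocolConfig(
            species_label="rat",
            session_minutes=25.0,
            timeout_seconds=15.0,
            schedule=ProbabilitySchedule(tuple((p, 1) for p in DEFAULT_P_LEVELS)),
        )
    if species_label == "marmoset":
        return ProtocolConfig(
            species_label="marmoset",
            session_minutes=5.0,
            timeout_seconds=6.0,
            schedule=ProbabilitySchedule(tuple((p, 3) for p in DEFAULT_P_LEVELS)),
        )
    raise ValueError(
        f"unknown species preset {species_label!r}; valid presets are {set(SPECIES_PRESETS)}"
    )


def set_odds(p: float) -> float:
    """Odds against large-reward delivery at set probability ``p``.

    odds = 1/p − 1: the mean number of omitted ("unlucky") deliveries before
    a successful ("lucky") one. Strictly decreasing in p; zero at certainty.
    """
    if not (0 < p <= 1):
        raise ValueError(f"set probability must lie in (0, 1], got {p}")
    return 1.0 / p - 1.0


def indifferent_point(reward_ratio: float) -> float:
    """Probability at which the expected LLL payoff equals the SS payoff.

    With a large reward ``reward_ratio`` times the small one, expected payoffs
    are equal when reward_ratio * p = 1, i.e. at p = 1/reward_ratio. Below
    that probability the small-certain option dominates.
    """
    if reward_ratio <= 1:
        raise ValueError(
            f"reward ratio must exceed 1 (got {reward_ratio}); otherwise the large "
            "uncertain option is never preferable"
        )
    return 1.0 / reward_ratio


def indifference_zone(reward: RewardSpec, nominal: bool = True) -> tuple[float, float]:
    """Probability band spanned by the indifferent points of a reward spec.

    Returns (p_low, p_high) = (1/r_max, 1/r_min) over the configured
    fold-ratios. With ``nominal=True`` (default) the declared nominal ratios
    are used (3–5 for the default spec, giving the 20%–33% zone); with
    ``nominal=False`` the extreme ratios of the actual pellet ranges are used.
    """
    r_min, r_max = (
        (reward.nominal_ratio_min, reward.nominal_ratio_max)
        if nominal
        else reward.actual_ratios()
    )
    return (1.0 / r_max, 1.0 / r_min)


# -- config file round trip --------------------------------------------------


def save_protocol(protocol: ProtocolConfig, destination: Union[str, Path, TextIO]) -> None:
    """Write a protocol to a human-editable YAML config file."""
    text = yaml.safe_dump(protocol.to_dict(), sort_keys=False)
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text, encoding="utf-8")


def load_protocol(source: Union[str, Path, TextIO]) -> ProtocolConfig:
    """Read a protocol from a YAML config file (inverse of :func:`save_protocol`)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    return ProtocolConfig.from_dict(yaml.safe_load(text))


def resolve_protocol(spec: Union[str, Path, ProtocolConfig]) -> ProtocolConfig:
    """Interpret a protocol argument: a preset name, a config path, or a config."""
    if isinstance(spec, ProtocolConfig):
        return spec
    if isinstance(spec, (str, Path)) and str(spec) in SPECIES_PRESETS:
        return default_protocol(str(spec))
    return load_protocol(spec)
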