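"""Phenotyping: inclusion filter, preference–odds slope, median split.

The gambling-proneness phenotype is assigned in three stages:

1. **Inclusion** — a subject enters the analysis only if its mean %LLL
   preference over the sessions before the indifferent point (set p = 1.0 and
   0.5 by default) is strictly greater than the threshold (60%): subjects
   that never acquired the large-reward preference are uninformative about
   its later erosion.
2. **Slope** — for each included subject, ordinary least squares of %LLL
   preference on log10(experienced odds + 1), one point per testing session.
   Sessions with undefined experienced odds are excluded from the fit.
   The slope (% per log10-odds unit) quantifies how steeply preference
   collapses as delivery is rarefied.
3. **Median split** — within each species, subjects with slopes strictly
   below the group median (steeper decline) are labeled ``non_gambler`` and
   those strictly above it ``gambler``. A subject sitting exactly at the
   median is assigned to the provisional group whose slopes its own value is
   closest to — by default the nearer group mean, with exact equidistance
   resolved to ``non_gambler``; ``tie_rule="nearest-neighbor"`` uses the
   nearest individual slope instead.

The labels are invariant to the base of the logarithm: changing base rescales
every slope by the same positive constant, leaving the median split intact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .protocol import ProtocolConfig

__all__ = [
    "SubjectProfile",
    "include_subject",
    "preference_odds_slope",
    "median_split",
    "classify_cohort",
    "write_profiles",
    "read_profiles",
]

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = (
    "subject_id",
    "species",
    "included",
    "exclusion_reason",
    "slope",
    "n_fit_points",
    "strategy",
)

GAMBLER = "gambler"
NON_GAMBLER = "non_gambler"


@dataclass(frozen=True)
class SubjectProfile:
    """Phenotyping outcome for one subject."""

    subject_id: str
    species: str
    included: bool
    exclusion_reason: str = ""
    slope: Optional[float] = None
    n_fit_points: int = 0
    strategy: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strategy is not None:
            if not self.included or self.slope is None:
                raise ValueError("a strategy label requires inclusion and a fitted slope")
            if self.strategy not in (GAMBLER, NON_GAMBLER):
                raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.slope is not None and self.n_fit_points < 2:
            raise ValueError("a fitted slope requires at least 2 fit points")


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def include_subject(
    metrics: pd.DataFrame, protocol: ProtocolConfig
) -> tuple[bool, str]:
    """Apply the inclusion filter to one subject's session-metrics rows.

    Mean %LLL preference over *all* sessions at the protocol's inclusion
    levels (replicates included) must strictly exceed the threshold.
    """
    prefs: list[float] = []
    for level in protocol.inclusion_session_levels:
        rows = metrics[np.isclose(metrics["p_set"].astype(float), level, atol=1e-9)]
        usable = [v for v in rows["pref_LLL"] if not _is_missing(v)]
        if not usable:
            raise ValueError(
                f"subject {_subject_of(metrics)!r}: no usable session at inclusion "
                f"level p = {level}"
            )
        prefs.extend(usable)
    mean_pref = float(np.mean(prefs))
    if mean_pref > protocol.inclusion_threshold:
        return True, ""
    return (
        False,
        f"mean pre-indifference LLL preference {mean_pref:.1f}% not above "
        f"{protocol.inclusion_threshold:g}%",
    )


def _subject_of(metrics: pd.DataFrame) -> str:
    ids = metrics["subject_id"].unique()
    return str(ids[0]) if len(ids) == 1 else str(list(ids))


def preference_odds_slope(
    metrics: pd.DataFrame, min_session_index: int = 1
) -> tuple[float, int]:
    """OLS slope of %LLL preference on log10(experienced odds + 1).

    Each testing session contributes one point; sessions with missing
    preference or experienced odds are excluded (and not counted in the
    returned number of fit points). Sessions below ``min_session_index`` are
    treated as training and ignored.
    """
    subject = _subject_of(metrics)
    rows = metrics[metrics["session_index"].astype(int) >= min_session_index]
    xs, ys = [], []
    for _, row in rows.iterrows():
        if _is_missing(row["pref_LLL"]) or _is_missing(row["experienced_odds"]):
            continue
        xs.append(math.log10(float(row["experienced_odds"]) + 1.0))
        ys.append(float(row["pref_LLL"]))
    n = len(xs)
    if n < 2:
        raise ValueError(
            f"subject {subject!r}: only {n} usable session(s) for the "
            "preference-odds fit (need at least 2)"
        )
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0:
        raise ValueError(
            f"subject {subject!r}: all usable sessions share one experienced-odds "
            "value; the preference-odds slope is undefined"
        )
    slope, _ = np.polyfit(x, y, 1)
    return float(slope), n


def _assign_tie(
    slope: float,
    below: np.ndarray,
    above: np.ndarray,
    tie_rule: str,
) -> str:
    """Assign a median-sitting subject to the closer provisional group."""
    if tie_rule == "group-mean":
        d_ng = abs(slope - below.mean()) if below.size else math.inf
        d_g = abs(slope - above.mean()) if above.size else math.inf
    elif tie_rule == "nearest-neighbor":
        d_ng = np.abs(below - slope).min() if below.size else math.inf
        d_g = np.abs(above - slope).min() if above.size else math.inf
    else:
        raise ValueError(
            f"unknown tie rule {tie_rule!r}; use 'group-mean' or 'nearest-neighbor'"
        )
    if d_ng == d_g == math.inf:  # both provisional groups empty: degenerate
        return NON_GAMBLER
    return NON_GAMBLER if d_ng <= d_g else GAMBLER


def median_split(
    profiles: Sequence[SubjectProfile],
    tie_rule: str = "group-mean",
    pooled: bool = False,
) -> list[SubjectProfile]:
    """Label included subjects gambler / non-gambler by a median split on slope.

    The split is computed independently within each species (or over the
    pooled cohort with ``pooled=True``). Steeper (more negative) slopes fall
    below the median and are labeled ``non_gambler``; shallower slopes,
    ``gambler``. Excluded subjects pass through unlabeled.
    """
    labeled: dict[str, SubjectProfile] = {p.subject_id: p for p in profiles}
    if len(labeled) != len(profiles):
        raise ValueError("duplicate subject_id in profiles")

    fitted = [p for p in profiles if p.included and p.slope is not None]
    groups: dict[str, list[SubjectProfile]] = {}
    for p in fitted:
        groups.setdefault("all" if pooled else p.species, []).append(p)

    for group_name, members in groups.items():
        if len(members) < 2:
            raise ValueError(
                f"median split needs at least 2 included subjects per group, "
                f"got {len(members)} for {group_name!r}"
            )
        slopes = np.array([p.slope for p in members], dtype=float)
        if np.ptp(slopes) == 0:
            raise ValueError(
                f"all slopes equal in group {group_name!r}: no separable "
                "subpopulations"
            )
        med = float(np.median(slopes))
        below = slopes[slopes < med]
        above = slopes[slopes > med]
        for p in members:
            s = float(p.slope)
            if s < med:
                strategy = NON_GAMBLER
            elif s > med:
                strategy = GAMBLER
            else:
                strategy = _assign_tie(s, below, above, tie_rule)
            labeled[p.subject_id] = replace(p, strategy=strategy)

    return [labeled[p.subject_id] for p in profiles]


def classify_cohort(
    metrics: pd.DataFrame,
    protocol: ProtocolConfig,
    tie_rule: str = "group-mean",
    pooled: bool = False,
    min_session_index: int = 1,
) -> list[SubjectProfile]:
    """Run the full phenotyping pipeline over a session-metrics table.

    Applies the inclusion filter, fits the preference–odds slope for each
    included subject, then median-splits per species. Returns one profile per
    subject (sorted by subject id) with exclusion reasons and fit diagnostics.
    """
    profiles: list[SubjectProfile] = []
    for subject_id, rows in metrics.groupby("subject_id", sort=True):
        species = str(rows["species"].iloc[0])
        included, reason = include_subject(rows, protocol)
        if not included:
            logger.warning("subject %s excluded: %s", subject_id, reason)
            profiles.append(
                SubjectProfile(
                    subject_id=str(subject_id),
                    species=species,
                    included=False,
                    exclusion_reason=reason,
                )
            )
            continue
        slope, n_fit = preference_odds_slope(rows, min_session_index=min_session_index)
        n_dropped = int((rows["session_index"].astype(int) >= min_session_index).sum()) - n_fit
        if n_dropped:
            logger.warning(
                "subject %s: %d session(s) without usable experienced odds "
                "excluded from the fit",
                subject_id,
                n_dropped,
            )
        profiles.append(
            SubjectProfile(
                subject_id=str(subject_id),
                species=species,
                included=True,
                slope=slope,
                n_fit_points=n_fit,
            )
        )
    return median_split(profiles, tie_rule=tie_rule, pooled=pooled)


# -- profiles table I/O -------------------------------------------------------


def profiles_frame(profiles: Sequence[SubjectProfile]) -> pd.DataFrame:
    """Profiles as a table with the standard column layout."""
    return pd.DataFrame([asdict(p) for p in profiles], columns=PROFILE_COLUMNS)


def write_profiles(
    profiles: Sequence[SubjectProfile], destination: Union[str, Path]
) -> None:
    """Write subject profiles as CSV; missing slope/strategy as empty cells."""
    profiles_frame(profiles).to_csv(destination, index=False)


def read_profiles(source: Union[str, Path]) -> list[SubjectProfile]:
    """Read a profiles table written by :func:`write_profiles`."""
    df = pd.read_csv(source)
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{source}: profiles table missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SubjectProfile(
                subject_id=str(row["subject_id"]),
                species=str(row["species"]),
                included=bool(row["included"]),
                exclusion_reason=""
                if _is_missing(row["exclusion_reason"])
                else str(row["exclusion_reason"]),
                slope=None if _is_missing(row["slope"]) else float(row["slope"]),
                n_fit_points=int(row["n_fit_points"]),
                strategy=None if _is_missing(row["strategy"]) else str(row["strategy"]),
            )
        )
    return out
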