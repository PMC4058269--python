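"""Group-level summaries and the end-to-end pipeline.

``group_summary`` aggregates the session metrics into the layout of the
published group comparisons: one row per species × strategy × probability
level with mean ± SEM of each dependent variable. Replicate sessions at the
same probability level (the marmoset triplets) are averaged within subject
first, so each subject contributes a single value per level; SEM is the
across-subject sample SD divided by sqrt(n), and is reported missing for
single-subject groups.

``run_pipeline`` wires the stages together — optional simulation, session
metrics, phenotyping, summaries — and writes all artifacts plus a run
manifest (seed, config hash, package version, stage timings, warnings) so a
run is fully reproducible from its config file.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    AgentParams,
    TrialRecord,
    read_event_log,
    simulate_cohort,
    write_event_log,
)
from .classify import (
    SubjectProfile,
    classify_cohort,
    profiles_frame,
    write_profiles,
)
from .metrics import cohort_metrics, write_metrics
from .protocol import ProtocolConfig, resolve_protocol

__all__ = ["group_summary", "run_pipeline", "PipelineResult", "plot_preference_curves"]

logger = logging.getLogger(__name__)

SUMMARY_METRICS = (
    "pref_LLL",
    "persistence",
    "restlessness",
    "trials_per_min",
    "pellets_per_min",
)


def group_summary(
    metrics: pd.DataFrame,
    profiles: Union[Sequence[SubjectProfile], pd.DataFrame],
) -> pd.DataFrame:
    """Mean ± SEM of each dependent variable per species × strategy × p level.

    Within-subject replicate sessions at a probability level are averaged
    before aggregating across subjects. Raises if a labeled subject has no
    metrics rows.
    """
    pdf = profiles if isinstance(profiles, pd.DataFrame) else profiles_frame(profiles)
    labeled = pdf[pdf["strategy"].notna() & (pdf["strategy"] != "")]
    missing = set(labeled["subject_id"]) - set(metrics["subject_id"])
    if missing:
        raise ValueError(f"labeled subject(s) with no metrics rows: {sorted(missing)}")

    merged = metrics.merge(
        labeled[["subject_id", "strategy"]], on="subject_id", how="inner"
    )
    # one value per subject per level, replicate sessions averaged first
    per_subject = (
        merged.groupby(["species", "strategy", "p_set", "subject_id"], sort=True)[
            list(SUMMARY_METRICS)
        ]
        .mean()
        .reset_index()
    )
    rows = []
    for (species, strategy, p_set), g in per_subject.groupby(
        ["species", "strategy", "p_set"], sort=True
    ):
        row: dict = {
            "species": species,
            "strategy": strategy,
            "p_set": p_set,
            "n_subjects": len(g),
        }
        for m in SUMMARY_METRICS:
            vals = g[m].dropna().to_numpy(dtype=float)
            row[f"{m}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{m}_sem"] = (
                vals.std(ddof=1) / np.sqrt(vals.size) if vals.size >= 2 else np.nan
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["species", "strategy", "p_set"], ascending=[True, True, False]
    ).reset_index(drop=True)


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run."""

    event_log: Optional[list[TrialRecord]]
    metrics: pd.DataFrame
    profiles: list[SubjectProfile]
    summary: pd.DataFrame
    manifest: dict


def _agents_from_config(spec) -> list[AgentParams]:
    if isinstance(spec, (str, Path)):
        with open(spec, encoding="utf-8") as fh:
            spec = yaml.safe_load(fh)
    if not isinstance(spec, list):
        raise ValueError("agents spec must be a list of agent parameter mappings")
    return [AgentParams(**a) for a in spec]


def run_pipeline(
    config: Union[dict, str, Path],
    out_dir: Optional[Union[str, Path]] = None,
) -> PipelineResult:
    """Execute the full pipeline described by a config mapping or YAML file.

    The config must name either an input event log (``log: <path>``) or a
    simulation block (``simulate: {protocol, agents, seed}``), plus optional
    ``protocol`` (preset name or config path; defaults to the simulation
    protocol), ``tie_rule`` and ``pooled``. With ``out_dir`` set, all tables
    and a run manifest are written there.
    """
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("pipeline config must be a mapping")
    has_log = "log" in config
    has_sim = "simulate" in config
    if has_log == has_sim:
        raise ValueError("config must name exactly one of 'log' or 'simulate'")

    config_hash = hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()
    manifest: dict = {
        "pdtask_version": __version__,
        "config_sha256": config_hash,
        "stages": {},
        "warnings": [],
    }
    t0 = time.perf_counter()

    if has_sim:
        sim = config["simulate"]
        protocol = resolve_protocol(sim.get("protocol", "rat"))
        agents = _agents_from_config(sim["agents"])
        seed = int(sim.get("seed", 0))
        manifest["seed"] = seed
        event_log = simulate_cohort(agents, protocol, seed=seed)
        manifest["stages"]["simulate"] = {
            "seconds": round(time.perf_counter() - t0, 4),
            "n_trials": len(event_log),
        }
    else:
        protocol = resolve_protocol(config.get("protocol", "rat"))
        event_log = read_event_log(config["log"])
        manifest["stages"]["load"] = {
            "seconds": round(time.perf_counter() - t0, 4),
            "n_trials": len(event_log),
        }

    t1 = time.perf_counter()
    metrics = cohort_metrics(event_log, protocol)
    n_missing_odds = int(metrics["experienced_odds"].isna().sum()) if len(metrics) else 0
    if n_missing_odds:
        manifest["warnings"].append(
            f"{n_missing_odds} session(s) without usable experienced odds"
        )
    manifest["stages"]["metrics"] = {
        "seconds": round(time.perf_counter() - t1, 4),
        "n_sessions": len(metrics),
    }

    t2 = time.perf_counter()
    profiles = classify_cohort(
        metrics,
        protocol,
        tie_rule=config.get("tie_rule", "group-mean"),
        pooled=bool(config.get("pooled", False)),
    )
    excluded = [p.subject_id for p in profiles if not p.included]
    if excluded:
        manifest["warnings"].append(f"excluded subjects: {excluded}")
    manifest["stages"]["classify"] = {
        "seconds": round(time.perf_counter() - t2, 4),
        "n_subjects": len(profiles),
        "n_included": sum(p.included for p in profiles),
    }

    t3 = time.perf_counter()
    summary = group_summary(metrics, profiles)
    manifest["stages"]["summary"] = {
        "seconds": round(time.perf_counter() - t3, 4),
        "n_rows": len(summary),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if has_sim:
            write_event_log(event_log, out / "event_log.csv")
        write_metrics(metrics, out / "metrics.csv")
        write_profiles(profiles, out / "profiles.csv")
        summary.to_csv(out / "summary.csv", index=False)
        with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)

    for w in manifest["warnings"]:
        logger.warning("%s", w)
    return PipelineResult(
        event_log=event_log if has_sim else event_log,
        metrics=metrics,
        profiles=profiles,
        summary=summary,
        manifest=manifest,
    )


def plot_preference_curves(
    metrics: pd.DataFrame,
    profiles: Sequence[SubjectProfile],
    ax=None,
):
    """Plot per-subject %LLL preference against log10(experienced odds + 1).

    Gamblers in warm, non-gamblers in cool colors. Requires matplotlib
    (optional dependency); numeric tables, not figures, are the contract.
    """
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    if ax is None:
        _, ax = plt.subplots()
    colors = {"gambler": "tab:red", "non_gambler": "tab:blue"}
    for p in profiles:
        if p.strategy is None:
            continue
        rows = metrics[metrics["subject_id"] == p.subject_id].dropna(
            subset=["experienced_odds", "pref_LLL"]
        )
        x = np.log10(rows["experienced_odds"].astype(float) + 1.0)
        ax.plot(x, rows["pref_LLL"], "o-", alpha=0.6, color=colors[p.strategy])
    ax.set_xlabel("log10(experienced odds + 1)")
    ax.set_ylabel("LLL preference (%)")
    handles = [
        plt.Line2D([], [], color=c, marker="o", label=lbl) for lbl, c in colors.items()
    ]
    ax.legend(handles=handles)
    return ax
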