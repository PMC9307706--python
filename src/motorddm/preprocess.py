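"""Trial- and participant-level exclusion rules with a reconciling report.

Order of operations: discard practice trials, then participant-level
exclusions (at-or-below-chance in any cell; accuracy <= 2 SD below the group
mean; overall mean RT outside the group mean +/- 2 SD), then per-participant
RT trimming (floor 0.2 s; above participant mean + 3 SD, thresholds computed
once before removal).  Group statistics are computed once, over all
participants, before any exclusion; participant RT statistics pool all
experimental trials across conditions.  "Chance" is 0.5 for this
two-alternative task.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import add_correct, validate_trials

__all__ = [
    "PreprocessConfig",
    "PreprocessReport",
    "remove_practice",
    "filter_rts",
    "exclude_participants",
    "preprocess",
]

RT_FLOOR = 0.2
RT_SD_MULTIPLIER = 3.0
GROUP_SD_MULTIPLIER = 2.0
CHANCE = 0.5


@dataclass(frozen=True)
class PreprocessConfig:
    rt_floor: float = RT_FLOOR
    rt_sd_multiplier: float = RT_SD_MULTIPLIER
    group_sd_multiplier: float = GROUP_SD_MULTIPLIER
    chance: float = CHANCE
    #: subjects excluded for data-collection events, with reason "malfunction"
    malfunction_subjects: tuple[str, ...] = ()


@dataclass
class PreprocessReport:
    trials_in: int = 0
    practice_removed: int = 0
    rt_filtered: int = 0
    excluded_subject_trials: int = 0
    trials_out: int = 0
    removed_fraction: float = 0.0  # RT-filtered fraction of experimental trials
    excluded_subjects: list = field(default_factory=list)  # (subject, reason)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def check_conservation(self) -> bool:
        return self.trials_out == (
            self.trials_in - self.practice_removed
            - self.excluded_subject_trials - self.rt_filtered
        )


def remove_practice(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop practice trials, preserving order."""
    return trials.loc[~trials["is_practice"].astype(bool)].copy()


def filter_rts(trials: pd.DataFrame, config: PreprocessConfig = PreprocessConfig()
               ) -> tuple[pd.DataFrame, int]:
    """Single-pass per-participant RT trimming; returns (kept, removed count).

    Thresholds (floor and participant mean + 3 SD) are computed once on the
    incoming trials, then applied.  Trials without a response time are
    removed here as well (they carry no RT to model).  A participant with
    fewer than 2 responded trials has no defined SD; only the floor applies.
    """
    if len(trials) == 0:
        return trials.copy(), 0
    keep = np.zeros(len(trials), dtype=bool)
    rt = trials["rt_seconds"].to_numpy(dtype=float)
    for _, idx in trials.groupby("subject", observed=True).indices.items():
        r = rt[idx]
        valid = ~np.isnan(r)
        if valid.sum() >= 2:
            m, s = float(np.nanmean(r)), float(np.nanstd(r, ddof=1))
            ceiling = m + config.rt_sd_multiplier * s
        else:
            ceiling = np.inf
        keep[idx] = valid & (r >= config.rt_floor) & (r <= ceiling)
    kept = trials.loc[keep].copy()
    return kept, int(len(trials) - len(kept))


def exclude_participants(trials: pd.DataFrame,
                         config: PreprocessConfig = PreprocessConfig(),
                         ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Participant-level exclusions; returns (kept trials, [(subject, reason)]).

    Reasons: "malfunction" (user-supplied list), "chance" (accuracy at or
    below 0.5 in any single condition), "low_accuracy" (overall accuracy
    <= group mean - 2 group SD), "extreme_rt" (overall mean RT outside group
    mean +/- 2 group SD).  Group statistics are computed over all
    participants before any exclusion; with fewer than 3 participants the
    group-level rules are skipped with a warning.
    """
    if len(trials) == 0:
        return trials.copy(), []
    df = add_correct(trials)
    exclusions: list[tuple[str, str]] = []
    flagged: set[str] = set()

    for sid in config.malfunction_subjects:
        if (df["subject"] == sid).any():
            exclusions.append((sid, "malfunction"))
            flagged.add(sid)

    by_cell = df.groupby(["subject", "set_size", "spring"], observed=True)["correct"].mean()
    for sid in by_cell.index.get_level_values(0).unique():
        if sid in flagged:
            continue
        if (by_cell.loc[sid] <= config.chance).any():
            exclusions.append((sid, "chance"))
            flagged.add(sid)

    overall_acc = df.groupby("subject", observed=True)["correct"].mean()
    overall_rt = df.groupby("subject", observed=True)["rt_seconds"].mean()
    if len(overall_acc) < 3:
        warnings.warn(
            "fewer than 3 participants: group-level exclusion rules skipped",
            stacklevel=2,
        )
    else:
        acc_floor = overall_acc.mean() - config.group_sd_multiplier * overall_acc.std(ddof=1)
        rt_lo = overall_rt.mean() - config.group_sd_multiplier * overall_rt.std(ddof=1)
        rt_hi = overall_rt.mean() + config.group_sd_multiplier * overall_rt.std(ddof=1)
        for sid in overall_acc.index:
            if sid in flagged:
                continue
            if overall_acc[sid] <= acc_floor:
                exclusions.append((sid, "low_accuracy"))
                flagged.add(sid)
        for sid in overall_rt.index:
            if sid in flagged:
                continue
            if not (rt_lo <= overall_rt[sid] <= rt_hi):
                exclusions.append((sid, "extreme_rt"))
                flagged.add(sid)

    kept = trials.loc[~trials["subject"].isin(flagged)].copy()
    return kept, exclusions


def preprocess(trials: pd.DataFrame,
               config: PreprocessConfig = PreprocessConfig(),
               ) -> tuple[pd.DataFrame, PreprocessReport]:
    """Full pipeline: practice -> participant exclusions -> RT trimming."""
    if len(trials) == 0:
        return trials.copy(), PreprocessReport()
    validate_trials(trials)
    report = PreprocessReport(trials_in=len(trials))
    experimental = remove_practice(trials)
    report.practice_removed = len(trials) - len(experimental)
    kept, exclusions = exclude_participants(experimental, config)
    report.excluded_subjects = [list(e) for e in exclusions]
    report.excluded_subject_trials = len(experimental) - len(kept)
    clean, removed = filter_rts(kept, config)
    report.rt_filtered = removed
    report.trials_out = len(clean)
    n_exp = len(kept)
    report.removed_fraction = removed / n_exp if n_exp else 0.0
    assert report.check_conservation()
    return clean, report
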