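"""Lottery-winner turnover detection in per-subject time series.

Within a host sampled at several time points, a lottery group's winner may be
replaced by a different group member — a *turnover*.  A (subject, group) pair
is eligible when at least two time points have group abundance strictly above
the inclusion floor (default 0.5%); turnover is declared when two eligible
time points carry different non-missing winners.  The predicate is
existential, so reverting to the initial winner still counts and time points
without a winner never create turnover on their own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .tables import AbundanceTable, FilterConfig, GroupAssignment, Lineage, build_groups, filter_groups
from .metrics import MetricConfig, NO_WINNER, WinnerCall

__all__ = ["TurnoverRecord", "TurnoverCensus", "detect_turnover", "turnover_census"]


@dataclass
class TurnoverRecord:
    """Winner timeline and turnover flag for one (subject, group) pair."""

    subject_id: object
    group_name: str
    timeline: list  # ordered (time_point, winner-or-None, group_abundance)
    n_eligible_timepoints: int
    eligible: bool
    turnover: bool

    @property
    def n_timepoints(self) -> int:
        return len(self.timeline)


@dataclass
class TurnoverCensus:
    """Cohort-wide turnover counts over all eligible (subject, group) pairs."""

    n_pairs_examined: int
    n_pairs_with_turnover: int
    records: list

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            winners = ",".join(str(w) if w is not NO_WINNER else "-" for _, w, _ in r.timeline)
            rows.append({
                "subject": r.subject_id,
                "group": r.group_name,
                "n_timepoints": r.n_timepoints,
                "n_eligible_timepoints": r.n_eligible_timepoints,
                "winners": winners,
                "eligible": r.eligible,
                "turnover": r.turnover,
            })
        return pd.DataFrame(rows)


def detect_turnover(timeline: Sequence[tuple], cfg: MetricConfig = MetricConfig(),
                    subject_id=None, group_name: str = "") -> TurnoverRecord:
    """Decide turnover from an ordered winner timeline for one pair.

    ``timeline`` holds ``(time_point, winner-or-None, group_abundance)``
    entries.  Only time points whose group abundance strictly exceeds the
    inclusion floor carry evidence; the pair is eligible with at least two
    such points, and turnover requires two of them to name different winners.
    Duplicate time points for one subject are an error.
    """
    if not timeline:
        raise ValueError("timeline must contain at least one time point")
    times = [t for t, _, _ in timeline]
    try:
        order = sorted(range(len(times)), key=lambda i: times[i])
    except TypeError as exc:
        raise ValueError(f"time points are not sortable: {exc}") from exc
    if len(set(times)) != len(times):
        raise ValueError(f"duplicate time points for subject {subject_id!r}: {sorted(times)}")
    ordered = [timeline[i] for i in order]
    floor = cfg.sample_inclusion_min_group_abundance
    eligible_entries = [(t, w) for t, w, g in ordered if g > floor]
    eligible = len(eligible_entries) >= 2
    winners = {w for _, w in eligible_entries if w is not NO_WINNER}
    turnover = eligible and len(winners) >= 2
    return TurnoverRecord(subject_id, group_name, ordered, len(eligible_entries),
                          eligible, turnover)


def turnover_census(table: AbundanceTable, lineages: Mapping[str, Lineage],
                    metadata: pd.DataFrame, cfg: MetricConfig = MetricConfig(),
                    rank: str = "genus",
                    filter_cfg: Optional[FilterConfig] = None) -> TurnoverCensus:
    """Enumerate eligible (subject, group) pairs and count turnovers.

    ``metadata`` needs columns ``sample_id``, ``subject_id`` and
    ``time_point`` covering every sample in the table.  Groups are built at
    ``rank`` and, when ``filter_cfg`` is given, restricted to those passing
    the cohort-level group filter; eligibility is then assessed per subject.
    Winner calls reuse the standard cutoff and the group-abundance floor.
    """
    for col in ("sample_id", "subject_id", "time_point"):
        if col not in metadata.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    meta = metadata.set_index("sample_id")
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing subject/time metadata: {missing[:10]}")
    bad = meta.loc[table.sample_ids, ["subject_id", "time_point"]].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"samples missing subject/time metadata: {list(bad.index[bad])[:10]}")

    groups = build_groups(lineages, rank)
    if filter_cfg is not None:
        groups = filter_groups(table, groups, filter_cfg)

    subjects = meta.loc[table.sample_ids].groupby("subject_id", sort=True)
    records = []
    floor = cfg.sample_inclusion_min_group_abundance
    for subject, meta_s in subjects:
        samples = list(meta_s.index)
        times = meta_s["time_point"]
        for grp in groups:
            sub = table.data.loc[list(grp.members), samples]
            gab = sub.sum(axis=0)
            timeline = []
            for s in samples:
                total = float(gab[s])
                winner = NO_WINNER
                if total > floor:
                    fr = sub[s] / total
                    i = int(np.argmax(fr.to_numpy()))
                    if float(fr.iloc[i]) > cfg.winner_cutoff:
                        winner = fr.index[i]
                timeline.append((times[s], winner, total))
            records.append(detect_turnover(timeline, cfg, subject_id=subject,
                                           group_name=grp.group_name))
    eligible = [r for r in records if r.eligible]
    return TurnoverCensus(
        n_pairs_examined=len(eligible),
        n_pairs_with_turnover=sum(1 for r in eligible if r.turnover),
        records=records,
    )
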