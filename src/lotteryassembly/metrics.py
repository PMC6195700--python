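"""Winner-prevalence and winner-diversity statistics for taxonomic groups.

The competitive-lottery schema predicts that, within a group of niche-
equivalent taxa, (i) one member captures essentially the whole group
abundance in each sample (the *winner*), and (ii) the winning member differs
between samples.  Two statistics quantify this:

* **winner prevalence** — the fraction of included samples in which some
  member's within-group fraction strictly exceeds the winner cutoff
  (default 0.9);
* **winner diversity** — the Shannon entropy (base 2) of the frequency
  distribution of winner identities across samples with a winner, normalized
  by ``log2`` of the number of distinct winners, hence in [0, 1].

A sample is included in a group's statistics only when the group's summed
abundance strictly exceeds an inclusion floor (default 0.5%), which keeps
Poisson sampling noise at low abundance from manufacturing artificial
winners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .tables import AbundanceTable, FilterConfig, GroupAssignment, filter_features

__all__ = [
    "MetricConfig",
    "WinnerCall",
    "GroupLotteryResult",
    "SweepVariant",
    "NO_WINNER",
    "within_group_fractions",
    "call_winner",
    "group_lottery_stats",
    "per_sample_entropy",
    "classify_group",
    "sensitivity_sweep",
    "order_samples_for_display",
    "results_to_frame",
]

#: Sentinel for "no member exceeded the winner cutoff in this sample".
NO_WINNER = None


@dataclass(frozen=True)
class MetricConfig:
    """Tunable thresholds of the lottery statistics.

    ``winner_cutoff`` must be in (0.5, 1) so at most one member can win a
    sample.  ``top_k`` optionally restricts each group to its k most abundant
    members before computing fractions; ``top_k_ranking`` selects whether the
    k members are chosen per sample or by mean abundance across included
    samples (per-sample ranking guarantees prevalence can only rise under the
    restriction, because the sample's most abundant member is always kept).
    """

    winner_cutoff: float = 0.9
    sample_inclusion_min_group_abundance: float = 0.005
    prevalence_threshold: float = 0.75
    diversity_threshold: float = 0.25
    top_k: Optional[int] = None
    top_k_ranking: str = "per_sample"

    def __post_init__(self) -> None:
        if not (0.5 < self.winner_cutoff < 1):
            raise ValueError(f"winner_cutoff must be in (0.5, 1), got {self.winner_cutoff}")
        for name in ("sample_inclusion_min_group_abundance",
                     "prevalence_threshold", "diversity_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.top_k_ranking not in ("per_sample", "mean"):
            raise ValueError("top_k_ranking must be 'per_sample' or 'mean'")


@dataclass(frozen=True)
class WinnerCall:
    """The winner call for one (group, sample) pair."""

    sample_id: object
    group_name: str
    winner: Optional[str]
    winner_fraction: float
    group_abundance: float


@dataclass
class GroupLotteryResult:
    """Lottery statistics for one group at one rank.

    ``winner_diversity_normalized`` is ``None`` when no sample has a winner
    and 0.0 when all winners are the same member (the single-winner
    convention: log2(1) = 0 makes the normalization degenerate, and a lone
    recurring winner is the least diverse outcome).
    """

    group_name: str
    rank: str
    n_members: int
    n_included_samples: int
    winner_prevalence: float
    winner_counts: dict
    n_distinct_winners: int
    winner_diversity_normalized: Optional[float]
    per_sample_entropy: pd.Series
    calls: list = field(default_factory=list, repr=False)


def _entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy in bits; 0*log(0) := 0. log2 is exact on powers of 2."""
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def within_group_fractions(table: AbundanceTable, group: GroupAssignment,
                           sample) -> Optional[pd.Series]:
    """Member abundances divided by the group's summed abundance in a sample.

    Returns ``None`` when the group abundance is zero (the sample carries no
    information about within-group structure and is excluded, not an error).
    """
    sub = table.data.loc[list(group.members), sample]
    total = float(sub.sum())
    if total <= 0:
        return None
    return sub / total


def call_winner(fractions: Mapping, cfg: MetricConfig = MetricConfig(), *,
                sample_id=None, group_name: str = "", group_abundance: float = float("nan"),
                ) -> WinnerCall:
    """Identify the winner among within-group fractions, if any.

    The winner is the unique member whose fraction strictly exceeds
    ``winner_cutoff``; because the cutoff is above 0.5 at most one such member
    exists.  Ties for the maximum are broken lexicographically by member id.
    """
    items = sorted(fractions.items())
    members = [m for m, _ in items]
    vals = np.array([v for _, v in items], dtype=float)
    i = int(np.argmax(vals))  # first max = lexicographically smallest member
    winner = members[i] if vals[i] > cfg.winner_cutoff else NO_WINNER
    return WinnerCall(sample_id, group_name, winner, float(vals[i]), group_abundance)


def _restrict_top_k(sub: pd.DataFrame, frac: pd.DataFrame, cfg: MetricConfig) -> pd.DataFrame:
    """Apply the top-k member restriction and renormalize fractions.

    Returns a members-by-samples fraction frame; columns where the restricted
    subset has zero abundance become NaN (no winner, no entropy).
    """
    k = cfg.top_k
    if k is None or k >= len(frac.index):
        return frac
    if cfg.top_k_ranking == "per_sample":
        # rank 'first' on the lexicographically sorted index breaks ties
        # toward the smaller member id, matching call_winner
        ranks = frac.rank(axis=0, method="first", ascending=False)
        masked = frac.where(ranks <= k, 0.0)
    else:
        means = sub.mean(axis=1).to_numpy()
        order = np.lexsort((np.array(sub.index, dtype=object), -means))
        top = sub.index[order[:k]]
        masked = frac.where(frac.index.isin(top), 0.0)
    totals = masked.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = masked.div(totals.where(totals > 0), axis=1)
    return out


def group_lottery_stats(table: AbundanceTable, group: GroupAssignment,
                        cfg: MetricConfig = MetricConfig()) -> GroupLotteryResult:
    """Compute winner prevalence, winner diversity, and per-sample entropies.

    Included samples are those whose group abundance strictly exceeds the
    inclusion floor.  Raises when no sample qualifies.
    """
    members = sorted(group.members)
    missing = [m for m in members if m not in table.data.index]
    if missing:
        raise KeyError(f"group {group.group_name!r} members absent from table: {missing[:5]}")
    sub = table.data.loc[members].astype(float)
    gab = sub.sum(axis=0)
    included = gab.index[gab > cfg.sample_inclusion_min_group_abundance]
    if len(included) == 0:
        raise ValueError(
            f"group {group.group_name!r} below inclusion threshold in all samples")
    sub_i = sub[included]
    frac = sub_i.div(gab[included], axis=1)
    frac = _restrict_top_k(sub_i, frac, cfg)

    valid = frac.notna().all(axis=0)
    max_frac = frac.max(axis=0)
    # fillna so all-NaN (dead top-k subset) columns don't break idxmax;
    # first max -> lexicographic tie-break on the sorted member index
    winner_of = frac.fillna(-1.0).idxmax(axis=0)
    has_winner = valid & (max_frac > cfg.winner_cutoff)

    counts: dict = {}
    for m in winner_of[has_winner]:
        counts[m] = counts.get(m, 0) + 1
    counts = dict(sorted(counts.items()))
    n_winner_samples = int(has_winner.sum())
    prevalence = n_winner_samples / len(included)

    n_distinct = len(counts)
    if n_distinct == 0:
        diversity = None
    elif n_distinct == 1:
        diversity = 0.0
    else:
        p = np.array(list(counts.values()), dtype=float) / n_winner_samples
        diversity = _entropy_bits(p) / float(np.log2(n_distinct))

    arr = frac.to_numpy()
    logf = np.log2(arr, out=np.zeros_like(arr), where=arr > 0)
    ent = pd.Series(-(arr * logf).sum(axis=0), index=included)
    ent[~valid] = np.nan

    calls = [
        WinnerCall(s, group.group_name,
                   winner_of[s] if has_winner[s] else NO_WINNER,
                   float(max_frac[s]) if valid[s] else float("nan"),
                   float(gab[s]))
        for s in included
    ]
    return GroupLotteryResult(
        group_name=group.group_name,
        rank=group.rank,
        n_members=len(members),
        n_included_samples=len(included),
        winner_prevalence=prevalence,
        winner_counts=counts,
        n_distinct_winners=n_distinct,
        winner_diversity_normalized=diversity,
        per_sample_entropy=ent,
        calls=calls,
    )


def per_sample_entropy(fractions: Mapping) -> float:
    """Shannon entropy (bits) of within-group fractions in one sample.

    The reference value for an idealized k-member group with uniform
    abundances is ``log2(k)``.
    """
    vals = np.array([v for _, v in sorted(fractions.items())], dtype=float)
    return _entropy_bits(vals)


def classify_group(result: GroupLotteryResult, cfg: MetricConfig = MetricConfig()) -> str:
    """Classify a group as lottery_like, fixed_winner, or non_lottery.

    Lottery-like groups have winner prevalence strictly above the prevalence
    threshold *and* normalized winner diversity strictly above the diversity
    threshold; high prevalence with low diversity marks a fixed winner.
    Groups with no winners at all (missing diversity) are non_lottery.
    """
    prev_ok = result.winner_prevalence > cfg.prevalence_threshold
    div = result.winner_diversity_normalized
    if div is None:
        return "non_lottery"
    if prev_ok and div > cfg.diversity_threshold:
        return "lottery_like"
    if prev_ok:
        return "fixed_winner"
    return "non_lottery"


@dataclass(frozen=True)
class SweepVariant:
    """One configuration in a robustness sweep.

    ``otu_min_abundance`` (when set) re-runs the feature filter at that floor
    before computing the group's statistics, restricting the group to the
    surviving members.
    """

    name: str
    metric_cfg: MetricConfig = MetricConfig()
    otu_min_abundance: Optional[float] = None


def sensitivity_sweep(table: AbundanceTable, group: GroupAssignment,
                      variants: Sequence[SweepVariant]) -> pd.DataFrame:
    """Recompute a group's statistics under alternative thresholds.

    Sweep axes: winner cutoff, feature-inclusion abundance floor, and top-k
    member restriction.  Returns one row per variant.
    """
    if not variants:
        raise ValueError("sensitivity_sweep requires at least one variant")
    rows = []
    for var in variants:
        grp = group
        tab = table
        if var.otu_min_abundance is not None:
            fcfg = FilterConfig(otu_min_abundance=var.otu_min_abundance)
            tab = filter_features(table, fcfg)
            members = tuple(m for m in group.members if m in tab.data.index)
            if not members:
                rows.append({"variant": var.name, "winner_cutoff": var.metric_cfg.winner_cutoff,
                             "top_k": var.metric_cfg.top_k,
                             "otu_min_abundance": var.otu_min_abundance,
                             "n_included_samples": 0, "winner_prevalence": np.nan,
                             "winner_diversity": np.nan})
                continue
            grp = GroupAssignment(group.rank, group.group_name, members)
        res = group_lottery_stats(tab, grp, var.metric_cfg)
        rows.append({
            "variant": var.name,
            "winner_cutoff": var.metric_cfg.winner_cutoff,
            "top_k": var.metric_cfg.top_k,
            "otu_min_abundance": var.otu_min_abundance,
            "n_included_samples": res.n_included_samples,
            "winner_prevalence": res.winner_prevalence,
            "winner_diversity": (np.nan if res.winner_diversity_normalized is None
                                 else res.winner_diversity_normalized),
        })
    return pd.DataFrame(rows)


def order_samples_for_display(table: AbundanceTable, group: GroupAssignment,
                              cfg: MetricConfig = MetricConfig(),
                              ) -> tuple[list, list]:
    """Deterministic sample ordering for within-group heatmaps.

    Included samples are grouped into contiguous blocks by the identity of
    their most abundant member; blocks are ordered by descending size (ties:
    lexicographic member id) and samples within a block by decreasing
    fraction of that member (ties: lexicographic sample id).

    Returns ``(ordered_sample_ids, blocks)`` where blocks is a list of
    ``(member, [sample ids])``.
    """
    members = sorted(group.members)
    sub = table.data.loc[members].astype(float)
    gab = sub.sum(axis=0)
    included = gab.index[gab > cfg.sample_inclusion_min_group_abundance]
    if len(included) == 0:
        return [], []
    frac = sub[included].div(gab[included], axis=1)
    dominant = frac.idxmax(axis=0)
    dom_frac = frac.max(axis=0)
    blocks: dict = {}
    for s in included:
        blocks.setdefault(dominant[s], []).append(s)
    ordered_blocks = sorted(blocks.items(), key=lambda kv: (-len(kv[1]), str(kv[0])))
    out_blocks = []
    ordered = []
    for member, samples in ordered_blocks:
        samples = sorted(samples, key=lambda s: (-dom_frac[s], str(s)))
        out_blocks.append((member, samples))
        ordered.extend(samples)
    return ordered, out_blocks


def results_to_frame(results: Sequence[GroupLotteryResult],
                     cfg: MetricConfig = MetricConfig()) -> pd.DataFrame:
    """Tidy long-format summary: one row per (rank, group)."""
    rows = []
    for r in results:
        rows.append({
            "group": r.group_name,
            "rank": r.rank,
            "n_members": r.n_members,
            "n_samples": r.n_included_samples,
            "winner_prevalence": r.winner_prevalence,
            "n_winners": r.n_distinct_winners,
            "winner_diversity": (np.nan if r.winner_diversity_normalized is None
                                 else r.winner_diversity_normalized),
            "classification": classify_group(r, cfg),
        })
    columns = ["group", "rank", "n_members", "n_samples", "winner_prevalence",
               "n_winners", "winner_diversity", "classification"]
    return pd.DataFrame(rows, columns=columns)
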