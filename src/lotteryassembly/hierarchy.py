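"""Lottery statistics at higher taxonomic ranks via subgroup aggregation.

A family, order, class, or phylum is scored exactly like a genus, except that
its "members" are the aggregated abundances of its child-rank subgroups (the
genera of a family, the families of an order, ...), each treated as a single
entity.  A group's score therefore depends only on the per-sample subgroup
sums, never on how abundance is distributed *within* a subgroup.

Features unannotated at the child rank are dropped from the aggregation so
that abundance from two different unknown lineages is never pooled, and
groups with a single annotated subgroup are skipped (a one-member lottery is
meaningless).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .tables import (RANKS, AbundanceTable, FilterConfig, GroupAssignment,
                     Lineage, min_required_samples)
from .metrics import GroupLotteryResult, MetricConfig, group_lottery_stats

__all__ = [
    "HierarchicalGroup",
    "RANK_LABELS",
    "aggregate_subgroups",
    "hierarchical_lottery_scan",
]

#: Single-letter rank labels used in report tables.
RANK_LABELS = {"kingdom": "k", "phylum": "p", "class": "c", "order": "o",
               "family": "f", "genus": "g", "species": "s"}


@dataclass
class HierarchicalGroup:
    """A taxon above the base rank with its aggregated child subgroups.

    ``subgroup_table`` is a subgroups-by-samples frame of summed member
    abundances; ``member_features`` maps each subgroup name to the base
    features it aggregates.
    """

    rank: str
    group_name: str
    subgroup_names: tuple
    subgroup_table: pd.DataFrame
    member_features: dict

    @property
    def n_subgroups(self) -> int:
        return len(self.subgroup_names)


def child_rank(rank: str) -> str:
    i = RANKS.index(rank)
    if i + 1 >= len(RANKS):
        raise ValueError(f"{rank!r} has no child rank")
    return RANKS[i + 1]


def aggregate_subgroups(table: AbundanceTable, lineages: Mapping[str, Lineage],
                        rank: str, min_subgroups: int = 2) -> list[HierarchicalGroup]:
    """Aggregate child-rank subgroup abundances for every group at ``rank``.

    A feature contributes only when annotated at both ``rank`` and the child
    rank; groups with fewer than ``min_subgroups`` annotated subgroups are
    omitted.  Subgroup abundance is the plain sum of member abundances, so
    conservation holds exactly: per sample, the group abundance equals the sum
    of its subgroup abundances over the contributing features.
    """
    crank = child_rank(rank)
    buckets: dict = {}
    for fid, lineage in lineages.items():
        if fid not in table.data.index:
            continue
        parent = lineage.get(rank)
        child = lineage.get(crank)
        if parent is None or child is None:
            continue
        buckets.setdefault(parent, {}).setdefault(child, []).append(fid)
    out = []
    for parent, children in sorted(buckets.items()):
        if len(children) < min_subgroups:
            continue
        rows = {child: table.data.loc[sorted(fids)].sum(axis=0)
                for child, fids in sorted(children.items())}
        frame = pd.DataFrame(rows).T
        out.append(HierarchicalGroup(
            rank=rank,
            group_name=parent,
            subgroup_names=tuple(sorted(children)),
            subgroup_table=frame,
            member_features={c: tuple(sorted(f)) for c, f in sorted(children.items())},
        ))
    return out


def _passes_group_filter(gab: pd.Series, n_samples: int, cfg: FilterConfig) -> bool:
    count = int((gab > cfg.group_min_abundance).sum())
    if cfg.group_min_samples_override is not None:
        return count > cfg.group_min_samples_override
    need = min_required_samples(n_samples, cfg.group_min_sample_fraction,
                                cfg.group_min_samples_floor)
    return count >= need


def hierarchical_lottery_scan(table: AbundanceTable, lineages: Mapping[str, Lineage],
                              cfg: MetricConfig = MetricConfig(),
                              filter_cfg: Optional[FilterConfig] = None,
                              base_rank: Optional[str] = None,
                              ) -> list[GroupLotteryResult]:
    """Score every multi-subgroup taxon at every rank above the base.

    ``base_rank`` is the grouping rank of the base-level analysis (genus for
    16S tables, species for shotgun tables); when omitted it is the deepest
    rank annotated anywhere in ``lineages``.  Ranks are scanned bottom-up from
    one above the base up to phylum; at each rank the group-abundance filter
    is re-applied (when ``filter_cfg`` is given) and each surviving group is
    scored with its subgroups as members.
    """
    if base_rank is None:
        depths = [ln.depth for ln in lineages.values()]
        if not depths or max(depths) <= 1:
            warnings.warn("lineages carry no rank structure; nothing to scan", stacklevel=2)
            return []
        base_rank = RANKS[max(depths) - 1]
    base_i = RANKS.index(base_rank)
    if base_i <= RANKS.index("phylum"):
        warnings.warn("base rank at or above phylum; nothing to scan", stacklevel=2)
        return []
    results = []
    for rank_i in range(base_i - 1, RANKS.index("phylum") - 1, -1):
        rank = RANKS[rank_i]
        for hgroup in aggregate_subgroups(table, lineages, rank):
            gab = hgroup.subgroup_table.sum(axis=0)
            if filter_cfg is not None and not _passes_group_filter(
                    gab, table.n_samples, filter_cfg):
                continue
            # treat subgroup sums as a small relative table; the lottery
            # statistics see each subgroup as a single member
            sub_table = AbundanceTable(hgroup.subgroup_table, "relative")
            group = GroupAssignment(rank, hgroup.group_name, hgroup.subgroup_names)
            try:
                res = group_lottery_stats(sub_table, group, cfg)
            except ValueError:
                continue  # below inclusion floor in every sample
            results.append(res)
    return results
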