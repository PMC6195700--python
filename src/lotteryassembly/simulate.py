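"""Synthetic community generators with known assembly schemas.

The generators emulate the statistical structure the lottery analysis
assumes, so every pipeline stage can be validated against ground truth:

* a **two-step assembly model**: each sample's total abundance (100%) is
  first allocated among groups (symmetric Dirichlet by default), then each
  group's share is divided among its members according to that group's
  within-group schema;
* three **within-group schemas** — ``lottery`` (a randomly drawn winner takes
  a fraction above the winner cutoff, losers share the remainder),
  ``fixed_winner`` (the same member always wins), and ``coexistence``
  (a symmetric Dirichlet with high concentration, i.e. even sharing);
* **stick-breaking** species-abundance nulls (GEM and classic broken-stick);
* **Poisson read-sampling noise** at a configurable sequencing depth, applied
  independently per feature;
* **longitudinal series** with planted winner turnovers.

All generators take explicit integer seeds and touch no global random state;
identical seeds reproduce identical tables bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .tables import AbundanceTable, Lineage

__all__ = [
    "SchemaSpec",
    "CommunitySpec",
    "stick_breaking_abundances",
    "simulate_community",
    "simulate_longitudinal",
    "poisson_noise_sweep",
    "simulate_gene_counts",
    "build_community_spec",
]

_SCHEMAS = ("lottery", "fixed_winner", "coexistence")


@dataclass(frozen=True)
class SchemaSpec:
    """Within-group assembly schema and its parameters.

    ``winner_distribution`` is the categorical law of the winner identity
    (uniform over members when omitted; a point mass on ``fixed_member`` for
    the fixed-winner schema).  The winner's within-group fraction is drawn
    uniformly from ``winner_fraction_range`` — the default (0.92, 1.0) sits
    strictly above the 0.9 winner cutoff, so noise-free lottery samples always
    carry a detectable winner.  Losers share the remainder by stick-breaking
    (heavy-tailed) or a symmetric Dirichlet.
    """

    schema: str
    n_members: int
    winner_distribution: Optional[tuple] = None
    winner_fraction_range: tuple = (0.92, 1.0)
    loser_allocation: str = "stick_breaking"
    stick_breaking_theta: float = 1.0
    coexistence_concentration: float = 10.0
    fixed_member: int = 0

    def __post_init__(self) -> None:
        if self.schema not in _SCHEMAS:
            raise ValueError(f"schema must be one of {_SCHEMAS}, got {self.schema!r}")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.winner_distribution is not None:
            w = np.asarray(self.winner_distribution, dtype=float)
            if len(w) != self.n_members:
                raise ValueError("winner_distribution length must equal n_members")
            if not np.isclose(w.sum(), 1.0, atol=1e-9) or (w < 0).any():
                raise ValueError("winner_distribution must be a probability vector")
            object.__setattr__(self, "winner_distribution", tuple(float(x) for x in w))
        lo, hi = self.winner_fraction_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("winner_fraction_range must satisfy 0 < lo <= hi <= 1")
        if self.loser_allocation not in ("stick_breaking", "symmetric_dirichlet"):
            raise ValueError("loser_allocation must be 'stick_breaking' or 'symmetric_dirichlet'")

    def winner_probs(self) -> np.ndarray:
        if self.schema == "fixed_winner":
            p = np.zeros(self.n_members)
            p[self.fixed_member] = 1.0
            return p
        if self.winner_distribution is None:
            return np.full(self.n_members, 1.0 / self.n_members)
        return np.asarray(self.winner_distribution, dtype=float)


@dataclass(frozen=True)
class CommunityGroup:
    """One simulated taxonomic group: its lineage and within-group schema."""

    lineage: Lineage
    schema: SchemaSpec

    @property
    def name(self) -> str:
        names = [n for n in self.lineage.names if n is not None]
        return names[-1] if names else "group"


@dataclass(frozen=True)
class CommunitySpec:
    """Full specification of a simulated cross-sectional community.

    ``read_depth=None`` means noise-free relative abundances; a finite depth
    draws per-feature counts from Poisson(abundance x depth).
    ``group_allocation_concentration`` parameterizes the symmetric Dirichlet
    of the first assembly step.
    """

    groups: tuple
    n_samples: int
    read_depth: Optional[int] = None
    group_allocation_concentration: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.read_depth is not None and self.read_depth < 1:
            raise ValueError("read_depth must be >= 1 or None")
        object.__setattr__(self, "groups", tuple(self.groups))
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate group names: {names}")


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def stick_breaking_abundances(n: int, theta: float = 1.0, variant: str = "gem",
                              seed=None) -> np.ndarray:
    """Random abundance vector from a stick-breaking null.

    ``gem``: sequential Beta(1, theta) breaks; the n-th piece receives the
    remaining stick.  ``broken_stick``: n-1 uniform cut points on [0, 1];
    the segment lengths are returned.  Either way the vector sums to 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    if n == 1:
        return np.array([1.0])
    if variant == "gem":
        out = np.empty(n)
        remaining = 1.0
        for i in range(n - 1):
            v = rng.beta(1.0, theta)
            out[i] = v * remaining
            remaining *= 1.0 - v
        out[n - 1] = remaining
        return out
    if variant == "broken_stick":
        cuts = np.sort(rng.uniform(0.0, 1.0, size=n - 1))
        edges = np.concatenate(([0.0], cuts, [1.0]))
        return np.diff(edges)
    raise ValueError(f"unknown variant {variant!r}")


def _within_group_fractions(schema: SchemaSpec, rng: np.random.Generator,
                            winner: Optional[int]) -> np.ndarray:
    """Draw one sample's within-group member fractions under a schema."""
    k = schema.n_members
    if schema.schema == "coexistence":
        return rng.dirichlet(np.full(k, schema.coexistence_concentration))
    if k == 1:
        return np.array([1.0])
    lo, hi = schema.winner_fraction_range
    f = rng.uniform(lo, hi)
    losers = np.array([i for i in range(k) if i != winner])
    if schema.loser_allocation == "stick_breaking":
        shares = stick_breaking_abundances(k - 1, schema.stick_breaking_theta,
                                           "gem", rng)
        shares = shares[rng.permutation(k - 1)]  # decouple share size from identity
    else:
        shares = rng.dirichlet(np.ones(k - 1))
    out = np.empty(k)
    out[winner] = f
    out[losers] = (1.0 - f) * shares
    return out


def _feature_ids(groups: Sequence[CommunityGroup]) -> tuple[list, dict, dict]:
    fids, lineages, owners = [], {}, {}
    for g in groups:
        for j in range(g.schema.n_members):
            fid = f"{g.name}_m{j:02d}"
            fids.append(fid)
            lineages[fid] = g.lineage
            owners.setdefault(g.name, []).append(fid)
    return fids, lineages, owners


def simulate_community(spec: CommunitySpec):
    """Simulate a cross-sectional community under the two-step model.

    Returns ``(table, lineages, truth)`` where ``truth`` is a per (sample,
    group) frame with the generating schema, the true winner feature (empty
    for coexistence groups or samples with no winner above the cutoff), the
    winner's within-group fraction, and the group's allocated abundance.
    The table holds relative abundances, or Poisson counts when the spec sets
    a finite read depth.
    """
    rng = np.random.default_rng(spec.seed)
    groups = spec.groups
    fids, lineages, owners = _feature_ids(groups)
    n_feat = len(fids)
    sample_ids = [f"S{i:04d}" for i in range(spec.n_samples)]
    rel = np.zeros((n_feat, spec.n_samples))
    truth_rows = []
    conc = np.full(len(groups), spec.group_allocation_concentration)
    row_of = {fid: i for i, fid in enumerate(fids)}
    for s, sid in enumerate(sample_ids):
        alloc = rng.dirichlet(conc) if len(groups) > 1 else np.array([1.0])
        for gi, g in enumerate(groups):
            schema = g.schema
            if schema.schema == "coexistence" or schema.n_members == 1:
                winner = None
            else:
                winner = int(rng.choice(schema.n_members, p=schema.winner_probs()))
            fr = _within_group_fractions(schema, rng, winner)
            member_ids = owners[g.name]
            for j, fid in enumerate(member_ids):
                rel[row_of[fid], s] = alloc[gi] * fr[j]
            # realized winner under the 0.9 rule, from the generator's own
            # fractions -- ground truth independent of the analysis path
            jmax = int(np.argmax(fr))
            realized = member_ids[jmax] if fr[jmax] > 0.9 else ""
            truth_rows.append({
                "sample_id": sid, "group": g.name, "schema": schema.schema,
                "true_winner": member_ids[winner] if winner is not None else "",
                "realized_winner": realized,
                "winner_fraction": float(fr.max()),
                "group_abundance": float(alloc[gi]),
            })
    truth = pd.DataFrame(truth_rows)
    if spec.read_depth is None:
        table = AbundanceTable(pd.DataFrame(rel, index=fids, columns=sample_ids), "relative")
    else:
        counts = rng.poisson(rel * spec.read_depth).astype(float)
        table = AbundanceTable(pd.DataFrame(counts, index=fids, columns=sample_ids), "counts")
    return table, lineages, truth


def simulate_longitudinal(spec: CommunitySpec, n_subjects: int,
                          timepoints_per_subject: int, turnover_rate: float,
                          seed: int = 0, eligibility_floor: float = 0.005,
                          winner_cutoff: float = 0.9):
    """Simulate per-subject time series with planted winner turnovers.

    For every subject and every lottery group, a winner is drawn once and
    persists across time points, except that with probability
    ``turnover_rate`` a switch to a different member is planted at a random
    interior time point.  Fixed-winner and coexistence groups never switch.

    Returns ``(table, metadata, planted)``.  ``planted`` has one row per
    (subject, group) with the generative ``switched`` flag and the expressed
    ``turnover`` flag — whether distinct realized winners actually occur at
    two time points whose group allocation exceeds ``eligibility_floor``
    (a planted switch at a time point where the group fell below the floor is
    not expressed and cannot be detected by any method).
    """
    if timepoints_per_subject < 2:
        raise ValueError("timepoints_per_subject must be >= 2")
    rng = np.random.default_rng(seed)
    groups = spec.groups
    fids, lineages, owners = _feature_ids(groups)
    row_of = {fid: i for i, fid in enumerate(fids)}
    T = timepoints_per_subject
    conc = np.full(len(groups), spec.group_allocation_concentration)
    rel_cols, sample_ids, meta_rows = [], [], []
    planted_rows = []
    for subj in range(n_subjects):
        subject_id = f"subj{subj:03d}"
        winner0, switch_t, winner1 = {}, {}, {}
        for g in groups:
            schema = g.schema
            if schema.schema == "coexistence" or schema.n_members < 2:
                continue
            w0 = int(rng.choice(schema.n_members, p=schema.winner_probs()))
            winner0[g.name] = w0
            if (schema.schema == "lottery" and schema.n_members >= 2
                    and rng.random() < turnover_rate):
                switch_t[g.name] = int(rng.integers(1, T))
                others = [i for i in range(schema.n_members) if i != w0]
                p = schema.winner_probs()[others]
                p = p / p.sum() if p.sum() > 0 else np.full(len(others), 1 / len(others))
                winner1[g.name] = int(rng.choice(others, p=p))
        # realized winners / allocations per group per time point
        realized: dict = {g.name: [] for g in groups}
        allocs: dict = {g.name: [] for g in groups}
        for t in range(T):
            sid = f"subj{subj:03d}_t{t:02d}"
            sample_ids.append(sid)
            meta_rows.append({"sample_id": sid, "subject_id": subject_id,
                              "time_point": t, "dataset": "simulated"})
            alloc = rng.dirichlet(conc) if len(groups) > 1 else np.array([1.0])
            col = np.zeros(len(fids))
            for gi, g in enumerate(groups):
                schema = g.schema
                if g.name in winner0:
                    w = winner0[g.name]
                    if g.name in switch_t and t >= switch_t[g.name]:
                        w = winner1[g.name]
                else:
                    w = None
                fr = _within_group_fractions(schema, rng, w)
                member_ids = owners[g.name]
                for j, fid in enumerate(member_ids):
                    col[row_of[fid]] = alloc[gi] * fr[j]
                jmax = int(np.argmax(fr))
                realized[g.name].append(member_ids[jmax] if fr[jmax] > winner_cutoff else "")
                allocs[g.name].append(float(alloc[gi]))
            rel_cols.append(col)
        for g in groups:
            a = np.array(allocs[g.name])
            eligible_t = a > eligibility_floor
            winners_seen = {w for w, ok in zip(realized[g.name], eligible_t) if ok and w}
            planted_rows.append({
                "subject": f"subj{subj:03d}", "group": g.name,
                "schema": g.schema.schema,
                "switched": g.name in switch_t,
                "n_eligible_timepoints": int(eligible_t.sum()),
                "eligible": bool(eligible_t.sum() >= 2),
                "turnover": bool(eligible_t.sum() >= 2 and len(winners_seen) >= 2),
            })
    rel = np.column_stack(rel_cols)
    if spec.read_depth is None:
        table = AbundanceTable(pd.DataFrame(rel, index=fids, columns=sample_ids), "relative")
    else:
        counts = rng.poisson(rel * spec.read_depth).astype(float)
        table = AbundanceTable(pd.DataFrame(counts, index=fids, columns=sample_ids), "counts")
    metadata = pd.DataFrame(meta_rows)
    planted = pd.DataFrame(planted_rows)
    return table, metadata, planted


def poisson_noise_sweep(n_members: int, abundance_grid: Sequence[float],
                        read_depth: int, n_reps: int, seed: int = 0,
                        winner_cutoff: float = 0.9) -> pd.DataFrame:
    """Estimate how sampling noise manufactures artificial winners.

    Each replicate puts ``n_members`` features at the *same* true abundance
    ``a`` and draws counts ~ Poisson(a x read_depth) per feature.  With
    perfect abundance estimates no member could exceed the winner cutoff, so
    any winner observed is an artifact of counting noise.  Replicates whose
    total count is zero are dropped.  Returns one row per grid abundance with
    the estimated winner prevalence, its Monte-Carlo standard error, and the
    number of retained replicates.
    """
    if n_members < 2:
        raise ValueError("n_members must be >= 2")
    grid = list(abundance_grid)
    if not grid:
        raise ValueError("abundance_grid must not be empty")
    if any(a <= 0 for a in grid):
        raise ValueError("grid abundances must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for a in grid:
        counts = rng.poisson(a * read_depth, size=(n_reps, n_members)).astype(float)
        totals = counts.sum(axis=1)
        kept = totals > 0
        n_kept = int(kept.sum())
        if n_kept == 0:
            prev, se = np.nan, np.nan
        else:
            fr = counts[kept] / totals[kept, None]
            wins = (fr.max(axis=1) > winner_cutoff)
            prev = float(wins.mean())
            se = float(np.sqrt(prev * (1 - prev) / n_kept))
        rows.append({"abundance": a, "expected_count": a * read_depth,
                     "winner_prevalence": prev, "mc_se": se, "n_kept": n_kept})
    return pd.DataFrame(rows)


def simulate_gene_counts(group_classes, effect: float, dispersion: float,
                         seed: int = 0, n_species_per_group: int = 5,
                         lottery_mean: float = 2000.0,
                         ko_fraction: float = 0.7) -> pd.DataFrame:
    """Draw per-species genome gene counts around class-dependent means.

    ``group_classes`` maps genus -> {"lottery_like", "non_lottery"}; species
    in lottery-like genera get mean ``lottery_mean`` total genes and species
    in non-lottery genera ``lottery_mean + effect``, with Gaussian dispersion,
    rounded to a positive integer.  The KO-annotated share is binomial with
    probability ``ko_fraction``.  Output matches the genome-table input
    contract: species_id, genus, n_genes_total, n_genes_ko, n_genes_no_ko.
    """
    classes = set(group_classes.values())
    if not classes <= {"lottery_like", "non_lottery"}:
        raise ValueError(f"unknown classes: {classes}")
    if len(classes) < 2:
        raise ValueError("need at least two group classes")
    rng = np.random.default_rng(seed)
    rows = []
    for genus in sorted(group_classes):
        mean = lottery_mean if group_classes[genus] == "lottery_like" else lottery_mean + effect
        for j in range(n_species_per_group):
            total = max(1, int(round(rng.normal(mean, dispersion))))
            n_ko = int(rng.binomial(total, ko_fraction))
            rows.append({"species_id": f"{genus}_sp{j:02d}", "genus": genus,
                         "n_genes_total": total, "n_genes_ko": n_ko,
                         "n_genes_no_ko": total - n_ko})
    return pd.DataFrame(rows)


def build_community_spec(schemas: Sequence[str], n_members: int = 5,
                         n_samples: int = 1000, seed: int = 0,
                         read_depth: Optional[int] = None,
                         group_allocation_concentration: float = 1.0,
                         genera_per_family: int = 2,
                         families_per_phylum: int = 2) -> CommunitySpec:
    """Convenience builder: one genus-level group per schema string.

    Genera are nested two-per-family and families two-per-phylum (by default)
    so the same community exercises the hierarchical scan.
    """
    groups = []
    for i, schema in enumerate(schemas):
        fam = i // genera_per_family
        phy = fam // families_per_phylum
        lineage = Lineage.from_ranks(
            kingdom="k__Bacteria", phylum=f"p__P{phy:02d}", **{"class": f"c__C{phy:02d}"},
            order=f"o__O{phy:02d}", family=f"f__F{fam:02d}", genus=f"g__G{i:02d}")
        groups.append(CommunityGroup(lineage, SchemaSpec(schema, n_members)))
    return CommunitySpec(tuple(groups), n_samples=n_samples, read_depth=read_depth,
                         group_allocation_concentration=group_allocation_concentration,
                         seed=seed)
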