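"""Cross-dataset comparison, genome gene-content tests, and report tables.

Lottery parameters estimated independently in two cohorts are compared by
Spearman rank correlation over the groups present in both.  For the genomic
question — do members of lottery-like genera carry fewer genes? — genera are
first partitioned by winner prevalence (restricted to genera with high winner
diversity, i.e. excluding fixed-winner groups), and per-species gene counts
are compared between classes with a two-sided Mann-Whitney rank-sum test
(Welch's t is available behind a flag).  No multiple-testing correction is
applied across the three gene-count fields (total / KO-annotated /
unannotated); the raw p-values are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import GroupLotteryResult, MetricConfig, results_to_frame

__all__ = [
    "DatasetResults",
    "ComparisonResult",
    "GeneComparisonResult",
    "compare_datasets",
    "select_genome_comparison_groups",
    "compare_gene_counts",
    "read_genome_table",
    "build_report",
]

GENOME_TABLE_COLUMNS = ("species_id", "genus", "n_genes_total", "n_genes_ko", "n_genes_no_ko")


@dataclass
class DatasetResults:
    """Lottery results for one dataset, keyed by (rank, group name)."""

    dataset_label: str
    results: dict

    @classmethod
    def from_results(cls, label: str, results: Sequence[GroupLotteryResult]) -> "DatasetResults":
        keyed: dict = {}
        for r in results:
            key = (r.rank, r.group_name)
            if key in keyed:
                raise ValueError(f"duplicate result for {key} in dataset {label!r}")
            keyed[key] = r
        return cls(label, keyed)

    def parameter(self, key: tuple, parameter: str) -> Optional[float]:
        r = self.results.get(key)
        if r is None:
            return None
        if parameter == "prevalence":
            return r.winner_prevalence
        if parameter == "diversity":
            return r.winner_diversity_normalized
        raise ValueError(f"unknown parameter {parameter!r}")


@dataclass
class ComparisonResult:
    rho: float
    p_value: float
    n_shared_groups: int
    paired: pd.DataFrame


def compare_datasets(a: DatasetResults, b: DatasetResults,
                     parameter: str = "prevalence") -> ComparisonResult:
    """Spearman correlation of a lottery parameter across two datasets.

    Only (rank, group) keys present in both datasets enter; groups with a
    missing value (e.g. diversity undefined because no winner was ever seen)
    are excluded.  Requires at least 3 shared groups.
    """
    rows = []
    for key in sorted(set(a.results) & set(b.results)):
        va, vb = a.parameter(key, parameter), b.parameter(key, parameter)
        if va is None or vb is None:
            continue
        rows.append({"rank": key[0], "group": key[1],
                     a.dataset_label: va, b.dataset_label: vb})
    if len(rows) < 3:
        raise ValueError(f"only {len(rows)} shared groups; need at least 3")
    paired = pd.DataFrame(rows)
    rho, p = stats.spearmanr(paired[a.dataset_label], paired[b.dataset_label])
    return ComparisonResult(float(rho), float(p), len(rows), paired)


def select_genome_comparison_groups(results: Sequence[DatasetResults],
                                    cfg: MetricConfig = MetricConfig(),
                                    rank: str = "genus") -> dict:
    """Partition genera into high / low winner-prevalence classes.

    The first dataset is the primary.  Only genus-rank groups whose winner
    diversity strictly exceeds the diversity threshold in the primary dataset
    are eligible (fixed-winner genera are ignored).  The *high* class requires
    prevalence strictly above the prevalence threshold in the primary AND in
    at least one other dataset; the *low* class requires prevalence strictly
    below the threshold in the primary.  Genera meeting neither rule (e.g.
    prevalence exactly at the threshold, or high only in the primary) are
    reported as "unclassified".
    """
    if len(results) < 2:
        raise ValueError("need a primary and at least one other dataset")
    primary, others = results[0], results[1:]
    classes: dict = {}
    for (r, name), res in sorted(primary.results.items()):
        if r != rank:
            continue
        div = res.winner_diversity_normalized
        if div is None or not div > cfg.diversity_threshold:
            continue
        prev = res.winner_prevalence
        if prev > cfg.prevalence_threshold:
            confirmed = any(
                (o.parameter((rank, name), "prevalence") or 0.0) > cfg.prevalence_threshold
                for o in others)
            classes[name] = "high" if confirmed else "unclassified"
        elif prev < cfg.prevalence_threshold:
            classes[name] = "low"
        else:
            classes[name] = "unclassified"
    for cls in ("high", "low"):
        if cls not in classes.values():
            raise ValueError(f"no genera in the {cls!r} winner-prevalence class")
    return classes


@dataclass
class GeneComparisonResult:
    field: str
    statistic: float
    p_value: float
    summaries: pd.DataFrame
    method: str


def read_genome_table(path) -> pd.DataFrame:
    """Read and validate the per-species genome gene-count TSV."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in GENOME_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"genome table missing columns: {missing}")
    for col in ("n_genes_total", "n_genes_ko", "n_genes_no_ko"):
        if (frame[col] < 0).any():
            raise ValueError(f"negative gene counts in column {col!r}")
    bad = frame["n_genes_total"] != frame["n_genes_ko"] + frame["n_genes_no_ko"]
    if bad.any():
        raise ValueError(
            f"n_genes_total != n_genes_ko + n_genes_no_ko for species "
            f"{frame.loc[bad, 'species_id'].tolist()[:5]}")
    return frame


_FIELD_COLUMNS = {"total": "n_genes_total", "ko_annotated": "n_genes_ko",
                  "unannotated": "n_genes_no_ko"}


def compare_gene_counts(genomes: pd.DataFrame, classes: Mapping[str, str],
                        field: str = "total", method: str = "ranksum",
                        ) -> GeneComparisonResult:
    """Compare per-species gene counts between prevalence classes.

    ``classes`` maps genus to "high" / "low" (other labels are ignored);
    species whose genus is not classified are dropped with a warning.  The
    default test is a two-sided Mann-Whitney rank-sum; ``method="welch"``
    uses Welch's unequal-variance t instead.
    """
    col = _FIELD_COLUMNS.get(field)
    if col is None:
        raise ValueError(f"field must be one of {sorted(_FIELD_COLUMNS)}, got {field!r}")
    cls = genomes["genus"].map(lambda g: classes.get(g))
    dropped = genomes.loc[~cls.isin(["high", "low"]), "species_id"]
    if len(dropped):
        warnings.warn(f"dropping {len(dropped)} species without a classified genus",
                      stacklevel=2)
    high = genomes.loc[cls == "high", col].to_numpy(dtype=float)
    low = genomes.loc[cls == "low", col].to_numpy(dtype=float)
    if len(high) < 2 or len(low) < 2:
        raise ValueError(
            f"need at least 2 species per class, got high={len(high)}, low={len(low)}")
    if method == "ranksum":
        stat, p = stats.mannwhitneyu(high, low, alternative="two-sided")
    elif method == "welch":
        stat, p = stats.ttest_ind(high, low, equal_var=False)
    else:
        raise ValueError(f"method must be 'ranksum' or 'welch', got {method!r}")
    summaries = pd.DataFrame({
        "class": ["high", "low"],
        "n_species": [len(high), len(low)],
        "mean": [high.mean(), low.mean()],
        "median": [float(np.median(high)), float(np.median(low))],
    })
    return GeneComparisonResult(field, float(stat), float(p), summaries, method)


def build_report(outdir, *, genus_results: Optional[Sequence[GroupLotteryResult]] = None,
                 hierarchy_results: Optional[Sequence[GroupLotteryResult]] = None,
                 ordered_matrices: Optional[Mapping[str, pd.DataFrame]] = None,
                 comparisons: Optional[Sequence[ComparisonResult]] = None,
                 turnover_frame: Optional[pd.DataFrame] = None,
                 gene_comparisons: Optional[Sequence[GeneComparisonResult]] = None,
                 cfg: MetricConfig = MetricConfig(),
                 run_config: Optional[dict] = None) -> list:
    """Write the analysis bundle as TSV files plus a run-metadata log.

    Only the pieces supplied are written.  Output is deterministic: the same
    inputs produce byte-identical files.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(frame: pd.DataFrame, name: str) -> None:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False)
        written.append(path)

    if genus_results is not None:
        _write(results_to_frame(genus_results, cfg), "group_stats.tsv")
        calls = [{"sample": c.sample_id, "group": c.group_name,
                  "winner": c.winner if c.winner is not None else "-",
                  "winner_fraction": c.winner_fraction}
                 for r in genus_results for c in r.calls]
        _write(pd.DataFrame(calls), "winner_calls.tsv")
    if hierarchy_results is not None:
        _write(results_to_frame(hierarchy_results, cfg), "hierarchy_stats.tsv")
    if ordered_matrices is not None:
        rows = []
        for group, frame in sorted(ordered_matrices.items()):
            long = frame.stack().rename("fraction").reset_index()
            long.columns = ["member", "sample", "fraction"]
            long.insert(0, "group", group)
            rows.append(long)
        if rows:
            _write(pd.concat(rows, ignore_index=True), "ordered_matrices.tsv")
    if comparisons is not None:
        rows = []
        for c in comparisons:
            labels = [col for col in c.paired.columns if col not in ("rank", "group")]
            rows.append({"dataset_a": labels[0], "dataset_b": labels[1],
                         "rho": c.rho, "p_value": c.p_value, "n_shared": c.n_shared_groups})
        _write(pd.DataFrame(rows), "dataset_comparison.tsv")
    if turnover_frame is not None:
        _write(turnover_frame, "turnover.tsv")
    if gene_comparisons is not None:
        rows = [{"field": g.field, "method": g.method, "statistic": g.statistic,
                 "p_value": g.p_value} for g in gene_comparisons]
        _write(pd.DataFrame(rows), "gene_comparison.tsv")

    import json

    from . import __version__

    meta = {"package_version": __version__, "metric_config": {
        "winner_cutoff": cfg.winner_cutoff,
        "sample_inclusion_min_group_abundance": cfg.sample_inclusion_min_group_abundance,
        "prevalence_threshold": cfg.prevalence_threshold,
        "diversity_threshold": cfg.diversity_threshold,
        "top_k": cfg.top_k,
    }}
    if run_config:
        meta["run_config"] = run_config
    path = outdir / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    written.append(path)
    return written
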