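"""Abundance-table I/O, inclusion filters, and taxonomic grouping.

This module holds the data model the rest of the pipeline consumes: a
feature-by-sample abundance matrix (:class:`AbundanceTable`), per-feature
taxonomic lineages (:class:`Lineage`), and the rank-wise grouping of features
into taxa (:class:`GroupAssignment`).  It reads the field-standard table
formats (BIOM 2.x HDF5, QIIME-classic TSV, MetaPhlAn merged tables) and
applies the standard inclusion filters used before any lottery statistic is
computed:

* drop low-depth samples (column sum below a read floor, on counts),
* convert to relative abundance per sample,
* drop rare features (present above an abundance floor in too few samples),
* drop rare taxonomic groups by the same logic on summed group abundance.

All abundance thresholds are strict inequalities, and the "minimum number of
samples" rules are ``max(floor, ceil(fraction * n_samples))``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "Lineage",
    "AbundanceTable",
    "FilterConfig",
    "GroupAssignment",
    "TableParseError",
    "read_biom_table",
    "read_tsv_table",
    "write_tsv_table",
    "read_metaphlan_table",
    "read_taxonomy_tsv",
    "read_sample_metadata",
    "filter_samples",
    "to_relative",
    "filter_features",
    "build_groups",
    "filter_groups",
    "min_required_samples",
]

#: Taxonomic ranks from coarsest to finest. 16S tables typically annotate
#: down to genus; shotgun (MetaPhlAn) tables reach species.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_PREFIX_TO_RANK = {
    "k": "kingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}
_RANK_TO_PREFIX = {v: k for k, v in _PREFIX_TO_RANK.items()}

# Tokens that mean "no annotation at this rank" in GreenGenes-style strings.
_MISSING_TOKENS = {"", "unclassified", "unknown", "unassigned", "none"}


class TableParseError(ValueError):
    """Raised when an input table or taxonomy file cannot be parsed."""


# ---------------------------------------------------------------------------
# Lineage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Lineage:
    """Ordered taxonomic annotation for one feature.

    ``names`` is a 7-tuple aligned with :data:`RANKS`; ``None`` marks an
    unannotated rank.  Once a rank is unannotated every finer rank is
    unannotated too (annotations are prefix-closed).
    """

    names: tuple

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise ValueError(f"lineage must have {len(RANKS)} ranks, got {len(self.names)}")
        gap = False
        for nm in self.names:
            if nm is None:
                gap = True
            elif gap:
                raise ValueError("rank annotated below an unannotated rank")
            elif not isinstance(nm, str) or not nm:
                raise ValueError(f"rank names must be non-empty strings, got {nm!r}")

    # -- constructors -------------------------------------------------------

    @classmethod
    def unannotated(cls) -> "Lineage":
        return cls((None,) * len(RANKS))

    @classmethod
    def from_ranks(cls, **kwargs: Optional[str]) -> "Lineage":
        """Build from keyword rank names, closing the annotation prefix."""
        names = [kwargs.get(rank) for rank in RANKS]
        return cls(_close(names))

    @classmethod
    def from_greengenes(cls, text: Optional[str]) -> "Lineage":
        """Parse a GreenGenes-style string ``k__Bacteria; p__Firmicutes; ...``.

        Empty suffixes (``g__``), "unclassified" tokens, and missing ranks all
        map to unannotated; everything below the first unannotated rank is
        dropped so the prefix-closure invariant holds.
        """
        names: list = [None] * len(RANKS)
        if text is None:
            return cls.unannotated()
        for token in str(text).split(";"):
            token = token.strip().strip('"').strip()
            if not token:
                continue
            if len(token) >= 3 and token[1:3] == "__":
                prefix, value = token[0].lower(), token[3:].strip()
            else:
                raise TableParseError(f"unrecognized lineage token {token!r}")
            rank = _PREFIX_TO_RANK.get(prefix)
            if rank is None:
                raise TableParseError(f"unrecognized rank prefix in token {token!r}")
            if value.lower() in _MISSING_TOKENS:
                continue
            names[RANKS.index(rank)] = value
        return cls(_close(names))

    @classmethod
    def from_clade_path(cls, path: str) -> "Lineage":
        """Parse a MetaPhlAn clade path ``k__A|p__B|...|s__X``.

        The path must start at kingdom and use ranks in canonical order with
        no gaps; anything else is a parse error.
        """
        names: list = [None] * len(RANKS)
        tokens = [t.strip() for t in str(path).split("|")]
        for i, token in enumerate(tokens):
            if len(token) < 3 or token[1:3] != "__":
                raise TableParseError(f"unrecognized clade token {token!r} in {path!r}")
            rank = _PREFIX_TO_RANK.get(token[0].lower())
            if rank is None or RANKS.index(rank) != i:
                raise TableParseError(f"clade path ranks out of order in {path!r}")
            value = token[3:].strip()
            if value.lower() in _MISSING_TOKENS:
                break
            names[i] = value
        return cls(_close(names))

    # -- accessors ----------------------------------------------------------

    def get(self, rank: str) -> Optional[str]:
        return self.names[RANKS.index(rank)]

    def annotated_at(self, rank: str) -> bool:
        return self.get(rank) is not None

    @property
    def depth(self) -> int:
        """Number of annotated ranks (prefix length)."""
        return sum(nm is not None for nm in self.names)

    def to_greengenes(self, n_ranks: int = 7) -> str:
        parts = []
        for rank, nm in zip(RANKS[:n_ranks], self.names[:n_ranks]):
            parts.append(f"{_RANK_TO_PREFIX[rank]}__{nm if nm is not None else ''}")
        return "; ".join(parts)


def _close(names: Sequence[Optional[str]]) -> tuple:
    """Truncate a rank-name list at its first unannotated rank."""
    out: list = []
    gap = False
    for nm in names:
        if nm is None or gap:
            out.append(None)
            gap = True
        else:
            out.append(nm)
    return tuple(out)


# ---------------------------------------------------------------------------
# AbundanceTable
# ---------------------------------------------------------------------------


@dataclass
class AbundanceTable:
    """A feature-by-sample abundance matrix.

    ``data`` has features as rows and samples as columns; ``kind`` is
    ``"counts"`` (non-negative reads) or ``"relative"`` (per-sample fractions;
    column sums may be below 1 after feature filtering, never above).
    """

    data: pd.DataFrame
    kind: str

    _REL_TOL = 1e-6

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise ValueError(f"kind must be 'counts' or 'relative', got {self.kind!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise TableParseError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise TableParseError(f"duplicate sample ids: {dups[:5]}")
        vals = self.data.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            raise ValueError("abundance values must be non-negative")
        if self.kind == "relative" and vals.size:
            sums = vals.sum(axis=0)
            if np.any(sums > 1 + self._REL_TOL):
                bad = self.data.columns[sums > 1 + self._REL_TOL].tolist()
                raise ValueError(f"relative columns sum above 1: {bad[:5]}")

    @property
    def feature_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(self.data.copy(), self.kind)


# ---------------------------------------------------------------------------
# Configuration & grouping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterConfig:
    """Inclusion thresholds applied before lottery statistics.

    Defaults: samples need at least 5000 reads; a feature must exceed 0.05%
    relative abundance in at least 0.5% of samples (minimum 10); a group must
    exceed 0.5% abundance by the same sample rule.  For very large cohorts an
    absolute override (e.g. "more than 200 samples") can replace the group
    sample rule.
    """

    min_reads_per_sample: int = 5000
    otu_min_abundance: float = 0.0005
    otu_min_sample_fraction: float = 0.005
    otu_min_samples_floor: int = 10
    group_min_abundance: float = 0.005
    group_min_sample_fraction: float = 0.005
    group_min_samples_floor: int = 10
    group_min_samples_override: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("otu_min_abundance", "otu_min_sample_fraction",
                     "group_min_abundance", "group_min_sample_fraction"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("min_reads_per_sample", "otu_min_samples_floor",
                     "group_min_samples_floor"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v}")
        if self.group_min_samples_override is not None and self.group_min_samples_override < 1:
            raise ValueError("group_min_samples_override must be >= 1")


@dataclass(frozen=True)
class GroupAssignment:
    """A taxonomic group at one rank: the set of member identifiers.

    At the base rank members are feature ids; at higher ranks they are the
    names of the immediately-lower-rank subgroups.
    """

    rank: str
    group_name: str
    members: tuple

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.group_name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"group {self.group_name!r} has duplicate members")
        object.__setattr__(self, "members", tuple(sorted(self.members)))

    @property
    def n_members(self) -> int:
        return len(self.members)


def min_required_samples(n_samples: int, fraction: float, floor: int) -> int:
    """``max(floor, ceil(fraction * n_samples))`` with float-noise guard."""
    return max(floor, math.ceil(fraction * n_samples - 1e-9))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_tsv_table(path) -> tuple[AbundanceTable, dict]:
    """Read a QIIME-classic TSV OTU table.

    Layout: optional leading comment lines starting with ``#``, then a header
    line beginning ``#OTU ID`` with sample ids (and optionally a final
    ``taxonomy`` column), then one row per feature.  Returns the counts table
    and a ``{feature_id: Lineage}`` dict (all-unannotated when no taxonomy
    column is present).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header = None
    data_lines = []
    for ln in lines:
        if not ln.strip():
            continue
        if header is None:
            if ln.startswith("#OTU ID"):
                header = ln.rstrip("\n").split("\t")
            elif ln.startswith("#"):
                continue
            else:
                raise TableParseError(f"{path}: expected '#OTU ID' header before row {ln[:40]!r}")
        else:
            data_lines.append(ln)
    if header is None:
        raise TableParseError(f"{path}: no '#OTU ID' header found")
    has_tax = header[-1].strip().lower() == "taxonomy"
    sample_ids = header[1:-1] if has_tax else header[1:]
    rows, lineages = {}, {}
    for ln in data_lines:
        parts = ln.split("\t")
        fid = parts[0]
        if fid in rows:
            raise TableParseError(f"{path}: duplicate feature id {fid!r}")
        vals = parts[1:len(sample_ids) + 1]
        if len(vals) != len(sample_ids):
            raise TableParseError(f"{path}: row {fid!r} has {len(vals)} values, expected {len(sample_ids)}")
        try:
            rows[fid] = [float(v) for v in vals]
        except ValueError as exc:
            raise TableParseError(f"{path}: non-numeric value in row {fid!r}: {exc}") from exc
        tax = parts[len(sample_ids) + 1] if has_tax and len(parts) > len(sample_ids) + 1 else None
        lineages[fid] = Lineage.from_greengenes(tax)
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    return AbundanceTable(frame, "counts"), lineages


def write_tsv_table(table: AbundanceTable, lineages: Optional[Mapping], path) -> None:
    """Write the QIIME-classic TSV dialect that :func:`read_tsv_table` reads."""
    path = Path(path)
    with path.open("w") as fh:
        cols = "\t".join(str(s) for s in table.sample_ids)
        fh.write(f"#OTU ID\t{cols}" + ("\ttaxonomy\n" if lineages is not None else "\n"))
        for fid in table.feature_ids:
            vals = "\t".join(repr(float(v)) for v in table.data.loc[fid])
            if lineages is not None:
                tax = lineages.get(fid, Lineage.unannotated()).to_greengenes(6)
                fh.write(f"{fid}\t{vals}\t{tax}\n")
            else:
                fh.write(f"{fid}\t{vals}\n")


def read_biom_table(path) -> tuple[AbundanceTable, dict]:
    """Read a BIOM 2.x (HDF5) table, or fall back to the TSV dialect.

    Taxonomy is taken from the ``observation/metadata/taxonomy`` dataset when
    present; features lacking taxonomy get an all-unannotated lineage.
    """
    import h5py

    path = Path(path)
    if not h5py.is_hdf5(path):
        return read_tsv_table(path)
    with h5py.File(path, "r") as f:
        try:
            obs_ids = [_decode(x) for x in f["observation/ids"][:]]
            samp_ids = [_decode(x) for x in f["sample/ids"][:]]
            data = f["observation/matrix/data"][:]
            indices = f["observation/matrix/indices"][:]
            indptr = f["observation/matrix/indptr"][:]
        except KeyError as exc:
            raise TableParseError(f"{path}: not a BIOM 2.x file (missing {exc})") from exc
        from scipy import sparse

        mat = sparse.csr_matrix((data, indices, indptr), shape=(len(obs_ids), len(samp_ids)))
        if len(set(obs_ids)) != len(obs_ids):
            dup = sorted({x for x in obs_ids if obs_ids.count(x) > 1})
            raise TableParseError(f"{path}: duplicate feature id {dup[0]!r}")
        frame = pd.DataFrame(mat.toarray(), index=obs_ids, columns=samp_ids, dtype=float)
        lineages = {fid: Lineage.unannotated() for fid in obs_ids}
        if "observation/metadata/taxonomy" in f:
            tax = f["observation/metadata/taxonomy"][:]
            for i, fid in enumerate(obs_ids):
                row = tax[i]
                if isinstance(row, (bytes, str)):
                    text = _decode(row)
                else:
                    text = "; ".join(_decode(t) for t in row)
                lineages[fid] = Lineage.from_greengenes(text)
    return AbundanceTable(frame, "counts"), lineages


def _decode(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


def read_metaphlan_table(path) -> tuple[AbundanceTable, dict]:
    """Read a MetaPhlAn-2-style merged relative-abundance table.

    First column: clade path with ``|`` rank separators; remaining columns:
    per-sample abundances in percent.  Only rows at the deepest rank present
    (species for full profiles) are kept as base features; intermediate-rank
    summary rows are dropped.  Percentages are converted to fractions.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    header = None
    records = []
    for ln in lines:
        if header is None:
            if ln.startswith("#") and "\t" not in ln:
                continue
            header = ln.lstrip("#").split("\t")
            continue
        parts = ln.split("\t")
        clade = parts[0]
        lineage = Lineage.from_clade_path(clade)
        vals = parts[1:]
        if len(vals) != len(header) - 1:
            raise TableParseError(f"{path}: row {clade!r} has wrong column count")
        values = [float(v) for v in vals]
        if any(v < 0 for v in values):
            raise TableParseError(f"{path}: negative abundance in row {clade!r}")
        records.append((clade, clade.count("|") + 1, lineage, values))
    if header is None or not records:
        raise TableParseError(f"{path}: no data rows")
    max_depth = max(depth for _, depth, _, _ in records)
    kept = [(clade, ln_, vals) for clade, depth, ln_, vals in records if depth == max_depth]
    if not kept:
        raise TableParseError(f"{path}: no base features")
    sample_ids = header[1:]
    rows, lineages = {}, {}
    for clade, lineage, vals in kept:
        fid = clade.split("|")[-1]
        if fid in rows:
            raise TableParseError(f"{path}: duplicate base feature {fid!r}")
        rows[fid] = [v / 100.0 for v in vals]
        lineages[fid] = lineage
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    return AbundanceTable(frame, "relative"), lineages


def read_taxonomy_tsv(path) -> dict:
    """Read a 2-column ``feature_id <tab> lineage-string`` TSV."""
    path = Path(path)
    out: dict = {}
    for ln in path.read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) < 2:
            raise TableParseError(f"{path}: expected 2 columns in line {ln[:40]!r}")
        fid = parts[0].strip()
        if fid.lower() in ("feature id", "feature_id", "otu id", "otu_id"):
            continue
        if fid in out:
            raise TableParseError(f"{path}: duplicate feature id {fid!r}")
        out[fid] = Lineage.from_greengenes(parts[1])
    return out


def read_sample_metadata(path) -> pd.DataFrame:
    """Read a sample-metadata TSV with required column ``sample_id``.

    Optional columns: ``subject_id``, ``time_point``, ``dataset``.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    frame.columns = [c.lstrip("#") for c in frame.columns]
    if "sample_id" not in frame.columns:
        raise TableParseError(f"{path}: metadata must have a 'sample_id' column")
    if frame["sample_id"].duplicated().any():
        dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise TableParseError(f"{path}: duplicate sample ids {dups[:5]}")
    if "time_point" in frame.columns:
        frame["time_point"] = pd.to_numeric(frame["time_point"])
    return frame


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_samples(table: AbundanceTable, cfg: FilterConfig = FilterConfig()) -> AbundanceTable:
    """Drop samples whose total counts fall below the read floor (strictly)."""
    if table.kind != "counts":
        raise ValueError("filter_samples operates on count tables")
    sums = table.data.sum(axis=0)
    keep = sums >= cfg.min_reads_per_sample
    if not keep.any():
        raise ValueError("no samples survive the read-depth filter")
    return AbundanceTable(table.data.loc[:, keep], "counts")


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide every sample column by its own sum over the current features."""
    if table.kind != "counts":
        raise ValueError("to_relative expects a count table")
    sums = table.data.sum(axis=0)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0].tolist()
        raise ValueError(f"zero-sum sample columns: {bad[:5]}")
    return AbundanceTable(table.data.div(sums, axis=1), "relative")


def filter_features(table: AbundanceTable, cfg: FilterConfig = FilterConfig()) -> AbundanceTable:
    """Drop features too rare to analyze.

    A feature is retained iff the number of samples where its relative
    abundance is strictly above ``otu_min_abundance`` reaches
    ``max(otu_min_samples_floor, ceil(otu_min_sample_fraction * n_samples))``.
    Columns are *not* renormalized afterwards, so within-group fractions are
    unaffected by unrelated features.
    """
    if table.kind != "relative":
        raise ValueError("filter_features operates on relative tables")
    need = min_required_samples(table.n_samples, cfg.otu_min_sample_fraction,
                                cfg.otu_min_samples_floor)
    qualifying = (table.data > cfg.otu_min_abundance).sum(axis=1)
    keep = qualifying >= need
    if not keep.any():
        warnings.warn("no features survive the abundance filter", stacklevel=2)
    return AbundanceTable(table.data.loc[keep], "relative")


def build_groups(lineages: Mapping[str, Lineage], rank: str) -> list[GroupAssignment]:
    """Group features by their annotated name at ``rank``.

    Features unannotated at the rank belong to no group.  Groups are returned
    sorted by name.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    buckets: dict = {}
    for fid, lineage in lineages.items():
        name = lineage.get(rank)
        if name is not None:
            buckets.setdefault(name, []).append(fid)
    return [GroupAssignment(rank, name, tuple(members))
            for name, members in sorted(buckets.items())]


def group_abundance(table: AbundanceTable, group: GroupAssignment) -> pd.Series:
    """Per-sample summed abundance of a group's members."""
    members = [m for m in group.members if m in table.data.index]
    if not members:
        return pd.Series(0.0, index=table.data.columns)
    return table.data.loc[members].sum(axis=0)


def filter_groups(table: AbundanceTable, groups: Sequence[GroupAssignment],
                  cfg: FilterConfig = FilterConfig()) -> list[GroupAssignment]:
    """Keep groups abundant enough for robust statistics.

    A group is retained iff the number of samples where its summed abundance
    is strictly above ``group_min_abundance`` reaches
    ``max(floor, ceil(fraction * n_samples))`` — or, when
    ``group_min_samples_override`` is set, strictly exceeds that override
    (used for very large cohorts).
    """
    if table.kind != "relative":
        raise ValueError("filter_groups operates on relative tables")
    need = min_required_samples(table.n_samples, cfg.group_min_sample_fraction,
                                cfg.group_min_samples_floor)
    kept = []
    for grp in groups:
        count = int((group_abundance(table, grp) > cfg.group_min_abundance).sum())
        if cfg.group_min_samples_override is not None:
            ok = count > cfg.group_min_samples_override
        else:
            ok = count >= need
        if ok:
            kept.append(grp)
    return kept
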