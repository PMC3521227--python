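"""Core containers and text I/O: expression matrices, labels, GMT catalogues.

Expression matrices are plain tab-separated text with genes in rows and a
header row of sample identifiers; class labels live in a separate
two-column file mapping each sample to ``class1`` (control) or ``class2``
(case).  Gene-set catalogues use the Broad GMT dialect: one set per line,
``name<TAB>description<TAB>gene1<TAB>gene2...``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

#: Label of the control group.
CONTROL = "class1"
#: Label of the case group (the more malignant phenotype by convention).
CASE = "class2"

VALID_LABELS = frozenset({CONTROL, CASE})


class DataError(ValueError):
    """Raised on malformed input files or invalid container state."""


@dataclass
class ExpressionDataset:
    """A genes x samples log-scale expression matrix with two-class labels.

    Parameters
    ----------
    name:
        Dataset identifier used in provenance tracking.
    values:
        DataFrame indexed by gene id with sample ids as columns; all
        entries must be finite.
    labels:
        Series mapping every sample id to ``class1`` or ``class2``.
    """

    name: str
    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DataError(f"duplicate gene id {dup!r} in dataset {self.name!r}")
        if self.values.columns.has_duplicates:
            raise DataError(f"duplicate sample id in dataset {self.name!r}")
        self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()][0]
            raise DataError(f"sample {missing!r} has no class label")
        bad = set(self.labels.unique()) - VALID_LABELS
        if bad:
            raise DataError(f"invalid class labels {sorted(bad)}; expected {sorted(VALID_LABELS)}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise DataError(
                f"non-finite value for gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_mask(self, label: str) -> np.ndarray:
        """Boolean mask over samples belonging to ``label``."""
        return (self.labels == label).to_numpy()

    def class_counts(self) -> tuple[int, int]:
        """(control, case) sample counts."""
        return int(self.class_mask(CONTROL).sum()), int(self.class_mask(CASE).sum())

    def subset_samples(self, sample_ids: Iterable[str], name: str | None = None) -> "ExpressionDataset":
        ids = list(sample_ids)
        return ExpressionDataset(
            name=name or self.name,
            values=self.values.loc[:, ids].copy(),
            labels=self.labels.loc[ids].copy(),
        )

    def subset_genes(self, gene_ids: Iterable[str], name: str | None = None) -> "ExpressionDataset":
        ids = list(gene_ids)
        return ExpressionDataset(
            name=name or self.name,
            values=self.values.loc[ids].copy(),
            labels=self.labels.copy(),
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise DataError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise DataError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)

    def measured_members(self, gene_ids: pd.Index | Iterable[str]) -> list[str]:
        """Members present in a measured gene universe, catalogue order."""
        universe = set(gene_ids)
        return [g for g in self.members if g in universe]


@dataclass
class GeneSetCollection:
    """An ordered mapping of pathway name -> :class:`GeneSet`."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise DataError(f"key {name!r} does not match set name {gs.name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    @classmethod
    def from_sets(cls, sets: Iterable[GeneSet]) -> "GeneSetCollection":
        out: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.name in out:
                raise DataError(f"duplicate gene set name {gs.name!r}")
            out[gs.name] = gs
        return cls(out)


@dataclass
class PathwayExpression:
    """A pathways x samples activity matrix produced by one method."""

    method: str
    values: pd.DataFrame  # pathways x samples
    provenance: str  # name of the training dataset the aggregator was fitted on

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise DataError(f"non-finite pathway activity ({self.method})")

    @property
    def pathway_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# GMT catalogues


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a Broad-style GMT file.

    Each non-blank line holds ``name<TAB>description<TAB>member...`` with at
    least one member.  Duplicate members within a line are collapsed keeping
    the first occurrence; duplicate set names are an error.
    """
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            name, description = fields[0], fields[1]
            members: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if g and g not in seen:
                    members.append(g)
                    seen.add(g)
            if not members:
                raise DataError(f"{path}: line {lineno}: gene set {name!r} has no members")
            if name in sets:
                raise DataError(f"{path}: line {lineno}: duplicate gene set name {name!r}")
            sets[name] = GeneSet(name, description, tuple(members))
    return GeneSetCollection(sets)


def write_gmt(col: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in col:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def filter_gene_sets(col: GeneSetCollection, min_size: int = 20, max_size: int = 300) -> GeneSetCollection:
    """Retain sets whose catalogue member count lies in [min_size, max_size].

    Sizes count all catalogue members; restriction to measured genes happens
    later, at aggregation time.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if max_size < min_size:
        raise ValueError("max_size must be >= min_size")
    return GeneSetCollection({n: gs for n, gs in col.sets.items() if min_size <= len(gs) <= max_size})


# ---------------------------------------------------------------------------
# Expression matrices and labels


def read_expression(matrix_path: str | Path, labels_path: str | Path, name: str | None = None) -> ExpressionDataset:
    """Read a TSV expression matrix plus a two-column sample-label file."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    for col in values.columns:
        if not pd.api.types.is_numeric_dtype(values[col]):
            bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()]
            raise DataError(
                f"{matrix_path}: non-numeric value {bad.iloc[0]!r} for gene "
                f"{bad.index[0]!r}, sample {col!r}"
            )
    lab = pd.read_csv(labels_path, sep="\t", index_col=0, header=None, comment="#").iloc[:, 0]
    lab.index = lab.index.astype(str)
    missing = [s for s in values.columns if s not in lab.index]
    if missing:
        raise DataError(f"{labels_path}: sample {missing[0]!r} has no label")
    return ExpressionDataset(
        name=name or Path(matrix_path).stem,
        values=values.astype(float),
        labels=lab.reindex(values.columns).astype(str),
    )


def write_expression(ds: ExpressionDataset, matrix_path: str | Path, labels_path: str | Path) -> None:
    ds.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    ds.labels.to_csv(labels_path, sep="\t", header=False)


def write_pathway_expression(pe: PathwayExpression, path: str | Path) -> None:
    """Write a pathway activity matrix with a ``# method=<tag>`` header line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# method={pe.method}\n")
        pe.values.to_csv(fh, sep="\t", index_label="pathway_id")


def read_pathway_expression(path: str | Path, provenance: str = "") -> PathwayExpression:
    method = "unknown"
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("# method="):
        method = first.strip().split("=", 1)[1]
    values = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return PathwayExpression(method=method, values=values, provenance=provenance)


# ---------------------------------------------------------------------------
# Structural preprocessing


def collapse_probes(ds: ExpressionDataset, probe_to_gene: Mapping[str, str]) -> ExpressionDataset:
    """Average rows of probes mapping to the same gene; drop unmapped probes."""
    mapped = [p for p in ds.gene_ids if probe_to_gene.get(p)]
    if not mapped:
        raise DataError("no probe maps to any gene")
    genes = pd.Series({p: probe_to_gene[p] for p in mapped})
    collapsed = ds.values.loc[mapped].groupby(genes, sort=False).mean()
    return ExpressionDataset(name=ds.name, values=collapsed, labels=ds.labels.copy())


def intersect_genes(a: ExpressionDataset, b: ExpressionDataset) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Restrict both datasets to their common genes, ordered as in ``a``."""
    common = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if not common:
        raise DataError(f"datasets {a.name!r} and {b.name!r} share no genes")
    return a.subset_genes(common), b.subset_genes(common)


def warn_dropped(pathway: str, reason: str) -> None:
    warnings.warn(f"pathway {pathway!r} dropped: {reason}", stacklevel=3)
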