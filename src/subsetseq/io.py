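"""Readers and writers for every external format the pipeline touches.

All tabular formats are tab-separated UTF-8 with a header row; gene sets use
the Broad GMT convention (name, description, then member gene ids).  Readers
validate rather than coerce: duplicate identifiers, negative or non-integer
counts and metadata/matrix mismatches raise :class:`ValidationError` naming
the offending record.  Gene matching across counts, annotation and GMT files
is by exact, case-sensitive gene id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: closed vocabulary of cell subsets in the study design
SUBSET_VOCABULARY = ("ILC1", "ILC2", "ILCP", "Th1", "Th2", "Th17")


class ValidationError(ValueError):
    """An input file violates a format invariant."""


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples, with identifiers.

    Parameters
    ----------
    gene_ids : ordered, unique gene identifiers (rows)
    sample_ids : ordered, unique sample identifiers (columns)
    counts : non-negative integer matrix, ``(len(gene_ids), len(sample_ids))``
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup = _duplicates(self.gene_ids)
        if dup:
            raise ValidationError(f"duplicate gene ids: {sorted(dup)[:5]}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValidationError(f"duplicate sample ids: {sorted(dup)[:5]}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            flo = np.asarray(self.counts, dtype=float)
            if not np.all(np.isfinite(flo)) or np.any(flo != np.round(flo)):
                bad = np.argwhere(~np.isfinite(flo) | (flo != np.round(flo)))
                g, s = bad[0]
                raise ValidationError(
                    f"non-integer count {flo[g, s]!r} at gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}"
                )
            self.counts = flo.astype(np.int64)
        if np.any(self.counts < 0):
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, keep: Sequence[int] | np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            [self.gene_ids[i] for i in keep], list(self.sample_ids), self.counts[keep]
        )


@dataclass
class SampleTable:
    """Per-sample metadata: subset label (closed vocabulary) and donor id."""

    frame: pd.DataFrame  # columns: sample_id, subset, donor

    def __post_init__(self) -> None:
        required = {"sample_id", "subset", "donor"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"sample table missing columns: {sorted(missing)}")
        self.frame = self.frame.astype({"sample_id": str, "subset": str, "donor": str})
        dup = _duplicates(self.frame["sample_id"])
        if dup:
            raise ValidationError(f"duplicate sample ids in metadata: {sorted(dup)[:5]}")
        bad = sorted(set(self.frame["subset"]) - set(SUBSET_VOCABULARY))
        if bad:
            raise ValidationError(
                f"unknown subset labels {bad}; expected one of {list(SUBSET_VOCABULARY)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def subset_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id, "subset"]
        if row.empty:
            raise KeyError(sample_id)
        return row.iloc[0]

    def aligned_subsets(self, sample_ids: Sequence[str]) -> list[str]:
        """Subset label per sample, in the given column order."""
        lookup = dict(zip(self.frame["sample_id"], self.frame["subset"]))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise ValidationError(f"metadata missing samples: {missing}")
        return [lookup[s] for s in sample_ids]

    def validate_against(self, counts: CountMatrix) -> None:
        meta = set(self.frame["sample_id"])
        cols = set(counts.sample_ids)
        if meta != cols:
            missing = sorted(cols - meta)
            extra = sorted(meta - cols)
            raise ValidationError(
                f"metadata/matrix mismatch: missing {missing or 'none'}, extra {extra or 'none'}"
            )


@dataclass
class AnnotationTable:
    """Gene annotation: id, symbol and biotype ('lncRNA' drives the sub-analysis)."""

    frame: pd.DataFrame  # columns: gene_id, symbol, biotype

    def __post_init__(self) -> None:
        required = {"gene_id", "symbol", "biotype"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        self.frame = self.frame.astype(str)
        dup = _duplicates(self.frame["gene_id"])
        if dup:
            raise ValidationError(f"duplicate gene ids in annotation: {sorted(dup)[:5]}")

    def biotype_map(self) -> dict[str, str]:
        return dict(zip(self.frame["gene_id"], self.frame["biotype"]))


@dataclass
class GeneSetCollection:
    """Named gene sets; duplicate members are removed on load, order preserved."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    #: ground-truth enrichment flags when generated synthetically
    truth: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def _duplicates(values: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for v in values:
        if v in seen:
            dup.add(v)
        seen.add(v)
    return dup


# ---------------------------------------------------------------------------
# readers


def read_counts(path: str | Path) -> CountMatrix:
    """Read a genes x samples TSV count matrix (first column = gene id)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.empty and frame.columns.empty:
        raise ValidationError(f"{path}: no samples in count matrix")
    return CountMatrix(list(frame.index.astype(str)), list(frame.columns.astype(str)), frame.values)


def read_metadata(path: str | Path) -> SampleTable:
    """Read the sample metadata TSV (sample_id, subset, donor)."""
    return SampleTable(pd.read_csv(path, sep="\t", dtype=str))


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read the gene annotation TSV (gene_id, symbol, biotype)."""
    return AnnotationTable(pd.read_csv(path, sep="\t", dtype=str))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-convention GMT file: name, description, member genes."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = members
            descriptions[name] = description
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# writers (fixed column order, stable numeric formatting, round-trip exact
# to the printed precision)

_FLOAT_FMT = "%.12g"


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    counts.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")


def write_metadata(samples: SampleTable, path: str | Path) -> None:
    samples.frame.to_csv(path, sep="\t", index=False)


def write_annotation(annotation: AnnotationTable, path: str | Path) -> None:
    annotation.frame.to_csv(path, sep="\t", index=False)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "na")
            handle.write("\t".join([name, desc, *members]) + "\n")


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV with stable float formatting."""
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_contrast_table(table, path: str | Path) -> None:
    """Write a differential-expression contrast table.

    Column order: gene_id, log2_fc, t, p, adj_p.
    """
    frame = table if isinstance(table, pd.DataFrame) else table.to_frame()
    cols = ["gene_id", "log2_fc", "t", "p", "adj_p"]
    write_table(frame[cols], path)


def read_contrast_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})


def write_gsea_table(results, path: str | Path) -> None:
    """Write GSEA results; one row per (set, direction) test.

    Column order: set, direction, size, es, nes, p, adj_p.
    """
    if isinstance(results, pd.DataFrame):
        frame = results
    else:
        frame = pd.DataFrame(
            [
                {
                    "set": r.set_name,
                    "direction": r.direction,
                    "size": r.size,
                    "es": r.es,
                    "nes": r.nes,
                    "p": r.p,
                    "adj_p": r.adj_p,
                }
                for r in results
            ]
        )
    write_table(frame[["set", "direction", "size", "es", "nes", "p", "adj_p"]], path)


def read_gsea_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"set": str, "direction": str})


def intersect_collection(
    collection: GeneSetCollection, universe: Sequence[str]
) -> GeneSetCollection:
    """Restrict every set to the gene universe; drop emptied sets with a warning."""
    allowed = set(universe)
    kept: dict[str, list[str]] = {}
    dropped_members = 0
    dropped_sets = []
    for name, members in collection.items():
        inside = [m for m in members if m in allowed]
        dropped_members += len(members) - len(inside)
        if inside:
            kept[name] = inside
        else:
            dropped_sets.append(name)
    if dropped_members:
        logger.warning("dropped %d gene-set members absent from the universe", dropped_members)
    if dropped_sets:
        logger.warning("skipped %d gene sets with empty universe intersection", len(dropped_sets))
    return GeneSetCollection(kept, dict(collection.descriptions), dict(collection.truth))
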