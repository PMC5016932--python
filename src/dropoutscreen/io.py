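"""Readers and writers for the external formats a pooled-screen analysis touches.

All tabular files are UTF-8, tab-delimited, with a header row; lines starting
with ``#`` are ignored.  Gene symbols are matched exactly and case-sensitively —
alias resolution is user preprocessing, not something this package guesses at.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SPACER_ALPHABET = frozenset("ACGT")


class ScreenFormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


@dataclass(frozen=True)
class SgRnaRecord:
    """One guide of the library.

    ``gene`` is the empty string exactly when the guide is a non-targeting
    control.  ``tags`` carries annotation labels joined in by gene symbol
    (e.g. ``"kinase"``, ``"published_essential"``).
    """

    sgrna_id: str
    spacer: str
    gene: str
    is_control: bool
    tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.spacer or set(self.spacer) - _SPACER_ALPHABET:
            raise ScreenFormatError(
                f"sgRNA {self.sgrna_id!r}: spacer must be non-empty A/C/G/T, "
                f"got {self.spacer!r}"
            )
        if self.is_control != (self.gene == ""):
            raise ScreenFormatError(
                f"sgRNA {self.sgrna_id!r}: is_control must hold exactly when "
                "the gene field is empty"
            )


class SgRnaLibrary:
    """The sgRNA universe: ordered records plus a gene → guide-id index."""

    def __init__(self, records: Sequence[SgRnaRecord]):
        self.records: list[SgRnaRecord] = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.sgrna_id in seen:
                raise ScreenFormatError(f"duplicate sgrna_id {rec.sgrna_id!r}")
            seen.add(rec.sgrna_id)
        self.gene_index: dict[str, list[str]] = {}
        for rec in self.records:
            if not rec.is_control:
                self.gene_index.setdefault(rec.gene, []).append(rec.sgrna_id)
        self._by_id = {rec.sgrna_id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, sgrna_id: str) -> SgRnaRecord:
        return self._by_id[sgrna_id]

    def __contains__(self, sgrna_id: str) -> bool:
        return sgrna_id in self._by_id

    @property
    def sgrna_ids(self) -> list[str]:
        return [rec.sgrna_id for rec in self.records]

    @property
    def genes(self) -> pd.Series:
        """Gene symbol per guide, aligned to library order ('' for controls)."""
        return pd.Series(
            [rec.gene for rec in self.records], index=self.sgrna_ids, name="gene"
        )

    @property
    def is_control(self) -> pd.Series:
        return pd.Series(
            [rec.is_control for rec in self.records],
            index=self.sgrna_ids,
            name="is_control",
        )

    @property
    def n_targeting(self) -> int:
        return sum(not rec.is_control for rec in self.records)

    @property
    def n_controls(self) -> int:
        return len(self) - self.n_targeting

    def ids_with_tag(self, tag: str) -> list[str]:
        return [rec.sgrna_id for rec in self.records if tag in rec.tags]

    def genes_with_tag(self, tag: str) -> set[str]:
        return {rec.gene for rec in self.records if tag in rec.tags and rec.gene}

    @property
    def all_tags(self) -> set[str]:
        tags: set[str] = set()
        for rec in self.records:
            tags |= rec.tags
        return tags

    def with_tags(self, annotations: Mapping[str, Iterable[str]]) -> "SgRnaLibrary":
        """Return a copy with ``tag -> genes`` annotations attached by symbol."""
        tag_by_gene: dict[str, set[str]] = {}
        for tag, genes in annotations.items():
            for g in genes:
                tag_by_gene.setdefault(g, set()).add(tag)
        out = []
        for rec in self.records:
            extra = tag_by_gene.get(rec.gene, set()) if rec.gene else set()
            out.append(
                SgRnaRecord(
                    rec.sgrna_id,
                    rec.spacer,
                    rec.gene,
                    rec.is_control,
                    rec.tags | frozenset(extra),
                )
            )
        return SgRnaLibrary(out)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    timepoint: str
    replicate: int
    is_baseline: bool = False

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ScreenFormatError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )


def _validate_samples(samples: Sequence[SampleMeta]) -> None:
    pairs = [(s.timepoint, s.replicate) for s in samples]
    if len(set(pairs)) != len(pairs):
        raise ScreenFormatError("duplicate (timepoint, replicate) pair in metadata")
    baseline_tps = {s.timepoint for s in samples if s.is_baseline}
    nonbase_tps = {s.timepoint for s in samples if not s.is_baseline}
    if len(baseline_tps) != 1:
        raise ScreenFormatError(
            "exactly one timepoint must be designated baseline, "
            f"found {sorted(baseline_tps)!r}"
        )
    if baseline_tps & nonbase_tps:
        raise ScreenFormatError(
            "a timepoint cannot be baseline for some replicates only"
        )


@dataclass
class ScreenCounts:
    """sgRNA × sample matrix plus sample metadata.

    ``values`` is indexed by sgrna_id in library order, one column per
    sample_id.  ``scale`` is ``"raw"`` (non-negative integers) or
    ``"normalized"`` (non-negative reals).
    """

    library: SgRnaLibrary
    samples: list[SampleMeta]
    values: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "normalized"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if list(self.values.index) != self.library.sgrna_ids:
            raise ScreenFormatError("count rows are not aligned to the library")
        if list(self.values.columns) != [s.sample_id for s in self.samples]:
            raise ScreenFormatError("count columns are not aligned to the metadata")
        if (self.values.to_numpy() < 0).any():
            raise ScreenFormatError("negative count encountered")
        _validate_samples(self.samples)

    @property
    def baseline_timepoint(self) -> str:
        return next(s.timepoint for s in self.samples if s.is_baseline)

    @property
    def timepoints(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.timepoint not in seen:
                seen.append(s.timepoint)
        return seen

    def samples_at(self, timepoint: str) -> list[SampleMeta]:
        return [s for s in self.samples if s.timepoint == timepoint]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the inclusive size bounds used when filtering.

    Size filtering is applied against the *measured* gene universe (the
    intersection), see :meth:`filtered`.
    """

    sets: dict[str, set[str]]
    size_bounds: tuple[int, int] = (20, 2000)

    def filtered(self, measured: Iterable[str]) -> dict[str, set[str]]:
        """Intersect every set with ``measured`` and keep those within bounds."""
        universe = set(measured)
        lo, hi = self.size_bounds
        out: dict[str, set[str]] = {}
        for name, genes in self.sets.items():
            inter = genes & universe
            if lo <= len(inter) <= hi:
                out[name] = inter
        return out


@dataclass
class ExpressionTable:
    """Per-gene abundance in library-normalized units (CPM/TPM-like)."""

    values: pd.Series
    expressed_threshold: float = 1.0

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ScreenFormatError("expression abundances must be non-negative")
        if self.expressed_threshold < 0:
            raise ScreenFormatError("expressed_threshold must be non-negative")

    def __contains__(self, gene: str) -> bool:
        return gene in self.values.index

    def expressed(self, gene: str) -> bool:
        return bool(self.values[gene] >= self.expressed_threshold)

    @property
    def is_expressed(self) -> pd.Series:
        return self.values >= self.expressed_threshold


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", encoding="utf-8", **kwargs)


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    genes: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


def read_library(
    path: str | Path,
    annotation_paths: Mapping[str, str | Path] | None = None,
) -> SgRnaLibrary:
    """Read a GeCKO-style guide table (columns sgrna_id, spacer, gene).

    Rows with an empty gene field become non-targeting controls.
    ``annotation_paths`` maps a tag name (e.g. ``"kinase"``) to a
    one-gene-per-line file; matching genes' guides carry that tag.
    """
    df = _read_tsv(path, dtype=str, keep_default_na=False)
    required = {"sgrna_id", "spacer", "gene"}
    if not required <= set(df.columns):
        raise ScreenFormatError(
            f"library file must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        spacer = row.spacer.strip().upper()
        if not spacer or set(spacer) - _SPACER_ALPHABET:
            raise ScreenFormatError(
                f"{path}, line {lineno}: spacer {row.spacer!r} is not A/C/G/T"
            )
        gene = row.gene.strip()
        records.append(
            SgRnaRecord(row.sgrna_id.strip(), spacer, gene, is_control=(gene == ""))
        )
    lib = SgRnaLibrary(records)
    if annotation_paths:
        lib = lib.with_tags(
            {tag: read_gene_list(p) for tag, p in annotation_paths.items()}
        )
    return lib


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Metadata TSV: sample_id, timepoint, replicate, baseline (0/1)."""
    df = _read_tsv(path, dtype=str, keep_default_na=False)
    required = {"sample_id", "timepoint", "replicate", "baseline"}
    if not required <= set(df.columns):
        raise ScreenFormatError(
            f"sample metadata must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    truthy = {"1", "true", "yes"}
    samples = [
        SampleMeta(
            row.sample_id.strip(),
            row.timepoint.strip(),
            int(row.replicate),
            row.baseline.strip().lower() in truthy,
        )
        for row in df.itertuples(index=False)
    ]
    _validate_samples(samples)
    return samples


def read_counts(
    path: str | Path, meta_path: str | Path, library: SgRnaLibrary
) -> ScreenCounts:
    """Read a raw count TSV (sgrna_id row key, one column per sample).

    The matrix is re-ordered to library order.  Library guides missing from
    the file are zero-filled with a logged warning — zero-read guides are a
    legitimate outcome of a dropout screen.  Samples present in the counts
    but absent from the metadata are a hard error, as are negative or
    non-integer raw counts.
    """
    samples = read_sample_meta(meta_path)
    df = _read_tsv(path, index_col="sgrna_id")
    meta_ids = [s.sample_id for s in samples]
    extra = [c for c in df.columns if c not in meta_ids]
    if extra:
        raise ScreenFormatError(
            f"samples in counts file absent from metadata: {extra}"
        )
    missing_samples = [c for c in meta_ids if c not in df.columns]
    if missing_samples:
        raise ScreenFormatError(
            f"samples in metadata absent from counts file: {missing_samples}"
        )
    unknown = [i for i in df.index if i not in library]
    if unknown:
        raise ScreenFormatError(
            f"counts file contains sgRNAs not in the library: {unknown[:5]}"
        )
    arr = df.to_numpy()
    if (arr < 0).any():
        raise ScreenFormatError("negative raw count encountered")
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ScreenFormatError("non-integer raw count encountered")
    missing = [i for i in library.sgrna_ids if i not in df.index]
    if missing:
        logger.warning(
            "%d library sgRNAs missing from %s; zero-filled (first: %s)",
            len(missing),
            path,
            missing[:5],
        )
    aligned = df.reindex(index=library.sgrna_ids, columns=meta_ids).fillna(0)
    aligned = aligned.astype(np.int64)
    return ScreenCounts(library, samples, aligned, scale="raw")


def read_gmt(
    path: str | Path, size_bounds: tuple[int, int] = (20, 2000)
) -> GeneSetCollection:
    """Read gene sets in GMT format: ``name<TAB>description<TAB>gene...``.

    Lines with an empty name or zero genes are skipped with a warning.
    Size filtering is deferred to :meth:`GeneSetCollection.filtered` so that
    it can be applied against the measured gene universe.
    """
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            name = fields[0].strip()
            genes = {g.strip() for g in fields[2:] if g.strip()}
            if not name or not genes:
                logger.warning("%s, line %d: empty set name or gene list, skipped",
                               path, lineno)
                continue
            sets[name] = genes
    return GeneSetCollection(sets, size_bounds)


def read_expression(
    path: str | Path, threshold: float = 1.0
) -> ExpressionTable:
    """Read a two-column gene/abundance TSV."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ScreenFormatError("expression table needs gene and abundance columns")
    gene_col, abund_col = df.columns[:2]
    values = pd.Series(
        df[abund_col].astype(float).to_numpy(),
        index=df[gene_col].astype(str),
        name="abundance",
    )
    if values.index.duplicated().any():
        dupes = values.index[values.index.duplicated()].tolist()
        raise ScreenFormatError(f"duplicate genes in expression table: {dupes[:5]}")
    return ExpressionTable(values, threshold)


# ---------------------------------------------------------------------------
# writers


def write_table(obj, path: str | Path) -> None:
    """Write a DataFrame, ScreenCounts, or index/value Series as deterministic TSV.

    Column order follows the object; floats use a fixed ``%.10g`` format so
    reruns are byte-identical.
    """
    if isinstance(obj, ScreenCounts):
        df = obj.values.copy()
        df.index.name = "sgrna_id"
        df.to_csv(path, sep="\t", float_format="%.10g")
        return
    if isinstance(obj, pd.Series):
        obj = obj.to_frame()
    if not isinstance(obj, pd.DataFrame):
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    obj.to_csv(path, sep="\t", float_format="%.10g",
               index=obj.index.name is not None)
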