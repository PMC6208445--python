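"""Readers and writers for the genomic file formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals
(BED convention).  GFF3 input, which is 1-based inclusive, is converted at
the boundary and never leaks its convention into downstream code.

Expression matrices are tab-separated with genes as rows and samples as
columns; sample identity (stage, replicate) is parsed from headers of the
form ``<stage>_rep<N>`` unless a sidecar metadata table is supplied.
"""

from __future__ import annotations

import os
import re
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STRANDS = {"+", "-", "."}
GENE_CLASSES = {"protein_coding", "miRNA_precursor"}


class ParseError(ValueError):
    """Malformed input file; message carries file and line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneRecord:
    """An annotated gene: interval plus class and TF status.

    ``gene_class`` is ``protein_coding`` or ``miRNA_precursor``; miRNA
    precursors are never transcription factors.
    """

    gene_id: str
    interval: GenomicInterval
    gene_class: str = "protein_coding"
    is_tf: bool = False
    symbol: str | None = None

    def __post_init__(self):
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene_class {self.gene_class!r}")
        if self.gene_class == "miRNA_precursor" and self.is_tf:
            raise ValueError(f"{self.gene_id}: a miRNA precursor cannot be a TF")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (0-based position)."""
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


@dataclass(frozen=True)
class PeakRecord:
    """One ChIP peak for one TF at one stage, with a normalized score."""

    interval: GenomicInterval
    tf: str
    stage: str
    score: float = 0.0
    summit_offset: int | None = None

    def __post_init__(self):
        if self.score < 0:
            raise ValueError(f"negative peak score {self.score}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside interval of "
                f"length {len(self.interval)}"
            )

    @property
    def reference_point(self) -> int:
        """Binding-point estimate: summit if present, else the midpoint."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.interval.midpoint


_SAMPLE_RE = re.compile(r"^(?P<stage>.+?)_rep(?P<rep>\d+)$")


@dataclass
class ExpressionTable:
    """Genes x samples abundance matrix (FPKM-like, non-negative).

    ``samples`` is an ordered list of (stage, replicate) pairs aligned with
    matrix columns.
    """

    genes: list[str]
    samples: list[tuple[str, int]]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in expression table")

    @property
    def stages(self) -> list[str]:
        """Stage labels in first-appearance order."""
        seen: dict[str, None] = {}
        for stage, _ in self.samples:
            seen.setdefault(stage)
        return list(seen)

    def stage_columns(self, stage: str) -> list[int]:
        return [i for i, (s, _) in enumerate(self.samples) if s == stage]

    def stage_means(self) -> pd.DataFrame:
        """Replicate-mean abundance per gene per stage."""
        data = {
            s: self.values[:, self.stage_columns(s)].mean(axis=1)
            for s in self.stages
        }
        return pd.DataFrame(data, index=self.genes)

    def subset(self, genes: Sequence[str]) -> "ExpressionTable":
        idx = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes absent from table: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionTable(list(genes), list(self.samples), self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{s}_rep{r}" for s, r in self.samples]
        return pd.DataFrame(self.values, index=self.genes, columns=cols)


# ---------------------------------------------------------------------------
# BED peaks


def read_peaks(path: str | os.PathLike, tf: str, stage: str) -> list[PeakRecord]:
    """Read a BED3/BED6(+summit) peak file for one TF at one stage.

    Columns beyond the first three are, in order: name (ignored), score,
    strand, summit offset from interval start.  Missing score -> 0; missing
    summit -> undefined (midpoint is used downstream).
    """
    records: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            score = 0.0
            if len(fields) >= 5 and fields[4] not in ("", "."):
                score = float(fields[4])
            strand = "."
            if len(fields) >= 6 and fields[5] in STRANDS:
                strand = fields[5]
            summit = None
            if len(fields) >= 7 and fields[6] not in ("", "."):
                summit = int(fields[6])
            try:
                records.append(
                    PeakRecord(
                        GenomicInterval(chrom, start, end, strand),
                        tf=tf,
                        stage=stage,
                        score=score,
                        summit_offset=summit,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_peaks(path: str | os.PathLike, peaks: Iterable[PeakRecord]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            summit = "." if p.summit_offset is None else str(p.summit_offset)
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t.\t{p.score:g}\t{p.interval.strand}\t{summit}\n"
            )


# ---------------------------------------------------------------------------
# Gene annotation (GFF3 or TSV)

_TSV_GENE_COLS = ["gene_id", "chrom", "start", "end", "strand", "gene_class"]


def read_genes(
    path: str | os.PathLike,
    tf_list: Iterable[str] = (),
) -> list[GeneRecord]:
    """Read gene annotation from GFF3 (1-based, converted) or TSV (0-based).

    A file is treated as GFF3 when its name ends in .gff/.gff3 or its first
    data line has 9 columns with integer columns 4-5.  ``is_tf`` is set by
    membership in ``tf_list``.
    """
    tf_set = set(tf_list)
    name = str(path)
    if name.endswith((".gff", ".gff3")):
        return _read_genes_gff3(path, tf_set)
    return _read_genes_tsv(path, tf_set)


def _read_genes_gff3(path, tf_set: set[str]) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if gene_id in seen:
            raise ParseError(f"{path}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        gclass = feat.attributes.get("gene_class", ["protein_coding"])[0]
        if gclass not in GENE_CLASSES:
            raise ParseError(f"{path}: unknown gene_class {gclass!r}")
        symbol = feat.attributes.get("Name", [None])[0]
        # GFF3 is 1-based inclusive -> 0-based half-open
        interval = GenomicInterval(
            feat.seqid, feat.start - 1, feat.end, feat.strand or "."
        )
        records.append(
            GeneRecord(
                gene_id=gene_id,
                interval=interval,
                gene_class=gclass,
                is_tf=gene_id in tf_set and gclass != "miRNA_precursor",
                symbol=symbol,
            )
        )
    return records


def _read_genes_tsv(path, tf_set: set[str]) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in _TSV_GENE_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ParseError(f"{path}: duplicate gene_id {dup!r}")
    bad = set(df["gene_class"]) - GENE_CLASSES
    if bad:
        raise ParseError(f"{path}: unknown gene_class {sorted(bad)}")
    has_tf_col = "is_tf" in df.columns
    records = []
    for row in df.itertuples(index=False):
        if has_tf_col:
            is_tf = bool(row.is_tf) and row.gene_class != "miRNA_precursor"
        else:
            is_tf = row.gene_id in tf_set and row.gene_class != "miRNA_precursor"
        symbol = getattr(row, "symbol", None)
        if isinstance(symbol, float) and np.isnan(symbol):
            symbol = None
        records.append(
            GeneRecord(
                gene_id=row.gene_id,
                interval=GenomicInterval(
                    row.chrom, int(row.start), int(row.end), row.strand
                ),
                gene_class=row.gene_class,
                is_tf=is_tf,
                symbol=symbol,
            )
        )
    return records


def write_genes_tsv(path: str | os.PathLike, genes: Iterable[GeneRecord]) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.interval.chrom,
            "start": g.interval.start,
            "end": g.interval.end,
            "strand": g.interval.strand,
            "gene_class": g.gene_class,
            "is_tf": g.is_tf,
            "symbol": g.symbol if g.symbol is not None else "",
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=_TSV_GENE_COLS + ["is_tf", "symbol"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression(
    path: str | os.PathLike,
    metadata: str | os.PathLike | None = None,
) -> ExpressionTable:
    """Read a genes x samples TSV matrix.

    Sample stage/replicate comes from headers like ``S4_rep2``; a sidecar
    metadata TSV with columns (sample, stage, replicate) takes precedence.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["."])
    if df.isna().any().any():
        raise ParseError(f"{path}: missing or non-numeric values in matrix")
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative expression values")
    if metadata is not None:
        meta = pd.read_csv(metadata, sep="\t", dtype={"sample": str, "stage": str})
        lookup = {
            row.sample: (row.stage, int(row.replicate))
            for row in meta.itertuples(index=False)
        }
        try:
            samples = [lookup[c] for c in df.columns]
        except KeyError as exc:
            raise ParseError(f"{metadata}: no metadata for sample {exc}") from exc
    else:
        samples = []
        for col in df.columns:
            m = _SAMPLE_RE.match(col)
            if m is None:
                raise ParseError(
                    f"{path}: cannot parse sample header {col!r} "
                    "(expected <stage>_rep<N>)"
                )
            samples.append((m["stage"], int(m["rep"])))
    return ExpressionTable(list(df.index.astype(str)), samples, df.values)


def write_expression(path: str | os.PathLike, table: ExpressionTable) -> None:
    df = table.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Generic edge lists (miRNA targets, PPI)


def read_edge_list(
    path: str | os.PathLike, columns: Sequence[str] = ("source", "target")
) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def write_edge_list(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
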