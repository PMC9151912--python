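"""Fragment counting over gene windows and count-table I/O.

Produces the gene x sample integer count matrices consumed by every
downstream stage. A fragment contributes to a gene iff it overlaps the
gene's (flank-expanded) window by at least 1 bp under half-open
coordinates; a fragment overlapping several windows increments each of
them. Counting is strand-blind.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import AnnotationSet

__all__ = [
    "ASSAYS",
    "SampleMeta",
    "CountMatrix",
    "CountParseError",
    "count_fragments",
    "load_count_tsv",
    "write_count_tsv",
    "load_samples_tsv",
    "write_samples_tsv",
    "read_fragment_bed",
]

ASSAYS = ("chip", "atac", "smallrna", "rnaseq")


class CountParseError(ValueError):
    """Raised for malformed count/sample tables; message carries the location."""


@dataclass
class SampleMeta:
    """Per-sample metadata: assay, ChIP factor, condition, replicate, depth."""

    sample_id: str
    assay: str = "chip"
    factor: str = ""
    condition: str = ""
    replicate: int = 1
    library_size: int = 0

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(
                f"sample {self.sample_id!r}: assay must be one of {ASSAYS}, "
                f"got {self.assay!r}"
            )
        if self.replicate < 1:
            raise ValueError(f"sample {self.sample_id!r}: replicate must be >= 1")
        if self.library_size < 0:
            raise ValueError(f"sample {self.sample_id!r}: negative library size")


@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample counts with sample metadata."""

    gene_ids: list[str]
    samples: list[SampleMeta]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be nonnegative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids in CountMatrix")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_ids in CountMatrix")
        self.counts = self.counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def column_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.column_index(sample_id)]

    def library_sizes(self) -> np.ndarray:
        """Per-sample library sizes; falls back to column sums when unset."""
        sizes = np.array([s.library_size for s in self.samples], dtype=np.int64)
        colsums = self.counts.sum(axis=0)
        return np.where(sizes > 0, sizes, colsums)

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return CountMatrix(list(gene_ids), list(self.samples), self.counts[rows, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.sample_ids,
        )


Interval = tuple[str, int, int]


def count_fragments(
    fragments: Mapping[str, Iterable[Interval]],
    windows: AnnotationSet,
    sample_meta: Mapping[str, SampleMeta] | None = None,
) -> CountMatrix:
    """Count aligned fragments over gene windows, one column per sample.

    ``fragments`` maps sample_id -> iterable of (chrom, start, end) in
    0-based half-open coordinates. Every supplied fragment counts toward
    the sample's library size, including fragments on chromosomes absent
    from the window set; inverted/empty intervals raise.
    """
    trees: dict[str, IntervalTree] = {}
    for i, rec in enumerate(windows):
        trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end, i)

    gene_ids = windows.gene_ids
    samples: list[SampleMeta] = []
    columns: list[np.ndarray] = []
    for sample_id, frags in fragments.items():
        col = np.zeros(len(gene_ids), dtype=np.int64)
        n_frag = 0
        for chrom, start, end in frags:
            if end <= start or start < 0:
                raise ValueError(
                    f"sample {sample_id!r}: invalid fragment {chrom}:{start}-{end}"
                )
            n_frag += 1
            tree = trees.get(chrom)
            if tree is None:
                continue
            for hit in tree.overlap(start, end):
                col[hit.data] += 1
        meta = (
            sample_meta[sample_id]
            if sample_meta is not None
            else SampleMeta(sample_id=sample_id)
        )
        meta = SampleMeta(
            sample_id=meta.sample_id,
            assay=meta.assay,
            factor=meta.factor,
            condition=meta.condition,
            replicate=meta.replicate,
            library_size=n_frag,
        )
        samples.append(meta)
        columns.append(col)
    counts = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(gene_ids), 0), dtype=np.int64)
    )
    return CountMatrix(list(gene_ids), samples, counts)


def read_fragment_bed(path: str | Path) -> list[Interval]:
    """Read a BED3+ file of aligned fragments (one interval per fragment)."""
    out: list[Interval] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise CountParseError(
                    f"{path.name}:{lineno}: expected >=3 BED columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise CountParseError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from None
            out.append((fields[0], start, end))
    return out


def write_count_tsv(cm: CountMatrix, path: str | Path) -> None:
    """Write a counts TSV: header of sample_ids, first column gene_id."""
    with Path(path).open("w") as fh:
        fh.write("gene_id\t" + "\t".join(cm.sample_ids) + "\n")
        for i, gid in enumerate(cm.gene_ids):
            fh.write(gid + "\t" + "\t".join(str(int(c)) for c in cm.counts[i]) + "\n")


def load_count_tsv(
    path: str | Path, samples: Mapping[str, SampleMeta] | None = None
) -> CountMatrix:
    """Load a counts TSV written by :func:`write_count_tsv`.

    Round-trips exactly. Sample metadata defaults to bare records (library
    size = column sum) unless supplied via ``samples``. Non-integer cells,
    ragged rows and duplicate gene ids raise :class:`CountParseError` with
    the offending location.
    """
    path = Path(path)
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise CountParseError(f"{path.name}: empty file") from None
        sample_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[int]] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise CountParseError(
                    f"{path.name}:{lineno}: expected {len(header)} fields, "
                    f"got {len(row)}"
                )
            gid = row[0]
            if gid in seen:
                raise CountParseError(
                    f"{path.name}:{lineno}: duplicate gene_id {gid!r}"
                )
            seen.add(gid)
            try:
                values = [int(v) for v in row[1:]]
            except ValueError:
                raise CountParseError(
                    f"{path.name}:{lineno}: non-integer count in row {gid!r}"
                ) from None
            gene_ids.append(gid)
            rows.append(values)
    counts = (
        np.array(rows, dtype=np.int64)
        if rows
        else np.zeros((0, len(sample_ids)), dtype=np.int64)
    )
    metas = []
    for j, sid in enumerate(sample_ids):
        if samples is not None and sid in samples:
            metas.append(samples[sid])
        else:
            lib = int(counts[:, j].sum()) if counts.size else 0
            metas.append(SampleMeta(sample_id=sid, library_size=lib))
    return CountMatrix(gene_ids, metas, counts)


_SAMPLE_COLUMNS = ["sample_id", "assay", "factor", "condition", "replicate",
                   "library_size"]


def write_samples_tsv(samples: Sequence[SampleMeta], path: str | Path,
                      paths: Mapping[str, str] | None = None) -> None:
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id, "assay": s.assay, "factor": s.factor,
            "condition": s.condition, "replicate": s.replicate,
            "library_size": s.library_size,
        }
        if paths is not None:
            row["path"] = paths.get(s.sample_id, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_samples_tsv(path: str | Path) -> tuple[dict[str, SampleMeta], dict[str, str]]:
    """Load a sample sheet; returns (metadata by sample_id, path by sample_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in ("sample_id", "assay") if c not in df.columns]
    if missing:
        raise CountParseError(f"{Path(path).name}: missing columns {missing}")
    metas: dict[str, SampleMeta] = {}
    frag_paths: dict[str, str] = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in metas:
            raise CountParseError(f"{Path(path).name}: duplicate sample {sid!r}")
        metas[sid] = SampleMeta(
            sample_id=sid,
            assay=row.get("assay", "chip") or "chip",
            factor=row.get("factor", ""),
            condition=row.get("condition", ""),
            replicate=int(row.get("replicate") or 1),
            library_size=int(row.get("library_size") or 0),
        )
        if "path" in df.columns and row["path"]:
            frag_paths[sid] = row["path"]
    return metas, frag_paths
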