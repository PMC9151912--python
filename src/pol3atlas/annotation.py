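"""Gene annotation handling for Pol III-transcribed gene sets.

The occupancy atlas is built over a consolidated noncoding-RNA annotation
(RNAcentral-style BED with URS identifiers). Because such annotations merge
several source databases, the same gene frequently appears several times with
coordinates that differ by a few base pairs; :func:`merge_duplicates`
collapses these near-duplicates. Counting windows for the different assays
are produced by :func:`expand_flanks` (150 bp for ChIP/ATAC, 25 bp for small
RNA in the default pipeline).

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

__all__ = [
    "GENE_CLASSES",
    "GeneRecord",
    "AnnotationSet",
    "BedParseError",
    "classify_gene",
    "parse_gene_bed",
    "merge_duplicates",
    "expand_flanks",
    "write_bed",
    "write_gene_table",
]

#: Recognised Pol III gene classes. "other" is the fall-through.
GENE_CLASSES = (
    "tRNA",
    "rRNA5S",
    "U6",
    "7SK",
    "7SL",
    "SNAR",
    "Y",
    "vault",
    "RPPH1",
    "RMRP",
    "BCYRN1",
    "other",
)

# Case-insensitive substring rules, applied in order. Order matters:
# vault RNAs (VTRNA*) contain the substring "trna" and must match first.
_CLASS_RULES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("vault", ("vault", "vtrna")),
    ("SNAR", ("snar",)),
    ("BCYRN1", ("bcyrn1",)),
    ("RMRP", ("rmrp",)),
    ("RPPH1", ("rpph1",)),
    ("7SK", ("rn7sk", "7sk")),
    ("7SL", ("rn7sl", "7sl")),
    ("tRNA", ("trna",)),
    ("Y", ("rny", "y_rna")),
    ("U6", ("rnu6", "u6")),
    ("rRNA5S", ("rna5s", "5s")),
)


class BedParseError(ValueError):
    """Raised for malformed BED input; message names the offending line."""


def classify_gene(*name_fields: str) -> str:
    """Assign a Pol III gene class from one or more name strings.

    Matching is case-insensitive substring search over the rules above;
    anything unrecognised falls through to ``"other"``.
    """
    if not name_fields:
        raise ValueError("at least one name field is required")
    haystack = " ".join(name_fields).lower()
    for gene_class, needles in _CLASS_RULES:
        if any(n in haystack for n in needles):
            return gene_class
    return "other"


@dataclass
class GeneRecord:
    """One annotated gene interval (0-based, half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    gene_class: str = "other"
    source_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"{self.gene_id}: empty chromosome name")
        if self.start < 0:
            raise ValueError(f"{self.gene_id}: negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"{self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"{self.gene_id}: unknown gene class {self.gene_class!r}")
        if not self.source_ids:
            self.source_ids = frozenset({self.gene_id})

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationSet:
    """An ordered collection of gene records, sorted by (chrom, start)."""

    records: list[GeneRecord]
    genome_label: str = ""

    def __post_init__(self) -> None:
        self.records = sorted(
            self.records, key=lambda r: (r.chrom, r.start, r.end, r.gene_id)
        )
        seen_ids: set[str] = set()
        seen_keys: set[tuple] = set()
        for r in self.records:
            if r.gene_id in seen_ids:
                raise ValueError(f"duplicate gene_id {r.gene_id!r}")
            seen_ids.add(r.gene_id)
            key = (r.chrom, r.start, r.end, r.gene_id)
            if key in seen_keys:  # pragma: no cover - implied by gene_id check
                raise ValueError(f"duplicate record {key}")
            seen_keys.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]


def parse_gene_bed(path: str | Path, genome_label: str = "") -> AnnotationSet:
    """Parse a BED4/BED6 gene annotation file into an :class:`AnnotationSet`.

    Column 4 carries the gene identifier, column 6 (if present) the strand;
    4-column files get strand ``"."``. Lines starting with ``#``, ``track``
    or ``browser`` are skipped. Malformed lines raise :class:`BedParseError`
    naming the line number.
    """
    records: list[GeneRecord] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise BedParseError(
                    f"{path.name}:{lineno}: expected >=4 BED columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise BedParseError(
                    f"{path.name}:{lineno}: non-integer coordinates "
                    f"({start_s!r}, {end_s!r})"
                ) from None
            if end <= start:
                raise BedParseError(
                    f"{path.name}:{lineno}: end ({end}) <= start ({start})"
                )
            strand = fields[5] if len(fields) >= 6 else "."
            if strand not in ("+", "-", "."):
                raise BedParseError(
                    f"{path.name}:{lineno}: invalid strand {strand!r}"
                )
            records.append(
                GeneRecord(
                    gene_id=name,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    gene_class=classify_gene(name),
                )
            )
    try:
        return AnnotationSet(records, genome_label=genome_label)
    except ValueError as exc:
        raise BedParseError(f"{path.name}: {exc}") from None


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_duplicates(ann: AnnotationSet, tolerance_bp: int = 50) -> AnnotationSet:
    """Collapse near-duplicate entries contributed by multiple source databases.

    Two records are mergeable iff they lie on the same chromosome and both
    their start and end coordinates are within ``tolerance_bp`` of each other.
    Mergeable pairs are closed transitively (single linkage); each group is
    replaced by a single record spanning min(start)..max(end), keeping the
    lexicographically smallest gene_id, the union of source ids and the
    majority gene class (ties resolved by the class of the smallest gene_id
    carrying a tied class).
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    recs = ann.records
    n = len(recs)
    uf = _UnionFind(n)
    # Records are sorted by (chrom, start); a pair can only merge if their
    # starts are within tolerance, so a bounded forward sweep finds all pairs.
    for i in range(n):
        for j in range(i + 1, n):
            if recs[j].chrom != recs[i].chrom:
                break
            if recs[j].start - recs[i].start > tolerance_bp:
                break
            if abs(recs[j].end - recs[i].end) <= tolerance_bp:
                uf.union(i, j)
    groups: dict[int, list[GeneRecord]] = {}
    for i, r in enumerate(recs):
        groups.setdefault(uf.find(i), []).append(r)
    merged: list[GeneRecord] = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        members = sorted(members, key=lambda r: r.gene_id)
        class_counts = Counter(r.gene_class for r in members)
        top = max(class_counts.values())
        tied = {c for c, k in class_counts.items() if k == top}
        gene_class = next(r.gene_class for r in members if r.gene_class in tied)
        source_ids = frozenset().union(*(r.source_ids for r in members))
        merged.append(
            GeneRecord(
                gene_id=members[0].gene_id,
                chrom=members[0].chrom,
                start=min(r.start for r in members),
                end=max(r.end for r in members),
                strand=members[0].strand,
                gene_class=gene_class,
                source_ids=source_ids,
            )
        )
    return AnnotationSet(merged, genome_label=ann.genome_label)


def expand_flanks(ann: AnnotationSet, flank_bp: int) -> AnnotationSet:
    """Extend each gene window by ``flank_bp`` on both sides, clamping at 0."""
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    if flank_bp == 0:
        return AnnotationSet(list(ann.records), genome_label=ann.genome_label)
    out = [
        replace(r, start=max(0, r.start - flank_bp), end=r.end + flank_bp)
        for r in ann.records
    ]
    return AnnotationSet(out, genome_label=ann.genome_label)


def write_bed(ann: AnnotationSet, path: str | Path) -> None:
    """Write the annotation as BED6 (score column 0)."""
    with Path(path).open("w") as fh:
        for r in ann:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")


def write_gene_table(ann: AnnotationSet, path: str | Path) -> None:
    """Write a TSV gene table (gene_id, coordinates, class, n_sources)."""
    with Path(path).open("w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\tgene_class\tn_sources\n")
        for r in ann:
            fh.write(
                f"{r.gene_id}\t{r.chrom}\t{r.start}\t{r.end}\t{r.strand}"
                f"\t{r.gene_class}\t{len(r.source_ids)}\n"
            )
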