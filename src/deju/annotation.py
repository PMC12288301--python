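"""Gene annotation: GTF parsing, exon flattening, and the splice-junction database.

Counting bins for differential exon-junction usage come from two annotation
products derived from transcript models:

* **flattened exons** — the per-gene disjoint union of all transcript exons,
  with overlapping or book-ended intervals merged; and
* **the junction database** — every intron implied by two consecutive exons of
  an annotated transcript, stored by the first and last base of the intron.

All coordinates are 1-based inclusive (GTF/SAF convention).  Junction tables
are read and written in an ``SJ.out.tab``-style dialect so they interoperate
with STAR-derived junction files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Exon",
    "Transcript",
    "GeneModel",
    "JunctionRecord",
    "parse_gtf",
    "flatten_gene_exons",
    "build_junction_database",
    "write_saf",
    "read_saf",
    "write_gtf",
    "write_junction_table",
    "read_junction_table",
]

SAF_COLUMNS = ["GeneID", "Chr", "Start", "End", "Strand"]

UNKNOWN_GENE = "UNKNOWN"


class GtfParseError(ValueError):
    """Raised for malformed GTF input; the message names the offending line."""


@dataclass(frozen=True, order=True)
class Exon:
    """A genomic exon interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Transcript:
    """An ordered chain of non-overlapping exons on one chromosome/strand.

    Exons are kept in genomic order (ascending start) regardless of strand.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[Exon, ...]

    def __post_init__(self) -> None:
        self.exons = tuple(sorted(self.exons, key=lambda e: e.start))
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id} mixes chromosomes/strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"transcript {self.transcript_id} has overlapping exons "
                    f"({a.start},{a.end}) and ({b.start},{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """(first, last) intron base for each pair of consecutive exons."""
        return [
            (a.end + 1, b.start - 1) for a, b in zip(self.exons, self.exons[1:])
        ]


@dataclass
class GeneModel:
    """A gene: its transcripts plus (once computed) flattened merged exons."""

    gene_id: str
    chrom: str
    strand: str
    flat_exons: tuple[Exon, ...] = ()
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) covered by any exon of the gene."""
        exons = self.flat_exons or tuple(
            e for t in self.transcripts for e in t.exons
        )
        return min(e.start for e in exons), max(e.end for e in exons)


@dataclass(frozen=True, order=True)
class JunctionRecord:
    """An intron implied by two consecutive exons of a transcript."""

    chrom: str
    intron_start: int
    intron_end: int
    strand: str
    gene_id: str = UNKNOWN_GENE
    annotated: bool = True

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ValueError(
                f"intron start {self.intron_start} > end {self.intron_end}"
            )


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field9: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field9))


def parse_gtf(
    path, feature_filter: set[str] | None = None
) -> list[GeneModel]:
    """Parse exon records of a GTF file into gene models.

    Parameters
    ----------
    path
        GTF file with standard 9-column records; ``gene_id`` and
        ``transcript_id`` attributes are required on exon lines.
    feature_filter
        Optional set of gene biotypes; genes whose ``gene_type`` /
        ``gene_biotype`` attribute is present but not in the set are skipped.

    Returns one :class:`GeneModel` per gene, transcripts grouped, with
    ``flat_exons`` left empty (populate via :func:`flatten_gene_exons`).
    """
    exons_by_tx: dict[str, list[Exon]] = {}
    tx_gene: dict[str, str] = {}
    tx_order: list[str] = []
    skipped_genes: set[str] = set()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, "
                    f"found {len(parts)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = parts
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GtfParseError(
                    f"line {lineno}: non-integer coordinates {start!r}/{end!r}"
                ) from exc
            attr = _parse_attributes(attrs)
            gene_id = attr.get("gene_id")
            tx_id = attr.get("transcript_id")
            if not gene_id:
                raise GtfParseError(f"line {lineno}: exon without gene_id")
            if not tx_id:
                raise GtfParseError(f"line {lineno}: exon without transcript_id")
            biotype = attr.get("gene_type") or attr.get("gene_biotype")
            if (
                feature_filter is not None
                and biotype is not None
                and biotype not in feature_filter
            ):
                skipped_genes.add(gene_id)
                continue
            if tx_id not in exons_by_tx:
                exons_by_tx[tx_id] = []
                tx_gene[tx_id] = gene_id
                tx_order.append(tx_id)
            exons_by_tx[tx_id].append(Exon(chrom, start_i, end_i, strand))

    genes: dict[str, GeneModel] = {}
    for tx_id in tx_order:
        gene_id = tx_gene[tx_id]
        tx = Transcript(tx_id, gene_id, tuple(exons_by_tx[tx_id]))
        if gene_id not in genes:
            genes[gene_id] = GeneModel(gene_id, tx.chrom, tx.strand)
        genes[gene_id].transcripts.append(tx)
    return list(genes.values())


def merge_intervals(
    intervals: Iterable[tuple[int, int]], merge_bookended: bool = True
) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals; gap-0 neighbours merge by default."""
    slop = 1 if merge_bookended else 0
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + slop:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(iv) for iv in merged]


def flatten_gene_exons(gene: GeneModel, merge_bookended: bool = True) -> GeneModel:
    """Return the gene with ``flat_exons`` set to the merged exon union.

    Overlapping and (by default) book-ended transcript exons collapse into
    single disjoint bins; total covered bases are preserved.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    chroms = {t.chrom for t in gene.transcripts}
    strands = {t.strand for t in gene.transcripts}
    if len(chroms) > 1 or len(strands) > 1:
        raise ValueError(
            f"gene {gene.gene_id} has transcripts on mixed chromosomes/strands"
        )
    intervals = [
        (e.start, e.end) for t in gene.transcripts for e in t.exons
    ]
    flat = tuple(
        Exon(gene.chrom, s, e, gene.strand)
        for s, e in merge_intervals(intervals, merge_bookended)
    )
    return replace(gene, flat_exons=flat)


def build_junction_database(genes: Sequence[GeneModel]) -> list[JunctionRecord]:
    """Collect every transcript-implied intron as an annotated junction.

    Duplicates (same chromosome, intron coordinates, strand and gene) are
    collapsed; one record is kept per (coordinates, gene) pair so junctions
    shared by overlapping genes stay attributed to each gene.  Output is
    sorted by (chrom, intron_start, intron_end, gene_id).
    """
    seen: set[JunctionRecord] = set()
    for gene in genes:
        for tx in gene.transcripts:
            for s, e in tx.introns():
                seen.add(
                    JunctionRecord(tx.chrom, s, e, tx.strand, gene.gene_id, True)
                )
    return sorted(
        seen, key=lambda j: (j.chrom, j.intron_start, j.intron_end, j.gene_id)
    )


def write_saf(genes: Sequence[GeneModel], path) -> None:
    """Write flattened exons as a SAF table (GeneID/Chr/Start/End/Strand)."""
    rows = []
    for gene in genes:
        if not gene.flat_exons:
            raise ValueError(
                f"gene {gene.gene_id} has no flattened exons; "
                "run flatten_gene_exons first"
            )
        for e in gene.flat_exons:
            rows.append((gene.gene_id, e.chrom, e.start, e.end, e.strand))
    pd.DataFrame(rows, columns=SAF_COLUMNS).to_csv(path, sep="\t", index=False)


def read_saf(path) -> pd.DataFrame:
    """Read a SAF table, validating the required columns."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in SAF_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"SAF file {path} missing column(s): {', '.join(missing)}")
    return table[SAF_COLUMNS].astype(
        {"GeneID": str, "Chr": str, "Start": int, "End": int, "Strand": str}
    )


def write_gtf(genes: Sequence[GeneModel], path, source: str = "deju") -> None:
    """Write transcript exon chains as minimal GTF exon records."""
    with open(path, "w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                for e in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{tx.transcript_id}";'
                    )
                    fh.write(
                        f"{e.chrom}\t{source}\texon\t{e.start}\t{e.end}\t.\t"
                        f"{e.strand}\t.\t{attrs}\n"
                    )


_STRAND_CODE = {"+": 1, "-": 2}
_STRAND_FROM_CODE = {1: "+", 2: "-", 0: "+"}

JUNCTION_COLUMNS = [
    "chrom",
    "intron_start",
    "intron_end",
    "strand",
    "motif",
    "annotated",
    "n_unique_reads",
    "n_multi_reads",
    "max_overhang",
]


def write_junction_table(
    junctions: Sequence[JunctionRecord],
    path,
    support: dict[tuple[str, int, int], int] | None = None,
) -> None:
    """Write junctions as an SJ.out.tab-style TSV (no header, 9 columns)."""
    support = support or {}
    rows = []
    for j in junctions:
        n_unique = support.get((j.chrom, j.intron_start, j.intron_end), 0)
        rows.append(
            (
                j.chrom,
                j.intron_start,
                j.intron_end,
                _STRAND_CODE[j.strand],
                0,
                int(j.annotated),
                n_unique,
                0,
                0,
            )
        )
    pd.DataFrame(rows, columns=JUNCTION_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_junction_table(path) -> list[JunctionRecord]:
    """Read an SJ.out.tab-style TSV back into junction records (gene UNKNOWN)."""
    table = pd.read_csv(path, sep="\t", header=None, names=JUNCTION_COLUMNS)
    return [
        JunctionRecord(
            str(r.chrom),
            int(r.intron_start),
            int(r.intron_end),
            _STRAND_FROM_CODE[int(r.strand)],
            UNKNOWN_GENE,
            bool(r.annotated),
        )
        for r in table.itertuples()
    ]
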