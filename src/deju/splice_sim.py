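"""Synthetic multi-isoform transcriptomes carrying known splicing events.

Each simulated gene starts from a "full chain" of exons (the reference
structure) and receives two isoforms that differ by one of four alternative
splicing patterns:

* **ES**  (exon skipping)          — isoform B omits one internal exon;
* **MXE** (mutually exclusive exons) — isoform A omits internal exon *i+1*,
  isoform B omits internal exon *i*, for an adjacent internal pair;
* **ASS** (alternative splice site) — isoform B truncates one boundary of an
  internal exon inward, so the flattened exons are unchanged and the event is
  visible only at the junction level;
* **IR**  (intron retention)       — isoform B fuses two consecutive exons and
  the intron between them into one contiguous exon block.

A configurable subset of genes is labelled as genuinely differentially
spliced ("true DEU"); these later receive a group-specific isoform switch.
The remaining genes get the same two-isoform structure without any
between-group abundance change, so the null contains realistic multi-isoform
genes with stable usage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .annotation import (
    Exon,
    GeneModel,
    Transcript,
    build_junction_database,
    flatten_gene_exons,
    write_gtf,
    write_saf,
    write_junction_table,
)

__all__ = [
    "Pattern",
    "EventLabel",
    "SimConfig",
    "SimTranscriptome",
    "generate_transcriptome",
    "inject_event",
]


class Pattern(str, Enum):
    ES = "ES"
    MXE = "MXE"
    ASS = "ASS"
    IR = "IR"
    NONE = "NONE"


#: minimum exon count of the full chain needed to host each pattern
_MIN_EXONS = {Pattern.ES: 3, Pattern.MXE: 4, Pattern.ASS: 3, Pattern.IR: 2}

#: exon bases an ASS truncation must leave behind
_ASS_MIN_REMAINDER = 30


@dataclass(frozen=True)
class EventLabel:
    pattern: Pattern
    is_true_deu: bool

    def __post_init__(self) -> None:
        if self.is_true_deu and self.pattern is Pattern.NONE:
            raise ValueError("a true-DEU gene must carry a splicing pattern")


@dataclass
class SimConfig:
    """Study conditions for the synthetic transcriptome.

    Defaults are a 1/10 linear scaling of the full-size study (5000 genes,
    1000 true DEU split equally over the four patterns); exon/intron geometry
    is drawn uniformly over the stated ranges.
    """

    n_genes: int = 500
    n_true_deu: int = 100
    transcripts_per_gene: int = 2
    exon_count_range: tuple[int, int] = (4, 12)
    exon_length_range: tuple[int, int] = (80, 300)
    intron_length_range: tuple[int, int] = (200, 2000)
    ass_shift_range: tuple[int, int] = (30, 100)
    patterns: tuple[Pattern, ...] = (Pattern.ES, Pattern.MXE, Pattern.ASS, Pattern.IR)
    genes_per_chrom: int = 100
    intergenic_gap: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        self.patterns = tuple(Pattern(p) for p in self.patterns)
        if self.n_true_deu > self.n_genes:
            raise ValueError("n_true_deu cannot exceed n_genes")
        if self.n_true_deu % len(self.patterns) != 0:
            raise ValueError(
                f"n_true_deu ({self.n_true_deu}) must be divisible by the "
                f"number of patterns ({len(self.patterns)})"
            )
        if self.transcripts_per_gene not in (2, 5):
            raise ValueError("transcripts_per_gene must be 2 or 5")
        if self.ass_shift_range[0] >= self.exon_length_range[0]:
            raise ValueError("ass_shift must be smaller than the minimum exon length")
        if self.exon_count_range[0] < max(_MIN_EXONS.values()):
            raise ValueError(
                "minimum exon count must allow every pattern "
                f"(need >= {max(_MIN_EXONS.values())})"
            )


@dataclass
class SimTranscriptome:
    """Simulated genes (two+ isoforms each) with ground-truth event labels.

    ``genes`` carry the simulated isoforms and flattened exons over those
    isoforms; ``reference_genes`` carry one full-chain transcript per gene and
    serve as the counting annotation (flattened exon bins + junction
    database), emulating quantification against a reference annotation that
    does not know about the injected events.
    """

    genes: list[GeneModel]
    labels: dict[str, EventLabel]
    seed: int
    reference_genes: list[GeneModel] = field(default_factory=list)

    def transcript_table(self) -> pd.DataFrame:
        """One row per simulated isoform: transcript_id, gene_id, role, length."""
        rows = []
        for gene in self.genes:
            for role, tx in zip("ABCDE", gene.transcripts):
                rows.append((tx.transcript_id, gene.gene_id, role, tx.length))
        return pd.DataFrame(
            rows, columns=["transcript_id", "gene_id", "role", "length"]
        )

    def truth_table(self) -> pd.DataFrame:
        rows = [
            (g, lab.pattern.value, lab.is_true_deu)
            for g, lab in self.labels.items()
        ]
        return pd.DataFrame(rows, columns=["gene_id", "pattern", "is_true_deu"])

    def write(self, outdir) -> dict[str, str]:
        """Write GTF/SAF/junction-db/truth artifacts; returns path map."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "transcriptome_gtf": os.path.join(outdir, "transcriptome.gtf"),
            "annotation_gtf": os.path.join(outdir, "annotation.gtf"),
            "flat_exons_saf": os.path.join(outdir, "flattened_exons.saf"),
            "junctions_tsv": os.path.join(outdir, "junction_db.tsv"),
            "truth_tsv": os.path.join(outdir, "truth_labels.tsv"),
        }
        write_gtf(self.genes, paths["transcriptome_gtf"])
        write_gtf(self.reference_genes, paths["annotation_gtf"])
        write_saf(self.reference_genes, paths["flat_exons_saf"])
        write_junction_table(
            build_junction_database(self.reference_genes), paths["junctions_tsv"]
        )
        self.truth_table().to_csv(paths["truth_tsv"], sep="\t", index=False)
        return paths


def _random_full_chain(
    gene_id: str, chrom: str, strand: str, start: int, config: SimConfig,
    rng: np.random.Generator,
) -> tuple[GeneModel, int]:
    """Draw a full exon chain; returns the gene and its rightmost coordinate."""
    n_exons = int(rng.integers(*config.exon_count_range, endpoint=True))
    exon_lens = rng.integers(*config.exon_length_range, endpoint=True, size=n_exons)
    intron_lens = rng.integers(
        *config.intron_length_range, endpoint=True, size=n_exons - 1
    )
    exons = []
    pos = start
    for i, elen in enumerate(exon_lens):
        exons.append(Exon(chrom, pos, pos + int(elen) - 1, strand))
        pos += int(elen)
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    tx = Transcript(f"{gene_id}.ref", gene_id, tuple(exons))
    gene = GeneModel(gene_id, chrom, strand, transcripts=[tx])
    return gene, pos - 1


def inject_event(
    gene: GeneModel,
    pattern: Pattern,
    rng: np.random.Generator,
    ass_shift_range: tuple[int, int] = (30, 100),
) -> GeneModel:
    """Derive isoforms A and B from the gene's single full-chain transcript.

    Isoform A is the full chain except under MXE, where A omits internal exon
    *i+1* and B omits internal exon *i* (leftmost eligible adjacent pair).
    Raises ``ValueError`` when the chain is too short to host the pattern.
    """
    pattern = Pattern(pattern)
    if len(gene.transcripts) != 1:
        raise ValueError("inject_event expects a gene with a single full chain")
    chain = gene.transcripts[0].exons
    n = len(chain)
    if pattern is Pattern.NONE or n < _MIN_EXONS.get(pattern, n + 1):
        raise ValueError(
            f"gene {gene.gene_id}: {n} exons cannot host pattern {pattern.value}"
        )

    exons_a = list(chain)
    if pattern is Pattern.ES:
        k = int(rng.integers(1, n - 1))
        exons_b = [e for i, e in enumerate(chain) if i != k]
    elif pattern is Pattern.MXE:
        i = 1  # leftmost eligible adjacent internal pair
        exons_a = [e for j, e in enumerate(chain) if j != i + 1]
        exons_b = [e for j, e in enumerate(chain) if j != i]
    elif pattern is Pattern.ASS:
        lo, hi = ass_shift_range
        eligible = [
            k
            for k in range(1, n - 1)
            if chain[k].length >= lo + _ASS_MIN_REMAINDER
        ]
        if not eligible:
            raise ValueError(
                f"gene {gene.gene_id}: no internal exon long enough for ASS"
            )
        k = int(eligible[rng.integers(len(eligible))])
        exon = chain[k]
        delta = int(
            rng.integers(lo, min(hi, exon.length - _ASS_MIN_REMAINDER), endpoint=True)
        )
        if rng.random() < 0.5:  # truncate the acceptor (left) side
            shifted = Exon(exon.chrom, exon.start + delta, exon.end, exon.strand)
        else:  # truncate the donor (right) side
            shifted = Exon(exon.chrom, exon.start, exon.end - delta, exon.strand)
        exons_b = list(chain)
        exons_b[k] = shifted
    elif pattern is Pattern.IR:
        i = int(rng.integers(0, n - 1))
        merged = Exon(
            chain[i].chrom, chain[i].start, chain[i + 1].end, chain[i].strand
        )
        exons_b = list(chain[:i]) + [merged] + list(chain[i + 2 :])
    else:  # pragma: no cover
        raise AssertionError(pattern)

    iso_a = Transcript(f"{gene.gene_id}.A", gene.gene_id, tuple(exons_a))
    iso_b = Transcript(f"{gene.gene_id}.B", gene.gene_id, tuple(exons_b))
    out = GeneModel(gene.gene_id, gene.chrom, gene.strand, transcripts=[iso_a, iso_b])
    return flatten_gene_exons(out)


def _extra_isoforms(
    gene: GeneModel, chain: tuple[Exon, ...],
    rng: np.random.Generator, count: int,
) -> list[Transcript]:
    """Random internal-exon-subset isoforms that avoid the labelled event.

    Used in five-transcript mode: each extra isoform drops one internal exon
    that is not adjacent to any exon touched by the A/B event, so the
    differential junctions of the labelled pattern stay exclusive to A/B.
    """
    shared = set(gene.transcripts[0].exons) & set(gene.transcripts[1].exons)
    touched = {i for i, e in enumerate(chain) if e not in shared}
    candidates = [
        i
        for i in range(1, len(chain) - 1)
        if not ({i - 1, i, i + 1} & touched)
    ]
    isoforms = []
    for c in range(count):
        if not candidates:
            break
        k = int(candidates[rng.integers(len(candidates))])
        candidates.remove(k)
        exons = tuple(e for i, e in enumerate(chain) if i != k)
        isoforms.append(
            Transcript(f"{gene.gene_id}.{'CDE'[c]}", gene.gene_id, exons)
        )
    return isoforms


def generate_transcriptome(config: SimConfig) -> SimTranscriptome:
    """Generate the synthetic transcriptome defined by ``config``.

    Genes are placed non-overlapping on synthetic chromosomes; ``n_true_deu``
    genes are selected uniformly at random and assigned patterns in equal
    proportions; all other genes also receive a (non-differential) two-isoform
    event so nulls are structurally realistic.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    true_idx = rng.choice(n, size=config.n_true_deu, replace=False)
    patterns = np.empty(n, dtype=object)
    null_pool = np.array(
        [config.patterns[i % len(config.patterns)] for i in range(n)], dtype=object
    )
    rng.shuffle(null_pool)
    patterns[:] = null_pool
    true_patterns = np.array(
        [
            config.patterns[i % len(config.patterns)]
            for i in range(config.n_true_deu)
        ],
        dtype=object,
    )
    rng.shuffle(true_patterns)
    patterns[true_idx] = true_patterns
    is_true = np.zeros(n, dtype=bool)
    is_true[true_idx] = True

    genes: list[GeneModel] = []
    reference: list[GeneModel] = []
    labels: dict[str, EventLabel] = {}
    cursor = 1
    for i in range(n):
        gene_id = f"G{i:05d}"
        chrom = f"chrS{i // config.genes_per_chrom + 1}"
        if i % config.genes_per_chrom == 0:
            cursor = 1
        strand = "+" if rng.random() < 0.5 else "-"
        for attempt in range(20):
            full, right = _random_full_chain(
                gene_id, chrom, strand, cursor, config, rng
            )
            try:
                sim_gene = inject_event(
                    full, patterns[i], rng, config.ass_shift_range
                )
                break
            except ValueError:
                continue
        else:
            raise RuntimeError(
                f"could not host pattern {patterns[i]} in gene {gene_id} "
                "after 20 attempts"
            )
        if config.transcripts_per_gene == 5:
            chain = full.transcripts[0].exons
            sim_gene.transcripts.extend(
                _extra_isoforms(sim_gene, chain, rng, 3)
            )
            sim_gene = flatten_gene_exons(sim_gene)
        genes.append(sim_gene)
        reference.append(flatten_gene_exons(full))
        labels[gene_id] = EventLabel(patterns[i], bool(is_true[i]))
        cursor = right + 1 + config.intergenic_gap

    return SimTranscriptome(genes, labels, config.seed, reference)
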