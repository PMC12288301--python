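"""Fragment-to-feature counting: exon-junction (DEJU) and legacy exon (DEU) modes.

DEJU mode implements the unique-assignment rule that motivates the method:

* a fragment with at least one junction-bridging mate is assigned to exactly
  **one junction feature** — the bridged junction with the longest minimum
  overhang (ties broken by leftmost intron start);
* any other fragment is assigned to the **single flattened exon** with the
  largest total overlap across both mates (ties broken by leftmost exon);
* fragments overlapping no exon bin (e.g. reads inside a retained intron that
  the counting annotation does not consider exonic) are UNASSIGNED.

Every fragment therefore contributes zero or one count, and per-sample
library sizes equal the number of assigned fragments.  Junction features are
kept only when their read support pooled over all samples is *strictly
greater* than ``min_junction_reads``; fragments on dropped junctions become
UNASSIGNED.

DEU mode reproduces legacy exon-level counting for contrast: junction
features do not exist and a fragment contributes one count to **every**
flattened exon either mate overlaps, so junction-bridging fragments are
double-counted and library sizes are inflated.

Two equivalent implementations are provided: a per-record reference path
(:meth:`FragmentCounter.count_records`) operating on explicit genomic blocks,
and a vectorised columnar path (:meth:`FragmentCounter.count_arrays`) used by
the pipeline; their agreement is asserted by the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, JunctionRecord, Transcript, UNKNOWN_GENE
from .read_sim import FragmentArrays, FragmentRecord

__all__ = [
    "QuantConfig",
    "CountMatrix",
    "FragmentCounter",
    "assign_junctions_to_genes",
    "build_count_matrix",
]

_SENTINEL = np.iinfo(np.int64).max


@dataclass
class QuantConfig:
    """Counting-mode parameters."""

    min_junction_reads: int = 3  # keep junctions with pooled support > this
    mode: str = "DEJU"  # "DEJU" or "DEU"
    assign_novel_junctions: bool = True
    min_overhang: int = 1

    def __post_init__(self) -> None:
        if self.min_junction_reads < 0:
            raise ValueError("min_junction_reads must be >= 0")
        if self.mode not in ("DEJU", "DEU"):
            raise ValueError(f"unknown counting mode {self.mode!r}")
        if self.min_overhang < 1:
            raise ValueError("min_overhang must be >= 1")


FEATURE_COLUMNS = [
    "feature_id",
    "feature_type",
    "gene_id",
    "chrom",
    "start",
    "end",
    "strand",
]


@dataclass
class CountMatrix:
    """Feature-by-sample integer counts with feature metadata."""

    features: pd.DataFrame  # FEATURE_COLUMNS
    samples: list[str]
    counts: np.ndarray  # (n_features, n_samples) int64
    library_sizes: np.ndarray  # per-sample assigned totals
    unassigned: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.features), len(self.samples)):
            raise ValueError("counts shape does not match features/samples")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_features(self) -> int:
        return len(self.features)

    def subset(self, keep: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.features.loc[keep].reset_index(drop=True),
            list(self.samples),
            self.counts[np.asarray(keep)],
            self.library_sizes.copy(),
            None if self.unassigned is None else self.unassigned.copy(),
        )

    def to_tsv(self, path) -> None:
        table = self.features.copy()
        for i, s in enumerate(self.samples):
            table[s] = self.counts[:, i]
        table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        table = pd.read_csv(path, sep="\t")
        samples = [c for c in table.columns if c not in FEATURE_COLUMNS]
        counts = table[samples].to_numpy(dtype=np.int64)
        return cls(
            table[FEATURE_COLUMNS], samples, counts, counts.sum(axis=0)
        )


def assign_junctions_to_genes(
    observed: Sequence[tuple[str, int, int]],
    junction_db: Sequence[JunctionRecord],
    genes: Sequence[GeneModel],
) -> list[JunctionRecord]:
    """Attribute observed junctions to genes.

    An exact (chrom, intron coordinates) match against the junction database
    inherits that record's gene; a novel junction is attributed to a gene iff
    both flanking exonic bases fall within exactly one gene's genomic span.
    Ambiguous or orphan junctions come back with gene ``UNKNOWN``.
    """
    db_index: dict[tuple[str, int, int], JunctionRecord] = {}
    for rec in junction_db:
        db_index.setdefault((rec.chrom, rec.intron_start, rec.intron_end), rec)
    spans: dict[str, list[tuple[int, int, str, str]]] = {}
    for g in genes:
        lo, hi = g.span
        spans.setdefault(g.chrom, []).append((lo, hi, g.gene_id, g.strand))

    out = []
    for chrom, s, e in observed:
        key = (chrom, s, e)
        if key in db_index:
            rec = db_index[key]
            out.append(
                JunctionRecord(chrom, s, e, rec.strand, rec.gene_id, True)
            )
            continue
        hits = [
            (gid, strand)
            for lo, hi, gid, strand in spans.get(chrom, [])
            if lo <= s - 1 <= hi and lo <= e + 1 <= hi
        ]
        if len(hits) == 1:
            out.append(JunctionRecord(chrom, s, e, hits[0][1], hits[0][0], False))
        else:
            out.append(JunctionRecord(chrom, s, e, "+", UNKNOWN_GENE, False))
    return out


class FragmentCounter:
    """Accumulates fragment counts over a fixed feature space.

    Parameters
    ----------
    annotation_genes
        Counting annotation with populated ``flat_exons`` (the exon bins).
    junction_db
        Annotated junction database used to attribute junctions to genes.
    sample_ids
        Ordered sample identifiers of the count matrix.
    config
        Counting mode and junction thresholds.
    transcripts
        Optional simulated isoforms; required for the vectorised columnar
        path, and used to pre-register their junctions as observable
        features.  The record path registers junctions from the records
        themselves when no transcripts are given.
    """

    def __init__(
        self,
        annotation_genes: Sequence[GeneModel],
        junction_db: Sequence[JunctionRecord],
        sample_ids: Sequence[str],
        config: QuantConfig | None = None,
        transcripts: Sequence[Transcript] | None = None,
        observed_junctions: Sequence[tuple[str, int, int]] | None = None,
    ) -> None:
        self.config = config or QuantConfig()
        self.sample_ids = list(sample_ids)
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self.genes = {g.gene_id: g for g in annotation_genes}
        self._junction_db = list(junction_db)

        # --- exon features, in (gene order, coordinate) order -------------
        rows = []
        self._exon_rows: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for g in annotation_genes:
            if not g.flat_exons:
                raise ValueError(
                    f"annotation gene {g.gene_id} has no flattened exons"
                )
            start_row = len(rows)
            for e in g.flat_exons:
                rows.append(
                    (
                        f"{g.gene_id}:E:{e.start}-{e.end}",
                        "EXON",
                        g.gene_id,
                        e.chrom,
                        e.start,
                        e.end,
                        e.strand,
                    )
                )
            starts = np.array([e.start for e in g.flat_exons])
            ends = np.array([e.end for e in g.flat_exons])
            self._exon_rows[g.gene_id] = (
                starts,
                ends,
                np.arange(start_row, len(rows)),
            )

        # --- junction features --------------------------------------------
        # the annotated junction catalogue is always observable; novel
        # junctions come from transcripts or the observed set
        observed: dict[tuple[str, int, int], None] = {}
        for rec in self._junction_db:
            observed.setdefault((rec.chrom, rec.intron_start, rec.intron_end), None)
        if transcripts is not None:
            for tx in transcripts:
                for s, e in tx.introns():
                    observed.setdefault((tx.chrom, s, e), None)
        if observed_junctions is not None:
            for key in observed_junctions:
                observed.setdefault(tuple(key), None)
        assigned = assign_junctions_to_genes(
            sorted(observed), self._junction_db, annotation_genes
        )
        self._junction_row: dict[tuple[str, int, int], int] = {}
        self._junction_first_row = len(rows)
        if self.config.mode == "DEJU":
            for rec in sorted(
                assigned, key=lambda r: (r.chrom, r.intron_start, r.intron_end)
            ):
                if rec.gene_id == UNKNOWN_GENE:
                    continue
                if not rec.annotated and not self.config.assign_novel_junctions:
                    continue
                key = (rec.chrom, rec.intron_start, rec.intron_end)
                self._junction_row[key] = len(rows)
                rows.append(
                    (
                        f"{rec.gene_id}:J:{rec.intron_start}-{rec.intron_end}",
                        "JUNCTION",
                        rec.gene_id,
                        rec.chrom,
                        rec.intron_start,
                        rec.intron_end,
                        rec.strand,
                    )
                )

        self.features = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
        self.counts = np.zeros(
            (len(rows), len(self.sample_ids)), dtype=np.int64
        )
        self.unassigned = np.zeros(len(self.sample_ids), dtype=np.int64)
        self.total_seen = np.zeros(len(self.sample_ids), dtype=np.int64)

        self._tx_index = None
        if transcripts is not None:
            self._build_transcript_index(list(transcripts))

    # ------------------------------------------------------------------ #
    # vectorised columnar path
    # ------------------------------------------------------------------ #

    def _build_transcript_index(self, transcripts: list[Transcript]) -> None:
        """Concatenated piece/junction arrays in a global coordinate system.

        Transcript *t* occupies global positions ``[off[t], off[t]+len-1]``;
        pieces are maximal transcript segments mapping to one exon bin (or
        none), and junction boundaries are the transcript positions of the
        first base after each intron.
        """
        self.transcripts = transcripts
        n = len(transcripts)
        off = np.zeros(n, dtype=np.int64)
        tx_len = np.zeros(n, dtype=np.int64)
        piece_end: list[int] = []  # global end-exclusive
        piece_len: list[int] = []
        piece_flat: list[int] = []
        jb: list[int] = []  # global junction boundary positions
        j_row: list[int] = []
        j_gstart: list[int] = []
        cursor = 0
        for t, tx in enumerate(transcripts):
            off[t] = cursor
            tx_len[t] = tx.length
            starts, ends, rowids = self._exon_rows[tx.gene_id]
            local = 0
            for i, exon in enumerate(tx.exons):
                if i > 0:
                    jb.append(cursor + local)
                    intron = (tx.exons[i - 1].end + 1, exon.start - 1)
                    key = (tx.chrom, intron[0], intron[1])
                    j_row.append(self._junction_row.get(key, -1))
                    j_gstart.append(intron[0])
                # split the exon into segments by the gene's exon bins
                pos = exon.start
                while pos <= exon.end:
                    k = np.searchsorted(ends, pos)
                    if k < len(starts) and starts[k] <= pos:
                        seg_end = min(int(ends[k]), exon.end)
                        flat = int(rowids[k])
                    else:
                        seg_end = (
                            min(int(starts[k]) - 1, exon.end)
                            if k < len(starts)
                            else exon.end
                        )
                        flat = -1
                    seg_len = seg_end - pos + 1
                    local += seg_len
                    piece_end.append(cursor + local)
                    piece_len.append(seg_len)
                    piece_flat.append(flat)
                    pos = seg_end + 1
            cursor += tx.length + 1

        self._tx_index = {
            "off": off,
            "tx_len": tx_len,
            "PE": np.array(piece_end, dtype=np.int64),
            "PL": np.array(piece_len, dtype=np.int64),
            "PF": np.array(piece_flat, dtype=np.int64),
            "JB": np.array(jb, dtype=np.int64),
            "JROW": np.array(j_row, dtype=np.int64),
            "JGS": np.array(j_gstart, dtype=np.int64),
        }
        self._tx_index["PS"] = self._tx_index["PE"] - self._tx_index["PL"]

    def _best_junction(self, ga, gb):
        """Per mate: bridged junction with max-min overhang (tie: leftmost)."""
        ix = self._tx_index
        JB = ix["JB"]
        mo = self.config.min_overhang
        lo = np.searchsorted(JB, ga + mo)
        hi = np.searchsorted(JB, gb - mo + 2)
        has = hi > lo
        him1 = np.maximum(hi - 1, lo)
        mid = (ga + gb + 1) // 2
        j = np.clip(np.searchsorted(JB, mid), lo, him1)
        jm1 = np.clip(j - 1, lo, him1)
        safe_j = np.where(has, j, 0)
        safe_m = np.where(has, jm1, 0)
        c_j = JB[safe_j]
        c_m = JB[safe_m]
        o_j = np.minimum(c_j - ga, gb - c_j + 1)
        o_m = np.minimum(c_m - ga, gb - c_m + 1)
        take_m = (o_m > o_j) | ((o_m == o_j) & (safe_m < safe_j))
        best = np.where(take_m, safe_m, safe_j)
        obest = np.where(has, np.where(take_m, o_m, o_j), -1)
        return has, best, obest

    def count_arrays(self, arrays: FragmentArrays, read_length: int = 75) -> None:
        """Vectorised counting of one sample's columnar fragments."""
        if self._tx_index is None:
            raise RuntimeError("columnar counting requires transcripts")
        s = self._sample_index[arrays.sample_id]
        ix = self._tx_index
        tx = arrays.tx_idx.astype(np.int64)
        start = arrays.start.astype(np.int64)
        length = arrays.length.astype(np.int64)
        self.total_seen[s] += tx.size
        if tx.size == 0:
            return
        off_t = ix["off"][tx]
        mate_len = np.minimum(read_length, length)
        ga1 = off_t + start
        gb1 = ga1 + mate_len - 1
        gb2 = off_t + start + length - 1
        ga2 = gb2 - mate_len + 1

        if self.config.mode == "DEU":
            self._count_deu(s, ga1, gb1, ga2, gb2)
            return

        has1, j1, o1 = self._best_junction(ga1, gb1)
        has2, j2, o2 = self._best_junction(ga2, gb2)
        JGS = ix["JGS"]
        gs1 = JGS[j1]
        gs2 = JGS[j2]
        pick1 = has1 & (~has2 | (o1 > o2) | ((o1 == o2) & (gs1 <= gs2)))
        jb_idx = np.where(pick1, j1, j2)
        spans = has1 | has2
        jrow = ix["JROW"][jb_idx]
        junction_assigned = spans & (jrow >= 0)
        if junction_assigned.any():
            self.counts[:, s] += np.bincount(
                jrow[junction_assigned], minlength=self.counts.shape[0]
            )

        # exon path for fragments bridging no junction
        idx = np.flatnonzero(~spans)
        if idx.size == 0:
            return
        PE, PF = ix["PE"], ix["PF"]
        a1, b1 = ga1[idx], gb1[idx]
        a2, b2 = ga2[idx], gb2[idx]
        r1s = np.searchsorted(PE, a1, "right")
        r1e = np.searchsorted(PE, b1, "right")
        r2s = np.searchsorted(PE, a2, "right")
        r2e = np.searchsorted(PE, b2, "right")
        simple = (r1s == r1e) & (r2s == r2e)
        f1 = PF[r1s]
        f2 = PF[r2s]
        chosen = np.where(f1 < 0, f2, np.where(f2 < 0, f1, np.minimum(f1, f2)))
        chosen = np.where(simple, chosen, -1)

        if not simple.all():
            sub = np.flatnonzero(~simple)
            chosen[sub] = self._largest_overlap_exon(
                a1[sub], b1[sub], a2[sub], b2[sub],
                r1s[sub], r1e[sub], r2s[sub], r2e[sub],
            )
        ok = chosen >= 0
        if ok.any():
            self.counts[:, s] += np.bincount(
                chosen[ok], minlength=self.counts.shape[0]
            )

    def _largest_overlap_exon(self, a1, b1, a2, b2, r1s, r1e, r2s, r2e):
        """Exon with largest summed overlap for mates crossing piece borders."""
        ix = self._tx_index
        PE, PS, PF = ix["PE"], ix["PS"], ix["PF"]
        K = int(
            max((r1e - r1s).max(initial=0), (r2e - r2s).max(initial=0))
        ) + 1
        n = a1.size
        ids = np.full((n, 2 * K), _SENTINEL, dtype=np.int64)
        ov = np.zeros((n, 2 * K), dtype=np.int64)
        for m, (ga, gb, rs, re) in enumerate(
            [(a1, b1, r1s, r1e), (a2, b2, r2s, r2e)]
        ):
            for k in range(K):
                rows = rs + k
                act = rows <= re
                rr = np.where(act, rows, 0)
                o = np.minimum(gb, PE[rr] - 1) - np.maximum(ga, PS[rr]) + 1
                fid = PF[rr]
                valid = act & (fid >= 0)
                col = m * K + k
                ids[:, col] = np.where(valid, fid, _SENTINEL)
                ov[:, col] = np.where(valid, o, 0)
        order = np.argsort(ids, axis=1, kind="stable")
        ids = np.take_along_axis(ids, order, axis=1)
        ov = np.take_along_axis(ov, order, axis=1)
        best_ov = np.zeros(n, dtype=np.int64)
        best_id = np.full(n, -1, dtype=np.int64)
        run = np.zeros(n, dtype=np.int64)
        prev = np.full(n, -2, dtype=np.int64)
        for col in range(2 * K):
            cur = ids[:, col]
            same = cur == prev
            run = np.where(same, run + ov[:, col], ov[:, col])
            prev = cur
            upd = (cur != _SENTINEL) & (run > best_ov)
            best_ov = np.where(upd, run, best_ov)
            best_id = np.where(upd, cur, best_id)
        return best_id

    def _count_deu(self, s, ga1, gb1, ga2, gb2) -> None:
        """Legacy counting: +1 to every exon bin either mate overlaps."""
        ix = self._tx_index
        PE, PF = ix["PE"], ix["PF"]
        r1s = np.searchsorted(PE, ga1, "right")
        r1e = np.searchsorted(PE, gb1, "right")
        r2s = np.searchsorted(PE, ga2, "right")
        r2e = np.searchsorted(PE, gb2, "right")
        # union of the two piece-row ranges (mate1 starts first)
        touch = r2s <= r1e + 1
        aS = r1s
        aE = np.where(touch, np.maximum(r1e, r2e), r1e)
        bS = np.where(touch, 1, r2s)
        bE = np.where(touch, 0, r2e)
        nF = self.counts.shape[0]
        for rs, re in ((aS, aE), (bS, bE)):
            span = int((re - rs).max(initial=-1))
            for k in range(span + 1):
                rows = rs + k
                act = rows <= re
                rr = np.where(act, rows, 0)
                fid = PF[rr]
                valid = act & (fid >= 0)
                if valid.any():
                    self.counts[:, s] += np.bincount(
                        fid[valid], minlength=nF
                    )

    # ------------------------------------------------------------------ #
    # record-level reference path
    # ------------------------------------------------------------------ #

    def classify_record(self, rec: FragmentRecord):
        """Classify one fragment record.

        Returns ``("JUNCTION", row)``, ``("EXON", row)`` or ``(None, -1)``
        in DEJU mode; in DEU mode returns ``("EXON_MULTI", rows)`` with the
        list of exon rows the fragment increments.
        """
        gene = self.genes[rec.gene_id]
        starts, ends, rowids = self._exon_rows[rec.gene_id]
        blocks = list(rec.mate1_blocks) + list(rec.mate2_blocks)

        if self.config.mode == "DEU":
            hit = set()
            for bs, be in blocks:
                for k in range(len(starts)):
                    if bs <= ends[k] and be >= starts[k]:
                        hit.add(int(rowids[k]))
            return "EXON_MULTI", sorted(hit)

        candidates: dict[tuple[int, int], int] = {}
        for mate_blocks, juncs in (
            (rec.mate1_blocks, rec.junctions1),
            (rec.mate2_blocks, rec.junctions2),
        ):
            for js, je in juncs:
                left = sum(
                    min(be, js - 1) - bs + 1
                    for bs, be in mate_blocks
                    if bs <= js - 1
                )
                right = sum(
                    be - max(bs, je + 1) + 1
                    for bs, be in mate_blocks
                    if be >= je + 1
                )
                o = min(left, right)
                if o >= self.config.min_overhang:
                    candidates[(js, je)] = max(candidates.get((js, je), 0), o)
        if candidates:
            best = max(candidates.items(), key=lambda kv: (kv[1], -kv[0][0]))
            row = self._junction_row.get((gene.chrom, best[0][0], best[0][1]), -1)
            return ("JUNCTION", row) if row >= 0 else (None, -1)

        overlap: dict[int, int] = {}
        for bs, be in blocks:
            for k in range(len(starts)):
                o = min(be, int(ends[k])) - max(bs, int(starts[k])) + 1
                if o > 0:
                    row = int(rowids[k])
                    overlap[row] = overlap.get(row, 0) + o
        if not overlap:
            return None, -1
        best_row = max(sorted(overlap), key=lambda r: (overlap[r], -r))
        return "EXON", best_row

    def count_records(self, records: Iterable[FragmentRecord]) -> None:
        for rec in records:
            s = self._sample_index[rec.sample_id]
            self.total_seen[s] += 1
            kind, row = self.classify_record(rec)
            if kind == "EXON_MULTI":
                for r in row:
                    self.counts[r, s] += 1
            elif kind is not None:
                self.counts[row, s] += 1

    # ------------------------------------------------------------------ #

    def result(self) -> CountMatrix:
        """Apply the junction support filter and assemble the count matrix."""
        counts = self.counts.copy()
        keep = np.ones(counts.shape[0], dtype=bool)
        if self.config.mode == "DEJU":
            jmask = np.zeros(counts.shape[0], dtype=bool)
            jmask[self._junction_first_row :] = True
            pooled = counts.sum(axis=1)
            keep = ~jmask | (pooled > self.config.min_junction_reads)
        kept_counts = counts[keep]
        lib = kept_counts.sum(axis=0)
        unassigned = self.total_seen - lib if self.config.mode == "DEJU" else None
        return CountMatrix(
            self.features.loc[keep].reset_index(drop=True),
            list(self.sample_ids),
            kept_counts,
            lib,
            unassigned,
        )


def build_count_matrix(
    frags: Iterable[FragmentRecord],
    annotation_genes: Sequence[GeneModel],
    junction_db: Sequence[JunctionRecord],
    config: QuantConfig | None = None,
    sample_ids: Sequence[str] | None = None,
) -> CountMatrix:
    """Count a stream of fragment records into a feature matrix.

    Observed junctions are taken from the records themselves; sample order
    defaults to first appearance.  Suited to desk-scale record streams — the
    pipeline uses :class:`FragmentCounter` with columnar fragments instead.
    """
    records = list(frags)
    gene_chrom = {g.gene_id: g.chrom for g in annotation_genes}
    observed = sorted(
        {
            (gene_chrom[r.gene_id], js, je)
            for r in records
            for js, je in (r.junctions1 | r.junctions2)
        }
    )
    if sample_ids is None:
        seen = dict.fromkeys(r.sample_id for r in records)
        sample_ids = list(seen)
    unknown = [r.sample_id for r in records if r.sample_id not in set(sample_ids)]
    if unknown:
        raise ValueError(f"sample id {unknown[0]!r} absent from the design")
    counter = FragmentCounter(
        annotation_genes,
        junction_db,
        sample_ids,
        config,
        observed_junctions=observed,
    )
    counter.count_records(records)
    return counter.result()
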