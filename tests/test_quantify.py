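"""Fragment classification and count-matrix construction."""

import numpy as np
import pytest

from deju.annotation import (
    Exon,
    GeneModel,
    Transcript,
    build_junction_database,
    flatten_gene_exons,
)
from deju.quantify import (
    FragmentCounter,
    QuantConfig,
    assign_junctions_to_genes,
    build_count_matrix,
)
from deju.read_sim import (
    ExpressionConfig,
    FragmentRecord,
    SampleDesign,
    assign_baseline_expression,
    fragment_arrays_to_records,
    make_fragment_record,
    sample_sample_abundances,
    simulate_fragment_arrays,
)


def _junction_fragment(sample="s1"):
    """Mate 1 bridges the intron (201, 499) of the toy gene."""
    return FragmentRecord(
        sample,
        "G.B",
        "G",
        ((180, 200), (500, 553)),
        ((560, 600),),
        frozenset({(201, 499)}),
        frozenset(),
    )


def _exon_fragment(sample="s1"):
    return FragmentRecord(
        sample, "G.A", "G", ((310, 384),), ((320, 394),), frozenset(), frozenset()
    )


class TestClassification:
    def test_junction_fragment_goes_to_the_junction_only(self, toy_annotation):
        genes, jdb = toy_annotation
        counter = FragmentCounter(
            genes, jdb, ["s1"], QuantConfig(),
            observed_junctions=[("chr1", 201, 499)],
        )
        kind, row = counter.classify_record(_junction_fragment())
        assert kind == "JUNCTION"
        assert counter.features.loc[row, "feature_id"] == "G:J:201-499"

    def test_same_fragment_double_counts_in_deu_mode(self, toy_annotation):
        genes, jdb = toy_annotation
        counter = FragmentCounter(genes, jdb, ["s1"], QuantConfig(mode="DEU"))
        kind, rows = counter.classify_record(_junction_fragment())
        assert kind == "EXON_MULTI"
        ids = counter.features.loc[rows, "feature_id"].tolist()
        assert ids == ["G:E:100-200", "G:E:500-600"]

    def test_non_split_fragment_goes_to_its_exon(self, toy_annotation):
        genes, jdb = toy_annotation
        counter = FragmentCounter(genes, jdb, ["s1"], QuantConfig())
        kind, row = counter.classify_record(_exon_fragment())
        assert kind == "EXON"
        assert counter.features.loc[row, "feature_id"] == "G:E:300-400"

    def test_intronic_fragment_is_unassigned(self, toy_annotation):
        genes, jdb = toy_annotation
        rec = FragmentRecord(
            "s1", "G.B", "G", ((420, 460),), ((430, 470),), frozenset(), frozenset()
        )
        counter = FragmentCounter(genes, jdb, ["s1"], QuantConfig())
        assert counter.classify_record(rec) == (None, -1)


class TestJunctionFilter:
    def _matrix_with_support(self, toy_annotation, n_junction_frags):
        genes, jdb = toy_annotation
        frags = [_junction_fragment() for _ in range(n_junction_frags)]
        frags += [_exon_fragment() for _ in range(5)]
        return build_count_matrix(frags, genes, jdb, QuantConfig())

    def test_well_supported_junction_is_kept(self, toy_annotation):
        matrix = self._matrix_with_support(toy_annotation, 10)
        row = matrix.features["feature_id"] == "G:J:201-499"
        assert row.any()
        assert matrix.counts[row.to_numpy()].sum() == 10

    def test_support_exactly_at_threshold_is_dropped(self, toy_annotation):
        matrix = self._matrix_with_support(toy_annotation, 3)
        assert not (matrix.features["feature_id"] == "G:J:201-499").any()
        # the dropped junction's fragments become unassigned
        assert matrix.unassigned.sum() == 3

    def test_support_one_above_threshold_is_kept(self, toy_annotation):
        matrix = self._matrix_with_support(toy_annotation, 4)
        assert (matrix.features["feature_id"] == "G:J:201-499").any()


class TestJunctionGeneAssignment:
    def test_exact_match_inherits_gene(self, toy_annotation):
        genes, jdb = toy_annotation
        [rec] = assign_junctions_to_genes([("chr1", 201, 299)], jdb, genes)
        assert rec.gene_id == "G" and rec.annotated

    def test_novel_junction_contained_in_one_gene(self, toy_annotation):
        genes, jdb = toy_annotation
        [rec] = assign_junctions_to_genes([("chr1", 201, 329)], jdb, genes)
        assert rec.gene_id == "G" and not rec.annotated

    def test_junction_between_overlapping_genes_is_unknown(self, toy_gene):
        other = flatten_gene_exons(
            GeneModel(
                "H",
                "chr1",
                "+",
                transcripts=[
                    Transcript(
                        "H.1",
                        "H",
                        (Exon("chr1", 150, 250), Exon("chr1", 450, 560)),
                    )
                ],
            )
        )
        genes = [toy_gene, other]
        jdb = build_junction_database(genes)
        [rec] = assign_junctions_to_genes([("chr1", 260, 440)], jdb, genes)
        assert rec.gene_id == "UNKNOWN"


class TestInvariants:
    @pytest.fixture(scope="class")
    @staticmethod
    def simulated(small_transcriptome, small_design, expression_config):
        tr = small_transcriptome
        rng = np.random.default_rng(77)
        baseline = assign_baseline_expression(tr, expression_config, rng)
        ab = sample_sample_abundances(
            baseline, tr, small_design, expression_config, rng
        )
        txs = [t for g in tr.genes for t in g.transcripts]
        lengths = np.array([t.length for t in txs])
        arrays = list(
            simulate_fragment_arrays(
                ab, lengths, small_design, expression_config, rng
            )
        )
        jdb = build_junction_database(tr.reference_genes)
        return tr, txs, arrays, jdb

    @pytest.mark.parametrize("mode", ["DEJU", "DEU"])
    def test_vectorised_and_record_paths_agree(self, simulated, small_design, mode):
        tr, txs, arrays, jdb = simulated
        cfg = QuantConfig(mode=mode)
        vec = FragmentCounter(
            tr.reference_genes, jdb, small_design.sample_ids, cfg, transcripts=txs
        )
        rec = FragmentCounter(
            tr.reference_genes, jdb, small_design.sample_ids, cfg, transcripts=txs
        )
        for arr in arrays:
            vec.count_arrays(arr, 75)
            rec.count_records(fragment_arrays_to_records(arr, txs, 75))
        np.testing.assert_array_equal(vec.counts, rec.counts)

    def test_unique_assignment_invariant(self, simulated, small_design):
        """DEJU: assigned + unassigned == simulated fragments, per sample."""
        tr, txs, arrays, jdb = simulated
        counter = FragmentCounter(
            tr.reference_genes,
            jdb,
            small_design.sample_ids,
            QuantConfig(),
            transcripts=txs,
        )
        for arr in arrays:
            counter.count_arrays(arr, 75)
        matrix = counter.result()
        np.testing.assert_array_equal(
            matrix.library_sizes + matrix.unassigned,
            small_design.library_sizes,
        )

    def test_deu_double_counting_inflates_totals(self, simulated, small_design):
        tr, txs, arrays, jdb = simulated
        totals = {}
        for mode in ("DEJU", "DEU"):
            counter = FragmentCounter(
                tr.reference_genes,
                jdb,
                small_design.sample_ids,
                QuantConfig(mode=mode),
                transcripts=txs,
            )
            for arr in arrays:
                counter.count_arrays(arr, 75)
            totals[mode] = counter.result().counts.sum(axis=0)
        assert (totals["DEU"] > totals["DEJU"]).all()

    def test_determinism(self, simulated, small_design):
        tr, txs, arrays, jdb = simulated
        results = []
        for _ in range(2):
            counter = FragmentCounter(
                tr.reference_genes,
                jdb,
                small_design.sample_ids,
                QuantConfig(),
                transcripts=txs,
            )
            for arr in arrays:
                counter.count_arrays(arr, 75)
            results.append(counter.result())
        np.testing.assert_array_equal(results[0].counts, results[1].counts)
        assert results[0].features.equals(results[1].features)


class TestBuildCountMatrix:
    def test_unknown_sample_rejected(self, toy_annotation):
        genes, jdb = toy_annotation
        with pytest.raises(ValueError, match="sample"):
            build_count_matrix(
                [_exon_fragment("mystery")], genes, jdb, sample_ids=["s1"]
            )

    def test_tsv_round_trip(self, tmp_path, toy_annotation):
        genes, jdb = toy_annotation
        frags = [_junction_fragment() for _ in range(5)] + [_exon_fragment()]
        matrix = build_count_matrix(frags, genes, jdb)
        path = tmp_path / "counts.tsv"
        matrix.to_tsv(path)
        from deju.quantify import CountMatrix

        back = CountMatrix.from_tsv(path)
        assert back.features["feature_id"].tolist() == matrix.features[
            "feature_id"
        ].tolist()
        np.testing.assert_array_equal(back.counts, matrix.counts)
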