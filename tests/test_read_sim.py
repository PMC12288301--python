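"""Abundance model and fragment simulation."""

import numpy as np
import pandas as pd
import pytest

from deju.annotation import Exon, Transcript
from deju.read_sim import (
    ExpressionConfig,
    SampleDesign,
    assign_baseline_expression,
    fragment_arrays_to_records,
    make_fragment_record,
    project_interval,
    read_fragments_tsv,
    sample_sample_abundances,
    simulate_fragment_arrays,
    write_fragments_tsv,
)
from deju.splice_sim import Pattern, SimConfig, generate_transcriptome


class TestBaseline:
    def test_zipf_weights_for_three_transcripts(self, rng):
        tr = generate_transcriptome(SimConfig(n_genes=8, n_true_deu=4, seed=0))
        weights = assign_baseline_expression(tr, ExpressionConfig(), rng)
        ranked = np.sort(weights.to_numpy())[::-1][:3]
        n = len(weights)
        harmonic = (1.0 / np.arange(1, n + 1)).sum()
        expected = np.array([1, 1 / 2, 1 / 3]) / harmonic
        np.testing.assert_allclose(ranked, expected, rtol=1e-12)
        # the documented 3-transcript case: 1/H3 = (0.5455, 0.2727, 0.1818)
        h3 = 1 + 1 / 2 + 1 / 3
        np.testing.assert_allclose(
            np.array([1, 0.5, 1 / 3]) / h3, [0.54545, 0.27273, 0.18182], atol=1e-5
        )

    def test_zero_exponent_gives_uniform(self, rng):
        tr = generate_transcriptome(SimConfig(n_genes=8, n_true_deu=4, seed=0))
        weights = assign_baseline_expression(
            tr, ExpressionConfig(zipf_exponent=0.0), rng
        )
        np.testing.assert_allclose(weights, 1.0 / len(weights))

    def test_same_seed_same_ranking(self):
        tr = generate_transcriptome(SimConfig(n_genes=8, n_true_deu=4, seed=0))
        a = assign_baseline_expression(tr, ExpressionConfig(), np.random.default_rng(7))
        b = assign_baseline_expression(tr, ExpressionConfig(), np.random.default_rng(7))
        assert a.equals(b)


class TestAbundances:
    def _single_true_gene(self):
        """Transcriptome whose only true-DEU gene dominates the baseline."""
        return generate_transcriptome(SimConfig(n_genes=4, n_true_deu=4, seed=2))

    def test_reciprocal_fold_change_without_noise(self):
        tr = self._single_true_gene()
        table = tr.transcript_table()
        baseline = pd.Series(
            1.0 / len(table), index=table["transcript_id"], name="baseline"
        )
        design = SampleDesign(n_per_group=2, library_size=1000)
        config = ExpressionConfig(bcv=0.0, fold_change=3.0)
        ab = sample_sample_abundances(
            baseline, tr, design, config, np.random.default_rng(0)
        )
        # per-gene isoform usage: 3:1 in group 1 and 1:3 in group 2
        gene = table["gene_id"].iloc[0]
        pair = table.loc[table["gene_id"] == gene, "transcript_id"]
        usage = ab.loc[pair].to_numpy()
        usage = usage / usage.sum(axis=0)
        np.testing.assert_allclose(usage[:, 0], [0.75, 0.25], rtol=1e-12)
        np.testing.assert_allclose(usage[:, -1], [0.25, 0.75], rtol=1e-12)

    def test_null_mode_columns_identical(self):
        tr = self._single_true_gene()
        baseline = assign_baseline_expression(
            tr, ExpressionConfig(), np.random.default_rng(1)
        )
        design = SampleDesign(n_per_group=3, library_size=1000)
        ab = sample_sample_abundances(
            baseline,
            tr,
            design,
            ExpressionConfig(bcv=0.2, null_mode=True),
            np.random.default_rng(5),
        )
        for col in ab.columns[1:]:
            np.testing.assert_array_equal(ab[col], ab.iloc[:, 0])

    def test_gamma_noise_has_requested_cv(self):
        """Monte-Carlo check of the mean-one gamma parameterisation."""
        rng = np.random.default_rng(123)
        bcv = 0.2
        draws = rng.gamma(1 / bcv**2, bcv**2, size=20_000)
        assert abs(draws.mean() - 1.0) < 0.01
        assert abs(draws.std() / draws.mean() - bcv) < 0.01

    def test_columns_sum_to_one(self):
        tr = self._single_true_gene()
        baseline = assign_baseline_expression(
            tr, ExpressionConfig(), np.random.default_rng(1)
        )
        ab = sample_sample_abundances(
            baseline,
            tr,
            SampleDesign(n_per_group=3, library_size=1000),
            ExpressionConfig(bcv=0.3),
            np.random.default_rng(5),
        )
        np.testing.assert_allclose(ab.sum(axis=0), 1.0, atol=1e-12)


class TestProjection:
    def test_documented_skipping_isoform_example(self):
        tx = Transcript(
            "T", "G", (Exon("chr1", 100, 200), Exon("chr1", 500, 600))
        )
        # transcript positions 95-135 (1-based) = 94..134 (0-based)
        blocks, juncs = project_interval(tx, 94, 134)
        assert blocks == ((194, 200), (500, 533))
        assert juncs == {(201, 499)}

    def test_mate_inside_one_exon_has_no_junctions(self):
        tx = Transcript(
            "T", "G", (Exon("chr1", 100, 200), Exon("chr1", 500, 600))
        )
        blocks, juncs = project_interval(tx, 10, 40)
        assert blocks == ((110, 140),) and juncs == frozenset()

    def test_round_trip_identity(self, small_transcriptome, rng):
        """Mapping blocks back through the exon chain recovers the interval."""
        transcripts = [
            t for g in small_transcriptome.genes for t in g.transcripts
        ]
        for _ in range(300):
            tx = transcripts[rng.integers(len(transcripts))]
            a = int(rng.integers(0, tx.length))
            b = int(rng.integers(a, tx.length))
            blocks, _ = project_interval(tx, a, b)
            # brute-force inverse: genomic position -> transcript coordinate
            lookup = {}
            offset = 0
            for e in tx.exons:
                for i in range(e.length):
                    lookup[e.start + i] = offset + i
                offset += e.length
            covered = sorted(
                lookup[p] for s, e in blocks for p in range(s, e + 1)
            )
            assert covered == list(range(a, b + 1))


class TestFragments:
    def test_library_size_is_exact(self, small_transcriptome, rng):
        tr = small_transcriptome
        baseline = assign_baseline_expression(tr, ExpressionConfig(), rng)
        design = SampleDesign(n_per_group=1, library_size=1000)
        ab = sample_sample_abundances(baseline, tr, design, ExpressionConfig(), rng)
        lengths = np.array([t.length for g in tr.genes for t in g.transcripts])
        for arrays in simulate_fragment_arrays(
            ab, lengths, design, ExpressionConfig(), rng
        ):
            assert len(arrays) == 1000

    def test_fragment_lengths_respect_bounds(self, small_transcriptome, rng):
        tr = small_transcriptome
        config = ExpressionConfig()
        baseline = assign_baseline_expression(tr, config, rng)
        design = SampleDesign(n_per_group=1, library_size=2000)
        ab = sample_sample_abundances(baseline, tr, design, config, rng)
        lengths = np.array([t.length for g in tr.genes for t in g.transcripts])
        for arrays in simulate_fragment_arrays(ab, lengths, design, config, rng):
            lt = lengths[arrays.tx_idx]
            assert (arrays.length <= lt).all()
            assert (
                arrays.length >= np.minimum(2 * config.read_length, lt)
            ).all()
            assert (arrays.start >= 0).all()
            assert (arrays.start + arrays.length <= lt).all()

    def test_record_serialisation_round_trip(self, tmp_path, rng):
        tx = Transcript(
            "T", "G", (Exon("chr1", 100, 200), Exon("chr1", 500, 600))
        )
        records = [
            make_fragment_record("s1", tx, 0, 180, read_length=75),
            make_fragment_record("s1", tx, 20, 150, read_length=75),
        ]
        path = tmp_path / "frags.tsv"
        write_fragments_tsv(records, path)
        back = read_fragments_tsv(path)
        assert back == records


class TestConfigValidation:
    def test_read_longer_than_fragment_rejected(self):
        with pytest.raises(ValueError):
            ExpressionConfig(read_length=300, fragment_length_mean=250)

    def test_design_properties(self):
        design = SampleDesign(n_per_group=3, library_size=10, balanced=False,
                              unbalanced_sizes=(5, 20))
        assert list(design.groups) == [1, 1, 1, 2, 2, 2]
        assert list(design.library_sizes) == [5, 20, 5, 20, 5, 20]
        assert len(design.sample_ids) == 6
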