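"""Stability statistics, HK calling and the gene-level comparison."""

import numpy as np
import pandas as pd
import pytest

from hkref import detect, io, normalize, synth


def _expr(rpkm, tissue_of=None):
    """NormalizedExpression from a plain RPKM table (no count provenance)."""
    df = pd.DataFrame(rpkm)
    df.index = [f"T{i}" for i in range(df.shape[0])]
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    tissues = tissue_of or ["all"] * df.shape[1]
    return normalize.NormalizedExpression(
        rpkm=df,
        tmm_factors=pd.Series(1.0, index=df.columns),
        library_sizes=pd.Series(1_000_000, index=df.columns),
        tissue_of=pd.Series(tissues, index=df.columns),
    )


def _ann_for(expr, **kwargs):
    return io.annotation_frame(
        [
            io.TranscriptAnnotation(t, f"G_{t}", f"S_{t}", 1000, **kwargs)
            for t in expr.transcript_ids
        ]
    )


class TestStabilityStats:
    def test_constant_series(self):
        stats = detect.stability_stats(_expr([[8.0] * 5]))
        row = stats.iloc[0]
        assert row["mean_rpkm"] == pytest.approx(8.0)
        assert row["sd_log2"] == pytest.approx(0.0, abs=1e-12)
        assert row["mfc"] == pytest.approx(1.0)

    def test_two_sample_hand_arithmetic(self):
        stats = detect.stability_stats(_expr([[2.0, 8.0]]))
        row = stats.iloc[0]
        assert row["mean_rpkm"] == pytest.approx(5.0)
        expected_sd = np.std(
            [np.log2(2.001), np.log2(8.001)], ddof=1
        )
        assert abs(row["sd_log2"] - expected_sd) < 1e-12
        assert abs(row["sd_log2"] - 1.414) < 0.01

    def test_all_zero_transcript(self):
        stats = detect.stability_stats(_expr([[0.0] * 4]))
        row = stats.iloc[0]
        assert row["mean_rpkm"] == 0.0
        assert row["sd_log2"] == pytest.approx(0.0, abs=1e-12)
        assert row["mfc"] == pytest.approx(1.0)  # log2(pseudo)/log2(pseudo)
        assert not row["mfc_valid"]  # negative mean log2: fails MFC at call time

    def test_single_sample_tissue(self):
        stats = detect.stability_stats(_expr([[4.0]]))
        row = stats.iloc[0]
        assert row["sd_log2"] == 0.0 and row["mfc"] == 1.0 and row["n_samples"] == 1

    def test_per_tissue_grouping(self):
        expr = _expr([[4.0, 4.0, 16.0, 16.0]], tissue_of=["a", "a", "b", "b"])
        stats = detect.stability_stats(expr)
        assert set(stats["tissue"]) == {"a", "b"}
        assert (stats["sd_log2"] < 1e-3).all()  # constant within each tissue

    def test_pooled_mode(self):
        expr = _expr([[4.0, 4.0, 16.0, 16.0]], tissue_of=["a", "a", "b", "b"])
        stats = detect.stability_stats(expr, pooled=True)
        assert list(stats["tissue"]) == ["__pooled__"]
        assert stats.iloc[0]["sd_log2"] > 1.0  # between-tissue spread now visible


class TestCallHk:
    def test_stable_supported_transcript_is_hk(self):
        expr = _expr([[50.0] * 6], tissue_of=["a"] * 3 + ["b"] * 3)
        stats = detect.stability_stats(expr)
        calls = detect.call_hk(stats, _ann_for(expr))
        assert calls.hk_transcripts == ["T0"]
        assert calls.hk_genes == ["G_T0"]

    def test_low_expression_in_one_tissue_fails_and_is_recorded(self):
        expr = _expr(
            [[0.5, 0.5, 50.0, 50.0]], tissue_of=["a", "a", "b", "b"]
        )
        stats = detect.stability_stats(expr)
        calls = detect.call_hk(stats, _ann_for(expr))
        assert calls.hk_transcripts == []
        row = calls.transcripts.loc["T0"]
        assert not row["pass_expression"]
        assert "a" in row["fail_expression_tissues"]
        assert "b" not in row["fail_expression_tissues"]

    def test_unsupported_model_blocks_hk(self):
        expr = _expr([[50.0] * 4], tissue_of=["a", "a", "b", "b"])
        stats = detect.stability_stats(expr)
        calls = detect.call_hk(stats, _ann_for(expr, has_supported_model=False))
        assert calls.hk_transcripts == []
        assert not calls.transcripts.loc["T0", "pass_model"]

    def test_missing_tissue_coverage_rejected(self):
        expr = _expr([[50.0] * 4], tissue_of=["a", "a", "b", "b"])
        stats = detect.stability_stats(expr)
        extra = _expr([[50.0] * 2, [50.0] * 2], tissue_of=["a", "a"])
        partial = pd.concat(
            [stats, detect.stability_stats(extra).query("transcript_id == 'T1'")],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="missing tissue coverage"):
            detect.call_hk(partial, _ann_for(extra))

    def test_complementary_isoforms_gene_rescue(self):
        # isoform A stable in tissue a only, isoform B in tissue b only
        rpkm = pd.DataFrame(
            {
                "s0": [50.0, 0.5],
                "s1": [50.0, 0.5],
                "s2": [0.5, 50.0],
                "s3": [0.5, 50.0],
            },
            index=["TA", "TB"],
        )
        expr = normalize.NormalizedExpression(
            rpkm=rpkm,
            tmm_factors=pd.Series(1.0, index=rpkm.columns),
            library_sizes=pd.Series(1_000_000, index=rpkm.columns),
            tissue_of=pd.Series(["a", "a", "b", "b"], index=rpkm.columns),
        )
        ann = io.annotation_frame(
            [
                io.TranscriptAnnotation("TA", "G", "S", 1000),
                io.TranscriptAnnotation("TB", "G", "S", 1000),
            ]
        )
        stats = detect.stability_stats(expr)
        strict = detect.call_hk(stats, ann)
        assert strict.hk_transcripts == [] and strict.hk_genes == []
        relaxed = detect.call_hk(stats, ann, allow_complementary_isoforms=True)
        assert relaxed.hk_transcripts == []  # still no constitutive transcript
        assert relaxed.hk_genes == ["G"]  # but the gene is covered jointly

    def test_hk_transcript_implies_hk_gene(self, pipeline):
        calls = pipeline["calls"]
        gene_of = pipeline["ann"]["gene_id"]
        for t in calls.hk_transcripts:
            assert gene_of[t] in calls.hk_genes

    @pytest.mark.parametrize("param,values", [
        ("rpkm_min", [0.5, 1.0, 2.0]),
        ("sd_max", [2.0, 1.0, 0.5]),
        ("mfc_max", [3.0, 2.0, 1.5]),
    ])
    def test_threshold_monotonicity(self, pipeline, param, values):
        """Tightening any threshold never adds HK calls (nested sets)."""
        prev = None
        for v in values:
            calls = detect.call_hk(pipeline["stats"], pipeline["ann"], **{param: v})
            cur = set(calls.hk_transcripts)
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_planted_recovery_single_seed(self, pipeline):
        called = set(pipeline["calls"].hk_transcripts)
        true = set(pipeline["data"].true_hk)
        assert called == true


class TestSummarizeToGene:
    def test_additivity(self):
        rpkm = pd.DataFrame({"s0": [3.0, 4.0]}, index=["TA", "TB"])
        expr = normalize.NormalizedExpression(
            rpkm=rpkm,
            tmm_factors=pd.Series(1.0, index=rpkm.columns),
            library_sizes=pd.Series(1_000_000, index=rpkm.columns),
            tissue_of=pd.Series(["a"], index=rpkm.columns),
        )
        ann = io.annotation_frame(
            [
                io.TranscriptAnnotation("TA", "G", "S", 1000),
                io.TranscriptAnnotation("TB", "G", "S", 2000),
            ]
        )
        gene_expr, gene_ann = detect.summarize_to_gene(expr, ann)
        assert gene_expr.rpkm.loc["G", "s0"] == pytest.approx(7.0)

    def test_single_transcript_identity(self, pipeline):
        gene_expr, _ = detect.summarize_to_gene(pipeline["expr"], pipeline["ann"])
        # every synthetic gene has one transcript: values carry over exactly
        gene_of = pipeline["ann"]["gene_id"]
        tx = pipeline["expr"].transcript_ids[0]
        assert np.allclose(
            gene_expr.rpkm.loc[gene_of[tx]], pipeline["expr"].rpkm.loc[tx]
        )

    def test_anticorrelated_isoforms_diverge(self):
        data = synth.generate_anticorrelated_isoforms(seed=4)
        expr = normalize.normalize_by_tissue(data.counts, data.metadata, data.annotation)
        ann = io.annotation_frame(data.annotation)
        tx_stats = detect.stability_stats(expr)
        tx_calls = detect.call_hk(tx_stats, ann)
        gene_expr, gene_ann = detect.summarize_to_gene(expr, ann)
        gene_calls = detect.call_hk(detect.stability_stats(gene_expr), gene_ann)

        iso_tx = data.truth.index[data.truth["class"] == "anticorrelated_isoform"]
        iso_genes = ann.loc[iso_tx, "gene_id"].unique()
        # gene level passes, neither isoform does
        assert set(iso_genes) <= set(gene_calls.hk_genes)
        assert not (set(iso_tx) & set(tx_calls.hk_transcripts))
        # single-isoform controls agree between the two paths
        ctl_tx = data.truth.index[data.truth["class"] == "single_isoform_control"]
        ctl_genes = ann.loc[ctl_tx, "gene_id"]
        assert set(ctl_tx) <= set(tx_calls.hk_transcripts)
        assert set(ctl_genes) <= set(gene_calls.hk_genes)
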