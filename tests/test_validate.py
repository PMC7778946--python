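"""geNorm M and the subsampling simulations."""

import numpy as np
import pandas as pd
import pytest

from hkref import detect, io, normalize, synth, validate
from oracle_helpers import brute_force_genorm


def _table(arr, ids=None):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=ids or [f"C{i}" for i in range(arr.shape[0])],
        columns=[f"s{i}" for i in range(arr.shape[1])],
    )


class TestGenorm:
    def test_constant_ratio_pair_gives_zero(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 3.0])
        res = validate.genorm_m(_table([x, 3.0 * x]), pseudo=0)
        assert np.allclose(res.m_values, 0.0, atol=1e-12)

    def test_noisy_candidate_excluded_first(self):
        rng = np.random.default_rng(0)
        x = np.array([2.0, 4.0, 8.0, 16.0, 5.0, 6.0, 7.0])
        noisy = x * np.exp(rng.normal(0, 1.0, x.size))
        res = validate.genorm_m(_table([x, 2 * x, noisy]), pseudo=0)
        assert res.m_values.idxmax() == "C2"
        assert res.stepwise_exclusion_order[0] == "C2"
        assert res.ranking[-1] == "C2"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            table = _table(rng.lognormal(3.0, 1.0, size=(4, 7)))
            res = validate.genorm_m(table, pseudo=0)
            oracle = brute_force_genorm(np.log2(table.to_numpy()))
            assert np.abs(res.m_values.to_numpy() - oracle).max() < 1e-10

    def test_fewer_than_two_candidates_rejected(self):
        with pytest.raises(ValueError, match="2 candidates"):
            validate.genorm_m(_table([[1.0, 2.0]]))

    def test_stepwise_covers_all_candidates(self):
        rng = np.random.default_rng(1)
        table = _table(rng.lognormal(3.0, 0.5, size=(5, 6)))
        res = validate.genorm_m(table)
        assert sorted(res.stepwise_exclusion_order) == sorted(table.index)


@pytest.fixture(scope="module")
def diversity_fixture():
    data = synth.generate_tissue_private_instability(seed=7)
    expr = normalize.normalize_by_tissue(data.counts, data.metadata, data.annotation)
    ann = io.annotation_frame(data.annotation)
    return data, expr, ann


class TestTissueDiversity:
    def test_full_group_matches_full_data_count(self, diversity_fixture):
        data, expr, ann = diversity_fixture
        n_tissues = len(expr.tissues())
        calls = detect.call_hk(detect.stability_stats(expr), ann)
        res = validate.simulate_tissue_diversity(
            expr, ann, group_sizes=[n_tissues], n_perm=5, seed=1
        )
        assert (res.counts == len(calls.hk_transcripts)).all()

    def test_seed_reproducibility(self, diversity_fixture, pipeline):
        _, expr, ann = diversity_fixture
        a = validate.simulate_tissue_diversity(expr, ann, group_sizes=[5, 10], n_perm=10, seed=3)
        b = validate.simulate_tissue_diversity(expr, ann, group_sizes=[5, 10], n_perm=10, seed=3)
        assert np.array_equal(a.counts, b.counts)
        # on a tissue-unbalanced table, different seeds choose different
        # tissue subsets and hence different counts
        rng = np.random.default_rng(0)
        tissues = [f"t{i}" for i in range(8)]
        cols = [f"{t}_s{k}" for t in tissues for k in range(2)]
        passes = rng.random((30, 8)) > 0.4  # irregular per-tissue pass sets
        rpkm = pd.DataFrame(
            np.repeat(np.where(passes, 50.0, 0.1), 2, axis=1),
            index=[f"T{i}" for i in range(30)],
            columns=cols,
        )
        expr2 = normalize.NormalizedExpression(
            rpkm=rpkm,
            tmm_factors=pd.Series(1.0, index=cols),
            library_sizes=pd.Series(1_000_000, index=cols),
            tissue_of=pd.Series([c.rsplit("_s", 1)[0] for c in cols], index=cols),
        )
        ann2 = io.annotation_frame(
            [io.TranscriptAnnotation(f"T{i}", f"G{i}", f"S{i}", 1000) for i in range(30)]
        )
        c = validate.simulate_tissue_diversity(expr2, ann2, group_sizes=[3], n_perm=10, seed=3)
        d = validate.simulate_tissue_diversity(expr2, ann2, group_sizes=[3], n_perm=10, seed=4)
        assert not np.array_equal(c.counts, d.counts)

    def test_median_decreases_with_diversity(self, diversity_fixture):
        data, expr, ann = diversity_fixture
        res = validate.simulate_tissue_diversity(
            expr, ann, group_sizes=[5, 10, 15, 20, 30, 50], n_perm=20, seed=2
        )
        med = res.median_stable_count.to_numpy()
        assert (np.diff(med) < 0).all()
        # disjoint per-tissue blocks: counts are exactly base - block * g
        always = int((data.truth["class"] == "always_stable").sum())
        block = int(
            (data.truth["class"] == "tissue_private_unstable").sum()
        ) // len(expr.tissues())
        total = len(data.truth)
        for g, m in zip(res.group_sizes, med):
            assert m == total - block * g

    def test_oversized_group_rejected(self, diversity_fixture):
        _, expr, ann = diversity_fixture
        with pytest.raises(ValueError, match="exceeds"):
            validate.simulate_tissue_diversity(expr, ann, group_sizes=[999], n_perm=1, seed=0)

    def test_subset_count_equals_direct_detection(self, diversity_fixture):
        """The precomputed per-tissue pass table must agree with running
        call_hk on the tissue subset directly."""
        data, expr, ann = diversity_fixture
        tissues = expr.tissues()[:6]
        samples = [s for t in tissues for s in expr.samples_in(t)]
        sub = normalize.NormalizedExpression(
            rpkm=expr.rpkm[samples],
            tmm_factors=expr.tmm_factors[samples],
            library_sizes=expr.library_sizes[samples],
            tissue_of=expr.tissue_of[samples],
        )
        direct = detect.call_hk(detect.stability_stats(sub), ann)
        res = validate.simulate_tissue_diversity(
            expr, ann, group_sizes=[6], n_perm=50, seed=0
        )
        # the fixture's counts are deterministic per subset size
        assert (res.counts == len(direct.hk_transcripts)).all()


@pytest.fixture(scope="module")
def sample_size_fixture():
    cfg = synth.SynthConfig(
        seed=13,
        n_tissues=6,
        samples_per_tissue=10,
        n_hk=80,
        n_reference_grade=40,
        n_violators_per_criterion=20,
        n_background=30,
        n_marginal=120,
    )
    return synth.generate(cfg)


class TestSampleSize:
    def test_full_size_matches_full_data(self, sample_size_fixture):
        data = sample_size_fixture
        ann = io.annotation_frame(data.annotation)
        expr = normalize.normalize_by_tissue(data.counts, data.metadata, data.annotation)
        full_calls = detect.call_hk(detect.stability_stats(expr), ann)
        res = validate.simulate_sample_size(
            data.counts, data.metadata, ann, sizes=[10], n_perm=2, seed=0
        )
        assert (res.counts == len(full_calls.hk_transcripts)).all()

    def test_reproducible_single_permutation(self, sample_size_fixture):
        data = sample_size_fixture
        ann = io.annotation_frame(data.annotation)
        a = validate.simulate_sample_size(
            data.counts, data.metadata, ann, sizes=[4], n_perm=1, seed=9
        )
        b = validate.simulate_sample_size(
            data.counts, data.metadata, ann, sizes=[4], n_perm=1, seed=9
        )
        assert np.array_equal(a.counts, b.counts)

    def test_median_non_increasing_with_sample_size(self, sample_size_fixture):
        """Marginally unstable transcripts (true SD just above the
        criterion) slip through at small n but are rejected as the
        per-tissue sample size grows."""
        data = sample_size_fixture
        ann = io.annotation_frame(data.annotation)
        res = validate.simulate_sample_size(
            data.counts, data.metadata, ann, sizes=[3, 5, 10], n_perm=15, seed=21
        )
        med = res.median_stable_count.to_numpy()
        assert (np.diff(med) <= 0).all()
        assert med[0] > med[-1]  # small n admits false positives

    def test_oversized_request_rejected(self, sample_size_fixture):
        data = sample_size_fixture
        ann = io.annotation_frame(data.annotation)
        with pytest.raises(ValueError, match="fewer"):
            validate.simulate_sample_size(
                data.counts, data.metadata, ann, sizes=[99], n_perm=1, seed=0
            )


class TestSubsampleResult:
    def test_median_self_consistency(self, diversity_fixture):
        _, expr, ann = diversity_fixture
        res = validate.simulate_tissue_diversity(
            expr, ann, group_sizes=[5, 20], n_perm=9, seed=5
        )
        assert np.array_equal(
            res.median_stable_count.to_numpy(), np.median(res.counts, axis=1)
        )

    def test_frame_shape(self, diversity_fixture):
        _, expr, ann = diversity_fixture
        res = validate.simulate_tissue_diversity(
            expr, ann, group_sizes=[5], n_perm=4, seed=5
        )
        df = res.to_frame()
        assert df.shape == (1, 5)  # median + 4 permutations
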