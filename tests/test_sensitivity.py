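"""Shift metrics, Tippett combiner and consensus ranking."""

import os

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scshift import (
    ScshiftError,
    ShiftParams,
    SynthConfig,
    consensus_from_ranks,
    consensus_rank,
    euclidean_shift,
    generate_dataset,
    normalize,
    subsample_deg_count,
    svm_shift,
    tippett_meta_p,
    top_expressed_genes,
    zscore_genes,
)

from conftest import make_expr, two_group_annotation

REFERENCE_TSV = os.path.join(os.path.dirname(__file__), "data", "consensus_rank_reference.tsv")


class TestTopExpressedGenes:
    def test_forced_ordering(self):
        expr = make_expr([[5, 5], [1, 1], [3, 3]], gene_ids=["g1", "g2", "g3"])
        assert top_expressed_genes(expr, [0, 1], 2) == ["g1", "g3"]

    def test_saturation(self):
        expr = make_expr([[5, 5], [1, 1]], gene_ids=["a", "b"])
        assert top_expressed_genes(expr, [0, 1], 10) == ["a", "b"]

    def test_tie_broken_lexicographically(self):
        expr = make_expr([[2, 2], [2, 2]], gene_ids=["zz", "aa"])
        assert top_expressed_genes(expr, [0, 1], 1) == ["aa"]

    def test_matches_bruteforce(self, rng):
        x = rng.gamma(1.0, 1.0, size=(200, 30))
        genes = [f"g{i:03d}" for i in range(200)]
        expr = make_expr(x, gene_ids=genes)
        got = top_expressed_genes(expr, np.arange(30), 50)
        means = x.mean(axis=1)
        brute = sorted(zip(genes, means), key=lambda t: (-t[1], t[0]))[:50]
        assert got == [g for g, _ in brute]


class TestZscore:
    def test_closed_form_sample_sd(self):
        z = zscore_genes(np.array([[1.0, 2.0, 3.0]]))
        assert np.allclose(z, [[-1.0, 0.0, 1.0]])

    def test_constant_gene_maps_to_zero(self):
        z = zscore_genes(np.array([[4.0, 4.0, 4.0], [1.0, 2.0, 3.0]]))
        assert np.all(z[0] == 0)

    def test_rows_standardized(self, rng):
        z = zscore_genes(rng.normal(size=(20, 15)))
        assert np.all(np.abs(z.mean(axis=1)) < 1e-10)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0)

    def test_single_cell_rejected(self):
        with pytest.raises(ScshiftError):
            zscore_genes(np.array([[1.0]]))


class TestTippett:
    def test_identity_for_single_p(self):
        assert tippett_meta_p([0.2]) == pytest.approx(0.2, abs=1e-12)

    def test_closed_form(self):
        assert tippett_meta_p([0.01, 0.5, 0.9]) == pytest.approx(1 - 0.99**3, abs=1e-12)

    def test_all_ones_boundary(self):
        assert tippett_meta_p([1.0, 1.0, 1.0]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ScshiftError):
            tippett_meta_p([])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=10),
        st.floats(min_value=1e-12, max_value=1.0),
    )
    def test_monotone_nonincreasing_in_min_p(self, ps, smaller):
        base = tippett_meta_p(ps, k=len(ps) + 1)
        shrunk = tippett_meta_p(ps + [min(min(ps), smaller)], k=len(ps) + 1)
        assert shrunk <= base + 1e-12


def _reference_euclidean(x, n1):
    """Straight-line reference: z-score per gene (sample sd, zero-variance
    to zero), then the distance between the two group mean vectors."""
    z = np.zeros_like(x, dtype=float)
    for i in range(x.shape[0]):
        sd = np.std(x[i], ddof=1)
        if sd > 0:
            z[i] = (x[i] - x[i].mean()) / sd
    d = z[:, :n1].mean(axis=1) - z[:, n1:].mean(axis=1)
    return float(np.sqrt((d**2).sum()))


class TestEuclideanShift:
    def _params(self, **kw):
        defaults = dict(top_n_genes=30, n_permutations=200, min_cells_per_group=5, seed=1)
        defaults.update(kw)
        return ShiftParams(**defaults)

    def test_matches_bruteforce_reference(self, rng):
        x = rng.normal(2.0, 1.0, size=(30, 20)).clip(min=0)
        expr = make_expr(x)
        annot = two_group_annotation(expr.cell_ids, 10)
        res = euclidean_shift(expr, annot, "typeA", self._params(top_n_genes=30))
        assert res.observed_distance == pytest.approx(_reference_euclidean(x, 10), abs=1e-10)

    def test_constant_expression_degenerate(self):
        expr = make_expr(np.full((10, 24), 3.0))
        annot = two_group_annotation(expr.cell_ids, 12)
        res = euclidean_shift(expr, annot, "typeA", self._params())
        assert res.observed_distance == 0.0
        assert res.p_empirical == 1.0

    def test_gene_order_and_label_swap_invariance(self, rng):
        x = rng.normal(1.0, 0.5, size=(25, 30)).clip(min=0)
        annot = two_group_annotation([f"c{j}" for j in range(30)], 14)
        a = euclidean_shift(make_expr(x), annot, "typeA", self._params())
        perm = rng.permutation(25)
        b = euclidean_shift(
            make_expr(x[perm], gene_ids=[f"g{i}" for i in perm]), annot, "typeA", self._params()
        )
        swapped = euclidean_shift(
            make_expr(x), annot, "typeA", self._params(), conditions=("perturbed", "control")
        )
        assert b.observed_distance == pytest.approx(a.observed_distance, abs=1e-10)
        assert swapped.observed_distance == pytest.approx(a.observed_distance, abs=1e-10)

    def test_p_floor_and_small_group_skip(self, rng):
        x = rng.normal(1.0, 0.5, size=(10, 30)).clip(min=0)
        expr = make_expr(x)
        annot = two_group_annotation(expr.cell_ids, 15)
        res = euclidean_shift(expr, annot, "typeA", self._params(n_permutations=99))
        assert res.p_empirical >= 1 / 100
        tiny = two_group_annotation(expr.cell_ids, 3)
        skipped = euclidean_shift(expr, tiny, "typeA", self._params(min_cells_per_group=10))
        assert skipped.skipped and "min_cells_per_group" in skipped.reason


class TestSVMShift:
    def test_separable_toy_perfect_accuracy(self):
        x = np.concatenate([np.zeros((1, 20)), np.full((1, 20), 10.0)], axis=1)
        expr = make_expr(x, gene_ids=["g0"])
        annot = two_group_annotation(expr.cell_ids, 20)
        res = svm_shift(
            expr, annot, "typeA",
            ShiftParams(top_n_genes=1, n_bootstraps=20, cv_repeats=0, seed=2),
        )
        assert res.median_accuracy == 1.0

    def test_nine_cells_skipped(self, rng):
        x = rng.normal(size=(5, 29)).clip(min=0)
        expr = make_expr(x)
        annot = two_group_annotation(expr.cell_ids, 9)
        res = svm_shift(expr, annot, "typeA", ShiftParams(seed=0))
        assert res.skipped and "min_cells_per_group" in res.reason


class TestSubsampleDEG:
    def test_no_subsampling_when_groups_small(self, rng):
        cfg = SynthConfig(n_cell_types=1, cells_per_type_per_condition=40, n_genes=120, seed=11,
                          effects={"type0": (0.2, 2.0)})
        counts, annot, _ = generate_dataset(cfg)
        expr = normalize(counts)
        params = ShiftParams(subsample_n=100, n_permutations=50, min_cells_per_group=5, seed=3)
        a = subsample_deg_count(expr, annot, "type0", params)
        b = subsample_deg_count(expr, annot, "type0", params,
                                rng=np.random.default_rng(999))
        # groups are below the subsample size: every replicate is the whole
        # data, so the result cannot depend on the random stream
        assert a.n_significant == b.n_significant
        assert np.allclose(a.meta_p.to_numpy(), b.meta_p.to_numpy())

    def test_recovers_planted_degs(self):
        # higher baseline expression so the 10%-expressed pre-filter is not
        # the limiting factor for weakly expressed down-regulated genes
        cfg = SynthConfig(n_cell_types=1, cells_per_type_per_condition=300, n_genes=200, seed=12,
                          gene_mean_log_mean=0.0, effects={"type0": (0.15, 2.0)})
        counts, annot, truth = generate_dataset(cfg)
        expr = normalize(counts)
        params = ShiftParams(subsample_n=100, n_permutations=30, min_cells_per_group=5, seed=4)
        res = subsample_deg_count(expr, annot, "type0", params)
        hits = set(res.meta_p[res.meta_p < params.alpha].index)
        planted = set(truth.de_genes["type0"])
        assert len(hits & planted) >= 0.8 * len(planted)
        assert len(hits - planted) <= 5


class TestConsensusRank:
    def test_reproduces_reference_table(self):
        ref = pd.read_csv(REFERENCE_TSV, sep="\t")
        for (_, _), stratum in ref.groupby(["tissue", "timepoint"]):
            out = consensus_from_ranks(stratum[["cell_type", "ed_rank", "svm_rank", "deg_rank"]])
            merged = out.merge(stratum, on="cell_type", suffixes=("", "_ref"))
            assert np.allclose(merged["avg_rank"].round(2), merged["avg_rank_ref"])

    def test_worked_examples(self):
        df = pd.DataFrame({"ed_rank": [3, 1], "svm_rank": [1, 1], "deg_rank": [1, 1]})
        out = consensus_from_ranks(df)
        assert round(out.loc[out["ed_rank"] == 3, "avg_rank"].iloc[0], 2) == 1.67
        assert out.loc[out["ed_rank"] == 1, "avg_rank"].iloc[0] == 1.00

    def test_tied_statistics_get_average_ranks(self):
        out = consensus_rank(
            {"a": 2.0, "b": 2.0, "c": 1.0},
            {"a": 0.9, "b": 0.8, "c": 0.7},
            {"a": 5, "b": 4, "c": 3},
        )
        tied = out.set_index("cell_type")["ed_rank"]
        assert tied["a"] == tied["b"] == 1.5 and tied["c"] == 3.0

    def test_rank_direction_largest_statistic_is_rank_one(self):
        out = consensus_rank({"a": 9.0, "b": 1.0}, {"a": 1.0, "b": 0.5}, {"a": 10, "b": 0})
        assert out.iloc[0]["cell_type"] == "a" and out.iloc[0]["avg_rank"] == 1.0

    def test_mismatched_cell_type_sets_rejected(self):
        with pytest.raises(ScshiftError, match="differ"):
            consensus_rank({"a": 1.0}, {"a": 1.0, "b": 2.0}, {"a": 1.0})
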