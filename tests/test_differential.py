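"""Wilcoxon DE, conserved markers, reversal logic, Fisher enrichment."""

import numpy as np
import pandas as pd
import pytest

from scshift import (
    DEGParams,
    ScshiftError,
    conserved_markers,
    fisher_enrichment,
    reversed_genes,
    wilcoxon_de,
)
from scshift.differential import rank_sum_p

from conftest import make_expr


def loose_params(**kw):
    defaults = dict(min_expressed_fraction=0.0, min_abs_log_fc=0.0)
    defaults.update(kw)
    return DEGParams(**defaults)


class TestWilcoxonDE:
    def test_exact_enumeration_worked_case(self):
        # complete separation of 4 vs 4 distinct values: exact p = 2/70
        x = np.array([[1.0, 2, 3, 4, 5, 6, 7, 8]])
        expr = make_expr(x, gene_ids=["g0"])
        out = wilcoxon_de(expr, [0, 1, 2, 3], [4, 5, 6, 7], loose_params())
        assert out.loc[0, "p_raw"] == pytest.approx(2 / 70, abs=1e-12)

    def test_low_expression_gene_filtered(self, rng):
        # gene expressed in 5% of cells in both groups -> absent from output
        x = np.zeros((2, 80))
        x[0, [0, 40]] = 5.0  # 1/40 cells expressed per group
        x[1] = rng.gamma(2.0, 1.0, 80)
        expr = make_expr(x, gene_ids=["rare", "common"])
        out = wilcoxon_de(expr, np.arange(40), np.arange(40, 80), DEGParams())
        assert "rare" not in set(out["gene"])

    def test_small_log_fc_filtered(self):
        x = np.concatenate([np.full((1, 30), 1.0), np.full((1, 30), 1.1)], axis=1)
        expr = make_expr(x, gene_ids=["g0"])
        out = wilcoxon_de(expr, np.arange(30), np.arange(30, 60), DEGParams(min_abs_log_fc=0.25))
        assert len(out) == 0

    def test_group_swap_symmetry(self, rng):
        x = rng.gamma(2.0, 1.0, size=(30, 60))
        expr = make_expr(x)
        g1, g2 = np.arange(30), np.arange(30, 60)
        a = wilcoxon_de(expr, g1, g2, loose_params()).set_index("gene")
        b = wilcoxon_de(expr, g2, g1, loose_params()).set_index("gene")
        common = a.index.intersection(b.index)
        assert np.allclose(a.loc[common, "log_fc"], -b.loc[common, "log_fc"])
        assert np.allclose(a.loc[common, "p_raw"], b.loc[common, "p_raw"])

    def test_overlapping_groups_rejected(self, rng):
        expr = make_expr(rng.gamma(1.0, 1.0, size=(5, 20)))
        with pytest.raises(ScshiftError, match="overlap"):
            wilcoxon_de(expr, [0, 1, 2], [2, 3, 4], loose_params())

    def test_bonferroni_family_is_all_genes(self, rng):
        # the family is every gene in the matrix, not just the genes that
        # survive the pre-filters (the filter selects extreme fold changes,
        # so a tested-genes family would be anti-conservative)
        x = rng.gamma(2.0, 1.0, size=(40, 60))
        expr = make_expr(x)
        out = wilcoxon_de(expr, np.arange(30), np.arange(30, 60),
                          loose_params(min_abs_log_fc=0.1))
        assert len(out) < 40  # the filter did remove something
        assert np.allclose(
            out["p_adjusted"], np.minimum(out["p_raw"] * 40, 1.0)
        )

    def test_vectorized_asymptotic_matches_scipy_loop(self, rng):
        import scipy.stats

        x1 = rng.gamma(2.0, 1.0, size=(12, 40))
        x2 = rng.gamma(2.2, 1.0, size=(12, 35))
        p = rank_sum_p(x1, x2)
        for i in range(12):
            ref = scipy.stats.mannwhitneyu(
                x1[i], x2[i], alternative="two-sided", method="asymptotic"
            ).pvalue
            assert p[i] == pytest.approx(ref, rel=1e-12)


class TestConservedMarkers:
    def _dataset(self, marker_value=5.0):
        rng = np.random.default_rng(21)
        cells, rows = [], []
        blocks = []
        for tp in ("t0", "t1"):
            for cond in ("control", "perturbed"):
                for ct, n in (("X", 15), ("Y", 15)):
                    x = rng.gamma(1.0, 0.5, size=(20, n))
                    if ct == "X":
                        x[0] = marker_value  # gene g0 marks cluster X everywhere
                    blocks.append(x)
                    for j in range(n):
                        cid = f"{tp}_{cond}_{ct}_{j}"
                        cells.append(cid)
                        rows.append(
                            dict(cell_id=cid, sample_id="s", tissue="ti", timepoint=tp,
                                 condition=cond, batch="b0", cell_type=ct)
                        )
        expr = make_expr(np.concatenate(blocks, axis=1), cell_ids=cells)
        annot = pd.DataFrame(rows).set_index("cell_id")
        return expr, annot

    def test_planted_marker_found(self):
        expr, annot = self._dataset()
        table = conserved_markers(expr, annot, "X", DEGParams())
        assert "g0" in set(table["gene"])
        assert table.set_index("gene").loc["g0", "meta_p_adjusted"] < 0.05

    def test_uninformative_gene_not_emitted(self):
        expr, annot = self._dataset(marker_value=5.0)
        table = conserved_markers(expr, annot, "Y", DEGParams())
        assert "g1" not in set(table["gene"])

    def test_single_stratum_rejected(self):
        expr, annot = self._dataset()
        annot = annot[annot["timepoint"] == "t0"]
        annot = annot[annot["condition"] == "control"]
        expr_sub = make_expr(
            expr.dense(cell_cols=expr.cell_index(list(annot.index))),
            cell_ids=list(annot.index),
        )
        with pytest.raises(ScshiftError, match="strata"):
            conserved_markers(expr_sub, annot, "X", DEGParams())


def deg_table(rows):
    return pd.DataFrame(rows, columns=["gene", "log_fc", "p_adjusted"])


class TestReversedGenes:
    A = deg_table([
        ("up_rev", 0.5, 0.001),     # reversed: significant both, opposite signs
        ("down_rev", -0.8, 0.01),   # reversed the other way
        ("same_sign", 0.5, 0.001),  # both positive -> not reversed
        ("only_a", 0.9, 0.001),     # significant only in A
        ("ns_b", 0.6, 0.001),       # not significant in B
    ])
    B = deg_table([
        ("up_rev", -0.4, 0.01),
        ("down_rev", 0.3, 0.02),
        ("same_sign", 0.7, 0.001),
        ("ns_b", -0.6, 0.20),
        ("only_b", -0.5, 0.001),
    ])

    def test_exact_reversal_set(self):
        out = reversed_genes(self.A, self.B, alpha=0.05)
        assert sorted(out["gene"]) == ["down_rev", "up_rev"]
        rec = out.set_index("gene").loc["up_rev"]
        assert rec["log_fc_perturbation"] == 0.5 and rec["log_fc_treatment"] == -0.4

    def test_symmetric_as_gene_set(self):
        ab = set(reversed_genes(self.A, self.B)["gene"])
        ba = set(reversed_genes(self.B, self.A)["gene"])
        assert ab == ba


class TestFisherEnrichment:
    def test_zero_overlap_p_one(self):
        uni = [f"g{i}" for i in range(50)]
        out = fisher_enrichment(uni[:5], {"s": uni[10:20]}, uni)
        assert out.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_hypergeometric_tail_oracle(self):
        from scipy.stats import hypergeom

        uni = [f"g{i}" for i in range(100)]
        query = uni[:2] + uni[20:28]  # 10 genes, 8 inside the set
        sets = {"s": uni[20:40]}  # 20 genes
        out = fisher_enrichment(query, sets, uni)
        oracle = sum(hypergeom.pmf(k, 100, 20, 10) for k in range(8, 11))
        assert out.loc[0, "overlap"] == 8
        assert out.loc[0, "p_raw"] == pytest.approx(oracle, rel=1e-10)

    def test_degenerate_full_overlap(self):
        uni = [f"g{i}" for i in range(10)]
        out = fisher_enrichment(uni, {"s": uni}, uni)
        assert out.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ScshiftError):
            fisher_enrichment(["a"], {"s": ["a"]}, [])

    def test_bh_fdr_monotone_after_sort(self, rng):
        uni = [f"g{i}" for i in range(200)]
        sets = {
            f"s{j}": list(rng.choice(uni, size=20, replace=False)) for j in range(15)
        }
        out = fisher_enrichment(list(rng.choice(uni, 30, replace=False)), sets, uni)
        sorted_fdr = out.sort_values("p_raw")["fdr"].to_numpy()
        assert np.all(np.diff(sorted_fdr) >= -1e-12)
        assert np.all(out["fdr"] >= out["p_raw"] - 1e-12)
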