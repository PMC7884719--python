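"""Tests for directional ranking, tier counting and portrait assembly."""

import numpy as np
import pandas as pd
import pytest

from portraitforge import (
    DGETable,
    assemble_rank_matrix,
    build_portrait,
    default_weights,
    portrait_score,
    rank_directional,
    tier_counts,
)
from portraitforge.portrait import TierCounts

from conftest import TOY_TIERS, make_table, portrait_scores_oracle


class TestRankDirectional:
    def test_three_gene_closed_form(self):
        t = make_table("s", [("a", 6.0), ("b", 2.0), ("c", -3.0)])
        up = rank_directional(t, "up")
        down = rank_directional(t, "down")
        assert list(up) == [1, 2, 3]
        assert list(down) == [3, 2, 1]

    def test_single_gene_rank_one_both_ways(self):
        t = make_table("s", [("solo", -1.5)])
        assert rank_directional(t, "up").iloc[0] == 1
        assert rank_directional(t, "down").iloc[0] == 1

    def test_zero_scores_rank_last_in_both_directions(self):
        t = make_table("s", [("z", 0.0), ("u", 1.0), ("d", -1.0)])
        up = rank_directional(t, "up")
        down = rank_directional(t, "down")
        assert up["z"] == 3 and down["z"] == 3
        assert up["u"] == 1 and down["d"] == 1

    def test_matches_argsort_oracle(self, rng):
        scores = rng.normal(size=50)
        t = make_table("s", [(f"g{i:02d}", s) for i, s in enumerate(scores)])
        up = rank_directional(t, "up")
        # independent oracle: stable argsort of negated scores
        order = np.argsort(-scores, kind="stable")
        expected = np.empty(50, dtype=int)
        expected[order] = np.arange(1, 51)
        np.testing.assert_array_equal(up.to_numpy(), expected)

    def test_empty_table_rejected(self):
        t = make_table("s", [("a", 1.0)])
        t.data = t.data.iloc[0:0]
        with pytest.raises(ValueError):
            rank_directional(t, "up")


class TestAssembleRankMatrix:
    def three_tables(self, gene_in=2):
        """3 tables over {A,B,C,D}; gene X present in `gene_in` of them."""
        base = [("A", 3.0), ("B", -2.0), ("C", 1.0), ("D", -0.5)]
        tables = [make_table(f"s{i}", list(base)) for i in range(3)]
        for i in range(gene_in):
            tables[i].data = pd.concat(
                [tables[i].data, pd.DataFrame({"symbol": ["X"], "signed_score": [2.5]})],
                ignore_index=True,
            ).assign(p=np.nan, direction=lambda d: np.sign(d["signed_score"]).astype(int))
        return tables

    def test_boundary_one_third_missing_retained(self):
        rm = assemble_rank_matrix(self.three_tables(gene_in=2))
        assert "X" in rm.genes  # missing fraction exactly 1/3: kept

    def test_more_than_one_third_missing_dropped(self):
        rm = assemble_rank_matrix(self.three_tables(gene_in=1))
        assert "X" not in rm.genes

    def test_imputed_cells_carry_midpoint(self):
        rm = assemble_rank_matrix(self.three_tables(gene_in=2))
        g = rm.genes.index("X")
        j = rm.dataset_ids.index("s2")
        assert rm.missing_mask[g, j]
        assert rm.up_ranks[g, j] == rm.midpoint == rm.down_ranks[g, j]

    def test_nonmissing_columns_are_permutations(self, oracle_set):
        rm = assemble_rank_matrix(oracle_set)
        for j in range(rm.n_datasets):
            obs = ~rm.missing_mask[:, j]
            m = int(obs.sum())
            assert sorted(rm.up_ranks[obs, j]) == list(range(1, m + 1))
            assert sorted(rm.down_ranks[obs, j]) == list(range(1, m + 1))

    def test_fewer_than_two_tables_rejected(self):
        with pytest.raises(ValueError):
            assemble_rank_matrix([make_table("s", [("A", 1.0)])])

    def test_duplicate_symbols_rejected(self):
        bad = make_table("s0", [("A", 1.0), ("A", 2.0)])
        ok = make_table("s1", [("A", 1.0)])
        with pytest.raises(ValueError, match="duplicate"):
            assemble_rank_matrix([bad, ok])

    def test_missingness_oracle_recount(self, rng):
        # 4 studies x 100 genes, ~10% missing cells: per-gene presence
        # counts agree with a brute-force dict recount
        genes = [f"g{i:03d}" for i in range(100)]
        tables = []
        presence = {g: 0 for g in genes}
        for s in range(4):
            keep = rng.uniform(size=100) >= 0.1
            rows = [
                (g, float(sc))
                for g, k, sc in zip(genes, keep, rng.normal(size=100))
                if k
            ]
            for g, _ in rows:
                presence[g] += 1
            tables.append(make_table(f"s{s}", rows))
        rm = assemble_rank_matrix(tables)
        expected = sorted(g for g, c in presence.items() if 4 - c <= 4 / 3)
        assert rm.genes == expected
        got_counts = (~rm.missing_mask).sum(axis=1)
        np.testing.assert_array_equal(
            got_counts, [presence[g] for g in rm.genes]
        )


class TestTierCounts:
    def test_worked_example_counts(self):
        # a gene inside the top tier upregulated in 13 studies and never
        # downregulated scores U=13, D=0 there
        rm_like = TierCounts
        U = np.zeros((1, 8), dtype=int)
        D = np.zeros((1, 8), dtype=int)
        U[0, :] = 13
        tc = TierCounts(genes=["RPS23"], tiers=TOY_TIERS, U=U, D=D, n_datasets=29)
        assert tc.U[0, 0] == 13 and tc.D[0, 0] == 0

    def test_cumulative_monotone_and_bounded(self, oracle_set):
        rm = assemble_rank_matrix(oracle_set)
        tc = tier_counts(rm, TOY_TIERS)
        assert (np.diff(tc.U, axis=1) >= 0).all()
        assert (np.diff(tc.D, axis=1) >= 0).all()
        assert tc.U.min() >= 0 and tc.U.max() <= rm.n_datasets
        assert tc.D.min() >= 0 and tc.D.max() <= rm.n_datasets

    def test_gene_always_inside_first_tier(self):
        t1 = make_table("a", [("hit", 9.0), ("x", 1.0), ("y", -1.0)])
        t2 = make_table("b", [("hit", 8.0), ("x", 0.5), ("y", -2.0)])
        rm = assemble_rank_matrix([t1, t2])
        with pytest.warns(UserWarning):
            tc = tier_counts(rm, (1, 2, 3))
        g = tc.genes.index("hit")
        assert (tc.U[g] == 2).all()  # rank 1 in both studies, all tiers

    def test_exhaustive_double_loop_oracle(self, rng):
        tables = [
            make_table(
                f"s{j}", [(f"g{i:02d}", float(v)) for i, v in enumerate(rng.normal(size=30))]
            )
            for j in range(10)
        ]
        rm = assemble_rank_matrix(tables)
        tc = tier_counts(rm, (5, 10, 15))
        for g in range(rm.n_genes):
            for k, cut in enumerate((5, 10, 15)):
                u = sum(
                    1 for j in range(10) if rm.up_ranks[g, j] <= cut
                )
                d = sum(
                    1 for j in range(10) if rm.down_ranks[g, j] <= cut
                )
                assert tc.U[g, k] == u and tc.D[g, k] == d

    def test_non_increasing_tiers_rejected(self, oracle_set):
        rm = assemble_rank_matrix(oracle_set)
        with pytest.raises(ValueError):
            tier_counts(rm, (10, 10, 20))


class TestPortraitScore:
    def tc(self, U_row, D_row):
        return TierCounts(
            genes=["g"],
            tiers=tuple(range(1, len(U_row) + 1)),
            U=np.array([U_row]),
            D=np.array([D_row]),
            n_datasets=29,
        )

    def test_tier1_worked_examples(self):
        # starting scores of the two canonical genes: 13 up / 0 down -> 13.0
        # and 0 up / 16 down -> -16.0
        up13 = self.tc([13] + [13] * 7, [0] * 8)
        assert portrait_score(self.tc([13, 0, 0, 0, 0, 0, 0, 0], [0] * 8)).iloc[0] == 13.0
        assert (
            portrait_score(self.tc([0] * 8, [16, 0, 0, 0, 0, 0, 0, 0])).iloc[0]
            == -16.0
        )

    def test_full_tier_hand_summation(self):
        U = [2, 3, 3, 4, 4, 4, 4, 4]
        D = [0, 0, 1, 1, 1, 1, 1, 2]
        got = portrait_score(self.tc(U, D)).iloc[0]
        # spreadsheet-style oracle: explicit term-by-term sum
        expected = sum(0.1**k * (u - d) for k, (u, d) in enumerate(zip(U, D)))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_cancellation(self):
        tc = self.tc([5, 5, 5, 5, 5, 5, 5, 5], [5, 5, 5, 5, 5, 5, 5, 5])
        assert portrait_score(tc).iloc[0] == 0.0

    def test_weight_length_mismatch(self):
        with pytest.raises(ValueError):
            portrait_score(self.tc([1] * 8, [0] * 8), weights=[1.0, 0.1])


class TestBuildPortrait:
    def test_identical_pair_self_consistency(self):
        rows = [(f"g{i}", s) for i, s in enumerate([5.0, -4.0, 3.0, -2.0, 1.0, -0.5])]
        t1 = make_table("a", rows)
        t2 = make_table("b", rows)
        p = build_portrait([t1, t2], tiers=(1, 2, 3))
        # shared |signed_score| ordering is reproduced
        assert list(p.entries["symbol"]) == [r[0] for r in rows]
        assert (np.sign(p.entries["score"]) == [1, -1, 1, -1, 1, -1]).all()

    def test_sign_flip_antisymmetry(self, planted_set):
        _, tables, _ = planted_set
        p = build_portrait(tables, tiers=TOY_TIERS)
        flipped = []
        for t in tables:
            ft = t.copy()
            ft.data["signed_score"] = -ft.data["signed_score"]
            ft.data["direction"] = -ft.data["direction"]
            flipped.append(ft)
        pf_ = build_portrait(flipped, tiers=TOY_TIERS)
        assert list(p.entries["symbol"]) == list(pf_.entries["symbol"])
        np.testing.assert_allclose(
            pf_.entries["score"], -p.entries["score"], rtol=0, atol=0
        )

    def test_dataset_order_invariance(self, planted_set):
        _, tables, _ = planted_set
        p1 = build_portrait(tables, tiers=TOY_TIERS)
        p2 = build_portrait(list(reversed(tables)), tiers=TOY_TIERS)
        pd.testing.assert_frame_equal(p1.entries, p2.entries)

    def test_boundedness(self, planted_set):
        _, tables, _ = planted_set
        p = build_portrait(tables, tiers=TOY_TIERS)
        bound = len(tables) * default_weights(len(TOY_TIERS)).sum()
        assert p.entries["score"].abs().max() <= bound + 1e-12

    def test_triple_loop_oracle_equivalence(self, oracle_set):
        p = build_portrait(oracle_set, tiers=TOY_TIERS)
        expected = portrait_scores_oracle(list(oracle_set), TOY_TIERS)
        got = dict(zip(p.entries["symbol"], p.entries["score"]))
        assert set(got) == set(expected)
        for g in expected:
            assert got[g] == expected[g], g

    def test_planted_consistent_genes_dominate(self, planted_set):
        _, tables, truth = planted_set
        p = build_portrait(tables, tiers=TOY_TIERS)
        consistent = set(truth.loc[truth["class"] == "consistent", "symbol"])
        top = set(p.entries.head(len(consistent))["symbol"])
        # strong signal, low noise: the vast majority of the planted
        # consistent genes occupy the top of the portrait
        assert len(top & consistent) / len(consistent) >= 0.8

    def test_provenance_recorded(self, oracle_set):
        p = build_portrait(oracle_set, tiers=TOY_TIERS)
        assert p.provenance["tiers"] == list(TOY_TIERS)
        assert p.provenance["dataset_ids"] == [t.study_id for t in oracle_set]
        assert p.provenance["n_genes_retained"] == len(p)
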