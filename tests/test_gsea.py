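"""Enrichment walk, permutation null, NES/FDR, and GMT handling."""

import numpy as np
import pandas as pd
import pytest

from conftest import walk_oracle
from cpegx.association import ExpressionMatrix, gene_cpe_ranking
from cpegx.gsea import (
    GeneSetCollection, enrichment_score, leading_edge_fraction,
    permutation_null, normalize_and_fdr, gsea, _member_walk_extremum,
    _set_weights,
)


def _ranked_from_stats(stats):
    """A RankedGeneList whose gene g{i} carries statistic stats[i], already
    in descending order."""
    stats = np.asarray(stats, dtype=float)
    assert np.all(np.diff(stats) <= 0)
    table = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(stats.size)],
        "slope": stats, "se": np.ones_like(stats), "t": stats,
        "zero_variance": False,
    })
    table["rank"] = np.arange(1, stats.size + 1)
    from cpegx.association import RankedGeneList
    return RankedGeneList(table)


class TestGmt:
    def test_round_trip(self, tmp_path):
        c = GeneSetCollection({"A": ["g1", "g2", "g3"], "B": ["g2", "g4", "g5"]},
                              {"A": "first", "B": ""})
        path = tmp_path / "sets.gmt"
        c.write_gmt(path)
        back = GeneSetCollection.read_gmt(path)
        assert back.sets == c.sets
        assert back.descriptions["A"] == "first"

    def test_malformed_and_duplicates(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("ONLYNAME\tdesc\n")
        with pytest.raises(ValueError, match="malformed"):
            GeneSetCollection.read_gmt(path)
        with pytest.raises(ValueError, match="duplicate members"):
            GeneSetCollection({"A": ["g1", "g1"]})

    def test_size_filter(self):
        c = GeneSetCollection({"small": ["g1"], "ok": [f"g{i}" for i in range(6)],
                               "alien": ["x1", "x2", "x3", "x4", "x5"]})
        kept = c.filtered([f"g{i}" for i in range(10)], min_size=5)
        assert list(kept.sets) == ["ok"]


class TestEnrichmentScore:
    def test_top_k_set_is_perfect_front_loading(self):
        ranked = _ranked_from_stats(np.linspace(5, -5, 20))
        res = enrichment_score(ranked, [f"g{i}" for i in range(5)],
                               weight_exponent=0.0)
        assert res.es == pytest.approx(1.0, abs=1e-12)
        assert res.max_es_at == 5
        assert leading_edge_fraction(res) == 1.0

    def test_bottom_set_negative_es(self):
        ranked = _ranked_from_stats(np.linspace(5, -5, 20))
        res = enrichment_score(ranked, [f"g{i}" for i in range(15, 20)],
                               weight_exponent=0.0)
        assert res.es < 0
        assert leading_edge_fraction(res) == 1.0

    def test_hand_case_positions_1_4_8(self):
        ranked = _ranked_from_stats(np.linspace(3, -3, 10))
        members = ["g0", "g3", "g7"]  # 1-based positions 1, 4, 8
        walk, es, pos, le = walk_oracle(ranked.statistics,
                                        [g in members for g in ranked.gene_ids],
                                        p=0)
        res = enrichment_score(ranked, members, weight_exponent=0.0, min_size=3)
        assert res.es == pytest.approx(es, abs=1e-12)
        assert res.max_es_at == pos
        assert leading_edge_fraction(res) == pytest.approx(le, abs=1e-12)
        assert np.allclose(res.walk, walk, atol=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, 2.0])
    def test_matches_loop_oracle_random_instances(self, p):
        rng = np.random.default_rng(int(p * 7 + 1))
        for _ in range(25):
            n = rng.integers(10, 51)
            stats = -np.sort(-rng.normal(size=n))
            ranked = _ranked_from_stats(stats)
            k = rng.integers(3, max(4, n // 3))
            members = [f"g{i}" for i in rng.choice(n, size=k, replace=False)]
            mask = [g in set(members) for g in ranked.gene_ids]
            _, es, pos, le = walk_oracle(stats, mask, p)
            res = enrichment_score(ranked, members, weight_exponent=p, min_size=1)
            assert res.es == pytest.approx(es, abs=1e-12)
            assert res.max_es_at == pos
            assert leading_edge_fraction(res) == pytest.approx(le, abs=1e-12)

    def test_fast_path_matches_full_walk(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            stats = -np.sort(-rng.normal(size=n))
            ranked = _ranked_from_stats(stats)
            k = int(rng.integers(2, n // 2))
            members = [f"g{i}" for i in rng.choice(n, size=k, replace=False)]
            res = enrichment_score(ranked, members, weight_exponent=1.0, min_size=1)
            positions = res.member_positions
            w = _set_weights(np.abs(stats), positions, 1.0)
            es_fast, pos_fast = _member_walk_extremum(positions, w, n)
            assert es_fast == pytest.approx(res.es, abs=1e-12)
            assert pos_fast == res.max_es_at

    def test_walk_bounds_and_closure(self):
        rng = np.random.default_rng(12)
        stats = -np.sort(-rng.normal(size=30))
        ranked = _ranked_from_stats(stats)
        res = enrichment_score(ranked, [f"g{i}" for i in (2, 9, 15, 22, 28)],
                               weight_exponent=1.0)
        assert -1.0 <= res.es <= 1.0
        assert abs(res.walk[-1]) < 1e-12

    def test_reversal_maps_es_and_position(self):
        rng = np.random.default_rng(13)
        stats = -np.sort(-rng.normal(size=25))
        members = [f"g{i}" for i in (1, 5, 6, 14, 20)]
        ranked = _ranked_from_stats(stats)
        res = enrichment_score(ranked, members, weight_exponent=0.0)
        # reverse the ranking: member at position r moves to N - r + 1
        rev_stats = -stats[::-1]
        rev_ids = [f"g{i}" for i in range(24, -1, -1)]
        table = pd.DataFrame({"gene_id": rev_ids, "slope": rev_stats,
                              "se": 1.0, "t": rev_stats, "zero_variance": False})
        table["rank"] = np.arange(1, 26)
        from cpegx.association import RankedGeneList
        res_rev = enrichment_score(RankedGeneList(table), members,
                                   weight_exponent=0.0)
        assert res_rev.es == pytest.approx(-res.es, abs=1e-12)
        # a peak just after a member maps to a valley just before the
        # mirrored member: position N - pos
        assert res_rev.max_es_at == 25 - res.max_es_at

    def test_single_member_leading_edge_is_one(self):
        ranked = _ranked_from_stats(np.linspace(2, -2, 12))
        res = enrichment_score(ranked, ["g5"], weight_exponent=0.0, min_size=1)
        assert leading_edge_fraction(res) == 1.0

    def test_errors(self):
        ranked = _ranked_from_stats(np.linspace(2, -2, 12))
        with pytest.raises(ValueError, match="no members"):
            enrichment_score(ranked, ["zz"])
        with pytest.raises(ValueError, match="min_size"):
            enrichment_score(ranked, ["g0", "g1"], min_size=5)
        with pytest.raises(ValueError, match="universe"):
            enrichment_score(ranked, [f"g{i}" for i in range(12)], min_size=1)
        zero = _ranked_from_stats(np.zeros(12))
        with pytest.raises(ValueError, match="weights"):
            enrichment_score(zero, ["g0", "g1", "g2", "g3", "g4"],
                             weight_exponent=1.0)


class TestPermutationNull:
    def _toy(self, seed=0, n_genes=30, n=20):
        rng = np.random.default_rng(seed)
        expr = ExpressionMatrix(
            tuple(f"g{i}" for i in range(n_genes)),
            tuple(f"s{j}" for j in range(n)),
            rng.normal(size=(n_genes, n)), kind="continuous")
        return expr, rng.normal(size=n)

    def test_seeded_determinism(self):
        expr, cpe = self._toy()
        coll = GeneSetCollection({"A": ["g1", "g3", "g5", "g7", "g9"]})
        a = permutation_null(expr, cpe, coll, n_perm=60, seed=5)
        b = permutation_null(expr, cpe, coll, n_perm=60, seed=5)
        assert np.array_equal(a, b)

    def test_small_n_perm_warns(self):
        expr, cpe = self._toy()
        coll = GeneSetCollection({"A": ["g1", "g3", "g5", "g7", "g9"]})
        with pytest.warns(UserWarning, match="coarse"):
            permutation_null(expr, cpe, coll, n_perm=49, seed=1)

    def test_null_covers_observed_es_on_null_data(self):
        # with no planted effect the observed ES behaves like a null draw
        expr, cpe = self._toy(seed=3, n_genes=60, n=30)
        rng = np.random.default_rng(9)
        sets = {f"S{j}": [f"g{i}" for i in rng.choice(60, 8, replace=False)]
                for j in range(20)}
        coll = GeneSetCollection(sets)
        ranked = gene_cpe_ranking(expr, cpe)
        null = permutation_null(expr, cpe, coll, n_perm=200, seed=7)
        inside = 0
        for row, (name, members) in zip(null, coll.sets.items()):
            es = enrichment_score(ranked, members, min_size=1).es
            lo, hi = np.percentile(row, [2.5, 97.5])
            inside += lo <= es <= hi
        assert inside >= 16  # ~95% of 20, allowing sampling slack


class TestNormalizeAndFdr:
    def test_nes_identity_when_es_equals_null_mean(self):
        null = np.array([[0.2, 0.4, -0.3, -0.1]])
        obs = [{"set_name": "A", "size": 5, "es": 0.3, "max_es_at": 3,
                "leading_edge": 0.6}]
        res = normalize_and_fdr(obs, null)[0]
        assert res.nes == pytest.approx(1.0)

    def test_extreme_set_gets_zero_p_and_q(self):
        rng = np.random.default_rng(0)
        null = np.abs(rng.normal(0.2, 0.05, size=(2, 100)))
        obs = [{"set_name": "big", "size": 5, "es": 5.0, "max_es_at": 1,
                "leading_edge": 1.0},
               {"set_name": "meh", "size": 5, "es": 0.2, "max_es_at": 9,
                "leading_edge": 0.4}]
        res = normalize_and_fdr(obs, null)
        big = next(r for r in res if r.set_name == "big")
        assert big.p_perm == 0.0
        assert big.fdr_q == 0.0

    def test_no_signed_null_flags_undefined(self):
        null = np.array([[0.1, 0.2, 0.3]])  # no negative null values
        obs = [{"set_name": "A", "size": 5, "es": -0.4, "max_es_at": 3,
                "leading_edge": 0.5}]
        res = normalize_and_fdr(obs, null)[0]
        assert not res.nes_defined
        assert np.isnan(res.nes)

    def test_fdr_within_unit_interval(self):
        rng = np.random.default_rng(1)
        null = rng.normal(0, 0.3, size=(10, 200))
        obs = [{"set_name": f"S{i}", "size": 6, "es": float(e), "max_es_at": 4,
                "leading_edge": 0.5}
               for i, e in enumerate(rng.normal(0, 0.4, size=10))]
        for r in normalize_and_fdr(obs, null):
            if r.nes_defined:
                assert 0.0 <= r.fdr_q <= 1.0
                assert np.sign(r.nes) == np.sign(r.es) or r.es == 0


class TestGseaScreen:
    def test_planted_set_leads_screen(self, small_cohort):
        from cpegx.association import log_cpm
        expr = log_cpm(small_cohort.expression)
        table = gsea(expr, small_cohort.cpe_z, small_cohort.collection,
                     n_perm=100, seed=1)
        best = table.loc[table["nes"].abs().idxmax()]
        assert best["set_name"] == small_cohort.planted_set_name
        assert best["fdr_q"] < 0.25
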