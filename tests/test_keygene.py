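import numpy as np
import pytest

from redoxmir.keygene import (
    ExpressionProfile, classify_coupling, couple, end_to_end_keygenes,
    enrich_terms, pearson_r, rank_targets,
)
from oracles import fisher_greater_exact


def _prof(eid, values, organ="root"):
    return ExpressionProfile(entity_id=eid, organ=organ, values=tuple(values))


class TestPearson:
    def test_affine_maps(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_known_value(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_is_indeterminate_not_a_number(self):
        assert pearson_r([1, 1, 1, 1], [1, 2, 3, 4]) is None

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [3, 4])

    def test_affine_invariance_random(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            r = pearson_r(x, y)
            assert pearson_r(3 * x + 2, y) == pytest.approx(r, abs=1e-9)
            assert pearson_r(-2 * x + 1, y) == pytest.approx(-r, abs=1e-9)


class TestClassifyCoupling:
    @pytest.mark.parametrize("r,klass", [
        (-0.9, "inverse"), (-0.27, "inverse"), (-0.25, "inverse"),
        (-0.24, "indeterminate"), (0.0, "indeterminate"), (0.24, "indeterminate"),
        (0.25, "decoupled"), (0.95, "decoupled"), (None, "indeterminate"),
    ])
    def test_thresholds(self, r, klass):
        assert classify_coupling(r) == klass


class TestRankTargets:
    def test_key_gene_rule_and_ranking(self):
        profiles = [
            _prof("strong", (1, 0.5, 4, 1)),   # delta 3, NaCl+TU/NaCl fold 8
            _prof("flat", (1, 1, 1, 1)),       # delta 0
            _prof("nacl_only", (1, 3, 3, 3)),  # delta 0, fold 1
        ]
        reports = {r.target_id: r for r in rank_targets(profiles)}
        assert reports["strong"].rank == 1 and reports["strong"].key_gene
        assert reports["strong"].delta_tu == pytest.approx(3.0)
        assert reports["strong"].fold_nacl_vs_nacltu == pytest.approx(8.0)
        assert not reports["flat"].key_gene
        assert not reports["nacl_only"].key_gene

    def test_fold_without_positive_delta_is_not_key(self):
        (r,) = rank_targets([_prof("x", (1, 4, 1, 1))])  # fold 4 but delta 0
        assert not r.key_gene

    def test_ranks_are_total_order_with_id_ties(self):
        profiles = [_prof(f"g{i}", (1, 1, 1 + (i % 3), 1)) for i in range(9)]
        ranks = rank_targets(profiles)
        assert sorted(r.rank for r in ranks) == list(range(1, 10))
        tied = [r.target_id for r in ranks if r.delta_tu == 2]
        assert tied == sorted(tied)

    def test_dominated_profile_does_not_reorder_others(self):
        base = [_prof("a", (1, 1, 3, 1)), _prof("b", (1, 1, 2, 1))]
        with_dom = base + [_prof("z", (1, 1, 0.1, 1))]
        order_base = [r.target_id for r in rank_targets(base)]
        order_dom = [r.target_id for r in rank_targets(with_dom) if r.target_id != "z"]
        assert order_base == order_dom


class TestCouple:
    def test_inverse_and_decoupled_classes(self):
        m = {"mi1": _prof("mi1", (1, 2, 0.5, 1)), "mi2": _prof("mi2", (1, 2, 0.5, 1))}
        t = {
            "tx1": _prof("tx1", (2, 1, 2.5, 2)),   # decreasing in mi1
            "tx2": _prof("tx2", (1, 1.5, 0.75, 1)),  # increasing with mi2
        }
        recs = {c.mirna_id: c for c in couple(m, t, {"mi1": "tx1", "mi2": "tx2"})}
        assert recs["mi1"].klass == "inverse" and recs["mi1"].r < -0.9
        assert recs["mi2"].klass == "decoupled" and recs["mi2"].r > 0.9


class TestEnrichTerms:
    def test_exclusive_term_enriched(self):
        universe = {f"g{i}" for i in range(30)}
        selected = {f"g{i}" for i in range(5)}
        term_map = {g: {"stress"} if g in selected else {"other"} for g in universe}
        hits = enrich_terms(selected, universe, term_map)
        assert [t for t, _, _ in hits] == ["stress"]

    def test_proportional_term_not_enriched(self):
        universe = {f"g{i}" for i in range(40)}
        term_map = {g: {"common"} for g in universe}
        assert enrich_terms({f"g{i}" for i in range(10)}, universe, term_map) == []

    def test_p_matches_hypergeometric_oracle_and_bonferroni(self):
        # 8 of 10 selected have the term; 10 of 90 others do
        universe = {f"g{i}" for i in range(100)}
        selected = {f"g{i}" for i in range(10)}
        with_term = {f"g{i}" for i in range(8)} | {f"g{i}" for i in range(50, 60)}
        term_map = {g: ({"T"} if g in with_term else set()) | {"bg"} for g in universe}
        hits = enrich_terms(selected, universe, term_map, alpha=0.05)
        (term, p_raw, p_corr) = [h for h in hits if h[0] == "T"][0]
        expected = fisher_greater_exact(8, 2, 10, 80)
        assert p_raw == pytest.approx(expected, abs=1e-10)
        assert p_corr == pytest.approx(min(1.0, expected * 2), abs=1e-10)

    def test_empty_universe_and_bad_subset_rejected(self):
        with pytest.raises(ValueError):
            enrich_terms(set(), set(), {})
        with pytest.raises(ValueError):
            enrich_terms({"x"}, {"y"}, {})


class TestEndToEnd:
    def test_key_gene_recovered_and_decoupled_never_blocks(self):
        m = {
            "mi_key": _prof("mi_key", (1, 1.5, 0.2, 2.0)),
            "mi_dec": _prof("mi_dec", (1, 2, 1.5, 1)),
        }
        t = {
            "tx_key": _prof("tx_key", (1, 0.67, 1.53, 0.33)),
            "tx_dec": _prof("tx_dec", (1, 1.2, 1.1, 1)),
        }
        out = end_to_end_keygenes(
            {"mi_key", "mi_dec"}, {"mi_key": "tx_key", "mi_dec": "tx_dec"}, m, t
        )
        assert out["key_genes"] == {"tx_key"}
        ranking = {r.target_id: r for r in out["ranking"]}
        assert ranking["tx_key"].rank == 1
        classes = {c.mirna_id: c.klass for c in out["couplings"]}
        assert classes["mi_key"] == "inverse"
        assert classes["mi_dec"] == "decoupled"
        assert "tx_dec" in ranking  # decoupled pairs still ranked

    def test_missing_profile_excluded_not_fatal(self):
        m = {"mi1": _prof("mi1", (1, 2, 0.5, 1))}
        out = end_to_end_keygenes({"mi1"}, {"mi1": "tx_gone"}, m, {})
        assert out["couplings"] == [] and out["ranking"] == []
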