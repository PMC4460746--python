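"""Cross-locus prediction rules, checked against brute-force oracles."""

import itertools

import pytest

from gwas2drug.gene_prediction import (
    AnnotationTable,
    combine_predictions,
    predict_cmp,
    predict_cps,
    predict_crt,
    predict_mir,
    predict_ppi,
)

from conftest import make_space


def table(kind, *pairs):
    return AnnotationTable.from_pairs(kind, pairs)


def genes_of(predictions):
    return {p.gene for p in predictions}


class TestCps:
    def test_cross_locus_pathway_predicts_both(self):
        space = make_space({"L1": ["geneA"], "L2": ["geneB"]})
        preds = predict_cps(space, table("pathway", ("P", "geneA"), ("P", "geneB")))
        assert genes_of(preds) == {"geneA", "geneB"}

    def test_single_locus_sharing_never_predicts(self):
        space = make_space({"L1": ["a", "b", "c"]})
        preds = predict_cps(space, table("pathway", ("P", "a"), ("P", "b"), ("P", "c")))
        assert preds == set()

    def test_pathway_confined_to_one_locus(self):
        space = make_space({"L1": ["a", "b"], "L2": ["c"]})
        preds = predict_cps(space, table("pathway", ("P", "a"), ("P", "b")))
        assert preds == set()

    def test_empty_table_is_empty_result(self):
        assert predict_cps(make_space({"L1": ["a"]}), table("pathway")) == set()


class TestPpi:
    def test_cross_locus_edge_predicts_both_ends(self):
        space = make_space({"L1": ["a"], "L2": ["b"]})
        preds = predict_ppi(space, table("interaction", ("a", "b")))
        assert genes_of(preds) == {"a", "b"}

    def test_intra_locus_edge_predicts_neither(self):
        space = make_space({"L1": ["a", "c"], "L2": ["x"]})
        assert predict_ppi(space, table("interaction", ("a", "c"))) == set()

    def test_self_edge_ignored(self):
        space = make_space({"L1": ["a"], "L2": ["b"]})
        assert predict_ppi(space, table("interaction", ("a", "a"))) == set()

    def test_symmetry_of_stored_edges(self):
        space = make_space({"L1": ["a"], "L2": ["b"]})
        fwd = predict_ppi(space, table("interaction", ("a", "b")))
        rev = predict_ppi(space, table("interaction", ("b", "a")))
        assert fwd == rev


class TestCmp:
    @pytest.mark.parametrize(
        "gene_domains, seed_domains, tau, expected",
        [
            ({"D1", "D2"}, {"D1", "D2"}, 0.5, True),   # Jaccard 1.0
            ({"D1"}, {"D2", "D3"}, 0.5, False),        # Jaccard 0
            ({"D1", "D2", "D3", "D4", "D5"}, {"D1"}, 0.5, False),  # 1/5 < tau
        ],
    )
    def test_jaccard_threshold(self, gene_domains, seed_domains, tau, expected):
        space = make_space({"L1": ["g"]})
        pairs = [("g", d) for d in gene_domains] + [("s", d) for d in seed_domains]
        preds = predict_cmp(space, table("domain", *pairs), {"s"}, tau)
        assert (genes_of(preds) == {"g"}) is expected

    def test_empty_seed_set_gives_empty_result(self):
        space = make_space({"L1": ["g"]})
        assert predict_cmp(space, table("domain", ("g", "D1")), set(), 0.5) == set()

    def test_gene_without_domains_never_matches(self):
        space = make_space({"L1": ["g"]})
        preds = predict_cmp(space, table("domain", ("s", "D1")), {"s"}, 0.0)
        assert preds == set()


class TestCrt:
    def test_shared_tf_across_loci(self):
        space = make_space({"L1": ["a"], "L2": ["b"]})
        preds = predict_crt(space, table("tf_target", ("t", "a"), ("t", "b")))
        assert genes_of(preds) == {"a", "b"}

    def test_tf_confined_to_one_locus(self):
        space = make_space({"L1": ["a", "c"], "L2": ["x"]})
        assert predict_crt(space, table("tf_target", ("t", "a"), ("t", "c"))) == set()

    def test_empty_table(self):
        assert predict_crt(make_space({"L1": ["a"]}), table("tf_target")) == set()


class TestMir:
    def _space(self):
        return make_space({"L1": ["g"], "L2": ["h"]})

    def test_hub_and_shared_mirna_predicts(self):
        pairs = [("m0", "g"), ("m0", "h")] + [(f"m{i}", "g") for i in range(1, 6)]
        preds = predict_mir(self._space(), table("mirna_target", *pairs), hub_k=5)
        assert "g" in genes_of(preds)

    def test_below_hub_threshold_not_predicted(self):
        pairs = [("m0", "g"), ("m0", "h"), ("m1", "g")]
        preds = predict_mir(self._space(), table("mirna_target", *pairs), hub_k=5)
        assert "g" not in genes_of(preds)

    def test_no_cross_locus_sharing_not_predicted(self):
        pairs = [(f"m{i}", "g") for i in range(6)]
        assert predict_mir(self._space(), table("mirna_target", *pairs), hub_k=1) == set()


class TestCombine:
    def test_provenance_merged_per_gene(self):
        s1 = make_space({"L1": ["g"], "L2": ["x"]}, method="m1")
        s2 = make_space({"L3": ["g"], "L4": ["y"]}, method="m2")
        cps = predict_cps(s1, table("pathway", ("P", "g"), ("P", "x")))
        ppi = predict_ppi(s2, table("interaction", ("g", "y")))
        combined = combine_predictions([cps, ppi])
        rec = {p.gene: p for p in combined}["g"]
        assert rec.modules == {"CPS", "PPI"}
        assert ("WS", "m1") in rec.spaces and ("WS", "m2") in rec.spaces

    def test_all_empty_gives_empty(self):
        assert combine_predictions([set(), set()]) == set()

    def test_disjoint_results_sum(self):
        spaces = {m: make_space({"L1": [f"g{m}"], "L2": [f"h{m}"]}, method=m)
                  for m in "abcde"}
        sets = [
            predict_cps(spaces["a"], table("pathway", ("P", "ga"), ("P", "ha")))
        ]
        combined = combine_predictions(sets)
        assert len(combined) == 2 and all(len(p.modules) == 1 for p in combined)


def brute_force_cps(space, pathway_pairs):
    """Exhaustive oracle: enumerate (gene, locus, pathway, partner) tuples."""
    memb = space.locus_membership()
    predicted = set()
    pathways = {}
    for pw, g in pathway_pairs:
        pathways.setdefault(pw, set()).add(g)
    for g, loci in memb.items():
        for locus in loci:
            for members in pathways.values():
                if g not in members:
                    continue
                for h in members:
                    if h == g or h not in memb:
                        continue
                    if any(l2 != locus for l2 in memb[h]):
                        predicted.add(g)
    return predicted


class TestOracleAgreement:
    def test_cps_matches_bruteforce_on_random_instances(self, rng):
        genes = [f"g{i}" for i in range(12)]
        for _ in range(50):
            n_loci = int(rng.integers(1, 5))
            space = make_space({
                f"L{j}": [g for g in genes if rng.random() < 0.4]
                for j in range(n_loci)
            })
            pairs = [
                (f"P{int(rng.integers(0, 4))}", genes[int(rng.integers(0, 12))])
                for _ in range(int(rng.integers(0, 20)))
            ]
            expected = brute_force_cps(space, pairs)
            got = genes_of(predict_cps(space, table("pathway", *pairs)))
            assert got == expected

    def test_predictions_closed_over_space(self, rng):
        genes = [f"g{i}" for i in range(10)]
        space = make_space({"L1": genes[:3], "L2": genes[3:6]})
        pairs = [(f"P{i % 3}", g) for i, g in enumerate(genes)]
        for p in predict_cps(space, table("pathway", *pairs)):
            assert p.gene in space.gene_universe
            assert p.loci <= set(space.loci)


class TestMonotonicity:
    def test_adding_pairs_never_removes_predictions(self, rng):
        space = make_space({"L1": ["a", "b"], "L2": ["c", "d"]})
        base_pairs = [("P1", "a"), ("P1", "c")]
        base = genes_of(predict_cps(space, table("pathway", *base_pairs)))
        for extra in [("P1", "b"), ("P2", "b"), ("P2", "d"), ("P1", "d")]:
            more = genes_of(predict_cps(space, table("pathway", *base_pairs, extra)))
            assert base <= more

    def test_raising_tau_never_adds_predictions(self):
        space = make_space({"L1": ["g", "h"]})
        pairs = [("g", "D1"), ("g", "D2"), ("h", "D1"), ("s", "D1"), ("s", "D2")]
        prev = {"g", "h"}
        for tau in (0.0, 0.4, 0.6, 1.0):
            cur = genes_of(predict_cmp(space, table("domain", *pairs), {"s"}, tau))
            assert cur <= prev
            prev = cur

    def test_raising_hub_k_never_adds_predictions(self):
        space = make_space({"L1": ["g"], "L2": ["h"]})
        pairs = [("m0", "g"), ("m0", "h")] + [(f"m{i}", "g") for i in range(1, 4)]
        prev = None
        for hub_k in (1, 2, 4, 5):
            cur = genes_of(predict_mir(space, table("mirna_target", *pairs), hub_k))
            if prev is not None:
                assert cur <= prev
            prev = cur
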