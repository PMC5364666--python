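import random

import pytest

from orthobridge import (Proteome, SearchConfig, TaxonTree, bridge_search,
                         clade_summary, combine_profiles, consistency_check,
                         fraction_percent, reciprocal_best_hit)

from .conftest import family_universe, make_record, random_protein


def block_universe(seed=13, block=45, decoys=2):
    """Species a, b, c with overlapping-block proteins: a=X1X2, b=X2X3,
    c=X3X4.  Adjacent pairs share a full block (strong hits); a and c share
    nothing, so c is reachable from a only through b."""
    rng = random.Random(seed)
    x = [random_protein(rng, block) for _ in range(4)]
    uni = {}
    for sp, seq in (("a", x[0] + x[1]), ("b", x[1] + x[2]),
                    ("c", x[2] + x[3])):
        recs = [make_record(f"{sp}_fam", sp, seq)]
        recs += [make_record(f"{sp}_d{i}", sp, random_protein(rng, 2 * block))
                 for i in range(decoys)]
        uni[sp] = Proteome(species=sp, records=recs)
    return uni


CHAIN_TREE = TaxonTree.from_newick("((a:1,b:1)ab:1,c:2)root;", is_path=False)


def direct_rbh_present(seed_rec, universe, config):
    out = set()
    for sp in universe:
        if sp == seed_rec.species:
            continue
        if reciprocal_best_hit(seed_rec, universe[sp],
                               universe[seed_rec.species], config):
            out.add(sp)
    return out


def acceptance_edges(universe, members, config):
    """Oracle: the directed RBH-acceptance graph over true family members."""
    edges = {sp: [] for sp in universe}
    for s1 in universe:
        for s2 in universe:
            if s1 == s2 or members[s1] is None or members[s2] is None:
                continue
            call = reciprocal_best_hit(universe[s1].get(members[s1]),
                                       universe[s2], universe[s1], config)
            if call is not None:
                edges[s1].append(s2)
    return edges


class TestBridgeSearch:
    def test_direct_universe_equals_plain_rbh(self, relaxed_config):
        """When the seed reaches everything directly, bridging adds nothing
        and every chain has one link."""
        uni, _ = family_universe(3, ["a", "b", "c", "d"], divergence=15)
        tree = TaxonTree.from_newick("((a:1,b:1):1,(c:1,d:1):1)root;",
                                     is_path=False)
        seed = uni["a"].get("a_fam")
        profile = bridge_search(seed, uni, tree, relaxed_config, max_depth=4)
        assert set(profile.present_species()) == {"a", "b", "c", "d"}
        direct = direct_rbh_present(seed, uni, relaxed_config)
        assert direct == {"b", "c", "d"}
        for sp in direct:
            assert profile[sp].chain_length == 1

    def test_transitive_chain_through_intermediate(self, relaxed_config):
        """a–b–c block design: a↔c share nothing, so c is found with a
        two-link chain through b; matches the closure oracle."""
        uni = block_universe()
        seed = uni["a"].get("a_fam")
        assert direct_rbh_present(seed, uni, relaxed_config) == {"b"}
        profile = bridge_search(seed, uni, CHAIN_TREE, relaxed_config,
                                max_depth=3)
        assert profile["c"].status == "present"
        assert profile["c"].protein_id == "c_fam"
        assert profile["c"].chain_length == 2
        assert [p for _, p in profile["c"].chain] == \
               ["a_fam", "b_fam", "c_fam"]

    def test_max_depth_one_disables_bridging(self, relaxed_config):
        uni = block_universe()
        profile = bridge_search(uni["a"].get("a_fam"), uni, CHAIN_TREE,
                                SearchConfig.relaxed(), max_depth=1)
        assert profile["c"].status == "absent"

    def test_present_set_equals_transitive_closure_oracle(self, fungal_config):
        """On a small universe, the final present set equals BFS
        reachability in the all-vs-all RBH-acceptance graph, and every
        chain length equals the BFS hop distance."""
        from .oracles import bfs_reachable

        uni, members = family_universe(61, ["s1", "s2", "s3", "s4", "s5"],
                                       n_decoys=2, divergence=35)
        tree = TaxonTree.from_newick(
            "(((s1:1,s2:1):1,s3:2):1,(s4:1,s5:1):2)root;", is_path=False)
        seed = uni["s1"].get("s1_fam")
        profile = bridge_search(seed, uni, tree, fungal_config, max_depth=6)
        edges = acceptance_edges(uni, members, fungal_config)
        dist = bfs_reachable(edges, "s1")
        assert set(profile.present_species()) == set(dist)
        for sp in profile.present_species():
            assert profile[sp].chain_length == dist[sp]

    def test_bridging_never_loses_direct_hits(self, fungal_config):
        uni, _ = family_universe(71, ["a", "b", "c", "d", "e"],
                                 divergence=30)
        tree = TaxonTree.from_newick(
            "((a:1,b:1):1,((c:1,d:1):1,e:2):1)root;", is_path=False)
        seed = uni["a"].get("a_fam")
        direct = direct_rbh_present(seed, uni, fungal_config)
        profile = bridge_search(seed, uni, tree, fungal_config, max_depth=5)
        assert direct <= set(profile.present_species())

    def test_deterministic_under_fixed_inputs(self, relaxed_config):
        uni = block_universe()
        seed = uni["a"].get("a_fam")
        p1 = bridge_search(seed, uni, CHAIN_TREE, relaxed_config, max_depth=3)
        p2 = bridge_search(seed, uni, CHAIN_TREE, relaxed_config, max_depth=3)
        assert [(s, e.status, e.protein_id, e.chain)
                for s, e in sorted(p1.entries.items())] == \
               [(s, e.status, e.protein_id, e.chain)
                for s, e in sorted(p2.entries.items())]

    def test_seed_species_validated(self, relaxed_config):
        uni = block_universe()
        rogue = make_record("z_fam", "z", "MKRDDE")
        with pytest.raises(ValueError, match="z"):
            bridge_search(rogue, uni, CHAIN_TREE, relaxed_config)


class TestConsistencyCheck:
    def test_single_query_profile_vacuously_consistent(self, relaxed_config):
        uni = block_universe()
        profile = bridge_search(uni["a"].get("a_fam"), uni, CHAIN_TREE,
                                relaxed_config, max_depth=3)
        assert consistency_check(profile) == []

    def test_two_seeds_agreeing_everywhere(self, relaxed_config):
        uni, _ = family_universe(81, ["a", "b", "c"], divergence=15)
        tree = TaxonTree.from_newick("((a:1,b:1):1,c:2)root;", is_path=False)
        pa = bridge_search(uni["a"].get("a_fam"), uni, tree, relaxed_config)
        pb = bridge_search(uni["b"].get("b_fam"), uni, tree, relaxed_config)
        merged = combine_profiles(pa, pb)
        assert merged["c"].n_queries >= 2
        assert consistency_check(merged) == []

    def test_planted_duplicate_family_splits_queries(self, relaxed_config):
        """Species z carries two unrelated proteins, each mirroring a
        different seed; the two walks accept different z proteins and the
        check flags z."""
        rng = random.Random(91)
        b1, b2 = random_protein(rng, 90), random_protein(rng, 90)
        uni = {
            "x": Proteome(species="x", records=[make_record("x_fam", "x", b1)]),
            "y": Proteome(species="y", records=[make_record("y_fam", "y", b2)]),
            "z": Proteome(species="z", records=[
                make_record("z1", "z", b1[:80] + random_protein(rng, 10)),
                make_record("z2", "z", b2[:80] + random_protein(rng, 10))]),
        }
        tree = TaxonTree.from_newick("((x:1,y:1):1,z:2)root;", is_path=False)
        px = bridge_search(uni["x"].get("x_fam"), uni, tree, relaxed_config)
        py = bridge_search(uni["y"].get("y_fam"), uni, tree, relaxed_config)
        assert px["z"].protein_id == "z1"
        assert py["z"].protein_id == "z2"
        merged = combine_profiles(px, py)
        assert consistency_check(merged) == ["z"]


class TestCladeSummary:
    def test_percent_arithmetic_half_up_one_decimal(self):
        assert fraction_percent(84, 88) == 95.5
        assert fraction_percent(0, 12) == 0.0
        assert fraction_percent(1, 1) == 100.0
        assert fraction_percent(2, 11) == 18.2
        assert fraction_percent(34, 42) == 81.0

    def test_summary_counts_on_real_profile(self, relaxed_config):
        uni = block_universe()
        profile = bridge_search(uni["a"].get("a_fam"), uni, CHAIN_TREE,
                                relaxed_config, max_depth=3)
        (ab, root) = clade_summary(profile, CHAIN_TREE, ["ab", "root"])
        assert (ab.found, ab.analyzed, ab.percent) == (2, 2, 100.0)
        assert (root.found, root.analyzed, root.percent) == (3, 3, 100.0)

    def test_single_present_species_clade(self, relaxed_config):
        uni = block_universe()
        profile = bridge_search(uni["a"].get("a_fam"), uni, CHAIN_TREE,
                                relaxed_config, max_depth=3)
        (c,) = clade_summary(profile, CHAIN_TREE, ["c"])
        assert (c.found, c.analyzed, c.percent) == (1, 1, 100.0)

    def test_unknown_clade_label_errors(self, relaxed_config):
        uni = block_universe()
        profile = bridge_search(uni["a"].get("a_fam"), uni, CHAIN_TREE,
                                relaxed_config, max_depth=2)
        with pytest.raises(KeyError):
            clade_summary(profile, CHAIN_TREE, ["nonexistent"])
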