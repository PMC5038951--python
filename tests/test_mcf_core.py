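"""Seeds, heaviest simple-path search, target selection, feature building."""

import numpy as np
import pandas as pd
import pytest

import networkx as nx

from mcf.expression_mapping import DifferentialReactionSet
from mcf.mcf_core import (
    CompositeFeatureSet,
    HeaviestDistanceTable,
    SearchConfig,
    build_features,
    extract_pathway_reactions,
    find_seeds,
    heaviest_distances,
    select_targets,
)
from mcf.network_model import Metabolite, MetabolicModel, Reaction
from mcf import synthetic_data as syn
from oracles import brute_force_heaviest, random_weighted_digraph


def de_set(significant, all_ids=None):
    ids = sorted(set(significant) | set(all_ids or ()))
    p = pd.Series({r: (0.001 if r in significant else 0.5) for r in ids})
    return DifferentialReactionSet(p, p, frozenset(significant), 0.05, "none")


def wgraph(edges):
    """edges: (u, v, rid, w)"""
    g = nx.MultiDiGraph()
    for u, v, rid, w in edges:
        g.add_edge(u, v, key=rid, reaction=rid, weight=float(w))
    return g


class TestFindSeeds:
    def make_model(self, n_atp, n_h2o):
        mets = [Metabolite(m, "", "c") for m in ["atp", "h2o", "x"]]
        rxns = []
        for i in range(n_atp):
            rxns.append(Reaction(f"ra{i}", (("atp", 1.0),), (("x", 1.0),)))
        for i in range(n_h2o):
            rxns.append(Reaction(f"rw{i}", (("h2o", 1.0),), (("x", 1.0),)))
        return MetabolicModel(mets, rxns)

    def test_threshold_boundary(self):
        model = self.make_model(5, 0)
        de = de_set({f"ra{i}" for i in range(5)})
        assert find_seeds(de, model, k=5).selected == ("atp",)
        de4 = de_set({f"ra{i}" for i in range(4)}, all_ids=[f"ra{i}" for i in range(5)])
        assert find_seeds(de4, model, k=5).selected == ()

    def test_substrate_incidence_enumeration(self):
        model = self.make_model(7, 3)
        de = de_set({f"ra{i}" for i in range(7)} | {f"rw{i}" for i in range(3)})
        seeds = find_seeds(de, model, k=5)
        assert seeds.selected == ("atp",)
        assert seeds.counts["atp"] == 7 and seeds.counts["h2o"] == 3

    def test_reversible_products_count_as_substrates(self):
        mets = [Metabolite(m, "", "c") for m in ["a", "b"]]
        rxns = [Reaction(f"r{i}", (("a", 1.0),), (("b", 1.0),), reversible=True)
                for i in range(5)]
        model = MetabolicModel(mets, rxns)
        seeds = find_seeds(de_set({f"r{i}" for i in range(5)}), model, k=5)
        assert set(seeds.selected) == {"a", "b"}

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            find_seeds(de_set({"r"}), self.make_model(1, 0), k=0)


class TestHeaviestDistances:
    def cfg(self, **kw):
        kw.setdefault("restrict_first_hop_to_de", False)
        return SearchConfig(**kw)

    def test_line_graph(self):
        g = wgraph([("s", "a", "r1", 2), ("a", "b", "r2", 3)])
        table = heaviest_distances(g, "s", self.cfg(max_depth=2))
        assert table.distances == {"a": 2, "b": 5}

    def test_diamond_prefers_heavier_total(self):
        g = wgraph([("s", "a", "r_sa", 5), ("a", "t", "r_at", 1),
                    ("s", "b", "r_sb", 2), ("b", "t", "r_bt", 10)])
        table = heaviest_distances(g, "s", self.cfg(max_depth=2, record_paths=True))
        assert table.distances["t"] == 12
        assert table.path_reactions("t") == {"r_sb", "r_bt"}

    def test_cycle_never_extended(self):
        g = wgraph([("s", "a", "r1", 1), ("a", "s", "r2", 1), ("a", "t", "r3", 1)])
        table = heaviest_distances(g, "s", self.cfg(max_depth=10))
        assert table.distances["t"] == 2

    def test_self_loop_never_traversed(self):
        g = wgraph([("s", "s", "rloop", 100), ("s", "a", "r1", 1)])
        table = heaviest_distances(g, "s", self.cfg(max_depth=5))
        assert table.distances == {"a": 1}

    def test_first_hop_restriction(self):
        g = wgraph([("s", "a", "r_de", 1), ("s", "b", "r_not", 50),
                    ("a", "b", "r2", 1)])
        de = de_set({"r_de"}, all_ids=["r_not", "r2"])
        table = heaviest_distances(
            g, "s", SearchConfig(restrict_first_hop_to_de=True, max_depth=3), de
        )
        assert table.distances == {"a": 1, "b": 2}

    def test_no_admissible_first_hop_gives_empty_table(self):
        g = wgraph([("s", "a", "r1", 1)])
        de = de_set(set(), all_ids=["r1"])
        table = heaviest_distances(
            g, "s", SearchConfig(restrict_first_hop_to_de=True), de
        )
        assert table.distances == {}

    def test_unknown_source_rejected(self):
        g = wgraph([("a", "b", "r", 1)])
        with pytest.raises(KeyError):
            heaviest_distances(g, "zz", self.cfg())

    def test_exact_matches_brute_force_enumeration(self):
        """Depth-bounded DFS equals exhaustive simple-path enumeration."""
        rng = np.random.default_rng(123)
        for _ in range(40):
            n = int(rng.integers(5, 11))
            g = random_weighted_digraph(rng, n)
            cfg = self.cfg(strategy="exact_bounded", max_depth=n - 1)
            got = heaviest_distances(g, "m0", cfg).distances
            want = brute_force_heaviest(g, "m0", n - 1)
            assert got == want

    def test_beam_never_exceeds_exact_and_mostly_matches(self):
        rng = np.random.default_rng(9)
        total = matched = 0
        for _ in range(10):
            g = random_weighted_digraph(rng, 30, p_edge=0.08)
            exact = heaviest_distances(g, "m0", self.cfg(max_depth=6)).distances
            beam = heaviest_distances(
                g, "m0", self.cfg(strategy="beam", max_depth=6, beam_width=50)
            ).distances
            for t, w in beam.items():
                assert w <= exact[t] + 1e-9
            total += len(exact)
            matched += sum(1 for t in exact if beam.get(t) == exact[t])
        assert matched / total >= 0.9

    def test_adding_edge_never_decreases_distances(self):
        rng = np.random.default_rng(77)
        g = random_weighted_digraph(rng, 10, p_edge=0.2)
        cfg = self.cfg(max_depth=5)
        before = heaviest_distances(g, "m0", cfg).distances
        g.add_edge("m0", "m5", key="r_new", reaction="r_new", weight=50.0)
        after = heaviest_distances(g, "m0", cfg).distances
        for t, w in before.items():
            assert after[t] >= w

    def test_parallel_edges_heavier_dominates(self):
        g = wgraph([("s", "a", "r_light", 10), ("s", "a", "r_heavy", 30)])
        table = heaviest_distances(g, "s", self.cfg(max_depth=1, record_paths=True))
        assert table.distances["a"] == 30
        assert table.path_reactions("a") == {"r_heavy"}


class TestSelectTargets:
    def tables(self, per_sample):
        return {
            s: HeaviestDistanceTable("src", dict(d)) for s, d in per_sample.items()
        }

    def labels6(self):
        return pd.Series(
            ["normal"] * 3 + ["cancer"] * 3,
            index=["n0", "n1", "n2", "c0", "c1", "c2"],
        )

    def test_separating_target_ranked_first(self):
        per_sample = {
            "n0": {"t": 1, "u": 5}, "n1": {"t": 2, "u": 4}, "n2": {"t": 3, "u": 6},
            "c0": {"t": 10, "u": 5}, "c1": {"t": 11, "u": 4}, "c2": {"t": 12, "u": 6},
        }
        fs = select_targets(self.tables(per_sample), self.labels6(), L=2)
        assert fs.targets[0] == "t"
        assert fs.pvalues["t"] == pytest.approx(2 / 20)
        assert fs.directions["t"] == "up_in_cancer"
        assert list(fs.pvalues) == sorted(fs.pvalues)  # nondecreasing

    def test_equal_p_breaks_lexicographically(self):
        per_sample = {
            s: {"b_t": v, "a_t": v}
            for s, v in zip(self.labels6().index, [1, 2, 3, 10, 11, 12])
        }
        fs = select_targets(self.tables(per_sample), self.labels6(), L=2)
        assert fs.targets == ("a_t", "b_t")

    def test_direction_down_in_cancer(self):
        per_sample = {
            s: {"t": v}
            for s, v in zip(self.labels6().index, [10, 11, 12, 1, 2, 3])
        }
        fs = select_targets(self.tables(per_sample), self.labels6(), L=1)
        assert fs.directions["t"] == "down_in_cancer"

    def test_coverage_filter_and_zero_fill(self):
        per_sample = {
            s: ({"t": v} if s != "n0" else {})
            for s, v in zip(self.labels6().index, [9, 2, 3, 10, 11, 12])
        }
        # t reachable in 5/6 samples: passes 0.8 coverage, n0's feature is 0
        fs = select_targets(self.tables(per_sample), self.labels6(), L=1, coverage=0.8)
        assert fs.features.loc["n0", "t"] == 0.0
        assert bool(fs.missing.loc["n0", "t"])
        with pytest.raises(ValueError, match="coverage"):
            select_targets(self.tables(per_sample), self.labels6(), L=1, coverage=0.95)


class TestBuildFeatures:
    def test_planted_seed_recovered(self, planted_network, planted_model):
        feature_sets = build_features(
            planted_network, planted_model.graph,
            planted_model.reaction_expression, planted_model.labels,
        )
        assert syn.PLANTED_SEED_ID in {fs.seed for fs in feature_sets}
        planted = next(fs for fs in feature_sets if fs.seed == syn.PLANTED_SEED_ID)
        assert planted.features.shape == (100, planted.n_targets)

    def test_large_L_truncates_with_warning(self, planted_network, planted_model):
        with pytest.warns(UserWarning, match="eligible targets"):
            feature_sets = build_features(
                planted_network, planted_model.graph,
                planted_model.reaction_expression, planted_model.labels, L=10_000,
            )
        assert all(fs.n_targets < 10_000 for fs in feature_sets)

    def test_no_seeds_advises_lower_k(self, planted_network, planted_model):
        with pytest.raises(ValueError, match="lowering k"):
            build_features(
                planted_network, planted_model.graph,
                planted_model.reaction_expression, planted_model.labels, k=10_000,
            )

    def test_deterministic_given_inputs(self, planted_network, planted_model):
        kwargs = dict(
            model=planted_network, graph=planted_model.graph,
            rxn=planted_model.reaction_expression, labels=planted_model.labels,
        )
        a = build_features(**kwargs)
        b = build_features(**kwargs)
        assert [fs.seed for fs in a] == [fs.seed for fs in b]
        for x, y in zip(a, b):
            assert x.targets == y.targets
            pd.testing.assert_frame_equal(x.features, y.features)
            pd.testing.assert_series_equal(x.pvalues, y.pvalues)


class TestExtractPathwayReactions:
    def test_realized_paths_per_pair(self, planted_network, planted_model, planted_results):
        fs = next(f for f in planted_results.feature_sets
                  if f.seed == syn.PLANTED_SEED_ID)
        samples = list(planted_model.labels.index)[:4]
        per_pair = extract_pathway_reactions(
            fs, planted_model.graph, planted_model.reaction_expression, samples
        )
        assert set(per_pair) == {(fs.seed, t) for t in fs.targets}
        some = per_pair[(fs.seed, fs.targets[0])]
        assert set(some) == set(samples)
        # a chain target's realized path consists of that chain's reactions
        chain_targets = [t for t in fs.targets if t.startswith("chain")]
        for t in chain_targets:
            i = t.split("_")[0][len("chain"):]
            for s, rids in per_pair[(fs.seed, t)].items():
                if rids:
                    assert all(r.startswith(f"r_plant{i}_") for r in rids)

    def test_disabled_recording_raises(self):
        table = HeaviestDistanceTable("s", {"t": 1.0}, paths=None)
        with pytest.raises(ValueError, match="recording"):
            table.path_reactions("t")
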