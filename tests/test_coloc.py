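"""Co-localization networks, intersection and conservation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from harmonics import (
    HomologyMap,
    build_network,
    chromosome_coverage,
    conservation_from_counts,
    conservation_score,
    intersect,
    relabel_by_homology,
)


def assignment_of(chrom_of: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": list(chrom_of),
            "species": "s",
            "chromosome": list(chrom_of.values()),
            "period_class": "P8",
        }
    )


def identity_map(ids) -> HomologyMap:
    return HomologyMap(mapping={g: g for g in ids})


class TestBuild:
    def test_cliques_per_chromosome_and_isolate_removal(self, tiny_assignment):
        net = build_network(tiny_assignment, {"g1", "g2", "g3", "g4", "g5", "g6"})
        assert net.stats() == (5, 4, 2)  # g6 alone on c3 is pruned
        assert "g6" not in net.graph

    def test_all_distinct_chromosomes_empty_network(self):
        a = assignment_of({f"g{i}": f"c{i}" for i in range(6)})
        net = build_network(a, set(a["gene_id"]))
        assert net.stats() == (0, 0, 0)

    def test_component_sizes_4_3_2(self):
        chrom = {}
        for i, size in enumerate((4, 3, 2)):
            for j in range(size):
                chrom[f"g{i}_{j}"] = f"c{i}"
        net = build_network(assignment_of(chrom), set(chrom))
        assert net.stats() == (9, 6 + 3 + 1, 3)

    def test_gene_on_two_chromosomes_rejected(self, tiny_assignment):
        dup = pd.concat(
            [tiny_assignment, assignment_of({"g1": "c9"})], ignore_index=True
        )
        with pytest.raises(ValueError, match="more than one chromosome"):
            build_network(dup, {"g1", "g2"})

    def test_unknown_ids_skipped_and_counted(self, tiny_assignment):
        net = build_network(tiny_assignment, {"g1", "g2", "nope1", "nope2"})
        assert net.stats() == (2, 1, 1)
        assert net.n_skipped == 2

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 7), min_size=2, max_size=40))
    def test_components_are_cliques_with_binomial_edge_counts(self, chrom_idx):
        chrom = {f"g{i}": f"c{c}" for i, c in enumerate(chrom_idx)}
        net = build_network(assignment_of(chrom), set(chrom))
        net.validate()  # every component a clique, no isolates
        sizes = [len(c) for c in net.components()]
        assert net.n_edges == sum(m * (m - 1) // 2 for m in sizes)
        counts = pd.Series(list(chrom.values())).value_counts()
        assert net.n_components == int((counts >= 2).sum())


class TestRelabelAndIntersect:
    def test_identity_map_preserves_network(self, tiny_assignment):
        net = build_network(tiny_assignment, {"g1", "g2", "g3", "g4", "g5"})
        rel = relabel_by_homology(net, identity_map(net.graph.nodes))
        assert set(rel.graph.nodes) == set(net.graph.nodes)
        assert set(map(frozenset, rel.graph.edges)) == set(
            map(frozenset, net.graph.edges)
        )

    def test_unmapped_clique_member_shrinks_clique(self):
        chrom = {g: "c1" for g in ("a", "b", "c")}
        net = build_network(assignment_of(chrom), set(chrom))
        rel = relabel_by_homology(net, identity_map({"a", "b"}))
        assert rel.stats() == (2, 1, 1)

    def test_partial_map_on_ten_clique(self):
        chrom = {f"g{i}": "c1" for i in range(10)}
        net = build_network(assignment_of(chrom), set(chrom))
        keep = {f"g{i}": f"h{i}" for i in range(8)}
        rel = relabel_by_homology(net, HomologyMap(mapping=keep))
        assert rel.stats() == (8, math.comb(8, 2), 1)

    def test_noninjective_relabel_rejected(self, tiny_assignment):
        net = build_network(tiny_assignment, {"g1", "g2"})
        bad = HomologyMap.__new__(HomologyMap)
        bad.mapping = {"g1": "x", "g2": "x"}
        bad.unmapped = set()
        with pytest.raises(ValueError, match="injective"):
            relabel_by_homology(net, bad)

    def test_intersection_idempotent_and_commutative(self, tiny_assignment):
        net = build_network(tiny_assignment, {"g1", "g2", "g3", "g4", "g5"})
        same = intersect(net, net)
        assert same.stats() == net.stats()
        a = build_network(assignment_of({"a": "c1", "b": "c1", "c": "c2", "d": "c2"}), {"a", "b", "c", "d"})
        b = build_network(assignment_of({"a": "k1", "b": "k1", "c": "k1", "d": "k2"}), {"a", "b", "c", "d"})
        ab, ba = intersect(a, b), intersect(b, a)
        assert ab.stats() == ba.stats()
        assert set(ab.graph.nodes) == set(ba.graph.nodes)

    def test_disjoint_networks_intersect_empty(self):
        a = build_network(assignment_of({"a": "c1", "b": "c1"}), {"a", "b"})
        b = build_network(assignment_of({"x": "c1", "y": "c1"}), {"x", "y"})
        assert intersect(a, b).stats() == (0, 0, 0)

    def test_worked_intersection_example(self):
        # A = triangle {a,b,c} + edge {d,e};  B = cliques {a,b,c,d} and {e,f}
        a = build_network(
            assignment_of({"a": "c1", "b": "c1", "c": "c1", "d": "c2", "e": "c2"}),
            {"a", "b", "c", "d", "e"},
        )
        b = build_network(
            assignment_of({"a": "k1", "b": "k1", "c": "k1", "d": "k1", "e": "k2", "f": "k2"}),
            {"a", "b", "c", "d", "e", "f"},
        )
        inter = intersect(a, b)
        assert set(inter.graph.nodes) == {"a", "b", "c"}
        assert inter.stats() == (3, 3, 1)

    def test_cross_species_chromosome_identity_not_required(self):
        # co-membership on *different* chromosome names still intersects
        a = build_network(assignment_of({"a": "chr1", "b": "chr1"}), {"a", "b"})
        b = build_network(assignment_of({"a": "chr7", "b": "chr7"}), {"a", "b"})
        assert intersect(a, b).stats() == (2, 1, 1)

    def test_intersection_bounded_by_parents(self, tiny_assignment):
        a = build_network(tiny_assignment, {"g1", "g2", "g3", "g4", "g5"})
        b = build_network(
            assignment_of({"g1": "k1", "g3": "k1", "g4": "k1", "g5": "k2"}),
            {"g1", "g3", "g4", "g5"},
        )
        inter = intersect(a, b)
        assert inter.n_nodes <= min(a.n_nodes, b.n_nodes)
        assert inter.n_edges <= min(a.n_edges, b.n_edges)


class TestConservation:
    @pytest.mark.parametrize(
        "n_int,n_sp1,pct", [(33, 51, 65), (45, 199, 23), (103, 1827, 6), (0, 7, 0)]
    )
    def test_percentages_from_counts(self, n_int, n_sp1, pct):
        assert conservation_from_counts(n_int, n_sp1) == pct

    def test_rounding_is_half_up(self):
        assert conservation_from_counts(1, 40) == 3  # 2.5 rounds up
        assert conservation_from_counts(1, 41) == 2  # 2.439 rounds down

    def test_empty_species1_network_undefined(self):
        with pytest.raises(ValueError):
            conservation_from_counts(0, 0)

    def test_self_conservation_is_100(self, tiny_assignment):
        net = build_network(tiny_assignment, {"g1", "g2", "g3", "g4", "g5"})
        assert conservation_score(intersect(net, net), net) == 100


class TestCoverage:
    def test_fraction_per_chromosome(self):
        a = assignment_of({f"g{i}": "c1" for i in range(10)})
        cov = chromosome_coverage(a, {"g0", "g1"}, {"c1": 10})
        assert cov == {"c1": 0.2}

    def test_empty_set_all_zero(self, tiny_assignment):
        cov = chromosome_coverage(
            tiny_assignment, set(), {"c1": 5, "c2": 5, "c3": 5}
        )
        assert set(cov.values()) == {0.0}

    def test_constructed_fixture(self):
        chrom = {}
        for c, (total, hit) in enumerate(((5, 1), (10, 2), (20, 4))):
            for j in range(total):
                chrom[f"g{c}_{j}"] = f"c{c}"
        a = assignment_of(chrom)
        hits = {"g0_0", "g1_0", "g1_1", "g2_0", "g2_1", "g2_2", "g2_3"}
        totals = {"c0": 5, "c1": 10, "c2": 20}
        cov = chromosome_coverage(a, hits, totals)
        assert cov == {"c0": 0.2, "c1": 0.2, "c2": 0.2}

    def test_zero_total_with_members_rejected(self):
        a = assignment_of({"g1": "c1"})
        with pytest.raises(ValueError, match="total 0"):
            chromosome_coverage(a, {"g1"}, {"c1": 0})

    def test_totals_must_cover_assignment(self, tiny_assignment):
        with pytest.raises(ValueError, match="missing"):
            chromosome_coverage(tiny_assignment, {"g1"}, {"c1": 5})
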