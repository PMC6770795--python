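"""Chromosomal co-localization networks and cross-species conservation.

A co-localization network places the genes of a set as nodes and joins two
genes whenever they reside on the same chromosome, so every connected
component is by construction a clique (one per chromosome carrying at least
two set members).  Isolated nodes — genes alone on their chromosome within
the set — are removed before any statistics are reported.

Cross-species comparison proceeds by building the network in each species,
relabelling the second species' network onto the first species' gene ids
through a resolved one-to-one homology map, and intersecting: only nodes and
edges present in both networks survive.  Chromosome identity is deliberately
NOT required to match across species — an intersection edge means the two
genes are co-chromosomal in both genomes, whichever chromosomes those are.
The conservation score is the intersection's node count as a percentage of
the first species' network node count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .homology import HomologyMap

logger = logging.getLogger(__name__)


@dataclass
class ColocNetwork:
    """An isolate-free union of same-chromosome cliques."""

    graph: nx.Graph
    species: str = ""
    n_skipped: int = 0  # gene ids absent from the assignment table

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)

    def stats(self) -> tuple[int, int, int]:
        return (self.n_nodes, self.n_edges, self.n_components)

    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def validate(self) -> None:
        """Assert the structural invariants: simple, isolate-free, cliquey."""
        g = self.graph
        if any(a == b for a, b in g.edges()):
            raise AssertionError("self-loop in co-localization network")
        total = 0
        for comp in nx.connected_components(g):
            m = len(comp)
            if m == 1:
                raise AssertionError("isolate node survived pruning")
            n_edges = g.subgraph(comp).number_of_edges()
            if n_edges != m * (m - 1) // 2:
                raise AssertionError(
                    f"component of size {m} has {n_edges} edges; not a clique"
                )
            total += n_edges
        if total != g.number_of_edges():
            raise AssertionError("edge total does not match component sum")


def _prune_isolates(g: nx.Graph) -> nx.Graph:
    g.remove_nodes_from([n for n in g.nodes() if g.degree(n) == 0])
    return g


def build_network(
    assignment: pd.DataFrame, gene_set: set[str], species: str = ""
) -> ColocNetwork:
    """Build the co-localization network of ``gene_set`` from an assignment.

    ``assignment`` needs columns ``gene_id`` and ``chromosome`` and must
    place each set member on exactly one chromosome; a gene listed on two
    chromosomes is an input error.  Set members absent from the table are
    skipped with a warning and counted in ``n_skipped``.
    """
    sub = assignment[assignment["gene_id"].isin(gene_set)]
    dup = sub[sub.duplicated("gene_id", keep=False)]
    if not dup.empty:
        bad = sorted(dup["gene_id"].unique())[:5]
        raise ValueError(f"genes assigned to more than one chromosome: {bad}")
    known = set(sub["gene_id"])
    n_skipped = len(gene_set - known)
    if n_skipped:
        logger.warning(
            "%d of %d set members missing from the assignment; skipped",
            n_skipped,
            len(gene_set),
        )
    g = nx.Graph()
    for _, members in sub.groupby("chromosome")["gene_id"]:
        ids = sorted(members)
        g.add_nodes_from(ids)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                g.add_edge(ids[i], ids[j])
    net = ColocNetwork(_prune_isolates(g), species=species, n_skipped=n_skipped)
    net.validate()
    return net


def relabel_by_homology(net: ColocNetwork, hmap: HomologyMap) -> ColocNetwork:
    """Rename a network's nodes through a homology map, dropping the unmapped.

    The map is applied as-is: to move a species-2 network onto species-1
    ids, pass ``hmap.invert()``.  Nodes without a map entry are removed with
    their edges and the result is re-pruned of isolates.
    """
    targets = list(hmap.mapping.values())
    if len(set(targets)) != len(targets):
        raise ValueError("homology map must be injective to relabel a network")
    keep = [n for n in net.graph.nodes() if n in hmap.mapping]
    sub = net.graph.subgraph(keep).copy()
    renamed = nx.relabel_nodes(sub, {n: hmap.mapping[n] for n in keep}, copy=True)
    out = ColocNetwork(_prune_isolates(renamed), species=net.species)
    out.validate()
    return out


def intersect(net_a: ColocNetwork, net_b: ColocNetwork) -> ColocNetwork:
    """Keep only nodes and edges common to both networks; prune isolates.

    Both networks must already live on the same id namespace.  Because each
    parent is a union of cliques induced by a same-chromosome equivalence
    relation, the intersection is again a union of cliques.
    """
    common_nodes = set(net_a.graph.nodes()) & set(net_b.graph.nodes())
    edges_b = {frozenset(e) for e in net_b.graph.edges()}
    g = nx.Graph()
    g.add_nodes_from(common_nodes)
    for a, b in net_a.graph.edges():
        if frozenset((a, b)) in edges_b:
            g.add_edge(a, b)
    out = ColocNetwork(_prune_isolates(g), species=f"{net_a.species}&{net_b.species}")
    out.validate()
    return out


def conservation_from_counts(n_intersection: int, n_species1: int) -> int:
    """Conservation percentage from raw node counts, rounded half-up."""
    if n_species1 <= 0:
        raise ValueError("species-1 network has no nodes; conservation undefined")
    if n_intersection < 0:
        raise ValueError("negative intersection node count")
    if n_intersection > n_species1:
        raise ValueError("intersection larger than species-1 network")
    return int(math.floor(100.0 * n_intersection / n_species1 + 0.5))


def conservation_score(intersection: ColocNetwork, species1_net: ColocNetwork) -> int:
    """Percent of species-1 network nodes surviving into the intersection."""
    return conservation_from_counts(intersection.n_nodes, species1_net.n_nodes)


def chromosome_coverage(
    assignment: pd.DataFrame,
    gene_set: set[str],
    totals: dict[str, int],
) -> dict[str, float]:
    """Fraction of each chromosome's genes belonging to ``gene_set``.

    ``totals`` gives the denominator (total gene count) per chromosome and
    must cover every chromosome appearing in the assignment; chromosomes
    with no set member report 0.
    """
    chroms = set(assignment["chromosome"].astype(str))
    missing = chroms - set(totals)
    if missing:
        raise ValueError(f"totals missing for chromosomes: {sorted(missing)[:5]}")
    sub = assignment[assignment["gene_id"].isin(gene_set)]
    counts = sub.groupby("chromosome")["gene_id"].count()
    out: dict[str, float] = {}
    for c in sorted(totals):
        k = int(counts.get(c, 0))
        if totals[c] <= 0:
            if k:
                raise ValueError(f"chromosome {c} has members but total 0")
            out[c] = 0.0
        else:
            out[c] = k / totals[c]
    return out


@dataclass
class IntersectionResult:
    """An intersection network together with its conservation percentage."""

    network: ColocNetwork
    conservation_pct: int = field(default=0)
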