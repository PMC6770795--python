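"""Randomized-network connectivity test for gene sets.

Given a fixed protein–protein interaction (PPI) reference, the question is
whether a focal gene set (for instance an ultradian 8-h set) is more densely
connected to a designated subnetwork (such as a network of circadian
regulated genes) than expected by chance.  The null model resamples node
sets: random gene sets of the same size as the designated subnetwork are
drawn uniformly without replacement from the reference universe, and the
cross-set interaction count is recorded for each draw.  The observed count
is then summarized as a z-score against the empirical null mean and SD, and
as an empirical p-value with the standard +1/+1 pseudo-count so that p is
never exactly zero.

For small instances the null can be enumerated exhaustively, which serves as
an independent oracle for the Monte-Carlo sampler.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .io import read_edge_tsv, read_mitab

logger = logging.getLogger(__name__)


@dataclass
class InteractionReference:
    """A simple undirected PPI universe; duplicate records collapse to one
    edge but their multiplicity is kept as the edge attribute ``n_records``."""

    graph: nx.Graph
    provenance: str = ""

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], provenance: str = ""
    ) -> "InteractionReference":
        g = nx.Graph()
        n_loops = 0
        for a, b in edges:
            if a == b:
                n_loops += 1
                continue
            if g.has_edge(a, b):
                g[a][b]["n_records"] += 1
            else:
                g.add_edge(a, b, n_records=1)
        if n_loops:
            logger.warning("dropped %d self-interaction records", n_loops)
        return cls(graph=g, provenance=provenance)

    @classmethod
    def from_mitab(cls, path: str | Path) -> "InteractionReference":
        return cls.from_edges(read_mitab(path), provenance=str(path))

    @classmethod
    def from_edge_tsv(cls, path: str | Path) -> "InteractionReference":
        return cls.from_edges(read_edge_tsv(path), provenance=str(path))

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes())


@dataclass
class ConnectivityResult:
    """Observed-vs-null summary of cross-set connectivity."""

    observed: int
    null_mean: float
    null_sd: float
    z: float
    p_empirical: float
    n_iter: int
    seed: int | None = None
    null_counts: list[int] = field(default_factory=list)

    @classmethod
    def from_summary(
        cls, observed: float, null_mean: float, null_sd: float
    ) -> "ConnectivityResult":
        """Build the z-score from an already-computed null summary.

        Useful to score published summaries (observed count, null mean ± SD)
        without access to the underlying reference.
        """
        z = _z_score(observed, null_mean, null_sd)
        return cls(
            observed=int(observed),
            null_mean=null_mean,
            null_sd=null_sd,
            z=z,
            p_empirical=float("nan"),
            n_iter=0,
        )

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "p_empirical": self.p_empirical,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "null_counts": list(self.null_counts),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _z_score(observed: float, mean: float, sd: float) -> float:
    if sd == 0:
        if observed > mean:
            return math.inf
        if observed < mean:
            return -math.inf
        return 0.0
    return (observed - mean) / sd


def _count(
    adj: dict[str, set[str]],
    records: dict[frozenset, int] | None,
    set_a: set[str],
    set_b: set[str],
) -> int:
    # adj must cover set_a; records is None for unique-edge counting
    total = 0
    for a in set_a:
        for n in adj[a]:
            if n in set_b:
                total += records[frozenset((a, n))] if records is not None else 1
    return total


def _edge_records(ref: InteractionReference, count_records: bool):
    if not count_records:
        return None
    return {frozenset((u, v)): d["n_records"] for u, v, d in ref.graph.edges(data=True)}


def count_cross_interactions(
    ref: InteractionReference,
    set_a: set[str],
    set_b: set[str],
    count_records: bool = False,
) -> int:
    """Number of reference edges with one endpoint in each set.

    Ids absent from the reference are dropped (and logged); genes present in
    both sets are removed from ``set_b`` so that self-connectivity of the
    focal set cannot inflate the count.  With ``count_records=True`` an edge
    contributes its record multiplicity instead of 1.
    """
    nodes = ref.nodes
    a = set_a & nodes
    b = (set_b & nodes) - a
    dropped = (len(set_a) - len(set_a & nodes)) + (len(set_b) - len(set_b & nodes))
    if dropped:
        logger.info("%d set members absent from the interaction reference", dropped)
    if not a and not b:
        raise ValueError("both gene sets are empty after reduction to the reference")
    adj = {n: set(ref.graph.neighbors(n)) for n in a}
    return _count(adj, _edge_records(ref, count_records), a, b)


def connectivity_test(
    ref: InteractionReference,
    set_a: set[str],
    set_b: set[str],
    n_iter: int = 100,
    seed: int = 0,
    universe: set[str] | None = None,
    count_records: bool = False,
) -> ConnectivityResult:
    """Score the connectivity of ``set_a`` to ``set_b`` against a resampled null.

    ``n_iter`` random sets of size ``|set_b|`` (after reduction to the
    reference) are drawn uniformly without replacement from ``universe``
    (default: all reference nodes outside ``set_a``); each is scored with
    :func:`count_cross_interactions` against ``set_a``.  The SD uses the
    n−1 denominator and the empirical p is (1 + #{null ≥ observed}) /
    (n_iter + 1).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    nodes = ref.nodes
    a = set_a & nodes
    b = (set_b & nodes) - a
    if not a or not b:
        raise ValueError("focal or target set empty after reduction to the reference")
    pool = sorted((universe & nodes if universe is not None else nodes) - a)
    k = len(b)
    if len(pool) < k:
        raise ValueError(
            f"sampling universe ({len(pool)}) smaller than target set ({k})"
        )
    observed = count_cross_interactions(ref, a, b, count_records=count_records)

    adj = {n: set(ref.graph.neighbors(n)) for n in a}
    records = _edge_records(ref, count_records)
    rng = np.random.default_rng(seed)
    pool_arr = np.asarray(pool, dtype=object)
    null_counts = []
    for _ in range(n_iter):
        draw = set(rng.choice(pool_arr, size=k, replace=False))
        null_counts.append(_count(adj, records, a, draw))
    counts = np.asarray(null_counts, dtype=float)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if n_iter > 1 else 0.0
    p = (1 + int((counts >= observed).sum())) / (n_iter + 1)
    return ConnectivityResult(
        observed=observed,
        null_mean=mean,
        null_sd=sd,
        z=_z_score(observed, mean, sd),
        p_empirical=p,
        n_iter=n_iter,
        seed=seed,
        null_counts=[int(c) for c in null_counts],
    )


def exhaustive_null(
    ref: InteractionReference,
    set_a: set[str],
    universe: Sequence[str] | set[str],
    k: int,
    count_records: bool = False,
    max_subsets: int = 10**6,
) -> list[int]:
    """Cross-interaction count for every k-subset of ``universe``.

    Subsets are enumerated in lexicographic order over the sorted universe;
    this brute-force null is the oracle against which the Monte-Carlo
    sampler is validated on small instances.
    """
    pool = sorted(set(universe))
    n_subsets = math.comb(len(pool), k)
    if n_subsets > max_subsets:
        raise ValueError(f"C({len(pool)}, {k}) = {n_subsets} exceeds {max_subsets}")
    nodes = ref.nodes
    a = set_a & nodes
    if not a:
        raise ValueError("focal set empty after reduction to the reference")
    adj = {n: set(ref.graph.neighbors(n)) for n in a}
    records = _edge_records(ref, count_records)
    return [_count(adj, records, a, set(sub) - a) for sub in combinations(pool, k)]
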