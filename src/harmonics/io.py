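"""Readers and writers for the plain-text formats used across the pipeline.

Tables travel as TSV (pandas), gene sets as one-id-per-line text, interaction
references as either a 2-column edge TSV or minimal PSI-MI TAB 2.5 (MITAB),
and networks as Cytoscape SIF and GraphML.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

ASSIGNMENT_COLUMNS = ["gene_id", "species", "chromosome", "period_class"]
CANDIDATE_COLUMNS = [
    "query_id",
    "target_id",
    "confidence",
    "goc",
    "target_pid",
    "query_pid",
    "dn_ds",
]

_MITAB_NCOL = 15


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_gene_set(path: str | Path) -> set[str]:
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


def write_gene_set(ids: Iterable[str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(f"{g}\n" for g in sorted(ids)))


def read_edge_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Read a headerless or headered 2-column edge list."""
    edges: list[tuple[str, str]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed edge line: {line!r}")
        if parts[0] in ("node_a", "source", "id_a"):  # header
            continue
        edges.append((parts[0], parts[1]))
    return edges


def write_edge_tsv(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def _strip_db_prefix(field: str) -> str:
    # MITAB ids look like "uniprotkb:P12345"; keep the accession part
    return field.split(":", 1)[1] if ":" in field else field


def read_mitab(path: str | Path) -> list[tuple[str, str]]:
    """Read interactor-id pairs from a MITAB 2.5 file (columns 1-2).

    Returns one tuple per record, multiplicities preserved; callers decide
    whether duplicate records collapse to a single edge.
    """
    pairs: list[tuple[str, str]] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed MITAB line: {line!r}")
        pairs.append((_strip_db_prefix(parts[0]), _strip_db_prefix(parts[1])))
    return pairs


def write_mitab(
    pairs: Iterable[tuple[str, str]],
    path: str | Path,
    db: str = "uniprotkb",
    source: str = "synthetic",
) -> None:
    """Write edges as minimal MITAB 2.5: ids in columns 1-2, '-' elsewhere."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    filler = "\t".join("-" for _ in range(_MITAB_NCOL - 3))
    with open(path, "w") as fh:
        for a, b in pairs:
            fh.write(f"{db}:{a}\t{db}:{b}\t{source}\t{filler}\n")


def write_sif(graph: nx.Graph, path: str | Path, relation: str = "co_loc") -> None:
    """Write a graph in Cytoscape simple-interaction format.

    Isolated nodes are written as bare node lines so the file round-trips
    the full node set.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for n in sorted(graph.nodes()):
            if graph.degree(n) == 0:
                fh.write(f"{n}\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(graph, path)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
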