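"""End-to-end orchestration: simulate → map homologs → co-localization →
connectivity permutation test → stability statistics.

Every stage reads and writes plain files under the output directory, so
stages can be re-run independently from intermediates.  A JSON run manifest
records the configuration snapshot, per-stage status/timing and a SHA-256
hash of every output file; re-running with the same configuration and seed
reproduces the hashes bit for bit, which is the pipeline's regression test.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .coloc import (
    build_network,
    chromosome_coverage,
    conservation_score,
    intersect,
    relabel_by_homology,
)
from .homology import HomologyMap, mapping_coverage, resolve_homologs
from .io import (
    sha256_file,
    write_edge_tsv,
    write_gene_set,
    write_graphml,
    write_mitab,
    write_sif,
    write_tsv,
)
from .permutation import InteractionReference, connectivity_test
from .stability import group_comparison, spearman_matrix
from .synthetic import (
    SyntheticConfig,
    gen_energy_table,
    gen_ppi,
    gen_two_species_assignment,
    gene_sets_from_assignment,
)

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    version: str = __version__
    stages: dict[str, dict] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # relpath -> sha256

    def record_stage(self, name: str, status: str, seconds: float) -> None:
        self.stages[name] = {"status": status, "seconds": round(seconds, 3)}

    def record_outputs(self, out_dir: Path, paths: list[Path]) -> None:
        for p in paths:
            self.outputs[str(p.relative_to(out_dir))] = sha256_file(p)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))


def _stage(manifest: RunManifest, name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("=== stage: %s ===", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            manifest.record_stage(name, "failed" if exc else "ok", dt)
            if exc:
                logger.error("stage %s failed: %s", name, exc)
            return False

    return _Ctx()


def simulate(config: SyntheticConfig, out_dir: str | Path) -> list[Path]:
    """Generate and write every synthetic input; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    a1, a2, candidates = gen_two_species_assignment(config)
    sets = gene_sets_from_assignment(a1)

    paths = []

    def _w(fn, df_or_obj, rel):
        p = out / rel
        fn(df_or_obj, p)
        paths.append(p)

    _w(write_tsv, a1, "species1_assignment.tsv")
    _w(write_tsv, a2, "species2_assignment.tsv")
    _w(write_tsv, candidates.drop(columns=["planted"]), "homolog_candidates.tsv")
    for cls, ids in sets.items():
        _w(write_gene_set, ids, f"sets/{cls}.txt")

    # PPI with planted enrichment: focal = 8-h set, target = a synthetic
    # circadian-hub ("NCRG-like") subset of the 24-h set
    focal = sorted(sets.get("P8", set()))
    p24 = sorted(sets.get("P24", set()))
    target = p24[: config.ncrg_size]
    ref = gen_ppi(config, set(focal), set(target))
    edges = sorted(tuple(sorted(e)) for e in ref.graph.edges())
    _w(write_mitab, edges, "ppi.mitab")
    _w(write_edge_tsv, edges, "ppi_edges.tsv")
    _w(write_gene_set, target, "ncrg.txt")

    energy = gen_energy_table(config)
    _w(write_tsv, energy, "energy_features.tsv")
    return paths


def run_all(
    config: SyntheticConfig | str | Path,
    out_dir: str | Path,
    n_iter: int = 100,
) -> RunManifest:
    """Run the whole pipeline into ``out_dir`` and return the manifest.

    ``config`` may be a :class:`SyntheticConfig` or a path to its YAML
    form.  A stage failure is recorded in the manifest (written regardless)
    and re-raised.
    """
    if not isinstance(config, SyntheticConfig):
        config = SyntheticConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    summary: dict = {"seed": config.seed}

    try:
        with _stage(manifest, "simulate"):
            paths = simulate(config, out)
            manifest.record_outputs(out, paths)
            a1 = pd.read_csv(out / "species1_assignment.tsv", sep="\t")
            a2 = pd.read_csv(out / "species2_assignment.tsv", sep="\t")
            candidates = pd.read_csv(out / "homolog_candidates.tsv", sep="\t")
            sets = gene_sets_from_assignment(a1)

        with _stage(manifest, "map_homologs"):
            hmap = resolve_homologs(candidates)
            write_tsv(hmap.to_frame(), out / "homology_map.tsv")
            write_gene_set(hmap.unmapped, out / "homology_unmapped.txt")
            manifest.record_outputs(
                out, [out / "homology_map.tsv", out / "homology_unmapped.txt"]
            )
            summary["homology"] = {
                cls: dict(zip(("n_mapped", "n_total"), mapping_coverage(hmap, ids)))
                for cls, ids in sets.items()
            }

        with _stage(manifest, "coloc"):
            coloc_paths = _coloc_stage(a1, a2, sets, hmap, out, summary)
            manifest.record_outputs(out, coloc_paths)

        with _stage(manifest, "permtest"):
            ref = InteractionReference.from_edge_tsv(out / "ppi_edges.tsv")
            focal = sets.get("P8", set()) & ref.nodes
            target = {
                line
                for line in (out / "ncrg.txt").read_text().split()
                if line
            }
            result = connectivity_test(
                ref, focal, target, n_iter=n_iter, seed=config.seed
            )
            result.to_json(out / "connectivity.json")
            manifest.record_outputs(out, [out / "connectivity.json"])
            summary["connectivity"] = {
                "observed": result.observed,
                "null_mean": result.null_mean,
                "null_sd": result.null_sd,
                "z": result.z,
                "p_empirical": result.p_empirical,
            }

        with _stage(manifest, "stats"):
            energy = pd.read_csv(out / "energy_features.tsv", sep="\t")
            comp = group_comparison(energy, adjust_for_residues=True)
            write_tsv(comp.descriptive, out / "energy_descriptive.tsv")
            write_tsv(comp.kw, out / "energy_kw.tsv")
            write_tsv(comp.dunn, out / "energy_dunn.tsv")
            rho, pval = spearman_matrix(energy, groups=["P8", "P12", "P24"])
            rho.to_csv(out / "energy_spearman_rho.tsv", sep="\t")
            pval.to_csv(out / "energy_spearman_p.tsv", sep="\t")
            manifest.record_outputs(
                out,
                [
                    out / "energy_descriptive.tsv",
                    out / "energy_kw.tsv",
                    out / "energy_dunn.tsv",
                    out / "energy_spearman_rho.tsv",
                    out / "energy_spearman_p.tsv",
                ],
            )
            summary["n_significant_dunn_pairs"] = int(
                (comp.dunn["p_adj"] < 0.05).sum()
            )
    finally:
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        manifest.to_json(out / "manifest.json")
    return manifest


def _coloc_stage(
    a1: pd.DataFrame,
    a2: pd.DataFrame,
    sets: dict[str, set[str]],
    hmap: HomologyMap,
    out: Path,
    summary: dict,
) -> list[Path]:
    paths: list[Path] = []
    stats_rows = []
    conservation: dict[str, int] = {}
    inv = hmap.invert()
    for cls, set1 in sorted(sets.items()):
        net1 = build_network(a1, set1, species="species1")
        set2 = {hmap.mapping[g] for g in set1 if g in hmap.mapping}
        net2 = build_network(a2, set2, species="species2")
        net2_rel = relabel_by_homology(net2, inv)
        inter = intersect(net1, net2_rel)
        conservation[cls] = conservation_score(inter, net1)
        for label, net in (
            ("species1", net1),
            ("species2", net2),
            ("intersection", inter),
        ):
            n, e, c = net.stats()
            stats_rows.append(
                {"network": f"{cls}_{label}", "nodes": n, "edges": e, "components": c}
            )
        for label, net in (("species1", net1), ("intersection", inter)):
            sif = out / f"networks/{cls}_{label}.sif"
            gml = out / f"networks/{cls}_{label}.graphml"
            write_sif(net.graph, sif)
            write_graphml(net.graph, gml)
            paths += [sif, gml]
    stats = pd.DataFrame(stats_rows)
    write_tsv(stats, out / "coloc_stats.tsv")
    paths.append(out / "coloc_stats.tsv")

    osc = set().union(*sets.values())
    totals = a1.groupby("chromosome")["gene_id"].count().to_dict()
    cov = chromosome_coverage(a1, osc, totals)
    cov_df = pd.DataFrame(
        sorted(cov.items()), columns=["chromosome", "oscillating_fraction"]
    )
    write_tsv(cov_df, out / "chromosome_coverage_species1.tsv")
    paths.append(out / "chromosome_coverage_species1.tsv")

    summary["conservation_pct"] = conservation
    return paths


def estimate_conservation(config: SyntheticConfig) -> float:
    """Planted-conservation recovery harness: generate a two-species
    assignment, resolve homologs, build/relabel/intersect co-localization
    networks over the full gene universe, and return the conservation score
    as a fraction in [0, 1].

    With large same-chromosome cliques this estimates ``conservation_rho``
    (the per-gene synteny retention probability) up to a vanishing
    (1 − rho)^(m−1) term, m the clique size.
    """
    a1, a2, candidates = gen_two_species_assignment(config)
    hmap = resolve_homologs(candidates.drop(columns=["planted"]))
    set1 = set(a1["gene_id"])
    net1 = build_network(a1, set1, species="species1")
    set2 = {hmap.mapping[g] for g in set1 if g in hmap.mapping}
    net2 = build_network(a2, set2, species="species2")
    inter = intersect(net1, relabel_by_homology(net2, hmap.invert()))
    return inter.n_nodes / net1.n_nodes
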