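"""Seeded synthetic inputs for the whole pipeline.

Real runs of this analysis consume external resources (genome-wide homology
tables, curated PPI snapshots, structure-derived energy tables).  This
module generates stand-ins for all of them with known ground truth, so that
every downstream stage can be exercised and calibrated:

* a two-species gene/chromosome assignment with a *planted* degree of
  chromosomal co-localization conservation (``conservation_rho``),
* one-to-many homolog candidate tables whose true pair always carries the
  strictly best confidence score,
* a PPI graph with *planted* excess connectivity between a focal gene set
  and a designated target subnetwork (``enrichment_delta``),
* per-protein energy-feature tables sampled per period group from reference
  descriptive statistics (``FOLDX_GROUP_STATS``).

One global integer seed drives everything; each sub-generator derives its
own stream from a fixed offset, so modules can be regenerated independently
and outputs are byte-identical across runs for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .periods import PeriodClass, classify_period  # noqa: F401  (re-export)
from .permutation import InteractionReference
from .stability import FEATURES, RESIDUE_COLUMN

#: reference (mean, sd) of each energy feature per period group, as
#: published for structure-covered proteins of the 8-h, 12-h, 24-h and
#: non-oscillating classes; used as the default sampling parameters.
FOLDX_GROUP_STATS: dict[tuple[str, str], tuple[float, float]] = {}

_TABLE_ROWS: dict[str, dict[str, tuple[float, float]]] = {
    "Residue Number": {
        "P8": (224.0, 136.6), "P12": (373.3, 232.1),
        "P24": (321.8, 188.5), "NONOSC": (313.3, 165.5),
    },
    "Delta_G": {
        "P8": (81.91, 133.64), "P12": (13.53, 95.47),
        "P24": (21.64, 125.74), "NONOSC": (29.84, 91.09),
    },
    "H-bonds_Backbone": {
        "P8": (-135.4, 95.49), "P12": (-236.2, 157.46),
        "P24": (-206.0, 104.26), "NONOSC": (-209.4, 121.7),
    },
    "H-bonds_Sidechain": {
        "P8": (-61.66, 56.19), "P12": (-103.98, 65.35),
        "P24": (-87.67, 45.53), "NONOSC": (-89.31, 52.65),
    },
    "Energy_VanderWaals": {
        "P8": (-239.1, 168.5), "P12": (-407.4, 260.7),
        "P24": (-354.5, 191.4), "NONOSC": (-363.0, 211.2),
    },
    "Electrostat_Int": {
        "P8": (-8.291, 9.198), "P12": (-16.011, 9.858),
        "P24": (-13.710, 9.049), "NONOSC": (-14.03, 10.912),
    },
    "Penal_PolarGroups": {
        "P8": (335.0, 232.3), "P12": (541.5, 339.8),
        "P24": (472.6, 255.7), "NONOSC": (486.5, 278.3),
    },
    "Cont_Hydrophobic": {
        "P8": (-311.7, 219.0), "P12": (-542.3, 350.6),
        "P24": (-470.8, 254.0), "NONOSC": (-480.7, 281.7),
    },
    "Penal_VanderWaals": {
        "P8": (19.94, 27.56), "P12": (22.23, 23.03),
        "P24": (23.46, 53.31), "NONOSC": (24.85, 21.93),
    },
    "VanderWaals_Torsion": {
        "P8": (126.9, 91.05), "P12": (223.1, 151.23),
        "P24": (188.2, 100.39), "NONOSC": (191.1, 109.7),
    },
    "Backbone_VanderWaals": {
        "P8": (352.1, 228.7), "P12": (532.7, 331.3),
        "P24": (467.9, 263.5), "NONOSC": (485.1, 258.7),
    },
    "Water Bonds": {
        "P8": (0.237, 0.451), "P12": (0.550, 0.742),
        "P24": (0.745, 1.227), "NONOSC": (0.693, 1.024),
    },
    "Electrostatic_HelixDipole": {
        "P8": (8.414, 8.079), "P12": (12.091, 9.241),
        "P24": (11.769, 11.938), "NONOSC": (12.04, 8.639),
    },
    "Cost_PeptideBond": {
        "P8": (-3.399, 3.684), "P12": (-5.705, 5.276),
        "P24": (-5.401, 4.399), "NONOSC": (-5.511, 6.128),
    },
    "Electrostat_Precomplex": {
        "P8": (0.0, 0.0), "P12": (0.0, 0.0),
        "P24": (-1.373, 5.422), "NONOSC": (-3.606, 7.590),
    },
    "Interaction_BoundMetals": {
        "P8": (0.0, 0.0), "P12": (-0.053, 0.288),
        "P24": (-0.011, 0.129), "NONOSC": (0.0, 0.0),
    },
    "Energy_Ionisation": {
        "P8": (-1.984, 4.856), "P12": (-8.547, 14.491),
        "P24": (-4.628, 12.589), "NONOSC": (-6.075, 15.55),
    },
    "Entropy_Complex": {
        "P8": (0.865, 0.876), "P12": (1.379, 1.0124),
        "P24": (1.215, 0.951), "NONOSC": (1.108, 0.820),
    },
}
for _feat, _groups in _TABLE_ROWS.items():
    for _g, _ms in _groups.items():
        FOLDX_GROUP_STATS[(_g, _feat)] = _ms

# fixed per-sub-generator offsets mixed with the global seed
_STREAMS = {"assignment": 11, "candidates": 13, "ppi": 17, "energy": 19, "sets": 23}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic-data generator.

    Defaults mirror the scale of the motivating study: a ~3000-gene
    universe on 20 chromosomes, period-class sets of 56 / 205 / 2054 genes
    (8-h / 12-h / 24-h), moderate co-localization conservation, and energy
    parameters taken from the published group statistics.
    """

    seed: int = 0
    n_chromosomes_per_species: int = 20
    genes_per_chromosome: int | list[int] = 150
    #: species-2 chromosome count; None resolves to a partition fine enough
    #: that dispersed (non-conserved) genes never co-localize by chance
    n_chromosomes_species2: int | None = None
    set_sizes: dict[str, int] = field(
        default_factory=lambda: {"P8": 56, "P12": 205, "P24": 2054}
    )
    conservation_rho: float = 0.6
    multi_map_rate: float = 0.2
    ppi_n_nodes: int = 200
    ppi_edge_prob: float = 0.02
    enrichment_delta: float = 5.0
    ncrg_size: int = 20
    energy_params: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(FOLDX_GROUP_STATS)
    )
    energy_n_per_group: dict[str, int] = field(
        default_factory=lambda: {"P8": 56, "P12": 205, "P24": 2054, "NONOSC": 350}
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities ------------------------------------------------
    @property
    def genes_per_chromosome_list(self) -> list[int]:
        g = self.genes_per_chromosome
        if isinstance(g, int):
            return [g] * self.n_chromosomes_per_species
        return list(g)

    @property
    def n_genes(self) -> int:
        return sum(self.genes_per_chromosome_list)

    @property
    def n_chrom2(self) -> int:
        if self.n_chromosomes_species2 is not None:
            return self.n_chromosomes_species2
        return self.n_chromosomes_per_species + max(self.genes_per_chromosome_list) + 1

    def validate(self) -> None:
        for name in ("conservation_rho", "multi_map_rate", "ppi_edge_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.enrichment_delta < 0:
            raise ValueError("enrichment_delta must be non-negative")
        gpc = self.genes_per_chromosome_list
        if len(gpc) != self.n_chromosomes_per_species or any(g < 1 for g in gpc):
            raise ValueError("genes_per_chromosome must give >= 1 gene per chromosome")
        if sum(self.set_sizes.values()) > self.n_genes:
            raise ValueError(
                f"set sizes ({sum(self.set_sizes.values())}) exceed the "
                f"gene universe ({self.n_genes})"
            )
        if any(k not in ("P8", "P12", "P24") for k in self.set_sizes):
            raise ValueError("set_sizes keys must be P8/P12/P24")
        if self.n_chrom2 - 1 < max(gpc):
            raise ValueError(
                "species-2 chromosome count too small to disperse a full "
                "species-1 chromosome without collisions"
            )
        for (g, f), (m, s) in self.energy_params.items():
            if s < 0:
                raise ValueError(f"negative sd for energy_params[({g}, {f})]")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["energy_params"] = {
            g: {f: list(ms) for (gg, f), ms in self.energy_params.items() if gg == g}
            for g in {g for g, _ in self.energy_params}
        }
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "energy_params" in raw:
            flat = {}
            for g, feats in raw["energy_params"].items():
                for f, ms in feats.items():
                    flat[(g, f)] = (float(ms[0]), float(ms[1]))
            raw["energy_params"] = flat
        known = cls.__dataclass_fields__.keys()
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def gen_two_species_assignment(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the two-species assignment and homolog-candidate tables.

    Species-1 genes fill the configured chromosomes and receive period-class
    labels by drawing the configured set sizes from the universe.  Each
    species-1 chromosome has one syntenic partner chromosome in species 2
    (an injective partner map); a gene's true homolog lands on that partner
    with probability ``conservation_rho`` and is otherwise dispersed — each
    dispersed gene of a chromosome to a *distinct* non-partner species-2
    chromosome, so broken synteny never re-creates co-localization by
    chance.  A ``multi_map_rate`` fraction of genes additionally receives
    1–3 decoy candidates; the true candidate always has the strictly best
    confidence score (1 vs 0) and is flagged in the hidden ``planted``
    column of the returned candidate table.

    Returns ``(assignment_sp1, assignment_sp2, candidates)``.
    """
    rng = _rng(config.seed, "assignment")
    gpc = config.genes_per_chromosome_list
    n = config.n_genes

    ids1 = [f"mmu_g{i:05d}" for i in range(n)]
    ids2 = [f"hsa_g{i:05d}" for i in range(n)]
    chrom_idx = np.repeat(np.arange(config.n_chromosomes_per_species), gpc)

    # period-class labels: disjoint draws of the configured sizes
    labels = np.array(["NONE"] * n, dtype=object)
    order = rng.permutation(n)
    pos = 0
    for cls in ("P8", "P12", "P24"):
        k = config.set_sizes.get(cls, 0)
        labels[order[pos : pos + k]] = cls
        pos += k

    # species-2 placement
    k2 = config.n_chrom2
    partner = rng.permutation(k2)[: config.n_chromosomes_per_species]
    conserved = rng.random(n) < config.conservation_rho
    chrom2_idx = np.empty(n, dtype=int)
    for c in range(config.n_chromosomes_per_species):
        members = np.where(chrom_idx == c)[0]
        conserved_m = conserved[members]
        chrom2_idx[members[conserved_m]] = partner[c]
        n_disp = int((~conserved_m).sum())
        if n_disp:
            pool = np.delete(np.arange(k2), partner[c])
            chrom2_idx[members[~conserved_m]] = rng.choice(
                pool, size=n_disp, replace=False
            )

    a1 = pd.DataFrame(
        {
            "gene_id": ids1,
            "species": "species1",
            "chromosome": [f"chr{c + 1}" for c in chrom_idx],
            "period_class": labels,
        }
    )
    a2 = pd.DataFrame(
        {
            "gene_id": ids2,
            "species": "species2",
            "chromosome": [f"chr{c + 1}" for c in chrom2_idx],
            "period_class": labels,
        }
    )

    crng = _rng(config.seed, "candidates")
    rows: list[tuple] = []
    multi = crng.random(n) < config.multi_map_rate
    for i in range(n):
        rows.append(
            (
                ids1[i],
                ids2[i],
                1.0,
                round(float(crng.uniform(50, 100)), 2),
                round(float(crng.uniform(60, 100)), 2),
                round(float(crng.uniform(60, 100)), 2),
                round(float(crng.uniform(0.0, 0.3)), 4),
                True,
            )
        )
        if multi[i]:
            n_decoys = int(crng.integers(1, 4))
            choices = crng.integers(0, n - 1, size=n_decoys)
            for c in choices:
                j = int(c) + (1 if c >= i else 0)  # skip the true target
                rows.append(
                    (
                        ids1[i],
                        ids2[j],
                        0.0,
                        round(float(crng.uniform(0, 100)), 2),
                        round(float(crng.uniform(20, 100)), 2),
                        round(float(crng.uniform(20, 100)), 2),
                        round(float(crng.uniform(0.0, 2.0)), 4),
                        False,
                    )
                )
    candidates = pd.DataFrame(
        rows,
        columns=[
            "query_id",
            "target_id",
            "confidence",
            "goc",
            "target_pid",
            "query_pid",
            "dn_ds",
            "planted",
        ],
    )
    return a1, a2, candidates


def gene_sets_from_assignment(assignment: pd.DataFrame) -> dict[str, set[str]]:
    """Period-class gene sets ({P8, P12, P24} → id set) from an assignment."""
    out: dict[str, set[str]] = {}
    for cls in ("P8", "P12", "P24"):
        ids = set(assignment.loc[assignment["period_class"] == cls, "gene_id"])
        if ids:
            out[cls] = ids
    return out


def gen_ppi(
    config: SyntheticConfig,
    focal_set: set[str],
    target_set: set[str],
) -> InteractionReference:
    """Erdős–Rényi PPI background with planted focal↔target enrichment.

    Every unordered node pair is an edge with probability ``ppi_edge_prob``,
    except pairs with one node in ``focal_set`` and the other in
    ``target_set``, which use min(1, ppi_edge_prob × (1 + enrichment_delta)).
    The node universe is the union of the two (disjoint) sets padded with
    filler proteins up to ``ppi_n_nodes``.  The graph is simple and
    undirected with no self-loops; isolated nodes stay in the universe.
    """
    if focal_set & target_set:
        raise ValueError("focal and target sets must be disjoint")
    rng = _rng(config.seed, "ppi")
    nodes = sorted(focal_set) + sorted(target_set)
    n_fill = config.ppi_n_nodes - len(nodes)
    if n_fill < 0:
        raise ValueError("ppi_n_nodes smaller than |focal| + |target|")
    nodes += [f"prot_{i:05d}" for i in range(n_fill)]
    n = len(nodes)
    focal_idx = np.zeros(n, dtype=bool)
    focal_idx[: len(focal_set)] = True
    target_idx = np.zeros(n, dtype=bool)
    target_idx[len(focal_set) : len(focal_set) + len(target_set)] = True

    iu, ju = np.triu_indices(n, k=1)
    cross = (focal_idx[iu] & target_idx[ju]) | (target_idx[iu] & focal_idx[ju])
    if np.isinf(config.enrichment_delta):  # limit case: cap reached
        p_cross = 1.0
    else:
        p_cross = min(1.0, config.ppi_edge_prob * (1.0 + config.enrichment_delta))
    p = np.where(cross, p_cross, config.ppi_edge_prob)
    keep = rng.random(len(iu)) < p

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(nodes[i], nodes[j], n_records=1)
    return InteractionReference(graph=g, provenance="synthetic Erdős–Rényi + planted")


def gen_energy_table(
    config: SyntheticConfig, n_per_group: dict[str, int] | None = None
) -> pd.DataFrame:
    """Sample a per-protein energy-feature table group by group.

    Each feature is drawn independently from a normal law with the
    configured (mean, sd) of its (group, feature) pair; Residue Number is
    rounded to an integer with a floor of 30 residues.  Feature
    correlations are *not* modelled (a documented limitation).
    """
    n_per_group = n_per_group or config.energy_n_per_group
    rng = _rng(config.seed, "energy")
    frames = []
    for group in sorted(n_per_group, key=lambda g: (["P8", "P12", "P24", "NONOSC"] + sorted(n_per_group)).index(g)):
        n = n_per_group[group]
        data: dict[str, object] = {
            "protein_id": [f"{group}_{i:05d}" for i in range(n)],
            "group": group,
        }
        for feat in FEATURES:
            key = (group, feat)
            if key not in config.energy_params:
                raise ValueError(f"energy_params missing ({group}, {feat})")
            mean, sd = config.energy_params[key]
            vals = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, mean)
            if feat == RESIDUE_COLUMN:
                vals = np.maximum(np.rint(vals), 30).astype(int)
            data[feat] = vals
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)
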