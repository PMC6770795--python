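"""Group comparison of protein electrochemical (stability) features.

Proteins encoded by oscillating genes carry per-structure energy terms from
an empirical stability force field (solvation, van der Waals, H-bond,
electrostatic and entropy components, plus chain length as Residue Number).
Because these terms are heavy-tailed and chain-length dependent, the
comparisons across period groups are rank-based throughout:

* Kruskal–Wallis across groups, optionally after residualizing the
  rank-transformed feature against the rank-transformed Residue Number
  (a rank-based reading of "chain length as covariate" — larger proteins
  accumulate larger energy totals in every term);
* Dunn's post-hoc z for each group pair, with Benjamini–Hochberg FDR
  adjustment across the pairs within each feature;
* tie-aware Spearman correlation matrices between features.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: the 18 per-protein energy features, column names as they appear on disk
FEATURES = [
    "Residue Number",
    "Delta_G",
    "H-bonds_Backbone",
    "H-bonds_Sidechain",
    "Energy_VanderWaals",
    "Electrostat_Int",
    "Penal_PolarGroups",
    "Cont_Hydrophobic",
    "Penal_VanderWaals",
    "VanderWaals_Torsion",
    "Backbone_VanderWaals",
    "Water Bonds",
    "Electrostatic_HelixDipole",
    "Cost_PeptideBond",
    "Electrostat_Precomplex",
    "Interaction_BoundMetals",
    "Energy_Ionisation",
    "Entropy_Complex",
]

GROUPS = ["P8", "P12", "P24", "NONOSC"]

RESIDUE_COLUMN = "Residue Number"


def _group_values(table: pd.DataFrame, column: str) -> dict[str, np.ndarray]:
    if "group" not in table.columns:
        raise ValueError("table lacks a 'group' column")
    if column not in table.columns:
        raise ValueError(f"unknown feature column {column!r}")
    out = {}
    for g, sub in table.groupby("group", sort=False):
        out[str(g)] = np.asarray(sub[column], dtype=float)
    # deterministic group order
    return {g: out[g] for g in sorted(out, key=lambda g: (GROUPS + sorted(out)).index(g))}


def descriptive_table(table: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Per-(feature, group) sample mean, SD (n−1 denominator) and n.

    Every group must contribute at least two rows.
    """
    features = features or [c for c in FEATURES if c in table.columns]
    sizes = table.groupby("group").size()
    if (sizes < 2).any() or sizes.empty:
        raise ValueError("every group needs >= 2 rows for descriptive statistics")
    rows = []
    for feat in features:
        for g, vals in _group_values(table, feat).items():
            rows.append(
                {
                    "feature": feat,
                    "group": g,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)),
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)


def _residualize_ranks(y: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    ry = stats.rankdata(y)
    rc = stats.rankdata(covariate)
    design = np.column_stack([np.ones_like(rc), rc])
    beta, *_ = np.linalg.lstsq(design, ry, rcond=None)
    return ry - design @ beta


def kw_test(
    table: pd.DataFrame, feature: str, adjust_for_residues: bool = False
) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and p for a feature across groups.

    With ``adjust_for_residues`` the feature is rank-transformed,
    residualized by least squares against the rank-transformed Residue
    Number, and the test runs on the residuals (χ² reference with k−1 df
    throughout).  A constant covariate leaves the result unchanged.  If all
    values are identical across groups the degenerate answer (H=0, p=1) is
    returned.
    """
    groups = _group_values(table, feature)
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 members each")
    if adjust_for_residues:
        y = np.asarray(table[feature], dtype=float)
        cov = np.asarray(table[RESIDUE_COLUMN], dtype=float)
        resid = _residualize_ranks(y, cov)
        tmp = table[["group"]].copy()
        tmp["__resid__"] = resid
        groups = _group_values(tmp, "__resid__")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        # all values identical across groups: no signal by definition
        return 0.0, 1.0
    h, p = stats.kruskal(*groups.values())
    return float(h), float(p)


def kw_table(
    table: pd.DataFrame,
    features: list[str] | None = None,
    adjust_for_residues: bool = False,
) -> pd.DataFrame:
    """KW H and p for every feature; Residue Number is never adjusted
    against itself."""
    features = features or [c for c in FEATURES if c in table.columns]
    rows = []
    for feat in features:
        adj = adjust_for_residues and feat != RESIDUE_COLUMN
        h, p = kw_test(table, feat, adjust_for_residues=adj)
        rows.append({"feature": feat, "H": h, "p": p, "residue_adjusted": adj})
    return pd.DataFrame(rows)


def _dunn_z(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    n_total = len(values)
    ranks = stats.rankdata(values)
    # tie correction: sum of t^3 - t over tied groups of the pooled sample
    _, counts = np.unique(values, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    group_names = list(dict.fromkeys(labels))
    mean_ranks = {g: ranks[labels == g].mean() for g in group_names}
    sizes = {g: int((labels == g).sum()) for g in group_names}
    rows = []
    for g1, g2 in combinations(group_names, 2):
        denom = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        if denom == 0:
            z = 0.0
        else:
            z = (mean_ranks[g1] - mean_ranks[g2]) / denom
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": float(z), "p": float(p)})
    return pd.DataFrame(rows)


def dunn_posthoc(table: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Pairwise Dunn z, raw two-sided p and BH-adjusted p for a feature.

    z_ij = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − ΣT/(12(N−1))) (1/n_i + 1/n_j)]
    on the pooled ranks, with the usual tie correction; the FDR family is
    the set of group pairs within this feature.
    """
    groups = _group_values(table, feature)
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 members each")
    values = np.concatenate(list(groups.values()))
    labels = np.concatenate([np.repeat(g, len(v)) for g, v in groups.items()])
    out = _dunn_z(values, labels)
    out.insert(0, "feature", feature)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def dunn_table(table: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    features = features or [c for c in FEATURES if c in table.columns]
    return pd.concat(
        [dunn_posthoc(table, f) for f in features], ignore_index=True
    )


def spearman_matrix(
    table: pd.DataFrame,
    groups: list[str] | None = None,
    features: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tie-aware Spearman ρ and two-sided p between feature pairs.

    ``groups`` filters rows to a subset of period groups first (e.g.
    oscillating vs non-oscillating panels).  Pairs involving a constant
    column are reported as missing (NaN); the diagonal is 1 with p = 0.
    """
    sub = table if groups is None else table[table["group"].isin(groups)]
    features = features or [c for c in FEATURES if c in sub.columns]
    if len(sub) < 3:
        raise ValueError("need >= 3 rows for a correlation matrix")
    k = len(features)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    cols = [np.asarray(sub[f], dtype=float) for f in features]
    constant = [np.all(c == c[0]) for c in cols]
    for i in range(k):
        if not constant[i]:
            rho[i, i] = 1.0
            pval[i, i] = 0.0
        for j in range(i + 1, k):
            if constant[i] or constant[j]:
                continue
            r, p = stats.spearmanr(cols[i], cols[j])
            rho[i, j] = rho[j, i] = float(r)
            pval[i, j] = pval[j, i] = float(p)
    return (
        pd.DataFrame(rho, index=features, columns=features),
        pd.DataFrame(pval, index=features, columns=features),
    )


@dataclass
class GroupComparisonResult:
    """Bundle of the three analyses over one feature table."""

    descriptive: pd.DataFrame
    kw: pd.DataFrame
    dunn: pd.DataFrame

    def significant_pairs(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.dunn[self.dunn["p_adj"] < alpha].reset_index(drop=True)


def group_comparison(
    table: pd.DataFrame,
    adjust_for_residues: bool = True,
    features: list[str] | None = None,
) -> GroupComparisonResult:
    """Run descriptive statistics, KW and Dunn/FDR over a feature table."""
    return GroupComparisonResult(
        descriptive=descriptive_table(table, features),
        kw=kw_table(table, features, adjust_for_residues=adjust_for_residues),
        dunn=dunn_table(table, features),
    )
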