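"""Rank-based group comparison: KW, Dunn/FDR, Spearman."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as ss
from statsmodels.stats.multitest import multipletests

from harmonics import (
    descriptive_table,
    dunn_posthoc,
    kw_test,
    spearman_matrix,
)


def table_of(groups: dict[str, list[float]], feature="Delta_G") -> pd.DataFrame:
    rows = []
    for g, vals in groups.items():
        for i, v in enumerate(vals):
            rows.append({"protein_id": f"{g}_{i}", "group": g, feature: v})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- descriptive
def test_descriptive_mean_sd():
    tab = table_of({"P8": [0.0, 2.0], "P12": [5.0, 5.0, 5.0]})
    d = descriptive_table(tab, features=["Delta_G"])
    p8 = d[d.group == "P8"].iloc[0]
    assert p8["mean"] == 1.0 and p8["sd"] == pytest.approx(math.sqrt(2))
    p12 = d[d.group == "P12"].iloc[0]
    assert p12["sd"] == 0.0 and p12["n"] == 3


def test_descriptive_rejects_single_member_group():
    with pytest.raises(ValueError):
        descriptive_table(table_of({"P8": [1.0], "P12": [1.0, 2.0]}))


# ------------------------------------------------------------ Kruskal–Wallis
def test_kw_matches_direct_rank_formula():
    """H = 12/(N(N+1)) Σ n_i (R̄_i − R̄)² for untied data."""
    groups = {"P8": [1.0, 2.0], "P12": [3.0, 4.0], "P24": [5.0, 6.0]}
    h, p = kw_test(table_of(groups), "Delta_G")
    n_tot = 6
    ranks = {"P8": [1, 2], "P12": [3, 4], "P24": [5, 6]}
    rbar = (n_tot + 1) / 2
    h_direct = 12 / (n_tot * (n_tot + 1)) * sum(
        len(r) * (np.mean(r) - rbar) ** 2 for r in ranks.values()
    )
    assert h == pytest.approx(h_direct)  # = 32/7 ≈ 4.571
    assert p == pytest.approx(1 - ss.chi2.cdf(h_direct, df=2))


def test_kw_degenerate_identical_values():
    h, p = kw_test(table_of({"P8": [1.0, 1.0], "P12": [1.0, 1.0]}), "Delta_G")
    assert (h, p) == (0.0, 1.0)


def test_kw_constant_covariate_is_noop():
    rng = np.random.default_rng(3)
    tab = table_of({"P8": list(rng.normal(size=8)), "P12": list(rng.normal(1, 1, 8))})
    tab["Residue Number"] = 100
    plain = kw_test(tab, "Delta_G", adjust_for_residues=False)
    adjusted = kw_test(tab, "Delta_G", adjust_for_residues=True)
    assert adjusted == pytest.approx(plain)


def test_kw_adjustment_absorbs_covariate_driven_shift():
    # group shift induced purely through the covariate: adjustment removes it
    rng = np.random.default_rng(5)
    cov = np.concatenate([rng.uniform(30, 200, 40), rng.uniform(200, 500, 40)])
    y = 2.0 * cov + rng.normal(0, 10, 80)
    tab = pd.DataFrame(
        {"group": ["P8"] * 40 + ["P12"] * 40, "Delta_G": y, "Residue Number": cov}
    )
    h_plain, p_plain = kw_test(tab, "Delta_G", adjust_for_residues=False)
    h_adj, p_adj = kw_test(tab, "Delta_G", adjust_for_residues=True)
    assert p_plain < 0.001 and p_adj > 0.05


# ----------------------------------------------------------------------- Dunn
def test_dunn_hand_computed_z():
    tab = table_of({"A": [1.0, 2.0], "B": [3.0, 4.0], "C": [5.0, 6.0]})
    d = dunn_posthoc(tab, "Delta_G")
    z_ac = d[(d.group1 == "A") & (d.group2 == "C")].iloc[0]["z"]
    assert abs(z_ac) == pytest.approx(4 / math.sqrt(3.5), abs=1e-9)  # ≈ 2.138


def test_dunn_identical_groups_all_null():
    tab = table_of({"A": [1.0, 1.0], "B": [1.0, 1.0], "C": [1.0, 1.0]})
    d = dunn_posthoc(tab, "Delta_G")
    assert (d["z"] == 0).all() and (d["p"] == 1).all() and (d["p_adj"] == 1).all()


def _naive_dunn(groups: dict[str, list[float]]) -> dict[tuple[str, str], float]:
    """Independent oracle: ranks by counting, variance from first principles."""
    pooled = [v for vals in groups.values() for v in vals]
    n = len(pooled)

    def naive_rank(v):
        smaller = sum(1 for w in pooled if w < v)
        equal = sum(1 for w in pooled if w == v)
        return smaller + (equal + 1) / 2

    tie_sum = sum(
        t**3 - t for t in (pooled.count(u) for u in set(pooled))
    )
    var = n * (n + 1) / 12 - tie_sum / (12 * (n - 1))
    mean_rank = {g: sum(naive_rank(v) for v in vs) / len(vs) for g, vs in groups.items()}
    out = {}
    for g1, g2 in combinations(groups, 2):
        denom = math.sqrt(var * (1 / len(groups[g1]) + 1 / len(groups[g2])))
        out[(g1, g2)] = (mean_rank[g1] - mean_rank[g2]) / denom if denom else 0.0
    return out


@pytest.mark.parametrize(
    "groups",
    [
        {"A": [1, 2], "B": [3, 4], "C": [5, 6]},
        {"A": [1, 1], "B": [1, 2], "C": [3, 3]},  # heavy ties
        {"A": [5, 1, 3], "B": [2, 4], "C": [6, 7, 8]},
        {"A": [0, 0, 0, 0], "B": [1, 1, 1, 1]},
        {"A": [2, 9], "B": [4, 4, 4], "C": [1, 7, 7]},
        {"A": [1, 2, 3, 4, 5, 6], "B": [1, 2]},
    ],
)
def test_dunn_agrees_with_naive_oracle_small_n(groups):
    """Implementation matches a from-scratch rank/variance computation on
    every configuration of total n ≤ 8 exercised here (ties included)."""
    groups = {g: [float(v) for v in vs] for g, vs in groups.items()}
    oracle = _naive_dunn(groups)
    d = dunn_posthoc(table_of(groups), "Delta_G")
    for _, row in d.iterrows():
        key = (row.group1, row.group2)
        z_expected = oracle.get(key, -oracle.get((key[1], key[0]), np.nan))
        assert row.z == pytest.approx(z_expected, abs=1e-12)
        assert row.p == pytest.approx(2 * ss.norm.sf(abs(z_expected)), abs=1e-12)


# ------------------------------------------------------------------------ BH
def test_bh_step_up_example():
    tab = table_of({"A": [1.0, 2.0], "B": [3.0, 4.0], "C": [5.0, 6.0]})
    d = dunn_posthoc(tab, "Delta_G")
    # adjustment preserves raw ordering and never shrinks p
    assert (d["p_adj"] >= d["p"] - 1e-15).all()
    assert (d["p_adj"] <= 1).all()
    adj = multipletests([0.01, 0.02, 0.9], method="fdr_bh")[1]
    assert list(np.round(adj, 10)) == [0.03, 0.03, 0.9]


@settings(derandomize=True, max_examples=80)
@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8))
def test_bh_matches_sort_based_oracle(raw):
    """statsmodels BH equals the direct step-up computation."""
    m = len(raw)
    order = np.argsort(raw)
    stepped = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        k = m - rank_from_top
        running = min(running, raw[idx] * m / k)
        stepped[idx] = running
    adj = multipletests(raw, method="fdr_bh")[1]
    assert np.allclose(adj, stepped)


# ------------------------------------------------------------------- Spearman
def test_spearman_monotone_invariance_and_example():
    x = np.linspace(0, 3, 20)
    tab = pd.DataFrame(
        {"group": "P8", "Delta_G": x, "Entropy_Complex": np.exp(x)}
    )
    rho, p = spearman_matrix(tab, features=["Delta_G", "Entropy_Complex"])
    assert rho.loc["Delta_G", "Entropy_Complex"] == pytest.approx(1.0)

    tab2 = pd.DataFrame(
        {"group": "P8", "Delta_G": [1.0, 2.0, 3.0], "Entropy_Complex": [2.0, 1.0, 3.0]}
    )
    rho2, _ = spearman_matrix(tab2, features=["Delta_G", "Entropy_Complex"])
    assert rho2.loc["Delta_G", "Entropy_Complex"] == pytest.approx(0.5)


def test_spearman_symmetric_unit_diagonal_constant_missing():
    rng = np.random.default_rng(0)
    tab = pd.DataFrame(
        {
            "group": "P24",
            "Delta_G": rng.normal(size=10),
            "Entropy_Complex": rng.normal(size=10),
            "Water Bonds": 0.0,  # constant column
        }
    )
    feats = ["Delta_G", "Entropy_Complex", "Water Bonds"]
    rho, p = spearman_matrix(tab, features=feats)
    assert np.allclose(rho.values, rho.values.T, equal_nan=True)
    assert rho.loc["Delta_G", "Delta_G"] == 1.0
    assert math.isnan(rho.loc["Delta_G", "Water Bonds"])
    assert math.isnan(rho.loc["Water Bonds", "Water Bonds"])
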