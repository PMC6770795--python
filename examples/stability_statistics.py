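"""Group comparison of protein stability features.

Samples an energy-feature table at the reference group laws (8-h, 12-h,
24-h and non-oscillating proteins), then runs the rank-based battery:
Kruskal–Wallis (chain-length adjusted), Dunn's post hoc with BH-FDR, and a
Spearman correlation matrix.
"""

from harmonics import SyntheticConfig, gen_energy_table, group_comparison, spearman_matrix

cfg = SyntheticConfig(seed=2, set_sizes={})
table = gen_energy_table(cfg, {"P8": 56, "P12": 205, "P24": 500, "NONOSC": 350})

comp = group_comparison(table, adjust_for_residues=True)
print("Kruskal–Wallis (first rows):")
print(comp.kw.head(4).to_string(index=False))
print("\nFDR-significant Dunn contrasts (first rows):")
sig = comp.significant_pairs(alpha=0.05)
print(sig.head(6).to_string(index=False))

rho, _ = spearman_matrix(table, groups=["P8", "P12", "P24"])
print(
    "\nSpearman rho(Energy_VanderWaals, Residue Number) = "
    f"{rho.loc['Energy_VanderWaals', 'Residue Number']:.2f}"
)

# Smaller 8-h proteins drive strong Residue Number and energy-term contrasts
# against the 12-h group; because features are sampled independently here,
# between-feature correlations beyond chance are near zero by construction.
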