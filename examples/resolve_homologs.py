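"""Resolve a small one-to-many homolog table with the priority cascade.

Two mouse queries compete for the same human target; the cascade
(confidence, then GOC, then %IDs, then dN/dS) ranks candidates per query
and the greedy one-to-one assignment lets the loser fall through to its
next-best candidate.
"""

from harmonics import HomologCandidate, mapping_coverage, resolve_homologs

candidates = [
    HomologCandidate("Arntl1_mmu", "ARNTL_hsa", confidence=1, goc=100, dn_ds=0.05),
    HomologCandidate("Arntl1_mmu", "ARNTL2_hsa", confidence=1, goc=75, dn_ds=0.20),
    HomologCandidate("Arntl2_mmu", "ARNTL_hsa", confidence=1, goc=50, dn_ds=0.30),
    HomologCandidate("Arntl2_mmu", "ARNTL2_hsa", confidence=0, goc=80, dn_ds=0.10),
    HomologCandidate("Nr1d1_mmu", "NR1D1_hsa", confidence=1, goc=100),
    HomologCandidate("Orphan_mmu", "NR1D1_hsa", confidence=0),  # loses, no fallback
]

hmap = resolve_homologs(candidates)
for q, t in sorted(hmap.mapping.items()):
    print(f"{q:12s} -> {t}")
print("unmapped:", sorted(hmap.unmapped))
n_mapped, n_total = mapping_coverage(hmap, {c.query_id for c in candidates})
print(f"coverage: {n_mapped}/{n_total} queries resolved")

# Arntl1 keeps ARNTL (higher GOC at equal confidence); Arntl2, whose best
# surviving candidate is gone, falls through to ARNTL2; Orphan loses NR1D1
# to the higher-confidence Nr1d1 and, with no other candidate, is reported
# unmapped rather than imputed.
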