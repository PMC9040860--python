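"""Locus-level comparisons: ortholog protein identity and SNV catalogs.

Mating identity in M. smegmatis is carried by highly polymorphic mid
proteins inside the otherwise conserved esx1 locus: core ortholog pairs
exceed 96.6% amino-acid identity while Mid orthologs drop below ~35%.
Near-identical nucleotide loci are compared by cataloging their few
substitutions with coding effects.
"""

import numpy as np

from dctmosaic import (
    Feature,
    Interval,
    ProteinPair,
    global_identity,
    locus_snv_report,
    mid_identical,
)

# --- protein identity: a conserved core pair vs a polymorphic mid-like pair
rng = np.random.default_rng(0)
AA = "ACDEFGHIKLMNPQRSTVWY"
core = "".join(AA[i] for i in rng.integers(0, 20, 300))
core_ortholog = list(core)
for pos in rng.choice(300, 6, replace=False):  # 2% divergence
    core_ortholog[pos] = AA[(AA.index(core_ortholog[pos]) + 5) % 20]
mid_like = "".join(AA[i] for i in rng.integers(0, 20, 300))

for name, other in [("core ortholog", "".join(core_ortholog)), ("mid-like", mid_like)]:
    r = global_identity(ProteinPair("query", name, core, other))
    print(f"{name}: {r.percent_identity}% identity "
          f"({r.matches}/{r.alignment_columns} columns)")

# --- locus SNV catalog: a 33-kb locus pair differing by 2 substitutions
locus_a = list("".join("ACGT"[i] for i in rng.integers(0, 4, 33_000)))
locus_a[1500:1503] = "GCT"   # Ala codon inside gene1
locus_a[9300:9303] = "CGG"   # Arg codon inside gene2
locus_b = locus_a.copy()
locus_b[1502] = "C"          # GCT -> GCC, still Ala (silent)
locus_b[9301] = "C"          # CGG -> CCG, Arg -> Pro (missense)

features = [Feature("gene1", Interval(1_200, 2_400)),
            Feature("gene2", Interval(9_000, 10_500))]
snvs = locus_snv_report("".join(locus_a), "".join(locus_b), features)
print(f"\n{len(snvs)} SNVs in a {len(locus_a):,}-bp locus:")
for s in snvs:
    print(f"  position {s.position_a + 1} (1-based): {s.base_a}->{s.base_b} "
          f"in {s.feature} ({s.coding_effect})")

# --- the kin-recognition flag: identical mid interval => predicted incompatible
print("\nmid identical (kin, predicted incompatible):",
      mid_identical("".join(locus_a), "".join(locus_b), Interval(20_000, 25_000)))
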