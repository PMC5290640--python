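"""Extract the dihedral feature matrix from a small synthetic corpus.

Builds 20 kinase-like structures (10 active, 10 inactive), writes them as
PDB files, reads them back, aligns each chain to the corpus profile and
measures every phi/psi/chi1/pseudo-dihedral feature. The printed matrix
shape is chains x features; missing cells mark disordered or undefined
angles (chain termini, glycines, deleted activation-segment stretches).
"""

import tempfile
from pathlib import Path

from kinconf.features import extract_matrix, presence_filter
from kinconf.structure import read_pdb
from kinconf.synth import standard_benchmark

corpus = standard_benchmark(seed=1, n_per_class=10)
with tempfile.TemporaryDirectory() as tmp:
    out = corpus.write(Path(tmp) / "corpus")
    structures = [m for p in sorted(out.glob("*.pdb")) for m in read_pdb(p)]

matrix = extract_matrix(structures, corpus.profile)
kept = presence_filter(matrix, threshold=0.75)

print(f"feature matrix: {matrix.values.shape[0]} chains x "
      f"{matrix.values.shape[1]} features")
print(f"missing cells: {int(matrix.values.isna().sum().sum())}")
print(f"features present in >75% of chains: {len(kept)}")
print("\nactivation-segment angles of the first chain (degrees):")
row = matrix.values.iloc[0]
for name in ("Phi_31", "Psi_31", "Pd_30-33", "Pd_34-37"):
    print(f"  {name:10s} {row[name]:8.1f}")
print("\nAn active chain shows extended (strand-like) activation-segment "
      "torsions; an inactive one a short helix (Pd near +50 deg).")
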