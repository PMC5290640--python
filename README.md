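# kinconf

Active/inactive classification of protein kinase conformations from
alignment-indexed dihedral angles.

## The problem

Protein kinases switch between an active conformation — β3-Lys/αC-Glu (K-E)
salt bridge formed, DFG-in, activation segment clear of the substrate
groove — and many inactive ones. Classical annotation rules measure a few
active-site distances or energies and fail whenever the relevant atoms are
disordered, which in the activation segment is common. `kinconf` instead
describes each chain by the torsions the whole domain exposes and lets a
classifier find the discriminating regions.

For a chain aligned to a C-column kinase-domain profile the feature vector
is

- φ_c, ψ_c, χ1_c for every column c (3C features), and
- the Cα pseudo-dihedral Pd_c–(c+3) for every run of four consecutive
  columns (C − 3 features),

i.e. 961 features for the standard 241-column ePK profile. Angles are
encoded on the unit circle, θ → (sin θ, cos θ), and missing angles are
imputed from training statistics, so the classifier covers 100% of chains.
Features measurable in ≤ 75% of the corpus are discarded so coordinate
presence itself cannot become the signal. Feature importance is the average
rank over four single-attribute evaluators (OneR, chi-squared, ReliefF,
gain ratio) across 10 CV folds; classifiers are random forest, naive
Bayes, neural network and SVM, with the forest as the default. The package
also implements the classical geometric rules (K-E bridge < 4 Å,
Brooijmans, ABC, R-spine vdW assembly, Kufareva's template measures), a
log-space chi-squared/Fisher dependence test between predicted conformation
and bridge formation, a two-stage circular PCA for inactive-state
structure, and a synthetic-structure generator with known conformational
truth that serves as the test bed. See `docs/methods.md` for the details.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/classify_benchmark.py` (200 synthetic chains, seed 1):

```
top 5 features by average rank:
Psi_35    4.000
Psi_34    4.100
Psi_30    4.175
Psi_36    4.200
Psi_31    4.900

hold-out accuracy with top-k features:
  feature_added  test_accuracy
k
1        Psi_35           0.99
2        Psi_34           1.00
...
```

Every top-ranked feature sits in the activation segment (columns 30–37 of
the benchmark profile, where the two conformational classes diverge), and a
single torsion already classifies 99% of the held-out chains — the
orientation of the activation segment alone carries the conformational
label. `examples/geometric_baselines.py` prints the contrasting behavior of
the distance/energy rules:

```
method        coverage  accuracy*   (*where determinate)
salt_bridge      0.900      0.939
brooijmans       0.875      0.503
abc              0.945      0.508
rspine           0.815      0.521
```

Each geometric rule abstains on 6–19% of chains (disordered atoms); the ML
classifier abstains on none. And `examples/bridge_dependence.py` runs the
dependence test on the published 2×2 contingency counts:

```
  chi-squared: statistic 227.2, log10 p = -50.61
  Fisher exact (two-sided): log10 p = -48.89
```

— salt-bridge formation and activation-segment orientation are anything but
independent, which is why the αC-helix never needs to be measured
separately.

The same operations are scriptable from a shell via the thin CLI:
`kinconf make-fixtures | extract | baseline | train | predict | pipeline |
inactive-pca` (see `kinconf --help`).

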