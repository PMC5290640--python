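# Methods

## The classification problem

The catalytic domain of eukaryotic protein kinases (ePKs) toggles between an
active conformation — K-E salt bridge formed, DFG-in, activation segment
pulled away from the substrate groove — and a heterogeneous family of
inactive conformations. `kinconf` classifies a crystallized kinase chain as
active or inactive from its backbone and side-chain torsions alone, indexed
by the columns of a curated kinase-domain profile alignment, and provides
the classical geometric rules as baselines.

## Feature construction

Every chain is aligned to the profile (BLOSUM62, affine gaps open 11 /
extend 1, free end gaps; best row by raw score, identity relative to the
row length as acceptance criterion, default ≥ 0.30). Each aligned column
contributes three features — φ, ψ, χ1 in degrees on (−180, 180] — and each
run of four consecutive columns one Cα pseudo-dihedral, giving
3C + max(0, C−3) features: 961 for the default 241-column ePK profile.
Pairwise inter-residue distances (28,920 further candidates at C = 241) are
deliberately excluded; they add overfitting risk without adding descriptive
power over the torsion set.

Torsions follow the IUPAC sign convention (cis = 0°, trans reported +180°);
the implementation was cross-checked against two independent references and
an independent oracle formula to 1e-9°. φ/ψ are only measured across
genuinely bonded neighbors (sequential author numbering); a disordered
stretch leaves the flanking angles missing rather than measured across the
gap. χ1 uses the residue-type-specific γ heavy atom (OG Ser, OG1 Thr,
SG Cys, CG1 Ile/Val, CG otherwise); Gly/Ala have none. Phospho-residues
(SEP/TPO/PTR) and selenomethionine are measured through their parent type.

**Presence filter.** A feature is retained only if measurable in strictly
more than 75% of the dataset (configurable). This prevents the learner from
exploiting mere presence/absence of activation-segment coordinates as a
label proxy.

**Circular encoding and imputation.** Angles are embedded on the unit
circle, θ → (sin θ, cos θ), before any linear machinery (PCA, classifiers).
Missing cells are imputed with the per-feature mean of the observed
(sin, cos) values — the circular-mean direction shrunk by the resultant
length, a neutral point for a linear model. Imputation statistics are
learned on training data and stored in the model, so prediction never
abstains; rows whose model features are all imputed are flagged
`low_information` instead. This is what makes the ML path's coverage 1.0
while every geometric baseline abstains on disordered chains.

## Geometric baselines

All motif positions are profile columns, configurable per corpus
(`MotifConfig.from_pka` translates PKA numbering — K72, E91, D184-F185-G186 —
through the reference row). Semantics:

- **K-E salt bridge**: min over Glu Oε1/Oε2 of the distance to Lys Nζ;
  bridged iff strictly < 4.0 Å.
- **Brooijmans**: bridged AND hinge-donor backbone N to DFG-Phe Cα distance
  consistent with the published "soft" 15 Å cutoff. We read "soft" as a band:
  ≤ 14 Å active-consistent, ≥ 16 Å forces inactive, inside the band the
  bridge decides. Band configurable. The hinge-donor column itself is not
  fixed by the literature; it defaults to PKA 123.
- **ABC**: αC-in iff ‖Cα(αC-Glu) − Cα(DFG-Phe)‖ strictly < 10.5 Å; DFG-in
  iff three configured Cα pseudo-dihedrals fall in configured circular
  ranges; active only when both hold. The numeric ranges belong to the cited
  method's publication and are therefore config-supplied, not hard-coded;
  the synthetic benchmark centers them (±40°) on its active template.
- **R-spine**: four spine residues in stack order (default PKA
  L106-L95-F185-Y164); each adjacent pair's side-chain heavy atoms are summed
  over 12-6 Lennard-Jones terms (Lorentz–Berthelot combining; generic
  per-element r_min/ε table, overridable) and the spine is assembled iff
  every pair energy is strictly below −1.5 kcal/mol — the conjunctive, i.e.
  stricter, reading.
- **Kufareva measures**: after least-squares Cα superposition on all shared
  columns, O_phe sums the cosines between corresponding Cα-Cβ, Cβ-Cγ,
  Cγ-Cδ1, Cγ-Cδ2 bond vectors of the DFG-Phe; P_phe is the Cα displacement.
  The combined DFG-in score built from them has no public functional form
  and is not computed.

Every rule returns *indeterminate* when a required atom is missing.
Consensus labeling returns a label only when all determinate verdicts agree
(disagreements, settled by manual curation in the original corpus work,
stay unlabeled here).

## Feature selection and classifiers

Four single-attribute evaluators score every retained feature on the
training part of each of 10 stratified CV folds; scores become ordinal ranks
(1 = best, ties broken by the canonical feature enumeration order) and ranks
are averaged over evaluators × folds:

- **OneR**: accuracy of the best single-feature rule over 10 equal-width
  bins.
- **Chi-squared**: Pearson statistic of the binned feature vs class.
- **Gain ratio**: information gain over split information, same bins.
- **ReliefF**: k = 10 neighbors, all instances, circular distance
  min(|Δ|, 360−|Δ|)/180.

Binning operates on *untangled* angles — each value re-expressed as its
signed circular deviation from the feature's circular mean — so equal-width
bins never split a population across the ±180° seam. CFS (greedy forward
search on the merit k·r̄cf / √(k + k(k−1)·r̄ff), absolute Pearson
correlations on untangled imputed angles) returns a subset and is reported
separately from the rank average, since it does not produce per-feature
ranks. Class correlations below the ~2σ sampling floor (2/√n) are zeroed so
chance correlations cannot grow the subset on uninformative data.

Classifiers are scikit-learn estimators on the encoded features: random
forest (default 250 trees, √d features), Gaussian naive Bayes, an MLP
(one hidden layer of 50), and an SVM (RBF; scores from the decision
function through a logistic map). Grid search is exhaustive over a
configurable grid (default for the forest: trees ∈ {50, 100, 250, 500},
max-features ∈ {√d, log₂d, 0.1d}) by mean CV accuracy, ties resolved toward
fewer trees then lexicographically.

## Dependence test and circular PCA

The 2×2 dependence test (predicted conformation × bridge formation) uses
Pearson chi-squared (closed form, df = 1, upper tail via the normal-tail
identity sf = 2Φ(−√x) so p-values far below double underflow remain exact
in log space) and a two-sided Fisher exact test by the point-probability
rule: hypergeometric log-pmfs summed over all tables no more probable than
the observed one, with a 1e-7 relative slack absorbing floating-point ties.
The Fisher implementation reproduces exact rational enumeration to 1e-12
over every table with N ≤ 40 and agrees with independent implementations
on large tables.

Two-stage PCA runs on the centered (no variance scaling — sin/cos pairs
already share a scale) circular encoding; a feature's weight is the maximum
over the first three components of the Euclidean norm of its (sin, cos)
loading pair, so each angle is scored once. The top 10 features (default)
are kept and PCA re-run on the restriction to confirm the pattern is not an
artifact of discarded features. No clustering algorithm is applied; on
planted synthetic structure a silhouette score serves as the test statistic.

## The synthetic corpus

The generator is first-class, tested code and defines the package's study
conditions. Chains are built from internal coordinates (N-Cα 1.458 Å,
Cα-C 1.525 Å, C-N 1.329 Å; angles 111.2°/116.2°/121.7°; ω = 180°) by NeRF
placement, so measured torsions equal prescribed targets to 1e-6° — the
round-trip that validates the measurement code. Side chains carry Cβ and
the γ heavy atom (enough for χ1), Phe additionally Cδ1/Cδ2, Glu a full
carboxylate; the β3-Lys gets an Nζ placed at a class-coupled distance from
the αC-Glu Oε1 (active 3.2 ± 0.25 Å, inactive 8.0 ± 0.8 Å, 8% class flips)
so the salt-bridge baseline has realistic signal and error.

The standard benchmark: 60-column profile, 300 + 300 chains, seed 1.
Both class templates share a helical scaffold (φ,ψ = −63,−42; χ1 = −60) and
differ only at 8 contiguous activation-segment columns (30–37): extended
(−120, +135) in the active class vs a short helix (−57, −47) in the
inactive class — the DFG-in vs 1½-turn-helix contrast. Wrapped-normal noise
σ = 15° on every angle; with probability 0.10 per chain a 3-residue stretch
inside the disorder-prone span (28–39) is deleted; each residue loses its
side chain with probability 0.05. Sample sizes, noise and missingness were
chosen once as a desk-scale analogue of a curated crystal-structure corpus
(hundreds of labeled chains, activation-segment disorder in a minority of
entries) and are not tuned per experiment.

**What the benchmark does and does not emulate.** It reproduces the features
the method actually consumes — class-divergent activation-segment torsions,
angular noise, realistic missingness patterns, a class-coupled salt bridge —
and so supports the qualitative claims: planted features dominate the rank
aggregation, one feature already classifies > 90%, a handful saturate
≥ 99%, ~200 training rows suffice, ML coverage is 1.0 while every geometric
baseline abstains on part of the corpus. It does *not* reproduce the 3D
packing of a real kinase: inter-motif *distances* (hinge-to-DFG,
αC-Glu-to-DFG-Phe) carry no class signal in the synthetic geometry, so the
Brooijmans and ABC rules sit near chance accuracy there even though their
abstention behavior (the quantity under comparison) is faithful. Published
accuracies on the real 5,131-chain PDB corpus are consequently not
reproduced here — they require that corpus and its manual curation.

## Numerical choices and degenerate inputs

- Angles live on (−180, 180]; wrapping maps −180 to +180.
- Torsions of coincident/collinear points return missing, never raise.
- Altloc resolution: highest occupancy, ties to the smaller altloc
  identifier; at most one atom per (residue, atom name).
- Only the first model of a multi-model entry is read by default.
- Resolution filtering is strict (< cutoff) and drops entries with no
  recorded resolution.
- Rank ties, grid-search ties and best-row ties all have documented
  deterministic tie-breaks; every stochastic step takes an explicit seed.

## Known limitations

- The curated 241-column ePK profile is not distributable with the package;
  the profile is a required input. Column↔PKA offsets are profile-specific
  and validated only against the supplied reference row.
- CFS merit uses absolute Pearson correlation rather than symmetric
  uncertainty; on strongly non-monotone feature-class relationships the
  subset may differ from discretization-based CFS variants.
- The R-spine energy uses a generic per-element LJ table, not a force
  field; only relative contact strength vs the −1.5 kcal/mol convention is
  meaningful.
- Consensus labeling on the synthetic benchmark is dominated by the
  distance-based rules' lack of signal there; pipelines on synthetic
  corpora should use the generator's truth labels (the CLI does so when
  `labels.tsv` is present).
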