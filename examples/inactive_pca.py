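"""Two-stage circular PCA of inactive-like structures with planted rotamers.

Two groups share an identical backbone but differ in the chi1 rotamer at
five columns (gauche- vs trans), mimicking kinase-group-specific side-chain
orientations. PCA on the (sin, cos) encoding finds those chi1 features as
the top-weighted directions, and the stage-2 PC1/PC2 plane separates the
groups cleanly.
"""

import numpy as np
from sklearn.metrics import silhouette_score

from kinconf.features import encode_circular, extract_matrix, presence_filter
from kinconf.stats import two_stage_pca
from kinconf.synth import ConformationTemplate, generate_corpus

SEQ = "MSLTVDRLEQLRNDKVLTRESEYLVMQLSDFGLSRDELWEQIDTMENLRSKVTDLEQWIR"
ROTAMER_COLS = [10, 18, 25, 41, 52]

base = np.zeros((60, 3))
base[:, 0], base[:, 1], base[:, 2] = -63.0, -42.0, -60.0
flipped = base.copy()
for col in ROTAMER_COLS:
    flipped[col - 1, 2] = 180.0

common = dict(residue_types=SEQ, activation_span=(1, 60), noise_sigma=8.0)
corpus = generate_corpus(
    ConformationTemplate(label="active", targets=base, **common),
    ConformationTemplate(label="inactive", targets=flipped, **common),
    n_per_class=60, seed=4,
)

matrix = extract_matrix(corpus.structures, corpus.profile)
enc = encode_circular(matrix, presence_filter(matrix))
stage1, stage2, top = two_stage_pca(enc, n_top_features=10)

print("planted chi1 columns:", ROTAMER_COLS)
print("top-10 features by stage-1 weight:")
for name in top:
    print(f"  {name:10s} weight {stage1.feature_weights[name]:.3f}")

groups = (corpus.labels.loc[matrix.values.index] == "active").to_numpy()
sil = silhouette_score(stage2.projections[["PC1", "PC2"]].to_numpy(), groups)
print(f"\nstage-2 PC1/PC2 silhouette between groups: {sil:.3f}")
print("Side-chain rotamers, not backbone angles, dominate the variance — "
      "the groups separate in the principal-component plane.")
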