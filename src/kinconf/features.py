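"""Alignment-indexed dihedral featurization of kinase chains.

Each profile column contributes three features — the backbone φ and ψ and the
first side-chain torsion χ1 of the residue mapped to that column — and every
run of four consecutive columns contributes one Cα pseudo-dihedral. For the
default 241-column ePK profile this yields 241*3 + 238 = 961 features.
Pairwise residue distances are deliberately not featurized: the 241·240/2 =
28,920 extra columns would invite overfitting for no descriptive gain.

Angles are degrees in (-180, 180]. A cell is missing when any defining atom
is absent (disorder), the column is unmapped, the residue is a chain
terminus (φ of the first residue, ψ of the last), or the residue type has no
χ1 (Gly, Ala). Missingness is first-class: the presence filter and the
legacy baselines consume it, and the circular encoder imputes over it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .geometry import torsion
from .profiles import ColumnMap, Profile, align_chain
from .structure import Chain, StructureModel, get_atom

__all__ = [
    "AngleFeature",
    "FeatureMatrix",
    "EncodedMatrix",
    "CHI1_GAMMA_ATOM",
    "phi_psi_chi1",
    "pseudo_dihedral",
    "enumerate_features",
    "extract_matrix",
    "presence_filter",
    "encode_circular",
    "excluded_pairwise_distance_count",
]

# residue-type-specific heavy atom defining chi1 (N-CA-CB-gamma)
CHI1_GAMMA_ATOM = {
    "SER": "OG",
    "THR": "OG1",
    "CYS": "SG",
    "ILE": "CG1",
    "VAL": "CG1",
}
NO_CHI1 = {"GLY", "ALA"}


@dataclass(frozen=True)
class AngleFeature:
    """One named angle feature tied to profile column(s)."""

    kind: Literal["phi", "psi", "chi1", "pseudo"]
    columns: tuple[int, ...]  # 1 column, or 4 consecutive for pseudo

    def __post_init__(self):
        if self.kind == "pseudo":
            if len(self.columns) != 4 or any(
                b - a != 1 for a, b in zip(self.columns, self.columns[1:])
            ):
                raise ValueError("pseudo feature must span 4 consecutive columns")
        elif len(self.columns) != 1:
            raise ValueError(f"{self.kind} feature must reference exactly 1 column")

    @property
    def name(self) -> str:
        c = self.columns
        if self.kind == "phi":
            return f"Phi_{c[0]}"
        if self.kind == "psi":
            return f"Psi_{c[0]}"
        if self.kind == "chi1":
            return f"Chi1_{c[0]}"
        return f"Pd_{c[0]}-{c[3]}"


@dataclass
class FeatureMatrix:
    """Chains x angle-features table with an explicit presence mask."""

    features: list[AngleFeature]
    values: pd.DataFrame  # rows indexed by (structure_id, chain_id); NaN = missing
    labels: pd.Series | None = None  # optional per-row 'active'/'inactive'

    def __post_init__(self):
        expected = [f.name for f in self.features]
        if list(self.values.columns) != expected:
            raise ValueError("value columns do not match the feature list")

    @property
    def mask(self) -> pd.DataFrame:
        """True where a measurement is present."""
        return self.values.notna()

    @property
    def n_rows(self) -> int:
        return len(self.values)

    def feature_by_name(self, name: str) -> AngleFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def subset(self, names: Sequence[str]) -> "FeatureMatrix":
        feats = [self.feature_by_name(n) for n in names]
        return FeatureMatrix(
            features=feats, values=self.values[list(names)].copy(), labels=self.labels
        )

    def to_tsv(self, path) -> None:
        df = self.values.copy()
        df.insert(0, "chain_id", [i[1] for i in df.index])
        df.insert(0, "structure_id", [i[0] for i in df.index])
        if self.labels is not None:
            df["label"] = self.labels.values
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        labels = None
        if "label" in df.columns:
            labels_raw = df.pop("label")
        else:
            labels_raw = None
        idx = pd.MultiIndex.from_arrays(
            [df.pop("structure_id"), df.pop("chain_id")], names=["structure_id", "chain_id"]
        )
        df.index = idx
        feats = [_feature_from_name(c) for c in df.columns]
        if labels_raw is not None:
            labels = pd.Series(labels_raw.values, index=idx, name="label")
        return cls(features=feats, values=df, labels=labels)


def _feature_from_name(name: str) -> AngleFeature:
    kind_map = {"Phi": "phi", "Psi": "psi", "Chi1": "chi1"}
    head, _, tail = name.partition("_")
    if head == "Pd":
        a, b = tail.split("-")
        a = int(a)
        return AngleFeature("pseudo", tuple(range(a, a + 4)))
    return AngleFeature(kind_map[head], (int(tail),))


@dataclass
class EncodedMatrix:
    """Unit-circle (sin, cos) encoding of a FeatureMatrix subset.

    Missing cells are imputed (per-feature mean of the observed sin and cos
    values — the circular-mean direction scaled by the resultant length) and
    recorded in ``imputed`` so downstream consumers can flag low-information
    rows.
    """

    feature_names: list[str]
    data: pd.DataFrame  # columns: '<name>:sin', '<name>:cos'
    imputed: pd.DataFrame  # same shape as the source subset; True where imputed
    imputation_stats: dict[str, tuple[float, float]]  # name -> (mean sin, mean cos)

    @property
    def n_rows(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# per-residue angle measurement


def _xyz(residue, atom_name):
    a = get_atom(residue, atom_name)
    return None if a is None else a.xyz


def _sequential(res_a, res_b) -> bool:
    """True when res_b directly follows res_a in the polypeptide."""
    return res_b.seqnum == res_a.seqnum + 1 or (
        res_b.seqnum == res_a.seqnum and res_b.icode > res_a.icode
    )


def phi_psi_chi1(chain: Chain, res_index: int):
    """Backbone φ, ψ and side-chain χ1 of one residue (each may be None).

    φ = C(i-1)-N(i)-Cα(i)-C(i); ψ = N(i)-Cα(i)-C(i)-N(i+1);
    χ1 = N-Cα-Cβ-γ with the residue-type-specific γ heavy atom. Neighbors
    must be sequential in author numbering — a gap of missing residues breaks
    the peptide bond and the flanking φ/ψ are reported missing rather than
    measured across the gap.
    """
    res = chain.residues[res_index]
    n = _xyz(res, "N")
    ca = _xyz(res, "CA")
    c = _xyz(res, "C")

    phi = psi = chi1 = None

    if res_index > 0:
        prev = chain.residues[res_index - 1]
        if _sequential(prev, res):
            c_prev = _xyz(prev, "C")
            if all(p is not None for p in (c_prev, n, ca, c)):
                phi = torsion(c_prev, n, ca, c)

    if res_index + 1 < len(chain.residues):
        nxt = chain.residues[res_index + 1]
        if _sequential(res, nxt):
            n_next = _xyz(nxt, "N")
            if all(p is not None for p in (n, ca, c, n_next)):
                psi = torsion(n, ca, c, n_next)

    parent = res.parent_name3
    if parent not in NO_CHI1:
        gamma_name = CHI1_GAMMA_ATOM.get(parent, "CG")
        cb = _xyz(res, "CB")
        gamma = _xyz(res, gamma_name)
        if all(p is not None for p in (n, ca, cb, gamma)):
            chi1 = torsion(n, ca, cb, gamma)

    return phi, psi, chi1


def pseudo_dihedral(chain: Chain, four_res: Sequence[int]):
    """Torsion through the Cα atoms of four sequential residues, or None."""
    if len(four_res) != 4:
        raise ValueError("pseudo-dihedral requires exactly 4 residue indices")
    residues = [chain.residues[i] for i in four_res]
    if any(b - a != 1 for a, b in zip(four_res, four_res[1:])):
        return None
    for r1, r2 in zip(residues, residues[1:]):
        if not _sequential(r1, r2):
            return None
    cas = [_xyz(r, "CA") for r in residues]
    if any(p is None for p in cas):
        return None
    return torsion(*cas)


# ---------------------------------------------------------------------------
# feature enumeration and matrix assembly


def enumerate_features(profile: Profile) -> list[AngleFeature]:
    """The canonical ordered feature list for a profile: 3C + max(0, C-3)."""
    c = profile.n_columns
    feats: list[AngleFeature] = []
    for col in range(1, c + 1):
        feats.append(AngleFeature("phi", (col,)))
        feats.append(AngleFeature("psi", (col,)))
        feats.append(AngleFeature("chi1", (col,)))
    for col in range(1, c - 2):
        feats.append(AngleFeature("pseudo", (col, col + 1, col + 2, col + 3)))
    return feats


def excluded_pairwise_distance_count(profile: Profile) -> int:
    """How many pairwise Cα distance features the design deliberately omits."""
    c = profile.n_columns
    return c * (c - 1) // 2


def _evaluate_chain(chain: Chain, cmap: ColumnMap, features: list[AngleFeature]) -> list[float]:
    cache: dict[int, tuple] = {}

    def angles_at(res_idx: int):
        if res_idx not in cache:
            cache[res_idx] = phi_psi_chi1(chain, res_idx)
        return cache[res_idx]

    row: list[float] = []
    for f in features:
        value = None
        if f.kind == "pseudo":
            idxs = [cmap.residue_at(c) for c in f.columns]
            if all(i is not None for i in idxs):
                value = pseudo_dihedral(chain, idxs)
        else:
            idx = cmap.residue_at(f.columns[0])
            if idx is not None:
                phi, psi, chi1 = angles_at(idx)
                value = {"phi": phi, "psi": psi, "chi1": chi1}[f.kind]
        row.append(np.nan if value is None else value)
    return row


def extract_matrix(
    structures: Iterable[StructureModel],
    profile: Profile,
    min_identity: float = 0.30,
) -> FeatureMatrix:
    """Align every chain and evaluate the full feature list per accepted chain.

    Chains that fail alignment (too short or identity below threshold) are
    dropped; an empty result raises ValueError.
    """
    features = enumerate_features(profile)
    names = [f.name for f in features]
    rows = {}
    for sm in structures:
        for chain in sm.chains:
            cmap = align_chain(chain, profile, min_identity, structure_id=sm.structure_id)
            if cmap is None:
                continue
            rows[(sm.structure_id, chain.chain_id)] = _evaluate_chain(chain, cmap, features)
    if not rows:
        raise ValueError("no chain aligned to the profile; empty feature matrix")
    idx = pd.MultiIndex.from_tuples(rows.keys(), names=["structure_id", "chain_id"])
    values = pd.DataFrame(list(rows.values()), index=idx, columns=names)
    return FeatureMatrix(features=features, values=values)


def presence_filter(matrix: FeatureMatrix, threshold: float = 0.75) -> list[AngleFeature]:
    """Features measurable in strictly more than ``threshold`` of the rows.

    Activation-segment residues are frequently disordered in crystal
    structures; to keep the classifier from learning mere presence/absence of
    coordinates, a feature must be present in more than 75% (default) of the
    dataset to survive.
    """
    if matrix.n_rows == 0:
        raise ValueError("empty matrix")
    frac = matrix.mask.mean(axis=0)
    return [f for f in matrix.features if frac[f.name] > threshold]


def encode_circular(
    matrix: FeatureMatrix,
    features: Sequence[AngleFeature] | None = None,
    imputation: Literal["circular_mean", "none"] = "circular_mean",
    imputation_stats: dict[str, tuple[float, float]] | None = None,
) -> EncodedMatrix:
    """Encode each angle θ as the unit-circle point (sin θ, cos θ).

    PCA and the classifiers are linear machines; the encoding removes the
    ±180° seam so that -179° and +181° land at the same point. Missing cells
    are imputed with the per-feature mean of the observed (sin, cos) values
    (training-set statistics can be supplied for out-of-sample encoding).
    """
    feats = list(features) if features is not None else matrix.features
    names = [f.name for f in feats]
    sub = matrix.values[names]

    out = {}
    imputed = sub.isna()
    stats: dict[str, tuple[float, float]] = {}
    for name in names:
        theta = np.radians(sub[name].to_numpy(dtype=float))
        s, c = np.sin(theta), np.cos(theta)
        obs = ~np.isnan(theta)
        if imputation_stats is not None and name in imputation_stats:
            ms, mc = imputation_stats[name]
        elif obs.any():
            ms, mc = float(np.mean(s[obs])), float(np.mean(c[obs]))
        elif imputation == "circular_mean":
            raise ValueError(f"feature {name} has no observed values; filter it first")
        else:
            ms = mc = math.nan
        stats[name] = (ms, mc)
        if imputation == "circular_mean":
            s = np.where(obs, s, ms)
            c = np.where(obs, c, mc)
        out[f"{name}:sin"] = s
        out[f"{name}:cos"] = c

    data = pd.DataFrame(out, index=sub.index)
    return EncodedMatrix(
        feature_names=names, data=data, imputed=imputed, imputation_stats=stats
    )
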