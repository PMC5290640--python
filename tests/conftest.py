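"""Shared fixtures: synthetic corpora, an independent torsion oracle, and
small hand-built chains used across the suite."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from kinconf.features import FeatureMatrix, extract_matrix, presence_filter
from kinconf.profiles import ColumnMap
from kinconf.structure import Atom, Chain, Residue
from kinconf.synth import standard_benchmark


def torsion_oracle(p1, p2, p3, p4) -> float:
    """Independent dihedral formula: angle between plane normals, signed by
    the determinant of (b1, b2, b3). Used only to cross-check the production
    implementation."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    cosang = min(1.0, max(-1.0, cosang))
    ang = math.degrees(math.acos(cosang))
    if np.linalg.det(np.stack([b1, b2, b3])) < 0:
        ang = -ang
    if ang <= -180.0:
        ang += 360.0
    return ang


@pytest.fixture(scope="session")
def oracle():
    return torsion_oracle


def toy_residue(name3: str, seqnum: int, atoms: dict[str, tuple]) -> Residue:
    """Residue from a dict of atom name -> coordinates (element = first letter)."""
    return Residue(
        name3=name3,
        seqnum=seqnum,
        atoms=[Atom(n, n[0], np.asarray(x, dtype=float)) for n, x in atoms.items()],
    )


def identity_map(chain: Chain, structure_id: str = "TOY") -> ColumnMap:
    """Column i+1 <-> residue i, as for a chain built directly from a profile."""
    return ColumnMap(
        chain_ref=(structure_id, chain.chain_id),
        col_to_res={i + 1: i for i in range(len(chain.residues))},
        identity=1.0,
        best_row="PKA",
    )


@pytest.fixture
def make_residue():
    return toy_residue


@pytest.fixture
def make_identity_map():
    return identity_map


@pytest.fixture(scope="session")
def benchmark600():
    """The standard cross-module benchmark corpus: 300 active + 300 inactive,
    15 deg angular noise, activation-segment disorder, seed 1."""
    return standard_benchmark(seed=1)


@pytest.fixture(scope="session")
def benchmark_matrix(benchmark600) -> FeatureMatrix:
    matrix = extract_matrix(benchmark600.structures, benchmark600.profile)
    matrix.labels = benchmark600.labels.loc[matrix.values.index]
    return matrix


@pytest.fixture(scope="session")
def benchmark_filtered(benchmark_matrix) -> FeatureMatrix:
    kept = presence_filter(benchmark_matrix)
    sub = benchmark_matrix.subset([f.name for f in kept])
    sub.labels = benchmark_matrix.labels
    return sub


def make_angle_matrix(class0: np.ndarray, class1: np.ndarray,
                      feature_kind: str = "phi") -> FeatureMatrix:
    """FeatureMatrix from two (n, d) blocks of angles with labels."""
    from kinconf.features import AngleFeature

    d = class0.shape[1]
    feats = [AngleFeature(feature_kind, (i + 1,)) for i in range(d)]
    values = np.vstack([class0, class1])
    idx = pd.MultiIndex.from_tuples(
        [(f"S{i:04d}", "A") for i in range(len(values))],
        names=["structure_id", "chain_id"],
    )
    labels = pd.Series(
        ["active"] * len(class0) + ["inactive"] * len(class1), index=idx, name="label"
    )
    fm = FeatureMatrix(
        features=feats,
        values=pd.DataFrame(values, index=idx, columns=[f.name for f in feats]),
        labels=labels,
    )
    return fm


@pytest.fixture
def angle_matrix_factory():
    return make_angle_matrix
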