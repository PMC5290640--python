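"""Synthetic kinase-like structures with known conformational class.

The generator is the package's test bed: it builds polypeptide chains in
Cartesian space from prescribed internal coordinates (standard bond lengths
and angles, ω fixed at 180°), so every φ/ψ/χ1/pseudo-dihedral measured from
the built coordinates equals its prescribed target to numerical precision.
Two class templates share residue types and differ only inside the
activation-segment span — the generator encodes the premise that activation
segment orientation alone separates active from inactive conformations —
with wrapped-normal angular noise, whole-residue disorder stretches, and
side-chain truncation emulating the missingness patterns of real crystal
structures. A β3-Lys NZ / αC-Glu carboxylate pair is placed at a
class-coupled distance so the salt-bridge baseline is exercised.

No physical realism is attempted beyond that: no sterics, no rotamer
libraries, no packing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import place_atom, wrap_angle
from .legacy import MotifConfig, SpineParams
from .profiles import Profile
from .structure import Atom, Chain, Residue, StructureModel, write_pdb

__all__ = [
    "BOND_GEOMETRY",
    "ConformationTemplate",
    "SaltBridgeSpec",
    "SyntheticCorpus",
    "build_chain",
    "generate_corpus",
    "standard_benchmark",
    "benchmark_motif_config",
    "benchmark_spine_params",
]

# standard polypeptide internal coordinates (lengths in A, angles in degrees)
BOND_GEOMETRY = {
    "n_ca": 1.458,
    "ca_c": 1.525,
    "c_n": 1.329,
    "n_ca_c": 111.2,
    "ca_c_n": 116.2,
    "c_n_ca": 121.7,
    "omega": 180.0,
    "ca_cb": 1.530,
    "n_ca_cb": 110.5,
    "c_n_ca_cb": -122.6,  # improper placing Cβ for an L-amino acid
    "cb_g": 1.520,
    "ca_cb_g": 114.0,
}

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_GAMMA = {"SER": "OG", "THR": "OG1", "CYS": "SG", "ILE": "CG1", "VAL": "CG1"}
_GAMMA_ELEMENT = {"OG": "O", "OG1": "O", "SG": "S", "CG1": "C", "CG": "C"}


def build_chain(residue_types: Sequence[str], targets: np.ndarray,
                chain_id: str = "A", start_seqnum: int = 1) -> Chain:
    """Build a chain whose measured dihedrals equal the prescribed targets.

    ``residue_types`` are one-letter codes; ``targets`` is an (n, 3) array of
    (φ, ψ, χ1) in degrees (φ of the first and ψ of the last residue are
    ignored by construction; χ1 is ignored for Gly/Ala). Backbone N/Cα/C are
    chained by NeRF placement; Cβ and the γ heavy atom realize χ1; Phe
    additionally gets Cδ1/Cδ2 (for template-orientation measures), Glu gets a
    Cδ-Oε1-Oε2 carboxylate.
    """
    n_res = len(residue_types)
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    targets = np.asarray(targets, dtype=float)
    if targets.shape != (n_res, 3):
        raise ValueError(f"targets must have shape ({n_res}, 3)")
    g = BOND_GEOMETRY

    residues: list[Residue] = []
    prev_n = prev_ca = prev_c = None
    for i, aa in enumerate(residue_types):
        phi, psi, chi1 = targets[i]
        if i == 0:
            n = np.zeros(3)
            ca = np.array([g["n_ca"], 0.0, 0.0])
            c = place_atom(np.array([0.0, 1.0, 0.0]), n, ca, g["ca_c"], g["n_ca_c"], 0.0)
        else:
            n = place_atom(prev_n, prev_ca, prev_c, g["c_n"], g["ca_c_n"],
                           targets[i - 1, 1])  # ψ of the previous residue
            ca = place_atom(prev_ca, prev_c, n, g["n_ca"], g["c_n_ca"], g["omega"])
            c = place_atom(prev_c, n, ca, g["ca_c"], g["n_ca_c"], phi)

        name3 = _THREE[aa]
        atoms = [
            Atom("N", "N", n),
            Atom("CA", "C", ca),
            Atom("C", "C", c),
        ]
        if name3 not in ("GLY", "ALA"):
            cb = place_atom(c, n, ca, g["ca_cb"], g["n_ca_cb"], g["c_n_ca_cb"])
            gamma_name = _GAMMA.get(name3, "CG")
            chi = chi1 if np.isfinite(chi1) else -60.0
            gamma = place_atom(n, ca, cb, g["cb_g"], g["ca_cb_g"], chi)
            atoms.append(Atom("CB", "C", cb))
            atoms.append(Atom(gamma_name, _GAMMA_ELEMENT[gamma_name], gamma))
            if name3 == "PHE":
                atoms.append(Atom("CD1", "C", place_atom(ca, cb, gamma, 1.39, 120.0, 60.0)))
                atoms.append(Atom("CD2", "C", place_atom(ca, cb, gamma, 1.39, 120.0, -120.0)))
            elif name3 == "GLU":
                cd = place_atom(ca, cb, gamma, 1.52, 114.0, 180.0)
                atoms.append(Atom("CD", "C", cd))
                atoms.append(Atom("OE1", "O", place_atom(cb, gamma, cd, 1.25, 118.0, 0.0)))
                atoms.append(Atom("OE2", "O", place_atom(cb, gamma, cd, 1.25, 118.0, 180.0)))
        elif name3 == "ALA":
            cb = place_atom(c, n, ca, g["ca_cb"], g["n_ca_cb"], g["c_n_ca_cb"])
            atoms.append(Atom("CB", "C", cb))

        residues.append(Residue(name3=name3, seqnum=start_seqnum + i, atoms=atoms))
        prev_n, prev_ca, prev_c = n, ca, c

    return Chain(chain_id=chain_id, residues=residues)


@dataclass
class ConformationTemplate:
    """Per-column dihedral targets for one conformational class."""

    label: str  # 'active' | 'inactive'
    residue_types: str  # one-letter sequence, shared between classes
    targets: np.ndarray  # (n_columns, 3): φ, ψ, χ1 in degrees
    activation_span: tuple[int, int]  # 1-based inclusive column span
    noise_sigma: float = 0.0  # wrapped-normal angular noise, degrees
    missing_residue_prob: float = 0.0  # per-chain probability of a disorder stretch
    missing_stretch: int | None = None  # stretch length; None = whole span
    missing_sidechain_prob: float = 0.0  # per-residue side-chain truncation

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=float)
        if self.targets.shape != (len(self.residue_types), 3):
            raise ValueError("targets shape must be (n_columns, 3)")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        lo, hi = self.activation_span
        if not (1 <= lo <= hi <= len(self.residue_types)):
            raise ValueError("activation span outside the column range")


@dataclass
class SaltBridgeSpec:
    """Class-coupled NZ-to-OE1 distance used to plant the K-E bridge signal."""

    lys_col: int
    glu_col: int
    active_distance: tuple[float, float] = (3.2, 0.25)  # mean, sd in A
    inactive_distance: tuple[float, float] = (8.0, 0.8)
    flip_prob: float = 0.0  # chance a chain draws the other class's distance


@dataclass
class SyntheticCorpus:
    structures: list[StructureModel]
    labels: pd.Series  # (structure_id, chain_id) -> 'active' | 'inactive'
    truth_angles: pd.DataFrame  # noisy per-column targets actually built
    profile: Profile
    seed: int
    params: dict = field(default_factory=dict)

    def write(self, out_dir) -> Path:
        """Write PDB files, truth tables and the profile FASTA to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sm in self.structures:
            write_pdb(sm, out / f"{sm.structure_id}.pdb")
        self.labels.rename("label").reset_index().to_csv(
            out / "labels.tsv", sep="\t", index=False
        )
        self.truth_angles.to_csv(out / "truth_angles.tsv", sep="\t", float_format="%.6f")
        with open(out / "profile.fasta", "w") as fh:
            for row_id, seq in self.profile.rows.items():
                fh.write(f">{row_id}\n{seq}\n")
        return out


def _divergent_columns(a: ConformationTemplate, b: ConformationTemplate) -> list[int]:
    diff = np.zeros(len(a.residue_types), dtype=bool)
    for j in range(3):
        da = np.abs([wrap_angle(x) for x in (a.targets[:, j] - b.targets[:, j])])
        diff |= np.where(np.isnan(da), False, da > 1e-9)
    return [i + 1 for i in np.nonzero(diff)[0]]


def generate_corpus(template_active: ConformationTemplate,
                    template_inactive: ConformationTemplate,
                    n_per_class: int,
                    seed: int,
                    bridge: SaltBridgeSpec | None = None,
                    resolution_range: tuple[float, float] = (1.5, 2.8)) -> SyntheticCorpus:
    """Sample a labeled corpus of synthetic structures from two class templates.

    Per chain: targets = class template + wrapped-normal noise; a disorder
    stretch inside the activation span is deleted with the template's
    missing-residue probability; side chains truncate independently per
    residue; the NZ/OE distance is drawn from the class's bridge
    distribution. Regeneration with the same seed is bit-identical.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if template_active.residue_types != template_inactive.residue_types:
        raise ValueError("class templates must share residue types")
    div = _divergent_columns(template_active, template_inactive)
    lo, hi = template_active.activation_span
    if any(not (lo <= c <= hi) for c in div):
        raise ValueError("class-divergent columns must lie inside the activation span")

    rng = np.random.default_rng(seed)
    n_cols = len(template_active.residue_types)
    structures: list[StructureModel] = []
    labels = {}
    truth_rows = {}

    counter = 0
    for template in (template_active, template_inactive):
        for _ in range(n_per_class):
            counter += 1
            sid = f"SYN{counter:04d}"
            noisy = template.targets + rng.normal(0.0, template.noise_sigma,
                                                  size=template.targets.shape)
            noisy = np.vectorize(wrap_angle)(noisy)

            chain = build_chain(template.residue_types, noisy)

            if bridge is not None:
                _place_salt_bridge(chain, bridge, template.label, rng)

            # side-chain truncation: keep backbone only
            drop_side = rng.random(n_cols) < template.missing_sidechain_prob
            for i, res in enumerate(chain.residues):
                if drop_side[i]:
                    res.atoms = [a for a in res.atoms if a.name in ("N", "CA", "C")]

            # whole-residue disorder stretch inside the activation span
            if rng.random() < template.missing_residue_prob:
                span_lo, span_hi = template.activation_span
                length = template.missing_stretch or (span_hi - span_lo + 1)
                start = span_lo if length >= span_hi - span_lo + 1 else int(
                    rng.integers(span_lo, span_hi - length + 2)
                )
                gone = set(range(start, start + length))
                chain.residues = [
                    r for i, r in enumerate(chain.residues, start=1) if i not in gone
                ]

            resolution = round(float(rng.uniform(*resolution_range)), 2)
            structures.append(
                StructureModel(structure_id=sid, chains=[chain], resolution=resolution)
            )
            labels[(sid, "A")] = template.label
            truth_rows[(sid, "A")] = noisy.reshape(-1)

    profile = Profile(rows={"PKA": template_active.residue_types}, reference_row="PKA")
    idx = pd.MultiIndex.from_tuples(labels.keys(), names=["structure_id", "chain_id"])
    angle_cols = [
        f"{kind}_{c}" for c in range(1, n_cols + 1) for kind in ("phi", "psi", "chi1")
    ]
    truth = pd.DataFrame(
        [truth_rows[k] for k in labels], index=idx, columns=angle_cols
    )
    return SyntheticCorpus(
        structures=structures,
        labels=pd.Series(labels, name="label").reindex(idx),
        truth_angles=truth,
        profile=profile,
        seed=seed,
        params={
            "n_per_class": n_per_class,
            "noise_sigma": template_active.noise_sigma,
            "divergent_columns": div,
        },
    )


def _place_salt_bridge(chain: Chain, bridge: SaltBridgeSpec, label: str,
                       rng: np.random.Generator) -> None:
    lys = chain.residues[bridge.lys_col - 1]
    glu = chain.residues[bridge.glu_col - 1]
    oe1 = glu.atom("OE1")
    cg = lys.atom("CG")
    if oe1 is None or cg is None:
        return
    spec = bridge.active_distance if label == "active" else bridge.inactive_distance
    if bridge.flip_prob > 0 and rng.random() < bridge.flip_prob:
        spec = bridge.inactive_distance if label == "active" else bridge.active_distance
    mean, sd = spec
    lo = 2.7 if mean < 5 else 6.5  # keep draws on the intended side of the cutoff
    d = float(np.clip(rng.normal(mean, sd), lo, mean + 3 * sd))
    v = cg.xyz - oe1.xyz
    v = v / np.linalg.norm(v)
    lys.atoms.append(Atom("NZ", "N", oe1.xyz + d * v))


# ---------------------------------------------------------------------------
# the standard benchmark corpus


_BENCH_N_COLS = 60
_BENCH_SEQUENCE = (
    "MSLTVDRLEQ"        # 1-10
    "LRNDKVLTRE"        # 11-20: K at 15 (β3 Lys analogue)
    "SEYLVMQLSD"        # 21-30: E at 22 (αC Glu), D at 30 (DFG Asp)
    "FGLSRDELWE"        # 31-40: F31 G32 (DFG Phe/Gly)
    "QIDTMENLRS"        # 41-50: M45 hinge donor analogue
    "KVTDLEQWIR"        # 51-60
)
_BENCH_ACT_SPAN = (28, 39)
_BENCH_DIVERGENT = range(30, 38)  # 8 contiguous class-divergent columns

# backbone targets: helical scaffold; the active class straightens the
# activation segment into an extended (DFG-in-like) strand while the
# inactive class keeps a short helix there (the "1 1/2 turn" motif)
_HELIX = (-63.0, -42.0)
_ACTIVE_SEG = (-120.0, 135.0)
_INACTIVE_SEG = (-57.0, -47.0)


def _benchmark_templates(noise_sigma: float = 15.0,
                         missing_residue_prob: float = 0.10,
                         missing_sidechain_prob: float = 0.05):
    n = _BENCH_N_COLS
    base = np.zeros((n, 3))
    base[:, 0], base[:, 1] = _HELIX
    base[:, 2] = -60.0
    active = base.copy()
    inactive = base.copy()
    for col in _BENCH_DIVERGENT:
        active[col - 1, :2] = _ACTIVE_SEG
        inactive[col - 1, :2] = _INACTIVE_SEG
    common = dict(
        residue_types=_BENCH_SEQUENCE,
        activation_span=_BENCH_ACT_SPAN,
        noise_sigma=noise_sigma,
        missing_residue_prob=missing_residue_prob,
        missing_stretch=3,
        missing_sidechain_prob=missing_sidechain_prob,
    )
    return (
        ConformationTemplate(label="active", targets=active, **common),
        ConformationTemplate(label="inactive", targets=inactive, **common),
    )


def benchmark_bridge_spec() -> SaltBridgeSpec:
    return SaltBridgeSpec(lys_col=15, glu_col=22, flip_prob=0.08)


def standard_benchmark(seed: int = 1, n_per_class: int = 300,
                       noise_sigma: float = 15.0) -> SyntheticCorpus:
    """The canonical cross-module benchmark: 300+300 chains, σ=15° noise,
    10% activation-segment disorder, 5% side-chain truncation, class-coupled
    salt bridge."""
    act, inact = _benchmark_templates(noise_sigma=noise_sigma)
    return generate_corpus(act, inact, n_per_class=n_per_class, seed=seed,
                           bridge=benchmark_bridge_spec())


def planted_feature_names() -> list[str]:
    """Feature names carrying class signal in the standard benchmark."""
    names = []
    for col in _BENCH_DIVERGENT:
        names.append(f"Phi_{col}")
        names.append(f"Psi_{col}")
    first, last = min(_BENCH_DIVERGENT), max(_BENCH_DIVERGENT)
    # pseudo-dihedrals overlapping the divergent span (plus the ψ of the
    # preceding residue feeds the first divergent φ's neighborhood)
    for start in range(max(1, first - 3), min(last, _BENCH_N_COLS - 3) + 1):
        names.append(f"Pd_{start}-{start + 3}")
    return names


def benchmark_motif_config() -> MotifConfig:
    """Motif columns and ABC ranges for the standard benchmark corpus.

    The ABC DFG-in ranges are centered (±40°) on the noise-free active
    template's pseudo-dihedrals, so the rule recognizes the planted active
    geometry the way the published ranges recognize real DFG-in chains.
    """
    act, _ = _benchmark_templates(noise_sigma=0.0)
    chain = build_chain(act.residue_types, act.targets)
    from .features import pseudo_dihedral  # local import to avoid cycle

    quads = ((29, 30, 31, 32), (30, 31, 32, 33), (31, 32, 33, 34))
    ranges = []
    for quad in quads:
        val = pseudo_dihedral(chain, [q - 1 for q in quad])
        ranges.append((wrap_angle(val - 40.0), wrap_angle(val + 40.0)))
    return MotifConfig(
        lys_col=15,
        glu_col=22,
        dfg_asp_col=30,
        dfg_phe_col=31,
        dfg_gly_col=32,
        hinge_col=45,
        activation_span=_BENCH_ACT_SPAN,
        abc_quads=quads,
        abc_ranges=tuple(ranges),
    )


def benchmark_spine_params() -> SpineParams:
    """Spine columns for the benchmark (one inside the disorder-prone span)."""
    return SpineParams(positions=(8, 24, 31, 50))
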