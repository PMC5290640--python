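"""Coordinate hierarchy for kinase structures parsed from PDB files.

Parsing is delegated to gemmi; the hierarchy kept here is deliberately small:
only what the downstream dihedral and distance measurements need. Alternate
locations are resolved to a single atom per (residue, atom name) — highest
occupancy wins, ties broken by altloc identifier — and hydrogens are dropped,
since none of the implemented measures use them.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "read_pdb",
    "write_pdb",
    "get_atom",
    "filter_by_resolution",
    "EmptyStructureError",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Common modified residues mapped to their parent type. Activation-loop
# phospho-residues (SEP/TPO/PTR) are frequent in kinase structures and must
# align as their parent amino acid. Editable by callers.
MODIFIED_PARENT = {
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "MSE": "MET",
    "CSO": "CYS",
    "CME": "CYS",
    "KCX": "LYS",
    "MLY": "LYS",
    "HYP": "PRO",
}


class EmptyStructureError(ValueError):
    """Raised when a coordinate file contains no standard protein residues."""


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    name3: str
    seqnum: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def parent_name3(self) -> str:
        return MODIFIED_PARENT.get(self.name3, self.name3)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.parent_name3, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureModel:
    structure_id: str
    chains: list[Chain] = field(default_factory=list)
    resolution: float | None = None
    model_number: int = 1

    def chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None


def get_atom(residue: Residue, atom_name: str) -> Atom | None:
    """The unique atom of that name in the residue, or None. Never raises."""
    return residue.atom(atom_name)


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, altloc-id order breaks ties."""
    by_name: dict[str, Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
        elif (a.occupancy, _neg_ord(a.altloc)) > (prev.occupancy, _neg_ord(prev.altloc)):
            by_name[a.name] = a
    return list(by_name.values())


def _neg_ord(altloc: str):
    # smaller altloc identifier preferred, so invert for max()
    return tuple(-ord(ch) for ch in altloc) if altloc else (1,)


def _is_amino_acid(res: gemmi.Residue) -> bool:
    if res.name in THREE_TO_ONE or res.name in MODIFIED_PARENT:
        return True
    info = gemmi.find_tabulated_residue(res.name)
    return bool(info and info.is_amino_acid())


def read_pdb(path, model_policy: Literal["first", "all"] = "first") -> list[StructureModel]:
    """Read a PDB (optionally gzipped) file into StructureModel hierarchies.

    One StructureModel per coordinate model block; by default only the first
    model is kept (crystal structures have one; for NMR ensembles one
    conformation per chain is the intended unit of analysis). Hydrogens and
    waters are dropped; non-amino-acid heteroatoms are ignored.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    resolution = st.resolution if st.resolution and st.resolution > 0 else None

    models = []
    for im, model in enumerate(st):
        if model_policy == "first" and im > 0:
            break
        chains = []
        for ch in model:
            residues = []
            for res in ch:
                if not _is_amino_acid(res):
                    continue
                atoms = []
                for at in res:
                    if at.is_hydrogen():
                        continue
                    atoms.append(
                        Atom(
                            name=at.name,
                            element=at.element.name,
                            xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            occupancy=at.occ,
                            altloc=at.altloc if at.altloc != "\x00" else "",
                            bfactor=at.b_iso,
                        )
                    )
                if not atoms:
                    continue
                residues.append(
                    Residue(
                        name3=res.name,
                        seqnum=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        atoms=_resolve_altlocs(atoms),
                    )
                )
            if residues:
                residues.sort(key=lambda r: (r.seqnum, r.icode))
                chains.append(Chain(chain_id=ch.name, residues=residues))
        models.append(
            StructureModel(
                structure_id=path.name.split(".")[0],
                chains=chains,
                resolution=resolution,
                model_number=im + 1,
            )
        )

    if not models or all(not m.chains for m in models):
        raise EmptyStructureError(f"no protein residues found in {path}")
    return models


def write_pdb(model: StructureModel, path) -> None:
    """Write the hierarchy as fixed-format PDB text (deterministic output)."""
    lines = []
    if model.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {model.resolution:4.2f} ANGSTROMS.")
    serial = 1
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                name = atom.name
                # columns 13-16: element right-justified into cols 13-14
                pad = f" {name}" if len(name) < 4 and len(atom.element) == 1 else name
                lines.append(
                    f"ATOM  {serial:5d} {pad:<4s}{'':1s}{res.name3:>3s} "
                    f"{chain.chain_id:1s}{res.seqnum:4d}{res.icode:1s}   "
                    f"{atom.xyz[0]:8.3f}{atom.xyz[1]:8.3f}{atom.xyz[2]:8.3f}"
                    f"{atom.occupancy:6.2f}{atom.bfactor:6.2f}          "
                    f"{atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {chain.residues[-1].name3:>3s} "
                     f"{chain.chain_id:1s}{chain.residues[-1].seqnum:4d}")
        serial += 1
    lines.append("END")
    text = "\n".join(lines) + "\n"
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        path.write_text(text)


def filter_by_resolution(structures: Iterable[StructureModel], max_res: float) -> list[StructureModel]:
    """Retain structures whose known resolution is strictly below ``max_res``.

    Structures without a recorded resolution are excluded — the high-resolution
    repeat of the inactive-cluster analysis is restricted to entries where the
    criterion can actually be checked.
    """
    if max_res <= 0:
        raise ValueError("max_res must be positive")
    return [
        s for s in structures
        if s.resolution is not None and math.isfinite(s.resolution) and s.resolution < max_res
    ]
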