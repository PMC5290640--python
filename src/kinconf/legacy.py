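"""Previously published geometric active/inactive classifiers.

These are the distance/angle/energy rules that predate the dihedral-feature
classifier: the K-E salt-bridge distance rule, Brooijmans' salt-bridge +
hinge-to-DFG-Phe distance rule, the ABC αC-helix distance + pseudo-dihedral
rule, regulatory-spine assembly by pairwise van der Waals energy, and the
Kufareva template-based DFG-Phe orientation/position measures. Their shared
weakness — returning *indeterminate* whenever a required atom is disordered —
is reproduced faithfully, because the coverage comparison against the ML
classifier depends on it.

Motif positions are configurable profile columns. Conventional defaults are
expressed in PKA numbering: β3 Lys K72, αC Glu E91, DFG D184-F185-G186,
hinge donor V123 (a common choice; the literature does not fix one), and the
regulatory spine L106-L95-F185-Y164 in stack order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.spatial.transform import Rotation

from .features import pseudo_dihedral
from .geometry import wrap_angle
from .profiles import ColumnMap, Profile, pka_positions
from .structure import Chain, get_atom

__all__ = [
    "MotifConfig",
    "SpineParams",
    "GeometricVerdict",
    "ke_salt_bridge",
    "brooijmans",
    "abc_method",
    "rspine_assembled",
    "kufareva_measures",
    "consensus_label",
    "coverage",
    "DEFAULT_LJ_TABLE",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# generic per-element 12-6 parameters (r_min in A at the pair minimum for a
# like pair, well depth in kcal/mol); overridable via SpineParams
DEFAULT_LJ_TABLE = {
    "C": (4.00, 0.07),
    "N": (3.65, 0.17),
    "O": (3.50, 0.12),
    "S": (4.00, 0.45),
}


@dataclass
class MotifConfig:
    """Profile columns of the conserved motifs used by the geometric rules."""

    lys_col: int
    glu_col: int
    dfg_asp_col: int
    dfg_phe_col: int
    dfg_gly_col: int
    hinge_col: int
    hrd_col: int | None = None
    activation_span: tuple[int, int] | None = None
    # ABC: three Cα pseudo-dihedral quads and their DFG-in circular ranges
    abc_quads: tuple[tuple[int, int, int, int], ...] = ()
    abc_ranges: tuple[tuple[float, float], ...] = ()
    salt_bridge_cutoff: float = 4.0
    abc_distance_cutoff: float = 10.5
    # Brooijmans "soft cutoff of 15 A" as a band: below -> distance consistent
    # with active, above -> inactive, inside -> the salt bridge decides
    brooijmans_band: tuple[float, float] = (14.0, 16.0)

    @classmethod
    def from_pka(cls, profile: Profile, lys: int = 72, glu: int = 91,
                 dfg_asp: int = 184, dfg_phe: int = 185, dfg_gly: int = 186,
                 hinge: int = 123, **kwargs) -> "MotifConfig":
        """Build a config from PKA residue numbers via the profile's reference row."""
        wanted = {"lys_col": lys, "glu_col": glu, "dfg_asp_col": dfg_asp,
                  "dfg_phe_col": dfg_phe, "dfg_gly_col": dfg_gly, "hinge_col": hinge}
        cols = list(range(1, profile.n_columns + 1))
        numbers = pka_positions(profile, cols)
        by_number = {n: c for c, n in zip(cols, numbers) if n is not None}
        resolved = {}
        for key, pka in wanted.items():
            if pka not in by_number:
                raise ValueError(f"PKA position {pka} not present in the reference row")
            resolved[key] = by_number[pka]
        return cls(**resolved, **kwargs)


@dataclass
class SpineParams:
    """Regulatory-spine residue columns (stack order) and vdW parameters."""

    positions: tuple[int, int, int, int]
    lj_table: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LJ_TABLE)
    )
    threshold: float = -1.5  # kcal/mol; a pair is in contact below this

    def __post_init__(self):
        if len(set(self.positions)) != 4:
            raise ValueError("spine positions must be four distinct columns")
        if self.threshold >= 0:
            raise ValueError("vdW contact threshold must be negative")


@dataclass
class GeometricVerdict:
    method: str
    state: str  # 'active' | 'inactive' | 'indeterminate'
    measurements: dict[str, float] = field(default_factory=dict)

    @property
    def determinate(self) -> bool:
        return self.state != "indeterminate"


def _residue(chain: Chain, cmap: ColumnMap, col: int):
    idx = cmap.residue_at(col)
    return None if idx is None else chain.residues[idx]


def _min_ke_distance(chain: Chain, cmap: ColumnMap, cfg: MotifConfig) -> float | None:
    lys = _residue(chain, cmap, cfg.lys_col)
    glu = _residue(chain, cmap, cfg.glu_col)
    if lys is None or glu is None:
        return None
    nz = get_atom(lys, "NZ")
    oes = [a for name in ("OE1", "OE2") if (a := get_atom(glu, name)) is not None]
    if nz is None or not oes:
        return None
    return min(float(np.linalg.norm(nz.xyz - oe.xyz)) for oe in oes)


def ke_salt_bridge(chain: Chain, cmap: ColumnMap, cfg: MotifConfig) -> GeometricVerdict:
    """Intact K-E salt bridge: min NZ-to-OE distance strictly below 4 A.

    The bridged state is reported as 'active' (salt bridge formed); the rule
    cannot see DFG-out-with-bridge conformations, which is exactly the
    limitation the dependence analysis quantifies.
    """
    d = _min_ke_distance(chain, cmap, cfg)
    if d is None:
        return GeometricVerdict("salt_bridge", "indeterminate")
    state = "active" if d < cfg.salt_bridge_cutoff else "inactive"
    return GeometricVerdict("salt_bridge", state, {"ke_distance": d})


def brooijmans(chain: Chain, cmap: ColumnMap, cfg: MotifConfig) -> GeometricVerdict:
    """Brooijmans' rule: K-E bridge (<4 A) plus hinge-N-to-DFG-Phe-Ca distance.

    The published 15 A cutoff is "soft"; here distances below the band are
    active-consistent, above it force inactive, and inside the band the salt
    bridge decides.
    """
    d_ke = _min_ke_distance(chain, cmap, cfg)
    hinge = _residue(chain, cmap, cfg.hinge_col)
    phe = _residue(chain, cmap, cfg.dfg_phe_col)
    hinge_n = get_atom(hinge, "N") if hinge is not None else None
    phe_ca = get_atom(phe, "CA") if phe is not None else None
    if d_ke is None or hinge_n is None or phe_ca is None:
        return GeometricVerdict("brooijmans", "indeterminate")
    d_hinge = float(np.linalg.norm(hinge_n.xyz - phe_ca.xyz))
    bridged = d_ke < cfg.salt_bridge_cutoff
    _, hi = cfg.brooijmans_band
    state = "active" if (bridged and d_hinge < hi) else "inactive"
    return GeometricVerdict(
        "brooijmans", state, {"ke_distance": d_ke, "hinge_dfg_distance": d_hinge}
    )


def _in_circular_range(angle: float, lo: float, hi: float) -> bool:
    a = wrap_angle(angle)
    lo, hi = wrap_angle(lo), wrap_angle(hi)
    if lo <= hi:
        return lo <= a <= hi
    return a >= lo or a <= hi  # interval wraps through 180


def abc_method(chain: Chain, cmap: ColumnMap, cfg: MotifConfig) -> GeometricVerdict:
    """ABC rule: αC-in (Glu-Ca to DFG-Phe-Ca < 10.5 A) and DFG-in by three
    Cα pseudo-dihedrals inside configured ranges; active only when both hold."""
    if not cfg.abc_quads or len(cfg.abc_quads) != len(cfg.abc_ranges):
        raise ValueError("abc_quads and abc_ranges must be configured and parallel")
    glu = _residue(chain, cmap, cfg.glu_col)
    phe = _residue(chain, cmap, cfg.dfg_phe_col)
    glu_ca = get_atom(glu, "CA") if glu is not None else None
    phe_ca = get_atom(phe, "CA") if phe is not None else None
    if glu_ca is None or phe_ca is None:
        return GeometricVerdict("abc", "indeterminate")
    dist = float(np.linalg.norm(glu_ca.xyz - phe_ca.xyz))

    measurements = {"helixC_dfg_distance": dist}
    dfg_in = True
    for i, (quad, (lo, hi)) in enumerate(zip(cfg.abc_quads, cfg.abc_ranges), start=1):
        idxs = [cmap.residue_at(c) for c in quad]
        if any(j is None for j in idxs):
            return GeometricVerdict("abc", "indeterminate", measurements)
        pd_val = pseudo_dihedral(chain, idxs)
        if pd_val is None:
            return GeometricVerdict("abc", "indeterminate", measurements)
        measurements[f"pd{i}"] = pd_val
        dfg_in = dfg_in and _in_circular_range(pd_val, lo, hi)

    alpha_c_in = dist < cfg.abc_distance_cutoff
    state = "active" if (alpha_c_in and dfg_in) else "inactive"
    return GeometricVerdict("abc", state, measurements)


def _lj_pair_energy(res_a, res_b, lj_table) -> float | None:
    """Sum of 12-6 Lennard-Jones terms over side-chain heavy atom pairs.

    Lorentz-Berthelot combining: r_min averaged, well depth geometric mean.
    None when either residue has no side-chain heavy atoms (disorder).
    """
    side_a = [a for a in res_a.atoms if a.name not in BACKBONE_ATOMS]
    side_b = [a for a in res_b.atoms if a.name not in BACKBONE_ATOMS]
    if not side_a or not side_b:
        return None
    e = 0.0
    for a, b in product(side_a, side_b):
        pa = lj_table.get(a.element)
        pb = lj_table.get(b.element)
        if pa is None or pb is None:
            continue
        r_min = 0.5 * (pa[0] + pb[0])
        eps = (pa[1] * pb[1]) ** 0.5
        r = float(np.linalg.norm(a.xyz - b.xyz))
        if r < 1e-6:
            continue
        q = (r_min / r) ** 6
        e += eps * (q * q - 2.0 * q)
    return e


def rspine_assembled(chain: Chain, cmap: ColumnMap, spine: SpineParams) -> GeometricVerdict:
    """Regulatory spine assembly: every adjacent residue pair in the stack
    must interact with vdW energy below the threshold (default -1.5 kcal/mol)."""
    residues = []
    for col in spine.positions:
        res = _residue(chain, cmap, col)
        if res is None:
            return GeometricVerdict("rspine", "indeterminate")
        residues.append(res)
    measurements = {}
    assembled = True
    for i, (ra, rb) in enumerate(zip(residues, residues[1:]), start=1):
        e = _lj_pair_energy(ra, rb, spine.lj_table)
        if e is None:
            return GeometricVerdict("rspine", "indeterminate", measurements)
        measurements[f"pair{i}_energy"] = e
        assembled = assembled and e < spine.threshold
    state = "active" if assembled else "inactive"
    return GeometricVerdict("rspine", state, measurements)


_KUFAREVA_BONDS = (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"))


def kufareva_measures(chain: Chain, cmap: ColumnMap,
                      template_chain: Chain, template_map: ColumnMap,
                      dfg_phe_col: int) -> tuple[float | None, float | None]:
    """Template-referenced DFG-Phe orientation (O_phe) and position (P_phe).

    After least-squares superposition of the query onto the template over all
    columns with a Cα in both chains, O_phe sums the cosines of the angles
    between corresponding Cα-Cβ, Cβ-Cγ, Cγ-Cδ1, Cγ-Cδ2 bond vectors of the
    DFG-Phe (4 = identical orientation) and P_phe is the Cα displacement.
    The published combined DFG-in score built on these is not reproduced, as
    its functional form is not public; the raw measures are returned.
    """
    shared = sorted(set(cmap.col_to_res) & set(template_map.col_to_res))
    q_pts, t_pts = [], []
    for col in shared:
        qa = get_atom(chain.residues[cmap.col_to_res[col]], "CA")
        ta = get_atom(template_chain.residues[template_map.col_to_res[col]], "CA")
        if qa is not None and ta is not None:
            q_pts.append(qa.xyz)
            t_pts.append(ta.xyz)
    if len(q_pts) < 3:
        return None, None
    q_pts = np.asarray(q_pts)
    t_pts = np.asarray(t_pts)
    q_mean, t_mean = q_pts.mean(axis=0), t_pts.mean(axis=0)
    rot, _ = Rotation.align_vectors(t_pts - t_mean, q_pts - q_mean)

    def transform(xyz):
        return rot.apply(xyz - q_mean) + t_mean

    q_res = _residue(chain, cmap, dfg_phe_col)
    t_res = _residue(template_chain, template_map, dfg_phe_col)
    if q_res is None or t_res is None:
        return None, None

    o_phe = 0.0
    for a_name, b_name in _KUFAREVA_BONDS:
        qa, qb = get_atom(q_res, a_name), get_atom(q_res, b_name)
        ta, tb = get_atom(t_res, a_name), get_atom(t_res, b_name)
        if None in (qa, qb, ta, tb):
            return None, None
        v_q = transform(qb.xyz) - transform(qa.xyz)
        v_t = tb.xyz - ta.xyz
        cosine = float(np.dot(v_q, v_t) / (np.linalg.norm(v_q) * np.linalg.norm(v_t)))
        o_phe += min(1.0, max(-1.0, cosine))

    q_ca, t_ca = get_atom(q_res, "CA"), get_atom(t_res, "CA")
    if q_ca is None or t_ca is None:
        return None, None
    p_phe = float(np.linalg.norm(transform(q_ca.xyz) - t_ca.xyz))
    return o_phe, p_phe


def consensus_label(verdicts: list[GeometricVerdict]) -> str:
    """Label agreed on by every determinate verdict, else 'unlabeled'.

    Disagreements were settled by manual curation in the original corpus
    construction; curation is out of scope here, so disagreement simply
    leaves the chain unlabeled.
    """
    if not verdicts:
        raise ValueError("consensus over an empty verdict list")
    states = {v.state for v in verdicts if v.determinate}
    if len(states) == 1:
        return states.pop()
    return "unlabeled"


def coverage(verdicts: list[GeometricVerdict]) -> float:
    """Fraction of chains a method could actually classify."""
    if not verdicts:
        return 0.0
    return sum(v.determinate for v in verdicts) / len(verdicts)
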