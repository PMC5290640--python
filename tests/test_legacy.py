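"""Geometric baseline rules: thresholds, indeterminacy, invariances."""

import numpy as np
import pytest

from kinconf.features import pseudo_dihedral
from kinconf.legacy import (
    GeometricVerdict,
    MotifConfig,
    SpineParams,
    abc_method,
    brooijmans,
    consensus_label,
    coverage,
    ke_salt_bridge,
    kufareva_measures,
    rspine_assembled,
)
from kinconf.profiles import Profile
from kinconf.structure import Chain
from kinconf.synth import (
    benchmark_motif_config,
    build_chain,
    standard_benchmark,
)
from conftest import identity_map, toy_residue


def bridge_chain(ke_distance: float, hinge_distance: float = 10.0,
                 with_nz: bool = True) -> Chain:
    """Three residues: Lys (col 1), Glu (col 2), hinge Met (col 3), with the
    NZ-OE1 and hinge-N-to-PheCA distances set exactly. The DFG-Phe (col 4)
    Ca sits at the origin."""
    lys_atoms = {"N": (0, 5, 5), "CA": (1, 5, 5), "C": (2, 5, 5), "CB": (1, 6, 5),
                 "CG": (1, 7, 5)}
    if with_nz:
        lys_atoms["NZ"] = (ke_distance, 0, 0)
    res = [
        toy_residue("LYS", 1, lys_atoms),
        toy_residue("GLU", 2, {"N": (0, -5, 5), "CA": (1, -5, 5), "C": (2, -5, 5),
                               "CB": (1, -6, 5), "CG": (1, -7, 5), "CD": (1, -8, 5),
                               "OE1": (0, 0, 0), "OE2": (0, -2.2, 0)}),
        toy_residue("MET", 3, {"N": (hinge_distance, 3, 4), "CA": (hinge_distance + 1, 3, 4),
                               "C": (hinge_distance + 2, 3, 4)}),
        toy_residue("PHE", 4, {"N": (-1, 3, 4), "CA": (0, 3, 4), "C": (1, 3, 4)}),
    ]
    # place hinge N at the exact distance from Phe CA
    res[2].atom("N").xyz = np.array([0.0, 3.0, 4.0]) + np.array([hinge_distance, 0, 0])
    return Chain("A", res)


def bridge_cfg() -> MotifConfig:
    return MotifConfig(lys_col=1, glu_col=2, dfg_asp_col=4, dfg_phe_col=4,
                       dfg_gly_col=4, hinge_col=3)


class TestSaltBridge:
    def test_bridged_below_cutoff(self):
        ch = bridge_chain(3.5)
        v = ke_salt_bridge(ch, identity_map(ch), bridge_cfg())
        assert v.state == "active"
        assert v.measurements["ke_distance"] == pytest.approx(3.5)

    def test_exactly_four_angstroms_is_not_bridged(self):
        ch = bridge_chain(4.0)
        v = ke_salt_bridge(ch, identity_map(ch), bridge_cfg())
        assert v.state == "inactive"

    def test_minimum_over_both_carboxylate_oxygens(self):
        ch = bridge_chain(9.0)
        # NZ is 9.0 from OE1 but 3.0 from OE2 at (0,-2.2,0): move NZ there
        ch.residues[0].atom("NZ").xyz = np.array([3.0, -2.2, 0.0])
        v = ke_salt_bridge(ch, identity_map(ch), bridge_cfg())
        assert v.state == "active"
        assert v.measurements["ke_distance"] == pytest.approx(3.0)

    def test_disordered_side_chain_is_indeterminate(self):
        ch = bridge_chain(3.5, with_nz=False)
        v = ke_salt_bridge(ch, identity_map(ch), bridge_cfg())
        assert v.state == "indeterminate"


class TestBrooijmans:
    @pytest.mark.parametrize("ke, hinge, expected", [
        (3.5, 14.0, "active"),     # bridged, distance consistent
        (3.5, 15.0, "active"),     # inside the soft band: bridge decides
        (3.5, 17.0, "inactive"),   # beyond the band: inactive regardless
        (5.0, 10.0, "inactive"),   # unbridged
    ])
    def test_band_semantics(self, ke, hinge, expected):
        ch = bridge_chain(ke, hinge_distance=hinge)
        v = brooijmans(ch, identity_map(ch), bridge_cfg())
        assert v.state == expected

    def test_missing_hinge_nitrogen_indeterminate(self):
        ch = bridge_chain(3.5)
        ch.residues[2].atoms = [a for a in ch.residues[2].atoms if a.name != "N"]
        v = brooijmans(ch, identity_map(ch), bridge_cfg())
        assert v.state == "indeterminate"


def abc_fixture(distance: float):
    """Helical 12-residue chain; Glu Ca moved to an exact distance from the
    DFG-Phe Ca; pseudo-dihedral ranges taken around the measured values."""
    targets = np.tile([-63.0, -42.0, -60.0], (12, 1))
    chain = build_chain("LELLLLDFGLLL", targets)
    cmap = identity_map(chain)
    quads = ((5, 6, 7, 8), (6, 7, 8, 9), (7, 8, 9, 10))
    ranges = []
    for quad in quads:
        v = pseudo_dihedral(chain, [q - 1 for q in quad])
        ranges.append((v - 10.0, v + 10.0))
    phe_ca = chain.residues[7].atom("CA").xyz
    glu_ca = chain.residues[1].atom("CA")
    direction = (glu_ca.xyz - phe_ca) / np.linalg.norm(glu_ca.xyz - phe_ca)
    glu_ca.xyz = phe_ca + direction * distance
    cfg = MotifConfig(lys_col=1, glu_col=2, dfg_asp_col=7, dfg_phe_col=8,
                      dfg_gly_col=9, hinge_col=3, abc_quads=quads,
                      abc_ranges=tuple(ranges))
    return chain, cmap, cfg


class TestAbc:
    def test_within_cutoff_and_ranges_active(self):
        chain, cmap, cfg = abc_fixture(10.4)
        v = abc_method(chain, cmap, cfg)
        assert v.state == "active"
        assert v.measurements["helixC_dfg_distance"] == pytest.approx(10.4)

    def test_beyond_cutoff_inactive_regardless(self):
        chain, cmap, cfg = abc_fixture(10.6)
        assert abc_method(chain, cmap, cfg).state == "inactive"

    def test_pseudo_dihedral_out_of_range_inactive(self):
        chain, cmap, cfg = abc_fixture(10.4)
        cfg.abc_ranges = tuple((lo + 120, hi + 120) for lo, hi in cfg.abc_ranges)
        assert abc_method(chain, cmap, cfg).state == "inactive"

    def test_missing_quad_ca_indeterminate(self):
        chain, cmap, cfg = abc_fixture(10.4)
        chain.residues[5].atoms = [a for a in chain.residues[5].atoms if a.name != "CA"]
        assert abc_method(chain, cmap, cfg).state == "indeterminate"


def spine_chain(separations: tuple[float, float, float]) -> tuple[Chain, SpineParams]:
    """Four single-carbon side chains on a line at prescribed CB separations."""
    x = [0.0]
    for s in separations:
        x.append(x[-1] + s)
    residues = [
        toy_residue("LEU", i + 1, {"N": (xi, 10, 0), "CA": (xi, 11, 0),
                                   "C": (xi, 12, 0), "CB": (xi, 0, 0)})
        for i, xi in enumerate(x)
    ]
    spine = SpineParams(positions=(1, 2, 3, 4), lj_table={"C": (4.0, 1.6)})
    return Chain("A", residues), spine


class TestRspine:
    def test_all_pairs_at_minimum_is_assembled(self):
        # at r = r_min each pair energy is exactly -eps = -1.6 < -1.5
        chain, spine = spine_chain((4.0, 4.0, 4.0))
        v = rspine_assembled(chain, identity_map(chain), spine)
        assert v.state == "active"
        for key in ("pair1_energy", "pair2_energy", "pair3_energy"):
            assert v.measurements[key] == pytest.approx(-1.6, abs=1e-12)

    def test_one_weak_pair_breaks_the_spine(self):
        chain, spine = spine_chain((4.0, 4.0, 4.7))
        v = rspine_assembled(chain, identity_map(chain), spine)
        assert v.measurements["pair3_energy"] > -1.5
        assert v.state == "inactive"

    def test_lj_minimum_identity(self):
        chain, spine = spine_chain((4.0, 4.0, 4.0))
        v = rspine_assembled(chain, identity_map(chain), spine)
        assert v.measurements["pair1_energy"] == pytest.approx(-spine.lj_table["C"][1])

    def test_missing_side_chain_indeterminate(self):
        chain, spine = spine_chain((4.0, 4.0, 4.0))
        chain.residues[1].atoms = [a for a in chain.residues[1].atoms
                                   if a.name in ("N", "CA", "C")]
        v = rspine_assembled(chain, identity_map(chain), spine)
        assert v.state == "indeterminate"

    def test_threshold_must_be_negative(self):
        with pytest.raises(ValueError):
            SpineParams(positions=(1, 2, 3, 4), threshold=0.5)


def phe_chain(chi1: float) -> Chain:
    targets = np.tile([-63.0, -42.0, -60.0], (8, 1))
    targets[4, 2] = chi1  # the Phe at index 4
    return build_chain("LLDLFGLL", targets)


class TestKufareva:
    def test_self_comparison_identity(self):
        chain = phe_chain(-60.0)
        cmap = identity_map(chain)
        o_phe, p_phe = kufareva_measures(chain, cmap, chain, cmap, dfg_phe_col=5)
        assert o_phe == pytest.approx(4.0, abs=1e-9)
        assert p_phe == pytest.approx(0.0, abs=1e-9)

    def test_rotated_chi1_lowers_orientation_not_position(self):
        template = phe_chain(-60.0)
        query = phe_chain(120.0)  # same backbone, ring flipped 180 deg
        t_map, q_map = identity_map(template), identity_map(query)
        o_phe, p_phe = kufareva_measures(query, q_map, template, t_map, dfg_phe_col=5)
        assert o_phe < 3.0
        assert p_phe == pytest.approx(0.0, abs=1e-6)

    def test_missing_delta_atoms_absent(self):
        template = phe_chain(-60.0)
        query = phe_chain(-60.0)
        query.residues[4].atoms = [a for a in query.residues[4].atoms
                                   if a.name not in ("CD1", "CD2")]
        o_phe, p_phe = kufareva_measures(query, identity_map(query),
                                         template, identity_map(template), dfg_phe_col=5)
        assert o_phe is None and p_phe is None


class TestConsensus:
    def test_agreement_over_determinate_subset(self):
        vs = [GeometricVerdict("a", "active"), GeometricVerdict("b", "active"),
              GeometricVerdict("c", "indeterminate")]
        assert consensus_label(vs) == "active"

    def test_disagreement_is_unlabeled(self):
        vs = [GeometricVerdict("a", "active"), GeometricVerdict("b", "inactive"),
              GeometricVerdict("c", "active")]
        assert consensus_label(vs) == "unlabeled"

    def test_all_indeterminate_is_unlabeled(self):
        vs = [GeometricVerdict("a", "indeterminate"), GeometricVerdict("b", "indeterminate")]
        assert consensus_label(vs) == "unlabeled"

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            consensus_label([])


def test_verdicts_rigid_motion_invariant():
    from scipy.spatial.transform import Rotation

    corpus = standard_benchmark(seed=5, n_per_class=2, noise_sigma=5.0)
    cfg = benchmark_motif_config()
    rot = Rotation.random(random_state=42).as_matrix()
    shift = np.array([13.0, -8.0, 21.0])
    for sm in corpus.structures:
        chain = sm.chains[0]
        cmap = identity_map_for_corpus(chain)
        before = [ke_salt_bridge(chain, cmap, cfg), brooijmans(chain, cmap, cfg),
                  abc_method(chain, cmap, cfg)]
        for res in chain.residues:
            for atom in res.atoms:
                atom.xyz = rot @ atom.xyz + shift
        after = [ke_salt_bridge(chain, cmap, cfg), brooijmans(chain, cmap, cfg),
                 abc_method(chain, cmap, cfg)]
        for v1, v2 in zip(before, after):
            assert v1.state == v2.state
            for key, val in v1.measurements.items():
                assert v2.measurements[key] == pytest.approx(val, abs=1e-9)


def identity_map_for_corpus(chain: Chain):
    """Map columns to residues by seqnum (synthetic chains: column == seqnum)."""
    from kinconf.profiles import ColumnMap

    return ColumnMap(chain_ref=("SYN", chain.chain_id),
                     col_to_res={r.seqnum: i for i, r in enumerate(chain.residues)},
                     identity=1.0, best_row="PKA")


def test_coverage_fraction():
    vs = [GeometricVerdict("a", "active"), GeometricVerdict("a", "indeterminate"),
          GeometricVerdict("a", "inactive"), GeometricVerdict("a", "indeterminate")]
    assert coverage(vs) == pytest.approx(0.5)
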