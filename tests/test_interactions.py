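"""Interaction detection: typing, H-bond geometry vs a brute-force oracle,
metal coordination, hydrophobic nodule, cleft counts."""

import math

import numpy as np
import pytest

from tklscan.interactions import (
    GeometryParams,
    KD_SCALE,
    cleft_check,
    count_protein_groups,
    detect_hbonds,
    detect_metal_coordination,
    hydrophobic_nodule,
    type_atoms,
    type_ligand_atoms,
)
from tklscan.structure_io import Atom, Chain, Residue, Structure
from tklscan.superpose import RigidTransform
from tklscan.synthetic import (
    LigandAtomSpec,
    PlantedHBond,
    ToyComplexSpec,
    make_toy_dimer,
)
from conftest import PLANTED_SIX, rotation


def brute_force_hbonds(protein, ligand, p):
    """Independent all-pairs enumeration with plain trigonometry; no trees,
    no shared code path with the detector."""

    def ang(a, b, c):
        v1, v2 = np.asarray(a) - b, np.asarray(c) - b
        cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))

    pairs = {}
    for x in protein:
        for y in ligand:
            for d_atom, a_atom in ((x, y), (y, x)):
                if "donor" not in d_atom.roles or "acceptor" not in a_atom.roles:
                    continue
                d = float(np.linalg.norm(d_atom.coords - a_atom.coords))
                if d > p.d_DA_max or d < 1.5:
                    continue
                if any(
                    ang(nb, d_atom.coords, a_atom.coords) < p.donor_angle_min
                    for nb in d_atom.neighbors
                ):
                    continue
                if any(
                    ang(nb, a_atom.coords, d_atom.coords) < p.acceptor_angle_min
                    for nb in a_atom.neighbors
                ):
                    continue
                key = tuple(sorted((d_atom.key, a_atom.key)))
                pairs[key] = d
    return pairs


@pytest.fixture(scope="module")
def planted(toy_complex):
    template, _, truth = toy_complex
    protein = type_atoms(template)
    ligand = type_ligand_atoms(template, truth["ligand_typing"])
    return template, truth, protein, ligand


# ---------------------------------------------------------------------------
# typing

def test_lysine_and_glycine_and_histidine_typing(planted):
    _, _, protein, _ = planted
    by_res = {}
    for t in protein:
        by_res.setdefault((t.residue.name, t.atom.name), t)
    nz = by_res[("LYS", "NZ")]
    assert nz.roles == ("donor",)
    assert nz.group == "epsilon-NH2"
    # glycine: backbone entries only
    gly = [t for t in protein if t.residue.name == "GLY"]
    assert {t.atom.name for t in gly} <= {"N", "O", "OXT"}
    assert any(t.group == "backbone-amide" for t in gly)
    assert any(t.group == "backbone-carbonyl" for t in gly)
    ne2 = by_res[("HIS", "NE2")]
    assert set(ne2.roles) == {"donor", "acceptor"}
    assert ne2.group == "tau-NH"
    nd1 = by_res[("HIS", "ND1")]
    assert nd1.group == "pi-NH"


# ---------------------------------------------------------------------------
# hydrogen bonds

def test_planted_hbonds_detected_exactly(planted):
    _, truth, protein, ligand = planted
    hbonds = detect_hbonds(protein, ligand)
    assert len(hbonds) == len(truth["hbonds"])
    detected = {
        (hb.protein_atom.pointer.number, hb.protein_atom.atom.name,
         hb.ligand_atom.atom.name): hb.d_DA
        for hb in hbonds
    }
    for planted_hb in truth["hbonds"]:
        key = (planted_hb["resnum"], planted_hb["atom"], planted_hb["ligand_atom"])
        assert key in detected
        assert detected[key] == pytest.approx(planted_hb["d_DA"], abs=1e-6)


def test_distant_pair_not_reported(planted):
    _, _, protein, ligand = planted
    tight = GeometryParams(d_DA_max=2.0, d_HA_max=1.5)
    far = detect_hbonds(protein, ligand, tight)
    assert far == []


@pytest.mark.parametrize("params", [
    GeometryParams(),
    GeometryParams(d_DA_max=3.0, d_HA_max=2.2),
    GeometryParams(d_DA_max=4.5, donor_angle_min=60.0, acceptor_angle_min=60.0),
    GeometryParams(donor_angle_min=150.0, acceptor_angle_min=120.0),
])
def test_detector_equals_brute_force_oracle(planted, params):
    _, _, protein, ligand = planted
    assert len(protein) + len(ligand) <= 500
    mine = {
        tuple(sorted((hb.donor.key, hb.acceptor.key))): hb.d_DA
        for hb in detect_hbonds(protein, ligand, params)
    }
    oracle = brute_force_hbonds(protein, ligand, params)
    assert mine.keys() == oracle.keys()
    for k in mine:
        assert mine[k] == pytest.approx(oracle[k], abs=1e-9)


def test_loosening_any_threshold_never_removes_bonds(planted):
    _, _, protein, ligand = planted
    base_p = GeometryParams(d_DA_max=3.0, donor_angle_min=110.0,
                            acceptor_angle_min=110.0)
    base = {
        tuple(sorted((hb.donor.key, hb.acceptor.key)))
        for hb in detect_hbonds(protein, ligand, base_p)
    }
    looser = [
        GeometryParams(d_DA_max=3.6, donor_angle_min=110.0, acceptor_angle_min=110.0),
        GeometryParams(d_DA_max=3.0, donor_angle_min=80.0, acceptor_angle_min=110.0),
        GeometryParams(d_DA_max=3.0, donor_angle_min=110.0, acceptor_angle_min=70.0),
    ]
    for p in looser:
        loose = {
            tuple(sorted((hb.donor.key, hb.acceptor.key)))
            for hb in detect_hbonds(protein, ligand, p)
        }
        assert base <= loose


def test_hbond_list_invariant_under_rigid_transform(toy_complex):
    template, _, truth = toy_complex
    ref = detect_hbonds(
        type_atoms(template), type_ligand_atoms(template, truth["ligand_typing"])
    )
    tf = RigidTransform(rotation([40.0, 10.0, -75.0]), np.array([3.0, -9.0, 2.0]))
    moved = template.copy()
    for _, atom in moved.all_atoms():
        atom.coords = tf.apply(atom.coords)
    new = detect_hbonds(
        type_atoms(moved), type_ligand_atoms(moved, truth["ligand_typing"])
    )
    assert len(new) == len(ref)
    for a, b in zip(ref, new):
        assert a.donor.key == b.donor.key
        assert a.acceptor.key == b.acceptor.key
        assert a.d_DA == pytest.approx(b.d_DA, abs=1e-6)


def test_count_protein_groups_collapses_same_group():
    # two bonds from the same lysine NZ to two oxygens count as one group
    spec = ToyComplexSpec(
        seed=1, n_residues_per_chain=30,
        planted_hbonds=(
            PlantedHBond(6, "NZ", "O1", 2.9),
            PlantedHBond(19, "OG", "O4", 2.85),
        ),
    )
    template, _, truth = make_toy_dimer(spec)
    protein = type_atoms(template)
    ligand = type_ligand_atoms(template, truth["ligand_typing"])
    hbonds = detect_hbonds(protein, ligand)
    # move O2 next to O1's lysine: simulate second bond from the same NZ
    assert count_protein_groups([], None) == 0
    assert count_protein_groups(hbonds) == 2
    assert count_protein_groups(hbonds, "diphosphate") == 1
    assert count_protein_groups(hbonds, "xylulose") == 1
    duplicated = list(hbonds) + [h for h in hbonds if h.ligand_side == "diphosphate"]
    assert count_protein_groups(duplicated, "diphosphate") == 1


def test_five_distinct_diphosphate_groups():
    """Five residues donating to the diphosphate side tally as five groups,
    even when one residue makes two bonds."""
    lig = (
        LigandAtomSpec("O1", "O", "diphosphate", ("acceptor",), "phosphate-O"),
        LigandAtomSpec("O2", "O", "diphosphate", ("acceptor",), "phosphate-O"),
        LigandAtomSpec("O3", "O", "diphosphate", ("acceptor",), "phosphate-O"),
        LigandAtomSpec("O6", "O", "diphosphate", ("acceptor",), "phosphate-O"),
        LigandAtomSpec("O7", "O", "diphosphate", ("acceptor",), "phosphate-O"),
        LigandAtomSpec("O8", "O", "diphosphate", ("acceptor",), "phosphate-O"),
        LigandAtomSpec("C7", "C", "methylene-bridge", (), "methylene"),
        LigandAtomSpec("S1", "S", "thiazole", ("acceptor",), "thiazole-S"),
    )
    plant = (
        PlantedHBond(6, "NZ", "O1", 2.9),
        PlantedHBond(29, "NZ", "O2", 2.9),
        PlantedHBond(16, "ND2", "O3", 3.0),
        PlantedHBond(19, "OG", "O6", 2.8),
        PlantedHBond(10, "OG1", "O7", 2.85),
        PlantedHBond(18, "NE2", "O8", 3.0),
    )
    template, _, truth = make_toy_dimer(
        ToyComplexSpec(seed=1, n_residues_per_chain=30, ligand_spec=lig,
                       planted_hbonds=plant)
    )
    hbonds = detect_hbonds(
        type_atoms(template), type_ligand_atoms(template, truth["ligand_typing"])
    )
    assert len(hbonds) == 6
    assert count_protein_groups(hbonds, "diphosphate") == 6  # 6 residues here
    # now a true duplicate: K6 NZ bonded to two oxygens collapses to 5 groups
    dup = [h for h in hbonds if h.protein_atom.pointer.number != 18]
    assert count_protein_groups(dup, "diphosphate") == 5


# ---------------------------------------------------------------------------
# metal coordination

def test_no_metal_no_contacts(toy_complex):
    template, _, _ = toy_complex
    assert detect_metal_coordination(template) == []


def test_planted_magnesium_coordination():
    spec = ToyComplexSpec(seed=3, n_residues_per_chain=12, include_metal=True,
                          metal_distance=2.1)
    template, _, _ = spec, None, None
    template, _, _ = make_toy_dimer(spec)
    contacts = detect_metal_coordination(template)
    lig_partners = [c for c in contacts if c.partner_is_ligand]
    assert len(lig_partners) == 2  # the two planted oxygens
    for c in lig_partners:
        assert c.distance == pytest.approx(2.1, abs=1e-6)
    # brute-force check over every O/N/S atom in the structure
    metal = [r for r in template.ligands if r.is_metal][0]
    mc = metal.atoms[0].coords
    expect = sum(
        1
        for res, atom in list(template.polymer_atoms())
        + [(r, a) for r in template.ligands if not r.is_metal for a in r.atoms]
        if atom.element.upper() in ("O", "N", "S")
        and np.linalg.norm(atom.coords - mc) <= 2.6
    )
    assert len(contacts) == expect


def test_metal_mediated_pairs_excluded_from_hbonds():
    spec = ToyComplexSpec(seed=3, n_residues_per_chain=12, include_metal=True)
    template, _, truth = make_toy_dimer(spec)
    contacts = detect_metal_coordination(template)
    metal_xyz = np.array(
        [r.atoms[0].coords for r in template.ligands if r.is_metal]
    )
    hbonds = detect_hbonds(
        type_atoms(template),
        type_ligand_atoms(template, truth["ligand_typing"]),
        metal_coords=metal_xyz,
    )
    coordinated = {
        (c.partner_residue.pointer, c.partner_atom.name) for c in contacts
    }
    for hb in hbonds:
        pair = {
            (hb.donor.pointer, hb.donor.atom.name),
            (hb.acceptor.pointer, hb.acceptor.atom.name),
        }
        assert not pair <= coordinated


# ---------------------------------------------------------------------------
# hydrophobic nodule and cleft

def _residue_with(name, number, atoms, chain="A"):
    res = Residue(name=name, number=number, chain_id=chain)
    for i, (aname, elem, xyz) in enumerate(atoms):
        res.atoms.append(Atom(serial=i + 1, name=aname, element=elem, coords=xyz))
    return res


def test_nodule_ranks_leucine_and_excludes_polar():
    probe = np.array([[0.0, 0.0, 0.0]])
    leu = _residue_with(
        "LEU", 10,
        [("N", "N", [8, 0, 0]), ("CA", "C", [7, 0, 0]), ("C", "C", [8, 1, 0]),
         ("O", "O", [9, 1, 0]), ("CB", "C", [5.5, 0, 0]), ("CG", "C", [3.6, 0, 0])],
    )
    arg = _residue_with(
        "ARG", 11,
        [("N", "N", [8, 5, 0]), ("CA", "C", [7, 5, 0]), ("C", "C", [8, 6, 0]),
         ("O", "O", [9, 6, 0]), ("CB", "C", [5, 5, 0]), ("NH1", "N", [0, 3.4, 0])],
    )
    s = Structure(id="toy", chains=[Chain(id="A", residues=[leu, arg])])
    hits = hydrophobic_nodule(s, probe, kd_min=0.0)
    assert [h.residue.name for h in hits] == ["LEU"]
    assert hits[0].kd == KD_SCALE["LEU"] == 3.8
    assert hits[0].min_distance_to_probe == pytest.approx(3.6)
    # with the polarity filter off, the closer arginine outranks the leucine
    hits_all = hydrophobic_nodule(s, probe, kd_min=-4.5)
    assert [h.residue.name for h in hits_all] == ["ARG", "LEU"]


def test_probe_in_empty_space_is_empty(toy_complex):
    template, _, _ = toy_complex
    probe = np.array([[500.0, 500.0, 500.0]])
    assert hydrophobic_nodule(template, probe) == []


def test_symmetric_dimer_cleft_counts_equal():
    template, _, _ = make_toy_dimer(
        ToyComplexSpec(seed=2, n_residues_per_chain=24)
    )
    for radius in (6.0, 8.0, 10.0):
        res = cleft_check(template, radius)
        counts = list(res["per_chain"].values())
        assert counts[0] == counts[1]
    assert cleft_check(template, 8.0)["inter_subunit_cleft"] is True


def test_ligand_far_away_flag_false():
    template, _, _ = make_toy_dimer(ToyComplexSpec(seed=2, n_residues_per_chain=24))
    moved = template.copy()
    for r in moved.ligands:
        for a in r.atoms:
            a.coords = a.coords + np.array([500.0, 0.0, 0.0])
    res = cleft_check(moved, 5.0)
    assert all(v == 0 for v in res["per_chain"].values())
    assert res["inter_subunit_cleft"] is False
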