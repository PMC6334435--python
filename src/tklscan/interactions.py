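"""Geometric detection of protein--ligand interactions.

Hydrogen bonds are called from heavy-atom geometry in the style of the
published distance/angle criteria used by interactive structure viewers:
a donor--acceptor distance cutoff plus coarse angular screens at both ends,
computed from covalently attached heavy atoms (crystal structures and
homology models rarely carry hydrogens).  Metal coordination, hydrophobic
contacts around a probe (the cofactor's methylene bridge for the
transketolase use case) and the dimer-interface cleft check live here too.

Atoms are classified by a donor/acceptor typing table whose group labels
("epsilon-NH2", "tau-NH", "backbone-amide", ...) are the vocabulary used in
the active-site literature; distinct hydrogen bonds from one chemical group
count once when group-level tallies are requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from tklscan.structure_io import Atom, Residue, ResiduePointer, Structure

__all__ = [
    "GeometryParams",
    "TypedAtom",
    "HBond",
    "MetalContact",
    "HydropathyContact",
    "KD_SCALE",
    "PROTEIN_TYPING",
    "type_atoms",
    "type_ligand_atoms",
    "detect_hbonds",
    "count_protein_groups",
    "detect_metal_coordination",
    "hydrophobic_nodule",
    "cleft_check",
]


@dataclass
class GeometryParams:
    """Distance/angle thresholds for interaction detection (Angstrom, degrees).

    Defaults are the package's heavy-atom realization of the classic
    geometric hydrogen-bond criteria; every run report records the values
    used.
    """

    d_DA_max: float = 3.5
    d_HA_max: float = 2.5
    angle_DHA_min: float = 120.0
    donor_angle_min: float = 90.0
    acceptor_angle_min: float = 90.0
    heavy_atom_only: bool = True
    metal_coord_max: float = 2.6
    contact_max: float = 4.5

    def __post_init__(self) -> None:
        numeric = (
            self.d_DA_max,
            self.d_HA_max,
            self.angle_DHA_min,
            self.donor_angle_min,
            self.acceptor_angle_min,
            self.metal_coord_max,
            self.contact_max,
        )
        if any(v <= 0 for v in numeric):
            raise ValueError("geometry thresholds must be positive")
        if self.d_HA_max >= self.d_DA_max:
            raise ValueError("d_HA_max must be smaller than d_DA_max")


# ---------------------------------------------------------------------------
# donor/acceptor typing

# per residue: atom -> (roles, group label, attached-H count)
# the histidine ring nitrogens are typed donor-or-acceptor because model
# files carry no protonation; NE2 carries the tau label, ND1 the pi label.
PROTEIN_TYPING: dict[str, dict[str, tuple[tuple[str, ...], str, int]]] = {
    "SER": {"OG": (("donor", "acceptor"), "hydroxyl", 1)},
    "THR": {"OG1": (("donor", "acceptor"), "hydroxyl", 1)},
    "TYR": {"OH": (("donor", "acceptor"), "hydroxyl", 1)},
    "CYS": {"SG": (("donor", "acceptor"), "thiol", 1)},
    "MET": {"SD": (("acceptor",), "thioether-S", 0)},
    "ASP": {
        "OD1": (("acceptor",), "carboxylate", 0),
        "OD2": (("acceptor",), "carboxylate", 0),
    },
    "GLU": {
        "OE1": (("acceptor",), "carboxylate", 0),
        "OE2": (("acceptor",), "carboxylate", 0),
    },
    "ASN": {
        "OD1": (("acceptor",), "amide-CO", 0),
        "ND2": (("donor",), "amide-NH2", 2),
    },
    "GLN": {
        "OE1": (("acceptor",), "amide-CO", 0),
        "NE2": (("donor",), "amide-NH2", 2),
    },
    "LYS": {"NZ": (("donor",), "epsilon-NH2", 3)},
    "ARG": {
        "NE": (("donor",), "guanidinium", 1),
        "NH1": (("donor",), "guanidinium", 2),
        "NH2": (("donor",), "guanidinium", 2),
    },
    "HIS": {
        "ND1": (("donor", "acceptor"), "pi-NH", 1),
        "NE2": (("donor", "acceptor"), "tau-NH", 1),
    },
    "TRP": {"NE1": (("donor",), "indole-NH", 1)},
}

#: Kyte-Doolittle hydropathy, -4.5 (Arg) .. +4.5 (Ile)
KD_SCALE: dict[str, float] = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

_COVALENT_RADII = {
    "C": 0.77, "N": 0.70, "O": 0.66, "S": 1.04, "P": 1.10, "H": 0.32,
    "SE": 1.17, "F": 0.64, "CL": 0.99, "BR": 1.14,
}


@dataclass
class TypedAtom:
    """An atom annotated with its hydrogen-bonding role and chemical group."""

    residue: Residue
    atom: Atom
    roles: tuple[str, ...]
    group: str
    h_count: int = 0
    ligand_side: Optional[str] = None
    neighbors: list[np.ndarray] = field(default_factory=list)
    hydrogens: list[np.ndarray] = field(default_factory=list)

    @property
    def pointer(self) -> ResiduePointer:
        return self.residue.pointer

    @property
    def coords(self) -> np.ndarray:
        return self.atom.coords

    @property
    def key(self) -> tuple:
        p = self.pointer
        return (p.chain_id, p.number, p.icode, self.atom.name)


def _bond_cutoff(e1: str, e2: str) -> float:
    r1 = _COVALENT_RADII.get(e1.upper(), 0.77)
    r2 = _COVALENT_RADII.get(e2.upper(), 0.77)
    return 1.3 * (r1 + r2)


def _neighbors_within(atom: Atom, pool: Iterable[Atom]) -> tuple[list, list]:
    """Heavy neighbors and attached hydrogens of ``atom`` among ``pool``."""
    heavy, hs = [], []
    for other in pool:
        if other is atom:
            continue
        d = float(np.linalg.norm(atom.coords - other.coords))
        if d < 1e-6:
            continue
        if other.element.upper() in ("H", "D"):
            if d <= _bond_cutoff(atom.element, "H"):
                hs.append(other.coords)
        elif d <= _bond_cutoff(atom.element, other.element):
            heavy.append(other.coords)
    return heavy, hs


def type_atoms(
    s: Structure,
    include_waters: bool = False,
) -> list[TypedAtom]:
    """Classify every polymer N/O/S atom as donor/acceptor/both with a group
    label. Backbone amide N and carbonyl O are typed for all residues
    (proline N excepted — it has no amide hydrogen)."""
    typed: list[TypedAtom] = []
    for chain in s.chains:
        residues = chain.residues
        for idx, res in enumerate(residues):
            pool = list(res.atoms)
            # inter-residue backbone bonds matter for the angle screens
            if idx > 0:
                prev_c = residues[idx - 1].atom("C")
                if prev_c is not None:
                    pool.append(prev_c)
            if idx + 1 < len(residues):
                next_n = residues[idx + 1].atom("N")
                if next_n is not None:
                    pool.append(next_n)
            side = PROTEIN_TYPING.get(res.name, {})
            for atom in res.atoms:
                entry = None
                if atom.name == "N" and res.name != "PRO":
                    entry = (("donor",), "backbone-amide", 1)
                elif atom.name == "O":
                    entry = (("acceptor",), "backbone-carbonyl", 0)
                elif atom.name == "OXT":
                    entry = (("acceptor",), "carboxylate", 0)
                elif atom.name in side:
                    entry = side[atom.name]
                if entry is None:
                    continue
                heavy, hs = _neighbors_within(atom, pool)
                typed.append(
                    TypedAtom(
                        residue=res,
                        atom=atom,
                        roles=entry[0],
                        group=entry[1],
                        h_count=entry[2],
                        neighbors=heavy,
                        hydrogens=hs,
                    )
                )
    if include_waters:
        for res in s.ligands:
            if not res.is_water:
                continue
            for atom in res.atoms:
                if atom.element.upper() == "O":
                    typed.append(
                        TypedAtom(
                            residue=res,
                            atom=atom,
                            roles=("donor", "acceptor"),
                            group="water",
                            h_count=2,
                        )
                    )
    return typed


def type_ligand_atoms(
    s: Structure,
    ligand_config: dict[str, dict[str, dict]],
) -> list[TypedAtom]:
    """Type hetero-residue atoms from a ligand template config.

    ``ligand_config`` maps het code -> atom name -> {roles, group, side};
    het residues without a template are left untyped with a warning.
    The ligand partition (diphosphate / aminopyrimidine / thiazole /
    methylene-bridge / xylulose / ...) rides in on the ``side`` field.
    """
    typed: list[TypedAtom] = []
    missing: set[str] = set()
    group_atoms = [
        (res, atom)
        for res in s.ligands
        if not res.is_water and not res.is_metal
        for atom in res.atoms
    ]
    for res in s.ligands:
        if res.is_water or res.is_metal:
            continue
        template = ligand_config.get(res.name)
        if template is None:
            missing.add(res.name)
            continue
        for atom in res.atoms:
            spec = template.get(atom.name)
            if spec is None:
                continue
            heavy, hs = _neighbors_within(
                atom, [a for r, a in group_atoms]
            )
            typed.append(
                TypedAtom(
                    residue=res,
                    atom=atom,
                    roles=tuple(spec.get("roles", ())),
                    group=spec.get("group", atom.name),
                    h_count=int(spec.get("h_count", 0)),
                    ligand_side=spec.get("side", "other"),
                    neighbors=heavy,
                    hydrogens=hs,
                )
            )
    if missing:
        import warnings

        warnings.warn(
            f"no ligand template for het residue(s) {sorted(missing)}; "
            "their atoms are untyped",
            stacklevel=2,
        )
    return typed


# ---------------------------------------------------------------------------
# hydrogen bonds

@dataclass
class HBond:
    donor: TypedAtom
    acceptor: TypedAtom
    d_DA: float
    angle_at_donor: Optional[float] = None
    ligand_side: Optional[str] = None

    @property
    def protein_atom(self) -> TypedAtom:
        return self.donor if self.donor.ligand_side is None else self.acceptor

    @property
    def ligand_atom(self) -> TypedAtom:
        return self.acceptor if self.donor.ligand_side is None else self.donor

    def group_key(self) -> tuple:
        p = self.protein_atom
        ptr = p.pointer
        return (ptr.chain_id, ptr.number, ptr.icode, p.group)

    def to_row(self) -> dict:
        return {
            "donor": f"{self.donor.residue.name} {self.donor.pointer} {self.donor.atom.name}",
            "donor_group": self.donor.group,
            "acceptor": f"{self.acceptor.residue.name} {self.acceptor.pointer} {self.acceptor.atom.name}",
            "acceptor_group": self.acceptor.group,
            "d_DA": round(self.d_DA, 3),
            "angle_at_donor": None
            if self.angle_at_donor is None
            else round(self.angle_at_donor, 1),
            "ligand_side": self.ligand_side,
        }


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        return 180.0
    cosv = float(np.dot(v1, v2) / (n1 * n2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def _pair_is_hbond(
    donor: TypedAtom, acceptor: TypedAtom, p: GeometryParams
) -> Optional[HBond]:
    if "donor" not in donor.roles or "acceptor" not in acceptor.roles:
        return None
    if donor.key == acceptor.key:
        return None
    d = float(np.linalg.norm(donor.coords - acceptor.coords))
    if d > p.d_DA_max or d < 1.5:  # closer than 1.5 A is covalent/clash
        return None
    for nb in donor.neighbors:
        if _angle(nb, donor.coords, acceptor.coords) < p.donor_angle_min:
            return None
    for nb in acceptor.neighbors:
        if _angle(nb, acceptor.coords, donor.coords) < p.acceptor_angle_min:
            return None
    angle_dha = None
    if donor.hydrogens:
        best = None
        for h in donor.hydrogens:
            ah = float(np.linalg.norm(h - acceptor.coords))
            ang = _angle(donor.coords, h, acceptor.coords)
            if best is None or ang > best[1]:
                best = (ah, ang)
        angle_dha = best[1]
        if not p.heavy_atom_only:
            ok = any(
                float(np.linalg.norm(h - acceptor.coords)) <= p.d_HA_max
                and _angle(donor.coords, h, acceptor.coords) >= p.angle_DHA_min
                for h in donor.hydrogens
            )
            if not ok:
                return None
    side = donor.ligand_side if donor.ligand_side is not None else acceptor.ligand_side
    return HBond(donor=donor, acceptor=acceptor, d_DA=d, angle_at_donor=angle_dha,
                 ligand_side=side)


def detect_hbonds(
    protein: Sequence[TypedAtom],
    ligand: Sequence[TypedAtom],
    p: GeometryParams = GeometryParams(),
    metal_coords: Optional[np.ndarray] = None,
) -> list[HBond]:
    """All protein--ligand donor/acceptor pairs satisfying the geometric
    criteria, in deterministic (chain, residue, atom) order.

    Pairs in which both partners coordinate the same metal (within
    ``metal_coord_max``) are treated as metal-mediated and excluded.
    """
    if not protein or not ligand:
        return []
    lig_xyz = np.array([t.coords for t in ligand])
    tree = cKDTree(lig_xyz)
    found: list[HBond] = []
    for prot in protein:
        for j in tree.query_ball_point(prot.coords, p.d_DA_max):
            lig = ligand[j]
            for donor, acceptor in ((prot, lig), (lig, prot)):
                hb = _pair_is_hbond(donor, acceptor, p)
                if hb is None:
                    continue
                if metal_coords is not None and len(metal_coords):
                    dm1 = np.linalg.norm(metal_coords - hb.donor.coords, axis=1)
                    dm2 = np.linalg.norm(metal_coords - hb.acceptor.coords, axis=1)
                    if np.any((dm1 <= p.metal_coord_max) & (dm2 <= p.metal_coord_max)):
                        continue
                found.append(hb)
    found.sort(key=lambda h: (h.donor.key, h.acceptor.key))
    # a donor-or-acceptor pair facing another donor-or-acceptor can satisfy
    # the test in both directions; keep the first (deterministic) direction
    seen: set[tuple] = set()
    unique = []
    for hb in found:
        pair = tuple(sorted((hb.donor.key, hb.acceptor.key)))
        if pair in seen:
            continue
        seen.add(pair)
        unique.append(hb)
    return unique


def count_protein_groups(
    hbonds: Sequence[HBond], ligand_side: Optional[str] = None
) -> int:
    """Distinct (residue, chemical-group) pairs on the protein side among
    hydrogen bonds to the selected ligand side."""
    keys = {
        hb.group_key()
        for hb in hbonds
        if ligand_side is None or hb.ligand_side == ligand_side
    }
    return len(keys)


# ---------------------------------------------------------------------------
# metal coordination

@dataclass
class MetalContact:
    metal: Residue
    partner_residue: Residue
    partner_atom: Atom
    distance: float
    partner_is_ligand: bool

    def to_row(self) -> dict:
        return {
            "metal": f"{self.metal.name} {self.metal.pointer}",
            "partner": f"{self.partner_residue.name} {self.partner_residue.pointer} "
                       f"{self.partner_atom.name}",
            "distance": round(self.distance, 3),
            "partner_is_ligand": self.partner_is_ligand,
        }


def detect_metal_coordination(
    s: Structure,
    p: GeometryParams = GeometryParams(),
    elements: Optional[set[str]] = None,
) -> list[MetalContact]:
    """O/N/S atoms (protein or ligand) within ``metal_coord_max`` of each
    metal ion."""
    metals = [
        r for r in s.ligands
        if r.is_metal and (elements is None or r.atoms[0].element.upper() in elements)
    ]
    contacts: list[MetalContact] = []
    if not metals:
        return contacts
    candidates: list[tuple[Residue, Atom, bool]] = []
    for res, atom in s.polymer_atoms():
        if atom.element.upper() in ("O", "N", "S"):
            candidates.append((res, atom, False))
    for res in s.ligands:
        if res.is_metal or res.is_water:
            continue
        for atom in res.atoms:
            if atom.element.upper() in ("O", "N", "S"):
                candidates.append((res, atom, True))
    for metal in metals:
        mc = metal.atoms[0].coords
        for res, atom, is_lig in candidates:
            d = float(np.linalg.norm(atom.coords - mc))
            if d <= p.metal_coord_max:
                contacts.append(MetalContact(metal, res, atom, d, is_lig))
    contacts.sort(key=lambda c: (c.metal.pointer.chain_id, c.metal.number, c.distance))
    return contacts


# ---------------------------------------------------------------------------
# hydrophobic contacts and the cleft

@dataclass
class HydropathyContact:
    residue: Residue
    kd: float
    min_distance_to_probe: float
    side_chain_heavy_atoms_in_contact: int

    def to_row(self) -> dict:
        return {
            "residue": f"{self.residue.name} {self.residue.pointer}",
            "kd": self.kd,
            "min_distance": round(self.min_distance_to_probe, 3),
            "atoms_in_contact": self.side_chain_heavy_atoms_in_contact,
        }


def hydrophobic_nodule(
    s: Structure,
    probe_coords: np.ndarray,
    p: GeometryParams = GeometryParams(),
    kd_min: float = 0.0,
) -> list[HydropathyContact]:
    """Residues whose side-chain heavy atoms touch the probe selection
    (within ``contact_max``) and whose Kyte-Doolittle value is >= ``kd_min``,
    ranked by minimum distance.

    For the transketolase cofactor the natural probe is the methylene bridge
    linking the aminopyrimidine and thiazole rings; the top-ranked residue is
    the "hydrophobic nodule" bracing the cofactor's V-conformation.
    """
    probe = np.atleast_2d(np.asarray(probe_coords, dtype=float))
    if probe.size == 0:
        raise ValueError("empty probe selection")
    out: list[HydropathyContact] = []
    for chain in s.chains:
        for res in chain:
            kd = KD_SCALE.get(res.name)
            if kd is None or kd < kd_min:
                continue
            side_atoms = [
                a for a in res.heavy_atoms() if a.name not in BACKBONE_NAMES
            ]
            if not side_atoms:
                continue
            dmin = math.inf
            n_contact = 0
            for a in side_atoms:
                d = float(np.min(np.linalg.norm(probe - a.coords, axis=1)))
                dmin = min(dmin, d)
                if d <= p.contact_max:
                    n_contact += 1
            if n_contact:
                out.append(HydropathyContact(res, kd, dmin, n_contact))
    out.sort(key=lambda c: c.min_distance_to_probe)
    return out


def cleft_check(
    s: Structure,
    radius: float = 5.0,
    include_waters: bool = False,
) -> dict:
    """Count protein atoms within ``radius`` of the ligand, per chain.

    The inter-subunit cleft flag is true iff at least two chains contact the
    ligand — the signature of an active site at a homodimer interface.
    """
    lig_xyz = np.array(
        [a.coords for r, a in s.ligand_atoms(include_waters) if not r.is_metal]
    )
    counts: dict[str, int] = {}
    for chain in s.chains:
        n = 0
        if lig_xyz.size:
            tree = cKDTree(lig_xyz)
            for res in chain:
                for a in res.atoms:
                    if tree.query_ball_point(a.coords, radius):
                        n += 1
        counts[chain.id] = n
    touching = sum(1 for v in counts.values() if v > 0)
    return {
        "per_chain": counts,
        "inter_subunit_cleft": (touching >= 2) if len(s.chains) >= 2 else None,
        "radius": radius,
    }
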