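"""Deterministic generators for synthetic structures and alignments.

Everything the test suite needs is built here, from a seed, at run time:
dimeric toy proteins with an inter-chain pseudo-ligand, planted hydrogen-bond
geometries, a known rigid transform plus coordinate noise relating a
"template" and a "query" copy, torsion-true peptides, and two-row alignments
with prescribed identity/conservation structure.  Each generator returns its
ground truth alongside the data, so detection results can be checked against
what was planted rather than against re-derived quantities.

The protein scaffold is a coarse helix with ideal bond lengths and
tree-placed side chains: chemically plausible distances and connectivity,
not energy-minimised realism — which is all the geometric operators see.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from tklscan.msa_metrics import ConservationScheme, DEFAULT_SCHEME
from tklscan.structure_io import Atom, Chain, Residue, ResiduePointer, Structure
from tklscan.superpose import RigidTransform

__all__ = [
    "LigandAtomSpec",
    "PlantedHBond",
    "ToyComplexSpec",
    "PlantingError",
    "make_toy_dimer",
    "make_toy_alignment",
    "make_torsion_peptide",
    "DEFAULT_LIGAND",
]


class PlantingError(ValueError):
    """A requested geometric planting cannot be satisfied."""


# ---------------------------------------------------------------------------
# internal-coordinate placement (NeRF)

def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position a new atom bonded to ``c`` at the given internal coordinates
    (angle = angle(b,c,new); torsion = dihedral(a,b,c,new)), degrees."""
    ang = math.radians(angle)
    tor = -math.radians(torsion)  # sign matched to the IUPAC dihedral
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("collinear reference atoms in internal placement")
    n /= nn
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


# ideal backbone geometry
_B = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_A = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.5}

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

# side-chain heavy-atom trees: (atom, parent, element)
_SIDE: dict[str, list[tuple[str, str, str]]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", "CB", "O")],
    "CYS": [("SG", "CB", "S")],
    "THR": [("OG1", "CB", "O"), ("CG2", "CB", "C")],
    "VAL": [("CG1", "CB", "C"), ("CG2", "CB", "C")],
    "LEU": [("CG", "CB", "C"), ("CD1", "CG", "C"), ("CD2", "CG", "C")],
    "ILE": [("CG1", "CB", "C"), ("CG2", "CB", "C"), ("CD1", "CG1", "C")],
    "MET": [("CG", "CB", "C"), ("SD", "CG", "S"), ("CE", "SD", "C")],
    "PHE": [("CG", "CB", "C"), ("CD1", "CG", "C"), ("CD2", "CG", "C"),
            ("CE1", "CD1", "C"), ("CE2", "CD2", "C"), ("CZ", "CE1", "C")],
    "TYR": [("CG", "CB", "C"), ("CD1", "CG", "C"), ("CD2", "CG", "C"),
            ("CE1", "CD1", "C"), ("CE2", "CD2", "C"), ("CZ", "CE1", "C"),
            ("OH", "CZ", "O")],
    "TRP": [("CG", "CB", "C"), ("CD1", "CG", "C"), ("NE1", "CD1", "N"),
            ("CD2", "CG", "C")],
    "ASP": [("CG", "CB", "C"), ("OD1", "CG", "O"), ("OD2", "CG", "O")],
    "GLU": [("CG", "CB", "C"), ("CD", "CG", "C"), ("OE1", "CD", "O"),
            ("OE2", "CD", "O")],
    "ASN": [("CG", "CB", "C"), ("OD1", "CG", "O"), ("ND2", "CG", "N")],
    "GLN": [("CG", "CB", "C"), ("CD", "CG", "C"), ("OE1", "CD", "O"),
            ("NE2", "CD", "N")],
    "LYS": [("CG", "CB", "C"), ("CD", "CG", "C"), ("CE", "CD", "C"),
            ("NZ", "CE", "N")],
    "ARG": [("CG", "CB", "C"), ("CD", "CG", "C"), ("NE", "CD", "N"),
            ("CZ", "NE", "C"), ("NH1", "CZ", "N"), ("NH2", "CZ", "N")],
    "HIS": [("CG", "CB", "C"), ("ND1", "CG", "N"), ("CD2", "CG", "C"),
            ("CE1", "ND1", "C"), ("NE2", "CE1", "N")],
    "PRO": [("CG", "CB", "C"), ("CD", "CG", "C")],
}

_SIDE_BOND = {"C": 1.52, "N": 1.47, "O": 1.42, "S": 1.81}


def _build_backbone(
    phi_psi: Sequence[tuple[Optional[float], Optional[float]]],
) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C/O positions realizing the requested torsions with
    ideal bond lengths and angles; omega fixed trans (180 degrees)."""
    n = len(phi_psi)
    if n == 0:
        return []
    coords: list[dict[str, np.ndarray]] = []
    N0 = np.zeros(3)
    CA0 = np.array([_B["N-CA"], 0.0, 0.0])
    ang = math.radians(_A["N-CA-C"])
    C0 = CA0 + _B["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": N0, "CA": CA0, "C": C0})
    for i in range(1, n):
        prev = coords[i - 1]
        psi_prev = phi_psi[i - 1][1]
        psi_prev = 180.0 if psi_prev is None else psi_prev
        Ni = _place(prev["N"], prev["CA"], prev["C"],
                    _B["C-N"], _A["CA-C-N"], psi_prev)
        CAi = _place(prev["CA"], prev["C"], Ni,
                     _B["N-CA"], _A["C-N-CA"], 180.0)
        phi_i = phi_psi[i][0]
        phi_i = 180.0 if phi_i is None else phi_i
        Ci = _place(prev["C"], Ni, CAi, _B["CA-C"], _A["N-CA-C"], phi_i)
        coords.append({"N": Ni, "CA": CAi, "C": Ci})
    # carbonyl oxygens: anti to the next amide nitrogen
    for i in range(n):
        psi_i = phi_psi[i][1]
        tor = (psi_i + 180.0) if psi_i is not None else 0.0
        coords[i]["O"] = _place(
            coords[i]["N"], coords[i]["CA"], coords[i]["C"],
            _B["C-O"], _A["CA-C-O"], tor,
        )
    return coords


def _build_chain(
    sequence: str,
    chain_id: str,
    phi: float = -57.0,
    psi: float = -47.0,
    start_number: int = 1,
) -> Chain:
    """Helical poly-peptide chain with tree-placed side chains."""
    n = len(sequence)
    bb = _build_backbone([(phi, psi)] * n)
    chain = Chain(id=chain_id)
    serial = 1
    for i, letter in enumerate(sequence):
        resname = _ONE_TO_THREE.get(letter.upper(), "ALA")
        res = Residue(
            name=resname, number=start_number + i, chain_id=chain_id
        )
        pos: dict[str, np.ndarray] = dict(bb[i])
        order = ["N", "CA", "C", "O"]
        if resname != "GLY":
            # CB along the tetrahedral direction away from N and C
            ca, nn, cc = pos["CA"], pos["N"], pos["C"]
            d1 = (nn - ca) / np.linalg.norm(nn - ca)
            d2 = (cc - ca) / np.linalg.norm(cc - ca)
            perp = np.cross(d2, d1)
            bisec = -(d1 + d2)
            bisec /= np.linalg.norm(bisec)
            cb_dir = bisec * math.cos(math.radians(54.0)) + perp * math.sin(
                math.radians(54.0)
            )
            pos["CB"] = ca + 1.53 * cb_dir / np.linalg.norm(cb_dir)
            order.append("CB")
            parent = {"CB": "CA", "CA": "N", "N": "C"}
            placed_children: dict[str, int] = {}
            for name, par, elem in _SIDE.get(resname, []):
                g = parent.get(par)
                gg = parent.get(g, "N")
                k = placed_children.get(par, 0)
                placed_children[par] = k + 1
                torsion = {0: 180.0, 1: -60.0, 2: 60.0}.get(k, 180.0)
                if par == "CB":
                    torsion = {0: -175.0, 1: -55.0, 2: 65.0}.get(k, 180.0)
                pos[name] = _place(
                    pos[gg], pos[g], pos[par],
                    _SIDE_BOND.get(elem, 1.52), 112.0, torsion,
                )
                parent[name] = par
                order.append(name)
        for name in order:
            elem = name[:1] if name[:1] in ("N", "C", "O", "S") else "C"
            if name in ("SG", "SD"):
                elem = "S"
            res.atoms.append(
                Atom(serial=serial, name=name, element=elem, coords=pos[name])
            )
            serial += 1
        chain.residues.append(res)
    return chain


# ---------------------------------------------------------------------------
# toy dimer with pseudo-ligand

@dataclass(frozen=True)
class LigandAtomSpec:
    name: str
    element: str = "O"
    side: str = "other"
    roles: tuple[str, ...] = ("acceptor",)
    group: str = "pseudo-O"


@dataclass(frozen=True)
class PlantedHBond:
    """Plant a ligand atom at H-bond geometry from a protein donor atom."""

    resnum: int
    atom: str
    ligand_atom: str
    d_DA: float = 2.9
    chain_id: str = "A"


#: a TDP-X5P-adduct-shaped pseudo-ligand: diphosphate oxygens, ring
#: heteroatoms on either side of a methylene bridge, and sugar hydroxyls
DEFAULT_LIGAND: tuple[LigandAtomSpec, ...] = (
    LigandAtomSpec("O1", "O", "diphosphate", ("acceptor",), "phosphate-O"),
    LigandAtomSpec("O2", "O", "diphosphate", ("acceptor",), "phosphate-O"),
    LigandAtomSpec("O3", "O", "diphosphate", ("acceptor",), "phosphate-O"),
    LigandAtomSpec("N1", "N", "aminopyrimidine", ("acceptor",), "ring-N"),
    LigandAtomSpec("C7", "C", "methylene-bridge", (), "methylene"),
    LigandAtomSpec("S1", "S", "thiazole", ("acceptor",), "thiazole-S"),
    LigandAtomSpec("O4", "O", "xylulose", ("acceptor", "donor"), "sugar-OH"),
    LigandAtomSpec("O5", "O", "xylulose", ("acceptor", "donor"), "sugar-OH"),
)


@dataclass
class ToyComplexSpec:
    seed: int = 0
    n_residues_per_chain: int = 40
    sequence: Optional[str] = None
    ligand_spec: tuple[LigandAtomSpec, ...] = DEFAULT_LIGAND
    planted_hbonds: tuple[PlantedHBond, ...] = ()
    planted_transform: RigidTransform = field(default_factory=RigidTransform.identity)
    noise_sigma: float = 0.0
    planted_deletion: Optional[tuple[int, int]] = None
    chain_gap: float = 22.0
    ligand_spacing: float = 3.2
    query_numbering_offset: int = 0
    include_metal: bool = False
    metal_distance: float = 2.1

    def resolved_sequence(self) -> str:
        if self.sequence is not None:
            if len(self.sequence) != self.n_residues_per_chain:
                raise ValueError("sequence length != n_residues_per_chain")
            return self.sequence.upper()
        rng = np.random.default_rng(self.seed)
        letters = "ASKLETNVQHGRFDYIM"  # varied, donor-rich, no W/C/P surprises
        return "".join(
            letters[int(i)] for i in rng.integers(0, len(letters),
                                                  self.n_residues_per_chain)
        )


def _default_sequence_check(spec: ToyComplexSpec) -> None:
    if spec.planted_deletion is not None:
        a, b = spec.planted_deletion
        if not (1 <= a <= b <= spec.n_residues_per_chain):
            raise PlantingError(
                f"deletion interval {spec.planted_deletion} outside chain "
                f"numbering 1..{spec.n_residues_per_chain}"
            )


def make_toy_dimer(
    spec: ToyComplexSpec,
) -> tuple[Structure, Structure, dict]:
    """Build (template, query, truth).

    The template is a two-chain helical scaffold with the pseudo-ligand in
    the inter-chain cleft (chain B is chain A rotated 180 degrees about the
    cleft axis, so an unplanted ligand sees both chains symmetrically).  The
    query is the template with the planted deletion removed, the ligand
    stripped, the planted rigid transform applied and Gaussian coordinate
    noise added.  The truth record carries every planted quantity.
    """
    _default_sequence_check(spec)
    rng = np.random.default_rng(spec.seed)
    seq = spec.resolved_sequence()

    chain_a = _build_chain(seq, "A")
    a_xyz = np.array([a.coords for r in chain_a for a in r.atoms])
    centroid = a_xyz.mean(axis=0)
    # principal axis of the chain; the cleft opens perpendicular to it
    _, _, vt = np.linalg.svd(a_xyz - centroid)
    axis, normal = vt[0], vt[2]
    cleft_center = centroid + normal * (spec.chain_gap / 2.0)

    # chain B: rotate A by 180 deg about the cleft axis through the center,
    # so an axis-aligned ligand sees both chains with identical distance sets
    R_flip = 2.0 * np.outer(axis, axis) - np.eye(3)
    chain_b = Chain(id="B")
    serial = 100000
    for res in chain_a.residues:
        rb = Residue(name=res.name, number=res.number, chain_id="B")
        for at in res.atoms:
            serial += 1
            rb.atoms.append(
                Atom(
                    serial=serial, name=at.name, element=at.element,
                    coords=R_flip @ (at.coords - cleft_center) + cleft_center,
                )
            )
        chain_b.residues.append(rb)

    template = Structure(id="toy-template", chains=[chain_a, chain_b])

    # --- ligand ------------------------------------------------------------
    planted_names = {p.ligand_atom for p in spec.planted_hbonds}
    unplanted = [s for s in spec.ligand_spec if s.name not in planted_names]
    for p in spec.planted_hbonds:
        if p.ligand_atom not in {s.name for s in spec.ligand_spec}:
            raise PlantingError(
                f"planted ligand atom {p.ligand_atom!r} not in the ligand spec"
            )

    lig = Residue(name="TLX", number=500, chain_id="X")
    positions: dict[str, np.ndarray] = {}
    # unplanted atoms: spaced along the cleft axis (x), symmetric around the
    # cleft center
    for k, aspec in enumerate(unplanted):
        off = (k - (len(unplanted) - 1) / 2.0) * spec.ligand_spacing
        positions[aspec.name] = cleft_center + off * axis
    # planted atoms: extended from the donor along its free valence
    protein_atoms = [
        (r, a) for c in template.chains for r in c for a in r.atoms
    ]
    for p in spec.planted_hbonds:
        res = template.chain(p.chain_id).residue(p.resnum)
        if res is None:
            raise PlantingError(f"planted residue {p.chain_id}/{p.resnum} not found")
        donor = res.atom(p.atom)
        if donor is None:
            raise PlantingError(
                f"planted atom {p.atom!r} not found on {res.name} {p.resnum}"
            )
        neighbors = [
            a.coords for a in res.atoms
            if a is not donor
            and np.linalg.norm(a.coords - donor.coords) < 2.0
        ]
        if not neighbors:
            direction = donor.coords - res.atom("CA").coords
        else:
            direction = np.zeros(3)
            for nb in neighbors:
                v = donor.coords - nb
                direction += v / np.linalg.norm(v)
            if np.linalg.norm(direction) < 1e-6:
                raise PlantingError(
                    f"donor {p.atom} of residue {p.resnum}: no free valence direction"
                )
        direction /= np.linalg.norm(direction)
        positions[p.ligand_atom] = donor.coords + p.d_DA * direction

    # satisfiability checks
    order = [s.name for s in spec.ligand_spec]
    for i, n1 in enumerate(order):
        for n2 in order[i + 1:]:
            if np.linalg.norm(positions[n1] - positions[n2]) < 2.2:
                raise PlantingError(
                    f"ligand atoms {n1} and {n2} closer than 2.2 A; adjust "
                    "spacing or planted geometry"
                )
    donors_by_plant = {
        p.ligand_atom: (p.chain_id, p.resnum, p.atom) for p in spec.planted_hbonds
    }
    for aspec in spec.ligand_spec:
        pos = positions[aspec.name]
        guard = 1.5 if aspec.name in planted_names else 4.0
        for r, a in protein_atoms:
            if aspec.name in planted_names and (
                (r.chain_id, r.number, a.name) == donors_by_plant[aspec.name]
            ):
                continue
            d = float(np.linalg.norm(pos - a.coords))
            if d < guard:
                raise PlantingError(
                    f"ligand atom {aspec.name} clashes with protein atom "
                    f"{a.name} of {r.name} {r.chain_id}/{r.number} at {d:.2f} A "
                    f"(< {guard} A)"
                )
    for k, aspec in enumerate(spec.ligand_spec):
        lig.atoms.append(
            Atom(serial=900 + k, name=aspec.name, element=aspec.element,
                 coords=positions[aspec.name], is_hetero=True)
        )
    template.ligands.append(lig)

    if spec.include_metal:
        # metal planted near the first two unplanted ligand oxygens
        oxy = [positions[s.name] for s in unplanted if s.element == "O"][:2]
        if len(oxy) < 2:
            raise PlantingError("metal planting needs two unplanted oxygens")
        mid = (oxy[0] + oxy[1]) / 2.0
        axis = oxy[1] - oxy[0]
        half = float(np.linalg.norm(axis)) / 2.0
        if spec.metal_distance <= half:
            raise PlantingError(
                "metal_distance smaller than half the oxygen separation"
            )
        perp = np.cross(axis, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        lift = math.sqrt(spec.metal_distance**2 - half**2)
        mg = Residue(name="MG", number=501, chain_id="X")
        mg.atoms.append(
            Atom(serial=990, name="MG", element="MG", coords=mid + lift * perp,
                 is_hetero=True)
        )
        template.ligands.append(mg)

    # --- query -------------------------------------------------------------
    query = Structure(id="toy-query")
    correspondence: list[tuple[ResiduePointer, Optional[ResiduePointer]]] = []
    for chain in template.chains:
        qc = Chain(id=chain.id)
        for res in chain:
            deleted = (
                chain.id == "A"
                and spec.planted_deletion is not None
                and spec.planted_deletion[0] <= res.number <= spec.planted_deletion[1]
            )
            if deleted:
                if chain.id == "A":
                    correspondence.append((res.pointer, None))
                continue
            qnum = res.number + spec.query_numbering_offset
            qr = Residue(name=res.name, number=qnum, chain_id=chain.id)
            for at in res.atoms:
                noise = (
                    rng.normal(0.0, spec.noise_sigma, 3)
                    if spec.noise_sigma > 0
                    else np.zeros(3)
                )
                qr.atoms.append(
                    Atom(
                        serial=at.serial, name=at.name, element=at.element,
                        coords=spec.planted_transform.apply(at.coords) + noise,
                    )
                )
            qc.residues.append(qr)
            if chain.id == "A":
                correspondence.append(
                    (res.pointer, ResiduePointer(chain.id, qnum))
                )
        query.chains.append(qc)

    # --- truth -------------------------------------------------------------
    tmpl_seq = seq
    if spec.planted_deletion is None:
        qry_row = tmpl_seq
    else:
        a, b = spec.planted_deletion
        qry_row = "".join(
            "-" if a <= i + 1 <= b else ch for i, ch in enumerate(tmpl_seq)
        )
    from tklscan.structure_io import Alignment

    truth = {
        "seed": spec.seed,
        "transform": spec.planted_transform,
        "noise_sigma": spec.noise_sigma,
        "sequence": seq,
        "alignment": Alignment(names=["template", "query"],
                               rows=[tmpl_seq, qry_row]),
        "deletion": None
        if spec.planted_deletion is None
        else {
            "start": spec.planted_deletion[0],
            "end": spec.planted_deletion[1],
            "length": spec.planted_deletion[1] - spec.planted_deletion[0] + 1,
            "start_name": seq[spec.planted_deletion[0] - 1],
            "end_name": seq[spec.planted_deletion[1] - 1],
        },
        "correspondence": correspondence,
        "hbonds": [
            {
                "chain": p.chain_id,
                "resnum": p.resnum,
                "atom": p.atom,
                "ligand_atom": p.ligand_atom,
                "d_DA": p.d_DA,
            }
            for p in spec.planted_hbonds
        ],
        "ligand_typing": {
            "TLX": {
                s.name: {
                    "roles": list(s.roles),
                    "group": s.group,
                    "side": s.side,
                }
                for s in spec.ligand_spec
            }
        },
    }
    return template, query, truth


# ---------------------------------------------------------------------------
# alignments with prescribed column-category counts

def make_toy_alignment(
    seed: int,
    length: int,
    target_identical: int,
    target_conserved: int,
    scheme: ConservationScheme = DEFAULT_SCHEME,
    names: tuple[str, str] = ("ref", "query"),
):
    """Two ungapped rows with exactly the requested numbers of identical and
    conserved (identical-or-similar) columns under ``scheme``."""
    from tklscan.structure_io import Alignment

    if not (0 <= target_identical <= target_conserved <= length):
        raise ValueError(
            "need 0 <= target_identical <= target_conserved <= length"
        )
    rng = np.random.default_rng(seed)
    multi = [g for g in scheme.groups if len(g) >= 2]
    if not multi and target_conserved > target_identical:
        raise ValueError("scheme has no multi-letter group for similar columns")
    categories = (
        ["identical"] * target_identical
        + ["similar"] * (target_conserved - target_identical)
        + ["different"] * (length - target_conserved)
    )
    rng.shuffle(categories)
    all_letters = "ACDEFGHIKLMNPQRSTVWY"
    row_a, row_b = [], []
    for cat in categories:
        if cat == "identical":
            ch = all_letters[int(rng.integers(0, 20))]
            row_a.append(ch)
            row_b.append(ch)
        elif cat == "similar":
            g = multi[int(rng.integers(0, len(multi)))]
            i, j = rng.choice(len(g), size=2, replace=False)
            row_a.append(g[int(i)])
            row_b.append(g[int(j)])
        else:
            while True:
                x = all_letters[int(rng.integers(0, 20))]
                y = all_letters[int(rng.integers(0, 20))]
                if x != y and not scheme.conserved(x, y):
                    break
            row_a.append(x)
            row_b.append(y)
    aln = Alignment(names=list(names), rows=["".join(row_a), "".join(row_b)])
    truth = {
        "seed": seed,
        "n_identical": target_identical,
        "n_conserved": target_conserved,
        "length": length,
        "categories": categories,
    }
    return aln, truth


# ---------------------------------------------------------------------------
# torsion-true peptides

def make_torsion_peptide(
    seed: int,
    phi_psi_list: Sequence[tuple[float, float]],
    sequence: Optional[str] = None,
) -> Structure:
    """Backbone built by successive internal-coordinate placement realizing
    the requested (phi, psi) per residue (the first phi and last psi have no
    geometric meaning and are ignored)."""
    n = len(phi_psi_list)
    chain = Chain(id="A")
    if n:
        seq = (sequence or "A" * n).upper()
        if len(seq) != n:
            raise ValueError("sequence length != number of torsion pairs")
        bb = _build_backbone(list(phi_psi_list))
        serial = 0
        for i in range(n):
            res = Residue(
                name=_ONE_TO_THREE.get(seq[i], "ALA"), number=i + 1, chain_id="A"
            )
            for name in ("N", "CA", "C", "O"):
                serial += 1
                res.atoms.append(
                    Atom(serial=serial, name=name, element=name[0],
                         coords=bb[i][name])
                )
            chain.residues.append(res)
    return Structure(id=f"torsion-peptide-{seed}", chains=[chain])
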