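"""Stereochemical validation: backbone torsions and Ramachandran fractions.

phi is the C(i-1)-N-CA-C torsion, psi the N-CA-C-N(i+1) torsion, both signed
per the IUPAC convention and reported in (-180, 180].  Residues are binned
into the usual four torsion classes (general / glycine / proline /
pre-proline) and classified against editable region polygons; the shipped
polygons are coarse, so fractions against numbers printed by external
validation servers are tolerance comparisons by design.

Rotamer analysis and 3D-1D environment profiling are intentionally not
computed here; every summary says so explicitly so that downstream reports
cannot silently imply them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from matplotlib.path import Path as MplPath

from tklscan.structure_io import ResiduePointer, Structure

__all__ = [
    "RamaRecord",
    "dihedral",
    "phi_psi",
    "load_region_map",
    "rama_classify",
    "NOT_COMPUTED",
]

#: validation analyses this module deliberately does not perform
NOT_COMPUTED = ("3D-1D profile score", "rotamer analysis")

CHAIN_BREAK_CA_CA = 4.5


@dataclass
class RamaRecord:
    pointer: ResiduePointer
    name: str
    phi: Optional[float]
    psi: Optional[float]
    residue_class: str = "general"
    region: str = "undefined"

    @property
    def defined(self) -> bool:
        return self.phi is not None and self.psi is not None


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, range (-180, 180].

    Positive when, looking down the p2->p3 axis, the far bond is rotated
    clockwise from the near bond (IUPAC).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if min(np.linalg.norm(b1), np.linalg.norm(b2), np.linalg.norm(b3)) < 1e-9:
        raise ValueError("degenerate geometry: consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("degenerate geometry: collinear points")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def phi_psi(s: Structure, chain_id: str) -> list[RamaRecord]:
    """Backbone torsions for a chain; chain breaks (CA-CA > 4.5 A or missing
    backbone atoms) are treated as termini and leave angles undefined."""
    chain = s.chain(chain_id)
    residues = chain.residues
    n = len(residues)

    def backbone(i):
        if i < 0 or i >= n:
            return None
        r = residues[i]
        atoms = {name: r.atom(name) for name in ("N", "CA", "C")}
        if any(a is None for a in atoms.values()):
            return None
        return atoms

    def connected(i, j) -> bool:
        a, b = backbone(i), backbone(j)
        if a is None or b is None:
            return False
        return (
            float(np.linalg.norm(a["CA"].coords - b["CA"].coords))
            <= CHAIN_BREAK_CA_CA
        )

    records: list[RamaRecord] = []
    for i, res in enumerate(residues):
        bb = backbone(i)
        phi = psi = None
        if bb is not None:
            if connected(i - 1, i):
                prev_c = residues[i - 1].atom("C")
                phi = dihedral(
                    prev_c.coords, bb["N"].coords, bb["CA"].coords, bb["C"].coords
                )
            if connected(i, i + 1):
                next_n = residues[i + 1].atom("N")
                psi = dihedral(
                    bb["N"].coords, bb["CA"].coords, bb["C"].coords, next_n.coords
                )
        if res.name == "GLY":
            rclass = "glycine"
        elif res.name == "PRO":
            rclass = "proline"
        elif i + 1 < n and residues[i + 1].name == "PRO":
            rclass = "pre-proline"
        else:
            rclass = "general"
        records.append(
            RamaRecord(
                pointer=res.pointer, name=res.name, phi=phi, psi=psi,
                residue_class=rclass,
            )
        )
    return records


# ---------------------------------------------------------------------------
# region classification

def load_region_map(path: Optional[str | Path] = None) -> dict:
    """Load region polygons (default: the packaged coarse map)."""
    if path is None:
        text = (
            resources.files("tklscan").joinpath("data/rama_regions.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    out: dict[str, dict[str, list[MplPath]]] = {}
    for rclass, levels in raw.items():
        out[rclass] = {
            level: [MplPath(np.asarray(poly, dtype=float)) for poly in polys]
            for level, polys in levels.items()
        }
    return out


def _inside(polys: Sequence[MplPath], phi: float, psi: float) -> bool:
    for dx in (-360.0, 0.0, 360.0):
        for dy in (-360.0, 0.0, 360.0):
            pt = (phi + dx, psi + dy)
            # half-degree slack so polygon edges (including the +/-180 seam)
            # count as inside; the sign of matplotlib's radius expansion
            # depends on vertex orientation, so test both
            if any(
                p.contains_point(pt, radius=0.5)
                or p.contains_point(pt, radius=-0.5)
                for p in polys
            ):
                return True
    return False


def rama_classify(
    records: Sequence[RamaRecord],
    region_map: Optional[dict] = None,
) -> dict:
    """Assign favored/allowed/outlier to each defined record and summarise.

    "allowed" in the summary is cumulative (favored polygons are inside the
    allowed envelope), matching how validation reports quote "residues in
    allowed regions".
    """
    if region_map is None:
        region_map = load_region_map()
    n_fav = n_allowed_only = n_out = n_undef = 0
    for rec in records:
        if not rec.defined:
            rec.region = "undefined"
            n_undef += 1
            continue
        levels = region_map.get(rec.residue_class) or region_map["general"]
        if _inside(levels.get("favored", []), rec.phi, rec.psi):
            rec.region = "favored"
            n_fav += 1
        elif _inside(levels.get("allowed", []), rec.phi, rec.psi) or _inside(
            levels.get("favored", []), rec.phi, rec.psi
        ):
            rec.region = "allowed"
            n_allowed_only += 1
        else:
            rec.region = "outlier"
            n_out += 1
    n_def = n_fav + n_allowed_only + n_out
    summary = {
        "n_residues": len(records),
        "n_defined": n_def,
        "n_undefined": n_undef,
        "n_favored": n_fav,
        "n_allowed": n_fav + n_allowed_only,
        "n_outlier": n_out,
        "pct_favored": 100.0 * n_fav / n_def if n_def else None,
        "pct_allowed": 100.0 * (n_fav + n_allowed_only) / n_def if n_def else None,
        "not_computed": list(NOT_COMPUTED),
    }
    return summary
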