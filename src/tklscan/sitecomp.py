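"""Active-site residue equivalence mapping and interaction-fate
classification.

Given the alignment map, each template site residue is paired with the query
residue occupying the same alignment column (or flagged absent — e.g. the
TKT residues H77 and H110 that fall inside the TKTL1 deletion).  With
interaction lists computed on the superposed, ligand-transplanted complexes,
every template interaction is then classified:

* conserved — the equivalent query residue interacts with the same region of
  the ligand;
* substituted — a *different* query residue, spatially close to where the
  template partner sat, takes over the interaction (the N185->H158 and
  I364->M337 cases);
* lost — nobody does;
* gained — a query-side interaction with no template counterpart.

Catalytic annotations are metadata carried on the site list; they are
reported but never used by the classification logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from tklscan.interactions import HBond
from tklscan.msa_metrics import AlignmentMap, ConservationScheme, DEFAULT_SCHEME
from tklscan.structure_io import ResiduePointer

__all__ = [
    "SiteResidue",
    "EquivalenceRecord",
    "load_site_config",
    "map_site_residues",
    "classify_interactions",
    "site_report",
]


@dataclass(frozen=True)
class SiteResidue:
    """A template active-site residue of interest, with optional catalytic
    annotation (reported, never used in classification)."""

    number: int
    name: str
    chain_id: str = "A"
    icode: str = ""
    catalytic: bool = False
    note: str = ""

    @property
    def pointer(self) -> ResiduePointer:
        return ResiduePointer(self.chain_id, self.number, self.icode)

    @property
    def label(self) -> str:
        one = _THREE_TO_ONE.get(self.name, "X")
        return f"{one}{self.number}{self.icode}"


@dataclass
class EquivalenceRecord:
    template: SiteResidue
    query_pointer: Optional[ResiduePointer]
    query_name: Optional[str]
    relation: str  # identical | similar | different | absent
    interaction_status: str = "not-detected"
    evidence_template: list[int] = field(default_factory=list)
    evidence_query: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.relation == "absent") != (self.query_pointer is None):
            raise ValueError("relation 'absent' must coincide with a missing query residue")

    @property
    def query_label(self) -> Optional[str]:
        if self.query_pointer is None:
            return None
        one = _THREE_TO_ONE.get(self.query_name or "", "X")
        return f"{one}{self.query_pointer.number}{self.query_pointer.icode}"


_ONE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
_THREE_TO_ONE = {v: k for k, v in _ONE.items()}


def load_site_config(path: Optional[str | Path] = None) -> list[SiteResidue]:
    """Site residue list (default: the packaged TKT active-site config)."""
    if path is None:
        text = (
            resources.files("tklscan").joinpath("data/site_residues_tkt.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return [
        SiteResidue(
            number=int(e["number"]),
            name=str(e["name"]).upper(),
            chain_id=str(e.get("chain", "A")),
            icode=str(e.get("icode", "")),
            catalytic=bool(e.get("catalytic", False)),
            note=str(e.get("note", "")),
        )
        for e in raw["residues"]
    ]


def map_site_residues(
    amap: AlignmentMap,
    template_site: Sequence[SiteResidue],
    template_id: str,
    query_id: str,
    scheme: ConservationScheme = DEFAULT_SCHEME,
) -> list[EquivalenceRecord]:
    """One record per template site residue, query counterpart taken from the
    same alignment column."""
    records = []
    for site in template_site:
        col = amap.column_of(template_id, site.pointer)
        if col is None:
            raise KeyError(
                f"template residue {site.label} not present in the alignment "
                f"binding for {template_id!r}"
            )
        qptr = amap.pointers[query_id][col]
        if qptr is None:
            records.append(
                EquivalenceRecord(site, None, None, relation="absent")
            )
            continue
        q_letter = amap.residue_names[query_id][col]
        t_letter = _THREE_TO_ONE.get(site.name, "X")
        if q_letter == t_letter:
            relation = "identical"
        elif scheme.conserved(t_letter, q_letter or "X"):
            relation = "similar"
        else:
            relation = "different"
        records.append(
            EquivalenceRecord(site, qptr, _ONE.get(q_letter or "", "UNK"), relation)
        )
    return records


def _interactions_by_residue(
    interactions: Sequence[HBond],
) -> dict[tuple[int, str], list[int]]:
    by_res: dict[tuple[int, str], list[int]] = {}
    for i, hb in enumerate(interactions):
        ptr = hb.protein_atom.pointer
        by_res.setdefault((ptr.number, ptr.icode), []).append(i)
    return by_res


def classify_interactions(
    records: Sequence[EquivalenceRecord],
    template_interactions: Sequence[HBond],
    query_interactions: Sequence[HBond],
    spatial_tolerance: float = 3.0,
) -> list[EquivalenceRecord]:
    """Fill ``interaction_status`` on each record.

    Both interaction lists must be computed in one coordinate frame (the
    query complex carrying the transplanted ligand, with the template
    superposed).  A substitution requires a different query residue whose
    interacting group sits within ``spatial_tolerance`` of the template
    partner's position *and* touches the same ligand side.
    """
    t_by_res = _interactions_by_residue(template_interactions)
    q_by_res = _interactions_by_residue(query_interactions)

    for rec in records:
        tp = rec.template.pointer
        t_ids = t_by_res.get((tp.number, tp.icode), [])
        rec.evidence_template = list(t_ids)
        q_ids: list[int] = []
        if rec.query_pointer is not None:
            q_ids = q_by_res.get(
                (rec.query_pointer.number, rec.query_pointer.icode), []
            )
        rec.evidence_query = list(q_ids)

        if not t_ids:
            rec.interaction_status = "gained" if q_ids else "not-detected"
            continue

        t_sides = {template_interactions[i].ligand_side for i in t_ids}
        q_sides = {query_interactions[i].ligand_side for i in q_ids}
        if t_sides & q_sides:
            rec.interaction_status = "conserved"
            continue

        # substitution: any other query residue interacting with the same
        # ligand side from near the template partner's position
        substituted = False
        sub_evidence: list[int] = []
        for i in t_ids:
            t_hb = template_interactions[i]
            t_pos = t_hb.protein_atom.coords
            for j, q_hb in enumerate(query_interactions):
                if rec.query_pointer is not None and (
                    q_hb.protein_atom.pointer.number == rec.query_pointer.number
                    and q_hb.protein_atom.pointer.icode == rec.query_pointer.icode
                ):
                    continue
                if q_hb.ligand_side != t_hb.ligand_side:
                    continue
                if float(np.linalg.norm(q_hb.protein_atom.coords - t_pos)) <= spatial_tolerance:
                    substituted = True
                    sub_evidence.append(j)
        if substituted:
            rec.interaction_status = "substituted"
            rec.evidence_query = sorted(set(rec.evidence_query) | set(sub_evidence))
        else:
            rec.interaction_status = "lost"
    return list(records)


def site_report(
    records: Sequence[EquivalenceRecord],
    stats=None,
    superposition=None,
    validation: Optional[dict] = None,
) -> dict:
    """Machine-readable summary: per-residue table, status tallies, headline
    metrics, and an explicit list of analyses not performed."""
    rows = []
    for rec in records:
        rows.append(
            {
                "template": rec.template.label,
                "query": rec.query_label,
                "relation": rec.relation,
                "interaction_status": rec.interaction_status,
                "catalytic": rec.template.catalytic,
                "n_template_interactions": len(rec.evidence_template),
                "n_query_interactions": len(rec.evidence_query),
            }
        )
    tallies: dict[str, int] = {}
    for rec in records:
        tallies[rec.interaction_status] = tallies.get(rec.interaction_status, 0) + 1
    with_t = [r for r in records if r.evidence_template]
    conserved_frac = (
        sum(1 for r in with_t if r.interaction_status == "conserved") / len(with_t)
        if with_t
        else None
    )
    report = {
        "residues": rows,
        "tallies": tallies,
        "n_site_residues": len(records),
        "conserved_interaction_fraction": conserved_frac,
        "not_computed": ["3D-1D profile score", "rotamer analysis"],
    }
    if stats is not None:
        report["conservation"] = {
            "pct_identity": stats.pct_identity,
            "pct_conserved": stats.pct_conserved,
            "denominator": stats.denominator,
        }
    if superposition is not None:
        report["superposition"] = superposition.to_dict()
    if validation is not None:
        report["validation"] = validation
    return report
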