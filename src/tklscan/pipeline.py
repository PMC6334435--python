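"""End-to-end orchestration: stats -> alignment map -> superposition ->
ligand transplantation -> interaction detection -> site comparison ->
validation, with all reports written to an output directory.

The run configuration is a plain YAML document; it is echoed verbatim into
the output directory so every report is traceable to its inputs and
parameters.  Two runs with the same config and inputs produce byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from tklscan import msa_metrics, sitecomp, superpose, validate
from tklscan.interactions import (
    GeometryParams,
    cleft_check,
    count_protein_groups,
    detect_hbonds,
    detect_metal_coordination,
    hydrophobic_nodule,
    type_atoms,
    type_ligand_atoms,
)
from tklscan.msa_metrics import DEFAULT_SCHEME, ConservationScheme
from tklscan.structure_io import read_alignment, read_structure, write_structure
from tklscan.superpose import LigandSelection

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    template_path: str
    template_chain: str
    template_id: str
    query_path: str
    query_chain: str
    query_id: str
    alignment_path: str
    alignment_dialect: str = "fasta"
    ligand_het_codes: list[str] = field(default_factory=list)
    ligand_chain: Optional[str] = None
    ligand_config_path: Optional[str] = None
    ligand_config: Optional[dict] = None  # inline alternative to the path
    params: GeometryParams = field(default_factory=GeometryParams)
    scheme: ConservationScheme = DEFAULT_SCHEME
    prune_cutoff: float = 2.0
    prune_max_rounds: int = 20
    region: Optional[tuple[int, int]] = None
    site_config_path: Optional[str] = None
    probe_side: str = "methylene-bridge"
    spatial_tolerance: float = 3.0
    cleft_radius: float = 5.0
    output_dir: str = "tklscan_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scheme"] = {"name": self.scheme.name, "groups": list(self.scheme.groups)}
        return d


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    params = GeometryParams(**raw.get("params", {}))
    scheme_raw = raw.get("scheme")
    scheme = (
        ConservationScheme(
            name=scheme_raw.get("name", "custom"),
            groups=tuple(scheme_raw["groups"]),
        )
        if scheme_raw
        else DEFAULT_SCHEME
    )
    lig = raw.get("ligand", {})
    region = raw.get("region")
    return RunConfig(
        template_path=raw["template"]["path"],
        template_chain=raw["template"].get("chain", "A"),
        template_id=raw["template"]["id"],
        query_path=raw["query"]["path"],
        query_chain=raw["query"].get("chain", "A"),
        query_id=raw["query"]["id"],
        alignment_path=raw["alignment"]["path"],
        alignment_dialect=raw["alignment"].get("dialect", "fasta"),
        ligand_het_codes=list(lig.get("het_codes", [])),
        ligand_chain=lig.get("chain"),
        ligand_config_path=lig.get("config"),
        params=params,
        scheme=scheme,
        prune_cutoff=float(raw.get("prune", {}).get("cutoff", 2.0)),
        prune_max_rounds=int(raw.get("prune", {}).get("max_rounds", 20)),
        region=tuple(region) if region else None,
        site_config_path=raw.get("site_residues"),
        probe_side=raw.get("probe_side", "methylene-bridge"),
        spatial_tolerance=float(raw.get("spatial_tolerance", 3.0)),
        cleft_radius=float(raw.get("cleft_radius", 5.0)),
        output_dir=raw.get("output_dir", "tklscan_out"),
    )


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_ligand_config(cfg: RunConfig) -> dict:
    if cfg.ligand_config is not None:
        return cfg.ligand_config
    if cfg.ligand_config_path is not None:
        return yaml.safe_load(Path(cfg.ligand_config_path).read_text())
    from importlib import resources

    return yaml.safe_load(
        resources.files("tklscan").joinpath("data/ligand_tdp_x5p.yaml").read_text()
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full comparison; returns the report bundle as a dict and
    writes it under ``cfg.output_dir``.

    Raises :class:`PipelineError` naming the failed stage; outputs produced
    by earlier stages stay on disk with a ``FAILED`` marker file.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_entries: list[dict] = []

    def log(stage: str, **info) -> None:
        log_entries.append({"stage": stage, **info})
        with log_path.open("w") as fh:
            for e in log_entries:
                fh.write(json.dumps(e, sort_keys=True) + "\n")

    stage = "inputs"
    try:
        for p in (cfg.template_path, cfg.query_path, cfg.alignment_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file missing: {p}")
        (out / "config_echo.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
        log(stage, checksums={
            p: _sha256(p)
            for p in (cfg.template_path, cfg.query_path, cfg.alignment_path)
        })

        stage = "read"
        template = read_structure(cfg.template_path)
        query = read_structure(cfg.query_path)
        aln = read_alignment(cfg.alignment_path, cfg.alignment_dialect)
        log(stage, template=template.id, query=query.id, columns=aln.length)

        stage = "stats"
        stats = msa_metrics.pairwise_stats(
            aln, cfg.template_id, cfg.query_id, scheme=cfg.scheme
        )
        region_stats = (
            msa_metrics.pairwise_stats(
                aln, cfg.template_id, cfg.query_id, region=cfg.region,
                scheme=cfg.scheme,
            )
            if cfg.region
            else None
        )
        blocks = msa_metrics.find_deletion_blocks(
            aln, cfg.template_id, cfg.query_id
        )
        stats_rows = [{
            "ref": cfg.template_id, "query": cfg.query_id,
            "region": "full", "pct_identity": round(stats.pct_identity, 2),
            "pct_conserved": round(stats.pct_conserved, 2),
        }]
        if region_stats:
            stats_rows.append({
                "ref": cfg.template_id, "query": cfg.query_id,
                "region": f"{cfg.region[0]}:{cfg.region[1]}",
                "pct_identity": round(region_stats.pct_identity, 2),
                "pct_conserved": round(region_stats.pct_conserved, 2),
            })
        pd.DataFrame(stats_rows).to_csv(out / "stats.tsv", sep="\t", index=False)
        log(stage, pct_identity=stats.pct_identity,
            pct_conserved=stats.pct_conserved,
            deletion_blocks=[str(b) for b in blocks])

        stage = "map"
        amap = msa_metrics.build_alignment_map(
            aln,
            [
                (cfg.template_id, template, cfg.template_chain),
                (cfg.query_id, query, cfg.query_chain),
            ],
        )
        (out / "alignment_map.json").write_text(
            json.dumps(amap.to_dict(), indent=1, sort_keys=True)
        )
        log(stage, bound=list(amap.pointers))

        stage = "superpose"
        pairs = superpose.matched_calpha_pairs(
            amap,
            (template, cfg.template_chain),
            (query, cfg.query_chain),
            ref_id=cfg.template_id,
            query_id=cfg.query_id,
        )
        sup = superpose.iterative_prune_fit(
            pairs, cutoff=cfg.prune_cutoff, max_rounds=cfg.prune_max_rounds
        )
        (out / "superposition.json").write_text(
            json.dumps(sup.to_dict(), indent=1, sort_keys=True)
        )
        log(stage, rmsd_all=sup.rmsd_all, rmsd_pruned=sup.rmsd_pruned,
            n_pairs=sup.n_pairs_all, retained=sup.n_pairs_retained)

        stage = "transplant"
        selection = LigandSelection(
            het_codes=cfg.ligand_het_codes, chain_id=cfg.ligand_chain
        )
        complexed = superpose.transplant_ligand(
            sup.transform, template, selection, query
        )
        write_structure(complexed, out / "transplanted_complex.pdb")
        log(stage, ligands=[r.name for r in complexed.ligands])

        stage = "interactions"
        ligand_config = _load_ligand_config(cfg)
        params = cfg.params

        def fingerprint(structure):
            prot = type_atoms(structure)
            lig = type_ligand_atoms(structure, ligand_config)
            metals = detect_metal_coordination(structure, params)
            import numpy as np

            metal_xyz = np.array(
                [r.atoms[0].coords for r in structure.ligands if r.is_metal]
            )
            hbonds = detect_hbonds(prot, lig, params,
                                   metal_coords=metal_xyz if metal_xyz.size else None)
            probe = np.array(
                [t.coords for t in lig if t.ligand_side == cfg.probe_side]
            )
            nodule = (
                hydrophobic_nodule(structure, probe, params)
                if probe.size
                else []
            )
            cleft = cleft_check(structure, cfg.cleft_radius)
            return prot, lig, hbonds, metals, nodule, cleft

        _, _, t_hbonds, t_metals, t_nodule, t_cleft = fingerprint(template)
        _, _, q_hbonds, q_metals, q_nodule, q_cleft = fingerprint(complexed)
        for name, hb in (("template", t_hbonds), ("query", q_hbonds)):
            pd.DataFrame([h.to_row() for h in hb]).to_csv(
                out / f"hbonds_{name}.tsv", sep="\t", index=False
            )
        log(stage,
            template_hbonds=len(t_hbonds), query_hbonds=len(q_hbonds),
            template_diphosphate_groups=count_protein_groups(
                t_hbonds, "diphosphate"),
            query_diphosphate_groups=count_protein_groups(
                q_hbonds, "diphosphate"),
            template_nodule=[c.to_row() for c in t_nodule[:3]],
            query_nodule=[c.to_row() for c in q_nodule[:3]],
            template_cleft=t_cleft, query_cleft=q_cleft)

        stage = "sitecomp"
        if cfg.site_config_path:
            site = sitecomp.load_site_config(cfg.site_config_path)
        else:
            # default: every template residue seen interacting with the ligand
            seen = {}
            for hb in t_hbonds:
                p = hb.protein_atom
                seen[(p.pointer.number, p.pointer.icode)] = sitecomp.SiteResidue(
                    number=p.pointer.number,
                    name=p.residue.name,
                    chain_id=p.pointer.chain_id,
                    icode=p.pointer.icode,
                )
            site = [seen[k] for k in sorted(seen)]
        records = sitecomp.map_site_residues(
            amap, site, cfg.template_id, cfg.query_id, cfg.scheme
        )
        records = sitecomp.classify_interactions(
            records, t_hbonds, q_hbonds, cfg.spatial_tolerance
        )

        stage = "validate"
        q_records = validate.phi_psi(query, cfg.query_chain)
        q_summary = validate.rama_classify(q_records)
        t_records = validate.phi_psi(template, cfg.template_chain)
        t_summary = validate.rama_classify(t_records)
        pd.DataFrame(
            [
                {
                    "residue": str(r.pointer), "name": r.name,
                    "phi": None if r.phi is None else round(r.phi, 2),
                    "psi": None if r.psi is None else round(r.psi, 2),
                    "class": r.residue_class, "region": r.region,
                }
                for r in q_records
            ]
        ).to_csv(out / "rama_query.tsv", sep="\t", index=False)
        log(stage, query_pct_allowed=q_summary["pct_allowed"],
            template_pct_allowed=t_summary["pct_allowed"])

        stage = "report"
        report = sitecomp.site_report(
            records, stats=stats, superposition=sup,
            validation={"template": t_summary, "query": q_summary},
        )
        report["deletion_blocks"] = [
            {"start": b.ref_start, "end": b.ref_end, "length": b.length,
             "start_name": b.start_name, "end_name": b.end_name}
            for b in blocks
        ]
        if region_stats:
            report["region_conservation"] = {
                "region": list(cfg.region),
                "pct_identity": region_stats.pct_identity,
                "pct_conserved": region_stats.pct_conserved,
            }
        report["interaction_summary"] = {
            "template_diphosphate_groups": count_protein_groups(
                t_hbonds, "diphosphate"
            ),
            "query_diphosphate_groups": count_protein_groups(
                q_hbonds, "diphosphate"
            ),
            "template_metal_contacts": len(t_metals),
            "query_metal_contacts": len(q_metals),
            "template_nodule_top": t_nodule[0].to_row() if t_nodule else None,
            "query_nodule_top": q_nodule[0].to_row() if q_nodule else None,
            "template_cleft": t_cleft,
            "query_cleft": q_cleft,
        }
        (out / "site_report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True)
        )
        pd.DataFrame(report["residues"]).to_csv(
            out / "site_report.tsv", sep="\t", index=False
        )
        log(stage, done=True)
        return report
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\n{exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
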