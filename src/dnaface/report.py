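"""End-to-end pipeline driver and complex summaries.

:func:`summarize_complex` aggregates interface area, interface-residue
counts (N_aa / N_nuc), hydrogen bonds with their donor-side split, and
hydrophobic-contact counts into one record, echoing every parameter so
results are reproducible from the report alone.  :func:`run_pipeline`
orchestrates the stage order build ODN -> dock -> analyze from a flat
key-value config file.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

from .contacts import (ContactCriteria, classify_donor_side,
                       find_hbonds, find_hydrophobic_contacts)
from .core import Structure
from .dna import build_ssdna
from .docking import DockParams, apply_pose, dock_fft
from .interface import (InterfacePartition, interface_area,
                        interface_residues)
from .pdbio import read_pdb, write_pdb
from .radii import DEFAULT_RADII, RadiusSet, assign_radii
from .sasa import SASAParams

logger = logging.getLogger("dnaface")


@dataclass
class ComplexSummary:
    protein_label: str
    nucleic_label: str
    interface_area: float            # A^2, both faces
    n_aa: int                        # interface residues, protein side
    n_nuc: int                       # interface residues, nucleic side
    n_hbonds: int
    n_hydrophobic_contacts: int
    donor_side_counts: dict[str, int]
    protein_area: float
    protein_percent: float
    parameters: dict = field(default_factory=dict)
    hbonds: list = field(default_factory=list)
    hydrophobic: list = field(default_factory=list)
    interface_residues_a: list = field(default_factory=list)
    interface_residues_b: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_complex(complex_structure: Structure,
                      partition: InterfacePartition,
                      sasa_params: SASAParams | None = None,
                      criteria: ContactCriteria | None = None,
                      burial_threshold: float = 0.1,
                      radius_set: RadiusSet = DEFAULT_RADII) -> ComplexSummary:
    """One-call interface + interaction census of a protein-DNA complex."""
    sasa_params = sasa_params or SASAParams()
    criteria = criteria or ContactCriteria()
    report = interface_area(complex_structure, partition, sasa_params)
    res_a, res_b = interface_residues(report, burial_threshold)
    hbonds = find_hbonds(complex_structure, partition, criteria)
    hydro = find_hydrophobic_contacts(complex_structure, partition, criteria)
    donor_counts = {"protein": 0, "nucleic": 0}
    for hb in hbonds:
        donor_counts[classify_donor_side(hb)] += 1
    return ComplexSummary(
        protein_label="+".join(partition.side_a),
        nucleic_label="+".join(partition.side_b),
        interface_area=round(report.interface_area, 1),
        n_aa=len(res_a),
        n_nuc=len(res_b),
        n_hbonds=len(hbonds),
        n_hydrophobic_contacts=len(hydro),
        donor_side_counts=donor_counts,
        protein_area=round(report.side_a_area, 1),
        protein_percent=report.side_a_percent,
        parameters={
            "radius_set": radius_set.set_name,
            "probe_radius": sasa_params.probe_radius,
            "slice_spacing": sasa_params.slice_spacing,
            "burial_threshold": burial_threshold,
            "hydrophobic_cutoff": criteria.hydrophobic_cutoff,
            "hbond_h_acceptor_max": criteria.hbond_h_acceptor_max,
            "hbond_dha_min_angle": criteria.hbond_dha_min_angle,
        },
        hbonds=[asdict(h) for h in hbonds],
        hydrophobic=[asdict(c) for c in hydro],
        interface_residues_a=[(list(k), round(v, 2)) for k, v in res_a],
        interface_residues_b=[(list(k), round(v, 2)) for k, v in res_b],
    )


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "receptor_pdb": "",
    "ligand_pdb": "",
    "odn_sequence": "",
    "side_a": "A",
    "side_b": "S",
    "probe_radius": "1.4",
    "slice_spacing": "0.1",
    "burial_threshold": "0.1",
    "hydrophobic_cutoff": "4.5",
    "hbond_h_acceptor_max": "2.6",
    "hbond_dha_min_angle": "80",
    "grid_spacing": "0.6",
    "translation_extent": "40",
    "rotation_step": "15",
    "n_keep": "5",
    "n_report_poses": "3",
}


def read_config(path: str | os.PathLike) -> dict[str, str]:
    """Flat ``key = value`` config; unknown keys rejected."""
    conf = dict(_DEFAULT_CONFIG)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in _DEFAULT_CONFIG:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            conf[key] = value
    return conf


def run_pipeline(config_path: str | os.PathLike,
                 out_dir: str | os.PathLike) -> str:
    """Build-ODN -> dock -> analyze, driven by a config file.

    Writes poses.json, per-pose summaries.tsv and the full top-pose report
    to ``out_dir``; aborts naming the failing stage.
    """
    conf = read_config(config_path)
    if not conf["receptor_pdb"]:
        raise ValueError("config error: receptor_pdb is required")
    if not conf["ligand_pdb"] and not conf["odn_sequence"]:
        raise ValueError(
            "config error: either ligand_pdb or odn_sequence is required")
    os.makedirs(out_dir, exist_ok=True)

    def stage(name):
        logger.info("stage %s", name)
        return time.time()

    t0 = stage("load receptor")
    receptor = assign_radii(read_pdb(conf["receptor_pdb"]))
    logger.info("receptor: %d atoms (%.2fs)", receptor.atom_count(),
                time.time() - t0)

    t0 = stage("prepare ligand")
    if conf["ligand_pdb"]:
        ligand = assign_radii(read_pdb(conf["ligand_pdb"]))
    else:
        ligand = assign_radii(build_ssdna(conf["odn_sequence"],
                                          chain_id=conf["side_b"][0]))
    logger.info("ligand: %d atoms (%.2fs)", ligand.atom_count(),
                time.time() - t0)

    t0 = stage("dock")
    dock_params = DockParams(
        grid_spacing=float(conf["grid_spacing"]),
        translation_extent=float(conf["translation_extent"]),
        rotation_step=float(conf["rotation_step"]),
        n_keep=int(conf["n_keep"]))
    poses = dock_fft(receptor, ligand, dock_params)
    if not poses:
        raise RuntimeError("stage dock: no poses produced")
    logger.info("dock: %d poses (%.2fs)", len(poses), time.time() - t0)
    with open(os.path.join(out_dir, "poses.json"), "w") as fh:
        json.dump([{
            "rank": i + 1,
            "euler_zyz_deg": list(pose.euler_zyz),
            "translation_A": [round(float(v), 3) for v in pose.translation],
            "shape_score": pose.shape_score,
            "electrostatic_score": pose.electrostatic_score,
            "total_score": pose.total_score,
        } for i, pose in enumerate(poses)], fh, indent=1)

    t0 = stage("analyze")
    partition = InterfacePartition(tuple(conf["side_a"].split("+")),
                                   tuple(conf["side_b"].split("+")))
    sasa_params = SASAParams(probe_radius=float(conf["probe_radius"]),
                             slice_spacing=float(conf["slice_spacing"]))
    criteria = ContactCriteria(
        hydrophobic_cutoff=float(conf["hydrophobic_cutoff"]),
        hbond_h_acceptor_max=float(conf["hbond_h_acceptor_max"]),
        hbond_dha_min_angle=float(conf["hbond_dha_min_angle"]))
    rows = []
    top_summary = None
    for i, pose in enumerate(poses[:int(conf["n_report_poses"])]):
        placed = apply_pose(ligand, pose)
        merged = Structure(chains=[c for c in receptor.chains]
                           + [c for c in placed.chains])
        summary = summarize_complex(
            merged, partition, sasa_params, criteria,
            burial_threshold=float(conf["burial_threshold"]))
        rows.append((i + 1, pose.total_score, summary))
        if top_summary is None:
            top_summary = summary
            write_pdb(merged, os.path.join(out_dir, "top_pose.pdb"))
    with open(os.path.join(out_dir, "summaries.tsv"), "w") as fh:
        fh.write("rank\ttotal_score\tinterface_area\tn_aa\tn_nuc\t"
                 "n_hbonds\tn_hydrophobic\n")
        for rank, score, s in rows:
            fh.write(f"{rank}\t{score:.1f}\t{s.interface_area:.1f}\t"
                     f"{s.n_aa}\t{s.n_nuc}\t{s.n_hbonds}\t"
                     f"{s.n_hydrophobic_contacts}\n")
    with open(os.path.join(out_dir, "top_pose_report.json"), "w") as fh:
        json.dump(top_summary.to_dict(), fh, indent=1)
    logger.info("analyze: done (%.2fs)", time.time() - t0)
    return str(out_dir)
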