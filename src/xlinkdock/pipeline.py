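"""End-to-end orchestration: simulate (or load), dock, cluster, annotate,
filter, rescore, select, validate, report.

Every stage writes a plain TSV/PDB artifact so it can be re-run
independently; a manifest records the seed, the config hash and per-stage
counts, and the whole run is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .docking import (DEFAULT_CLASH_PENALTY, DEFAULT_SPACING, Pose,
                      make_rotations, search, write_poses_tsv)
from .errors import StageError, XlinkDockError
from .pose_analysis import (DEFAULT_CLUSTER_RADIUS,
                            FilterCriteria, PoseRecord, cluster_poses,
                            export_pose_table, export_score_density_points,
                            filter_poses, interface_residues, pose_density,
                            read_criteria_yaml)
from .rescoring import RescoreWeights, energy_terms, rescore, select_models
from .restraints import RestraintSet, read_restraints_tsv, write_restraints_tsv
from .structure_io import Structure, read_pdb, write_pdb
from .synthetic_data import (DEFAULT_N_LIGAND, DEFAULT_N_RECEPTOR,
                             make_block_complex)
from .pose_analysis import write_criteria_yaml
from .validation import (backbone_dihedrals, classify_outcome,
                         count_classifications, ramachandran_classify,
                         verify_score)

log = logging.getLogger("xlinkdock")


@dataclass
class RunConfig:
    seed: int = 0
    # either simulate=True (synthetic system) or explicit input paths
    simulate: bool = True
    n_receptor: int = DEFAULT_N_RECEPTOR
    n_ligand: int = DEFAULT_N_LIGAND
    interface_size: int = 9
    receptor_pdb: str | None = None
    ligand_pdb: str | None = None
    restraints_tsv: str | None = None
    criteria_yaml: str | None = None
    # docking
    spacing: float = DEFAULT_SPACING
    n_rotations: int = 24
    top_n: int = 60
    clash_penalty: float = DEFAULT_CLASH_PENALTY
    # analysis; the pipeline default cutoff is wider than the 5 Å
    # per-operation default so near-native poses keep their contacts
    interface_cutoff: float = 7.0
    cluster_radius: float = DEFAULT_CLUSTER_RADIUS
    # density counts rotations that agree on a placement; on toy systems a
    # tight radius (about two grid cells) makes it a consensus signal
    # rather than a measure of how crowded the receptor surface is
    density_radius: float = 4.0
    require_all_restraints: bool = True
    # rescoring / selection
    select_k: int = 5
    weights_yaml: str | None = None
    outdir: str = "xlinkdock_run"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f: raw[f] for f in raw if f in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise StageError("config", "unknown-keys",
                             f"unrecognised config keys: {sorted(unknown)}")
        return cls(**known)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunResult:
    outdir: Path
    poses: list[Pose]
    records: list[PoseRecord]
    selected: list[PoseRecord]
    manifest: dict


def _load_weights(path: str | None) -> RescoreWeights:
    if path is None:
        return RescoreWeights()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RescoreWeights(**raw)


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline; any stage error aborts with the stage name
    and a machine-readable code."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # ---- inputs -------------------------------------------------------
    stage = "simulate" if config.simulate else "load"
    try:
        if config.simulate:
            system = make_block_complex(config.seed, config.n_receptor,
                                        config.n_ligand, config.interface_size)
            receptor = system.receptor
            ligand = system.ligand_reference
            restraints = system.planted_restraints
            criteria = system.criteria()
            write_pdb(receptor, outdir / "receptor.pdb")
            write_pdb(ligand, outdir / "ligand.pdb")
            write_restraints_tsv(restraints, outdir / "restraints.tsv")
            write_criteria_yaml(criteria, outdir / "criteria.yaml")
        else:
            if not (config.receptor_pdb and config.ligand_pdb):
                raise StageError("load", "missing-input",
                                 "receptor_pdb and ligand_pdb are required")
            if config.restraints_tsv is None or \
                    not Path(config.restraints_tsv).exists():
                raise StageError("restrain", "missing-file",
                                 f"restraint file {config.restraints_tsv!r} "
                                 "is required")
            receptor = read_pdb(config.receptor_pdb)
            ligand = read_pdb(config.ligand_pdb)
            restraints = read_restraints_tsv(config.restraints_tsv)
            criteria = (read_criteria_yaml(config.criteria_yaml)
                        if config.criteria_yaml else FilterCriteria())
    except StageError:
        raise
    except (XlinkDockError, OSError) as exc:
        raise StageError(stage, "input-error", str(exc)) from exc
    counts["receptor_residues"] = receptor.n_residues()
    counts["ligand_residues"] = ligand.n_residues()
    log.info("stage=%s receptor=%d ligand=%d restraints=%d", stage,
             counts["receptor_residues"], counts["ligand_residues"],
             len(restraints))

    # ---- dock ---------------------------------------------------------
    try:
        rotations = make_rotations(config.n_rotations, config.seed)
        poses = search(receptor, ligand, rotations, spacing=config.spacing,
                       blocked=criteria.blocked, top_n=config.top_n,
                       clash_penalty=config.clash_penalty)
        write_poses_tsv(poses, outdir / "poses.tsv")
    except XlinkDockError as exc:
        raise StageError("dock", "search-failed", str(exc)) from exc
    counts["poses"] = len(poses)
    log.info("stage=dock poses=%d", len(poses))

    # ---- cluster / density / annotate --------------------------------
    try:
        clusters = cluster_poses(poses, ligand, config.cluster_radius)
        density = pose_density(poses, ligand, config.density_radius)
        cluster_of = {pid: cl.cluster_id for cl in clusters
                      for pid in cl.member_pose_ids}
        records = []
        for pose in poses:
            posed = pose.transform_structure(ligand)
            iface = interface_residues(receptor, posed, config.interface_cutoff)
            entries = restraints.evaluate_all(receptor, posed)
            records.append(PoseRecord(
                pose_id=pose.id,
                cluster_id=cluster_of[pose.id],
                density=density[pose.id],
                primary_score=pose.primary_score,
                restraint_distances={
                    e.label: (e.distance if math.isfinite(e.distance)
                              else float("inf"))
                    for e in entries},
                restraints_satisfied=sum(e.satisfied for e in entries),
                interface=iface,
            ))
    except XlinkDockError as exc:
        raise StageError("cluster", "analysis-failed", str(exc)) from exc
    counts["clusters"] = len(clusters)
    log.info("stage=cluster clusters=%d", len(clusters))

    # ---- filter -------------------------------------------------------
    try:
        passing = filter_poses(records, criteria, receptor, ligand)
        if config.require_all_restraints and len(restraints):
            for rec in records:
                if rec.passed_filters and \
                        rec.restraints_satisfied < len(restraints):
                    rec.passed_filters = False
                    rec.failure_reasons.append(
                        f"restraints satisfied {rec.restraints_satisfied}"
                        f"/{len(restraints)}")
            passing = [r for r in records if r.passed_filters]
    except XlinkDockError as exc:
        raise StageError("filter", "criteria-error", str(exc)) from exc
    counts["passing"] = len(passing)
    log.info("stage=filter passing=%d/%d", len(passing), len(records))

    # ---- rescore ------------------------------------------------------
    try:
        weights = _load_weights(config.weights_yaml)
        pose_by_id = {p.id: p for p in poses}
        for rec in passing:
            posed = pose_by_id[rec.pose_id].transform_structure(ligand)
            rec.rescore = rescore(energy_terms(receptor, posed), weights)
    except XlinkDockError as exc:
        raise StageError("rescore", "energy-error", str(exc)) from exc
    log.info("stage=rescore rescored=%d", len(passing))

    # ---- select -------------------------------------------------------
    selected = select_models(passing, config.select_k) if passing else []
    counts["selected"] = len(selected)
    for rank, rec in enumerate(selected, start=1):
        posed = pose_by_id[rec.pose_id].transform_structure(ligand)
        complex_struct = Structure(f"model_{rank:02d}_pose{rec.pose_id}")
        for cid, residues in receptor.chains.items():
            complex_struct.chains[cid] = [r for r in receptor.copy().chains[cid]]
        for cid, residues in posed.chains.items():
            out_cid = cid if cid not in complex_struct.chains else cid.lower()
            complex_struct.chains[out_cid] = residues
        write_pdb(complex_struct, outdir / f"model_{rank:02d}.pdb")
    log.info("stage=select selected=%d", len(selected))

    # ---- validate -----------------------------------------------------
    rama = ramachandran_classify(backbone_dihedrals(ligand))
    rama_counts = count_classifications(rama)
    profile = verify_score(ligand)
    outcome = classify_outcome(profile)
    with open(outdir / "validation.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        for key, val in rama_counts.items():
            fh.write(f"ramachandran_{key}\t{val}\n")
        fh.write(f"verify_score\t{profile.verify_score:.4f}\n")
        fh.write(f"expected_high\t{profile.expected_high:.4f}\n")
        fh.write(f"expected_low\t{profile.expected_low:.4f}\n")
        fh.write(f"outcome\t{outcome.label}\n")
        fh.write(f"band\t{outcome.band}\n")
    log.info("stage=validate outcome=%s", outcome.label)

    # ---- report -------------------------------------------------------
    export_pose_table(records, outdir / "pose_table.tsv")
    export_score_density_points(records, outdir / "score_density.tsv")
    manifest = {
        "package": "xlinkdock",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": asdict(config),
        "counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return RunResult(outdir, poses, records, selected, manifest)
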