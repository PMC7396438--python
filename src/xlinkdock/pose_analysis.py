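"""Interface detection, pose clustering/density, and criteria-based filtering.

This stage turns raw docking output into annotated, filtered model sets:
heavy-atom interface maps, greedy leader clustering on the transformed
ligand centroid, a consensus pose-density count, and pass/fail filtering
against experimentally derived interface criteria (required receptor
contacts, a required ligand docking domain, orientation residue sets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from .docking import Pose
from .errors import ConfigError
from .structure_io import ResidueId, Structure

DEFAULT_INTERFACE_CUTOFF = 5.0   # Å, heavy-atom
DEFAULT_CLUSTER_RADIUS = 10.0    # Å, ligand-centroid leader clustering
DEFAULT_DOMAIN_FRACTION = 0.5    # "mainly through the docking domain"


@dataclass
class InterfaceMap:
    receptor_residues: set[ResidueId]
    ligand_residues: set[ResidueId]
    contact_pairs: list[tuple[ResidueId, ResidueId, float]]


@dataclass
class FilterCriteria:
    required_receptor_interface: set[ResidueId] = field(default_factory=set)
    required_ligand_domain: set[ResidueId] = field(default_factory=set)
    min_domain_fraction: float = DEFAULT_DOMAIN_FRACTION
    orientation_required: set[ResidueId] = field(default_factory=set)
    orientation_min_count: int = 1
    orientation_forbidden: set[ResidueId] = field(default_factory=set)
    orientation_max_count: int = 0
    blocked: set[ResidueId] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_domain_fraction <= 1.0:
            raise ConfigError("min_domain_fraction must be in [0, 1]")


@dataclass
class Cluster:
    cluster_id: int
    member_pose_ids: list[int]
    representative: int


@dataclass
class PoseRecord:
    pose_id: int
    cluster_id: int = -1
    density: int = 1
    primary_score: float = 0.0
    rescore: float = float("nan")
    restraint_distances: dict[str, float] = field(default_factory=dict)
    restraints_satisfied: int = 0
    interface: InterfaceMap | None = None
    passed_filters: bool = False
    failure_reasons: list[str] = field(default_factory=list)


def _residue_atom_table(s: Structure):
    coords, owner = [], []
    residues = list(s.residues())
    for i, res in enumerate(residues):
        for a in res.heavy_atoms():
            coords.append(a.coord)
            owner.append(i)
    return residues, np.array(coords) if coords else np.empty((0, 3)), np.array(owner, int)


def interface_residues(receptor: Structure, ligand_posed: Structure,
                       cutoff: float = DEFAULT_INTERFACE_CUTOFF) -> InterfaceMap:
    """All residue pairs whose heavy-atom minimum distance is <= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    r_res, r_xyz, r_owner = _residue_atom_table(receptor)
    l_res, l_xyz, l_owner = _residue_atom_table(ligand_posed)
    if r_xyz.size == 0 or l_xyz.size == 0:
        return InterfaceMap(set(), set(), [])
    tree_r, tree_l = cKDTree(r_xyz), cKDTree(l_xyz)
    pairs = tree_r.sparse_distance_matrix(tree_l, cutoff, output_type="coo_matrix")
    best: dict[tuple[int, int], float] = {}
    for i, j, d in zip(pairs.row, pairs.col, pairs.data):
        key = (r_owner[i], l_owner[j])
        if d < best.get(key, np.inf):
            best[key] = d
    contact_pairs = sorted(
        (r_res[ri].id, l_res[li].id, float(d)) for (ri, li), d in best.items()
    )
    return InterfaceMap(
        {p[0] for p in contact_pairs},
        {p[1] for p in contact_pairs},
        contact_pairs,
    )


def _pose_centroids(poses: Sequence[Pose], ligand_reference: Structure) -> np.ndarray:
    c = ligand_reference.centroid()
    return np.array([p.apply(c[None, :])[0] for p in poses]) if poses else np.empty((0, 3))


def cluster_poses(poses: Sequence[Pose], ligand_reference: Structure,
                  radius: float = DEFAULT_CLUSTER_RADIUS) -> list[Cluster]:
    """Greedy leader clustering on the transformed ligand centroid.

    Poses are visited in descending primary score (pose id breaks ties); a
    pose joins the first cluster whose representative centroid is within
    ``radius``, else founds a new cluster.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not poses:
        return []
    centroids = _pose_centroids(poses, ligand_reference)
    order = sorted(range(len(poses)),
                   key=lambda i: (-poses[i].primary_score, poses[i].id))
    clusters: list[Cluster] = []
    leader_pts: list[np.ndarray] = []
    for i in order:
        placed = False
        for cl, leader in zip(clusters, leader_pts):
            if np.linalg.norm(centroids[i] - leader) <= radius:
                cl.member_pose_ids.append(poses[i].id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(len(clusters), [poses[i].id], poses[i].id))
            leader_pts.append(centroids[i])
    return clusters


def pose_density(poses: Sequence[Pose], ligand_reference: Structure,
                 radius: float = DEFAULT_CLUSTER_RADIUS) -> dict[int, int]:
    """density(p) = number of poses (incl. p) with centroid within radius."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not poses:
        return {}
    centroids = _pose_centroids(poses, ligand_reference)
    tree = cKDTree(centroids)
    counts = tree.query_ball_point(centroids, radius, return_length=True)
    return {p.id: int(c) for p, c in zip(poses, counts)}


def _check_criteria_residues(criteria: FilterCriteria, receptor: Structure,
                             ligand: Structure) -> None:
    missing = []
    for rid in sorted(criteria.required_receptor_interface | criteria.blocked):
        if not receptor.has_residue(*rid):
            missing.append(f"receptor {rid[0]}:{rid[1]}")
    for rid in sorted(criteria.required_ligand_domain
                      | criteria.orientation_required
                      | criteria.orientation_forbidden):
        if not ligand.has_residue(*rid):
            missing.append(f"ligand {rid[0]}:{rid[1]}")
    if missing:
        raise ConfigError("criteria reference absent residues: " + ", ".join(missing))


def filter_poses(records: Sequence[PoseRecord], criteria: FilterCriteria,
                 receptor: Structure | None = None,
                 ligand: Structure | None = None) -> list[PoseRecord]:
    """Annotate every record with pass/fail and reasons; return the passers.

    A pose passes iff (i) every required receptor residue is in its
    interface, (ii) at least ``min_domain_fraction`` of its ligand interface
    residues lie in the required ligand domain, (iii) its interface contains
    at least ``orientation_min_count`` of the required orientation residues
    and at most ``orientation_max_count`` of the forbidden ones.
    """
    if receptor is not None and ligand is not None:
        _check_criteria_residues(criteria, receptor, ligand)
    passing = []
    for rec in records:
        if rec.interface is None:
            raise ValueError(f"pose {rec.pose_id}: interface not computed")
        reasons: list[str] = []
        iface = rec.interface
        missing = criteria.required_receptor_interface - iface.receptor_residues
        if missing:
            names = ",".join(f"{c}:{n}" for c, n, _ in sorted(missing))
            reasons.append(f"required receptor residues not in interface: {names}")
        if criteria.required_ligand_domain:
            n_iface = len(iface.ligand_residues)
            in_domain = len(iface.ligand_residues & criteria.required_ligand_domain)
            frac = in_domain / n_iface if n_iface else 0.0
            if frac < criteria.min_domain_fraction:
                reasons.append(
                    f"ligand-domain fraction {frac:.2f} < {criteria.min_domain_fraction}"
                )
        if criteria.orientation_required:
            n_up = len(iface.ligand_residues & criteria.orientation_required)
            if n_up < criteria.orientation_min_count:
                reasons.append(
                    f"orientation: {n_up} required residues in interface "
                    f"< {criteria.orientation_min_count}"
                )
        if criteria.orientation_forbidden:
            n_forbidden = len(iface.ligand_residues & criteria.orientation_forbidden)
            if n_forbidden > criteria.orientation_max_count:
                reasons.append(
                    f"orientation: {n_forbidden} forbidden residues in interface "
                    f"> {criteria.orientation_max_count}"
                )
        rec.failure_reasons = reasons
        rec.passed_filters = not reasons
        if rec.passed_filters:
            passing.append(rec)
    return passing


# ---------------------------------------------------------------------------
# criteria.yaml and pose-table serialisation


def _parse_residue_token(token: str) -> list[tuple[str, int]]:
    """Parse "A:64" or a range "S:1-9" into (chain, number) tuples."""
    chain, _, spec = token.partition(":")
    if not spec:
        raise ConfigError(f"bad residue token {token!r} (expect CHAIN:NUM or CHAIN:A-B)")
    if "-" in spec[1:]:  # allow negative-free ranges only
        lo, hi = spec.split("-", 1)
        return [(chain, n) for n in range(int(lo), int(hi) + 1)]
    return [(chain, int(spec))]


def _parse_residue_list(tokens: Iterable[str]) -> set[ResidueId]:
    out: set[ResidueId] = set()
    for tok in tokens:
        out.update((c, n, "") for c, n in _parse_residue_token(str(tok)))
    return out


def read_criteria_yaml(path: str) -> FilterCriteria:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    orient_req = raw.get("orientation_required", {}) or {}
    orient_forb = raw.get("orientation_forbidden", {}) or {}
    return FilterCriteria(
        required_receptor_interface=_parse_residue_list(
            raw.get("required_receptor_interface", [])),
        required_ligand_domain=_parse_residue_list(
            raw.get("required_ligand_domain", [])),
        min_domain_fraction=float(raw.get("min_domain_fraction",
                                          DEFAULT_DOMAIN_FRACTION)),
        orientation_required=_parse_residue_list(orient_req.get("residues", [])),
        orientation_min_count=int(orient_req.get("min_count", 1)),
        orientation_forbidden=_parse_residue_list(orient_forb.get("residues", [])),
        orientation_max_count=int(orient_forb.get("max_count", 0)),
        blocked=_parse_residue_list(raw.get("blocked", [])),
    )


def write_criteria_yaml(criteria: FilterCriteria, path: str) -> None:
    def fmt(ids: set[ResidueId]) -> list[str]:
        return [f"{c}:{n}" for c, n, _ in sorted(ids)]

    doc = {
        "required_receptor_interface": fmt(criteria.required_receptor_interface),
        "required_ligand_domain": fmt(criteria.required_ligand_domain),
        "min_domain_fraction": criteria.min_domain_fraction,
        "orientation_required": {
            "residues": fmt(criteria.orientation_required),
            "min_count": criteria.orientation_min_count,
        },
        "orientation_forbidden": {
            "residues": fmt(criteria.orientation_forbidden),
            "max_count": criteria.orientation_max_count,
        },
        "blocked": fmt(criteria.blocked),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _fmt_ids(ids: set[ResidueId]) -> str:
    return ";".join(f"{c}:{n}{i}" for c, n, i in sorted(ids))


def records_to_frame(records: Sequence[PoseRecord]) -> pd.DataFrame:
    labels = sorted({lab for r in records for lab in r.restraint_distances})
    rows = []
    for r in records:
        row = {
            "pose_id": r.pose_id,
            "cluster_id": r.cluster_id,
            "density": r.density,
            "primary_score": r.primary_score,
            "rescore": r.rescore,
            "restraints_satisfied": r.restraints_satisfied,
            "passed": r.passed_filters,
            "failure_reasons": "|".join(r.failure_reasons),
            "receptor_interface": _fmt_ids(r.interface.receptor_residues)
            if r.interface else "",
            "ligand_interface": _fmt_ids(r.interface.ligand_residues)
            if r.interface else "",
        }
        for lab in labels:
            row[f"dist[{lab}]"] = r.restraint_distances.get(lab, np.nan)
        rows.append(row)
    columns = ["pose_id", "cluster_id", "density", "primary_score", "rescore",
               "restraints_satisfied", "passed", "failure_reasons",
               "receptor_interface", "ligand_interface"] + [f"dist[{l}]" for l in labels]
    return pd.DataFrame(rows, columns=columns)


def export_pose_table(records: Sequence[PoseRecord], path: str) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def _parse_ids(cell) -> set[ResidueId]:
    if not isinstance(cell, str) or not cell:
        return set()
    out = set()
    for tok in cell.split(";"):
        chain, _, num = tok.partition(":")
        icode = num.lstrip("-0123456789")
        out.add((chain, int(num[: len(num) - len(icode)] or 0), icode))
    return out


def read_pose_table(path: str) -> list[PoseRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        dists = {
            col[5:-1]: float(row[col])
            for col in df.columns if col.startswith("dist[")
        }
        iface = InterfaceMap(_parse_ids(row.get("receptor_interface", "")),
                             _parse_ids(row.get("ligand_interface", "")), [])
        reasons = row.get("failure_reasons", "")
        records.append(PoseRecord(
            pose_id=int(row["pose_id"]),
            cluster_id=int(row["cluster_id"]),
            density=int(row["density"]),
            primary_score=float(row["primary_score"]),
            rescore=float(row["rescore"]),
            restraint_distances=dists,
            restraints_satisfied=int(row["restraints_satisfied"]),
            interface=iface,
            passed_filters=bool(row["passed"]),
            failure_reasons=[x for x in str(reasons).split("|")
                             if x and x != "nan"],
        ))
    return records


def export_score_density_points(records: Sequence[PoseRecord], path: str) -> None:
    """(score, density, cluster_id) triples for 3-D score/density plots."""
    df = pd.DataFrame(
        [(r.primary_score, r.density, r.cluster_id) for r in records],
        columns=["primary_score", "density", "cluster_id"],
    )
    df.to_csv(path, sep="\t", index=False)
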