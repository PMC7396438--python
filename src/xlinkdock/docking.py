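"""Rigid-body docking by grid discretization and exhaustive translation search.

The receptor and (per-rotation) ligand are discretized onto cubic grids whose
occupied cells are labelled *surface* (an empty 6-neighbour exists) or *core*.
For every integer translation the pairwise shape-complementarity score

    sum over cells of  f(receptor cell, ligand cell)
    f(surface, occupied) = +1, f(core, occupied) = -C, f(empty, .) = 0

is computed via spectral (FFT) convolution, which equals the direct
double-loop sum. Receptor residues declared *blocked* (e.g. a
membrane-embedded region) contribute nothing to contact or clash.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import fftconvolve
from scipy.spatial.transform import Rotation

from .errors import ConfigError, EmptyInputError, GridCompatibilityError, GridResourceError
from .structure_io import ResidueId, Structure

EMPTY, SURFACE, CORE = 0, 1, 2

#: Default heavy-atom occupancy radius (Å) used when projecting atoms onto
#: the grid; a cell is occupied when its cube intersects the atom sphere.
DEFAULT_ATOM_RADIUS = 1.6
DEFAULT_SPACING = 2.0  # Å; matched to the 4 Å pseudo-residue lattice of the
                       # synthetic systems (the surface shell is one cell
                       # thick, so the cell size sets the contact tolerance)
DEFAULT_CLASH_PENALTY = 9.0
GRID_DIM_CAP = 128


@dataclass
class Grid:
    origin: np.ndarray        # Å position of the centre of cell (0,0,0)
    spacing: float
    occupancy: np.ndarray     # bool, shape dims

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        self.occupancy = np.asarray(self.occupancy, bool)
        if self.occupancy.ndim != 3 or min(self.occupancy.shape) < 1:
            raise ValueError("occupancy must be a non-empty 3-D array")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def labels(self) -> np.ndarray:
        """Per-cell label array: EMPTY, SURFACE or CORE."""
        occ = self.occupancy
        padded = np.pad(occ, 1, constant_values=False)
        n_occ_neighbors = np.zeros(occ.shape, dtype=int)
        for axis in range(3):
            for step in (1, -1):
                n_occ_neighbors += np.roll(padded, step, axis=axis)[1:-1, 1:-1, 1:-1]
        labels = np.zeros(occ.shape, dtype=np.int8)
        labels[occ & (n_occ_neighbors < 6)] = SURFACE
        labels[occ & (n_occ_neighbors == 6)] = CORE
        return labels

    def weights(self, clash_penalty: float = DEFAULT_CLASH_PENALTY) -> np.ndarray:
        """Receptor-side score weights: +1 on surface, -C on core cells."""
        labels = self.labels
        w = np.zeros(labels.shape, dtype=float)
        w[labels == SURFACE] = 1.0
        w[labels == CORE] = -float(clash_penalty)
        return w

    def cell_center(self, index: Sequence[int]) -> np.ndarray:
        return self.origin + np.asarray(index, float) * self.spacing


@dataclass
class Pose:
    """One rigid placement of the ligand: x -> R x + t, with scores attached."""

    id: int
    quaternion: np.ndarray     # (w, x, y, z), unit norm
    translation: np.ndarray    # Å
    primary_score: float = 0.0

    def __post_init__(self) -> None:
        self.quaternion = np.asarray(self.quaternion, float)
        self.translation = np.asarray(self.translation, float)
        norm = np.linalg.norm(self.quaternion)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"pose {self.id}: quaternion norm {norm} != 1")
        self.quaternion = self.quaternion / norm

    @property
    def rotation_matrix(self) -> np.ndarray:
        w, x, y, z = self.quaternion
        return Rotation.from_quat([x, y, z, w]).as_matrix()

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation_matrix.T + self.translation

    def transform_structure(self, s: Structure) -> Structure:
        return s.transformed(self.rotation_matrix, self.translation)

    @classmethod
    def identity(cls, pose_id: int = 0) -> "Pose":
        return cls(pose_id, np.array([1.0, 0, 0, 0]), np.zeros(3))

    @classmethod
    def from_matrix(cls, pose_id: int, R: np.ndarray, t: np.ndarray,
                    score: float = 0.0) -> "Pose":
        x, y, z, w = Rotation.from_matrix(R).as_quat()
        return cls(pose_id, np.array([w, x, y, z]), np.asarray(t, float), score)


@dataclass
class RotationSet:
    """A deterministic set of unit quaternions (w, x, y, z)."""

    rotations: list[np.ndarray]
    scheme: str
    seed: int

    def __len__(self) -> int:
        return len(self.rotations)

    def matrices(self) -> list[np.ndarray]:
        out = []
        for q in self.rotations:
            w, x, y, z = q
            out.append(Rotation.from_quat([x, y, z, w]).as_matrix())
        return out


def make_rotations(count: int, seed: int, scheme: str = "random",
                   include_identity: bool = True) -> RotationSet:
    """Uniform random unit quaternions; the identity is prepended by default
    so the input orientation of the ligand is always scanned."""
    if count < 1:
        raise ConfigError("rotation count must be >= 1")
    rng = np.random.default_rng(seed)
    rotations: list[np.ndarray] = []
    if include_identity:
        rotations.append(np.array([1.0, 0.0, 0.0, 0.0]))
    while len(rotations) < count:
        q = rng.normal(size=4)
        n = np.linalg.norm(q)
        if n < 1e-12:
            continue
        rotations.append(q / n)
    return RotationSet(rotations[:count], scheme, seed)


def _occupancy_from_coords(coords: np.ndarray, origin: np.ndarray, dims: tuple,
                           spacing: float, radius: float) -> np.ndarray:
    occ = np.zeros(dims, dtype=bool)
    half = spacing / 2.0
    reach = int(np.ceil((radius + half) / spacing))
    offsets = np.arange(-reach, reach + 1)
    ox, oy, oz = np.meshgrid(offsets, offsets, offsets, indexing="ij")
    neighborhood = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3)
    for atom in coords:
        center_idx = np.round((atom - origin) / spacing).astype(int)
        cells = center_idx + neighborhood
        centers = origin + cells * spacing
        # sphere-cube intersection test per candidate cell
        d = np.maximum(np.abs(atom - centers) - half, 0.0)
        hit = (d ** 2).sum(axis=1) <= radius ** 2
        cells = cells[hit]
        inside = np.all((cells >= 0) & (cells < np.array(dims)), axis=1)
        cells = cells[inside]
        occ[cells[:, 0], cells[:, 1], cells[:, 2]] = True
    return occ


def discretize(s: Structure, spacing: float = DEFAULT_SPACING,
               blocked: Iterable[ResidueId] = (),
               radius: float = DEFAULT_ATOM_RADIUS,
               dim_cap: int = GRID_DIM_CAP) -> Grid:
    """Project heavy atoms of non-blocked residues onto a cubic grid.

    Cells owed solely to blocked residues are cleared (they contribute
    neither contact nor clash); blocking every residue yields an empty grid
    with unit dims.
    """
    if s.n_residues() == 0:
        raise EmptyInputError(f"structure {s.id!r} is empty")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    blocked_set = {tuple(b) if len(b) == 3 else (b[0], b[1], "") for b in blocked}
    coords = [
        a.coord
        for res in s.residues()
        if res.id not in blocked_set
        for a in res.heavy_atoms()
    ]
    if not coords:
        return Grid(np.zeros(3), spacing, np.zeros((1, 1, 1), dtype=bool))
    pts = np.array(coords)
    # margin is a whole number of cells so the minimum atom coordinate maps
    # onto a cell centre (a single atom then occupies exactly one cell when
    # the spacing exceeds its extent)
    margin = spacing * math.ceil((radius + spacing) / spacing)
    origin = pts.min(axis=0) - margin
    top = pts.max(axis=0) + margin
    dims = tuple(int(np.floor((t - o) / spacing)) + 1 for o, t in zip(origin, top))
    if max(dims) > dim_cap:
        raise GridResourceError(
            f"grid dims {dims} exceed cap {dim_cap} at spacing {spacing} Å"
        )
    occ = _occupancy_from_coords(pts, origin, dims, spacing, radius)
    return Grid(origin, spacing, occ)


@dataclass
class CorrelationResult:
    """Scores over every integer translation of the ligand grid.

    ``scores[k]`` is the shape-complementarity score for cell offset
    ``t = k - (ligand_dims - 1)``, i.e. ligand cell j aligned with receptor
    cell j + t. ``real_shift`` converts an offset to the Å shift applied to
    the (already rotated) ligand coordinates.
    """

    scores: np.ndarray
    receptor_origin: np.ndarray
    ligand_origin: np.ndarray
    spacing: float
    ligand_dims: tuple[int, int, int]

    def offset_of_index(self, k: Sequence[int]) -> np.ndarray:
        return np.asarray(k, int) - (np.asarray(self.ligand_dims, int) - 1)

    def real_shift(self, offset: Sequence[int]) -> np.ndarray:
        return (self.receptor_origin - self.ligand_origin
                + np.asarray(offset, float) * self.spacing)


def correlate(receptor: Grid, ligand: Grid,
              clash_penalty: float = DEFAULT_CLASH_PENALTY) -> CorrelationResult:
    """Score every integer translation via FFT cross-correlation.

    Equals the direct double-loop sum of f(receptor cell, ligand cell) to
    within floating-point rounding (~1e-10 on toy grids).
    """
    if abs(receptor.spacing - ligand.spacing) > 1e-9:
        raise GridCompatibilityError(
            f"grid spacings differ: {receptor.spacing} vs {ligand.spacing}"
        )
    w = receptor.weights(clash_penalty)
    lig = ligand.occupancy.astype(float)
    scores = fftconvolve(w, lig[::-1, ::-1, ::-1], mode="full")
    return CorrelationResult(scores, receptor.origin, ligand.origin,
                             receptor.spacing, ligand.dims)


def correlate_direct(receptor: Grid, ligand: Grid,
                     clash_penalty: float = DEFAULT_CLASH_PENALTY) -> np.ndarray:
    """Brute-force double-loop correlation (reference oracle; O(G^2))."""
    if abs(receptor.spacing - ligand.spacing) > 1e-9:
        raise GridCompatibilityError("grid spacings differ")
    w = receptor.weights(clash_penalty)
    occ = ligand.occupancy
    rd = np.array(receptor.dims)
    ld = np.array(ligand.dims)
    out = np.zeros(tuple(rd + ld - 1))
    lig_cells = np.argwhere(occ)
    for k in np.ndindex(*out.shape):
        t = np.array(k) - (ld - 1)
        total = 0.0
        for cell in lig_cells:
            r = cell + t
            if np.all(r >= 0) and np.all(r < rd):
                total += w[tuple(r)]
        out[k] = total
    return out


def search(receptor: Structure, ligand: Structure, rotations: RotationSet,
           spacing: float = DEFAULT_SPACING,
           blocked: Iterable[ResidueId] = (),
           top_n: int = 50,
           clash_penalty: float = DEFAULT_CLASH_PENALTY,
           radius: float = DEFAULT_ATOM_RADIUS) -> list[Pose]:
    """Exhaustive translational search for each sampled rotation.

    Rotations are applied about the ligand centroid; the global ``top_n``
    rotation-translation pairs by score are returned with deterministic
    tie-breaking (score desc, rotation index, lexicographic cell offset).
    Candidates closer than one cell in translation at the same rotation are
    merged keeping the higher score.
    """
    if top_n < 1:
        raise ConfigError("top_n must be >= 1")
    if len(rotations) == 0:
        raise ConfigError("rotation set is empty")
    lig_coords = ligand.heavy_coords()
    if lig_coords.size == 0:
        warnings.warn("ligand has no heavy atoms; returning no poses")
        return []
    receptor_grid = discretize(receptor, spacing, blocked=blocked, radius=radius)
    centroid = lig_coords.mean(axis=0)
    candidates: list[tuple[float, int, tuple, np.ndarray, np.ndarray]] = []
    per_rotation_keep = max(top_n, 8)
    for r_idx, R in enumerate(rotations.matrices()):
        rotated = (lig_coords - centroid) @ R.T + centroid
        lig_struct_grid = _grid_from_coords(rotated, spacing, radius)
        corr = correlate(receptor_grid, lig_struct_grid, clash_penalty)
        flat = corr.scores.ravel()
        k = min(per_rotation_keep * 4, flat.size)
        idx = np.argpartition(flat, -k)[-k:]
        order = sorted(idx, key=lambda i: (-flat[i], np.unravel_index(i, corr.scores.shape)))
        kept: list[tuple] = []
        for i in order:
            cell = np.unravel_index(i, corr.scores.shape)
            offset = corr.offset_of_index(cell)
            # merge candidates closer than one cell (for integer offsets:
            # exact duplicates), keeping the higher-scoring one
            if any(np.max(np.abs(offset - np.array(o))) < 1 for o in kept):
                continue
            kept.append(tuple(offset))
            shift = corr.real_shift(offset)
            candidates.append((float(flat[i]), r_idx, tuple(offset), R, shift))
            if len(kept) >= per_rotation_keep:
                break
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    poses: list[Pose] = []
    for pose_id, (score, r_idx, offset, R, shift) in enumerate(candidates[:top_n]):
        # full real-space map: x -> R (x - c) + c + shift  ==  R x + t
        t = centroid - R @ centroid + shift
        poses.append(Pose.from_matrix(pose_id, R, t, score))
    return poses


def write_poses_tsv(poses: Iterable[Pose], path: str) -> None:
    """poses.tsv columns: id, qw, qx, qy, qz, tx, ty, tz, score."""
    with open(path, "w") as fh:
        fh.write("id\tqw\tqx\tqy\tqz\ttx\tty\ttz\tscore\n")
        for p in poses:
            q = p.quaternion
            t = p.translation
            fh.write(f"{p.id}\t{q[0]:.9f}\t{q[1]:.9f}\t{q[2]:.9f}\t{q[3]:.9f}"
                     f"\t{t[0]:.6f}\t{t[1]:.6f}\t{t[2]:.6f}\t{p.primary_score:.6f}\n")


def read_poses_tsv(path: str) -> list[Pose]:
    poses = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError(f"{path}: not a poses.tsv file")
        for line in fh:
            cols = line.split("\t")
            poses.append(Pose(int(cols[0]),
                              np.array([float(c) for c in cols[1:5]]),
                              np.array([float(c) for c in cols[5:8]]),
                              float(cols[8])))
    return poses


def _grid_from_coords(coords: np.ndarray, spacing: float, radius: float) -> Grid:
    margin = spacing * math.ceil((radius + spacing) / spacing)
    origin = coords.min(axis=0) - margin
    top = coords.max(axis=0) + margin
    dims = tuple(int(np.floor((t - o) / spacing)) + 1 for o, t in zip(origin, top))
    if max(dims) > GRID_DIM_CAP:
        raise GridResourceError(f"ligand grid dims {dims} exceed cap {GRID_DIM_CAP}")
    occ = _occupancy_from_coords(coords, origin, dims, spacing, radius)
    return Grid(origin, spacing, occ)
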