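"""Generators for toy receptor-ligand systems with a known native pose.

`make_block_complex` builds two pseudo-protein bodies (poly-alanine-like
backbones with side-chain pseudo-atoms on a jittered lattice), mimicking the
docking inputs of a periplasmic chaperone landing on a membrane-complex
face:

* the receptor is a wide slab carrying a walled binding socket: a pocket
  floor flanked by a two-layer ring wall, sized so the docked ligand keeps
  ~3 Å clearance to the floor and walls. The native placement touches the
  floor and all four walls at once, which makes it the unique
  shape-complementarity optimum of the grid search — every other face of
  either body offers a single flat contact that scores lower;
* the receptor's exposed region is chain A; a deeper membrane-embedded
  slab is chain B, whose residues are *blocked* for docking and kept
  >= 8 Å from the docked ligand;
* lysine/cysteine-analogue anchors are planted across the native interface
  at exactly 10.0 Å (NZ-NZ, inside a 12 Å amine-amine spacer arm) and
  4.0 Å (SG-NZ, inside a 6.8 Å amine-sulfhydryl spacer arm);
* the interface-facing ligand layer is the designated docking domain
  ("P2-like") and doubles as the "upper" orientation set; the far layer is
  the "bottom" set.

The native pose is the identity transform by construction, so every
downstream stage has an exact ground truth. All generators are pure
functions of their seed and parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .docking import Pose
from .errors import GenerationError
from .pose_analysis import FilterCriteria, interface_residues
from .restraints import AMINE_AMINE, AMINE_SULFHYDRYL, CrossLink, RestraintSet
from .structure_io import Atom, Residue, ResidueId, Structure

LATTICE_STEP = 4.0       # Å between residue centres; bodies stay solid on a
                         # 2 Å docking grid
FLOOR_X = -1.5           # CA x of the pocket-floor residue layer
LIGAND_X = 4.5           # CA x of the ligand's contact layer, placed at the
                         # contact optimum of the 2 Å grid search so the
                         # discrete argmax stays within half a cell of the
                         # native placement
WALL_X = (2.5, 4.5, 6.5, 8.5)  # CA x of the wall layers; stacked every
                         # 2 Å so the wall face is smooth in x (no lattice
                         # phase a sliding ligand could re-align with) and
                         # flush with the ligand top in the native pose
BLOCKED_X = -13.5        # CA x of the first membrane-embedded (blocked) layer
WALL_CLEARANCE = 3.0     # Å gap between ligand flank atoms and wall atoms
JITTER_SD = 0.1          # Å, clipped at 0.25 so planted margins survive
BLOCK_MIN_CLEARANCE = 8.0
#: Heavy-atom cutoff used to define the native interface that seeds the
#: ligand docking domain and orientation sets. One grid cell wider than the
#: native contact gap so that poses within one cell of the native placement
#: still register every native contact.
DOMAIN_CUTOFF = 7.0


@dataclass
class SyntheticSystem:
    receptor: Structure
    ligand_reference: Structure
    native_pose: Pose
    planted_restraints: RestraintSet
    blocked_receptor_residues: set[ResidueId]
    ligand_domain: set[ResidueId]
    orientation_upper: set[ResidueId]
    orientation_bottom: set[ResidueId]
    seed: int

    def criteria(self, min_domain_fraction: float = 0.5) -> FilterCriteria:
        """Filter criteria encoding the planted experimental knowledge."""
        required = {
            (r.receptor_anchor[0], r.receptor_anchor[1], "")
            for r in self.planted_restraints
        }
        return FilterCriteria(
            required_receptor_interface=required,
            required_ligand_domain=set(self.ligand_domain),
            min_domain_fraction=min_domain_fraction,
            orientation_required=set(self.orientation_upper),
            orientation_min_count=1,
            # a pose one grid cell from native can pull a single
            # just-outside-the-cutoff residue into the interface, so one
            # forbidden residue is tolerated; flipped poses show many more
            orientation_forbidden=set(self.orientation_bottom),
            orientation_max_count=1,
            blocked=set(self.blocked_receptor_residues),
        )


def _pocket_axis(f: int) -> list[float]:
    return [LATTICE_STEP * (i - (f - 1) / 2.0) for i in range(f)]


def _jitter(rng: np.random.Generator) -> np.ndarray:
    return np.clip(rng.normal(0.0, JITTER_SD, 3), -0.25, 0.25)


def _backbone(ca: np.ndarray) -> list[Atom]:
    return [
        Atom("N", "N", ca + np.array([0.0, -1.2, 0.4])),
        Atom("CA", "C", ca.copy()),
        Atom("C", "C", ca + np.array([0.0, 1.2, 0.4])),
    ]


def _lateral_dir(y: float, z: float, rng: np.random.Generator) -> np.ndarray:
    v = np.array([0.0, y, z])
    n = np.linalg.norm(v)
    if n < 1e-9:
        v = rng.normal(size=3)
        v[0] = 0.0
        n = np.linalg.norm(v) or 1.0
    return v / n


def _build_block_complex(seed: int, n_receptor: int, n_ligand: int,
                         interface_size: int) -> SyntheticSystem:
    rng = np.random.default_rng(seed)
    f = math.ceil(math.sqrt(interface_size))
    pocket = _pocket_axis(f)
    # ring radius leaves WALL_CLEARANCE between the ligand flank atoms
    # (pocket half-width + 1.5 Å side-chain/backbone spread) and the wall's
    # inward-most backbone atoms (1.2 Å inside the ring radius)
    ring = pocket[-1] + 1.5 + WALL_CLEARANCE + 1.2
    base_axis = sorted(set(pocket + [-ring, ring]))
    ring_slots = []
    for t in pocket:
        ring_slots += [(-ring, t), (ring, t), (t, -ring), (t, ring)]
    ring_slots += [(-ring, -ring), (-ring, ring), (ring, -ring), (ring, ring)]

    receptor = Structure("synthetic_receptor")
    chain_counters = {"A": 0, "B": 0}
    blocked: set[ResidueId] = set()
    rec_interface_res: list[Residue] = []
    budget = n_receptor

    def add_receptor(chain: str, y: float, z: float, ca: np.ndarray,
                     cb_dir: np.ndarray) -> Residue | None:
        nonlocal budget
        if budget <= 0:
            return None
        budget -= 1
        chain_counters[chain] += 1
        res = Residue(chain, chain_counters[chain], "ALA", _backbone(ca))
        res.atoms.append(Atom("CB", "C", ca + 1.5 * cb_dir))
        receptor.chains.setdefault(chain, []).append(res)
        if chain == "B":
            blocked.add(res.id)
        return res

    # pocket floor (the native binding site), then the rest of the top base
    # layer, the socket walls, the backing base layer, and finally the
    # membrane-embedded blocked slab — in priority order so small budgets
    # still produce a floor to dock against.
    for y in pocket:
        for z in pocket:
            res = add_receptor("A", y, z,
                               np.array([FLOOR_X, y, z]) + _jitter(rng),
                               _lateral_dir(y, z, rng))
            if res is not None and len(rec_interface_res) < interface_size:
                rec_interface_res.append(res)
    for y, z in ring_slots:
        add_receptor("A", y, z, np.array([FLOOR_X, y, z]) + _jitter(rng),
                     _lateral_dir(y, z, rng))
    for wall_x in WALL_X:
        for y, z in ring_slots:
            out = np.array([0.0,
                            np.sign(y) if abs(y) == ring else 0.0,
                            np.sign(z) if abs(z) == ring else 0.0])
            norm = np.linalg.norm(out)
            add_receptor("A", y, z, np.array([wall_x, y, z]) + _jitter(rng),
                         out / norm if norm else _lateral_dir(y, z, rng))
    for y in base_axis:
        for z in base_axis:
            add_receptor("A", y, z,
                         np.array([FLOOR_X - LATTICE_STEP, y, z]) + _jitter(rng),
                         _lateral_dir(y, z, rng))
    depth = 0
    while budget > 0:
        for y in base_axis:
            for z in base_axis:
                add_receptor("B", y, z,
                             np.array([BLOCKED_X - LATTICE_STEP * depth, y, z])
                             + _jitter(rng),
                             _lateral_dir(y, z, rng))
        depth += 1

    # ---- ligand: a two-layer slab that fits the socket -----------------
    ligand = Structure("synthetic_ligand")
    ligand.chains["S"] = []
    lig_interface_res: list[Residue] = []
    num = 0
    placed = 0
    layer = 0
    while placed < n_ligand:
        x0 = LIGAND_X + LATTICE_STEP * layer
        for y in pocket:
            for z in pocket:
                if placed >= n_ligand:
                    break
                ca = np.array([x0, y, z]) + _jitter(rng)
                num += 1
                res = Residue("S", num, "ALA", _backbone(ca))
                # side chains along z keep the y-flank clearance to the wall
                cb = np.array([0.0, 0.0, 1.0 if z >= 0 else -1.0])
                res.atoms.append(Atom("CB", "C", ca + 1.5 * cb))
                ligand.chains["S"].append(res)
                if layer == 0 and len(lig_interface_res) < interface_size:
                    lig_interface_res.append(res)
                placed += 1
        layer += 1

    if len(rec_interface_res) < 2 or len(lig_interface_res) < 3:
        raise GenerationError("interface too small to plant both anchor pairs")

    # ---- planted anchors ----------------------------------------------
    # Anchor atoms are placed along the line towards their partner so the
    # exact planted distances survive lattice jitter.
    def pick_partner(point: np.ndarray, target_dist: float,
                     exclude=()) -> Residue:
        candidates = [r for r in lig_interface_res if r not in exclude]
        return min(candidates, key=lambda r: abs(
            float(np.linalg.norm(r.get_atom("CA").coord
                                 + np.array([1.0, 0, 0]) - point))
            - target_dist))

    # sulfhydryl pair at exactly 4.0 Å (inside the 6.8 Å spacer arm, with
    # enough slack that a pose one grid cell from native still reaches)
    cys = rec_interface_res[0]
    cys.aa_type = "CYS"
    # anchor atoms sit on exact lattice positions (no jitter) so the
    # planted distances and the anchor-in-interface margin are deterministic
    sg = np.array([FLOOR_X + 1.8, pocket[0], pocket[0]])
    cys.atoms.append(Atom("SG", "S", sg))
    lys0 = pick_partner(sg, 4.0)
    lys0.aa_type = "LYS"
    u = lys0.get_atom("CA").coord + np.array([1.0, 0, 0]) - sg
    u = u / np.linalg.norm(u)
    lys0.atoms.append(Atom("NZ", "N", sg + 4.0 * u))

    # amine pair at exactly 10.0 Å (inside the 12 Å spacer arm)
    lys_r = rec_interface_res[1]
    lys_r.aa_type = "LYS"
    nz_r = np.array([FLOOR_X + 1.8, pocket[0], pocket[1 % len(pocket)]])
    lys_r.atoms.append(Atom("NZ", "N", nz_r))
    lys_l = pick_partner(nz_r, 10.0, exclude=(lys0,))
    lys_l.aa_type = "LYS"
    u = lys_l.get_atom("CA").coord + np.array([1.0, 0, 0]) - nz_r
    u = u / np.linalg.norm(u)
    lys_l.atoms.append(Atom("NZ", "N", nz_r + 10.0 * u))

    restraints = RestraintSet([
        CrossLink(AMINE_SULFHYDRYL, (cys.chain_id, cys.seq_number),
                  (lys0.chain_id, lys0.seq_number), 6.8, "planted_spdp"),
        CrossLink(AMINE_AMINE, (lys_r.chain_id, lys_r.seq_number),
                  (lys_l.chain_id, lys_l.seq_number), 12.0, "planted_dsp"),
    ])

    # the docking domain and orientation sets are read off the native
    # interface: "upper" = ligand residues contacting the receptor in the
    # native pose (floor and wall contacts alike), "bottom" = the rest
    native_iface = interface_residues(receptor, ligand, DOMAIN_CUTOFF)
    domain = set(native_iface.ligand_residues)
    all_ligand_ids = {r.id for r in ligand.residues()}
    system = SyntheticSystem(
        receptor=receptor,
        ligand_reference=ligand,
        native_pose=Pose.identity(),
        planted_restraints=restraints,
        blocked_receptor_residues=blocked,
        ligand_domain=domain,
        orientation_upper=set(domain),
        orientation_bottom=all_ligand_ids - domain,
        seed=seed,
    )
    _validate_system(system)
    return system


def _validate_system(system: SyntheticSystem) -> None:
    for entry in system.planted_restraints.evaluate_all(
            system.receptor, system.ligand_reference):
        if not entry.satisfied:
            raise GenerationError(
                f"native pose violates planted restraint {entry.label} "
                f"({entry.distance:.2f} Å)")
    lig = system.ligand_reference.heavy_coords()
    for rid in system.blocked_receptor_residues:
        res = system.receptor.residue(*rid)
        for a in res.heavy_atoms():
            d = np.linalg.norm(lig - a.coord, axis=1).min()
            if d < BLOCK_MIN_CLEARANCE:
                raise GenerationError(
                    f"blocked residue {rid} is {d:.2f} Å from the ligand")
    if system.orientation_upper & system.orientation_bottom:
        raise GenerationError("orientation sets overlap")


#: Default residue budgets give the full socket architecture for a 3x3
#: pocket: floor 9 + base ring 16 + four stacked wall rings 64 + backing
#: layer 25 (chain A) and one blocked slab layer 25 (chain B).
DEFAULT_N_RECEPTOR = 139
DEFAULT_N_LIGAND = 18


def make_block_complex(seed: int = 0, n_receptor: int = DEFAULT_N_RECEPTOR,
                       n_ligand: int = DEFAULT_N_LIGAND,
                       interface_size: int = 9, max_retries: int = 5
                       ) -> SyntheticSystem:
    """Deterministic toy receptor-ligand complex with planted ground truth.

    With the default budgets the receptor socket is complete and the native
    pose is the global optimum of the shape-complementarity search; smaller
    budgets still satisfy every restraint/interface invariant but weaken
    the docking funnel.
    """
    if min(n_receptor, n_ligand) < 5:
        raise ValueError("residue counts must be >= 5")
    if not 2 <= interface_size < min(n_receptor, n_ligand):
        raise ValueError("need 2 <= interface_size < min(n_receptor, n_ligand)")
    last: GenerationError | None = None
    for attempt in range(max_retries):
        try:
            return _build_block_complex(seed + 10007 * attempt, n_receptor,
                                        n_ligand, interface_size)
        except GenerationError as exc:
            last = exc
    raise GenerationError(f"generation failed after {max_retries} attempts: {last}")


def make_decoys(system: SyntheticSystem, n: int, rot_sigma: float,
                trans_sigma: float, seed: int) -> list[Pose]:
    """Rigid perturbations of the native pose.

    Rotation noise is a random-axis rotation with a normally distributed
    angle (degrees, sd = rot_sigma) about the ligand centroid; translation
    noise is isotropic normal (Å, sd = trans_sigma). Zero sigmas return n
    copies of the native pose.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rot_sigma < 0 or trans_sigma < 0:
        raise ValueError("sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    centroid = system.ligand_reference.centroid()
    poses: list[Pose] = []
    for i in range(n):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis) or 1.0
        angle = math.radians(rng.normal(0.0, rot_sigma)) if rot_sigma > 0 else 0.0
        half = angle / 2.0
        q = np.array([math.cos(half), *(math.sin(half) * axis)])
        noise = rng.normal(0.0, trans_sigma, 3) if trans_sigma > 0 else np.zeros(3)
        pose = Pose(i, q, np.zeros(3))
        R = pose.rotation_matrix
        t = centroid - R @ centroid + noise
        poses.append(Pose(i, q, t))
    return poses


# --- ideal helix fixture ----------------------------------------------------

_BOND_N_CA, _BOND_CA_C, _BOND_C_N = 1.458, 1.525, 1.329
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA = 111.2, 116.2, 121.7
HELIX_PHI, HELIX_PSI, OMEGA = -57.0, -47.0, 180.0


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural extension reference frame placement of atom d after a-b-c."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -math.cos(angle),
        math.sin(angle) * math.cos(torsion),
        math.sin(angle) * math.sin(torsion),
    ])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def make_helix_backbone(n: int) -> Structure:
    """Ideal alpha-helical N/CA/C backbone, phi = -57, psi = -47 throughout."""
    if n < 4:
        raise ValueError("need at least 4 residues")
    coords: list[tuple[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANG_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.extend([("N", n0), ("CA", ca0), ("C", c0)])
    prev_n, prev_ca, prev_c = n0, ca0, c0
    for _ in range(1, n):
        nn = _place_atom(prev_n, prev_ca, prev_c, _BOND_C_N, _ANG_CA_C_N, HELIX_PSI)
        ca = _place_atom(prev_ca, prev_c, nn, _BOND_N_CA, _ANG_C_N_CA, OMEGA)
        cc = _place_atom(prev_c, nn, ca, _BOND_CA_C, _ANG_N_CA_C, HELIX_PHI)
        coords.extend([("N", nn), ("CA", ca), ("C", cc)])
        prev_n, prev_ca, prev_c = nn, ca, cc
    helix = Structure("ideal_helix")
    helix.chains["H"] = []
    for i in range(n):
        atoms = [Atom(name, name[0], xyz) for name, xyz in coords[3 * i:3 * i + 3]]
        helix.chains["H"].append(Residue("H", i + 1, "ALA", atoms))
    return helix
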