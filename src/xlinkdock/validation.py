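"""Model-quality checks: backbone dihedrals with Ramachandran classification
and a 3D-1D environment-profile score with expected-high/low calibration.

The Ramachandran stage computes phi/psi torsions and classifies each residue
against favourable-region polygons shipped as package data (a two-level
favoured+allowed set collapsed to "favorable"). The profile stage assigns
each residue one of 18 environment classes (3 burial x 2 environment
polarity x 3 secondary structure), looks up a per-residue 3D-1D score in an
embedded 20x18 table, and sums them into a Verify Score that is compared
with a length-calibrated Expected High Score and an Expected Low Score fixed
at 45% of the high score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.spatial import cKDTree

from .errors import ConfigError, ParameterizationError
from .structure_io import ResidueId, Structure

EXPECTED_LOW_FRACTION = 0.45
BACKBONE_NAMES = {"N", "CA", "C", "O"}

BURIAL_BINS = ((0.4, "exposed"), (0.7, "partial"), (1.01, "buried"))
POLAR_ELEMENTS = {"N", "O"}
POLAR_ENV_THRESHOLD = 0.35
NEIGHBOR_CUTOFF = 4.5  # Å around side-chain atoms for environment polarity


# --- dihedrals --------------------------------------------------------------


def dihedral_angle(p0, p1, p2, p3) -> float | None:
    """Signed torsion angle in degrees, right-handed; None when degenerate."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.linalg.norm(n1)
    m2 = np.linalg.norm(n2)
    if m1 < 1e-9 or m2 < 1e-9:
        return None
    b1n = b1 / np.linalg.norm(b1)
    x = n1 @ n2
    y = np.cross(n1, n2) @ b1n
    angle = math.degrees(math.atan2(y, x))
    return 180.0 if angle <= -180.0 else angle


@dataclass
class DihedralRecord:
    residue_id: ResidueId
    phi: float | None
    psi: float | None
    classification: str = "undefined"
    reason: str = ""


def backbone_dihedrals(s: Structure) -> list[DihedralRecord]:
    """phi(C_{i-1}, N_i, CA_i, C_i) and psi(N_i, CA_i, C_i, N_{i+1}).

    Chain-terminal residues lack one angle; a missing backbone atom or
    degenerate (collinear) geometry yields an undefined angle with a reason
    rather than an exception.
    """
    records: list[DihedralRecord] = []
    for residues in s.chains.values():
        for i, res in enumerate(residues):
            reason_parts = []
            n, ca, c = (res.get_atom(x) for x in ("N", "CA", "C"))
            phi = psi = None
            if n is None or ca is None or c is None:
                reason_parts.append("missing backbone atom")
            else:
                if i > 0:
                    prev_c = residues[i - 1].get_atom("C")
                    if prev_c is None:
                        reason_parts.append("previous residue lacks C")
                    else:
                        phi = dihedral_angle(prev_c.coord, n.coord, ca.coord, c.coord)
                        if phi is None:
                            reason_parts.append("degenerate geometry for phi")
                else:
                    reason_parts.append("chain start: no phi")
                if i < len(residues) - 1:
                    next_n = residues[i + 1].get_atom("N")
                    if next_n is None:
                        reason_parts.append("next residue lacks N")
                    else:
                        psi = dihedral_angle(n.coord, ca.coord, c.coord, next_n.coord)
                        if psi is None:
                            reason_parts.append("degenerate geometry for psi")
                else:
                    reason_parts.append("chain end: no psi")
            records.append(DihedralRecord(res.id, phi, psi,
                                          reason="; ".join(reason_parts)))
    return records


# --- Ramachandran regions ---------------------------------------------------


def load_regions(path: str | None = None) -> dict[str, MplPath]:
    """Load named (phi, psi) polygons from the packaged (or given) text file.

    Format: ``region <name>`` headers followed by one ``phi psi`` pair per
    line; blank lines and ``#`` comments ignored.
    """
    if path is None:
        text = (resources.files("xlinkdock.data") / "rama_regions.txt").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    regions: dict[str, list[tuple[float, float]]] = {}
    current: str | None = None
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("region "):
            current = line.split(None, 1)[1]
            regions[current] = []
            continue
        if current is None:
            raise ConfigError(f"region file line {lineno}: vertex before any header")
        cols = line.split()
        if len(cols) != 2:
            raise ConfigError(f"region file line {lineno}: expected 'phi psi'")
        try:
            regions[current].append((float(cols[0]), float(cols[1])))
        except ValueError:
            raise ConfigError(f"region file line {lineno}: non-numeric vertex") from None
    paths = {}
    for name, verts in regions.items():
        if len(verts) < 3:
            raise ConfigError(f"region {name!r} needs >= 3 vertices")
        paths[name] = MplPath(verts)
    return paths


def _in_any_region(phi: float, psi: float, regions: dict[str, MplPath]) -> bool:
    # wrap-around at +-180 handled by testing all +-360 shifts
    for dphi in (-360.0, 0.0, 360.0):
        for dpsi in (-360.0, 0.0, 360.0):
            point = (phi + dphi, psi + dpsi)
            for path in regions.values():
                if path.contains_point(point):
                    return True
    return False


def ramachandran_classify(records: Sequence[DihedralRecord],
                          regions: dict[str, MplPath] | None = None
                          ) -> list[DihedralRecord]:
    """Mark each record favorable/unfavorable by polygon membership.

    Residues missing either angle stay "undefined". Classification is
    invariant to +-360 degree shifts of the input angles.
    """
    regions = regions or load_regions()
    for rec in records:
        if rec.phi is None or rec.psi is None:
            rec.classification = "undefined"
        elif _in_any_region(rec.phi, rec.psi, regions):
            rec.classification = "favorable"
        else:
            rec.classification = "unfavorable"
    return records


def count_classifications(records: Sequence[DihedralRecord]) -> dict[str, int]:
    out = {"favorable": 0, "unfavorable": 0, "undefined": 0}
    for rec in records:
        out[rec.classification] += 1
    return out


# --- accessible surface / burial --------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic Fibonacci lattice on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])

_ASA_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2}


def _accessible_fraction(coords: np.ndarray, radii: np.ndarray, probe: float,
                         points: np.ndarray) -> np.ndarray:
    """Fraction of sphere points accessible per atom (Shrake-Rupley style)."""
    n = len(coords)
    out = np.ones(n)
    if n == 1:
        return out
    expanded = radii + probe
    tree = cKDTree(coords)
    for i in range(n):
        neighbors = [j for j in tree.query_ball_point(coords[i], expanded[i]
                                                      + expanded.max())
                     if j != i]
        if not neighbors:
            continue
        surface = coords[i] + expanded[i] * points
        occluded = np.zeros(len(points), dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(surface - coords[j], axis=1)
            occluded |= d < expanded[j]
        out[i] = 1.0 - occluded.mean()
    return out


def accessible_area(s: Structure, probe: float = 1.4,
                    n_points: int = 128) -> dict[ResidueId, float]:
    """Per-residue side-chain buried fraction.

    buried = 1 - (accessible in the full structure / accessible for the
    isolated residue), aggregated over side-chain atoms (CA for glycine-like
    residues without a side chain). A fully isolated residue scores 0.
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a stable estimate")
    residues = list(s.residues())
    coords, radii, owner, is_side = [], [], [], []
    for idx, res in enumerate(residues):
        heavy = res.heavy_atoms()
        side = [a for a in heavy if a.name not in BACKBONE_NAMES] or \
               [a for a in heavy if a.name == "CA"]
        side_ids = {id(a) for a in side}
        for a in heavy:
            coords.append(a.coord)
            radii.append(_ASA_RADII.get(a.element.capitalize(), 1.7))
            owner.append(idx)
            is_side.append(id(a) in side_ids)
    if not coords:
        return {}
    coords = np.array(coords)
    radii = np.array(radii)
    owner = np.array(owner)
    is_side = np.array(is_side)
    points = _sphere_points(n_points)

    frac_complex = _accessible_fraction(coords, radii, probe, points)
    result: dict[ResidueId, float] = {}
    for idx, res in enumerate(residues):
        mask = owner == idx
        iso = _accessible_fraction(coords[mask], radii[mask], probe, points)
        weights = (radii[mask] + probe) ** 2
        sel = is_side[mask]
        if not sel.any():
            result[res.id] = 0.0
            continue
        area_iso = (iso[sel] * weights[sel]).sum()
        area_cpx = (frac_complex[mask][sel] * weights[sel]).sum()
        result[res.id] = 0.0 if area_iso <= 0 else \
            float(np.clip(1.0 - area_cpx / area_iso, 0.0, 1.0))
    return result


# --- 3D-1D verify score -----------------------------------------------------

AA_ORDER = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
            "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
            "TYR", "VAL"]
SS_CLASSES = ("helix", "sheet", "other")
ENV_CLASSES = [f"{burial}-{pol}-{ss}"
               for burial in ("exposed", "partial", "buried")
               for pol in ("nonpolar", "polar")
               for ss in SS_CLASSES]


def load_score_table(path: str | None = None) -> dict[tuple[str, str], float]:
    """20x18 3D-1D score table: rows amino acids, columns environment classes."""
    if path is None:
        text = (resources.files("xlinkdock.data") / "profile3d_scores.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")[1:]
    if set(header) != set(ENV_CLASSES):
        raise ConfigError("score table header does not list the 18 environment classes")
    table: dict[tuple[str, str], float] = {}
    for ln in lines[1:]:
        cols = ln.split("\t")
        aa = cols[0]
        for env, val in zip(header, cols[1:]):
            table[(aa, env)] = float(val)
    return table


def secondary_structure_class(phi: float | None, psi: float | None) -> str:
    """Coarse helix/sheet/other assignment from (phi, psi) bins."""
    if phi is None or psi is None:
        return "other"
    if -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0:
        return "helix"
    if -180.0 <= phi <= -40.0 and (psi >= 60.0 or psi <= -150.0):
        return "sheet"
    return "other"


def _burial_class(fraction: float) -> str:
    for bound, name in BURIAL_BINS:
        if fraction < bound:
            return name
    return "buried"


def _environment_polarity(s: Structure) -> dict[ResidueId, str]:
    residues = list(s.residues())
    coords, owner, polar = [], [], []
    for idx, res in enumerate(residues):
        for a in res.heavy_atoms():
            coords.append(a.coord)
            owner.append(idx)
            polar.append(a.element.capitalize() in POLAR_ELEMENTS)
    coords = np.array(coords)
    owner = np.array(owner)
    polar = np.array(polar)
    tree = cKDTree(coords)
    out: dict[ResidueId, str] = {}
    for idx, res in enumerate(residues):
        side = [a for a in res.heavy_atoms() if a.name not in BACKBONE_NAMES] or \
               res.heavy_atoms()
        neighbor_polar: list[bool] = []
        for a in side:
            for j in tree.query_ball_point(a.coord, NEIGHBOR_CUTOFF):
                if owner[j] != idx:
                    neighbor_polar.append(bool(polar[j]))
        frac = np.mean(neighbor_polar) if neighbor_polar else 0.0
        out[res.id] = "polar" if frac >= POLAR_ENV_THRESHOLD else "nonpolar"
    return out


def expected_high_score(n_residues: int) -> float:
    """Length calibration from the original 3D-1D profile literature:
    exp(-0.83 + 1.008 ln L)."""
    if n_residues <= 0:
        return 0.0
    return math.exp(-0.83 + 1.008 * math.log(n_residues))


@dataclass
class ResidueProfile:
    residue_id: ResidueId
    aa_type: str
    environment: str
    score: float


@dataclass
class VerifyProfile:
    residues: list[ResidueProfile] = field(default_factory=list)
    verify_score: float = 0.0
    expected_high: float = 0.0
    expected_low: float = 0.0


def verify_score(s: Structure, expected_high: float | None = None,
                 table: dict[tuple[str, str], float] | None = None,
                 probe: float = 1.4, n_points: int = 128) -> VerifyProfile:
    """Per-residue 3D-1D environment scores and their total.

    ``expected_high`` defaults to the length calibration; the expected low
    score is always 45% of the high score.
    """
    table = table or load_score_table()
    residues = list(s.residues())
    if not residues:
        high = expected_high if expected_high is not None else 0.0
        return VerifyProfile([], 0.0, high, EXPECTED_LOW_FRACTION * high)
    burial = accessible_area(s, probe=probe, n_points=n_points)
    polarity = _environment_polarity(s)
    dihedrals = {r.residue_id: r for r in backbone_dihedrals(s)}
    profiles = []
    for res in residues:
        rec = dihedrals[res.id]
        env = (f"{_burial_class(burial[res.id])}-{polarity[res.id]}-"
               f"{secondary_structure_class(rec.phi, rec.psi)}")
        key = (res.aa_type, env)
        if key not in table:
            raise ParameterizationError(f"no 3D-1D score for {key}")
        profiles.append(ResidueProfile(res.id, res.aa_type, env, table[key]))
    total = float(sum(p.score for p in profiles))
    high = expected_high if expected_high is not None \
        else expected_high_score(len(residues))
    return VerifyProfile(profiles, total, high, EXPECTED_LOW_FRACTION * high)


@dataclass
class Outcome:
    label: str   # mostly_correct | grossly_misfolded
    band: str    # above_expected_high | intermediate | below_expected_low


def classify_outcome(profile: VerifyProfile) -> Outcome:
    """Grade a model from its Verify Score bands.

    Scores at or above the expected high, and scores in the band between
    the expected low (inclusive) and high, are both "mostly correct" (the
    band field distinguishes them); below the expected low is grossly
    misfolded.
    """
    if profile.verify_score >= profile.expected_high:
        return Outcome("mostly_correct", "above_expected_high")
    if profile.verify_score >= profile.expected_low:
        return Outcome("mostly_correct", "intermediate")
    return Outcome("grossly_misfolded", "below_expected_low")
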