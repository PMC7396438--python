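"""Detailed-energy rescoring of filtered poses and final model selection.

The primary docking score ranks poses by shape complementarity only; this
stage re-ranks the survivors with a weighted sum of physically motivated
pairwise terms (lower is better): attractive/repulsive Lennard-Jones,
attractive/repulsive screened Coulomb on residue-typed formal charges, and
a contact desolvation score. The published rescoring function this emulates
is used only ordinally, so weights and tables are configuration, not claims.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError, ParameterizationError
from .pose_analysis import PoseRecord
from .structure_io import Structure

DEFAULT_CUTOFF = 9.0      # Å pairwise cutoff for every term
COULOMB_CONSTANT = 332.0  # kcal mol^-1 Å e^-2
DIELECTRIC_SLOPE = 4.0    # distance-dependent dielectric eps(r) = slope * r
LJ_EPSILON = 0.1          # kcal/mol well depth (uniform toy well)

#: Per-element van der Waals radii (Å); the combined radius of a pair is the
#: sum. Overridable via the ``params`` mapping of :func:`energy_terms`.
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}
VDW_DEFAULT_RADIUS = 1.7

#: Formal charges by (residue type, atom name): lysine/arginine side-chain
#: terminal +1, aspartate/glutamate carboxylate midpoint atom -1.
FORMAL_CHARGES = {
    ("LYS", "NZ"): 1.0,
    ("ARG", "CZ"): 1.0,
    ("ASP", "CG"): -1.0,
    ("GLU", "CD"): -1.0,
}

#: Desolvation contact matrix over atom polarity classes. Burying nonpolar
#: against nonpolar is favourable; burying a polar atom against nonpolar
#: costs desolvation.
POLAR_ELEMENTS = {"N", "O"}
DESOLVATION_MATRIX = {
    ("nonpolar", "nonpolar"): -0.5,
    ("nonpolar", "polar"): 0.3,
    ("polar", "nonpolar"): 0.3,
    ("polar", "polar"): 0.0,
}


@dataclass
class EnergyTerms:
    vdw_attractive: float = 0.0
    vdw_repulsive: float = 0.0
    elec_attractive: float = 0.0
    elec_repulsive: float = 0.0
    desolvation: float = 0.0

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])


@dataclass
class RescoreWeights:
    vdw_attractive: float = 1.0
    vdw_repulsive: float = 0.8
    elec_attractive: float = 0.4
    elec_repulsive: float = 0.4
    desolvation: float = 1.0

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])


def _atom_table(s: Structure):
    coords, elements, charges = [], [], []
    for res in s.residues():
        for a in res.heavy_atoms():
            coords.append(a.coord)
            elements.append(a.element.capitalize())
            charges.append(FORMAL_CHARGES.get((res.aa_type, a.name), 0.0))
    return coords, elements, charges


def energy_terms(receptor: Structure, ligand_posed: Structure,
                 params: Mapping | None = None) -> EnergyTerms:
    """Pairwise heavy-atom energy terms between receptor and posed ligand.

    All pairs within ``cutoff`` contribute; pairs farther apart contribute
    exactly zero, so a non-contacting pose has all-zero terms. Tables
    (radii, charges, desolvation matrix, epsilon) are overridable through
    ``params``.
    """
    params = dict(params or {})
    cutoff = float(params.get("cutoff", DEFAULT_CUTOFF))
    radii_table = dict(VDW_RADII)
    radii_table.update(params.get("radii", {}))
    default_radius = params.get("default_radius", None)
    epsilon = float(params.get("epsilon", LJ_EPSILON))
    desolv = dict(DESOLVATION_MATRIX)
    desolv.update(params.get("desolvation_matrix", {}))

    rc, re_, rq = _atom_table(receptor)
    lc, le, lq = _atom_table(ligand_posed)
    if not rc or not lc:
        raise ConfigError("both structures must contain heavy atoms")

    def radius_of(element: str) -> float:
        if element in radii_table:
            return radii_table[element]
        if default_radius is not None:
            return float(default_radius)
        if element in ("F", "Cl", "Br", "I", "Se", "X"):
            raise ParameterizationError(f"no van der Waals radius for element {element!r}")
        return VDW_DEFAULT_RADIUS

    rxyz, lxyz = np.array(rc), np.array(lc)
    rrad = np.array([radius_of(e) for e in re_])
    lrad = np.array([radius_of(e) for e in le])
    rq, lq = np.array(rq), np.array(lq)
    rpol = np.array([e in POLAR_ELEMENTS for e in re_])
    lpol = np.array([e in POLAR_ELEMENTS for e in le])

    pairs = cKDTree(rxyz).sparse_distance_matrix(
        cKDTree(lxyz), cutoff, output_type="coo_matrix")
    terms = EnergyTerms()
    if pairs.nnz == 0:
        return terms
    i, j, d = pairs.row, pairs.col, np.maximum(pairs.data, 0.5)

    r0 = rrad[i] + lrad[j]
    ratio6 = (r0 / d) ** 6
    lj = epsilon * (ratio6 ** 2 - 2.0 * ratio6)
    terms.vdw_attractive = float(np.minimum(lj, 0.0).sum())
    terms.vdw_repulsive = float(np.maximum(lj, 0.0).sum())

    qq = rq[i] * lq[j]
    elec = COULOMB_CONSTANT * qq / (DIELECTRIC_SLOPE * d * d)
    terms.elec_attractive = float(np.minimum(elec, 0.0).sum())
    terms.elec_repulsive = float(np.maximum(elec, 0.0).sum())

    classes_r = np.where(rpol[i], "polar", "nonpolar")
    classes_l = np.where(lpol[j], "polar", "nonpolar")
    contact = np.array([desolv[(a, b)] for a, b in zip(classes_r, classes_l)])
    terms.desolvation = float((contact * (1.0 - d / cutoff)).sum())
    return terms


def rescore(terms: EnergyTerms, weights: RescoreWeights | None = None) -> float:
    """Weighted sum of the energy terms; lower is better."""
    w = weights or RescoreWeights()
    return float(terms.as_vector() @ w.as_vector())


def _dominates(a: PoseRecord, b: PoseRecord) -> bool:
    """a dominates b on (density up, primary score up, rescore down)."""
    ge = (a.density >= b.density and a.primary_score >= b.primary_score
          and a.rescore <= b.rescore)
    strict = (a.density > b.density or a.primary_score > b.primary_score
              or a.rescore < b.rescore)
    return ge and strict


def select_models(records: Sequence[PoseRecord], k: int) -> list[PoseRecord]:
    """Select up to ``k`` final models by the triple criterion.

    Records are ordered lexicographically by (density desc, primary score
    desc, rescore asc, pose id); Pareto-dominated records are deferred until
    every non-dominated record has been taken, so a dominated pose is never
    selected before its dominator.
    """
    if k <= 0:
        raise ConfigError("k must be >= 1")
    ordered = sorted(records, key=lambda r: (-r.density, -r.primary_score,
                                             r.rescore, r.pose_id))
    dominated = [
        any(_dominates(other, rec) for other in ordered if other is not rec)
        for rec in ordered
    ]
    front = [r for r, dom in zip(ordered, dominated) if not dom]
    rest = [r for r, dom in zip(ordered, dominated) if dom]
    return (front + rest)[:k]
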