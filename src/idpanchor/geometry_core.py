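"""Geometric primitives: dihedral angles, side-chain chi angles, Kabsch
superposition and backbone RMSD series.

Conventions
-----------
* Angles are reported in degrees in the half-open range (-180, +180], IUPAC
  sign convention (clockwise positive looking from the second toward the
  third atom).
* chi1 is the torsion N-CA-CB-G where G is the gamma atom of the residue
  type (CG for most, OG for Ser, OG1 for Thr); chi2 is CA-CB-CG-D with the
  delta atom CD1 for Phe/Trp/Leu and CD (or OD1) otherwise.
* Missing atoms yield explicit ``None`` values, never zeros or exceptions,
  so ensemble statistics can exclude those frames from the denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure_io import Ensemble, Residue, Structure, select

logger = logging.getLogger(__name__)


class DegenerateGeometryError(ValueError):
    """Raised when a dihedral is requested for collinear/zero-length bonds."""


class SuperpositionError(ValueError):
    """Raised when a superposition problem is underdetermined or mismatched."""


def wrap_angle(deg: float | np.ndarray) -> float | np.ndarray:
    """Wrap degrees into (-180, +180]."""
    a = -np.mod(-np.asarray(deg, dtype=float) + 180.0, 360.0) + 180.0
    return float(a) if np.isscalar(deg) or np.ndim(deg) == 0 else a


def circular_difference(a: float | np.ndarray, b: float | np.ndarray):
    """Signed circular difference a-b in (-180, +180] degrees."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle (degrees) defined by four points.

    Uses the standard atan2 formulation; 0 deg is cis (p1 and p4 eclipsed),
    180 deg is trans.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-10:
            raise DegenerateGeometryError("zero-length bond vector in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("collinear atoms in dihedral")
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    return wrap_angle(np.degrees(np.arctan2(y, x)))


# gamma / delta atom names per residue type (chi1 = N-CA-CB-gamma,
# chi2 = CA-CB-CG-delta).  Only residue types occurring in the p53 segment
# plus the other standard chi-bearing types are listed.
CHI_GAMMA_ATOM = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}
CHI_DELTA_ATOM = {
    "ARG": "CD", "ASN": "OD1", "ASP": "OD1", "GLN": "CD", "GLU": "CD",
    "HIS": "ND1", "ILE": "CD1", "LEU": "CD1", "LYS": "CD", "MET": "SD",
    "PHE": "CD1", "PRO": "CD", "TRP": "CD1", "TYR": "CD1",
}


def chi_angles(residue: Residue) -> tuple[float | None, float | None]:
    """(chi1, chi2) of a residue in degrees; ``None`` where undefined.

    chi2 is taken through the CD1 atom for Phe/Trp/Leu.  Residues without
    the required side-chain atoms (Gly, Ala, or incomplete side chains)
    return ``None`` for the affected angle.
    """
    gname = CHI_GAMMA_ATOM.get(residue.name)
    if gname is None:
        return (None, None)
    atoms = {a.name: a.coord for a in residue.atoms}
    chi1 = chi2 = None
    need1 = ("N", "CA", "CB", gname)
    if all(n in atoms for n in need1):
        chi1 = dihedral(*(atoms[n] for n in need1))
    else:
        missing = [n for n in need1 if n not in atoms]
        logger.debug("%s%d: chi1 undefined (missing %s)",
                     residue.name, residue.seq_id, missing)
    dname = CHI_DELTA_ATOM.get(residue.name)
    if dname is not None:
        need2 = ("CA", "CB", CHI_GAMMA_ATOM[residue.name], dname)
        if all(n in atoms for n in need2):
            chi2 = dihedral(*(atoms[n] for n in need2))
    return (chi1, chi2)


def phi_psi(prev: Residue | None, res: Residue, nxt: Residue | None
            ) -> tuple[float | None, float | None]:
    """Backbone (phi, psi) for a residue given its neighbours (or None)."""
    atoms = {a.name: a.coord for a in res.atoms}
    phi = psi = None
    if prev is not None:
        pa = {a.name: a.coord for a in prev.atoms}
        if "C" in pa and all(n in atoms for n in ("N", "CA", "C")):
            phi = dihedral(pa["C"], atoms["N"], atoms["CA"], atoms["C"])
    if nxt is not None:
        na = {a.name: a.coord for a in nxt.atoms}
        if "N" in na and all(n in atoms for n in ("N", "CA", "C")):
            psi = dihedral(atoms["N"], atoms["CA"], atoms["C"], na["N"])
    return (phi, psi)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray     # (3,3) proper rotation applied to mobile
    translation: np.ndarray  # (3,) applied after rotation
    rmsd: float              # Angstrom

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, ref: np.ndarray,
              weights: np.ndarray | None = None) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch, SVD form).

    Returns the proper rotation + translation minimising the (weighted) RMSD
    of ``mobile`` onto ``ref``; reflections are rejected by construction.
    """
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if mobile.shape != ref.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise SuperpositionError(
            f"point sets must both be (n,3); got {mobile.shape} vs {ref.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise SuperpositionError("need at least 3 points for a superposition")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise SuperpositionError("weights must be non-negative, length n")
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * ref).sum(axis=0)
    x = mobile - mc
    y = ref - rc
    h = (w[:, None] * x).T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    resid = x @ rot.T - y
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", resid, resid)).sum()))
    trans = rc - rot @ mc
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def backbone_rmsd_series(
    ensemble: Ensemble,
    ref_structure: Structure,
    seq_range: tuple[int, int],
    atoms: Sequence[str] = ("N", "CA", "C", "O"),
    chain_id: str | None = None,
) -> np.ndarray:
    """Per-frame minimised backbone RMSD (Angstrom) against a fixed reference.

    The reference is explicit (frame 0 of a trajectory, or a separately
    supplied helix structure).  Raises :class:`SuperpositionError` naming the
    residue on topology mismatch.
    """
    chains = [chain_id] if chain_id is not None else None
    ref_sel = select(ref_structure, chain_ids=chains, seq_range=seq_range,
                     atom_names=tuple(atoms))
    ref_xyz = ref_sel.coords()
    ref_sig = ref_sel.atom_signature()
    out = np.empty(len(ensemble))
    for i, frame in enumerate(ensemble):
        sel = select(frame, chain_ids=chains, seq_range=seq_range,
                     atom_names=tuple(atoms))
        if sel.atom_signature() != ref_sig:
            for (ra, sa) in zip(ref_sig, sel.atom_signature()):
                if ra != sa:
                    raise SuperpositionError(
                        f"frame {i}: topology mismatch at {sa} (reference {ra})")
            raise SuperpositionError(
                f"frame {i}: atom count {sel.n_atoms()} != reference {len(ref_sig)}")
        out[i] = superpose(sel.coords(), ref_xyz).rmsd
    return out
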