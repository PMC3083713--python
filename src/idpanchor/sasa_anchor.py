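"""Shrake-Rupley solvent-accessible surface area and anchor-residue calls.

Anchor residues of a peptide--protein complex are the residues that are
solvent-exposed in the unbound peptide but become essentially fully buried
(total SASA <= 15 A^2 by default) on binding.  The "unbound" reference can
be either the complexed conformation with the partner deleted, or the mean
over an unbound conformational ensemble.

The SASA engine is the classic Shrake-Rupley point-counting scheme with a
deterministic Fibonacci-lattice point set (no RNG), probe radius 1.4 A, and
NACCESS-style van der Waals radii (Chothia 1976 values with element
fallback).  Hydrogens are excluded by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structure_io import BACKBONE_ATOMS, Ensemble, Structure, select

logger = logging.getLogger(__name__)

DEFAULT_PROBE_RADIUS = 1.4   # A, water probe
DEFAULT_N_POINTS = 960
BURIED_THRESHOLD = 15.0      # A^2, "fully buried after binding"
EXPOSED_THRESHOLD = 30.0     # A^2, "exposed in the unbound state" (our default)


class RadiusLookupError(KeyError):
    """Raised when no van der Waals radius can be resolved for an atom."""


@dataclass(frozen=True)
class RadiiTable:
    """Van der Waals radii in Angstrom, resolved by element symbol.

    Default values follow the NACCESS convention (Chothia-type united-heavy-
    atom radii).  All entries must lie in (0.5, 3.0) A.
    """

    name: str = "chothia-naccess"
    by_element: dict = field(default_factory=lambda: dict(_CHOTHIA_ELEMENT))

    def __post_init__(self) -> None:
        for el, r in self.by_element.items():
            if not (0.5 < r < 3.0):
                raise ValueError(f"radius for {el!r} out of range: {r}")

    def radius(self, element: str, atom_name: str = "") -> float:
        el = element.strip().upper()
        if not el and atom_name:
            el = atom_name.strip()[0].upper()
        try:
            return self.by_element[el]
        except KeyError:
            raise RadiusLookupError(
                f"no van der Waals radius for element {element!r} (atom {atom_name!r})"
            ) from None


_CHOTHIA_ELEMENT = {
    "C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.80,
    "H": 1.00, "D": 1.00, "SE": 1.90,
}


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley_coords(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom SASA (A^2) for explicit coordinates and radii.

    Each atom's accessible sphere (radius r_i + probe) carries ``n_points``
    Fibonacci-lattice test points; a point is exposed when it lies outside
    every neighbouring atom's accessible sphere.  SASA_i = exposed fraction
    x 4 pi (r_i + probe)^2.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    if n_points < 60:
        raise ValueError("n_points must be >= 60 for a usable point density")
    n = coords.shape[0]
    if n == 0:
        return np.zeros(0)
    expanded = radii + probe_radius
    unit = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_exp = expanded.max()
    neighbor_lists = tree.query_ball_point(coords, expanded + max_exp)
    out = np.empty(n)
    for i in range(n):
        r_i = expanded[i]
        cand = np.asarray(neighbor_lists[i], dtype=int)
        cand = cand[cand != i]
        area = 4.0 * np.pi * r_i * r_i
        if cand.size:
            d = np.linalg.norm(coords[cand] - coords[i], axis=1)
            cand = cand[d < r_i + expanded[cand]]
        if not cand.size:
            out[i] = area
            continue
        pts = coords[i] + r_i * unit                     # (P,3)
        d2 = cdist(pts, coords[cand], "sqeuclidean")     # (P,M)
        exposed = np.all(d2 > expanded[cand] ** 2, axis=1)
        out[i] = area * exposed.mean()
    return out


def shrake_rupley(
    structure: Structure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    radii_table: RadiiTable | None = None,
    include_hydrogens: bool = False,
) -> np.ndarray:
    """Per-atom SASA of a Structure, in the order of ``structure.atoms()``."""
    table = radii_table or RadiiTable()
    pairs = structure.atoms(include_hydrogens=include_hydrogens)
    coords = np.array([a.coord for _, a in pairs]).reshape(-1, 3)
    radii = np.array([table.radius(a.element, a.name) for _, a in pairs])
    return shrake_rupley_coords(coords, radii, probe_radius, n_points)


@dataclass
class ResidueSASAProfile:
    """Per-residue SASA table.

    ``table`` is indexed by (chain_id, seq_id) with columns ``name``,
    ``sasa_total`` and ``sasa_side_chain`` (A^2).  For ensembles the
    per-frame totals are retained in ``per_frame`` (frames x residues) and
    ``table`` holds the mean with an extra ``sasa_sd`` column.
    """

    table: pd.DataFrame
    context: str = "bound"          # bound | unbound_from_complex | unbound_ensemble_mean
    per_frame: pd.DataFrame | None = None

    def total(self, chain_id: str, seq_id: int) -> float:
        return float(self.table.loc[(chain_id, seq_id), "sasa_total"])

    def residues(self) -> list[tuple[str, int]]:
        return list(self.table.index)


def _profile_from_structure(structure: Structure, context: str,
                            **sr_kwargs) -> ResidueSASAProfile:
    per_atom = shrake_rupley(structure, **sr_kwargs)
    include_h = sr_kwargs.get("include_hydrogens", False)
    rows: dict[tuple[str, int], dict] = {}
    for (res, atom), sasa in zip(structure.atoms(include_hydrogens=include_h), per_atom):
        row = rows.setdefault(res.key, {"name": res.name, "sasa_total": 0.0,
                                        "sasa_side_chain": 0.0})
        row["sasa_total"] += sasa
        if atom.name not in BACKBONE_ATOMS:
            row["sasa_side_chain"] += sasa
    idx = pd.MultiIndex.from_tuples(rows.keys(), names=["chain_id", "seq_id"])
    table = pd.DataFrame(list(rows.values()), index=idx)
    return ResidueSASAProfile(table=table, context=context)


def residue_sasa(structure: Structure, selection: dict | None = None,
                 **sr_kwargs) -> ResidueSASAProfile:
    """Per-residue SASA sums (total and side-chain) of a structure.

    ``selection`` (chain_ids/seq_range keys for :func:`select`) restricts the
    *reported* residues but the whole structure still occludes.
    """
    profile = _profile_from_structure(structure, context="bound", **sr_kwargs)
    if selection:
        keep = {r.key for r in select(structure, **selection).residues}
        if not keep:
            logger.warning("residue_sasa: empty selection, empty profile returned")
        profile.table = profile.table.loc[[k for k in profile.table.index if k in keep]]
    return profile


def unbound_sasa_from_complex(complex_structure: Structure,
                              peptide_selection: dict,
                              **sr_kwargs) -> ResidueSASAProfile:
    """SASA of the peptide alone, in its complexed conformation.

    Emulates deleting the binding partner from the complex and recomputing
    SASA of what remains.
    """
    peptide = select(complex_structure, **peptide_selection)
    if peptide.n_atoms() == 0:
        raise ValueError("peptide selection matched no atoms")
    if peptide.n_atoms() == complex_structure.n_atoms():
        logger.warning("peptide selection equals the whole complex; nothing removed")
    prof = _profile_from_structure(peptide, context="unbound_from_complex", **sr_kwargs)
    return prof


def ensemble_sasa(ensemble: Ensemble, selection: dict | None = None,
                  **sr_kwargs) -> ResidueSASAProfile:
    """Per-frame residue SASA of an unbound ensemble plus mean +/- sd."""
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    totals, side_chains = [], []
    table = None
    for frame in ensemble:
        st = select(frame, **selection) if selection else frame
        prof = _profile_from_structure(st, context="frame", **sr_kwargs)
        if table is None:
            table = prof.table.copy()
        totals.append(prof.table["sasa_total"])
        side_chains.append(prof.table["sasa_side_chain"])
    per_frame = pd.DataFrame(totals).reset_index(drop=True)
    table["sasa_total"] = per_frame.mean(axis=0)
    table["sasa_sd"] = per_frame.std(axis=0, ddof=0)
    table["sasa_side_chain"] = pd.DataFrame(side_chains).mean(axis=0)
    return ResidueSASAProfile(table=table, context="unbound_ensemble_mean",
                              per_frame=per_frame)


@dataclass
class AnchorReport:
    """Anchor classification result, sorted by delta-SASA descending."""

    table: pd.DataFrame          # per residue: sasa_bound, sasa_unbound, delta_sasa, is_anchor
    buried_threshold: float
    exposed_threshold: float
    mode: str = "total"          # total | side_chain

    @property
    def anchors(self) -> list[tuple[str, int]]:
        return list(self.table.index[self.table["is_anchor"]])

    def anchor_seq_ids(self) -> set[int]:
        return {seq_id for _, seq_id in self.anchors}


def classify_anchors(
    bound_profile: ResidueSASAProfile,
    unbound_profile: ResidueSASAProfile,
    buried_threshold: float = BURIED_THRESHOLD,
    exposed_threshold: float = EXPOSED_THRESHOLD,
    mode: str = "total",
) -> AnchorReport:
    """Two-sided anchor rule: buried in the complex, exposed when unbound.

    A residue is an anchor when its bound SASA <= ``buried_threshold`` AND
    its unbound SASA >= ``exposed_threshold``.  ``mode`` selects total
    residue SASA (default, matching per-residue profiles) or side-chain-only
    SASA.
    """
    col = "sasa_total" if mode == "total" else "sasa_side_chain"
    b = bound_profile.table[col]
    u = unbound_profile.table[col]
    if set(b.index) != set(u.index):
        only_b = set(b.index) - set(u.index)
        only_u = set(u.index) - set(b.index)
        raise ValueError(f"profiles cover different residues "
                         f"(bound-only={sorted(only_b)}, unbound-only={sorted(only_u)})")
    u = u.reindex(b.index)
    table = pd.DataFrame({
        "name": bound_profile.table["name"],
        "sasa_bound": b,
        "sasa_unbound": u,
        "delta_sasa": u - b,
        "is_anchor": (b <= buried_threshold) & (u >= exposed_threshold),
    })
    table = table.sort_values("delta_sasa", ascending=False)
    return AnchorReport(table=table, buried_threshold=buried_threshold,
                        exposed_threshold=exposed_threshold, mode=mode)
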