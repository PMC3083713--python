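"""Rotamer-region classification and bound-like population statistics.

Side-chain torsions (chi1, chi2) of each anchor residue are classified into
named angular regions (e.g. the three chi1 regions A/B/C of Phe19, or the
six chi1 x chi2 rectangles 1-6 of Trp23), and the fraction of ensemble
frames falling into each region - or matching a specific bound-state
reference conformation within a circular tolerance - is estimated with a
binomial sampling error.  Joint two-residue occupancy matrices, debounced
transition counting, and comparison against an empirical rotamer-library
reference complete the analysis.

Conventions
-----------
* All intervals are circular and half-open [lo, hi) in degrees; boundary
  frames go to the lower-labelled region (regions are tested in label
  order), making classification deterministic.
* Phe/Tyr chi2 is folded into [-90, +90) before any region or reference
  test (the aromatic ring is two-fold symmetric); Trp is never folded.
* Frames with undefined chi angles are excluded from every denominator;
  region fractions are reported over defined frames, so the disjoint-region
  partition plus "unassigned" sums to one exactly.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .geometry_core import chi_angles, circular_difference, wrap_angle
from .structure_io import Ensemble

#: residue types whose chi2 has two-fold ring symmetry
SYMMETRIC_CHI2 = {"PHE", "TYR"}

SUPPORTED_RESIDUES = {"PHE", "TRP", "LEU", "GLU", "LYS", "ASP", "ASN",
                      "SER", "THR", "PRO", "TYR", "MET", "GLN", "ARG",
                      "HIS", "ILE", "VAL", "CYS"}

DEFAULT_MATCH_TOLERANCE = 40.0  # deg per chi angle, circular


class UnsupportedResidueError(ValueError):
    pass


class RegionConfigError(ValueError):
    pass


class UndefinedPopulationError(ZeroDivisionError):
    pass


def fold_symmetric_chi2(chi2):
    """Map an aromatic-ring chi2 into [-90, +90) (180-degree periodicity)."""
    a = np.mod(np.asarray(chi2, dtype=float) + 90.0, 180.0) - 90.0
    return float(a) if np.ndim(chi2) == 0 else a


def _in_circular_interval(angle, lo: float, hi: float):
    """Membership in the circular half-open interval [lo, hi) degrees."""
    width = (hi - lo) % 360.0
    if width == 0.0:
        width = 360.0
    return np.mod(np.asarray(angle, dtype=float) - lo, 360.0) < width


@dataclass(frozen=True)
class StateRegion:
    """Named angular region in chi1 (1-D) or chi1 x chi2 (2-D) space."""

    label: str
    chi1: tuple[float, float]               # [lo, hi) circular, degrees
    chi2: tuple[float, float] | None = None

    def contains(self, chi1, chi2=None):
        m = _in_circular_interval(chi1, *self.chi1)
        if self.chi2 is not None:
            if chi2 is None:
                raise ValueError(f"region {self.label!r} needs chi2")
            m = m & _in_circular_interval(chi2, *self.chi2)
        return m


def _intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    wa = (a[1] - a[0]) % 360.0 or 360.0
    wb = (b[1] - b[0]) % 360.0 or 360.0
    d = (b[0] - a[0]) % 360.0
    return d < wa or (360.0 - d) % 360.0 < wb


@dataclass
class StateRegionSet:
    """Ordered, pairwise-disjoint regions for one residue."""

    residue_key: tuple[str, int]          # (chain_id, seq_id)
    regions: list[StateRegion]
    residue_name: str = ""

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise RegionConfigError(f"duplicate region labels: {labels}")
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1:]:
                if not _intervals_overlap(a.chi1, b.chi1):
                    continue
                if a.chi2 is None or b.chi2 is None:
                    raise RegionConfigError(
                        f"regions {a.label!r} and {b.label!r} overlap in chi1")
                if _intervals_overlap(a.chi2, b.chi2):
                    raise RegionConfigError(
                        f"regions {a.label!r} and {b.label!r} overlap")

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.regions]


@dataclass(frozen=True)
class BoundReference:
    """A bound-state (chi1, chi2) reference conformation for one residue."""

    residue_key: tuple[str, int]
    complex_label: str                    # e.g. "p53N-MDM2"
    chi1: float
    chi2: float | None
    tolerance: float = DEFAULT_MATCH_TOLERANCE
    role: str = "anchor-type"             # anchor-type | non-anchor

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("match tolerance must be positive")

    def matches(self, chi1, chi2=None):
        m = np.abs(circular_difference(chi1, self.chi1)) <= self.tolerance
        if self.chi2 is not None:
            if chi2 is None:
                return np.zeros_like(np.asarray(chi1, dtype=float), dtype=bool)
            m = m & (np.abs(circular_difference(chi2, self.chi2)) <= self.tolerance)
        return m


# ---------------------------------------------------------------------------
# chi-series extraction

def extract_chi_series(ensemble: Ensemble, chain_id: str, seq_id: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (chi1, chi2) arrays in degrees; NaN marks missing frames.

    Phe/Tyr chi2 is symmetry-folded into [-90, +90) here, before any
    downstream region or reference test.
    """
    res0 = ensemble[0].residue(chain_id, seq_id)
    if res0.name not in SUPPORTED_RESIDUES:
        raise UnsupportedResidueError(
            f"residue type {res0.name!r} has no chi-angle definition")
    n = len(ensemble)
    chi1 = np.full(n, np.nan)
    chi2 = np.full(n, np.nan)
    fold = res0.name in SYMMETRIC_CHI2
    for i, frame in enumerate(ensemble):
        c1, c2 = chi_angles(frame.residue(chain_id, seq_id))
        if c1 is not None:
            chi1[i] = c1
        if c2 is not None:
            chi2[i] = fold_symmetric_chi2(c2) if fold else c2
    return chi1, chi2


def classify_frames(chi1: np.ndarray, chi2: np.ndarray | None,
                    region_set: StateRegionSet) -> np.ndarray:
    """Per-frame region labels; "unassigned" when no region matches,
    "" (empty) when the chi angles are undefined for that frame."""
    chi1 = np.asarray(chi1, dtype=float)
    n = len(chi1)
    labels = np.full(n, "unassigned", dtype=object)
    defined = ~np.isnan(chi1)
    needs2 = any(r.chi2 is not None for r in region_set.regions)
    if needs2:
        if chi2 is None:
            raise ValueError("region set needs chi2 but none supplied")
        defined &= ~np.isnan(np.asarray(chi2, dtype=float))
    labels[~defined] = ""
    taken = np.zeros(n, dtype=bool)
    for region in region_set.regions:      # label order = tie priority
        m = region.contains(chi1, chi2) & defined & ~taken
        labels[m] = region.label
        taken |= m
    return labels


# ---------------------------------------------------------------------------
# populations

@dataclass
class PopulationEstimate:
    count: int
    n_defined: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.count / self.n_defined

    @property
    def se(self) -> float:
        p = self.fraction
        return float(np.sqrt(p * (1.0 - p) / self.n_defined))


def population(
    target: StateRegion | BoundReference | str,
    chi1: np.ndarray | None = None,
    chi2: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> PopulationEstimate:
    """Fraction of frames in a region (by ``labels``) or matching a
    :class:`BoundReference` (by chi series), with binomial standard error.

    The denominator is the number of frames with defined chi angles;
    unassigned-but-defined frames remain in it.
    """
    if isinstance(target, BoundReference):
        if chi1 is None:
            raise ValueError("bound-reference population needs chi series")
        chi1 = np.asarray(chi1, dtype=float)
        defined = ~np.isnan(chi1)
        if target.chi2 is not None and chi2 is not None:
            defined &= ~np.isnan(np.asarray(chi2, dtype=float))
        n_def = int(defined.sum())
        if n_def == 0:
            raise UndefinedPopulationError("no frames with defined chi angles")
        m = target.matches(chi1, chi2)
        count = int((m & defined).sum())
        return PopulationEstimate(count, n_def, len(chi1))
    label = target.label if isinstance(target, StateRegion) else str(target)
    if labels is None:
        raise ValueError("region population needs per-frame labels")
    labels = np.asarray(labels, dtype=object)
    defined = labels != ""
    n_def = int(defined.sum())
    if n_def == 0:
        raise UndefinedPopulationError("no frames with defined chi angles")
    count = int((labels == label).sum())
    return PopulationEstimate(count, n_def, len(labels))


def population_table(
    residue_key: tuple[str, int],
    state_name: str,
    labels: np.ndarray,
    region_set: StateRegionSet,
    bound_refs: Sequence[BoundReference] = (),
    chi1: np.ndarray | None = None,
    chi2: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tidy per-target population table for one residue in one ensemble state.

    Rows cover every region, "unassigned", and any bound references; columns
    are count / n_defined / n_total / fraction / se.
    """
    rows = []
    for target in [*region_set.labels, "unassigned"]:
        est = population(target, labels=labels)
        rows.append((state_name, *residue_key, f"region:{target}",
                     est.count, est.n_defined, est.n_total, est.fraction, est.se))
    for ref in bound_refs:
        est = population(ref, chi1=chi1, chi2=chi2)
        rows.append((state_name, *residue_key, f"bound:{ref.complex_label}",
                     est.count, est.n_defined, est.n_total, est.fraction, est.se))
    return pd.DataFrame(rows, columns=[
        "state", "chain_id", "seq_id", "target",
        "count", "n_defined", "n_total", "fraction", "se"])


def joint_population(labels_res1: np.ndarray, labels_res2: np.ndarray
                     ) -> pd.DataFrame:
    """Matrix of pair fractions over frames where both residues are defined.

    Rows are residue-1 labels, columns residue-2 labels; summing over one
    axis recovers the other residue's marginal populations exactly.
    """
    a = np.asarray(labels_res1, dtype=object)
    b = np.asarray(labels_res2, dtype=object)
    if len(a) != len(b):
        raise ValueError(f"label series lengths differ: {len(a)} vs {len(b)}")
    ok = (a != "") & (b != "")
    n = int(ok.sum())
    if n == 0:
        raise UndefinedPopulationError("no jointly defined frames")
    a, b = a[ok], b[ok]
    la = sorted(set(a), key=str)
    lb = sorted(set(b), key=str)
    mat = pd.DataFrame(0.0, index=la, columns=lb)
    for x, y in zip(a, b):
        mat.loc[x, y] += 1.0
    return mat / n


def count_transitions(labels: Sequence, min_dwell_frames: int = 1) -> int:
    """Number of state changes after suppressing runs shorter than
    ``min_dwell_frames`` (debouncing).

    With ``min_dwell_frames`` = 1 this is the raw change count.  Runs
    shorter than the dwell are dropped; surviving consecutive runs of equal
    label merge before counting.
    """
    labs = [l for l in labels]
    if not labs:
        return 0
    if min_dwell_frames < 1:
        raise ValueError("min_dwell_frames must be >= 1")
    runs: list[tuple[object, int]] = []
    for l in labs:
        if runs and runs[-1][0] == l:
            runs[-1] = (l, runs[-1][1] + 1)
        else:
            runs.append((l, 1))
    kept = [lab for lab, length in runs if length >= min_dwell_frames]
    merged = [kept[0]] if kept else []
    for lab in kept[1:]:
        if lab != merged[-1]:
            merged.append(lab)
    return max(0, len(merged) - 1)


# ---------------------------------------------------------------------------
# rotamer-library comparison

def load_rotamer_library(path: str | Path | None = None) -> pd.DataFrame:
    """Packaged empirical rotamer-library populations for the p53 anchors.

    Columns: residue label, complex, library population (%) of the bound
    conformation in that complex, and a qualifier ("<" for upper bounds).
    """
    if path is None:
        ref = importlib.resources.files("idpanchor.data") / "rotamer_library_p53n.tsv"
        with importlib.resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t", comment="#")
    return pd.read_csv(path, sep="\t", comment="#")


def compare_with_library(
    populations: Mapping[tuple[str, str], float],
    library: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Side-by-side ensemble vs library populations, flagging reversals.

    ``populations`` maps (residue label, complex label) -> ensemble fraction
    (0-1).  For each residue present with both complexes, the preference
    ordering in the ensemble is compared with the library's; ``reversed``
    is True when the two disagree on which bound conformation is preferred.
    """
    lib = library if library is not None else load_rotamer_library()
    rows = []
    for (residue, complex_label), frac in populations.items():
        hit = lib[(lib["residue"] == residue) & (lib["complex"] == complex_label)]
        if hit.empty:
            raise KeyError(f"no library entry for {residue!r} in {complex_label!r}")
        rows.append({
            "residue": residue,
            "complex": complex_label,
            "ensemble_pct": 100.0 * frac,
            "library_pct": float(hit["library_pct"].iloc[0]),
            "qualifier": str(hit["qualifier"].iloc[0]) if "qualifier" in hit else "",
        })
    out = pd.DataFrame(rows)
    out["reversed"] = False
    for residue in out["residue"].unique():
        sub = out[out["residue"] == residue]
        if len(sub) == 2:
            ens_pref = sub.sort_values("ensemble_pct")["complex"].iloc[-1]
            lib_pref = sub.sort_values("library_pct")["complex"].iloc[-1]
            out.loc[out["residue"] == residue, "reversed"] = ens_pref != lib_pref
    return out


# ---------------------------------------------------------------------------
# config loading

def load_region_config(path: str | Path | None = None
                       ) -> tuple[dict[int, StateRegionSet], list[BoundReference]]:
    """Load region sets and bound references from the YAML config.

    Without a path, the packaged defaults for the p53 segment are used (the
    region bounds there are documented estimates, not printed values).
    """
    if path is None:
        ref = importlib.resources.files("idpanchor.data") / "p53n_regions.yaml"
        with importlib.resources.as_file(ref) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    chain = raw.get("chain_id", "A")
    region_sets: dict[int, StateRegionSet] = {}
    for entry in raw.get("region_sets", []):
        seq_id = int(entry["seq_id"])
        regions = []
        for r in entry["regions"]:
            chi2 = tuple(r["chi2"]) if "chi2" in r else None
            regions.append(StateRegion(str(r["label"]), tuple(r["chi1"]), chi2))
        region_sets[seq_id] = StateRegionSet(
            residue_key=(chain, seq_id), regions=regions,
            residue_name=entry.get("residue", ""))
    refs: list[BoundReference] = []
    tol = float(raw.get("match_tolerance", DEFAULT_MATCH_TOLERANCE))
    for entry in raw.get("bound_references", []):
        refs.append(BoundReference(
            residue_key=(chain, int(entry["seq_id"])),
            complex_label=str(entry["complex"]),
            chi1=float(entry["chi1"]),
            chi2=float(entry["chi2"]) if entry.get("chi2") is not None else None,
            tolerance=float(entry.get("tolerance", tol)),
            role=str(entry.get("role", "anchor-type")),
        ))
    return region_sets, refs
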