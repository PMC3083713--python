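"""Helix assignment, helix/disordered state partitioning, and unfolding times.

The transient helix of the p53 N-terminal segment (formed over roughly
Thr18-Leu26) is only metastable in isolation: trajectories started from a
bound helical pose relax within the helix basin and later unfold to the
disordered state.  This module assigns per-residue helicity with a
simplified two-criterion rule, detects the unfolding time of a trajectory
from a sustained loss of helix content together with a backbone-RMSD
excursion, partitions frames into helix-state and disordered-state sets,
and summarises unfolding times over trajectory groups.

Helix criterion (a deliberate simplification of a full hydrogen-bond-energy
secondary-structure assignment): a residue is helical when EITHER
(a) its (phi, psi) lies in the alpha basin box (phi in [-100, -30],
    psi in [-80, -5] degrees) as part of a run of >= 4 consecutive
    in-basin residues, OR
(b) it participates in an O(i)->N(i+4) contact shorter than 3.5 A
    (hydrogen-bond proxy; residues i..i+4 are marked helical).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry_core import backbone_rmsd_series, phi_psi
from .structure_io import Ensemble, Structure

ALPHA_PHI_RANGE = (-100.0, -30.0)
ALPHA_PSI_RANGE = (-80.0, -5.0)
HBOND_ON_DISTANCE = 3.5     # A, O(i)->N(i+4) proxy
MIN_HELIX_RUN = 4

DEFAULT_HELIX_WINDOW = (19, 26)       # Phe19-Leu26 (RMSD window)
ALT_HELIX_WINDOW = (18, 26)           # Thr18-Leu26 (text window)

DEFAULT_RMSD_THRESHOLD = 2.5          # A over the helix-window backbone
DEFAULT_HELIX_FRACTION_THRESHOLD = 0.25
DEFAULT_DWELL_FRAMES = 10
DEFAULT_EQUILIBRATION_NS = 1.0


class WindowError(ValueError):
    pass


class PartitionError(ValueError):
    pass


class SummaryError(ValueError):
    pass


@dataclass
class HelixAssignment:
    """Per-frame, per-residue helix flags plus per-frame helix fraction."""

    flags: pd.DataFrame          # frames x seq_id booleans (window residues)
    window: tuple[int, int]

    @property
    def helix_fraction(self) -> np.ndarray:
        return self.flags.mean(axis=1).to_numpy()


def _assign_structure(structure: Structure, window: tuple[int, int],
                      chain_id: str | None) -> pd.Series:
    chain = chain_id or structure.chain_ids[0]
    residues = [r for r in structure.chain(chain)]
    seq_ids = [r.seq_id for r in residues]
    lo, hi = window
    if sum(1 for s in seq_ids if lo <= s <= hi) < MIN_HELIX_RUN:
        raise WindowError(f"window {window} spans fewer than {MIN_HELIX_RUN} residues")
    n = len(residues)
    in_basin = np.zeros(n, dtype=bool)
    for i, res in enumerate(residues):
        prev = residues[i - 1] if i > 0 else None
        nxt = residues[i + 1] if i < n - 1 else None
        phi, psi = phi_psi(prev, res, nxt)
        if phi is None or psi is None:
            continue
        in_basin[i] = (ALPHA_PHI_RANGE[0] <= phi <= ALPHA_PHI_RANGE[1]
                       and ALPHA_PSI_RANGE[0] <= psi <= ALPHA_PSI_RANGE[1])
    helical = np.zeros(n, dtype=bool)
    # (a) >= 4 consecutive residues in the alpha basin
    run_start = None
    for i in range(n + 1):
        if i < n and in_basin[i]:
            run_start = i if run_start is None else run_start
        else:
            if run_start is not None and i - run_start >= MIN_HELIX_RUN:
                helical[run_start:i] = True
            run_start = None
    # (b) O(i) -> N(i+4) hydrogen-bond proxy
    for i in range(n - 4):
        o = residues[i].get("O")
        nn = residues[i + 4].get("N")
        if o is None or nn is None:
            continue
        if np.linalg.norm(o.coord - nn.coord) < HBOND_ON_DISTANCE:
            helical[i:i + 5] = True
    data = {s: helical[i] for i, s in enumerate(seq_ids) if lo <= s <= hi}
    return pd.Series(data)


def assign_helix(obj: Structure | Ensemble,
                 window: tuple[int, int] = DEFAULT_HELIX_WINDOW,
                 chain_id: str | None = None) -> HelixAssignment:
    """Helix flags over the stated residue window for a structure or ensemble."""
    frames = obj.frames if isinstance(obj, Ensemble) else [obj]
    rows = [_assign_structure(f, window, chain_id) for f in frames]
    return HelixAssignment(flags=pd.DataFrame(rows).reset_index(drop=True),
                           window=window)


@dataclass
class UnfoldingResult:
    """Unfolding time of one trajectory, with the criteria that produced it."""

    label: str
    unfolding_time_ns: float | None       # None = never unfolded
    unfolding_frame: int | None
    criteria: dict = field(default_factory=dict)
    rmsd_series: np.ndarray | None = None
    helix_fraction_series: np.ndarray | None = None

    @property
    def unfolded(self) -> bool:
        return self.unfolding_frame is not None


def detect_unfolding(
    ensemble: Ensemble,
    ref_helix: Structure,
    rmsd_threshold: float = DEFAULT_RMSD_THRESHOLD,
    helix_fraction_threshold: float = DEFAULT_HELIX_FRACTION_THRESHOLD,
    dwell: int = DEFAULT_DWELL_FRAMES,
    window: tuple[int, int] = DEFAULT_HELIX_WINDOW,
    chain_id: str | None = None,
) -> UnfoldingResult:
    """First sustained loss of the helix.

    The unfolding frame is the first frame of the first run of >= ``dwell``
    consecutive frames in which the backbone RMSD over the helix window
    exceeds ``rmsd_threshold`` AND the helix fraction is below
    ``helix_fraction_threshold``.  Shorter excursions are ignored.
    """
    if rmsd_threshold <= 0 or helix_fraction_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if dwell < 1:
        raise ValueError("dwell must be >= 1 frame")
    rmsd = backbone_rmsd_series(ensemble, ref_helix, window, chain_id=chain_id)
    frac = assign_helix(ensemble, window, chain_id).helix_fraction
    unfolded = (rmsd > rmsd_threshold) & (frac < helix_fraction_threshold)
    criteria = {
        "rmsd_threshold_A": rmsd_threshold,
        "helix_fraction_threshold": helix_fraction_threshold,
        "dwell_frames": dwell,
        "window": window,
    }
    frame = _first_sustained(unfolded, dwell)
    time_ns = None
    if frame is not None and ensemble.dt is not None:
        time_ns = frame * ensemble.dt
    return UnfoldingResult(label=ensemble.label, unfolding_time_ns=time_ns,
                           unfolding_frame=frame, criteria=criteria,
                           rmsd_series=rmsd, helix_fraction_series=frac)


def _first_sustained(flags: np.ndarray, dwell: int) -> int | None:
    run = 0
    for i, f in enumerate(flags):
        run = run + 1 if f else 0
        if run >= dwell:
            return i - dwell + 1
    return None


def partition_states(
    ensemble: Ensemble,
    unfolding_result: UnfoldingResult | None = None,
    whole_trajectory_state: str | None = None,
    equilibration_ns: float = DEFAULT_EQUILIBRATION_NS,
    margin_frames: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split frame indices into (helix-state, disordered-state).

    Helix-state frames run from the end of the equilibration prefix to the
    unfolding frame; disordered-state frames start ``margin_frames`` after
    it.  A trajectory that never unfolds is all helix; a trajectory labelled
    ``whole_trajectory_state`` ("helix" or "disordered") bypasses detection.
    """
    n = len(ensemble)
    if whole_trajectory_state is not None:
        idx = np.arange(n)
        if whole_trajectory_state == "helix":
            return idx, np.array([], dtype=int)
        if whole_trajectory_state == "disordered":
            return np.array([], dtype=int), idx
        raise PartitionError(f"unknown state label {whole_trajectory_state!r}")
    if unfolding_result is None:
        raise PartitionError("need an UnfoldingResult or a whole-trajectory label")
    skip = 0
    if ensemble.dt is not None and equilibration_ns > 0:
        skip = int(round(equilibration_ns / ensemble.dt))
    if unfolding_result.unfolding_frame is None:
        return np.arange(skip, n), np.array([], dtype=int)
    uf = unfolding_result.unfolding_frame
    helix_idx = np.arange(min(skip, uf), uf)
    dis_idx = np.arange(min(uf + margin_frames, n), n)
    return helix_idx, dis_idx


def summarize_unfolding(results, group_of=None) -> pd.DataFrame:
    """Mean +/- sample sd of unfolding times per trajectory group.

    ``results`` is an iterable of :class:`UnfoldingResult` or a DataFrame
    with ``group`` and ``unfolding_time_ns`` columns (NaN = not unfolded).
    Not-unfolded trajectories are excluded from the statistics but counted.
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        rows = []
        for r in results:
            grp = group_of(r) if group_of else (r.label or "all")
            rows.append({"group": grp, "unfolding_time_ns": (
                np.nan if r.unfolding_time_ns is None else r.unfolding_time_ns)})
        df = pd.DataFrame(rows)
    if df["unfolding_time_ns"].notna().sum() == 0:
        raise SummaryError("no trajectory has a defined unfolding time")
    out = []
    for grp, sub in df.groupby("group"):
        times = sub["unfolding_time_ns"].dropna()
        if len(times) == 0:
            out.append({"group": grp, "n_unfolded": 0,
                        "n_not_unfolded": len(sub),
                        "mean_ns": np.nan, "sd_ns": np.nan})
            continue
        out.append({
            "group": grp,
            "n_unfolded": int(len(times)),
            "n_not_unfolded": int(len(sub) - len(times)),
            "mean_ns": float(times.mean()),
            "sd_ns": float(times.std(ddof=1)) if len(times) > 1 else 0.0,
        })
    return pd.DataFrame(out).set_index("group")


def load_reference_unfolding_times(path: str | Path | None = None) -> pd.DataFrame:
    """Packaged unfolding-time table of the published simulation set."""
    if path is None:
        ref = importlib.resources.files("idpanchor.data") / "unfolding_times.tsv"
        with importlib.resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t", comment="#")
    return pd.read_csv(path, sep="\t", comment="#")
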