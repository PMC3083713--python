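"""Synthetic peptide ensembles with known ground truth.

The analyses in this package were designed for molecular-dynamics ensembles
of the disordered p53 transactivation segment (Glu17-Asn29, sequence
ETFSDLWKLLPEN).  Real MD is out of scope here; instead this module builds
geometry-only ensembles in which every quantity the analysis stages measure
(backbone state, per-residue rotamer state, exact chi angles, switch frames)
is known by construction:

* an internal-coordinate (NeRF) peptide builder with ideal bond lengths and
  angles that reproduces requested phi/psi/chi torsions exactly;
* a two-state (helix/coil) backbone switching schedule with geometric dwell
  times, and per-residue rotamer-state Markov sampling with target
  stationary populations, optional two-residue joint coupling, angular
  jitter around state centres, and optional Gaussian coordinate noise;
* a rigid "cage" receptor that occludes chosen peptide residues, the
  fixture for anchor-residue classification.

No energies, sterics or solvent are modelled: the emitted coordinates are
geometrically valid but not physically relaxed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .structure_io import Atom, Ensemble, Residue, Structure

P53N_SEQUENCE = "ETFSDLWKLLPEN"   # Glu17..Asn29
P53N_START = 17

AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-120.0, 120.0)

# backbone ideal internal coordinates (lengths A, angles deg)
_B = {
    "N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.530,
    "ang_N-CA-C": 111.2, "ang_CA-C-N": 116.2, "ang_C-N-CA": 121.7,
    "ang_CA-C-O": 120.8, "ang_N-CA-CB": 110.4, "omega": 180.0,
    # improper torsion C-N-CA-CB fixing L-chirality (sign checked in tests)
    "tor_C-N-CA-CB": -122.6,
}


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D so that |CD|=bond, angle(B,C,D)=angle, tors(A,B,C,D)=torsion."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# side-chain templates
#
# Each entry: (atom_name, (ref1, ref2, ref3), bond, angle, torsion) where the
# torsion is a float (fixed) or ("chi1"|"chi2", offset).  Reference atoms are
# names already placed within the residue.  Geometry is idealised; rings are
# approximately planar/closed, which is irrelevant to torsion readback.

def _chi(which: str, offset: float = 0.0):
    return (which, offset)


SIDE_CHAIN_TEMPLATES: dict[str, list[tuple]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.42, 110.8, _chi("chi1"))],
    "THR": [
        ("OG1", ("N", "CA", "CB"), 1.43, 109.5, _chi("chi1")),
        ("CG2", ("N", "CA", "CB"), 1.52, 110.5, _chi("chi1", -120.0)),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.52, 113.1, _chi("chi1")),
        ("OD1", ("CA", "CB", "CG"), 1.25, 118.4, _chi("chi2")),
        ("OD2", ("CA", "CB", "CG"), 1.25, 118.4, _chi("chi2", 180.0)),
    ],
    "ASN": [
        ("CG", ("N", "CA", "CB"), 1.52, 112.6, _chi("chi1")),
        ("OD1", ("CA", "CB", "CG"), 1.23, 120.8, _chi("chi2")),
        ("ND2", ("CA", "CB", "CG"), 1.33, 116.4, _chi("chi2", 180.0)),
    ],
    "GLU": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, _chi("chi1")),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, _chi("chi2")),
        ("OE1", ("CB", "CG", "CD"), 1.25, 118.3, 0.0),
        ("OE2", ("CB", "CG", "CD"), 1.25, 118.3, 180.0),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, _chi("chi1")),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, _chi("chi2")),
        ("CE", ("CB", "CG", "CD"), 1.52, 111.3, 180.0),
        ("NZ", ("CG", "CD", "CE"), 1.49, 111.9, 180.0),
    ],
    "LEU": [
        ("CG", ("N", "CA", "CB"), 1.53, 116.3, _chi("chi1")),
        ("CD1", ("CA", "CB", "CG"), 1.52, 110.7, _chi("chi2")),
        ("CD2", ("CA", "CB", "CG"), 1.52, 110.7, _chi("chi2", 122.0)),
    ],
    "PHE": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, _chi("chi1")),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, _chi("chi2")),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, _chi("chi2", 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.8, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.8, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ],
    "TRP": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.6, _chi("chi1")),
        ("CD1", ("CA", "CB", "CG"), 1.37, 126.9, _chi("chi2")),
        ("CD2", ("CA", "CB", "CG"), 1.43, 126.8, _chi("chi2", 180.0)),
        ("NE1", ("CB", "CG", "CD1"), 1.38, 110.2, 180.0),
        ("CE2", ("CD1", "CG", "CD2"), 1.41, 107.2, 0.0),
        ("CE3", ("CD1", "CG", "CD2"), 1.40, 133.9, 180.0),
        ("CZ2", ("CG", "CD2", "CE2"), 1.40, 122.4, 180.0),
        ("CZ3", ("CG", "CD2", "CE3"), 1.39, 118.6, 180.0),
        ("CH2", ("CD2", "CE2", "CZ2"), 1.37, 117.5, 0.0),
    ],
    "PRO": [
        ("CG", ("N", "CA", "CB"), 1.50, 104.5, _chi("chi1")),
        ("CD", ("CA", "CB", "CG"), 1.51, 106.1, _chi("chi2")),
    ],
}

#: residues with no chi1 at all
NO_CHI = {"ALA", "GLY"}

#: fallback chi values used when the caller does not assign them
DEFAULT_CHI = {"chi1": -65.0, "chi2": 180.0}
DEFAULT_CHI_PRO = {"chi1": -25.0, "chi2": 37.0}


class SequenceError(ValueError):
    pass


def build_peptide(
    sequence: str = P53N_SEQUENCE,
    backbone: str | Sequence[tuple[float, float]] = "helix",
    chi_assignments: Mapping[int, Mapping[str, float]] | None = None,
    start_seq_id: int = P53N_START,
    chain_id: str = "A",
) -> Structure:
    """Build a peptide with exact requested torsions from ideal geometry.

    ``backbone`` is "helix" (phi=-57, psi=-47), "extended" (-120, +120) or an
    explicit per-residue (phi, psi) list.  ``chi_assignments`` maps author
    seq_id -> {"chi1": deg, "chi2": deg}; unassigned torsions fall back to a
    common rotamer.  Heavy atoms only.
    """
    sequence = sequence.strip().upper()
    for letter in sequence:
        if letter not in AA3:
            raise SequenceError(f"unknown residue letter {letter!r}")
    n_res = len(sequence)
    if isinstance(backbone, str):
        if backbone == "helix":
            phipsi = [HELIX_PHI_PSI] * n_res
        elif backbone == "extended":
            phipsi = [EXTENDED_PHI_PSI] * n_res
        else:
            raise ValueError(f"backbone must be 'helix', 'extended' or a list, got {backbone!r}")
    else:
        phipsi = [tuple(map(float, pp)) for pp in backbone]
        if len(phipsi) != n_res:
            raise ValueError("backbone list length must equal sequence length")
    chi_assignments = chi_assignments or {}

    # backbone trace
    bb: list[dict[str, np.ndarray]] = []
    for i in range(n_res):
        phi_i = phipsi[i][0]
        if i == 0:
            n_pos = np.zeros(3)
            ca = np.array([_B["N-CA"], 0.0, 0.0])
            ang = np.radians(_B["ang_N-CA-C"])
            c = ca + _B["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            prev = bb[i - 1]
            psi_prev = phipsi[i - 1][1]
            n_pos = nerf(prev["N"], prev["CA"], prev["C"],
                         _B["C-N"], _B["ang_CA-C-N"], psi_prev)
            ca = nerf(prev["CA"], prev["C"], n_pos,
                      _B["N-CA"], _B["ang_C-N-CA"], _B["omega"])
            c = nerf(prev["C"], n_pos, ca,
                     _B["CA-C"], _B["ang_N-CA-C"], phi_i)
        bb.append({"N": n_pos, "CA": ca, "C": c})
    # carbonyl O uses psi(i) + 180 (anti to the next N)
    for i in range(n_res):
        psi_i = phipsi[i][1]
        bb[i]["O"] = nerf(bb[i]["N"], bb[i]["CA"], bb[i]["C"],
                          _B["C-O"], _B["ang_CA-C-O"], psi_i + 180.0)

    element_of = lambda name: "O" if name.startswith("O") else (
        "N" if name.startswith("N") else ("S" if name.startswith("S") else "C"))

    residues: list[Residue] = []
    for i, letter in enumerate(sequence):
        res3 = AA3[letter]
        seq_id = start_seq_id + i
        placed: dict[str, np.ndarray] = dict(bb[i])
        order = ["N", "CA", "C", "O"]
        if res3 not in ("GLY",):
            placed["CB"] = nerf(bb[i]["C"], bb[i]["N"], bb[i]["CA"],
                                _B["CA-CB"], _B["ang_N-CA-CB"], _B["tor_C-N-CA-CB"])
            order.append("CB")
        defaults = DEFAULT_CHI_PRO if res3 == "PRO" else DEFAULT_CHI
        chi = dict(defaults)
        chi.update({k: float(v) for k, v in chi_assignments.get(seq_id, {}).items()
                    if v is not None})
        for (aname, refs, bond, angle, torsion) in SIDE_CHAIN_TEMPLATES.get(res3, []):
            if isinstance(torsion, tuple):
                tor = chi[torsion[0]] + torsion[1]
            else:
                tor = torsion
            placed[aname] = nerf(placed[refs[0]], placed[refs[1]], placed[refs[2]],
                                 bond, angle, tor)
            order.append(aname)
        atoms = [Atom(name=a, element=element_of(a), coord=placed[a]) for a in order]
        residues.append(Residue(name=res3, seq_id=seq_id, chain_id=chain_id,
                                atoms=atoms))
    return Structure(residues=residues)


# ---------------------------------------------------------------------------
# ensembles

#: default rotamer-state centres (chi1, chi2) for the p53 segment anchors;
#: labels follow the region naming used by the analysis config.  "A"/"1"
#: are the MDM2-bound-like states, the Taz2-bound-like states are "B"/"3"
#: (Phe19/Trp23) and "mt" (Leu22).  Centres are representative rotamers;
#: only Phe19's (177, 71) comes from a printed bound-pose value.
DEFAULT_ROTAMER_STATES: dict[int, dict[str, tuple[float, float]]] = {
    19: {"A": (177.0, 71.0), "B": (-65.0, -30.0), "B2": (-65.0, 60.0),
         "C": (62.0, 80.0)},                                            # Phe
    22: {"mt": (-65.0, 175.0), "tp": (177.0, 65.0)},                    # Leu
    23: {"1": (180.0, 90.0), "2": (180.0, -90.0), "3": (-60.0, 90.0),
         "4": (-60.0, -90.0), "5": (60.0, 90.0), "6": (60.0, -90.0)},   # Trp
    26: {"mt": (-65.0, 175.0), "tp": (177.0, 65.0)},                    # Leu
}

#: study-condition rotamer-state populations for the p53-segment anchors in
#: the helix and disordered backbone states.  The bound-like entries (Phe19
#: "A"/"B", Trp23 "1", Leu22 "mt" Taz2-type / "tp" MDM2-type, Leu26 "mt")
#: carry the published ensemble populations; the remaining mass is spread
#: over decoy states as a fixed modelling choice.
HELIX_STATE_TARGETS: dict[int, dict[str, float]] = {
    19: {"A": 0.595, "B": 0.122, "B2": 0.183, "C": 0.100},
    22: {"mt": 0.818, "tp": 0.182},
    23: {"1": 0.624, "2": 0.100, "3": 0.050, "4": 0.076, "5": 0.080, "6": 0.070},
    26: {"mt": 0.827, "tp": 0.173},
}
DISORDERED_STATE_TARGETS: dict[int, dict[str, float]] = {
    19: {"A": 0.192, "B": 0.060, "B2": 0.448, "C": 0.300},
    22: {"mt": 0.671, "tp": 0.329},
    23: {"1": 0.187, "2": 0.200, "3": 0.050, "4": 0.200, "5": 0.200, "6": 0.163},
    26: {"mt": 0.762, "tp": 0.238},
}
TABLE_STATE_TARGETS = {
    seq_id: {"helix": HELIX_STATE_TARGETS[seq_id],
             "coil": DISORDERED_STATE_TARGETS[seq_id]}
    for seq_id in HELIX_STATE_TARGETS
}


@dataclass
class GeneratorSpec:
    """Study conditions for a synthetic ensemble.

    Rotamer targets map author seq_id -> {state label -> probability}; the
    remainder (1 - sum) is sampled uniformly at random over the full torsion
    circle ("free" label).  Probabilities may instead be given per backbone
    state: {"helix": {...}, "coil": {...}}.
    """

    sequence: str = P53N_SEQUENCE
    start_seq_id: int = P53N_START
    chain_id: str = "A"
    n_frames: int = 2000
    dt: float = 0.005                      # ns per frame (5 ps save interval)
    backbone: str | Sequence[str] = "helix"   # "helix", "coil", per-frame labels
    backbone_mean_dwell: float | None = None  # frames; geometric switching if set
    rotamer_states: Mapping[int, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ROTAMER_STATES.items()})
    rotamer_targets: Mapping[int, Mapping] = field(default_factory=dict)
    rotamer_mean_dwell: Mapping[int, float] = field(default_factory=dict)  # frames
    joint_targets: Mapping[tuple[int, int], Mapping[tuple[str, str], float]] = field(
        default_factory=dict)
    chi_jitter: float = 10.0               # deg, uniform half-width around centres
    backbone_jitter: float = 8.0           # deg, uniform half-width in the helix basin
    noise_sigma: float = 0.0               # A, Gaussian coordinate noise
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for seq_id, targets in self.rotamer_targets.items():
            per_state = targets if _is_per_backbone(targets) else {"*": targets}
            for probs in per_state.values():
                total = sum(probs.values())
                if total > 1.0 + 1e-9:
                    raise ValueError(
                        f"rotamer targets for residue {seq_id} sum to {total} > 1")
                for lbl in probs:
                    if lbl not in self.rotamer_states.get(seq_id, {}):
                        raise ValueError(
                            f"residue {seq_id}: no state centre for label {lbl!r}")


def _is_per_backbone(targets: Mapping) -> bool:
    return set(targets.keys()) <= {"helix", "coil"} and all(
        isinstance(v, Mapping) for v in targets.values())


@dataclass
class GroundTruth:
    """Exact construction record for a generated ensemble."""

    backbone_states: list[str]
    switch_frames: list[int]
    rotamer_labels: dict[int, list[str]]      # seq_id -> per-frame labels
    chi_values: dict[int, np.ndarray]         # seq_id -> (n_frames, 2), NaN if absent
    phi_psi: np.ndarray                       # (n_frames, n_res, 2)
    rng_algorithm: str = "numpy.random.Generator(PCG64)"

    def to_frame(self) -> pd.DataFrame:
        data = {"frame": np.arange(len(self.backbone_states)),
                "backbone_state": self.backbone_states}
        for seq_id in sorted(self.rotamer_labels):
            data[f"state_{seq_id}"] = self.rotamer_labels[seq_id]
            data[f"chi1_{seq_id}"] = self.chi_values[seq_id][:, 0]
            data[f"chi2_{seq_id}"] = self.chi_values[seq_id][:, 1]
        return pd.DataFrame(data)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def two_state_schedule(n_frames: int, mean_dwell: float, rng: np.random.Generator,
                       initial: str = "helix") -> list[str]:
    """Alternating helix/coil labels with geometric dwell times."""
    if mean_dwell < 1:
        raise ValueError("mean_dwell must be >= 1 frame")
    p_switch = 1.0 / mean_dwell
    states = []
    current = initial
    for _ in range(n_frames):
        states.append(current)
        if rng.random() < p_switch:
            current = "coil" if current == "helix" else "helix"
    return states


def sample_state_labels(
    probs: Mapping[str, float],
    n_frames: int,
    rng: np.random.Generator,
    mean_dwell: float = 1.0,
) -> list[str]:
    """Per-frame state labels with stationary distribution ``probs``.

    Residual probability mass (1 - sum) goes to the "free" label.  With
    ``mean_dwell`` > 1 the chain resamples from the stationary distribution
    with probability 1/mean_dwell per frame (sticky Markov chain whose
    stationary law is exactly ``probs``).
    """
    labels = list(probs.keys())
    p = np.array([probs[l] for l in labels], dtype=float)
    rest = 1.0 - p.sum()
    if rest < -1e-9:
        raise ValueError(f"state probabilities sum to {p.sum()} > 1")
    if rest > 1e-12:
        labels.append("free")
        p = np.append(p, rest)
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    if mean_dwell <= 1.0:
        idx = rng.choice(len(labels), size=n_frames, p=p)
        return [labels[i] for i in idx]
    out = []
    current = labels[rng.choice(len(labels), p=p)]
    for _ in range(n_frames):
        out.append(current)
        if rng.random() < 1.0 / mean_dwell:
            current = labels[rng.choice(len(labels), p=p)]
    return out


def joint_from_marginals(
    p1: Mapping[str, float], p2: Mapping[str, float],
    forced: Mapping[tuple[str, str], float],
) -> dict[tuple[str, str], float]:
    """Joint label distribution with given cells forced to target mass.

    Starts from the independent product of the marginals, pins the ``forced``
    cells, and rescales the remaining cells to unit total.  The marginals of
    the result are close to, but not exactly, the inputs; this is a synthetic
    coupling device, not an exact IPF fit.
    """
    joint = {(a, b): pa * pb for a, pa in p1.items() for b, pb in p2.items()}
    free_mass = 1.0 - sum(joint.values())
    if free_mass > 1e-12:
        joint[("free", "free")] = free_mass
    forced_total = sum(forced.values())
    if forced_total > 1.0 + 1e-9:
        raise ValueError("forced joint mass exceeds 1")
    other = {k: v for k, v in joint.items() if k not in forced}
    scale = (1.0 - forced_total) / sum(other.values())
    out = {k: v * scale for k, v in other.items()}
    out.update({k: float(v) for k, v in forced.items()})
    return out


def _resolve_targets(targets: Mapping, backbone_state: str) -> Mapping[str, float]:
    if _is_per_backbone(targets):
        return targets.get(backbone_state, {})
    return targets


def sample_ensemble(spec: GeneratorSpec) -> tuple[Ensemble, GroundTruth]:
    """Draw an ensemble per the spec; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    n_res = len(spec.sequence)
    seq_ids = [spec.start_seq_id + i for i in range(n_res)]

    # backbone schedule
    if isinstance(spec.backbone, str):
        if spec.backbone_mean_dwell is not None:
            states = two_state_schedule(n, spec.backbone_mean_dwell, rng,
                                        initial=spec.backbone)
        else:
            states = [spec.backbone] * n
    else:
        states = list(spec.backbone)
        if len(states) != n:
            raise ValueError("per-frame backbone labels must have length n_frames")
    switch_frames = [i for i in range(1, n) if states[i] != states[i - 1]]

    # rotamer labels, joint pairs first
    labels: dict[int, list[str]] = {}
    jointly_handled: set[int] = set()
    for (r1, r2), cells in spec.joint_targets.items():
        pair_labels = list(cells.keys())
        pj = np.array([cells[k] for k in pair_labels], dtype=float)
        if abs(pj.sum() - 1.0) > 1e-6:
            raise ValueError(f"joint targets for {(r1, r2)} must sum to 1")
        idx = rng.choice(len(pair_labels), size=n, p=pj / pj.sum())
        labels[r1] = [pair_labels[i][0] for i in idx]
        labels[r2] = [pair_labels[i][1] for i in idx]
        jointly_handled.update((r1, r2))
    for seq_id, targets in spec.rotamer_targets.items():
        if seq_id in jointly_handled:
            continue
        if _is_per_backbone(targets):
            # draw separately inside each backbone-state segment
            lab = [""] * n
            for bstate in ("helix", "coil"):
                idxs = [i for i in range(n) if states[i] == bstate]
                if not idxs:
                    continue
                seg = sample_state_labels(
                    targets.get(bstate, {}), len(idxs), rng,
                    spec.rotamer_mean_dwell.get(seq_id, 1.0))
                for i, l in zip(idxs, seg):
                    lab[i] = l
            labels[seq_id] = lab
        else:
            labels[seq_id] = sample_state_labels(
                targets, n, rng, spec.rotamer_mean_dwell.get(seq_id, 1.0))

    # chi values: state centre + jitter, or free sampling
    chi_values: dict[int, np.ndarray] = {}
    for seq_id in labels:
        centres = spec.rotamer_states.get(seq_id, {})
        vals = np.full((n, 2), np.nan)
        for i, lbl in enumerate(labels[seq_id]):
            if lbl == "free" or lbl not in centres:
                vals[i] = rng.uniform(-180.0, 180.0, size=2)
            else:
                c1, c2 = centres[lbl]
                vals[i, 0] = c1 + rng.uniform(-spec.chi_jitter, spec.chi_jitter)
                vals[i, 1] = c2 + rng.uniform(-spec.chi_jitter, spec.chi_jitter)
        chi_values[seq_id] = vals

    # backbone torsions per frame
    phi_psi = np.empty((n, n_res, 2))
    for i, st in enumerate(states):
        if st == "helix":
            jit = rng.uniform(-spec.backbone_jitter, spec.backbone_jitter,
                              size=(n_res, 2))
            phi_psi[i] = np.array(HELIX_PHI_PSI) + jit
        else:
            phi_psi[i, :, 0] = rng.uniform(-160.0, -60.0, size=n_res)
            phi_psi[i, :, 1] = rng.uniform(100.0, 180.0, size=n_res)

    frames = []
    for i in range(n):
        chi_assign = {
            seq_id: {"chi1": chi_values[seq_id][i, 0], "chi2": chi_values[seq_id][i, 1]}
            for seq_id in chi_values
        }
        st = build_peptide(spec.sequence, [tuple(pp) for pp in phi_psi[i]],
                           chi_assign, spec.start_seq_id, spec.chain_id)
        if spec.noise_sigma > 0:
            for res in st.residues:
                for atom in res.atoms:
                    atom.coord = atom.coord + rng.normal(0.0, spec.noise_sigma, 3)
        st.model_id = i + 1
        frames.append(st)

    ensemble = Ensemble(frames=frames, dt=spec.dt, label=spec.label)
    truth = GroundTruth(
        backbone_states=states,
        switch_frames=switch_frames,
        rotamer_labels=labels,
        chi_values=chi_values,
        phi_psi=phi_psi,
    )
    return ensemble, truth


# ---------------------------------------------------------------------------
# synthetic complex

def build_synthetic_complex(
    peptide: Structure,
    pocket_seq_ids: Sequence[int],
    cage_chain_id: str = "Z",
    points_per_atom: int = 80,
    probe_radius: float = 1.4,
    cage_radius: float = 1.87,
) -> Structure:
    """Peptide plus a rigid cage of carbon atoms occluding chosen residues.

    Cage atoms are placed on each pocket-residue atom's accessible sphere so
    that its Shrake-Rupley test points are occluded (bound SASA driven toward
    zero), then pruned wherever they could occlude atoms of non-pocket,
    non-adjacent residues.  Remaining residues therefore stay exposed and
    only the pocket residues become buried, which makes the constructed
    anchor set exact ground truth for the classifier.
    """
    pocket = set(int(s) for s in pocket_seq_ids)
    known = {r.seq_id for r in peptide.residues}
    missing = pocket - known
    if missing:
        raise ValueError(f"pocket residues absent from peptide: {sorted(missing)}")

    from .sasa_anchor import RadiiTable, fibonacci_sphere
    table = RadiiTable()
    unit = fibonacci_sphere(points_per_atom)

    cage_pts: list[np.ndarray] = []
    for res in peptide.residues:
        if res.seq_id not in pocket:
            continue
        for atom in res.atoms:
            r_acc = table.radius(atom.element, atom.name) + probe_radius
            cage_pts.extend(atom.coord + r_acc * unit)
    if not cage_pts:
        return Structure(residues=list(peptide.residues))
    cage = np.array(cage_pts)

    # Prune cage atoms that could shadow other residues.  A cage atom can
    # occlude surface of an atom with radius r_o out to r_o + 2*probe +
    # cage_radius, so distant residues get that full protection radius.
    # Residues spatially close to the pocket cannot be fully protected
    # without opening holes in the cage; they only get clash avoidance and
    # tolerate partial occlusion (they stay far above the burial threshold).
    pocket_xyz = np.array([a.coord for r in peptide.residues
                           if r.seq_id in pocket for a in r.atoms])
    keep = np.ones(len(cage), dtype=bool)
    for res in peptide.residues:
        if res.seq_id in pocket:
            continue
        for atom in res.atoms:
            r_o = table.radius(atom.element, atom.name)
            near_pocket = np.linalg.norm(pocket_xyz - atom.coord, axis=1).min() < 6.0
            if near_pocket:
                cutoff = r_o + cage_radius + 0.4   # clash-avoidance only
            else:
                cutoff = r_o + probe_radius + cage_radius + probe_radius
            d = np.linalg.norm(cage - atom.coord, axis=1)
            keep &= d > cutoff
    cage = cage[keep]

    cage_residues = []
    for i, pos in enumerate(cage, start=1):
        cage_residues.append(
            Residue(name="CAG", seq_id=i, chain_id=cage_chain_id,
                    atoms=[Atom(name="C", element="C", coord=pos)]))
    return Structure(residues=list(peptide.residues) + cage_residues)
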