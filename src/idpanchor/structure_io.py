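"""Read/write PDB coordinate files and the in-memory structure/ensemble model.

The package works on short peptides (the p53 transactivation segment
Glu17-Asn29 and toy complexes around it), so the in-memory model is a
deliberately small object tree: ``Structure`` -> ``Residue`` -> ``Atom``,
plus ``Ensemble`` for ordered multi-model collections.  Residue numbering is
always the author numbering found in the file (p53 numbering 17-29); nothing
is ever re-indexed.

Parsing and serialisation of the fixed-column PDB format are delegated to
gemmi; this module owns the conversion to and from the lightweight types and
the selection logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: residues treated as standard amino acids (for backbone-completeness checks)
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed."""


class SelectionError(KeyError):
    """Raised when a selection refers to entities that do not exist."""


class PDBFormatError(ValueError):
    """Raised when coordinates cannot be represented in PDB fixed columns."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coord must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    name: str
    seq_id: int
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    def get(self, atom_name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == atom_name:
                return a
        return None

    def coord(self, atom_name: str) -> np.ndarray:
        a = self.get(atom_name)
        if a is None:
            raise KeyError(f"{self.name}{self.seq_id}: no atom {atom_name!r}")
        return a.coord

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_id)

    @property
    def has_backbone(self) -> bool:
        names = {a.name for a in self.atoms}
        return all(n in names for n in BACKBONE_ATOMS)


@dataclass
class Structure:
    """One conformer: ordered residues (grouped by chain) with atoms."""

    residues: list[Residue] = field(default_factory=list)
    model_id: int = 1

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chain_ids:
            raise SelectionError(f"unknown chain id {chain_id!r}")
        return [r for r in self.residues if r.chain_id == chain_id]

    def residue(self, chain_id: str, seq_id: int) -> Residue:
        for r in self.residues:
            if r.chain_id == chain_id and r.seq_id == seq_id:
                return r
        raise SelectionError(f"no residue {chain_id}/{seq_id}")

    def atoms(self, include_hydrogens: bool = True) -> list[tuple[Residue, Atom]]:
        out = []
        for r in self.residues:
            for a in r.atoms:
                if not include_hydrogens and a.is_hydrogen:
                    continue
                out.append((r, a))
        return out

    def coords(
        self,
        atom_names: Sequence[str] | None = None,
        include_hydrogens: bool = True,
    ) -> np.ndarray:
        pts = [
            a.coord
            for _, a in self.atoms(include_hydrogens=include_hydrogens)
            if atom_names is None or a.name in atom_names
        ]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def atom_signature(self) -> tuple:
        """Topology key: (chain, seq_id, atom name) in order."""
        return tuple(
            (r.chain_id, r.seq_id, a.name) for r, a in self.atoms()
        )


@dataclass
class Ensemble:
    """Ordered frames of identical topology, optionally with a time axis."""

    frames: list[Structure]
    dt: float | None = None  # ns per frame
    label: str = ""

    def __post_init__(self) -> None:
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive when given")
        if self.frames:
            sig = self.frames[0].atom_signature()
            for i, f in enumerate(self.frames[1:], start=1):
                if f.atom_signature() != sig:
                    raise ValueError(f"frame {i} topology differs from frame 0")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    def times_ns(self) -> np.ndarray | None:
        if self.dt is None:
            return None
        return np.arange(len(self.frames)) * self.dt


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)

def _from_gemmi_model(model: gemmi.Model) -> Structure:
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            atoms: list[Atom] = []
            for at in res:
                if at.altloc not in ("", "\0", "A"):
                    continue  # keep blank or 'A' altlocs only
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name,
                        coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        altloc="" if at.altloc in ("", "\0") else at.altloc,
                    )
                )
            if not atoms:
                continue
            icode = res.seqid.icode.strip()
            if icode:
                logger.warning(
                    "residue %s %s%d has insertion code %r (passed through)",
                    res.name, chain.name, res.seqid.num, icode,
                )
            residues.append(
                Residue(
                    name=res.name,
                    seq_id=res.seqid.num,
                    chain_id=chain.name,
                    atoms=atoms,
                    icode=icode,
                )
            )
    return Structure(residues=residues, model_id=model.num)


def read_pdb(path: str | Path, model_policy: str = "first") -> Structure | Ensemble:
    """Read a PDB file.

    model_policy="first" returns a single :class:`Structure` (the first
    MODEL, or the bare coordinate block); "all" returns an :class:`Ensemble`
    with one frame per MODEL in file order.  Only blank/'A' altlocs are kept.
    """
    path = Path(path)
    if model_policy not in ("first", "all"):
        raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_atom_records(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    models = [_from_gemmi_model(m) for m in st]
    models = [m for m in models if m.n_atoms() > 0]
    if not models:
        raise PDBParseError(f"{path}: no atoms found")
    if model_policy == "first":
        return models[0]
    return Ensemble(frames=models, label=path.stem)


def _validate_atom_records(path: Path) -> None:
    """Reject malformed ATOM/HETATM records, naming the offending line."""
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(
                f"{path}:{lineno}: ATOM record shorter than the coordinate fields")
        try:
            float(line[30:38]); float(line[38:46]); float(line[46:54])
        except ValueError:
            raise PDBParseError(
                f"{path}:{lineno}: malformed ATOM record: {line[:54]!r}") from None


def _to_gemmi_structure(frames: Iterable[Structure], name: str = "idpanchor") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    for i, frame in enumerate(frames, start=1):
        model = gemmi.Model(i)
        for chain_id in frame.chain_ids:
            chain = gemmi.Chain(chain_id)
            for r in frame.chain(chain_id):
                gr = gemmi.Residue()
                gr.name = r.name
                gr.seqid = gemmi.SeqId(r.seq_id, r.icode or " ")
                if r.name in STANDARD_AA:
                    gr.entity_type = gemmi.EntityType.Polymer
                for a in r.atoms:
                    if np.any(np.abs(a.coord) >= 10000.0):
                        raise PDBFormatError(
                            f"coordinate {a.coord} of {r.name}{r.seq_id}:{a.name} "
                            "exceeds the PDB fixed-column width"
                        )
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element)
                    ga.pos = gemmi.Position(*a.coord)
                    ga.occ = a.occupancy
                    ga.altloc = a.altloc or "\0"
                    gr.add_atom(ga)
                chain.add_residue(gr)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(obj: Structure | Ensemble, path: str | Path) -> None:
    """Write a Structure (bare coordinates) or Ensemble (MODEL/ENDMDL blocks)."""
    path = Path(path)
    if isinstance(obj, Ensemble):
        if not obj.frames:
            raise ValueError("cannot write an empty ensemble")
        frames = obj.frames
    else:
        frames = [obj]
    st = _to_gemmi_structure(frames)
    opts = gemmi.PdbWriteOptions()
    opts.minimal_file = True
    path.write_text(st.make_pdb_string(opts))


# ---------------------------------------------------------------------------
# selection

def select(
    structure: Structure,
    chain_ids: Sequence[str] | None = None,
    seq_range: tuple[int, int] | None = None,
    atom_names: Sequence[str] | None = None,
) -> Structure:
    """Sub-structure by chain, author seq-id range (inclusive) and atom names.

    Preserves order; never reorders atoms.  An empty result is allowed but
    logged as a warning.  Unknown chain ids raise :class:`SelectionError`.
    """
    if chain_ids is not None:
        known = set(structure.chain_ids)
        for c in chain_ids:
            if c not in known:
                raise SelectionError(f"unknown chain id {c!r} (have {sorted(known)})")
    out: list[Residue] = []
    for r in structure.residues:
        if chain_ids is not None and r.chain_id not in chain_ids:
            continue
        if seq_range is not None and not (seq_range[0] <= r.seq_id <= seq_range[1]):
            continue
        atoms = r.atoms
        if atom_names is not None:
            atoms = [a for a in r.atoms if a.name in atom_names]
            if not atoms:
                continue
        out.append(Residue(r.name, r.seq_id, r.chain_id, list(atoms), r.icode))
    if not out:
        logger.warning("selection is empty (chains=%s seq_range=%s atoms=%s)",
                       chain_ids, seq_range, atom_names)
    return Structure(residues=out, model_id=structure.model_id)
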