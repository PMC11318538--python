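"""Hierarchical structure model and PDB input/output.

The model is deliberately small: chains hold ordered residues, residues hold
atoms with coordinates in Angstrom. Alternate locations are resolved at parse
time (highest occupancy wins, ties broken by lexicographically smallest altloc
identifier), waters are dropped, and hydrogens are kept but excluded from every
distance computation in the package.

Reading goes through :mod:`gemmi`; writing emits fixed-column ATOM/HETATM
records directly so that a write/parse round trip preserves atom counts and
coordinates to the format's 0.001 A resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1
from scipy.spatial.distance import cdist

from .errors import (
    EmptyStructureError,
    IncompleteBackboneError,
    PDBFormatError,
)

_HYDROGEN = {"H", "D"}
BACKBONE_ATOMS = ("N", "CA", "C")
# O/OXT belong to the backbone for bookkeeping (grafting keeps them) even
# though superposition uses only N, CA, C.
BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}
ONE_TO_THREE = {k: v.upper() for k, v in protein_letters_1to3.items()}


def three_to_one(res_name: str) -> str:
    """Map a 3-letter residue code to 1-letter; unknown codes give 'X'."""
    return THREE_TO_ONE.get(res_name.upper(), "X")


@dataclass
class Atom3D:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    alt_id: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN

    def copy(self) -> "Atom3D":
        return Atom3D(self.name, self.element, self.position.copy(),
                      self.occupancy, self.alt_id)


@dataclass
class ResidueUnit:
    chain_id: str
    author_number: int
    insertion_code: str
    res_name: str
    atoms: list[Atom3D] = field(default_factory=list)
    seq_index: int = 0

    @property
    def backbone_complete(self) -> bool:
        names = {a.name for a in self.atoms}
        return all(n in names for n in BACKBONE_ATOMS)

    @property
    def label(self) -> str:
        """Human-facing label, e.g. ``A:K101`` (insertion code appended)."""
        return (f"{self.chain_id}:{three_to_one(self.res_name)}"
                f"{self.author_number}{self.insertion_code}")

    def atom(self, name: str) -> Atom3D | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom3D]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        atoms = self.heavy_atoms()
        if not atoms:
            return np.empty((0, 3))
        return np.array([a.position for a in atoms])

    def side_chain_atoms(self, heavy_only: bool = True) -> list[Atom3D]:
        out = [a for a in self.atoms if a.name not in BACKBONE_NAMES]
        if heavy_only:
            out = [a for a in out if a.is_heavy]
        return out

    def copy(self) -> "ResidueUnit":
        return ResidueUnit(self.chain_id, self.author_number, self.insertion_code,
                           self.res_name, [a.copy() for a in self.atoms],
                           self.seq_index)


@dataclass
class MolecularModel:
    chains: list[tuple[str, list[ResidueUnit]]] = field(default_factory=list)
    source_id: str = ""

    def chain(self, chain_id: str) -> list[ResidueUnit]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(f"chain {chain_id!r} not in model {self.source_id!r}")

    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def residues(self):
        for _, res_list in self.chains:
            yield from res_list

    def find_residue(self, chain_id: str, author_number: int,
                     insertion_code: str = "") -> ResidueUnit | None:
        try:
            residues = self.chain(chain_id)
        except KeyError:
            return None
        for r in residues:
            if r.author_number == author_number and r.insertion_code == insertion_code:
                return r
        return None

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def all_heavy_coords(self) -> np.ndarray:
        parts = [r.heavy_coords() for r in self.residues()]
        parts = [p for p in parts if len(p)]
        return np.vstack(parts) if parts else np.empty((0, 3))

    def copy(self) -> "MolecularModel":
        return MolecularModel(
            [(cid, [r.copy() for r in residues]) for cid, residues in self.chains],
            self.source_id,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MolecularModel":
        """Return a copy with every atom position mapped to R x + t."""
        out = self.copy()
        for r in out.residues():
            for a in r.atoms:
                a.position = rotation @ a.position + translation
        return out


def _validate_coordinate_columns(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fieldtxt = line[lo:hi]
                try:
                    float(fieldtxt)
                except ValueError:
                    raise PDBFormatError(
                        f"line {lineno}: unparsable coordinate field {fieldtxt!r}"
                    ) from None


def _resolve_altlocs(atoms: list[Atom3D]) -> list[Atom3D]:
    # keep highest occupancy; ties: lexicographically smallest alt_id
    by_name: dict[str, Atom3D] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            by_name[a.name] = a
            order.append(a.name)
        else:
            b = by_name[a.name]
            if (a.occupancy, [b.alt_id]) > (b.occupancy, [a.alt_id]):
                # higher occupancy, or equal occupancy with smaller alt_id
                by_name[a.name] = a
    for a in by_name.values():
        a.alt_id = ""
    return [by_name[n] for n in order]


def _convert_gemmi_model(gmodel: gemmi.Model, source_id: str) -> MolecularModel:
    chains: list[tuple[str, list[ResidueUnit]]] = []
    seen: set[tuple[str, int, str]] = set()
    for gchain in gmodel:
        residues: list[ResidueUnit] = []
        for gres in gchain:
            if gres.is_water():
                continue
            icode = gres.seqid.icode.strip()
            key = (gchain.name, gres.seqid.num, icode)
            if key in seen:
                continue
            seen.add(key)
            atoms = [
                Atom3D(
                    name=ga.name,
                    element=ga.element.name,
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=float(ga.occ),
                    alt_id=ga.altloc.strip("\x00").strip(),
                )
                for ga in gres
            ]
            residues.append(
                ResidueUnit(gchain.name, gres.seqid.num, icode, gres.name,
                            _resolve_altlocs(atoms), seq_index=len(residues))
            )
        if residues:
            chains.append((gchain.name, residues))
    return MolecularModel(chains, source_id)


def parse_pdb(text: str, model_select: str = "first",
              source_id: str = "") -> MolecularModel | list[MolecularModel]:
    """Parse PDB-format text.

    Multi-model files yield the first model unless ``model_select="all"``,
    in which case a list of models is returned.
    """
    if model_select not in ("first", "all"):
        raise ValueError("model_select must be 'first' or 'all'")
    _validate_coordinate_columns(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBFormatError(str(exc)) from exc
    models = [_convert_gemmi_model(m, source_id) for m in st]
    models = [m for m in models if m.n_atoms > 0]
    if not models:
        raise EmptyStructureError("no ATOM/HETATM records (after dropping waters)")
    if model_select == "all":
        return models
    return models[0]


def parse_pdb_file(path, model_select: str = "first"):
    from pathlib import Path

    p = Path(path)
    return parse_pdb(p.read_text(), model_select=model_select, source_id=p.stem)


_STANDARD_RES = set(THREE_TO_ONE)


def _format_atom_name(name: str, element: str) -> str:
    if len(name) > 4:
        raise PDBFormatError(f"atom name {name!r} exceeds 4 characters")
    if len(name) < 4 and len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(model: MolecularModel) -> str:
    """Serialize a model to PDB text (ATOM/HETATM/TER/END, fixed columns)."""
    if model.n_atoms == 0:
        raise EmptyStructureError("cannot write an empty model")
    lines: list[str] = []
    serial = 0
    for cid, residues in model.chains:
        last = None
        for r in residues:
            record = "ATOM  " if r.res_name.upper() in _STANDARD_RES else "HETATM"
            for a in r.atoms:
                serial += 1
                x, y, z = a.position
                if max(abs(a.position)) >= 10000:
                    raise PDBFormatError("coordinate out of fixed-column range")
                lines.append(
                    f"{record}{serial:5d} {_format_atom_name(a.name, a.element)}"
                    f"{a.alt_id or ' '}{r.res_name:>3s} {cid:1s}{r.author_number:4d}"
                    f"{r.insertion_code or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}"
                )
            last = r
        if last is not None:
            serial += 1
            lines.append(f"TER   {serial:5d}      {last.res_name:>3s} "
                         f"{cid:1s}{last.author_number:4d}{last.insertion_code or ' '}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def backbone_coordinates(residues: list[ResidueUnit],
                         atom_set: str = "N-CA-C") -> np.ndarray:
    """Ordered backbone coordinates for a residue run.

    ``atom_set="CA-only"`` gives one point per residue, ``"N-CA-C"`` three
    (in N, CA, C order within each residue).
    """
    if atom_set not in ("CA-only", "N-CA-C"):
        raise ValueError(f"unknown atom_set {atom_set!r}")
    wanted = ("CA",) if atom_set == "CA-only" else BACKBONE_ATOMS
    coords = []
    for r in residues:
        for name in wanted:
            a = r.atom(name)
            if a is None:
                raise IncompleteBackboneError(
                    f"residue {r.label} is missing backbone atom {name}")
            coords.append(a.position)
    return np.array(coords)


def min_heavy_distance(a: ResidueUnit, b: ResidueUnit) -> float:
    """Minimum heavy-atom Euclidean distance between two residues (A)."""
    ca, cb = a.heavy_coords(), b.heavy_coords()
    if len(ca) == 0 or len(cb) == 0:
        raise ValueError("both residues must contain at least one heavy atom")
    return float(cdist(ca, cb).min())
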