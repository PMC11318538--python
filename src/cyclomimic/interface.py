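"""Target interface definition: hotspot selection and ligand-proximity search.

Hotspots — interface residues with a strongly favorable per-residue binding
free-energy contribution — are either supplied explicitly (labels such as
``A:K101``) or derived from a per-residue energy decomposition table (e.g. an
MM-GBSA output) by thresholding at -5 kcal/mol. The table is consumed as
input only; no energy is ever computed here.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import HotspotResolutionError
from .structure import MolecularModel, ResidueUnit, three_to_one

logger = logging.getLogger(__name__)

DEFAULT_HOTSPOT_THRESHOLD = -5.0  # kcal/mol
DEFAULT_INTERFACE_CUTOFF = 5.0    # heavy-atom distance, A
HOTSPOT_GROUP_GUIDANCE = 7        # warn above this many hotspots


@dataclass
class EnergyTable:
    """Residue label -> binding free-energy contribution (kcal/mol)."""

    entries: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, value in self.entries.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite energy for {label}")

    @classmethod
    def from_text(cls, text: str) -> "EnergyTable":
        df = pd.read_csv(io.StringIO(text), sep=None, engine="python",
                         comment="#")
        df.columns = [c.strip().lower() for c in df.columns]
        if "label" not in df.columns or "dg_kcal_mol" not in df.columns:
            raise ValueError("energy table needs columns: label, dG_kcal_mol")
        entries: dict[str, float] = {}
        for _, row in df.iterrows():
            label = str(row["label"]).strip()
            if label in entries:
                raise ValueError(f"duplicate label {label} in energy table")
            entries[label] = float(row["dg_kcal_mol"])
        return cls(entries)

    @classmethod
    def from_file(cls, path) -> "EnergyTable":
        with open(path) as fh:
            return cls.from_text(fh.read())

    def get(self, label: str, default: float = 0.0) -> float:
        return self.entries.get(label, default)


def select_hotspots(table: EnergyTable,
                    threshold: float = DEFAULT_HOTSPOT_THRESHOLD) -> list[str]:
    """Labels with dG strictly below the threshold, most favorable first.

    Ties are broken by label so the ordering is independent of the input
    row order.
    """
    if not table.entries:
        raise ValueError("energy table is empty")
    qualifying = [(v, k) for k, v in table.entries.items() if v < threshold]
    qualifying.sort()
    return [k for _, k in qualifying]


_LABEL_RE = re.compile(r"^(?:(?P<chain>[A-Za-z0-9]+):)?"
                       r"(?P<aa>[A-Za-z])(?P<num>-?\d+)(?P<icode>[A-Za-z]?)$")


def parse_label(label: str) -> tuple[str | None, str, int, str]:
    """Split ``A:K101`` into (chain, one-letter name, author number, icode)."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"malformed residue label {label!r} "
                         "(expected chain:NameNumber, e.g. A:K101)")
    return (m.group("chain"), m.group("aa").upper(), int(m.group("num")),
            m.group("icode").upper())


@dataclass
class HotspotSet:
    residues: list[ResidueUnit]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.residues]

    def in_sequence_order(self) -> list[ResidueUnit]:
        return sorted(self.residues, key=lambda r: (r.chain_id, r.seq_index))


@dataclass
class InterfaceDefinition:
    target_chain: str
    hotspots: HotspotSet
    ligand_chain: str | None = None
    ligand_resnames: tuple[str, ...] = ()
    mode: str = "non_consecutive"


def select_ligand_residues(model: MolecularModel, chain: str | None = None,
                           resnames=()) -> list[ResidueUnit]:
    resnames = {r.upper() for r in resnames}
    out = []
    for cid, residues in model.chains:
        for r in residues:
            if chain is not None and cid != chain:
                continue
            if resnames and r.res_name.upper() not in resnames:
                continue
            if chain is None and not resnames:
                continue
            out.append(r)
    return out


def residues_near_ligand(model: MolecularModel, ligand_residues,
                         cutoff: float = DEFAULT_INTERFACE_CUTOFF,
                         target_chain: str | None = None) -> list[ResidueUnit]:
    """Target residues with any heavy atom within ``cutoff`` of the ligand."""
    ligand_residues = list(ligand_residues)
    if not ligand_residues:
        raise ValueError("ligand selection is empty")
    lig_ids = {id(r) for r in ligand_residues}
    lig_coords = np.vstack([r.heavy_coords() for r in ligand_residues])
    out = []
    for cid, residues in model.chains:
        if target_chain is not None and cid != target_chain:
            continue
        for r in residues:
            if id(r) in lig_ids:
                continue
            hc = r.heavy_coords()
            if len(hc) and cdist(hc, lig_coords).min() <= cutoff:
                out.append(r)
    return out


def resolve_hotspots(model: MolecularModel, labels,
                     default_chain: str | None = None) -> HotspotSet:
    """Map residue labels onto structure residues; fail loudly on any miss.

    The one-letter residue name in each label is checked against the
    structure (catches numbering drift between an energy table and the
    model); all unresolved labels are reported together.
    """
    residues: list[ResidueUnit] = []
    problems: list[str] = []
    seen: set[str] = set()
    for label in labels:
        try:
            chain, aa, num, icode = parse_label(label)
        except ValueError as exc:
            problems.append(str(exc))
            continue
        chain = chain or default_chain
        if chain is None:
            problems.append(f"{label}: no chain given and no default chain set")
            continue
        key = f"{chain}:{aa}{num}{icode}"
        if key in seen:
            problems.append(f"{label}: duplicate hotspot label")
            continue
        seen.add(key)
        res = model.find_residue(chain, num, icode)
        if res is None:
            problems.append(f"{label}: no residue {num}{icode} in chain {chain}")
            continue
        found = three_to_one(res.res_name)
        if found != aa:
            problems.append(f"{label}: residue {chain}:{num} is {res.res_name} "
                            f"({found}), not {aa}")
            continue
        if not res.backbone_complete:
            problems.append(f"{label}: residue has an incomplete backbone")
            continue
        residues.append(res)
    if problems:
        raise HotspotResolutionError("; ".join(problems))
    if len(residues) > HOTSPOT_GROUP_GUIDANCE:
        logger.warning(
            "%d hotspots requested; combinatorial motif enumeration grows fast "
            "— consider segmenting into groups of 5-7 structurally related "
            "residues", len(residues))
    return HotspotSet(residues)
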