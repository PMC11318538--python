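"""Cyclic-peptide template database.

One record per cyclic peptide chain: identity, cyclization type, sequence,
a coarse secondary-structure string, and a motif fingerprint index built from
Calpha-Calpha distances of consecutive residue windows (with wrap-around for
head-to-tail rings).

Cyclization is detected from covalent-range heavy-atom distances:

* head-to-tail — C of the last residue within 1.7 A of N of the first;
* disulfide   — any CYS SG-SG pair within 2.3 A;
* side chain to side chain — any other inter-residue side-chain heavy-atom
  pair within 1.8 A;
* mixed       — two or more distinct closure mechanisms at once.

Linear chains (no closure) are excluded from the database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from . import matching
from .errors import EmptyDatabaseError
from .geometry import angular_difference, dihedral
from .structure import (
    MolecularModel,
    ResidueUnit,
    backbone_coordinates,
    parse_pdb_file,
    three_to_one,
)

logger = logging.getLogger(__name__)

HEAD_TO_TAIL_CUTOFF = 1.7   # peptide-bond covalent range, A
DISULFIDE_CUTOFF = 2.3      # S-S covalent range, A
SIDECHAIN_LINK_CUTOFF = 1.8  # generic covalent range, A

DEFAULT_MOTIF_SIZES = (4, 5, 6, 7)


class CyclizationType(str, Enum):
    HEAD_TO_TAIL = "head_to_tail"
    DISULFIDE = "disulfide"
    SIDECHAIN_SIDECHAIN = "sidechain_sidechain"
    MIXED = "mixed"
    NONE = "none"


@dataclass
class ClosureEvidence:
    kind: str                  # one of the non-mixed CyclizationType values
    residue_pair: tuple[str, str]
    distance: float


@dataclass
class CyclizationResult:
    ctype: CyclizationType
    evidence: list[ClosureEvidence]
    indeterminate: bool = False

    @property
    def has_head_to_tail(self) -> bool:
        return any(e.kind == CyclizationType.HEAD_TO_TAIL.value for e in self.evidence)


def detect_cyclization(chain: list[ResidueUnit]) -> CyclizationResult:
    """Classify the closure of a peptide chain from covalent-range contacts."""
    if len(chain) < 3:
        raise ValueError("cyclization detection needs at least 3 residues")
    evidence: list[ClosureEvidence] = []
    indeterminate = False

    first_n = chain[0].atom("N")
    last_c = chain[-1].atom("C")
    if first_n is None or last_c is None:
        indeterminate = True
    else:
        d = float(np.linalg.norm(last_c.position - first_n.position))
        if d <= HEAD_TO_TAIL_CUTOFF:
            evidence.append(ClosureEvidence(
                CyclizationType.HEAD_TO_TAIL.value,
                (chain[-1].label, chain[0].label), d))

    sgs = [(r, r.atom("SG")) for r in chain if r.res_name.upper() == "CYS"]
    sgs = [(r, a) for r, a in sgs if a is not None and a.is_heavy]
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i][1].position - sgs[j][1].position))
            if d <= DISULFIDE_CUTOFF:
                evidence.append(ClosureEvidence(
                    CyclizationType.DISULFIDE.value,
                    (sgs[i][0].label, sgs[j][0].label), d))

    for i in range(len(chain)):
        ai = [a for a in chain[i].side_chain_atoms() if a.name != "SG"]
        if not ai:
            continue
        for j in range(i + 1, len(chain)):
            aj = [a for a in chain[j].side_chain_atoms() if a.name != "SG"]
            if not aj:
                continue
            pi = np.array([a.position for a in ai])
            pj = np.array([a.position for a in aj])
            d = float(np.min(np.linalg.norm(pi[:, None, :] - pj[None, :, :], axis=-1)))
            if d <= SIDECHAIN_LINK_CUTOFF:
                evidence.append(ClosureEvidence(
                    CyclizationType.SIDECHAIN_SIDECHAIN.value,
                    (chain[i].label, chain[j].label), d))

    kinds = {e.kind for e in evidence}
    if len(kinds) >= 2:
        ctype = CyclizationType.MIXED
    elif len(kinds) == 1:
        ctype = CyclizationType(next(iter(kinds)))
    else:
        ctype = CyclizationType.NONE
    return CyclizationResult(ctype, evidence, indeterminate)


# (phi, psi) centers and tolerances of the dihedral assignment rule, degrees
_HELIX_CENTER, _HELIX_TOL = (-63.0, -42.0), 30.0
_STRAND_CENTER, _STRAND_TOL = (-120.0, 130.0), 40.0


def assign_secondary_structure(chain: list[ResidueUnit]) -> str:
    """Coarse per-residue secondary structure over {H, E, C, U}.

    H if (phi, psi) is within 30 deg of the canonical alpha-helix center
    (-63, -42), E if within 40 deg of the beta-strand center (-120, 130),
    C otherwise; U where a dihedral is undefined (chain termini, missing
    backbone atoms). This is database metadata only and is never consumed
    by the matching algorithm.
    """
    n = len(chain)
    out = []
    for i, r in enumerate(chain):
        if i == 0 or i == n - 1:
            out.append("U")
            continue
        prev_c = chain[i - 1].atom("C")
        next_n = chain[i + 1].atom("N")
        rn, rca, rc = r.atom("N"), r.atom("CA"), r.atom("C")
        if any(a is None for a in (prev_c, next_n, rn, rca, rc)):
            out.append("U")
            continue
        phi = dihedral(prev_c.position, rn.position, rca.position, rc.position)
        psi = dihedral(rn.position, rca.position, rc.position, next_n.position)
        if (angular_difference(phi, _HELIX_CENTER[0]) <= _HELIX_TOL
                and angular_difference(psi, _HELIX_CENTER[1]) <= _HELIX_TOL):
            out.append("H")
        elif (angular_difference(phi, _STRAND_CENTER[0]) <= _STRAND_TOL
                and angular_difference(psi, _STRAND_CENTER[1]) <= _STRAND_TOL):
            out.append("E")
        else:
            out.append("C")
    return "".join(out)


@dataclass
class CyclicPeptideRecord:
    pdb_id: str
    chain_id: str
    length: int
    sequence: str
    cyclization: CyclizationType
    ss_string: str
    file_ref: str
    wrapped: bool = False   # head-to-tail closure present -> windows wrap

    @property
    def key(self) -> str:
        return f"{self.pdb_id}:{self.chain_id}"


@dataclass
class MotifIndexEntry:
    record_key: str
    residue_indices: tuple[int, ...]
    fingerprint: "matching.DistanceFingerprint"


def consecutive_windows(n: int, m: int, wrap: bool) -> list[tuple[int, ...]]:
    """Consecutive index windows: n of them on a ring, n-m+1 on an open chain."""
    if m > n:
        return []
    if wrap:
        return [tuple((s + k) % n for k in range(m)) for s in range(n)]
    return [tuple(range(s, s + m)) for s in range(n - m + 1)]


@dataclass
class PeptideDatabase:
    records: list[CyclicPeptideRecord] = field(default_factory=list)
    index: list[MotifIndexEntry] = field(default_factory=list)
    motif_sizes: tuple[int, ...] = DEFAULT_MOTIF_SIZES
    _models: dict[str, MolecularModel] = field(default_factory=dict, repr=False)

    def record(self, key: str) -> CyclicPeptideRecord:
        for r in self.records:
            if r.key == key:
                return r
        raise KeyError(key)

    def model_for(self, record: CyclicPeptideRecord) -> MolecularModel:
        if record.key not in self._models:
            self._models[record.key] = parse_pdb_file(record.file_ref)
        return self._models[record.key]

    def chain_for(self, record: CyclicPeptideRecord) -> list[ResidueUnit]:
        return self.model_for(record).chain(record.chain_id)

    def add_record(self, record: CyclicPeptideRecord,
                   model: MolecularModel | None = None) -> None:
        self.records.append(record)
        if model is not None:
            self._models[record.key] = model
        chain = self.chain_for(record)
        ca = backbone_coordinates(chain, "CA-only")
        for m in self.motif_sizes:
            for window in consecutive_windows(record.length, m, record.wrapped):
                fp = matching.compute_fingerprint(ca[list(window)])
                self.index.append(MotifIndexEntry(record.key, window, fp))

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "records.tsv", "w") as fh:
            fh.write("# cyclomimic peptide database v1\n")
            fh.write("pdb_id\tchain\tlength\tsequence\tcyclization\tss_string"
                     "\twrapped\tfile_ref\n")
            for r in self.records:
                fh.write(f"{r.pdb_id}\t{r.chain_id}\t{r.length}\t{r.sequence}\t"
                         f"{r.cyclization.value}\t{r.ss_string}\t"
                         f"{int(r.wrapped)}\t{r.file_ref}\n")
        with open(out / "fingerprints.tsv", "w") as fh:
            fh.write("# cyclomimic fingerprint index v1\n")
            fh.write("record_key\tm\tindices\tdistances\n")
            for e in self.index:
                idx = ",".join(map(str, e.residue_indices))
                dist = ",".join(f"{d:.6f}" for d in e.fingerprint.distances)
                fh.write(f"{e.record_key}\t{e.fingerprint.m}\t{idx}\t{dist}\n")

    @classmethod
    def load(cls, in_dir) -> "PeptideDatabase":
        src = Path(in_dir)
        db = cls(motif_sizes=())
        with open(src / "records.tsv") as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("pdb_id"):
                    continue
                (pdb_id, chain, length, seq, cyc, ss, wrapped, file_ref) = \
                    line.rstrip("\n").split("\t")
                db.records.append(CyclicPeptideRecord(
                    pdb_id, chain, int(length), seq, CyclizationType(cyc),
                    ss, file_ref, bool(int(wrapped))))
        sizes = set()
        with open(src / "fingerprints.tsv") as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("record_key"):
                    continue
                key, m, idx, dist = line.rstrip("\n").split("\t")
                indices = tuple(int(i) for i in idx.split(","))
                distances = np.array([float(d) for d in dist.split(",")])
                sizes.add(int(m))
                db.index.append(MotifIndexEntry(
                    key, indices, matching.DistanceFingerprint(int(m), distances)))
        db.motif_sizes = tuple(sorted(sizes))
        return db


def build_database(source_dir, motif_sizes=DEFAULT_MOTIF_SIZES,
                   all_chains: bool = False) -> PeptideDatabase:
    """Build the template database from a directory of PDB files.

    Each file is parsed, chains are screened for a covalent closure, and one
    record per qualifying chain (the first such chain unless ``all_chains``)
    is fingerprinted for every requested motif size. Linear chains and
    unparsable files are logged and skipped. Ordering is deterministic:
    sorted filename, then chain order.
    """
    motif_sizes = tuple(sorted(set(motif_sizes)))
    for m in motif_sizes:
        if not 4 <= m <= 7:
            raise ValueError(f"motif size {m} outside the supported range 4-7")
    src = Path(source_dir)
    files = sorted(p for p in src.iterdir() if p.suffix.lower() in (".pdb", ".ent"))
    if not files:
        raise EmptyDatabaseError(f"no PDB files in {src}")
    db = PeptideDatabase(motif_sizes=motif_sizes)
    for path in files:
        try:
            model = parse_pdb_file(path)
        except Exception as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            continue
        for cid, chain in model.chains:
            if len(chain) < 3 or not all(r.backbone_complete for r in chain):
                continue
            cyc = detect_cyclization(chain)
            if cyc.ctype is CyclizationType.NONE:
                logger.info("skipping linear chain %s:%s", path.stem, cid)
                continue
            record = CyclicPeptideRecord(
                pdb_id=path.stem,
                chain_id=cid,
                length=len(chain),
                sequence="".join(three_to_one(r.res_name) for r in chain),
                cyclization=cyc.ctype,
                ss_string=assign_secondary_structure(chain),
                file_ref=str(path),
                wrapped=cyc.has_head_to_tail,
            )
            db.add_record(record, model)
            if not all_chains:
                break
    if not db.records:
        raise EmptyDatabaseError(f"no cyclic peptides found in {src}")
    return db
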