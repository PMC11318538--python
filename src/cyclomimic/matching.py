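"""Backbone motif matching between a target interface and cyclic peptides.

The algorithm characterizes a motif of m residues by the vector of its
m(m-1)/2 pairwise Calpha-Calpha distances — a rigid-motion invariant — and
screens every (target motif x peptide motif x orientation) pairing through a
filter chain:

1. fingerprint gate: maximum absolute component deviation within tolerance;
2. Fit-RMSD gate: least-squares rigid superposition (Kabsch) of the matched
   residues' backbone atoms, threshold 3 A by default;
3. clash gate: the whole peptide is posed with the fitted transform and
   heavy-atom contacts against the ligand are counted.

Target motifs come from hotspot residues, either as consecutive runs or —
for the elongated, sequentially non-consecutive binding sites typical of
glycosaminoglycan-binding proteins — as all size-m combinations. The peptide
side is enumerated the same way (consecutive windows wrap around the ring
for head-to-tail peptides). Each pairing is additionally tried with the
peptide motif traversed in reverse, since a mimic's backbone may run
antiparallel to the target's.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateGeometryError, ParameterError
from .geometry import RigidTransform, kabsch_superpose
from .structure import MolecularModel, ResidueUnit, backbone_coordinates

if TYPE_CHECKING:  # pragma: no cover
    from .interface import HotspotSet, InterfaceDefinition
    from .peptide_db import CyclicPeptideRecord, PeptideDatabase

logger = logging.getLogger(__name__)

MOTIF_SIZE_RANGE = (4, 7)
_DEGENERATE_DIST = 1e-6


@dataclass
class DistanceFingerprint:
    """Pairwise Calpha distances of an m-residue motif, A.

    Components are ordered lexicographically by index pair:
    (1,2), (1,3), ..., (m-1,m).
    """

    m: int
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.shape != (self.m * (self.m - 1) // 2,):
            raise ValueError("fingerprint length must be m(m-1)/2")


def pair_index_arrays(m: int) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j), i<j, in the fingerprint's lexicographic order."""
    iu = np.triu_indices(m, k=1)
    return iu[0], iu[1]


def reversal_permutation(m: int) -> np.ndarray:
    """Fingerprint component permutation under motif order reversal.

    Reversing the residue order maps pair (i, j) to (m-1-j, m-1-i); the
    returned permutation p satisfies fp(reversed)[k] = fp(original)[p[k]].
    """
    ii, jj = pair_index_arrays(m)
    pos = {(int(a), int(b)): k for k, (a, b) in enumerate(zip(ii, jj))}
    return np.array([pos[(m - 1 - int(b), m - 1 - int(a))]
                     for a, b in zip(ii, jj)])


def compute_fingerprint(coords: np.ndarray) -> DistanceFingerprint:
    """Fingerprint of an ordered set of m Calpha positions."""
    coords = np.asarray(coords, dtype=float)
    m = coords.shape[0]
    ii, jj = pair_index_arrays(m)
    d = np.linalg.norm(coords[ii] - coords[jj], axis=1)
    if np.any(d < _DEGENERATE_DIST):
        raise DegenerateGeometryError("coincident points in motif")
    return DistanceFingerprint(m, d)


def fingerprint_deviation(a: DistanceFingerprint, b: DistanceFingerprint) -> float:
    """Maximum absolute component difference between two fingerprints, A."""
    if a.m != b.m:
        raise ValueError(f"fingerprint size mismatch: {a.m} vs {b.m}")
    return float(np.max(np.abs(a.distances - b.distances)))


@dataclass
class MotifSpec:
    residue_indices: tuple[int, ...]
    consecutive: bool
    wrapped: bool = False

    @property
    def m(self) -> int:
        return len(self.residue_indices)


def _check_motif_size(m: int) -> None:
    lo, hi = MOTIF_SIZE_RANGE
    if not lo <= m <= hi:
        raise ParameterError(f"motif size {m} outside supported range {lo}-{hi}")


def enumerate_target_motifs(hotspots: "HotspotSet", m: int,
                            mode: str = "non_consecutive") -> list[MotifSpec]:
    """Size-m motifs over the hotspot residues.

    ``non_consecutive`` yields every size-m combination (C(|H|, m) motifs,
    members in ascending sequence order); ``consecutive`` yields only runs
    of adjacent author numbering.
    """
    _check_motif_size(m)
    residues = hotspots.in_sequence_order()
    if len(residues) < m:
        raise ParameterError(
            f"{len(residues)} hotspots but motif size {m}: need at least m")
    indices = list(range(len(residues)))
    if mode == "non_consecutive":
        return [MotifSpec(c, consecutive=False)
                for c in itertools.combinations(indices, m)]
    if mode == "consecutive":
        out = []
        for s in range(len(residues) - m + 1):
            run = residues[s:s + m]
            if all(run[k + 1].author_number - run[k].author_number == 1
                   and run[k + 1].chain_id == run[k].chain_id
                   for k in range(m - 1)):
                out.append(MotifSpec(tuple(range(s, s + m)), consecutive=True))
        return out
    raise ParameterError(f"unknown mode {mode!r}")


def enumerate_peptide_motifs(record: "CyclicPeptideRecord", m: int,
                             mode: str = "non_consecutive") -> list[MotifSpec]:
    """Size-m motifs over a peptide's residues (wrap for head-to-tail rings)."""
    _check_motif_size(m)
    n = record.length
    if m > n:
        return []
    if mode == "consecutive":
        from .peptide_db import consecutive_windows

        return [MotifSpec(w, consecutive=True, wrapped=record.wrapped)
                for w in consecutive_windows(n, m, record.wrapped)]
    if mode == "non_consecutive":
        return [MotifSpec(c, consecutive=False)
                for c in itertools.combinations(range(n), m)]
    raise ParameterError(f"unknown mode {mode!r}")


def count_clashes(posed_coords: np.ndarray, ligand_coords: np.ndarray,
                  severe_cutoff: float = 1.8,
                  soft_cutoff: float = 2.5) -> tuple[int, int]:
    """Heavy-atom contact counts below the severe and soft cutoffs.

    ``posed_coords``/``ligand_coords`` are heavy-atom coordinate arrays.
    Soft counts include severe ones (every pair closer than ``soft_cutoff``).
    """
    if soft_cutoff < severe_cutoff:
        raise ParameterError("soft_cutoff must be >= severe_cutoff")
    if len(posed_coords) == 0 or len(ligand_coords) == 0:
        raise ValueError("both atom sets must be non-empty")
    d = cdist(posed_coords, ligand_coords)
    return int((d < severe_cutoff).sum()), int((d < soft_cutoff).sum())


def count_model_clashes(posed: MolecularModel, ligand_residues,
                        severe_cutoff: float = 1.8,
                        soft_cutoff: float = 2.5) -> tuple[int, int]:
    lig = np.vstack([r.heavy_coords() for r in ligand_residues])
    return count_clashes(posed.all_heavy_coords(), lig, severe_cutoff, soft_cutoff)


@dataclass
class MatchParams:
    motif_size: int = 5
    mode: str = "non_consecutive"         # or "consecutive"
    fp_tolerance: float = 1.0             # max abs fingerprint deviation, A
    fit_rmsd_max: float = 3.0             # Fit-RMSD gate, A
    superpose_atoms: str = "N-CA-C"       # or "CA-only"
    clash_severe: float = 1.8             # A
    clash_soft: float = 2.5               # A
    max_soft_clashes: int = 10
    try_reversed: bool = True

    def __post_init__(self) -> None:
        _check_motif_size(self.motif_size)
        if self.clash_soft < self.clash_severe:
            raise ParameterError("clash_soft must be >= clash_severe")


@dataclass
class MatchCandidate:
    record_key: str
    pdb_id: str
    chain_id: str
    peptide_motif: MotifSpec
    target_motif: MotifSpec
    target_labels: tuple[str, ...]
    orientation: str                      # "forward" | "reversed"
    fp_deviation: float
    transform: RigidTransform | None = None
    fit_rmsd: float = float("nan")
    clash_severe: int = 0
    clash_soft: int = 0
    status: str = "candidate"
    target_residues: list[ResidueUnit] = field(default_factory=list, repr=False)

    def correspondence(self) -> list[tuple[int, ResidueUnit]]:
        """(peptide seq_index, target residue) pairs in peptide-motif order."""
        pep = list(self.peptide_motif.residue_indices)
        tgt = list(self.target_residues)
        if self.orientation == "reversed":
            tgt = tgt[::-1]
        return list(zip(pep, tgt))

    @property
    def sort_key(self):
        return (self.fit_rmsd, self.record_key,
                self.peptide_motif.residue_indices,
                self.target_motif.residue_indices, self.orientation)


@dataclass
class RunSummary:
    candidates: int = 0
    rejected_fp: int = 0
    rejected_rmsd: int = 0
    rejected_clash: int = 0
    passed: int = 0
    degenerate_skipped: int = 0

    def consistent(self) -> bool:
        return self.candidates == (self.rejected_fp + self.rejected_rmsd
                                   + self.rejected_clash + self.passed)

    def as_dict(self) -> dict[str, int]:
        return dict(candidates=self.candidates, rejected_fp=self.rejected_fp,
                    rejected_rmsd=self.rejected_rmsd,
                    rejected_clash=self.rejected_clash, passed=self.passed,
                    degenerate_skipped=self.degenerate_skipped)


@dataclass
class MatchResult:
    passed: list[MatchCandidate]
    rejected: list[MatchCandidate]
    summary: RunSummary


def _motif_fingerprint_matrix(ca: np.ndarray, motifs: list[MotifSpec],
                              m: int) -> tuple[np.ndarray, np.ndarray]:
    """All motif fingerprints as a (P, d) matrix plus a validity mask."""
    idx = np.array([s.residue_indices for s in motifs], dtype=int)
    ii, jj = pair_index_arrays(m)
    diffs = ca[idx[:, ii]] - ca[idx[:, jj]]
    fps = np.linalg.norm(diffs, axis=2)
    valid = fps.min(axis=1) >= _DEGENERATE_DIST
    return fps, valid


def run_matching(target_model: MolecularModel, interface: "InterfaceDefinition",
                 db: "PeptideDatabase", params: MatchParams,
                 ligand_residues=None) -> MatchResult:
    """Run the full matching filter chain over the database.

    Survivors are returned sorted by Fit-RMSD ascending (ties broken by
    record key and motif indices for reproducibility); every rejection is
    tallied per stage in the run summary.
    """
    from .interface import select_ligand_residues

    m = params.motif_size
    summary = RunSummary()
    if ligand_residues is None:
        ligand_residues = select_ligand_residues(
            target_model, interface.ligand_chain, interface.ligand_resnames)
    lig_coords = (np.vstack([r.heavy_coords() for r in ligand_residues])
                  if ligand_residues else None)

    target_motifs = enumerate_target_motifs(interface.hotspots, m, params.mode)
    hotspot_residues = interface.hotspots.in_sequence_order()
    t_fps, t_specs, t_res = [], [], []
    for spec in target_motifs:
        residues = [hotspot_residues[i] for i in spec.residue_indices]
        ca = backbone_coordinates(residues, "CA-only")
        try:
            fp = compute_fingerprint(ca)
        except DegenerateGeometryError:
            summary.degenerate_skipped += 1
            logger.warning("skipping degenerate target motif %s",
                           spec.residue_indices)
            continue
        t_fps.append(fp.distances)
        t_specs.append(spec)
        t_res.append(residues)
    if not t_fps:
        return MatchResult([], [], summary)
    t_fps = np.array(t_fps)

    orientations = ["forward"] + (["reversed"] if params.try_reversed else [])
    rev_perm = reversal_permutation(m)

    passed: list[MatchCandidate] = []
    rejected: list[MatchCandidate] = []
    for record in db.records:
        pep_motifs = enumerate_peptide_motifs(record, m, params.mode)
        if not pep_motifs:
            continue
        chain = db.chain_for(record)
        ca = backbone_coordinates(chain, "CA-only")
        pep_heavy = np.vstack([r.heavy_coords() for r in chain])
        fps_fwd, valid = _motif_fingerprint_matrix(ca, pep_motifs, m)
        n_bad = int((~valid).sum())
        if n_bad:
            summary.degenerate_skipped += n_bad * len(t_specs) * len(orientations)
            logger.warning("%s: %d degenerate peptide motifs skipped",
                           record.key, n_bad)
        for orientation in orientations:
            fps = fps_fwd if orientation == "forward" else fps_fwd[:, rev_perm]
            for t in range(len(t_specs)):
                dev = np.max(np.abs(fps - t_fps[t]), axis=1)
                dev[~valid] = np.inf
                hit_idx = np.nonzero(dev <= params.fp_tolerance)[0]
                n_valid = int(valid.sum())
                summary.candidates += n_valid
                summary.rejected_fp += n_valid - len(hit_idx)
                for p in hit_idx:
                    spec = pep_motifs[p]
                    pep_order = list(spec.residue_indices)
                    if orientation == "reversed":
                        pep_order = pep_order[::-1]
                    cand = MatchCandidate(
                        record_key=record.key, pdb_id=record.pdb_id,
                        chain_id=record.chain_id, peptide_motif=spec,
                        target_motif=t_specs[t],
                        target_labels=tuple(r.label for r in t_res[t]),
                        orientation=orientation, fp_deviation=float(dev[p]),
                        target_residues=t_res[t],
                    )
                    moving = backbone_coordinates(
                        [chain[i] for i in pep_order], params.superpose_atoms)
                    fixed = backbone_coordinates(t_res[t], params.superpose_atoms)
                    try:
                        transform, rmsd = kabsch_superpose(moving, fixed)
                    except DegenerateGeometryError:
                        summary.candidates -= 1
                        summary.rejected_fp += 1  # keep counters consistent
                        summary.degenerate_skipped += 1
                        continue
                    cand.transform, cand.fit_rmsd = transform, rmsd
                    # 1e-9 A slack so an exact copy survives a 0.0 threshold
                    if rmsd > params.fit_rmsd_max + 1e-9:
                        cand.status = "rejected_rmsd"
                        summary.rejected_rmsd += 1
                        rejected.append(cand)
                        continue
                    if lig_coords is not None:
                        posed = transform.apply(pep_heavy)
                        sev, soft = count_clashes(posed, lig_coords,
                                                  params.clash_severe,
                                                  params.clash_soft)
                        cand.clash_severe, cand.clash_soft = sev, soft
                        if sev >= 1 or soft >= params.max_soft_clashes:
                            cand.status = "rejected_clash"
                            summary.rejected_clash += 1
                            rejected.append(cand)
                            continue
                    cand.status = "passed"
                    summary.passed += 1
                    passed.append(cand)
    passed.sort(key=lambda c: c.sort_key)
    return MatchResult(passed, rejected, summary)


def match_table(result: MatchResult, include_rejected: bool = False) -> str:
    """Delimited-text report of match candidates."""
    lines = ["rank\tpdb_id\tchain\tpeptide_indices\ttarget_labels\torientation"
             "\tfp_deviation\tfit_rmsd\tsevere_clashes\tsoft_clashes\tstatus"]
    rows = list(result.passed)
    if include_rejected:
        rows += sorted(result.rejected, key=lambda c: c.sort_key)
    for rank, c in enumerate(rows, start=1):
        idx = ",".join(str(i + 1) for i in c.peptide_motif.residue_indices)
        labels = ",".join(c.target_labels)
        lines.append(f"{rank}\t{c.pdb_id}\t{c.chain_id}\t{idx}\t{labels}\t"
                     f"{c.orientation}\t{c.fp_deviation:.4f}\t{c.fit_rmsd:.4f}\t"
                     f"{c.clash_severe}\t{c.clash_soft}\t{c.status}")
    return "\n".join(lines) + "\n"
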