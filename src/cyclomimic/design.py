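"""Mutation planning, side-chain grafting, and energy-based ranking.

A passed match pairs peptide backbone positions with target hotspot
residues. The designer mutates those peptide positions to the target residue
types by rigid side-chain grafting: the target residue's local backbone frame
(N, CA, C) is least-squares aligned onto the peptide residue's frame and the
target side-chain heavy atoms are copied across. Backbone atoms are never
moved. Designs are ranked by the summed per-residue binding free energies of
the mimicked target residues (most negative first), the rationale being that
a mimic reproducing the geometry of the strongest contributors has the best
chance of reproducing their interactions.

Cyclization-critical residues (cysteines of a detected disulfide, the
termini of a head-to-tail closure) are protected from mutation unless
explicitly allowed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import DesignError
from .interface import EnergyTable
from .geometry import kabsch_superpose
from .matching import MatchCandidate
from .peptide_db import CyclizationResult, CyclizationType
from .structure import (
    MolecularModel,
    ResidueUnit,
    backbone_coordinates,
    three_to_one,
    write_pdb,
)

logger = logging.getLogger(__name__)


@dataclass
class MutationEntry:
    peptide_index: int            # 0-based seq_index on the peptide
    target_label: str             # e.g. "A:K101"
    target_res_name: str          # 3-letter code
    target_residue: ResidueUnit | None = None
    no_op: bool = False
    incomplete: bool = False      # grafting skipped (target side chain missing)


@dataclass
class MutationPlan:
    entries: list[MutationEntry]
    match: MatchCandidate | None = None


def derive_mutation_plan(match: MatchCandidate,
                         peptide_chain: list[ResidueUnit]) -> MutationPlan:
    """Plan mapping each matched peptide position to its target identity."""
    if match.status != "passed":
        raise DesignError(f"cannot design from a {match.status} match")
    pairs = match.correspondence()
    if len(pairs) != match.peptide_motif.m:
        raise DesignError("correspondence length mismatch")
    entries = []
    for pep_idx, target_res in pairs:
        entries.append(MutationEntry(
            peptide_index=pep_idx,
            target_label=target_res.label,
            target_res_name=target_res.res_name,
            target_residue=target_res,
            no_op=(peptide_chain[pep_idx].res_name.upper()
                   == target_res.res_name.upper()),
        ))
    positions = [e.peptide_index for e in entries]
    if len(set(positions)) != len(positions):
        raise DesignError("duplicate peptide positions in mutation plan")
    return MutationPlan(entries, match)


def validate_plan(plan: MutationPlan, peptide_chain: list[ResidueUnit],
                  cyclization: CyclizationResult,
                  allow_cycle_breaking: bool = False) -> None:
    """Reject plans that would mutate cyclization-critical residues."""
    if allow_cycle_breaking:
        return
    protected: set[int] = set()
    for ev in cyclization.evidence:
        if ev.kind == CyclizationType.DISULFIDE.value:
            for r in peptide_chain:
                if r.res_name.upper() == "CYS" and r.label in ev.residue_pair:
                    protected.add(r.seq_index)
        if ev.kind == CyclizationType.HEAD_TO_TAIL.value:
            protected.add(peptide_chain[0].seq_index)
            protected.add(peptide_chain[-1].seq_index)
    offending = [e for e in plan.entries
                 if e.peptide_index in protected and not e.no_op]
    if offending:
        labels = ", ".join(peptide_chain[e.peptide_index].label
                           for e in offending)
        raise DesignError(
            f"plan mutates cyclization-critical residue(s) {labels}; "
            "pass allow_cycle_breaking to override")


def apply_plan_to_sequence(sequence: str, plan: MutationPlan) -> str:
    """Apply the plan's substitutions to a 1-letter sequence."""
    seq = list(sequence)
    for e in plan.entries:
        if not 0 <= e.peptide_index < len(seq):
            raise DesignError(
                f"plan position {e.peptide_index + 1} outside sequence "
                f"of length {len(seq)}")
        seq[e.peptide_index] = three_to_one(e.target_res_name)
    return "".join(seq)


def mutation_tokens(plan: MutationPlan, original_sequence: str) -> list[str]:
    """Human-facing substitution tokens, e.g. ``Y3N`` (1-based positions)."""
    out = []
    for e in plan.entries:
        old = original_sequence[e.peptide_index]
        new = three_to_one(e.target_res_name)
        if old != new:
            out.append(f"{old}{e.peptide_index + 1}{new}")
    return out


def graft_side_chains(posed: MolecularModel, plan: MutationPlan,
                      chain_id: str) -> MolecularModel:
    """Graft target side chains onto the posed peptide (backbone untouched).

    For each plan entry the peptide residue's side-chain atoms are removed
    and the target residue's side-chain heavy atoms are copied in after
    aligning the target (N, CA, C) frame onto the peptide's. Mutation to
    glycine simply leaves no side chain.
    """
    out = posed.copy()
    chain = out.chain(chain_id)
    for e in plan.entries:
        pep_res = chain[e.peptide_index]
        target = e.target_residue
        if target is None:
            raise DesignError(f"plan entry {e.target_label} has no target residue")
        if not pep_res.backbone_complete or not target.backbone_complete:
            raise DesignError(
                f"incomplete backbone for graft at {pep_res.label}")
        backbone = [a for a in pep_res.atoms
                    if a.name in {"N", "CA", "C", "O", "OXT"}]
        side = target.side_chain_atoms(heavy_only=True)
        if target.res_name.upper() != "GLY" and not side:
            logger.warning("target %s has no side-chain atoms; graft skipped",
                           e.target_label)
            e.incomplete = True
            continue
        t_frame = backbone_coordinates([target], "N-CA-C")
        p_frame = backbone_coordinates([pep_res], "N-CA-C")
        transform, _ = kabsch_superpose(t_frame, p_frame)
        grafted = []
        for a in side:
            b = a.copy()
            b.position = transform.apply(a.position)
            grafted.append(b)
        pep_res.atoms = backbone + grafted
        pep_res.res_name = target.res_name
    return out


@dataclass
class DesignedPeptide:
    design_id: str
    pdb_id: str
    chain_id: str
    sequence: str                  # mutated 1-letter sequence
    original_sequence: str
    model: MolecularModel          # posed in the target frame, grafted
    plan: MutationPlan
    match: MatchCandidate
    rank_score: float = 0.0        # kcal/mol, sum of mimicked hotspot dG
    tokens: list[str] = field(default_factory=list)


def build_design(match: MatchCandidate, db, allow_cycle_breaking: bool = False,
                 design_id: str | None = None) -> DesignedPeptide:
    """Pose, mutate, and graft one passed match into a design."""
    from .peptide_db import detect_cyclization

    record = db.record(match.record_key)
    model = db.model_for(record)
    chain = model.chain(record.chain_id)
    plan = derive_mutation_plan(match, chain)
    validate_plan(plan, chain, detect_cyclization(chain), allow_cycle_breaking)
    posed = model.transformed(match.transform.rotation, match.transform.translation)
    grafted = graft_side_chains(posed, plan, record.chain_id)
    mutated = apply_plan_to_sequence(record.sequence, plan)
    return DesignedPeptide(
        design_id=design_id or f"{record.key}",
        pdb_id=record.pdb_id, chain_id=record.chain_id,
        sequence=mutated, original_sequence=record.sequence,
        model=grafted, plan=plan, match=match,
        tokens=mutation_tokens(plan, record.sequence),
    )


def rank_designs(designs: list[DesignedPeptide],
                 energies: EnergyTable | None) -> list[DesignedPeptide]:
    """Rank by summed mimicked-residue binding free energy, best first.

    The score of a design is the sum of the energy-table values of all
    target residues it mimics; labels missing from the table contribute 0
    (logged). Ties fall back to Fit-RMSD, then design id.
    """
    for d in designs:
        score = 0.0
        for e in d.plan.entries:
            if energies is not None and e.target_label in energies.entries:
                score += energies.entries[e.target_label]
            elif energies is not None:
                logger.info("label %s missing from energy table; contributes 0",
                            e.target_label)
        d.rank_score = score
    return sorted(designs,
                  key=lambda d: (d.rank_score, d.match.fit_rmsd, d.design_id))


def write_design_outputs(designs: list[DesignedPeptide], out_dir,
                         ligand_residues=None) -> list[Path]:
    """Write one posed PDB per design plus a summary table; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    rows = ["design_id\tpdb_id\tchain\tsequence\tmutations\trank_score"
            "\tfit_rmsd\tsevere_clashes\tsoft_clashes"]
    for i, d in enumerate(designs, start=1):
        model = d.model.copy()
        if ligand_residues:
            lig = [r.copy() for r in ligand_residues]
            model.chains.append((lig[0].chain_id, lig))
        path = out / f"design_{i:03d}_{d.pdb_id}.pdb"
        path.write_text(write_pdb(model))
        written.append(path)
        rows.append(f"{d.design_id}\t{d.pdb_id}\t{d.chain_id}\t{d.sequence}\t"
                    f"{','.join(d.tokens) or '-'}\t{d.rank_score:.2f}\t"
                    f"{d.match.fit_rmsd:.4f}\t{d.match.clash_severe}\t"
                    f"{d.match.clash_soft}")
    summary = out / "designs.tsv"
    summary.write_text("\n".join(rows) + "\n")
    written.append(summary)
    return written
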