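"""Synthetic structures for testing every stage without external downloads.

The generator produces geometrically idealized (not Ramachandran-realistic)
cyclic peptide backbones: Calpha atoms on a circle at ~3.8 A spacing with N
and C placed at in-plane angular offsets chosen so that the peptide-bond
C(i)-N(i+1) distance is 1.33 A. Head-to-tail peptides close the full circle
(terminal C-N also 1.33 A); disulfide-only peptides sit on an open arc with
their termini far apart and carry two CYS whose SG atoms are placed 2.05 A
apart. This is sufficient because matching consumes only distances and local
backbone frames.

Planted targets copy the backbone of a chosen peptide motif into a fresh
"protein" chain (plus far-away spacer residues), add Gaussian coordinate
noise, place a pseudo-ligand of carbon beads 3.8 A above the motif centroid
on the face opposite the peptide plane (so the true pose is clash-free), and
emit an energy table that marks the planted residues as hotspots
(-10 kcal/mol scale vs -1 for spacers).

All randomness comes from ``numpy.random.default_rng(seed)``; a fixed seed
gives bit-identical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .interface import EnergyTable
from .peptide_db import CyclicPeptideRecord, detect_cyclization, assign_secondary_structure
from .structure import (
    Atom3D,
    MolecularModel,
    ResidueUnit,
    ONE_TO_THREE,
    three_to_one,
    write_pdb,
)

CA_SPACING = 3.8          # A
PEPTIDE_BOND = 1.33       # C-N, A
CA_C_BOND = 1.52          # A
CARBONYL_O = 1.23         # C=O, A, placed out of plane
SS_BOND = 2.05            # SG-SG, A

_AA_POOL = "ADEFGHIKLMNPQRSTVWY"  # no C: cysteines only where placed


@dataclass
class FixtureSpec:
    n_residues: int
    closure: str = "head_to_tail"      # head_to_tail | disulfide | mixed | none
    noise_sigma: float = 0.0           # A, per coordinate
    seed: int = 0
    motif_indices: tuple[int, ...] | None = None


def _ring_parameters(n: int, closed: bool) -> tuple[float, float, float, float]:
    delta = 2 * np.pi / n if closed else 2 * np.pi / (n + 2)
    radius = CA_SPACING / (2 * np.sin(delta / 2))
    alpha_c = 2 * np.arcsin(CA_C_BOND / (2 * radius))
    alpha_n = delta - alpha_c - 2 * np.arcsin(PEPTIDE_BOND / (2 * radius))
    if alpha_n <= 0:
        raise ValueError(f"{n} residues too few for the idealized ring geometry")
    return delta, radius, alpha_c, alpha_n


def _draw_deformation(rng: np.random.Generator, n: int):
    """Low-order Fourier modulation of the ring center-line.

    A perfect circle is rotationally symmetric, which would make every
    rotated copy of a motif an exact geometric duplicate; a smooth radial
    and out-of-plane modulation (harmonics 2 and 3, seed-drawn amplitudes
    and phases) breaks the symmetry while changing adjacent-atom distances
    only slightly, so covalent-closure distances stay in range. Amplitudes
    shrink with ring size to protect the terminal peptide bond on small
    rings.
    """
    scale = min(1.0, n / 13.0)
    params = []
    for _ in range(2):  # one set for radial, one for z
        params.append([(k, scale * rng.uniform(0.10, 0.25),
                        rng.uniform(0.0, 2 * np.pi)) for k in (2, 3)])
    return params[0], params[1]


def _curve_point(radius: float, angle: float, rho_params, z_params,
                 z_extra: float = 0.0) -> np.ndarray:
    rho = sum(a * np.sin(k * angle + p) for k, a, p in rho_params)
    z = sum(a * np.sin(k * angle + p) for k, a, p in z_params)
    r = radius + rho
    return np.array([r * np.cos(angle), r * np.sin(angle), z + z_extra])


def make_cyclic_peptide(spec: FixtureSpec,
                        chain_id: str = "P") -> tuple[MolecularModel, CyclicPeptideRecord]:
    """Build an idealized cyclic (or linear) peptide and its database record."""
    n = spec.n_residues
    if n < 5:
        raise ValueError("need at least 5 residues")
    closed = spec.closure in ("head_to_tail", "mixed")
    delta, radius, alpha_c, alpha_n = _ring_parameters(n, closed)
    rng = np.random.default_rng(spec.seed)

    if spec.closure == "disulfide":
        cys_pair: tuple[int, int] | None = (1, n - 2)
    elif spec.closure == "mixed":
        if n < 7:
            raise ValueError("mixed closure needs at least 7 residues")
        cys_pair = (2, n - 3)
    else:
        cys_pair = None

    rho_params, z_params = _draw_deformation(rng, n)
    letters = [_AA_POOL[i] for i in rng.integers(0, len(_AA_POOL), size=n)]
    if cys_pair:
        for i in cys_pair:
            letters[i] = "C"

    residues: list[ResidueUnit] = []
    for i in range(n):
        theta = i * delta
        atoms = [
            Atom3D("N", "N", _curve_point(radius, theta - alpha_n,
                                          rho_params, z_params)),
            Atom3D("CA", "C", _curve_point(radius, theta,
                                           rho_params, z_params)),
            Atom3D("C", "C", _curve_point(radius, theta + alpha_c,
                                          rho_params, z_params)),
            Atom3D("O", "O", _curve_point(radius, theta + alpha_c,
                                          rho_params, z_params, CARBONYL_O)),
        ]
        residues.append(ResidueUnit(chain_id, i + 1, "", ONE_TO_THREE[letters[i]],
                                    atoms, seq_index=i))

    if cys_pair:
        i, j = cys_pair
        ca_i = residues[i].atom("CA").position
        ca_j = residues[j].atom("CA").position
        mid = (ca_i + ca_j) / 2
        direction = (ca_j - ca_i) / np.linalg.norm(ca_j - ca_i)
        lift = np.array([0.0, 0.0, 0.5])
        residues[i].atoms.append(Atom3D("SG", "S", mid - direction * SS_BOND / 2 + lift))
        residues[j].atoms.append(Atom3D("SG", "S", mid + direction * SS_BOND / 2 + lift))

    if spec.noise_sigma > 0:
        for r in residues:
            for a in r.atoms:
                a.position = a.position + rng.normal(0.0, spec.noise_sigma, 3)

    model = MolecularModel([(chain_id, residues)], source_id=f"fixture{spec.seed}")
    cyc = detect_cyclization(residues)
    record = CyclicPeptideRecord(
        pdb_id=model.source_id, chain_id=chain_id, length=n,
        sequence="".join(letters), cyclization=cyc.ctype,
        ss_string=assign_secondary_structure(residues),
        file_ref="", wrapped=cyc.has_head_to_tail,
    )
    return model, record


@dataclass
class PlantedTarget:
    model: MolecularModel
    hotspot_labels: list[str]
    energy_table: EnergyTable
    target_chain: str = "A"
    ligand_chain: str = "L"
    motif_indices: tuple[int, ...] = ()


def make_planted_target(peptide_model: MolecularModel, peptide_chain_id: str,
                        motif_indices, noise_sigma: float = 0.0,
                        seed: int = 0, n_spacers: int = 4) -> PlantedTarget:
    """Target structure containing a (noisy) copy of a peptide motif.

    The planted residues keep the peptide's residue types and get author
    numbers 101, 102, ...; spacer residues sit >= 10 A away; the
    pseudo-ligand beads sit 3.8 A from the motif centroid on the +z face,
    opposite the in-plane peptide body, so the true pose passes the clash
    gate. The energy table assigns about -10 kcal/mol to planted residues
    and -1 to spacers.
    """
    motif_indices = tuple(sorted(motif_indices))
    if not 4 <= len(motif_indices) <= 7:
        raise ValueError("motif size must be in 4..7")
    rng = np.random.default_rng(seed)
    chain = peptide_model.chain(peptide_chain_id)

    residues: list[ResidueUnit] = []
    labels: list[str] = []
    energies: dict[str, float] = {}
    for k, idx in enumerate(motif_indices):
        src = chain[idx]
        atoms = []
        for name in ("N", "CA", "C", "O"):
            a = src.atom(name)
            if a is None:
                continue
            atoms.append(Atom3D(name, a.element,
                                a.position + rng.normal(0.0, noise_sigma, 3)
                                if noise_sigma > 0 else a.position.copy()))
        res = ResidueUnit("A", 101 + k, "", src.res_name, atoms, seq_index=k)
        residues.append(res)
        labels.append(res.label)
        energies[res.label] = -10.0 + 0.1 * k

    motif_ca = np.array([chain[i].atom("CA").position for i in motif_indices])
    centroid = motif_ca.mean(axis=0)
    spacer_base = centroid + np.array([0.0, 0.0, 15.0])
    for s in range(n_spacers):
        ca = spacer_base + np.array([4.0 * s, 0.0, 0.0])
        atoms = [
            Atom3D("N", "N", ca + np.array([-1.2, 0.4, 0.0])),
            Atom3D("CA", "C", ca),
            Atom3D("C", "C", ca + np.array([1.2, 0.4, 0.0])),
        ]
        res = ResidueUnit("A", 201 + s, "", "ALA", atoms,
                          seq_index=len(residues))
        residues.append(res)
        energies[res.label] = -1.0

    beads = []
    for b, dx in enumerate((0.0, 0.6, -0.6)):
        pos = centroid + np.array([dx, 0.0, 3.8])
        beads.append(Atom3D(f"C{b + 1}", "C", pos))
    ligand = ResidueUnit("L", 1, "", "LIG", beads, seq_index=0)

    model = MolecularModel([("A", residues), ("L", [ligand])],
                           source_id="planted_target")
    return PlantedTarget(model, labels, EnergyTable(energies),
                         motif_indices=motif_indices)


def make_decoy_database(k: int, seed: int, out_dir) -> list[Path]:
    """Write k cyclic peptide PDB files plus one linear chain.

    The first three lengths are 13, 18, and 23 residues (ring, disulfide,
    and mixed closures in rotation); further lengths are drawn from 8-23.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    closures = ("head_to_tail", "disulfide", "mixed")
    lengths = [13, 18, 23]
    while len(lengths) < k:
        lengths.append(int(rng.integers(8, 24)))
    lengths = lengths[:k]
    paths = []
    for i, n in enumerate(lengths):
        spec = FixtureSpec(n, closures[i % 3], noise_sigma=0.0,
                           seed=seed * 1000 + i)
        model, _ = make_cyclic_peptide(spec)
        path = out / f"decoy_{i:03d}.pdb"
        path.write_text(write_pdb(model))
        paths.append(path)
    linear_model, _ = make_cyclic_peptide(
        FixtureSpec(9, "none", seed=seed * 1000 + k))
    path = out / "linear.pdb"
    path.write_text(write_pdb(linear_model))
    paths.append(path)
    return paths


@dataclass
class Workspace:
    root: Path
    database_dir: Path
    target_pdb: Path
    energy_table: Path
    hotspots: list[str]
    config: Path
    motif_indices: tuple[int, ...] = ()
    planted_pdb_id: str = ""


def write_workspace(out_dir, n_decoys: int = 5, motif_size: int = 5,
                    noise_sigma: float = 0.0, seed: int = 0) -> Workspace:
    """Self-contained test workspace: database dir, target, energies, config.

    The planted peptide is a 13-residue head-to-tail ring written into the
    database alongside the decoys; the target plants a random size-m motif
    of it.
    """
    root = Path(out_dir)
    db_dir = root / "database"
    make_decoy_database(n_decoys, seed, db_dir)
    rng = np.random.default_rng(seed + 1)

    planted_model, _ = make_cyclic_peptide(
        FixtureSpec(13, "head_to_tail", seed=seed + 7))
    planted_path = db_dir / "planted.pdb"
    planted_path.write_text(write_pdb(planted_model))

    motif = tuple(sorted(rng.choice(13, size=motif_size, replace=False).tolist()))
    planted = make_planted_target(planted_model, "P", motif,
                                  noise_sigma=noise_sigma, seed=seed + 11)
    target_path = root / "target.pdb"
    target_path.write_text(write_pdb(planted.model))

    energy_path = root / "energies.tsv"
    with open(energy_path, "w") as fh:
        fh.write("label\tdG_kcal_mol\n")
        for label, value in planted.energy_table.entries.items():
            fh.write(f"{label}\t{value:.2f}\n")

    config_path = root / "config.yaml"
    config_path.write_text(
        "database: {db}\ntarget: {tgt}\ntarget_chain: A\nligand_chain: L\n"
        "energy_table: {en}\nmotif_size: {m}\nmode: non_consecutive\n"
        "fp_tolerance: 1.0\nfit_rmsd_max: 3.0\n".format(
            db=db_dir, tgt=target_path, en=energy_path, m=motif_size))
    return Workspace(root, db_dir, target_path, energy_path,
                     planted.hotspot_labels, config_path, motif,
                     planted_pdb_id="planted")
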