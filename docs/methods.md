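# Methods

## Model and procedure

`cyclomimic` treats interface mimicry as a rigid geometric search. The unit
of comparison is a *motif*: an ordered set of m residues (4 ≤ m ≤ 7)
represented by the vector of its m(m−1)/2 pairwise Cα–Cα distances in
lexicographic pair order. Two motifs with (near-)equal distance vectors are
(near-)congruent up to a rigid motion and a possible reflection; the
subsequent superposition step resolves the ambiguity because only proper
rotations are fitted, so mirror-image motifs fail the Fit-RMSD gate rather
than matching spuriously.

For each (target motif, peptide motif) pair the i-th target residue
(ascending sequence order) corresponds to the i-th peptide motif residue.
Because a mimic's backbone may run antiparallel to the target's, each pair
is additionally tried with the peptide motif traversed in reverse; both
orientations are reported and tagged. Full permutation correspondence is
not searched — it grows as m! and geometric matches under arbitrary residue
permutation would rarely be synthesizable as a contiguous scaffold anyway.

The filter chain is, in order:

1. **Fingerprint gate.** Maximum absolute component deviation between the
   two distance vectors, threshold `fp_tolerance` (default 1.0 Å). This is
   a cheap, rigid-invariant pre-filter computed vectorized over all
   combinations of a peptide; it exists to keep the superposition count
   tractable, and the Fit-RMSD gate remains the authoritative geometric
   filter.
2. **Fit-RMSD gate.** Kabsch superposition (SVD with determinant
   correction, reflections excluded) of the matched residues' backbone
   atoms — N, CA, C of each residue (3m points) by default, so the score
   reflects backbone orientation and not only Cα positions; `CA-only` is a
   switch. Threshold `fit_rmsd_max` (default 3.0 Å, the displacement
   tolerance that still preserves the pose of long flexible side chains
   such as Arg/Lys). A 10⁻⁹ Å slack is added to the comparison so that an
   exact geometric copy survives even a 0.0 Å threshold despite floating-
   point rounding.
3. **Clash gate.** The whole peptide is posed with the fitted transform and
   heavy-atom pairs against the ligand are counted; a pose is rejected on
   any pair < 1.8 Å (covalent-range overlap) or ≥ 10 pairs < 2.5 Å.
   The published workflow's "substantial overlap" elimination plus final
   visual inspection is replaced by this quantified, configurable
   surrogate; counts are reported per candidate so a human can still
   inspect borderline poses.

Survivors are sorted by Fit-RMSD with a deterministic tie-break
(record key, motif indices, orientation). Every stage rejection is
tallied, and the run manifest checks
`candidates = rejected_fp + rejected_rmsd + rejected_clash + passed`.

## Hotspots and ranking

Hotspot residues are consumed, never predicted: either an explicit label
list (`chain:NameNumber`, with a strict residue-name check that catches
numbering drift between an energy table and the structure) or a
per-residue binding free-energy decomposition table thresholded at
−5 kcal/mol (strict `<`, most favorable first, ties broken by label so the
ordering is independent of row order). Designs are ranked by the sum of the
mimicked residues' ΔG values; labels absent from the table contribute 0 and
are logged; ties fall back to Fit-RMSD, then design id.

## Side-chain grafting

Matched positions are mutated by rigid grafting: the target residue's
(N, CA, C) frame is least-squares aligned onto the peptide residue's frame
and the target's side-chain heavy atoms are copied across; backbone atoms
(N, CA, C, O) are never moved, and mutation to glycine simply leaves no
side chain. Rotamer optimization or restrained minimization of the grafted
side chains is deliberately out of scope — the output is a geometric pose
meant for downstream refinement — and the grafting function is the
documented extension point for plugging in a relaxation step.
Cyclization-critical residues (cysteines of a detected disulfide, termini
of a head-to-tail closure) are protected from mutation unless
`allow_cycle_breaking` is set.

## Database conventions

One record per cyclic chain: PDB id, chain, length, sequence, cyclization
type, secondary-structure string, file reference. Closure detection uses
covalent-range heavy-atom distances — C(last)–N(first) ≤ 1.7 Å
(head-to-tail), CYS SG–SG ≤ 2.3 Å (disulfide), any other inter-residue
side-chain pair ≤ 1.8 Å (side-chain–side-chain), ≥ 2 distinct mechanisms =
mixed; these are standard covalent ranges chosen by this package. Linear
chains are excluded. Consecutive fingerprint windows wrap (n windows)
exactly when a head-to-tail closure is present, else n−m+1.

Secondary structure is metadata only and never used by matching; it is
assigned by a coarse dihedral rule (H within 30° of (φ,ψ) = (−63°,−42°),
E within 40° of (−120°,130°), else C, undefined → U) rather than DSSP, so
annotations may differ from databases computed with other tools.

Parsing conventions: highest-occupancy alternate location kept
(lexicographically smallest altloc id on ties), waters dropped, hydrogens
parsed but excluded from every distance computation, HETATM ligands parsed
like residues and selected by chain and/or residue name.

## Synthetic fixtures

The generator emulates the study conditions at desk scale: cyclic peptide
backbones with the closure chemistries above, a target carrying a planted
copy of a peptide motif, a pseudo-ligand, and an energy table marking the
planted residues as hotspots (≈ −10 kcal/mol vs −1 for spacers, spanning
the −5 kcal/mol threshold from both sides).

Backbones are geometrically idealized, not Ramachandran-realistic: Cα atoms
on a circle at 3.8 Å spacing, N and C at in-plane angular offsets giving a
1.33 Å peptide bond, carbonyl O displaced 1.23 Å out of plane. A perfect
circle is rotationally symmetric, which would make every rotated copy of a
motif an exact duplicate; the center-line is therefore modulated radially
and out of plane by low-order Fourier harmonics (orders 2 and 3,
seed-drawn amplitudes ≤ 0.25 Å scaled down for small rings) — smooth
enough that closure distances stay in covalent range, irregular enough
that the planted motif is the unique exact match. Disulfide-only peptides
sit on an open arc (termini far apart) with SG atoms placed 2.05 Å apart;
"mixed" rings carry both closures. All coordinates derive from
`numpy.random.default_rng(seed)`; a fixed seed is bit-reproducible.

Decoy databases use lengths 13, 18, and 23 first (the size range of real
matched scaffolds) and then 8–23, plus one linear chain that database
construction must reject. Pseudo-ligand beads sit 3.8 Å from the planted
motif centroid on the out-of-plane face, so the true pose clears the clash
gate by construction while a flipped or shifted pose need not.

What passing these fixtures does **not** show: recovery on real,
conformationally diverse peptide databases; robustness to missing atoms,
insertion codes, or NMR multi-model heterogeneity beyond first-model
selection; or that geometric rank correlates with experimental affinity.
The fixtures validate the bookkeeping and the geometry engine, not the
biology.

## Problem sizes and numerical choices

Recovery statistics run 20 seeded fixtures per motif size (4–7) against a
4-record database; gate-monotonicity audits use a 51-record database
(50 decoys + planted) with 6 hotspots at noise σ = 0.2 Å — sizes chosen so
the whole suite re-derives every number in about a minute on one core
while still exercising C(23,5)-scale combinatorial enumeration
(~150 000 candidate pairings per run). The brute-force superposition
oracle refines Nelder-Mead from 16–24 random rotation starts plus the
identity, which reproduces the SVD minimum to ~10⁻¹⁴ Å on these sizes.
Degenerate motifs (coincident or, for superposition, collinear points
within 10⁻⁶ Å) are skipped with a logged warning rather than propagated.
Fingerprints compare with strict inequality at thresholds; the Fit-RMSD
gate adds the 10⁻⁹ Å slack noted above.

## Known limitations

- Rigid-body matching only: no backbone flexibility, no ensemble matching,
  no refinement of the pose.
- The fingerprint pre-filter tolerance trades recall against runtime; with
  very permissive settings the superposition count grows combinatorially
  (non-consecutive mode on many hotspots is intrinsically expensive —
  segment hotspot searches into groups of 5–7 residues).
- Grafted side chains keep the target rotamer, which may clash with the
  peptide scaffold; only ligand clashes are screened.
- Ranking is a sum of input ΔG values over mimicked residues; it inherits
  whatever errors the upstream decomposition has and is not a binding
  affinity prediction for the designed complex.
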