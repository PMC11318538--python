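# cyclomimic

Design cyclic-peptide mimics of protein binding sites by backbone
distance-matrix motif matching.

## The problem

Protein interfaces — in particular the elongated, basic grooves with which
proteins bind glycosaminoglycans (GAGs) such as heparin — concentrate their
binding free energy in a handful of *hotspot* residues that are usually not
adjacent in sequence. Cyclic peptides (head-to-tail, disulfide, or
side-chain–side-chain closed) are rigid, protease-resistant scaffolds that
can present such a residue constellation if their backbone happens to hold
the right geometry. `cyclomimic` searches a database of cyclic peptide
structures for backbone motifs that reproduce the spatial arrangement of a
chosen set of hotspot residues, poses the peptides on the target, mutates
the matched positions to the hotspot residue types, and ranks the designs —
giving structural biologists and peptide chemists posed, mutated candidates
ready for refinement (MD, free-energy rescoring, synthesis).

## The method

A motif of *m* residues (4 ≤ m ≤ 7) is characterized by its **distance
fingerprint**: the vector of all m(m−1)/2 pairwise Cα–Cα distances, ordered
lexicographically by index pair — a complete rigid-motion invariant of the
motif's shape (up to chirality). For a target with hotspot set *H* and a
peptide of *n* residues the search enumerates

- target motifs: all C(|H|, m) combinations (*non-consecutive* mode, the
  GAG-site case) or runs of adjacent numbering (*consecutive* mode);
- peptide motifs: all C(n, m) combinations, or n (ring) / n−m+1 (open
  chain) consecutive windows;

and pushes every (target motif × peptide motif × orientation) pairing
through a filter chain:

1. **fingerprint gate** — max |Δd| over components ≤ 1 Å (default);
2. **Fit-RMSD gate** — least-squares rigid superposition (Kabsch/SVD,
   proper rotations only) of the matched residues' N, CA, C atoms;
   RMSD ≤ 3 Å (default);
3. **clash gate** — the whole peptide is posed with the fitted transform
   and heavy-atom contacts against the bound ligand are counted
   (reject if any pair < 1.8 Å or ≥ 10 pairs < 2.5 Å).

Hotspots are supplied explicitly (`A:K101` labels) or selected from a
per-residue binding free-energy decomposition (e.g. MM-GBSA output) as
residues contributing < −5 kcal/mol. Surviving matches are mutated to the
target residue types by rigid side-chain grafting (local N–CA–C frame
alignment; the backbone never moves) and ranked by the summed ΔG of the
mimicked hotspot residues, most favorable first.

## Worked example

The package ships a synthetic-fixture generator, so the full pipeline runs
without any downloads. Build a workspace (a small decoy database plus a
target that contains a planted copy of one peptide's motif and a
pseudo-ligand), then match and design:

```sh
cyclomimic fixtures --out ws --n-decoys 5 --motif-size 5 --seed 0
# workspace -> ws (planted motif 1,5,6,9,12 of planted)

cyclomimic match --config ws/config.yaml --energy-table ws/energies.tsv --out run
# candidates: 147416
# rejected_fp: 147408
# rejected_rmsd: 0
# rejected_clash: 0
# passed: 8
```

`run/matches.tsv` ranks the survivors by Fit-RMSD; the planted motif is
recovered exactly at rank 1 (fingerprint deviation 0, Fit-RMSD 0, no
clashes), followed by near-duplicate ring registrations with sub-angstrom
Fit-RMSD:

```
rank  pdb_id     chain  peptide_indices  target_labels                        orientation  fp_deviation  fit_rmsd  severe  soft  status
1     planted    P      1,5,6,9,12       A:E101,A:T102,A:H103,A:R104,A:L105   forward      0.0000        0.0000    0       0     passed
2     planted    P      2,6,7,10,13      A:E101,A:T102,A:H103,A:R104,A:L105   forward      0.2525        0.2103    0       0     passed
3     decoy_000  P      1,5,6,9,12       A:E101,A:T102,A:H103,A:R104,A:L105   forward      0.5240        0.2485    0       0     passed
```

`cyclomimic design` additionally writes one posed, mutated PDB per match
and `designs.tsv` with the mutated sequence, `Y3N`-style mutation tokens,
and the rank score — the sum of the mimicked residues' ΔG (here
−49 kcal/mol, five planted hotspots at about −10 each):

```
design_id     pdb_id   chain  sequence       mutations              rank_score  fit_rmsd
D001_planted  planted  P      ETELTHIHRGYLM  -                      -49.00      0.0000
D002_planted  planted  P      EEELTTHHRRYLL  T2E,H6T,I7H,G10R,M13L  -49.00      0.2103
```

With real data the same flow is
`cyclomimic build-db --source <pdb_dir> --out db` followed by
`cyclomimic match --database db --target complex.pdb --target-chain A
--ligand-chain B --energy-table decomp.csv --motif-size 5`.

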