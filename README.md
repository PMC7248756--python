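# oligorot

Analysis toolkit for the quaternary dynamics of hexameric repressors built
as two stacked trimers. It quantifies the rotation of one trimer relative
to the other, scores cross-trimer salt-bridge / hydrogen-bond occupancies,
computes RMSF → B-factor and RMSD profiles, quasi-harmonic configurational
entropies (with the Schlitter upper bound) and PCA of atomic fluctuations,
monitors paired DNA-binding-domain distances, and classifies repressor
family sequences by their group-defining charge-triad motifs. A synthetic
rigid-body generator produces ground-truthed trajectories so every analysis
is testable without MD data or downloads.

## Modules

| module | what it does |
|---|---|
| `oligorot.structio` | multi-model PDB read/write, altloc resolution, assembly expansion, atom selection, hexamer topology |
| `oligorot.rotation` | per-frame signed trimer–trimer rotation angles, windowed statistics, topology inference from geometry |
| `oligorot.contacts` | probe-group distance series, strict `<3 Å` / `>50%` hydrogen-bond occupancy scoring, salt-bridge panels |
| `oligorot.fluct` | Kabsch superposition, RMSD series, heavy-atom RMSF profiles, `B = (8π²/3)·RMSF²`, residue-43 pair distances |
| `oligorot.entropy` | mass-weighted fluctuation covariance, Schlitter & quasi-harmonic entropy, determinant entropy differences, PCA + projections |
| `oligorot.motifs` | `LIARxxD` / `KxxRxxxD` / `RxxRxxxE` motif scanning and group assignment from FASTA |
| `oligorot.synth` | ground-truthed rigid-body hexamer, contact-count, and Gaussian pseudo-trajectory generators |
| `oligorot.crystal` | geometry benchmarks on deposited crystal structures (rotation angles, marker distances) |
| `oligorot.cli` | `oligorot` command-line interface and the end-to-end `run` pipeline |

## CLI

```bash
# synthesize a ground-truthed trajectory (multi-model PDB + truth JSON)
oligorot synth hexamer --seed 7 --out traj.pdb --truth truth.json

# rotation time series and windowed statistics
oligorot rotate --traj traj.pdb --window-last-ns 500 --out rotation.tsv

# salt-bridge probe panel and hydrogen-bond table
oligorot contacts --traj traj.pdb --panel saltbridge --out panel.tsv
oligorot hbonds --traj traj.pdb --candidates candidates.json --out hbonds.tsv

# fluctuations, pair distances, entropy
oligorot rmsf --traj traj.pdb --agg mean --out rmsf.tsv
oligorot pairdist --traj traj.pdb --residue 43 --threshold 26 --out arg43.tsv
oligorot entropy --traj traj.pdb --selection all --method schlitter --out entropy.json

# motif classification
oligorot motif classify seqs.fasta --labels labels.tsv

# everything at once, with a reproducibility manifest
oligorot run --traj traj.pdb --config config.json --out results/
```

Topology (chain grouping, cross-trimer pairing, domain ranges, probe atoms)
defaults to the canonical layout — trimers `{A,B,C}` / `{D,E,F}`, pairs
A–F, B–E, C–D, subunit centroids over Cα 85–149 — and can be overridden
with a JSON file (`HexamerTopology.to_json` / `from_json`).

## Conventions

* Coordinates in Å, author (PDB) residue numbering throughout.
* Rotation sign: positive = clockwise looking down the trimer axis from
  the trimer-1 side (configurable).
* Hydrogen bonds are scored by heavy-atom distance only: strictly `< 3 Å`
  in strictly more than 50% of the window frames.
* Entropies are reported per mole (R-based), J mol⁻¹ K⁻¹, with the six
  rigid-body null modes dropped after fitting.
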