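# groovedock

Anchored ensemble docking of short peptides into the MHC class I binding
groove.

MHC class I molecules present peptides of 8–11 (up to 15) residues to T
cells. The bound peptide's termini sit in conserved pockets at the ends of
the binding groove, while the middle bulges with sequence-dependent
flexibility. `groovedock` exploits that anchoring: given a peptide sequence
and a receptor structure, it rapidly generates an *ensemble* of plausible
bound conformations instead of a single docked pose — useful for modelling
peptides with no crystal structure, for structure-based immunogenicity
studies, and as input to downstream scoring or simulation.

## Method

Each round of the pipeline performs:

1. **Anchor alignment** — a solved peptide–MHC complex with a peptide of the
   same length (the *template*; defaults 2VAA / 1DUZ / 1I4F / 2NW3 for 8- to
   11-mers) is superposed onto the input receptor over the groove (α1/α2 CA
   atoms, Kabsch). The backbone atoms (N, CA, C, O) of the template
   peptide's first and last two residues are transferred into the receptor
   frame: the anchor positions.
2. **Backbone sampling** — 100 peptide backbones per round are built by
   randomized cyclic coordinate descent (CCD) with Gauss–Newton endgame:
   interior φ/ψ torsions start from a coarse Ramachandran mixture and are
   adjusted, one closed-form rotation at a time, until the terminal N/CA/C
   atoms match the anchors (closure RMSD ≤ 0.1 Å, anchor tolerance 1.0 Å).
   Closure alternates growth direction (N→C, C→N). A permissive steric
   filter (0.6 × summed vdW radii) removes clashing backbones.
3. **Sidechains and minimization** — full heavy-atom sidechains are placed
   from a small rotamer library by greedy clash avoidance, then each pose is
   locally minimized over peptide φ/ψ/χ torsions, a rigid-body transform,
   and the χ angles of receptor sidechains within 4 Å, using an empirical
   Vina-family pair potential (gauss/repulsion/hydrophobic/H-bond terms,
   optional screened electrostatics).
4. **Anchor filter and pooling** — minimization is unconstrained, so poses
   whose anchor CA atoms drifted more than 2 Å out of their pockets are
   discarded. Survivors pool into the ensemble; the best-scored pose's
   receptor (with its relaxed sidechains) seeds the next round. Default: 10
   rounds.

Ensembles are evaluated by the minimum full-atom and CA RMSD of any pose to
a reference conformation, measured after superposing receptor grooves (no
peptide re-fitting, so shifted binding modes are penalized).

## Worked example

Real template/receptor structures are user-supplied PDB files; the package
also ships a fully synthetic groove system for experimentation, which the
example below uses.

```sh
groovedock fixtures --length 9 --seed 1 --out fx/
groovedock run --peptide LASGVLASL --receptor fx/receptor.pdb \
    --template fx/template.pdb --rounds 3 --samples 50 --seed 1 --out run9/
groovedock eval --ensemble run9/ --reference fx/reference.pdb
```

which prints (numbers from this exact invocation):

```
ensemble size: 73; best score: -20.428; outputs in run9/
min full-atom RMSD: 0.960 A
min CA RMSD: 0.654 A
```

73 of 150 sampled conformations survived closure, clash screening and the
anchor filter; the best-scored pose has total energy −20.4 (arbitrary score
units; lower is better), and the ensemble contains a conformation within
0.65 Å CA RMSD of the planted reference peptide — the reference binding
mode was recovered. `run9/` holds every pose as PDB, `scores.tsv` with the
per-term energy breakdown, and a `config.json` snapshot.

The same run in Python:

```python
from groovedock import PipelineConfig, ClosureConfig, run_pipeline, ensemble_min_rmsd

cfg = PipelineConfig(peptide_sequence="LASGVLASL",
                     receptor_source="fx/receptor.pdb",
                     template_source="fx/template.pdb",
                     n_rounds=3, closure=ClosureConfig(n_samples=50),
                     rng_seed=1, output_dir="run9")
ensemble = run_pipeline(cfg)
```

To dock against a real receptor, pass its PDB file and either a
length-matched template complex (`--template my_template.pdb`) or a
directory of the default templates (`GROOVEDOCK_TEMPLATE_DIR`); a plain-text
manifest (`length  path  chain_id` per line) configures custom registries.

## Data files

* `src/groovedock/data/rotamers.txt` — whitespace-delimited rotamer library
  (`residue chi1..chi4 weight`).
* `src/groovedock/data/atom_types.txt` — heavy-atom interaction typing
  (`residue atom code`).
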