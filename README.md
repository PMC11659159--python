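# pocketdiff

SE(3)-equivariant denoising diffusion for structure-based drug design:
pocket-conditioned 3D molecule generation, substructure inpainting (scaffold
hopping/elaboration, fragment linking/growing/merging) and evolutionary
property optimization — engineered so that every algorithmic component is
trainable and testable at desk scale on synthetic ligand–pocket complexes,
with no dataset downloads and no GPU.

The neural denoiser (an E(3)-equivariant GNN with an optional
reflection-breaking cross-product term that restricts the symmetry group to
SE(3)) runs on a small built-in reverse-mode autodiff engine over NumPy, so
the package has no deep-learning framework dependency.

## Layout

| module | contents |
|---|---|
| `pocketdiff.molsys` | atomic point clouds, one-hot featurization, typed graphs with per-edge-type cut-offs, feature/coordinate scaling |
| `pocketdiff.schedule` | variance-preserving polynomial noise schedule and transition coefficients |
| `pocketdiff.diffusion` | forward noising, posterior denoising steps, training loss, COM handling, ligand-size model, full sampling loop |
| `pocketdiff.egnn` | the SE(3)-equivariant message-passing denoiser + checkpointing |
| `pocketdiff.inpaint` | replacement-method inpainting with COM alignment and resampling; automatic Bemis–Murcko / linker masks |
| `pocketdiff.optimize` | noise/denoise diversification, evolutionary loop, dual-objective (on/off-target) pruning |
| `pocketdiff.chemio` | PDB/SDF I/O, pocket extraction, dataset curation rules, bond perception + sanitization, evaluation metrics |
| `pocketdiff.synthdata` | deterministic toy ligand–pocket complexes and chiral point-set pairs |
| `pocketdiff.app` | run configuration, seeding, the training loop |
| `pocketdiff.nnet` | minimal NumPy autodiff (Tensor, MLP, Adam) |

## CLI

```bash
# generate toy fixtures (PDB/SDF pairs + manifest)
pocketdiff make-fixtures --n 1000 --seed 7 --out fixtures/

# train a conditional denoiser on them
pocketdiff train --fixtures fixtures/ --steps 8000 --seed 0 --out model.npz

# sample ligands for a pocket
pocketdiff sample --pdb pocket.pdb --ref-ligand lig.sdf --checkpoint model.npz \
    --n 100 --mode cond --seed 1 --out samples.sdf

# substructure inpainting (masks are 1-based SDF atom indices)
pocketdiff inpaint --pdb pocket.pdb --ref-ligand lig.sdf --checkpoint model.npz \
    --task scaffold_hopping --regime denovo --resamplings 10 --n 20 --seed 1 \
    --out designs.sdf

# evolutionary optimization against an oracle
pocketdiff optimize --pdb pocket.pdb --ligand start.sdf --checkpoint model.npz \
    --oracle qed --generations 5 --population 100 --top-k 10 --seed 1 \
    --out archive.csv

# dataset curation and metrics
pocketdiff curate --in pairs.csv --seed 0 --out curated/
pocketdiff evaluate --in mols.sdf --out metrics.csv
```

Configuration is YAML (`--config`) with keys `mode`, `seed`, `schedule.{T,offset,clip_lo}`,
`scaling.{feat,coord}`, `egnn.{n_layers,hidden_dim,reflection_sensitive,time_encoding}`,
`cutoffs.{ll,lp,pp}`, `pocket.mode`, `train.{n_steps,lr,clip_grad_norm}`;
unknown keys are rejected.

## Notes

- External docking programs are not shipped; the optimizer's oracle interface
  wraps any scorer (QED/SA built in, or a shell command reading SDF on stdin)
  with an explicit sign convention.
- Checkpoints (`.npz`) bundle weights, network config, schedule, feature
  scaling, element alphabet and the ligand-size model; joint-mode checkpoints
  refuse conditional sampling without `--force`.
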