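# enmspec

Exact low-frequency fluctuation spectra of coarse-grained protein elastic
networks, and a convolutional surrogate that predicts them from a
rotation/translation-invariant inverse-distance descriptor.

The pipeline:

1. **chainio** — read single-chain C-alpha traces from PDB files, generate
   protein-like synthetic chains (self-avoiding walks with tunable
   compactness, plus a two-domain "dumbbell" hinge fixture), cut fixed-length
   sliding-window decoys, and double datasets with sequence-reversed copies.
2. **betagm** — build the anisotropic-network Hessian of a C-alpha trace,
   optionally augmented with effective C-beta centroids placed from the local
   backbone geometry and analytically reduced back to C-alpha coordinates;
   extract the 10 lowest non-zero eigenvalues (exactly 6 zero modes for a
   connected, non-collinear structure).
3. **descriptor** — the N x N inverse-distance (Coulomb) matrix with zero
   diagonal, in sequence order (reversal maps to an anti-transpose).
4. **surrogate** — a CNN (3 x [5x5 conv, 32 kernels, ReLU, 2x2 average
   pool] -> dense 512 -> dense 128 -> linear 10, dropout 0.25, Adagrad,
   MAPE loss) mapping 100x100 descriptors to the 10 eigenvalues.
   Implemented on a small pure-NumPy kernel (`enmspec.nn`) whose gradients
   are verified against finite differences — no deep-learning framework is
   required.
5. **evalcv** — repeated k-fold cross-validation with the pairing
   constraint (a structure and its reversed copy share a fold), per-eigenvalue
   and overall MAPE, and the non-informative mean-predictor baseline.
6. **pruning** — fit longer chains into the fixed 100-residue input by
   removing residues under three schemes (uniform random, hinge-protected
   sphere, displaced sphere) and score ensemble predictions against the exact
   full-chain spectrum; the scheme-dependent error localizes hinge residues.
7. **workbench** — CLI and end-to-end recipes.

## CLI

```bash
enmspec synth --n 100 --count 10 --compactness 0.7 --seed 1 --out chains/
enmspec decoys --pdb file.pdb --chain A --window 100 --out decoys/
enmspec spectrum --pdb file.pdb --chain A --model beta_gm --out spectrum.tsv
enmspec pipeline build_dataset --config cfg.yaml
enmspec train --data data/ --seed 3 --out models/
enmspec predict --model models/seed3 --data data/ --out pred.tsv
enmspec cv --data data/ --k 5 --repeats 10 --out cv.tsv
enmspec baseline --data data/ --out baseline.tsv
enmspec prune-predict --pdb big.pdb --models models/ --scheme protected_sphere \
    --n-remove 20 --radius 10 --n-structures 100 --seed 7 --out report.tsv
```

All stages accept a YAML configuration (`RunConfig`); every stochastic stage
takes an explicit seed and artifacts carry provenance JSON (config hash,
seeds, library versions).

## Notes

- Spring constants default to 1 (model units); the spectrum scales linearly
  in them and MAPE is scale-free.
- Surrogate configs may store an affine input normalization fitted on the
  training set (`surrogate.input_normalization`); the default is identity
  (raw descriptors).
- Model checkpoints are a directory of `config.json` + `weights.npz` +
  `history.tsv`; datasets are HDF5 (descriptors, targets) plus a TSV
  manifest.
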