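# spasite

Prediction of protein–RNA interface residues from the 3D neighborhood of
each residue, with a hybrid SVM-KNN classifier.

The pipeline:

1. **Parse** a protein–RNA complex (PDB or mmCIF) into a residue/atom model
   (`spasite.structure_io`).
2. **Label** every protein residue as interface (1) when its closest
   heavy-atom distance to any RNA residue is strictly below 5 Å.
3. **Annotate** residues with solvent accessibility and 3-state secondary
   structure, read from classic DSSP files or computed by a built-in
   deterministic Shrake–Rupley fallback (`spasite.annotations`).
4. **Profile** each chain with PSI-BLAST ASCII PSSMs or a BLOSUM62
   pseudo-profile fallback (`spasite.profiles`).
5. **Encode** each residue from its spatial window — the residue plus its
   w−1 nearest chain residues in 3D:
   - `SpaPF` — concatenated profile rows (20·w dims; 300 at w=15)
   - `SpawASA` — distance-weighted window ASA (w dims; 15 at w=15)
   - `SpaSecond` — H/E/C occurrence frequencies (3 dims)
   plus sequence-window baselines `SeqProfile` and `SeqASA`
   (`spasite.features`).
6. **Classify** with SVM-KNN (`spasite.svmknn`): an RBF-kernel SVM decides
   samples whose functional margin |f(x)| exceeds a threshold T; samples
   inside the band go to a class-weighted k-nearest-neighbor vote among the
   support vectors, measured in kernel-space distance.
7. **Evaluate** with k-fold cross-validation and Q/Sen/Spe/MCC
   (`spasite.evaluation`), including a window-width sweep.

A synthetic-complex generator (`spasite.synthetic`) builds download-free
fixtures — an ideal helix with a geometric RNA probe creating a
controllable interface patch, seeded profiles with a tunable class signal,
and fallback annotations — so every stage is testable offline.

## CLI

```sh
# generate a synthetic fixture bundle (PDB + profile TSV + annotation TSV)
spasite simulate --n-residues 30 --patch 3,9 --rna-offset 4.0 \
    --profile-signal 3.0 --seed 13 --outdir bundle/

# label interface residues
spasite label --structure bundle/complex.pdb --out labels.tsv

# build a labeled feature table
spasite featurize --structure bundle/complex.pdb --encoding SpaPF -w 15 \
    --out features.tsv

# train / predict / cross-validate
spasite train --features features.tsv --out model.json
spasite predict --model model.json --features features.tsv --out pred.tsv
spasite evaluate --features features.tsv --folds 5 --seed 0 --out metrics.json

# window-width sweep
spasite sweep --structure bundle/complex.pdb --w-values 13,15,17,19 \
    --out sweep.tsv
```

Classifier defaults: C=1, γ=0.0625, T=1.0, k=5, vote weights C1=1 and
C2=N−/N+ of the training set. Exit codes: 0 success, 2 input/validation
error, 3 degenerate-data error.

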