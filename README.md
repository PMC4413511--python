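# glypred

Prediction of lysine glycation sites from protein sequence, built around
four stages:

1. **Window extraction** — 23-residue peptide windows (11 residues on
   each side of an annotated site), padded with the artificial residue
   `O` at sequence ends (`glypred.sequence_io`).
2. **Feature encoding** — each window becomes a canonical
   1900-dimensional vector: 21 residue occurrence frequencies, 5
   physicochemical factor scores per site (115), and 441 ordered
   k-spaced amino-acid pair compositions for spacings k = 1..4 (1764)
   (`glypred.features`).
3. **Feature ranking** — greedy maximum-relevance / minimum-redundancy
   (mRMR) ordering of all features by mutual information with the class
   label, penalized by average mutual information with already-selected
   features (`glypred.mrmr`).
4. **Incremental feature selection** — growing prefixes of the ranking
   are evaluated with an RBF-kernel SVM under stratified 10-fold
   cross-validation with a (C, gamma) grid search; the prefix with the
   best Matthews correlation coefficient defines the final predictor
   (`glypred.ifs`).

A seeded synthetic-data generator (`glypred.simulate`) plants k-spaced
pair signal around lysine-centered sites so the full pipeline is
testable without any external dataset.

## Command-line interface

All coordinates are 1-based and inclusive. Every subcommand writes a
JSON run manifest (config, seed, input digests) next to its primary
output and logs to stderr.

```sh
# generate a synthetic benchmark with a planted S..4..W pair
glypred simulate --n-pos 89 --n-neg 126 --plant S,W,4,0.9 --seed 1 \
    --fasta proteins.fasta --annotations sites.tsv

# extract windows (TSV: protein_id, position, label, peptide, pad_count)
glypred extract --fasta proteins.fasta --annotations sites.tsv --out windows.tsv

# encode the canonical 1900-feature matrix (TSV with named columns)
glypred encode --windows windows.tsv --out matrix.tsv

# mRMR ranking (rank, feature_index, feature_name, relevance, score)
glypred rank --matrix matrix.tsv --out ranking.tsv

# IFS curve (size, C, gamma, TP, FP, TN, FN, Sn, Sp, Ac, MCC)
glypred ifs --matrix matrix.tsv --ranking ranking.tsv --out curve.tsv \
    --seed 1 --stride 10 --max-size 200

# train / score / evaluate
glypred train --matrix matrix.tsv --features 1793,33,91 --c 8 --gamma 0.125 \
    --out model.joblib
glypred predict --model model.joblib --windows windows.tsv --out pred.tsv
glypred evaluate --predictions pred.tsv --truth sites.tsv --out metrics.tsv
```

Annotation files are tab-separated `protein_id  position  label` (label
tokens `1/+1/pos` and `-1/0/neg`; `--delimiter comma` for CSV). Real
site annotations in the same format can be substituted for the
simulated ones at any stage.

Useful flags: `--max-pad N` drops windows with more than N padding
residues; `--raw-counts` keeps unnormalized pair counts; `--kmax`
changes the maximum pair spacing (feature count becomes
21 + 115 + 441*kmax); `--permissive` maps non-standard residues to `O`.

## Notes

- Feature indices are 1-based and canonical: outputs always carry
  feature indices/names, never bare column positions.
- The center residue is expected to be lysine (K); other centers warn
  by default and fail under `--strict-center`-style strict usage
  (`build_dataset(..., strict_center=True)`).
- mRMR mutual information uses a three-state (mean ± theta*std)
  per-feature discretization, in bits; `--theta` controls the band.
- CV metrics are pooled over test folds into a single confusion table;
  fold assignment is stratified, deterministic per seed, with fold sizes
  and per-class counts each balanced within 1.
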