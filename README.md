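# sixma

Encode adenine-centred DNA windows with three feature schemes, train a
random-forest classifier to discriminate N6-methyladenine (6mA) sites from
unmethylated adenines, construct motif-ratio-matched negative sets, and
evaluate models with cross-validation, ratio-split, jackknife and
independent-test protocols.

The unit of data is a **sample window**: a 41-nt DNA string (configurable,
always odd length) with the adenine of interest at the centre, optionally
carrying a binary methylation label.

## Feature schemes

| scheme | description | features (41 nt) |
|--------|-------------|------------------|
| `knfc` | overlapping k-tuple frequencies, k = 2, 3, 4, each 4^k block normalised by its slot count | 16 + 64 + 256 = 336 |
| `mnbe` | per-position one-hot code A=(1,0,0,0), C=(0,1,0,0), G=(0,0,1,0), T=(0,0,0,1) | 4 × 41 = 164 |
| `nv`   | natural vector: per-base count, mean 1-based position and second-order normalised positional moment | 12 |

Schemes concatenate in any order (`--schemes knfc,mnbe,nv` → 512 features).

## Command line

All subcommands are deterministic given their `--seed` flags; defaults are
the reference configuration (window length 41, threshold 0.5, k = 2,3,4,
100 trees grown from seed 1).

```bash
# generate a deterministic labelled synthetic dataset (TSV + FASTA)
sixma synth -o fixture --n-pos 1000 --n-neg 1000 --bias 0.8 --seed 1

# encode windows into a feature matrix
sixma encode fixture.tsv -o features.csv --schemes mnbe

# train / persist a random forest
sixma train features.csv -o model.joblib --n-trees 100 --rf-seed 1

# score new windows (FASTA of 41-nt records or a table)
sixma predict model.joblib fixture.fasta -o scores.tsv

# stratified five-fold cross-validation with a pooled ROC/AUC report
sixma cv fixture.tsv --schemes mnbe --folds 5 --json cv_report.json

# evaluate a saved model on an independent labelled set
sixma eval model.joblib heldout.tsv --json eval_report.json

# build a balanced benchmark: identity-filtered positives plus negatives
# sampled to match the positives' central-motif ratios
sixma make-data --pos positives.fa --neg candidates.fa -o benchmark.tsv \
    --ratios gagg=0.1708,agg=0.1576,ag=0.1442 --identity-threshold 0.8 --seed 1
```

JSON reports embed the tool version, resolved configuration, seeds and
SHA-256 digests of the inputs, so any run can be reproduced from its report.

## Library layout

- `sixma.seqio` — FASTA / labelled-table I/O, window extraction and
  validation (central adenine, strict {A,C,G,T} alphabet).
- `sixma.encoders` — the three encoders and their concatenations; pure
  functions with stable, named feature columns.
- `sixma.dataset` — central-motif stratification (GAGG > AGG > AG > other,
  anchored at the central A, most-specific-first), largest-remainder
  stratified negative sampling, a greedy ungapped identity filter
  (a documented stand-in for CD-HIT, not a replacement), and class
  balancing.
- `sixma.model` — scikit-learn random forest behind a pluggable scoring
  seam; versioned joblib persistence.
- `sixma.evaluate` — confusion counts, Sn/Sp/Acc/MCC, ROC/AUC (trapezoid,
  cross-checked against the Mann–Whitney rank statistic), stratified
  k-fold CV with pooled out-of-fold scoring, ratio splits (testing plus
  internal-CV training metrics), capped jackknife, independent-test
  evaluation.
- `sixma.synthetic` — seeded generator of labelled fixtures whose classes
  share central-motif ratios and differ only by a tunable positional
  composition bias in the flanks.

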