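# ctdegron

Toolkit for discovering and quantifying C-terminal degradation signals
(degrons) in protein families, built around the analysis of bacterial
aldehyde-decarbonylase homologs:

- **seqio** — FASTA I/O over the 20 standard residues + X, exact-duplicate
  removal, greedy identity clustering.
- **phylo** — affine-gap global pairwise alignment, p-distances (optional
  Poisson correction), progressive multiple alignment over an NJ guide
  tree, Saitou–Nei neighbor joining, Felsenstein column bootstrap, and
  clade-based representative (medoid) selection.
- **motif** — terminal k-mer frequency profiling (default last 10
  residues), conservation-threshold consensus calling (strict >50% by
  default), right-anchored motif identity, composition scoring against
  the {L, A, V, S} set, dipeptide scanning, and a bundled reference
  catalogue (ADcon `RMSAYGLAAA`, ssrA `CAANDENYALAA`, ADpm helix
  `RMAAAALVS`, Euhalothece `RMSAYGLREV`).
- **simulate** — ground-truth generators: families evolved along random
  trees with a planted, differentially conserved terminal motif plus
  exact-duplicate injection; reporter fluorescence/OD600 time courses
  with known synthesis/decay kinetics and lognormal noise.
- **assay** — OD600 normalization, percent-of-control and degradation
  percentages at interpolated endpoints, knockout recovery indices,
  post-peak log-linear decay-rate fits, and fold-change / net-effect
  arithmetic (display folds truncated to two decimals).
- **pipeline / cli** — end-to-end orchestration with a JSON config,
  stage-level logging and machine-readable run reports.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (NJ additive-matrix
oracle, planted-motif consensus recovery, dedup exactness, profile
normalization, degradation identities, motif-score worked examples).

## CLI

```sh
# simulate a family with a planted terminal motif, then analyze it
ctdegron simulate-family --n-taxa 50 --seed 1 --out-fasta fam.fasta \
    --out-newick true.nwk --out-truth truth.json
ctdegron dedup --in fam.fasta --out dedup.fasta --report dedup.tsv
ctdegron align --in dedup.fasta --out aln.fasta
ctdegron tree --in aln.fasta --bootstrap 100 --seed 1 --out tree.nwk
ctdegron profile --in dedup.fasta --k 10 --out profile.tsv --logo logo.txt
ctdegron consensus --in dedup.fasta --k 10 --threshold 0.5
ctdegron score --motif RMSAYGLAAA

# reporter assay track
ctdegron simulate-assay --knockouts --seed 2 --out assay.tsv
ctdegron assay --in assay.tsv --endpoint 25 --outdir out

# or everything from one config
ctdegron run-all --config config.json
```

Exit codes: 0 success, 2 configuration error, 3 data/format error.

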