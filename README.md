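# medbias

Measurement of demographic bias in the word-embedding spaces of healthcare
language models.

The package implements two statistics over embedding vectors:

* **Binary association test** — compares two target term sets (e.g.
  male-linked vs. female-linked medical conditions) against two attribute
  term sets (gender or ethnicity terms) via a cosine-based effect size
  `d` (bounded by ±2 for balanced targets) and a one-sided permutation
  p-value over equal-size target re-partitions.
* **SD-of-effect-sizes statistic** — pools *all* attribute words into one
  list, draws K (default 100) small tests of four pooled words (two per
  attribute set), and summarizes bias as the standard deviation of the K
  effect sizes. Because draws ignore group boundaries, the statistic
  handles multi-class demographic groups (e.g. Black / Hispanic / White)
  that the binary test cannot. Its p-value uses a target-shuffle
  resampling null with add-one correction (pluggable).

Around the statistics the package provides:

* `medbias.benchmarks` — a JSON/CSV dataset format for bias benchmarks,
  seven bundled fixtures (`G-1`..`G-4` gender-linked, `E-1`/`E-2`
  ethnicity-linked, `H-1` hybrid control), shape validation against the
  documented term counts, and a vocabulary filter. The bundled fixtures
  carry the published example terms plus clearly named placeholder slots;
  `load_fixture(name, overrides_dir=...)` swaps in full term lists if you
  have them.
* `medbias.embeddings` — GloVe-text and word2vec-text vector loaders
  (gzip transparent), mean pooling for multi-word terms, per-role OOV
  policies, and a `ContextualBackend` protocol for model-backed sub-word
  embedders (no model library is imported by the core).
* `medbias.weat` — the binary test plus `pairwise_weat` over every
  ordered pair of labeled attribute groups in a multi-class benchmark.
* `medbias.sdweat` — the pooled SD statistic with a vectorized core.
* `medbias.importance` — attribute-word importance: augment the pool with
  16 inanimate-object noise words, run many draws, and attribute mean
  effect sizes to each word by the attribute slot it occupied.
* `medbias.synth` — synthetic embedding tables with planted bias strength
  `beta` (and an exact-geometry mode reproducing the analytic extremes),
  plus `calibration_experiment` for type-I / power studies. Everything in
  the repo is testable offline with these tables.
* `medbias.report` / the `medbias` CLI — suite runner and TSV / JSON /
  markdown report tables with `0.727*(0.003)`-style cells.

## CLI

```sh
# binary test on a bundled benchmark against a word-vector text file
medbias weat --benchmark G-1 --embeddings vectors.txt --dialect glove \
    --pair male,female --exhaustive

# all ordered group pairs of a multi-class benchmark
medbias weat --benchmark H-1 --embeddings vectors.txt --pairwise

# pooled SD statistic (writes a full-precision JSON sidecar)
medbias sdweat --benchmark E-2 --embeddings vectors.txt \
    --tests 100 --seed 1 --pvalue-reps 1000 --json-out e2.json

# attribute-word importance matrix (+ occupancy counts CSV)
medbias importance --benchmark G-1 --embeddings vectors.txt \
    --tests 500 --seed 1 --out importance.csv
python scripts/plot_importance.py importance.csv heatmap.png

# synthetic planted-bias table -> text vectors usable by every command
medbias synth --config synth.json --out table.txt

# whole suite from a YAML/JSON config; exit 3 if any cell failed
medbias report --config run.yaml --out report.tsv

# shape-check a benchmark file
medbias validate G-1
```

A `report` config looks like:

```yaml
benchmarks: [G-1, G-2, E-2]
embeddings:
  - {name: glove-840b, path: glove.840B.300d.txt, dialect: glove-text}
statistic: sdweat
n_tests: 100
pvalue_replicates: 1000
seed: 1
output_dir: out/
```

Running against real pretrained vectors (e.g. a downloaded
`glove.840B.300d.txt`) needs no extra code path — point `--embeddings` or
the report config at the file. No pretrained weights are bundled or
fetched by the package; contextual models plug in via the
`ContextualBackend` protocol (mean pooling of sub-word vectors is done by
the core).

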