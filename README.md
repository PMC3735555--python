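# ivclass

Associative classification of gene-expression profiles through
**expression intervals**. Each gene's range is discretized into intervals
(entropy-driven supervised splitting by default); per phenotype class the
samples become transactions of (gene, interval) items; maximal frequent
itemsets are mined per class and turned into class-association rules; an
unknown sample is assigned to the class whose rules it satisfies best
(mean matched-item fraction, linear `f1` or squared `f2`). The package
also ships a leave-one-out cross-validation driver with ROC/AUC, a
one-versus-all wrapper for more than two classes, and a synthetic-data
generator with planted interval structure for end-to-end testing without
external datasets.

## Input formats

* **Expression matrix** — tab-delimited text, first row sample IDs, first
  column gene IDs, cells numeric (`#`-prefixed preamble lines are
  skipped; `--transpose` accepts samples-in-rows files).
* **Labels** — two tab-separated columns: sample ID, class label.
* **Rules** — one per line, `GENE[lo,hi], ...<TAB>class`, open bounds
  written `-inf`/`+inf`; optional `support=`/`confidence=` fields.
* **Model** — versioned, human-auditable JSON (scheme cut points, rules
  with support/confidence, config snapshot).

## CLI

```sh
# generate synthetic data with planted structure
ivclass synth --out-prefix demo --samples-per-class 40 --structure shift

# train: filter -> discretize -> mine -> rules -> prune
ivclass train --matrix demo.matrix.tsv --labels demo.labels.tsv \
    --model model.json --discretizer id3 --minsup 0.4 --min-confidence 0.05

# classify unknowns
ivclass predict --model model.json --matrix demo.matrix.tsv --out pred.tsv

# leave-one-out cross-validation (full pipeline refit per fold)
ivclass loocv --matrix demo.matrix.tsv --labels demo.labels.tsv \
    --out report.tsv --roc roc.tsv
```

Key options (defaults): `--alpha 0.05` gene-filter cutoff, `--filter
{t,bf}` (Welch t-test / Brown-Forsythe spread test), `--discretizer
{id3,ewib,none,ternary}`, `--minsup 0.4`, `--min-interval-size 0.05`,
`--min-confidence 0.05`, `--score {f1,f2}`, `--no-prune`. Hyperparameters
can also come from a JSON config file (`--config`); flags win. Exit
codes: 0 ok, 2 validation error, 3 parse error.

With three or more classes, `train`/`loocv` automatically use a
one-versus-all ensemble of binary models, each with its own filtering,
discretization and mining.

## Python API

```python
import ivclass as iv

matrix, truth = iv.generate(iv.SyntheticSpec(seed=0))
model = iv.fit(matrix, iv.RunConfig())
pred, scores = model.predict_matrix(matrix)
report = iv.loocv(matrix, iv.RunConfig())   # accuracy, ROC points, AUC
```

## Tests and acceptance

```sh
python -m pytest -q                  # unit + property + acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the release criteria (miner equivalence
against a brute-force oracle, discretizer partition properties, Welch-t
closed-form agreement, score algebra, parameter recovery and
interval-vs-ternary superiority on synthetic data, pruning monotonicity,
end-to-end determinism). The acceptance script smoke-runs the pipeline
and writes the (empty — the criteria are property-based, with no numeric
headline targets) target report.

## Notes

* Intervals are left-open/right-closed `(lo, hi]` with the extreme
  intervals extended to ±infinity, so unseen test values always map to
  exactly one interval.
* The `none` discretizer is pass-through: one degenerate bin per distinct
  training value.
* The expression scale (log or linear) is up to the caller; the method
  only uses within-gene order and spacing.
* The `f1`/`f2` satisfaction functions are reconstructions of the two
  score variants (linear and squared matched fraction); see docstrings.
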