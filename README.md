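# cardwarm

Weighted class-association rule mining for categorical heart-disease
records.

The pipeline turns raw 14-column clinical records (thirteen attributes plus
a 0–4 diagnosis code, `?` for missing) into categorical data, scores each
(feature, level) item with a strength weight derived from feature-selection
occurrence counts and empirical level frequencies, and mines class rules
(`antecedent items ⇒ Heart Disease / No Heart Disease`) with an Apriori-style
level-wise search scored by weighted support and weighted confidence.

## What's inside

| module | role |
| --- | --- |
| `cardwarm.data_io` | raw-dialect reader/writer, occurrence-count table, rule and weight-table serialization (JSON/CSV) |
| `cardwarm.preprocessing` | record cleaning, outcome binarisation, clinical discretisation scheme |
| `cardwarm.strength_scores` | feature weights `W(n)`, value weights `W(value)`, total item weights `W(t)`, significant-feature selection |
| `cardwarm.warm_miner` | weighted support/confidence, level-wise frequent-itemset mining, class-rule generation |
| `cardwarm.rule_analysis` | deterministic ranking, sick/healthy partition, feature-frequency summaries, Markdown reports |
| `cardwarm.synthetic_data` | seeded generator with controlled marginals and planted rules |
| `cardwarm.cli` | `cardwarm` command-line entry point |

Bundled data (text only): the 13-feature occurrence-count table and a
20-record synthetic sample in the raw dialect. The real UCI Cleveland file
is **not** bundled; see below.

## CLI

```sh
# clean + discretize a raw file, keeping the 8 significant features
cardwarm preprocess --input processed.cleveland.data --subset significant --out encoded.csv

# or generate the default 297-record synthetic dataset
cardwarm preprocess --synthetic --out encoded.csv

# mine rules; writes weights.csv, rules.json, rules.csv, report.md
cardwarm mine --encoded encoded.csv --mode significant --out-dir results/

# other commands
cardwarm weights --encoded encoded.csv --out weights.csv
cardwarm report --rules results/rules.json --out report.md
cardwarm synth --seed 7 --format raw --out synthetic.data
cardwarm worked-examples
```

Mining knobs: `--min-wsupport` (default 0.005), `--min-confidence` (0.90),
`--max-antecedent` (6), `--top-k` (20). A flat YAML config file can supply
any of them (`--config`); explicit flags win.

## Notes on semantics

* Discretisation uses half-open `[lo, hi)` bins except where the published
  vocabulary states a strict `>` (maximum heart rate, ST depression), and
  extends the outermost bins to ±∞.
* Weighted support of an itemset is its raw support times the mean `W(t)`
  of its non-class items (class-only itemsets carry weight 1). For
  class-consequent rules the weight factor cancels in the confidence ratio;
  weights act by gating which itemsets are admitted and ranked.
* Pruning uses raw support (downward-closed), tightened by the global
  maximum item weight; the weighted threshold is a per-level post-filter.
* All weights are carried at full float precision; two-decimal figures in
  reports are display-only (round-half-up).
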