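# sbaenet

Sex-biased adverse-event (SBAE) detection and sex-specific gene-regulatory
network analysis.

The package implements a complete desk-scale pipeline linking
pharmacovigilance to regulatory genomics:

1. **Pharmacovigilance** — filter spontaneous case reports, build per
   drug–event 2×2 female/male contingency tables, score reporting odds
   ratios (ROR) with Fisher's exact test and Benjamini–Hochberg adjustment,
   and call sex-biased drug–adverse-event pairs.
2. **Drug-feature enrichment** — permutation tests asking whether the drugs
   behind sex-biased pairs share targets/enzymes more often than same-size
   random drug sets.
3. **Expression preparation** — sample/gene filtering and sex-aware smoothed
   quantile normalization of RNA-seq counts.
4. **Network inference** — message-passing refinement of a motif prior
   against TF–TF interactions and gene co-expression, yielding one weighted
   bipartite TF→gene network per sex.
5. **Differential-modularity communities** — Louvain communities on the
   excess edge weight of one sex's network over the strength-product
   expectation of the other, with per-node scores and core-gene extraction.
6. **Network statistics** — weighted in-degree comparisons, sex-biased edge
   calls, gene targeting classes, activator/repressor edge typing, and
   printed-style summary fractions.

A seeded synthetic-data generator (cases, drug annotations, expression with
planted sex effects and differential regulation) with recorded ground truth
backs the validation studies in `sbaenet.evaluation`.

## Quickstart: the full synthetic pipeline

```bash
sbaenet report --seed 7 --out-dir results/demo
```

Actual output:

```
pairs tested: 875
female-biased pairs: 1
male-biased pairs: 1
SBAE-associated drugs: 2
enriched targets: 0
edges_unique_to_one_sex: 4/481 = 0.83%
shared_edges_opposite_class: 0/477 = 0.0%
```

`results/demo/` then contains every stage artifact (`cases.tsv`,
`sbae_results.tsv`, `grn_female.tsv`, `communities.tsv`, `summary.json`, …)
plus `manifest.json` with a SHA-256 hash per file; reruns with the same seed
produce hash-identical artifacts.

## Worked example: stage by stage

```bash
sbaenet simulate --seed 3 --out-dir demo
# wrote synthetic inputs to demo

sbaenet sbae --cases demo/cases.tsv --out-dir demo
# tested 800 pairs; 2 sex-biased

sbaenet prep-expression --counts demo/expression_counts.tsv \
    --metadata demo/expression_samples.tsv --out-dir demo
# normalized 220 genes x 120 samples

sbaenet build-grn --matrix demo/normalized_liver_female.tsv \
    --motif demo/motif_prior.tsv --ppi demo/ppi.tsv --label female --out-dir demo
# female: 27 iterations, final delta 8.45e-04

sbaenet build-grn --matrix demo/normalized_liver_male.tsv \
    --motif demo/motif_prior.tsv --ppi demo/ppi.tsv --label male --out-dir demo
# male: 26 iterations, final delta 9.37e-04

sbaenet communities --female demo/grn_female.tsv --male demo/grn_male.tsv \
    --tissue liver --out-dir demo
# 16 communities across both orientations

sbaenet netstats --female demo/grn_female.tsv --male demo/grn_male.tsv \
    --counts demo/normalized_liver_all.tsv --metadata demo/expression_samples.tsv \
    --gene-set demo/core_genes.gmt --out-dir demo
# gene set 'liver_female-perturbed_c1': median degree diff 0.216, p = 0.0306
```

The comments show the actual printed output of each command.
`sbaenet enrich-targets` and `sbaenet enrich-genesets` run the permutation
enrichment stages on the corresponding artifacts.

## Python API

```python
import pandas as pd
from sbaenet import pharmacovigilance as pv

tables = pd.DataFrame([
    {"drug": "D0001", "event": "E005", "A": 120, "B": 2600, "C": 35, "D": 2700},
    {"drug": "D0002", "event": "E011", "A": 40, "B": 2100, "C": 44, "D": 2300},
])
scored = pv.score_pairs(tables)
print(scored[["drug", "event", "log2ror", "p_adj", "bias"]]
      .round(4).to_string(index=False))
```

Actual output:

```
 drug event  log2ror  p_adj   bias
D0001  E005   1.8321    0.0 female
D0002  E011  -0.0063    1.0   none
```

A pair is called sex-biased when |log2 ROR| > 1 and the BH-adjusted Fisher
p-value is below 0.05 (positive log2 ROR = female-biased). `A`/`C` are
female/male case counts with the drug and event; `B`/`D` the female/male
cases with the drug and any other event.

## Package layout

```
src/sbaenet/
  stats.py              exact tests, BH adjustment, correlation
  io.py                 case tables, GMT, edge lists, expression, config
  simulate.py           seeded synthetic data with recorded ground truth
  pharmacovigilance.py  filtering, contingency tables, ROR scoring
  enrichment.py         permutation feature / gene-set enrichment
  expression.py         sample & CPM filters, sex-aware quantile normalization
  grn.py                message-passing network inference
  communities.py        differential modularity, Louvain, core genes
  netstats.py           degree tests, sex-biased edges, edge typing
  report.py             summary fractions and end-to-end pipeline
  evaluation.py         calibration / recovery studies on synthetic truth
  cli.py                `sbaenet` command-line interface
```

## Testing and validation

```bash
python -m pytest -q tests/
```

The suite covers the statistical primitives against independent enumeration
oracles, every operation's documented edge cases, and end-to-end
calibration/recovery studies (`tests/test_acceptance.py`). Three documented
limitations are asserted at their target levels and currently fail there;
see `docs/methods.md` for the measured behavior and analysis:

- the signed-rank permutation p-value used by the gene-set enrichment is
  anti-conservative for null queries at a few hundred permutations;
- the raw weighted in-degree difference test has limited power against the
  default planted regulation boost;
- differential-modularity scores of a network against itself are small but
  not exactly zero (they equal the network's own modularity residuals).

`scripts/acceptance.py --seed <int> --out <path>` reruns the main validation
studies and writes the headline numbers as JSON.
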