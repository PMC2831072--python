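# bnexpand

Discrete Bayesian-network pathway learning and single-gene expansion for
gene-expression compendia.

Given a genes × samples expression matrix, a seed gene list and free-text
sample annotations, `bnexpand`:

1. **filters** genes by coefficient of variation and **discretizes** each
   gene into equal-frequency (maximum-entropy) terciles;
2. **learns** discrete Bayesian networks over the seed genes by simulated
   annealing over add/delete/reverse edge moves, scored with the
   Cooper–Herskovits (uniform-Dirichlet BDe) log marginal likelihood, with
   random restarts pooling the top distinct networks of each run;
3. builds a **consensus** network from the pool subset sharing the top score
   (edges unanimous in one orientation are directed; skeletons unanimous
   with both orientations present become undirected), optionally comparing
   it against a reference edge list;
4. **expands** a core network one candidate gene at a time: each
   out-of-network gene is attached as an isolated node, a fresh annealing
   run (all edges mutable) finds the best expanded network, and candidates
   are ranked by that score, with optional deeper re-ranking of the leaders
   and reporting of each candidate's induced parent/child edges;
5. runs **term enrichment**: sample annotations are tokenized into words,
   samples fall into the discretization bins of a chosen gene pair, and
   term-by-bin association is scored with Fisher's exact test
   (Benjamini–Hochberg adjusted);
6. can **simulate** fully specified ground-truth instances (random DAGs,
   sharpened CPTs, Gaussian per-state emissions, planted hidden regulators,
   noise candidates, planted metadata terms) so the whole pipeline is
   testable without external data.

The annealing inner loop is JIT-compiled with numba and uses its own
splitmix64 PRNG, so every search is bit-reproducible given a seed, across
runs and platforms.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based release criteria (exact
oracle equivalence of the score, enumerated-optimum search checks, planted
regulator and planted term recovery, byte-level CLI determinism); the other
files are per-module unit and property tests. The exact-arithmetic oracles
live in `tests/oracles.py` and use stdlib rationals only.

## CLI

All subcommands accept the global `--seed`, `--config <file>` (key=value
lines that override option defaults) and `--log-level`:

```sh
bnexpand --seed 1 simulate --nodes 8 --samples 300 --plant-regulator \
    --noise-candidates 20 --term biofilm --out-dir sim/

bnexpand filter     --matrix expr.tsv --threshold 1.0 --out kept.tsv
bnexpand discretize --matrix kept.tsv --levels 3 --out states.tsv --edges-out edges.tsv

bnexpand --seed 1 learn --states states.tsv --genes seeds.txt \
    --networks-per-run 100000 --restarts 10 --keep-top 5 \
    --out-pool pool.json --out-best best.sif

bnexpand consensus --pool pool.json --tolerance 1e-6 \
    --reference ref.tsv --out consensus.sif --out-report report.json

bnexpand --seed 1 expand --states states.tsv --core best.sif \
    --candidates candidates.txt --screen-budget 100000 \
    --rerank-top 200 --rerank-reps 150 \
    --out ranking.tsv --out-json expand.json --out-induced induced.tsv

bnexpand enrich --states states.tsv --metadata meta.tsv \
    --gene-a uspE --gene-b gadX --min-term-count 3 --out enrich.tsv
```

File formats: expression/state matrices are tab-delimited with genes as
rows (first column) and samples as columns (first row); gene lists are one
id per line (`#` comments allowed); metadata is a TSV with columns
`sample_id`, `title`, `description`; networks are SIF (`A<TAB>-><TAB>B`
directed, `A<TAB>--<TAB>B` undirected) or three-column TSV; result bundles
are TSV plus JSON with a `schema_version` field.

## Library layout

| module | contents |
| --- | --- |
| `bnexpand.io_formats` | matrix/list/metadata/network readers and writers |
| `bnexpand.preprocess` | `cv_filter`, `q3_discretize`, `DiscreteMatrix` |
| `bnexpand.scoring` | `Dag`, family counts, BDe log score, cached `Scorer` |
| `bnexpand.search` | `SearchConfig`, `anneal_run`, `multi_restart_search`, `NetworkPool` |
| `bnexpand.consensus` | `top_group`, `build_consensus`, `compare_to_reference` |
| `bnexpand.expansion` | `seed_expanded_dag`, `expand_one`, `bn_plus_one`, `rerank_top` |
| `bnexpand.enrichment` | `tokenize`, `assign_bins`, `fisher_pvalue`, `enrich_gene_pair` |
| `bnexpand.synthetic` | ground-truth DAG/CPT/sample/metadata generators |
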