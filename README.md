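# simdti

Similarity-based compound–target interaction prediction with
likelihood-ratio scoring, plus the downstream "network pharmacology"
layer: hypergeometric gene-set enrichment, Benjamini–Hochberg correction,
ingredient–target–pathway/disease association networks and multi-cluster
comparison.

## Method overview

For a query compound–protein pair, each of up to 18 classification
features (6 drug–drug similarity measures × 3 protein–protein measures)
is the **maximum similarity product** over a reference set of known
positive interactions: `max over (d', t') of S_drug(d, d') · S_prot(t, t')`,
with the query pair itself always excluded as its own reference.
Per-feature **likelihood ratios** are estimated on equal-width bins from a
golden-standard positive set (GSP) versus an equal-size randomly sampled
negative set (GSN); features are selected by greedy **mRMR** (difference
form, default 8 features) and a pair's score is the **maximum LR** across
the selected features. Candidate targets above a user `Score_cutoff`,
unioned with known targets, form the "potential targets" consumed by the
enrichment and network stages.

Similarity measures: Tanimoto (bit fingerprints), weighted Tanimoto
(functional-group counts), Jaccard (side-effect and GO term sets), ATC
level-prefix/5, rescaled Pearson (expression signatures), normalized
Smith–Waterman (BLOSUM62, gap open 10 / extend 1), shortest-path decay
(0.5^d) on a PPI network; text-mining association scores are ingested as
a precomputed matrix. Missing data is `NaN`, never zero-imputed.

Evaluation: leave-one-interaction-out CV (exact per-fold refitting via a
count-delta scheme, verified against naive refitting), leave-one-drug-out
CV ("ab initio" prediction) and an independent-test protocol, all pooled
into Mann–Whitney ROC/AUC.

## Layout

| module | contents |
|---|---|
| `simdti.similarity` | the 9 similarity measures, matrix builders, feature tables |
| `simdti.predictor` | GSN sampling, LR estimation, mRMR, max-LR scoring/ranking |
| `simdti.evaluation` | loio/lodo CV, independent test, ROC/AUC |
| `simdti.enrichment` | hypergeometric upper tail, BH, `enrich`, reverse term index |
| `simdti.network` | association network assembly, Venn partition, graph export |
| `simdti.fixtures` | synthetic planted-module universes and gene sets |
| `simdti.io` | TSV/GMT/FASTA/edge-list readers and writers |
| `simdti.cli` | `simdti` command-line interface |

## CLI

```sh
# synthetic universe (similarity TSVs, GSP, GMT gene sets, clusters)
simdti simulate --out-dir data --seed 7

# train an LR model
simdti train --gsp data/gsp.tsv \
  --drug-sim fp2=data/drug_sim_fp2.tsv --drug-sim atc=data/drug_sim_atc.tsv \
  --prot-sim sequence=data/prot_sim_sequence.tsv --prot-sim go=data/prot_sim_go.tsv \
  --out model.json --seed 1

# cross-validate
simdti evaluate --scheme loio --gsp data/gsp.tsv \
  --drug-sim fp2=data/drug_sim_fp2.tsv --prot-sim go=data/prot_sim_go.tsv \
  --out-dir eval --seed 1

# full analysis for one or more ingredient clusters
simdti analyze --model model.json --gsp data/gsp.tsv \
  --drug-sim fp2=data/drug_sim_fp2.tsv --prot-sim go=data/prot_sim_go.tsv \
  --ingredients herbA=data/cluster0.txt --ingredients herbB=data/cluster1.txt \
  --gene-sets pathway=data/gene_sets_pathway.gmt \
  --score-cutoff 2.0 --out-dir analysis

# reverse index: term -> formulas significantly associated with it
simdti function2tcm --analysis f1=analysis/herbA/enrichment_pathway.json \
  --out function2tcm.json
```

Exit codes: 0 ok, 2 input error, 3 invariant violation.

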