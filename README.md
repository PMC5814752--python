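# probefit

Objective, quantitative assessment of chemical probes from raw bioactivity
tables. `probefit` aggregates compound–target bioactivity measurements into
median pActivities (with censored-value handling and MAD dispersion), computes
six fitness-factor scores — potency, selectivity, cell activity, SAR,
inactive-analog availability and PAINS-freedom — plus a weighted Global Score
per compound–reference-target pair, and derives target-level summaries:
quality icons, minimum-standard probe counts, Information Richness and
liganded-proteome statistics.

## Concepts

* **pActivity** — −log10 of an activity concentration in molar units
  (100 nM ↔ 7). Per pair, the median over all `=` and `>` records is taken,
  capped at 10; pairs are *active* when the capped median exceeds 5 and the
  `=`/`>` evidence does not conflict.
* **Selectivity score** — mean of three factors: fraction of 10-fold-selective
  off-targets, a per-target min–max-normalized term built on the SIC
  statistic (sum over off-targets of Δ pActivity − 1), and the screened
  fraction of the liganded proteome. No off-target data ⇒ score 0.
* **Global Score** — weighted mean of the six components; default weights are
  selectivity 8, potency 4, cell 2, SAR/inactive-analog/PAINS 1. Setting a
  weight to 0 (e.g. `--weights f=0`) removes that factor.
* Two selectivity semantics coexist by design: the target *selectivity icon*
  requires at least one selective off-target (existence reading), while the
  *minimum standard* requires 10-fold selectivity against **all** tested
  off-targets. They are reported separately, never harmonized.

## CLI

```sh
# generate a deterministic synthetic landscape with one dominant planted probe
probefit simulate --seed 7 --targets 20 --compounds 200 \
    --planted C0042:T007 --out scratch/landscape

# score it: rankings, icons, Information Richness, proteome summary
probefit score --input scratch/landscape/measurements.tsv \
    --smiles scratch/landscape/compounds.smi --out scratch/run

# single-probe synopsis (scores, rank, selectivity breakdown, profile)
probefit probe-card --run scratch/run --compound C0042 --target T007

probefit summarize --run scratch/run
```

`score` accepts a flat `key = value` config file (`weights.a` … `weights.f`,
`order_key`, `liganded_target_count`, `proteome_size`); CLI flags override
config. Every run writes its resolved configuration, a machine-readable
rejects report and per-target ranked TSV/JSON (with all selectivity
intermediates) into the output directory; outputs are bit-reproducible from
inputs plus config.

Input tables are TSV (CSV selectable via `--sep`) with header columns
`compound_id, target_accession, assay_kind, cell_line_id, qualifier, value,
units, activity_type, pubmed_id, smiles`; structures may instead come from a
`.smi` or SDF file keyed by compound id. Units must be convertible to nM
(pM/nM/µM/mM/M); other rows are rejected with a reason, never silently
dropped.

## Package layout

| module | role |
| --- | --- |
| `probefit.ingest` | table parsing, unit normalization, pActivity, per-pair aggregation |
| `probefit.scoring` | the six fitness factors, Global Score, ranking, danger flag |
| `probefit.structures` | level-1 scaffolds, PAINS alerts, SAR / inactive-analog scores |
| `probefit.assess` | target icons, Information Richness, minimum standard, proteome summary |
| `probefit.synth` | deterministic synthetic landscapes and hand-computed toy fixtures |
| `probefit.pipeline` | orchestration (`run_scoring`) |
| `probefit.cli` | `probefit score / probe-card / simulate / summarize` |
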