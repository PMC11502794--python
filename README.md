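# epipattern

Differential multi-omic analysis of DNA methylation (5mC), hydroxymethylation
(5hmC) and gene expression, with combinatorial pattern tracking across
cell-differentiation stages.

The package models a common neuro-epigenetics study design: two neural
stem-cell derivative lines (glial-biased and neural-biased), each profiled
undifferentiated and after differentiation in normal medium (DM) or in
macrophage-conditioned, inflammatory medium (Mac-CM), with two biological
replicates per (line, condition) and three assays:

- **RRBS** per-CpG methylated/total read counts (5mC),
- **RRHP** strand-specific CCGG tag counts (5hmC), and
- **RNA-seq** gene counts.

It provides, in the statsmodels idiom (a model object whose `fit()` returns a
results object with `summary()`):

| Question | Model / function |
| --- | --- |
| Which CpGs change methylation? | `BetaBinomialDML` — beta-binomial Wald test with empirical-Bayes dispersion shrinkage |
| Which CCGG tags / genes change? | `NegativeBinomialDE` — NB Wald test, median-of-ratios size factors, mean-dispersion trend shrinkage |
| Which genes do these loci belong to? | `extend_and_merge` (±2 kb, half-open BED) + `assign_regions_to_genes` |
| What multi-omic pattern does each gene show? | `modality_pattern` — the 7 non-empty subsets of {RNA, 5mC, 5hmC} |
| Is a gene trackable across stages? Does it switch 5mC↔5hmC? | `classify_trackability`, `detect_switch` |
| Does the whole analysis recover known signal? | `simulate_dataset` (planted truth) + `run_pipeline` |

Exploratory utilities (`pca_embed`, `hierarchical_cluster`,
`ddct_fold_change`, `log2_normalized`) cover the usual QC companion plots and
qPCR-style relative quantification.

## Worked example

Simulate a coordinated dataset with planted effects, then test one
comparison:

```python
from epipattern import SimulationConfig, BetaBinomialDML, simulate_dataset
from epipattern.design import samples_for

ds = simulate_dataset(SimulationConfig(n_genes=120, seed=7))
undiff = samples_for(ds["design"], line="glial", condition="undiff")
maccm = samples_for(ds["design"], line="glial", condition="MacCM")

results = BetaBinomialDML.from_table(ds["rrbs"], undiff, maccm).fit()
print(results.summary())
```

```
Beta-binomial differential methylation (Wald test)
==================================================
loci tested:        478 of 480 (coverage >= 5 in all samples)
alpha (BH):         0.05
min |delta|:        0.1
significant DML:    9
  gain (delta > 0): 8
  loss (delta < 0): 1
median dispersion:  0.0800
```

```python
print(results.significant.head(5).to_string(
    index=False, columns=["chrom", "pos", "delta", "padj"],
    float_format="%.4g"))
```

```
chrom    pos  delta     padj
 chr1 221642 0.4967  0.03362
 chr1 373020 0.4729  0.02419
 chr1 462044 0.4277  0.04951
 chr1 512493 0.5219 0.005918
 chr1 694332 0.4801  0.04321
```

The full pipeline chains the three differential tests, gene annotation,
pattern classification and switch detection, and scores everything against
the planted truth:

```python
from epipattern.pipeline import PipelineConfig, run_pipeline
from epipattern.simulate import SimulationConfig

cfg = PipelineConfig(simulation=SimulationConfig(n_genes=120),
                     seed=7, out_dir="out")
summary = run_pipeline(cfg)
print(summary["patterns"]["switch_counts"])
print(summary["recovery"]["switch"])
```

```
{'gain5mC_loss5hmC': 4, 'gain5hmC_loss5mC': 1, 'none': 35}
{'n_true': 18, 'n_recovered': 5, 'sensitivity': 0.2777..., 'n_false_switch_calls': 0}
```

Note the honest numbers: with two replicates per cell and a methylation
dispersion of 0.1, per-CpG methylation tests have limited power, so only a
fraction of the planted reciprocal switches is recovered — with zero false
switch calls. `docs/methods.md` quantifies these power limits.

The same pipeline is available from the command line:

```
epipattern simulate --out data --seed 7
epipattern dml  --counts data/rrbs_counts.tsv --design data/design.tsv \
    --group-a glial_undiff_r1,glial_undiff_r2 \
    --group-b glial_MacCM_r1,glial_MacCM_r2 --out dml.tsv
epipattern run --out out --seed 7
```

All thresholds and generator parameters can be set in a YAML config (see
`examples/default_config.yaml` for the full default file):

```
epipattern run --config examples/default_config.yaml --out out --seed 7
```

## Outputs

`run_pipeline` writes, under `out_dir`: the input tables and truth records,
per-comparison `dml_*.tsv` / `dhml_*.tsv` / `deg_*.tsv`, merged-region BED
files, `gene_hits.tsv` / `tf_hits.tsv`, `track_records.tsv`,
`switch_calls.tsv`, `pattern_summary.tsv` and a machine-readable
`summary.json` that is byte-identical across runs with the same seed.

## Reproduction

```
python -m pytest -q tests/          # unit, property and acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script regenerates all headline quantities (calibration,
recovery, oracle agreement, determinism) from scratch at the given seed and
prints them as JSON; it takes a few seconds on one CPU.

Two acceptance assertions are expected to fail, deliberately: per-CpG DML
sensitivity ≥ 0.80 and reciprocal-switch recovery ≥ 95% are not attainable
at the study's design (methylation difference 0.30, coverage 30, dispersion
0.1, two or three replicates per group) by any calibrated test; the
assertions are kept at those thresholds rather than weakened. See
`docs/methods.md` ("Power limits") for the analysis.

## Methods

See `docs/methods.md` for the statistical models, the dispersion-shrinkage
and standard-error corrections, the generator's parameter choices and their
rationale, and known limitations.
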