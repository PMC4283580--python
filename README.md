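# funnorm

Functional normalization for two-color Infinium-style DNA methylation
arrays (450k-class), with the surrounding toolkit a methylation study
needs: noob-style background correction, control-probe quality summaries,
detection QC, probe-wise DMP calling, discovery–validation replication
benchmarks, and a synthetic-data generator with known ground truth.

## Who this is for, and the idea

Population-scale methylation studies — cancer cohorts in particular — are
caught between two failure modes at the normalization step. Batch effects
(plate, slide, position) distort each sample's marginal intensity
distribution and corrupt probe-level inference; but aggressive fixes such
as quantile normalization force all marginals to be identical and thereby
erase genuine genome-wide biology like the global hypomethylation of
tumors.

Functional normalization threads the needle. Each sample's methylated (M)
and unmethylated (U) intensity distributions are summarized by their
empirical quantile functions q_i^emp on a dense grid, and a
function-on-scalar regression

    q_i^emp(r) = α(r) + Σ_j Z_ij β_j(r) + ε_i(r)

is fitted pointwise on the grid. The covariates Z (default: the first m = 2
principal components of 42 control-probe summary measures) see only
technical variation, because control probes measure no biology. Only the
covariate-explained part is removed,

    q_i^norm(r) = q_i^emp(r) − Σ_j Z_ij β̂_j(r),

and values are pushed through q_i^norm ∘ (q_i^emp)⁻¹, preserving
within-sample ranks. With m = 0 nothing changes; with saturated covariates
the method collapses to quantile normalization — the two ends of the
trade-off it interpolates. Beta values use the standard β = M/(M+U+100).
The pipeline applies the fit in four autosomal strata ({M, U} × probe type
I/II) with the same Z, normalizes X within each sex, and quantile-normalizes
the small Y stratum within each sex. See `docs/methods.md` for the full
model, conventions and limitations.

## Worked example

Simulate a confounded discovery–validation pair, normalize both cohorts
separately, and measure how well the top DMPs replicate:

```python
from funnorm import (SimulationConfig, make_discovery_validation,
                     preprocess_funnorm, find_dmps, roc_vs_gold)
from funnorm.evaluation import ranking_from_dmps

cfg = SimulationConfig(seed=1, n_samples=40, n_dmp=200)
discovery, validation = make_discovery_validation(cfg)

rankings = {}
for name, cohort in (("discovery", discovery), ("validation", validation)):
    res = preprocess_funnorm(cohort.channels, cohort.manifest,
                             cohort.samplesheet, m=2, H=500,
                             background="noob")
    dmps = find_dmps(res.beta, cohort.truth.group.to_numpy())
    rankings[name] = ranking_from_dmps(dmps)

gold = set(rankings["discovery"][:200])
print(f"replication AUC: {roc_vs_gold(gold, rankings['validation']).auc:.3f}")
hits = len(gold & set(validation.truth.dmp_probes))
print(f"true DMPs in discovery top-200: {hits}/200")
```

Output:

```
replication AUC: 0.996
true DMPs in discovery top-200: 199/200
```

The validation cohort's cases and controls sit on disjoint plates (a
worst-case batch confounding), yet the separately normalized cohorts agree
almost perfectly on the top DMPs (AUC 0.996); running the same code with
raw beta values instead of `preprocess_funnorm` drops the AUC to about
0.91 (and to ~0.83 on average over seeds). The discovery top-200 itself
contains 199 of the 200 planted DMPs.

The same steps are available from the shell:

```sh
funnorm simulate --seed 1 --out-dir sim/
funnorm normalize --green sim/green.tsv --red sim/red.tsv \
    --manifest sim/manifest.tsv --samplesheet sim/samples.csv \
    --m 2 --background noob --out-prefix run1
funnorm dmp --beta run1.beta.tsv --samplesheet sim/samples.csv --out dmps.tsv
funnorm evaluate roc --discovery dmps.tsv --validation dmps.tsv \
    --gold-k 200 --out roc.tsv
```

Every run writes a provenance JSON (tool version, parameters, input
digests) next to its outputs.

## Layout

| Module | Contents |
| --- | --- |
| `funnorm.data_model` | manifest/sample-sheet/channel containers and I/O, raw matching, beta values, detection QC, locus filtering |
| `funnorm.controls` | 42-measure control summaries, PCA covariates, batch-association report |
| `funnorm.core` | quantile grid, function-on-scalar fit, covariate removal, value transform |
| `funnorm.background` | normal+exponential out-of-band correction, dye-bias equalization |
| `funnorm.pipeline` | `preprocess_funnorm`, sex prediction, spatial diagnostics |
| `funnorm.evaluation` | DMP calling, ROC/concordance, replicate variance, effect sizes, subsampling |
| `funnorm.simulate` | synthetic datasets with ground truth; discovery–validation construction |
| `funnorm.benchmarks` | end-to-end benchmark scenarios shared by tests and the acceptance script |
| `funnorm.cli` | `funnorm` command: simulate / summarize-controls / normalize / dmp / evaluate |
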