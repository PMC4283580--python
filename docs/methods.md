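# Methods

## The problem

Two-color Infinium-style methylation arrays (450k-class) estimate, for each
CpG probe, a methylated intensity M and an unmethylated intensity U; the
methylation proportion is β = M/(M+U+100). Population-scale studies —
especially cancer studies — face two conflicting pressures at the
normalization step. Batch effects (plate, slide, position, scanner drift)
distort the marginal intensity distributions of individual samples, which
corrupts probe-level inference. But genuinely global biology exists too:
cancers are typically hypomethylated genome-wide, so forcing every sample to
a common marginal distribution (quantile normalization) erases real signal.
Functional normalization resolves the tension by removing **only** the part
of each sample's marginal distribution that technical surrogates can
explain.

## Model

Let q_i^emp be the empirical quantile function of sample i's intensities
(M and U channels treated separately) and Z the n × m matrix of technical
covariates. The function-on-scalar model is

    q_i^emp(r) = α(r) + Σ_j Z_ij β_j(r) + ε_i(r),   r ∈ [0, 1],

fitted by ordinary least squares independently at each of the H+1 grid
points {d/H : d = 0..H} (default H = 500). Because empirical quantile
functions of high-dimensional continuous data have tiny jumps, neighboring
grid fits vary smoothly and no penalized smoothing is needed; between grid
points the coefficient functions are defined by linear interpolation. The
normalized quantile functions are

    q_i^norm(r) = q_i^emp(r) − Σ_j Z_ij β̂_j(r)

and each sample's values are pushed through
q_i^norm ∘ (q_i^emp)⁻¹, which preserves within-sample ranks and gives the
normalized values q_i^norm as marginal quantile function up to interpolation
error. Two limits anchor the method and are enforced by tests: m = 0 leaves
the data untouched, and a saturated Z reduces exactly to quantile
normalization (every sample mapped to the mean quantile function α̂).

## Covariates: control-probe summaries

The covariates are the first m = 2 principal components of a per-sample
summary of the array's control probes and out-of-band readings — probes
that hybridize to no genomic target and therefore measure technical state
only. The shipped summary scheme has 42 measures: 38 per-category,
per-channel means of log2(1+intensity) over the control categories
(bisulfite conversion I/II, specificity I/II, extension and non-polymorphic
probes per base in both channels, hybridization levels, target removal,
staining, restoration, normalization probes per base in their design
channel, negative controls per channel), plus the mean and 1st percentile of
log2(1+intensity) of the out-of-band values in each channel. The exact
composition of such control summaries is a package convention rather than a
published standard; the scheme is a plain data structure and can be replaced
via a YAML file (`controls.load_scheme`) when cross-implementation
concordance against another toolchain is needed. Columns are standardized
before the PCA (measures live on different scales), zero-variance columns
are dropped with a warning, and each component's sign is fixed by making its
largest-magnitude loading positive so results do not depend on the linear
algebra backend. Control summaries are always computed from the **raw**
control intensities, even when background correction is enabled: the
covariates are meant to capture the raw technical state of the array, while
the correction order applies to the signal probes.

m is user-settable; 2 is the default because the first two components
capture plate-scale background and dye variation in practice while leaving
little room to absorb biology. m = 0 is the no-normalization limit; larger
m removes more variation and approaches quantile normalization.

## The 450k-style pipeline

`preprocess_funnorm` runs, in order: raw channel-to-probe matching; optional
noob background correction and dye-bias equalization (the recommended
pre-step, `background="noob"`); control summaries and Z; then functional
normalization in four autosomal strata — {M, U} × {type I, type II} — all
sharing the same Z, because the two probe chemistries have different
intensity distributions. Sex chromosomes are handled separately: X probes
are normalized within males and within females (still split by probe type),
since X methylation differs systematically between the sexes; Y probes are
quantile-normalized within each sex because a handful of probes cannot
support a stable quantile-function regression. The same instability guard
generalizes to any stratum with fewer than 2(m+2) probes and to sex groups
with fewer than m+2 samples, which fall back to quantile normalization with
a warning. Covariate removal can push the lowest quantiles slightly
negative; normalized intensities are floored at zero so β stays in [0, 1].

Numerical conventions worth stating: empirical quantiles use continuous
order-statistic ("type 7") interpolation with q(0) = min and q(1) = max;
the inverse of a piecewise-linear quantile function maps a value on a flat
stretch to the midpoint of its plateau (symmetric and deterministic);
values outside the fitted range — possible only when a fit is reused on new
values — are clamped to the endpoints; and normalized quantile functions are
re-monotonized by sorting, the one-dimensional pool-adjacent repair, which
preserves each row's value multiset. Subtracting Σ Z β̂ can in fact break
monotonicity, so the repair is on by default.

## Background correction (noob-style)

Observed in-band intensities are modeled per sample and channel as
X = S + B, S ~ Exponential(α), B ~ Normal(µ, σ²). The out-of-band readings
of type I probes (their intensities in the opposite color channel) are pure
background draws, so µ and σ are estimated from them robustly — median and
MAD — rather than by maximum likelihood; α is the mean excess of the
observed values over µ, floored at a small positive value. Each value is
replaced by the posterior mean E[S | X = x], the mean of a normal truncated
to the positive axis:

    µ_sx = x − µ − σ²/α,    E[S|X=x] = µ_sx + σ·φ(µ_sx/σ)/Φ(µ_sx/σ),

computed via `scipy.special.log_ndtr` in log space so deep-background values
underflow gracefully instead of producing NaNs; a quadrature oracle verifies
the closed form to 1e-6 relative in the tests. A +15 offset is added after
correction. No locus is ever dropped here — detection filtering is a
separate, explicit step (`detection_qc`). Dye bias is then equalized per
sample: each channel is scaled so that the mean intensities of the red and
green normalization controls meet at their within-sample geometric mean.
The per-sample reference keeps samples independent, as an unsupervised
normalization requires, and makes the step exactly idempotent.

## Detection QC and locus filtering

The detection p-value of a locus is the upper-tail probability of its total
intensity M+U under a Normal background whose mean is the sum of the
per-channel negative-control medians and whose sd is the sum of the
per-channel MAD-based sds, per sample. A locus with p > 0.01 is undetected;
a sample fails QC when more than 10% of its loci are undetected. Loci known
to be problematic (SNP-overlapping, cross-hybridizing) are removed
**after** normalization via user-supplied id lists (`filter_loci`): such
probes still carry technical information useful for normalization even if
they should not enter inference.

## DMP calling and replication metrics

DMPs are ranked by probe-wise F-statistics for a group factor in a linear
model on β (optionally adjusting for a plate factor); ties are broken
lexicographically by probe id. The replication framework treats the top-k
DMPs of a separately normalized discovery cohort as gold standard and
scores the validation cohort's ranking with an ROC curve (trapezoidal AUC,
via scikit-learn) and a top-k concordance curve (percentage overlap,
evaluated on a log-spaced k grid by default). Sweeping the ranking by F or
by p-value is equivalent; F is used. Where a fixed-size gold set is not
wanted, Benjamini–Hochberg FDR control is the supported selection rule.
Technical quality is summarized by the probe-wise within-replicate-group
variance averaged over groups, effect sizes as group-mean β differences of
top-ranked probes, and a balanced subsampling scheme (B draws of n/2
samples per group, pointwise mean ROC with 0.025/0.975 percentile bands on
a common false-positive-rate grid).

## Synthetic data: what it emulates and what it does not

Real benchmark datasets for this problem are controlled-access, so the test
bed is a generator with known ground truth. It emulates: a bimodal
methylome (latent β from a Beta(0.5,8)/Beta(8,0.5) mixture); lognormal
probe intensities (median 4000, log-sd 0.25) over an additive Normal
background (mean 400, sd 60); true DMPs (default 200 probes shifted by 0.12
on the β scale — a realistic epigenome-wide effect size — with a 0.05
per-sample biological β noise); an optional genome-wide hypomethylation
shift; the full 848-probe control complement at real-design category counts
(613 negative, 186 normalization split 61/61/32/32 by base, 49 others);
plate effects that shift the background mean per channel (amplitude 250)
and tilt the green/red dye balance (log-amplitude 0.12), applied to signal,
control and out-of-band values alike and never to biology; slide layout
with an optional row gradient; sex chromosomes (males at half X/Y copy
intensity, females with Y at pure background); and technical replicates
that share a latent sample and redraw only technical noise. Plate effects
have a systematic per-plate component of the stated amplitude plus 25%
random jitter: a purely random draw could make two plates coincide by
chance, which is not the "plates that differ" condition being modeled.

The default discovery–validation construction balances groups across plates
in the discovery cohort and assigns cases and controls to disjoint plates in
the validation cohort, the in-silico confounding that a robustness benchmark
needs. Both cohorts share probe-level truth through a common random
sub-stream; all randomness descends from one seed via SeedSequence
spawn-keys, so every artifact is reproducible from its seed.

What the generator does **not** model: cell-type heterogeneity and other
biological unwanted variation (invisible to control probes by construction),
probe-sequence effects (GC content, cross-hybridization), spatial artifacts
beyond a row gradient, intensity saturation, and the 485k-probe scale.
Passing benchmarks therefore demonstrate the machinery removes the kinds of
technical variation that control probes can see, at desk scale — not that
any particular real dataset will replicate at a particular rate.

## Problem sizes used in the shipped benchmarks

The replication benchmark uses five seeds of paired 40-sample cohorts with
10,000 probes and 200 true DMPs; the global-shift benchmark one 40-sample
dataset with a 0.15 median-β shift; the replicate-variance benchmark five
seeds of 18 base samples with six triplicate groups over three plates; the
background-recovery check 100,000 simulated values. These sizes give stable
statistics while keeping a full run of the suite and the acceptance script
in the minutes range on a single core.

The global-shift benchmark runs both funnorm and the quantile comparator
without background correction: removing the additive background
deliberately de-attenuates β differences, so a "within 20% of raw"
comparison is only meaningful when all three pipelines share the raw
background. The quantile-normalization comparator is the saturated/mean
case of this package's own engine, not a reimplementation of any external
stratified variant.

## Known limitations

* The 42-measure control scheme matches the documented 38+4 structure but
  is not bit-compatible with any other implementation's summary values.
* The noob step uses robust moment estimation, not the MLE of the
  normal+exponential convolution; on simulated data the parameters are
  recovered well within 5%, but estimates differ from an MLE in the tails.
* Samples of unknown sex are rejected when sex-chromosome probes are
  present and the sample sheet is the sex source; prediction
  (`sex_source="predicted"`) is the supported path for unlabeled data.
* IDAT binaries are out of scope; the readers consume plain TSV/CSV tables
  and an adapter can be placed in front of them.
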