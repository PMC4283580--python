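"""End-to-end benchmark scenarios on synthetic data.

Each function builds a dataset with known ground truth, runs the package's
own pipeline(s) and measures an interpretable quantity: discovery-validation
replication under confounded batch effects, preservation of a global
methylation shift, technical-replicate variance, and recovery of the
background model.  They are shared by the test suite and the acceptance
script so both report numbers computed by exactly the same code path.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_model import beta_values, preprocess_raw
from .background import fit_normexp, normexp_correct
from .evaluation import batch_r2, find_dmps, ranking_from_dmps, roc_vs_gold
from .pipeline import (BACKGROUND_NONE, BACKGROUND_NOOB, ENGINE_QUANTILE,
                       preprocess_funnorm)
from .simulate import (SimulatedDataset, SimulationConfig,
                       make_discovery_validation, simulate_dataset)


def _beta_for(dataset: SimulatedDataset, method: str, m: int = 2, H: int = 500):
    """Beta values for one cohort under one processing method."""
    if method == "raw":
        return beta_values(preprocess_raw(dataset.channels, dataset.manifest))
    if method == "funnorm":
        res = preprocess_funnorm(dataset.channels, dataset.manifest,
                                 dataset.samplesheet, m=m, H=H,
                                 background=BACKGROUND_NOOB)
        return res.beta
    if method == "funnorm_raw_bg":
        res = preprocess_funnorm(dataset.channels, dataset.manifest,
                                 dataset.samplesheet, m=m, H=H,
                                 background=BACKGROUND_NONE)
        return res.beta
    if method == "quantile":
        res = preprocess_funnorm(dataset.channels, dataset.manifest,
                                 dataset.samplesheet, m=m, H=H,
                                 background=BACKGROUND_NONE,
                                 engine=ENGINE_QUANTILE)
        return res.beta
    raise ValueError(f"unknown method {method!r}")


def _sample_quantile_features(dataset: SimulatedDataset, method: str,
                              n_points: int = 51) -> np.ndarray:
    """Per-sample marginal quantiles of M and U, concatenated, as features
    for the plate-association R2."""
    if method == "raw":
        mset = preprocess_raw(dataset.channels, dataset.manifest)
    else:
        mset = preprocess_funnorm(dataset.channels, dataset.manifest,
                                  dataset.samplesheet,
                                  background=BACKGROUND_NOOB).mset
    grid = np.linspace(0.0, 1.0, n_points)
    qm = np.quantile(mset.M.to_numpy(), grid, axis=0).T
    qu = np.quantile(mset.U.to_numpy(), grid, axis=0).T
    return np.hstack([np.log2(1 + qm), np.log2(1 + qu)])


@dataclasses.dataclass
class ReplicationResult:
    auc_funnorm: list[float]
    auc_raw: list[float]
    r2_raw: list[float]
    r2_funnorm: list[float]

    @property
    def mean_auc_funnorm(self) -> float:
        return float(np.mean(self.auc_funnorm))

    @property
    def mean_auc_raw(self) -> float:
        return float(np.mean(self.auc_raw))

    @property
    def r2_reduction(self) -> float:
        return float(1.0 - np.mean(self.r2_funnorm) / np.mean(self.r2_raw))


def confounded_replication(seeds: list[int],
                           n_samples: int = 40,
                           n_dmp: int = 200) -> ReplicationResult:
    """Discovery-validation replication with group confounded by plate in
    the validation cohort.

    For each seed and each method the discovery cohort's top-``n_dmp`` DMPs
    are the gold standard, the separately processed validation cohort is
    ranked, and the ROC AUC measures internal consistency.  Also reports the
    plate-association R2 of the validation cohort's sample quantiles before
    and after normalization.
    """
    res = ReplicationResult([], [], [], [])
    for seed in seeds:
        cfg = SimulationConfig(seed=seed, n_samples=n_samples, n_dmp=n_dmp)
        discovery, validation = make_discovery_validation(cfg)
        for method, auc_list in (("funnorm", res.auc_funnorm),
                                 ("raw", res.auc_raw)):
            rankings = {}
            for name, cohort in (("disc", discovery), ("valid", validation)):
                beta = _beta_for(cohort, method)
                groups = cohort.truth.group.to_numpy()
                dmps = find_dmps(beta, groups)
                rankings[name] = ranking_from_dmps(dmps)
            gold = set(rankings["disc"][:n_dmp])
            auc_list.append(roc_vs_gold(gold, rankings["valid"]).auc)
        plates = validation.samplesheet.table["plate"].to_numpy()
        res.r2_raw.append(batch_r2(
            _sample_quantile_features(validation, "raw"), plates))
        res.r2_funnorm.append(batch_r2(
            _sample_quantile_features(validation, "funnorm"), plates))
    return res


@dataclasses.dataclass
class GlobalShiftResult:
    diff_raw: float
    diff_funnorm: float
    diff_quantile: float

    @property
    def funnorm_retention(self) -> float:
        return float(self.diff_funnorm / self.diff_raw)

    @property
    def quantile_retention(self) -> float:
        return float(self.diff_quantile / self.diff_raw)


def global_shift_preservation(seed: int, delta: float = 0.15,
                              n_samples: int = 40) -> GlobalShiftResult:
    """Genome-wide hypomethylation of one group, independent of control
    probes: compare how much of the raw between-group difference in
    per-sample median beta survives functional vs quantile normalization.

    Both normalizations run without background correction so that all three
    numbers share the same raw background attenuation and the comparison
    isolates the normalization step.
    """
    cfg = SimulationConfig(seed=seed, n_samples=n_samples, n_dmp=0,
                           global_shift=delta)
    dataset = simulate_dataset(cfg)
    groups = dataset.truth.group

    def group_diff(beta) -> float:
        med = np.median(beta.beta.to_numpy(), axis=0)
        g = groups.to_numpy()
        labels = sorted(set(g))
        return float(med[g == labels[1]].mean() - med[g == labels[0]].mean())

    return GlobalShiftResult(
        diff_raw=group_diff(_beta_for(dataset, "raw")),
        diff_funnorm=group_diff(_beta_for(dataset, "funnorm_raw_bg")),
        diff_quantile=group_diff(_beta_for(dataset, "quantile")),
    )


@dataclasses.dataclass
class ReplicateVarianceResult:
    median_raw: list[float]
    median_funnorm: list[float]

    @property
    def reduction(self) -> float:
        return float(1.0 - np.mean(self.median_funnorm) / np.mean(self.median_raw))


def replicate_variance_reduction(seeds: list[int],
                                 n_samples: int = 18,
                                 replicate_groups: int = 6) -> ReplicateVarianceResult:
    """Technical triplicates dispersed across plates: median probe-wise
    within-triplicate variance of beta, raw vs funnorm."""
    from .evaluation import replicate_variance

    res = ReplicateVarianceResult([], [])
    for seed in seeds:
        cfg = SimulationConfig(seed=seed, n_samples=n_samples, n_dmp=0,
                               replicate_groups=replicate_groups,
                               replicates_per_group=3, n_plates=3)
        dataset = simulate_dataset(cfg)
        sheet = dataset.samplesheet.table
        rep_groups = {}
        for base in sheet.loc[sheet["replicate_of"] == "", "sample_id"]:
            members = [base] + sheet.loc[sheet["replicate_of"] == base,
                                         "sample_id"].tolist()
            if len(members) >= 2:
                rep_groups[base] = members
        for method, store in (("raw", res.median_raw),
                              ("funnorm", res.median_funnorm)):
            beta = _beta_for(dataset, method)
            variances = replicate_variance(beta, rep_groups)
            store.append(float(variances.median()))
    return res


@dataclasses.dataclass
class NoobRecoveryResult:
    mu_error: float      # relative errors of the recovered parameters
    sigma_error: float
    alpha_error: float
    mse_raw: float
    mse_corrected: float


def noob_recovery(seed: int, n: int = 100_000,
                  mu: float = 500.0, sigma: float = 50.0,
                  alpha: float = 2000.0) -> NoobRecoveryResult:
    """Simulated Normal(mu, sigma) background plus Exponential(alpha)
    signal: recover the parameters from out-of-band draws and check that the
    conditional-expectation correction beats the raw values in mean squared
    error against the true signal."""
    rng = np.random.default_rng(seed)
    signal = rng.exponential(alpha, n)
    observed = signal + rng.normal(mu, sigma, n)
    oob = rng.normal(mu, sigma, n)
    params = fit_normexp(observed, oob)
    corrected = normexp_correct(observed, params)
    return NoobRecoveryResult(
        mu_error=abs(params.mu_bg - mu) / mu,
        sigma_error=abs(params.sigma_bg - sigma) / sigma,
        alpha_error=abs(params.alpha_sig - alpha) / alpha,
        mse_raw=float(np.mean((observed - signal) ** 2)),
        mse_corrected=float(np.mean((corrected - signal) ** 2)),
    )


def identity_limit_deviation(seed: int, n_samples: int = 8,
                             H: int = 500) -> float:
    """Maximum relative deviation between raw intensities and the pipeline
    output at m=0 with no background correction, on autosome-only data
    (the Y-chromosome rule is quantile normalization by design, which is not
    an identity, so sex chromosomes are excluded from this limit)."""
    counts = {"autosome.II": 3400, "autosome.I_GREEN": 800,
              "autosome.I_RED": 800}
    cfg = SimulationConfig(seed=seed, n_samples=n_samples, probe_counts=counts,
                           n_dmp=50)
    dataset = simulate_dataset(cfg)
    raw = preprocess_raw(dataset.channels, dataset.manifest)
    res = preprocess_funnorm(dataset.channels, dataset.manifest,
                             dataset.samplesheet, m=0, H=H,
                             background=BACKGROUND_NONE)
    dev = 0.0
    for a, b in ((raw.M, res.mset.M), (raw.U, res.mset.U)):
        av = a.to_numpy()
        bv = b.to_numpy()
        dev = max(dev, float(np.max(np.abs(av - bv) / (np.abs(av) + 1.0))))
    return dev
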