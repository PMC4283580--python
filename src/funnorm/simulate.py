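"""Synthetic two-channel methylation-array datasets with known ground truth.

The generator emulates the features of real 450k-style data that matter for
normalization benchmarking, at desk scale (default 40 samples x 10,000
probes):

* a bimodal methylome: latent probe methylation levels drawn from a
  Beta(0.5, 8) / Beta(8, 0.5) mixture;
* true DMPs (group-shifted probes) and, optionally, a genome-wide
  hypomethylation shift in one group that is independent of control probes;
* the full control-probe complement at real-design counts (613 negative,
  186 normalization split 61/61/32/32 by base, 49 across the remaining
  categories) plus out-of-band readings of type I probes;
* plate-level batch effects — per-plate background-mean shifts per channel
  and a per-plate dye imbalance — that hit signal probes, control probes and
  out-of-band values alike, with no group effect on controls;
* slide layout (6 rows x 2 columns), an optional row-gradient spatial
  effect, sex chromosomes (males: halved X/Y intensity; females: Y at pure
  background) and technical replicates that re-noise the same latent sample.

All randomness flows from a single seed through numpy SeedSequence
spawn-keys: probe-level structure (latent betas, DMP set, probe intensities)
lives on one stream so a discovery and a validation cohort can share the
same truth while drawing sample-level noise independently.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import (DESIGN_I_GREEN, DESIGN_I_RED, DESIGN_II, SEX_FEMALE,
                         SEX_MALE, ChannelData, ProbeManifest, SampleSheet,
                         write_channels, write_manifest, write_samplesheet)
from .errors import ConfigurationError

#: Probes per (chromosome class, design type) stratum; ~10k total.
DEFAULT_PROBE_COUNTS: dict[str, int] = {
    "autosome.II": 6400, "autosome.I_GREEN": 1600, "autosome.I_RED": 1600,
    "X.II": 240, "X.I_GREEN": 40, "X.I_RED": 40,
    "Y.II": 60, "Y.I_GREEN": 10, "Y.I_RED": 10,
}

#: Control probes at real-design counts (848 total: 613 negative, 186
#: normalization, 49 remainder).
DEFAULT_CONTROL_COUNTS: dict[str, int] = {
    "NEGATIVE": 613,
    "NORM_A": 32, "NORM_G": 32, "NORM_C": 61, "NORM_T": 61,
    "BISULFITE_I": 10, "BISULFITE_II": 4,
    "SPECIFICITY_I": 12, "SPECIFICITY_II": 3,
    "EXTENSION_A": 1, "EXTENSION_C": 1, "EXTENSION_G": 1, "EXTENSION_T": 1,
    "HYB_LOW": 1, "HYB_MEDIUM": 1, "HYB_HIGH": 1,
    "TARGET_REMOVAL_1": 1, "TARGET_REMOVAL_2": 1,
    "STAINING": 6,
    "NON_POLYMORPHIC_A": 1, "NON_POLYMORPHIC_C": 1,
    "NON_POLYMORPHIC_G": 1, "NON_POLYMORPHIC_T": 1,
    "RESTORATION": 1,
}

#: Characteristic control signal per category, (green, red), background
#: excluded.  Zero entries are pure-background readouts in that channel.
CONTROL_SIGNAL: dict[str, tuple[float, float]] = {
    "NEGATIVE": (0.0, 0.0),
    "NORM_A": (0.0, 8000.0), "NORM_T": (0.0, 8000.0),
    "NORM_C": (8000.0, 0.0), "NORM_G": (8000.0, 0.0),
    "BISULFITE_I": (3000.0, 3000.0), "BISULFITE_II": (0.0, 3000.0),
    "SPECIFICITY_I": (2000.0, 2000.0), "SPECIFICITY_II": (0.0, 2000.0),
    "EXTENSION_A": (0.0, 12000.0), "EXTENSION_T": (0.0, 12000.0),
    "EXTENSION_C": (12000.0, 0.0), "EXTENSION_G": (12000.0, 0.0),
    "HYB_LOW": (1000.0, 0.0), "HYB_MEDIUM": (4000.0, 0.0),
    "HYB_HIGH": (16000.0, 0.0),
    "TARGET_REMOVAL_1": (400.0, 0.0), "TARGET_REMOVAL_2": (400.0, 0.0),
    "STAINING": (6000.0, 6000.0),
    "NON_POLYMORPHIC_A": (0.0, 5000.0), "NON_POLYMORPHIC_T": (0.0, 5000.0),
    "NON_POLYMORPHIC_C": (5000.0, 0.0), "NON_POLYMORPHIC_G": (5000.0, 0.0),
    "RESTORATION": (500.0, 0.0),
}


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the desk-scale study conditions."""

    seed: int
    n_samples: int = 40
    probe_counts: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PROBE_COUNTS))
    control_counts: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CONTROL_COUNTS))
    n_plates: int = 2
    confound_group_with_plate: bool = False
    group_labels: tuple[str, str] = ("control", "case")
    n_dmp: int = 200
    dmp_effect: float = 0.12
    global_shift: float = 0.0           # genome-wide case hypomethylation
    female_fraction: float = 0.5
    intensity_median: float = 4000.0
    intensity_log_sd: float = 0.25      # probe-to-probe total intensity spread
    sample_intensity_log_sd: float = 0.08
    background_mean: float = 400.0
    background_sd: float = 60.0
    plate_background_sd: float = 250.0  # amplitude of per-plate bg-mean shifts
    plate_dye_log_sd: float = 0.12      # amplitude of per-plate dye imbalance
    plate_jitter: float = 0.25          # random jitter on plate effects
    beta_noise_sd: float = 0.05         # per-sample biological beta noise
    row_effect: float = 0.0             # beta gradient across slide rows
    replicate_groups: int = 0
    replicates_per_group: int = 3

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if self.n_samples < 4:
            raise ConfigurationError("need at least 4 samples")
        if any(v < 0 for v in self.probe_counts.values()):
            raise ConfigurationError("probe counts must be non-negative")
        if any(v < 0 for v in self.control_counts.values()):
            raise ConfigurationError("control counts must be non-negative")
        if not -1.0 <= self.global_shift <= 1.0:
            raise ConfigurationError("global_shift must be in [-1, 1]")
        if self.n_plates < 1:
            raise ConfigurationError("need at least one plate")
        if self.confound_group_with_plate and self.n_plates < 2:
            raise ConfigurationError("confounding requires at least 2 plates")
        if self.n_dmp < 0 or self.dmp_effect < 0:
            raise ConfigurationError("n_dmp and dmp_effect must be non-negative")
        if self.replicate_groups and self.replicates_per_group < 2:
            raise ConfigurationError("replicates_per_group must be >= 2")


@dataclasses.dataclass
class GroundTruth:
    dmp_probes: list[str]
    dmp_signs: pd.Series
    beta_bio: pd.DataFrame         # latent probe x sample methylation
    plate_background: pd.DataFrame  # plate x channel background-mean shifts
    plate_dye_log: pd.Series       # per-plate log dye imbalance (green-red)
    sex: pd.Series
    group: pd.Series


@dataclasses.dataclass
class SimulatedDataset:
    channels: ChannelData
    manifest: ProbeManifest
    samplesheet: SampleSheet
    truth: GroundTruth


def _build_manifest(config: SimulationConfig) -> ProbeManifest:
    rows = []
    addr = 0

    def next_addr() -> str:
        nonlocal addr
        addr += 1
        return f"addr{addr:06d}"

    probe = 0
    for key in sorted(config.probe_counts):
        chrom_class, design = key.split(".")
        chrom = {"autosome": "chr1", "X": "X", "Y": "Y"}[chrom_class]
        for _ in range(int(config.probe_counts[key])):
            probe += 1
            rows.append({
                "probe_id": f"cg{probe:07d}",
                "design_type": design,
                "chromosome": chrom,
                "is_control": False,
                "control_category": "",
                "address_a": next_addr(),
                "address_b": next_addr() if design != DESIGN_II else "",
            })
    ctl = 0
    for category in sorted(config.control_counts):
        for _ in range(int(config.control_counts[category])):
            ctl += 1
            rows.append({
                "probe_id": f"ctl{ctl:05d}_{category}",
                "design_type": DESIGN_II,
                "chromosome": "",
                "is_control": True,
                "control_category": category,
                "address_a": next_addr(),
                "address_b": "",
            })
    return ProbeManifest.from_frame(pd.DataFrame(rows))


def _build_samplesheet(config: SimulationConfig, prefix: str) -> pd.DataFrame:
    n = config.n_samples
    plates = [f"plate{p + 1}" for p in range(config.n_plates)]
    rows = []
    per_group_counter = {g: 0 for g in config.group_labels}
    for i in range(n):
        group = config.group_labels[i % 2]
        j = per_group_counter[group]
        per_group_counter[group] += 1
        if config.confound_group_with_plate:
            half = config.n_plates // 2
            pool = plates[:half] if group == config.group_labels[0] else plates[half:]
            plate = pool[j % len(pool)]
        else:
            plate = plates[j % len(plates)]
        group_size = (n + (1 if group == config.group_labels[0] else 0)) // 2
        sex = SEX_FEMALE if j < round(config.female_fraction * group_size) else SEX_MALE
        rows.append({"sample_id": f"{prefix}{i + 1:03d}", "sex": sex,
                     "plate": plate, "group": group, "replicate_of": ""})
    for g in range(config.replicate_groups):
        base = rows[g]
        for r in range(config.replicates_per_group - 1):
            plate = plates[(plates.index(base["plate"]) + r + 1) % len(plates)]
            rows.append({"sample_id": f"{base['sample_id']}r{r + 2}",
                         "sex": base["sex"], "plate": plate,
                         "group": base["group"],
                         "replicate_of": base["sample_id"]})
    for pos, row in enumerate(rows):
        row["slide"] = f"slide{pos // 12 + 1}"
        row["row"] = pos % 6 + 1
        row["column"] = (pos // 6) % 2 + 1
    return pd.DataFrame(rows)


def _simulate(config: SimulationConfig,
              probe_ss: np.random.SeedSequence,
              sample_ss: np.random.SeedSequence,
              prefix: str) -> SimulatedDataset:
    config.validate()
    manifest = _build_manifest(config)
    sheet_df = _build_samplesheet(config, prefix)
    samplesheet = SampleSheet.from_frame(
        sheet_df[["sample_id", "sex", "plate", "slide", "row", "column",
                  "group", "replicate_of"]])

    rng_probe = np.random.default_rng(probe_ss)
    rng_sample = np.random.default_rng(sample_ss)

    ann = manifest.non_control()
    n_probes = len(ann)
    chrom = ann["chromosome"].to_numpy()
    design = ann["design_type"].to_numpy()
    auto_mask = ~np.isin(chrom, ("X", "Y"))

    # --- probe-level truth (shared across cohorts built on the same stream)
    high = rng_probe.random(n_probes) < 0.5
    beta0 = np.where(high, rng_probe.beta(8.0, 0.5, n_probes),
                     rng_probe.beta(0.5, 8.0, n_probes))
    probe_intensity = rng_probe.lognormal(np.log(config.intensity_median),
                                          config.intensity_log_sd, n_probes)
    auto_idx = np.flatnonzero(auto_mask)
    if config.n_dmp > len(auto_idx):
        raise ConfigurationError("n_dmp exceeds the number of autosomal probes")
    dmp_idx = rng_probe.choice(auto_idx, size=config.n_dmp, replace=False)
    dmp_signs = rng_probe.choice([-1.0, 1.0], size=config.n_dmp)

    beta_control = beta0.copy()
    beta_case = beta0.copy()
    shifted = beta0[dmp_idx] + dmp_signs * config.dmp_effect
    flip = (shifted < 0.02) | (shifted > 0.98)
    shifted[flip] = beta0[dmp_idx][flip] - dmp_signs[flip] * config.dmp_effect
    beta_case[dmp_idx] = np.clip(shifted, 0.02, 0.98)
    if config.global_shift:
        beta_case = np.clip(beta_case - config.global_shift, 0.01, 0.99)

    # --- sample-level structure
    samples = sheet_df["sample_id"].tolist()
    n_total = len(samples)
    groups = sheet_df["group"].to_numpy()
    sexes = sheet_df["sex"].to_numpy()
    plates = sheet_df["plate"].to_numpy()
    plate_list = [f"plate{p + 1}" for p in range(config.n_plates)]
    replicate_of = sheet_df["replicate_of"].to_numpy()

    spread = (np.linspace(-1.0, 1.0, config.n_plates)
              if config.n_plates > 1 else np.zeros(1))
    jitter = config.plate_jitter
    bg_shift = pd.DataFrame(
        {ch: config.plate_background_sd * spread
         + rng_sample.normal(0, jitter * config.plate_background_sd + 1e-12,
                             config.n_plates)
         for ch in ("green", "red")}, index=plate_list)
    dye_log = pd.Series(
        config.plate_dye_log_sd * spread
        + rng_sample.normal(0, jitter * config.plate_dye_log_sd + 1e-12,
                            config.n_plates), index=plate_list)

    # latent biological methylation per base sample; replicates share it
    beta_bio = np.empty((n_probes, n_total))
    base_col = {sid: k for k, sid in enumerate(samples)}
    for k in range(n_total):
        if replicate_of[k]:
            beta_bio[:, k] = beta_bio[:, base_col[replicate_of[k]]]
            continue
        latent = beta_control if groups[k] == config.group_labels[0] else beta_case
        beta_bio[:, k] = np.clip(
            latent + rng_sample.normal(0, config.beta_noise_sd, n_probes), 0.0, 1.0)

    rows = sheet_df["row"].to_numpy()
    row_offsets = config.row_effect * (rows - 3.5) / 2.5
    beta_tech = np.clip(beta_bio + row_offsets[np.newaxis, :], 0.0, 1.0)

    sample_factor = rng_sample.lognormal(0.0, config.sample_intensity_log_sd,
                                         n_total)
    scale = np.ones((n_probes, n_total))
    male = sexes == SEX_MALE
    scale[np.ix_(chrom == "X", male)] = 0.5
    scale[np.ix_(chrom == "Y", male)] = 0.5
    scale[np.ix_(chrom == "Y", ~male)] = 0.0

    total = probe_intensity[:, np.newaxis] * sample_factor[np.newaxis, :] * scale
    M_sig = total * beta_tech
    U_sig = total * (1.0 - beta_tech)

    # --- place signal on addresses
    addresses = manifest.all_addresses()
    addr_index = pd.Index(pd.unique(addresses), name="address")
    n_addr = len(addr_index)
    sig_green = np.zeros((n_addr, n_total))
    sig_red = np.zeros((n_addr, n_total))

    pos_a = addr_index.get_indexer(ann["address_a"])
    has_b = ann["address_b"] != ""
    pos_b = addr_index.get_indexer(ann.loc[has_b, "address_b"])
    full_pos_b = np.full(n_probes, -1)
    full_pos_b[has_b.to_numpy()] = pos_b

    ii = design == DESIGN_II
    ig = design == DESIGN_I_GREEN
    ir = design == DESIGN_I_RED
    sig_green[pos_a[ii]] = M_sig[ii]
    sig_red[pos_a[ii]] = U_sig[ii]
    sig_green[pos_a[ig]] = U_sig[ig]
    sig_green[full_pos_b[ig]] = M_sig[ig]
    sig_red[pos_a[ir]] = U_sig[ir]
    sig_red[full_pos_b[ir]] = M_sig[ir]

    ctl = manifest.controls()
    ctl_pos = addr_index.get_indexer(ctl["address_a"])
    ctl_green = np.array([CONTROL_SIGNAL[c][0] for c in ctl["control_category"]])
    ctl_red = np.array([CONTROL_SIGNAL[c][1] for c in ctl["control_category"]])
    sig_green[ctl_pos] = ctl_green[:, np.newaxis]
    sig_red[ctl_pos] = ctl_red[:, np.newaxis]

    # --- measurement: background + plate shifts, dye imbalance, clipping
    plate_of = pd.Index(plate_list).get_indexer(plates)
    green = np.empty_like(sig_green)
    red = np.empty_like(sig_red)
    for k in range(n_total):
        p = plate_of[k]
        mu_g = max(config.background_mean + bg_shift.iloc[p]["green"], 0.0)
        mu_r = max(config.background_mean + bg_shift.iloc[p]["red"], 0.0)
        dg = np.exp(dye_log.iloc[p] / 2.0)
        dr = np.exp(-dye_log.iloc[p] / 2.0)
        green[:, k] = dg * (sig_green[:, k]
                            + rng_sample.normal(mu_g, config.background_sd, n_addr))
        red[:, k] = dr * (sig_red[:, k]
                          + rng_sample.normal(mu_r, config.background_sd, n_addr))
    np.clip(green, 0.0, None, out=green)
    np.clip(red, 0.0, None, out=red)

    channels = ChannelData(
        pd.DataFrame(green, index=addr_index, columns=samples),
        pd.DataFrame(red, index=addr_index, columns=samples))
    probe_index = pd.Index(ann["probe_id"], name="probe_id")
    truth = GroundTruth(
        dmp_probes=list(ann["probe_id"].to_numpy()[dmp_idx]),
        dmp_signs=pd.Series(dmp_signs,
                            index=ann["probe_id"].to_numpy()[dmp_idx]),
        beta_bio=pd.DataFrame(beta_bio, index=probe_index, columns=samples),
        plate_background=bg_shift,
        plate_dye_log=dye_log,
        sex=pd.Series(sexes, index=samples, name="sex"),
        group=pd.Series(groups, index=samples, name="group"),
    )
    return SimulatedDataset(channels, manifest, samplesheet, truth)


def simulate_dataset(config: SimulationConfig, prefix: str = "s") -> SimulatedDataset:
    """Generate one dataset from a single seed (deterministic)."""
    root = np.random.SeedSequence(config.seed)
    probe_ss, sample_ss = root.spawn(2)
    return _simulate(config, probe_ss, sample_ss, prefix)


def make_discovery_validation(config: SimulationConfig
                              ) -> tuple[SimulatedDataset, SimulatedDataset]:
    """Two cohorts sharing the same probe-level truth (same DMP set).

    Discovery: groups balanced across plates.  Validation: cases and
    controls assigned to disjoint plates, maximizing the confounding of
    group by plate (with 2 plates the confounding is complete).
    """
    if config.n_plates < 2:
        raise ConfigurationError("discovery/validation design needs >= 2 plates")
    root = np.random.SeedSequence(config.seed)
    probe_ss, disc_ss, valid_ss = root.spawn(3)
    disc_cfg = dataclasses.replace(config, confound_group_with_plate=False)
    valid_cfg = dataclasses.replace(config, confound_group_with_plate=True)
    discovery = _simulate(disc_cfg, probe_ss, disc_ss, prefix="d")
    validation = _simulate(valid_cfg, probe_ss, valid_ss, prefix="v")
    return discovery, validation


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, str]:
    """Write a dataset as the plain-text tables the readers consume,
    plus a ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "manifest": str(out / "manifest.tsv"),
        "green": str(out / "green.tsv"),
        "red": str(out / "red.tsv"),
        "samplesheet": str(out / "samples.csv"),
        "truth": str(out / "truth.json"),
    }
    write_manifest(dataset.manifest, paths["manifest"])
    write_channels(dataset.channels, paths["green"], paths["red"])
    write_samplesheet(dataset.samplesheet, paths["samplesheet"])
    truth = {
        "dmp_probes": dataset.truth.dmp_probes,
        "plate_background": dataset.truth.plate_background.to_dict(),
        "plate_dye_log": dataset.truth.plate_dye_log.to_dict(),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths


def config_from_yaml(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML mapping of field names."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ConfigurationError(f"unknown simulation config key(s): {sorted(unknown)}")
    if "seed" not in raw:
        raise ConfigurationError("simulation config must set a seed")
    if "group_labels" in raw:
        raw["group_labels"] = tuple(raw["group_labels"])
    return SimulationConfig(**raw)
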