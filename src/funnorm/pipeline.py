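"""End-to-end functional normalization of a 450k-style dataset.

The full recipe:

1. raw channel-to-probe matching;
2. optional noob background correction and dye-bias equalization
   (the recommended pre-step);
3. control summaries computed from the *raw* control intensities and
   condensed into m principal-component covariates Z;
4. autosomal probes normalized in four strata -- {methylated, unmethylated}
   channel x {type I, type II} design -- all with the same Z;
5. X-chromosome probes normalized within males and within females
   separately (still stratified by probe type), because X methylation
   differs systematically between the sexes;
6. Y-chromosome probes quantile-normalized within each sex: the handful of
   Y probes yields too unstable a quantile-function fit for the covariate
   model;
7. beta values from the normalized intensities.

Small strata and small sex groups fall back to quantile normalization; with
m = 0 covariates the funnorm strata pass data through unchanged.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .background import background_correct_noob, dye_bias_correct
from .controls import (ControlSummaryMatrix, CovariateMatrix, SummaryMeasure,
                       control_covariates, summarize_controls)
from .core import QuantileGrid, funnorm_matrix, quantile_normalize_matrix
from .data_model import (DESIGN_II, SEX_FEMALE, SEX_MALE, SEX_UNKNOWN,
                         BetaMatrix, ChannelData, MethylSet, ProbeManifest,
                         SampleSheet, beta_values, preprocess_raw)
from .errors import ConfigurationError, ValidationError

BACKGROUND_NONE = "none"
BACKGROUND_NOOB = "noob"
ENGINE_FUNNORM = "funnorm"
ENGINE_QUANTILE = "quantile"
SEX_SOURCE_SAMPLESHEET = "samplesheet"
SEX_SOURCE_PREDICTED = "predicted"


@dataclasses.dataclass
class FunnormResult:
    mset: MethylSet
    beta: BetaMatrix
    summary: ControlSummaryMatrix
    covariates: CovariateMatrix
    provenance: dict


def predict_sex(mset: MethylSet, manifest: ProbeManifest,
                cutoff: float = -2.0) -> pd.Series:
    """Classify samples as FEMALE when the median log2 total intensity on Y
    probes sits more than |cutoff| below the X median (absent Y chromosome);
    values at or above the cutoff are MALE."""
    ann = manifest.non_control()
    x_mask = (ann["chromosome"] == "X").to_numpy()
    y_mask = (ann["chromosome"] == "Y").to_numpy()
    if not y_mask.any():
        raise ValidationError("no Y-chromosome probes: cannot predict sex")
    if not x_mask.any():
        raise ValidationError("no X-chromosome probes: cannot predict sex")
    total = np.log2(mset.M.to_numpy() + mset.U.to_numpy() + 1.0)
    diff = np.median(total[y_mask], axis=0) - np.median(total[x_mask], axis=0)
    sexes = np.where(diff < cutoff, SEX_FEMALE, SEX_MALE)
    return pd.Series(sexes, index=mset.samples, name="sex")


def _resolve_sex(mset_raw: MethylSet, manifest: ProbeManifest,
                 samplesheet: SampleSheet | None, sex_source: str) -> pd.Series:
    if sex_source == SEX_SOURCE_PREDICTED:
        return predict_sex(mset_raw, manifest)
    if samplesheet is None:
        raise ConfigurationError(
            "sex-chromosome probes present: provide a sample sheet or use "
            "sex_source='predicted'")
    sheet = samplesheet.aligned_to(mset_raw.samples)
    sexes = sheet.set_index("sample_id")["sex"]
    if (sexes == SEX_UNKNOWN).any():
        raise ValidationError(
            "sample sheet contains UNKNOWN sex; use sex_source='predicted'")
    return sexes


def _normalize_stratum(values: np.ndarray, Z: np.ndarray, grid: QuantileGrid,
                       min_probes: int) -> tuple[np.ndarray, str]:
    """Normalize one values x samples stratum, falling back to quantile
    normalization when the stratum is too small to support the fit."""
    n = values.shape[1]
    m = Z.shape[1]
    if m == 0:
        return funnorm_matrix(values, Z, grid), ENGINE_FUNNORM
    if values.shape[0] < min_probes or n < m + 2:
        return quantile_normalize_matrix(values, grid), ENGINE_QUANTILE
    return funnorm_matrix(values, Z, grid), ENGINE_FUNNORM


def preprocess_funnorm(channels: ChannelData,
                       manifest: ProbeManifest,
                       samplesheet: SampleSheet | None = None,
                       m: int = 2,
                       H: int = 500,
                       background: str = BACKGROUND_NOOB,
                       sex_source: str = SEX_SOURCE_SAMPLESHEET,
                       engine: str = ENGINE_FUNNORM,
                       scheme: list[SummaryMeasure] | None = None,
                       beta_offset: float = 100.0) -> FunnormResult:
    """Functional normalization of a full two-channel dataset.

    ``engine='quantile'`` replaces every functional-normalization stratum by
    plain quantile normalization (the saturated limit), which serves as the
    classic between-array comparator.

    Returns normalized intensities, beta values, the control summary matrix,
    the covariates and a provenance record (parameters, stratum sizes and
    engines, PC variance explained).
    """
    if background not in (BACKGROUND_NONE, BACKGROUND_NOOB):
        raise ConfigurationError(f"unknown background mode {background!r}")
    if engine not in (ENGINE_FUNNORM, ENGINE_QUANTILE):
        raise ConfigurationError(f"unknown engine {engine!r}")

    mset_raw = preprocess_raw(channels, manifest)
    n_samples = len(mset_raw.samples)
    if n_samples < m + 2:
        raise ValidationError(f"need at least m+2={m + 2} samples, got {n_samples}")

    # control summaries always reflect the raw technical state of the array
    summary = summarize_controls(channels, manifest, mset_raw.oob_green,
                                 mset_raw.oob_red, scheme=scheme)
    cov = control_covariates(summary, m=m)
    Z = cov.Z

    mset = mset_raw
    if background == BACKGROUND_NOOB:
        mset = background_correct_noob(mset, manifest)
        mset, _ = dye_bias_correct(mset, channels, manifest)

    ann = manifest.non_control()
    chrom = ann["chromosome"].to_numpy()
    is_ii = (ann["design_type"] == DESIGN_II).to_numpy()
    auto = ~np.isin(chrom, ("X", "Y"))
    grid = QuantileGrid(H)
    min_probes = 2 * (m + 2)

    sexes: pd.Series | None = None
    if (~auto).any():
        sexes = _resolve_sex(mset_raw, manifest, samplesheet, sex_source)

    M = mset.M.to_numpy(copy=True)
    U = mset.U.to_numpy(copy=True)
    strata_records: list[dict] = []

    def run(channel_name: str, values: np.ndarray, probe_mask: np.ndarray,
            sample_idx: np.ndarray, label: str, force_quantile: bool = False) -> None:
        if not probe_mask.any() or sample_idx.size == 0:
            return
        sub = values[np.ix_(probe_mask, sample_idx)]
        if force_quantile or engine == ENGINE_QUANTILE:
            out = quantile_normalize_matrix(sub, grid)
            used = ENGINE_QUANTILE
        else:
            Zsub = Z[sample_idx]
            out, used = _normalize_stratum(sub, Zsub, grid, min_probes)
            if used == ENGINE_QUANTILE:
                warnings.warn(f"stratum {label}: falling back to quantile "
                              "normalization (too few probes or samples)")
        values[np.ix_(probe_mask, sample_idx)] = out
        strata_records.append({"stratum": label, "channel": channel_name,
                               "n_probes": int(probe_mask.sum()),
                               "n_samples": int(sample_idx.size),
                               "engine": used})

    all_samples = np.arange(n_samples)
    for channel_name, values in (("M", M), ("U", U)):
        # autosomes: type I and type II strata share the full sample set
        run(channel_name, values, auto & ~is_ii, all_samples, "autosome.I")
        run(channel_name, values, auto & is_ii, all_samples, "autosome.II")
        if sexes is not None:
            for sex in (SEX_MALE, SEX_FEMALE):
                idx = np.flatnonzero((sexes == sex).to_numpy())
                if idx.size == 0:
                    continue
                run(channel_name, values, (chrom == "X") & ~is_ii, idx,
                    f"X.I.{sex}")
                run(channel_name, values, (chrom == "X") & is_ii, idx,
                    f"X.II.{sex}")
                run(channel_name, values, chrom == "Y", idx, f"Y.{sex}",
                    force_quantile=True)

    # covariate removal can push low quantiles slightly negative
    np.clip(M, 0.0, None, out=M)
    np.clip(U, 0.0, None, out=U)
    mset_norm = MethylSet(
        pd.DataFrame(M, index=mset.M.index, columns=mset.M.columns),
        pd.DataFrame(U, index=mset.U.index, columns=mset.U.columns),
        mset.oob_green, mset.oob_red)
    beta = beta_values(mset_norm, offset=beta_offset)

    provenance = {
        "tool": "funnorm",
        "version": __version__,
        "m": m,
        "H": H,
        "background": background,
        "engine": engine,
        "sex_source": sex_source,
        "n_samples": n_samples,
        "n_probes": int(len(ann)),
        "pc_variance_explained": [float(v) for v in cov.explained_variance_ratio],
        "strata": strata_records,
    }
    return FunnormResult(mset_norm, beta, summary, cov, provenance)


def spatial_profile(beta: BetaMatrix,
                    samplesheet: SampleSheet,
                    percentiles: Sequence[float] = (10.0, 15.0, 85.0),
                    manifest: ProbeManifest | None = None,
                    design_type: str | None = None) -> pd.DataFrame:
    """Row/column diagnostic of the beta distribution on a 6x2 slide layout.

    For each requested percentile, compute the per-sample percentile of its
    beta distribution (optionally restricted to one probe design type),
    remove the slide mean, and average within each of the 12 (row, column)
    position cells, ordered rows 1-6 in column 1 followed by rows 1-6 in
    column 2.
    """
    sheet = samplesheet.aligned_to(list(beta.beta.columns))
    if sheet["row"].isna().any() or sheet["column"].isna().any():
        raise ValidationError("sample sheet lacks row/column layout metadata")
    values = beta.beta.to_numpy()
    if design_type is not None:
        if manifest is None:
            raise ConfigurationError("design_type filtering requires a manifest")
        mask = (manifest.non_control()["design_type"] == design_type).to_numpy()
        values = values[mask]

    per_sample = {f"p{int(p):02d}": np.percentile(values, p, axis=0)
                  for p in percentiles}
    out_rows = []
    cells = [(row, col) for col in (1, 2) for row in range(1, 7)]
    stats = pd.DataFrame(per_sample)
    stats["slide"] = sheet["slide"].to_numpy()
    stats["row"] = sheet["row"].to_numpy()
    stats["column"] = sheet["column"].to_numpy()
    for name in per_sample:
        stats[name] = stats[name] - stats.groupby("slide")[name].transform("mean")
    for position, (row, col) in enumerate(cells, start=1):
        cell = stats[(stats["row"] == row) & (stats["column"] == col)]
        rec = {"position": position, "row": row, "column": col,
               "n_samples": len(cell)}
        for name in per_sample:
            rec[name] = float(cell[name].mean()) if len(cell) else np.nan
        out_rows.append(rec)
    return pd.DataFrame(out_rows).set_index("position")
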