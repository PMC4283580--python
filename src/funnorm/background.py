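"""Normal-exponential background correction from out-of-band probes and
dye-bias equalization ("noob"-style pre-correction).

Observed in-band intensities are modeled per sample and per color channel as
X = S + B with signal S ~ Exponential(alpha) and background
B ~ Normal(mu, sigma^2).  The out-of-band readings of type I probes are pure
background draws in the same channel, so mu and sigma are estimated from
them robustly (median and MAD) and alpha from the mean excess of the
observed values.  Each value is replaced by the posterior mean E[S | X = x],
which for the normal+exponential convolution is the mean of a normal
distribution truncated to the positive axis:

    mu_sx = x - mu - sigma^2 / alpha
    E[S | X = x] = mu_sx + sigma * phi(mu_sx/sigma) / Phi(mu_sx/sigma)

computed in log space so deep-background values underflow gracefully instead
of producing NaNs.  A small positive offset is added after correction.

Dye bias is equalized per sample by scaling each channel so that the mean
intensities of the red and green normalization control probes agree at their
within-sample geometric mean; samples stay independent of each other.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import special, stats

from .data_model import (DESIGN_I_GREEN, DESIGN_I_RED, DESIGN_II, MAD_SCALE,
                         ChannelData, MethylSet, ProbeManifest)
from .errors import ConfigurationError, ValidationError

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

#: Normalization control categories read in each channel under the default
#: summary scheme: C/G-extending probes in green, A/T in red.
NORM_CATEGORIES_GREEN = ("NORM_C", "NORM_G")
NORM_CATEGORIES_RED = ("NORM_A", "NORM_T")


@dataclasses.dataclass
class NormExpParams:
    """Background/signal parameters for one sample in one channel."""

    mu_bg: float
    sigma_bg: float
    alpha_sig: float
    offset: float = 15.0

    def __post_init__(self) -> None:
        if self.sigma_bg <= 0 or self.alpha_sig <= 0:
            raise ValidationError("sigma_bg and alpha_sig must be positive")


def fit_normexp(observed: np.ndarray,
                oob: np.ndarray,
                offset: float = 15.0,
                min_oob: int = 50,
                sigma_floor: float = 1e-2,
                alpha_floor: float = 1e-2) -> NormExpParams:
    """Estimate background (from out-of-band values) and signal parameters.

    Robust moment estimation: mu = median(oob), sigma = MAD-based sd (with a
    small floor for degenerate inputs), alpha = max(mean(observed) - mu,
    floor).
    """
    oob = np.asarray(oob, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if oob.size < min_oob:
        raise ConfigurationError(
            f"only {oob.size} out-of-band values (need >= {min_oob}); "
            "consider skipping background correction")
    mu = float(np.median(oob))
    sigma = float(max(MAD_SCALE * stats.median_abs_deviation(oob), sigma_floor))
    alpha = float(max(np.mean(observed) - mu, alpha_floor))
    return NormExpParams(mu, sigma, alpha, offset)


def normexp_correct(values: np.ndarray, params: NormExpParams) -> np.ndarray:
    """Replace each observed value by E[signal | observed] + offset.

    Strictly positive and monotone increasing in the input.
    """
    x = np.asarray(values, dtype=float)
    mu_sx = x - params.mu_bg - params.sigma_bg ** 2 / params.alpha_sig
    z = mu_sx / params.sigma_bg
    # phi(z)/Phi(z) via log-space; log_ndtr is accurate far into the tail
    log_ratio = (-0.5 * z ** 2 - _LOG_SQRT_2PI) - special.log_ndtr(z)
    expected = mu_sx + params.sigma_bg * np.exp(log_ratio)
    return np.maximum(expected, 0.0) + params.offset


@dataclasses.dataclass
class DyeBiasFactors:
    """Per-sample channel multipliers equalizing the normalization controls."""

    scale_green: np.ndarray
    scale_red: np.ndarray
    reference_level: np.ndarray

    def __post_init__(self) -> None:
        if (self.scale_green <= 0).any() or (self.scale_red <= 0).any():
            raise ValidationError("dye-bias scale factors must be positive")


def dye_bias_factors(green_control_means: np.ndarray,
                     red_control_means: np.ndarray) -> DyeBiasFactors:
    """Channel scale factors from per-sample normalization-control means.

    The reference is the within-sample geometric mean of the two channel
    means; applying the factors and recomputing them yields factors of
    exactly 1 (the step is idempotent).
    """
    g = np.asarray(green_control_means, dtype=float)
    r = np.asarray(red_control_means, dtype=float)
    if (g <= 0).any() or (r <= 0).any():
        raise ValidationError("normalization-control channel means must be positive")
    reference = np.sqrt(g * r)
    return DyeBiasFactors(reference / g, reference / r, reference)


def _norm_control_means(channels: ChannelData, manifest: ProbeManifest
                        ) -> tuple[np.ndarray, np.ndarray]:
    ctl = manifest.controls()
    means = []
    for cats, mat in ((NORM_CATEGORIES_GREEN, channels.green),
                      (NORM_CATEGORIES_RED, channels.red)):
        sub = ctl[ctl["control_category"].isin(cats)]
        if sub.empty:
            raise ConfigurationError(
                f"no normalization control probes in categories {cats}")
        pos = mat.index.get_indexer(sub["address_a"])
        means.append(mat.to_numpy()[pos].mean(axis=0))
    return means[0], means[1]


def _channel_masks(manifest: ProbeManifest) -> dict[str, np.ndarray]:
    design = manifest.non_control()["design_type"].to_numpy()
    return {"ii": design == DESIGN_II,
            "ig": design == DESIGN_I_GREEN,
            "ir": design == DESIGN_I_RED}


def background_correct_noob(mset: MethylSet, manifest: ProbeManifest,
                            offset: float = 15.0) -> MethylSet:
    """Normal-exponential background correction of M and U, per sample and
    per color channel, using the sample's own out-of-band values.

    No locus is ever dropped; detection filtering is a separate concern.
    """
    masks = _channel_masks(manifest)
    M = mset.M.to_numpy(copy=True)
    U = mset.U.to_numpy(copy=True)
    for i in range(M.shape[1]):
        green_obs = np.concatenate([M[masks["ig"], i], U[masks["ig"], i],
                                    M[masks["ii"], i]])
        red_obs = np.concatenate([M[masks["ir"], i], U[masks["ir"], i],
                                  U[masks["ii"], i]])
        pg = fit_normexp(green_obs, mset.oob_green[:, i], offset=offset)
        pr = fit_normexp(red_obs, mset.oob_red[:, i], offset=offset)
        for mask, pm, pu in (("ig", pg, pg), ("ir", pr, pr), ("ii", pg, pr)):
            sel = masks[mask]
            M[sel, i] = normexp_correct(M[sel, i], pm)
            U[sel, i] = normexp_correct(U[sel, i], pu)
    return MethylSet(pd.DataFrame(M, index=mset.M.index, columns=mset.M.columns),
                     pd.DataFrame(U, index=mset.U.index, columns=mset.U.columns),
                     mset.oob_green.copy(), mset.oob_red.copy())


def dye_bias_correct(mset: MethylSet, channels: ChannelData,
                     manifest: ProbeManifest) -> tuple[MethylSet, DyeBiasFactors]:
    """Scale green- and red-derived intensities so the two channels'
    normalization controls agree within each sample."""
    g_means, r_means = _norm_control_means(channels, manifest)
    factors = dye_bias_factors(g_means, r_means)
    masks = _channel_masks(manifest)
    M = mset.M.to_numpy(copy=True)
    U = mset.U.to_numpy(copy=True)
    sg = factors.scale_green
    sr = factors.scale_red
    M[masks["ig"]] *= sg
    U[masks["ig"]] *= sg
    M[masks["ir"]] *= sr
    U[masks["ir"]] *= sr
    M[masks["ii"]] *= sg
    U[masks["ii"]] *= sr
    return (MethylSet(pd.DataFrame(M, index=mset.M.index, columns=mset.M.columns),
                      pd.DataFrame(U, index=mset.U.index, columns=mset.U.columns),
                      mset.oob_green * sg, mset.oob_red * sr), factors)
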