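"""Control-probe summary measures and their principal-component covariates.

Control probes (negative, normalization, bisulfite-conversion, specificity,
extension, hybridization, staining, ...) hybridize to no genomic target and
therefore carry technical signal only.  Together with the out-of-band
readings of type I probes they are condensed into a small per-sample summary
matrix; on a manifest declaring all standard categories the default scheme
yields 42 measures: 38 per-category-per-channel means of log2(1+intensity)
from the control probes plus 4 out-of-band measures (mean and 1st percentile
of log2(1+intensity) per channel).

The first few principal components of this matrix act as surrogate
covariates for plate/batch-driven technical variation and are the covariate
matrix Z consumed by the normalization engine.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import ChannelData, ProbeManifest, SampleSheet
from .errors import ConfigurationError, ValidationError

CHANNEL_GREEN = "green"
CHANNEL_RED = "red"


@dataclasses.dataclass(frozen=True)
class SummaryMeasure:
    """One control summary column: a statistic of one control category in
    one color channel."""

    name: str
    category: str
    channel: str
    statistic: str = "mean"


def _measures(*specs: tuple[str, str]) -> list[SummaryMeasure]:
    return [SummaryMeasure(f"{cat.lower()}.{ch}", cat, ch) for cat, ch in specs]


#: Default scheme: 38 control-probe measures.  The exact composition is a
#: package convention (documented here and replaceable via ``load_scheme``);
#: it covers every standard category with one column per category/channel.
STANDARD_CONTROL_SCHEME: list[SummaryMeasure] = _measures(
    ("BISULFITE_I", CHANNEL_GREEN), ("BISULFITE_I", CHANNEL_RED),
    ("BISULFITE_II", CHANNEL_GREEN), ("BISULFITE_II", CHANNEL_RED),
    ("SPECIFICITY_I", CHANNEL_GREEN), ("SPECIFICITY_I", CHANNEL_RED),
    ("SPECIFICITY_II", CHANNEL_GREEN), ("SPECIFICITY_II", CHANNEL_RED),
    ("EXTENSION_A", CHANNEL_GREEN), ("EXTENSION_A", CHANNEL_RED),
    ("EXTENSION_C", CHANNEL_GREEN), ("EXTENSION_C", CHANNEL_RED),
    ("EXTENSION_G", CHANNEL_GREEN), ("EXTENSION_G", CHANNEL_RED),
    ("EXTENSION_T", CHANNEL_GREEN), ("EXTENSION_T", CHANNEL_RED),
    ("HYB_LOW", CHANNEL_GREEN), ("HYB_MEDIUM", CHANNEL_GREEN),
    ("HYB_HIGH", CHANNEL_GREEN),
    ("TARGET_REMOVAL_1", CHANNEL_GREEN), ("TARGET_REMOVAL_2", CHANNEL_GREEN),
    ("STAINING", CHANNEL_GREEN), ("STAINING", CHANNEL_RED),
    ("NON_POLYMORPHIC_A", CHANNEL_GREEN), ("NON_POLYMORPHIC_A", CHANNEL_RED),
    ("NON_POLYMORPHIC_C", CHANNEL_GREEN), ("NON_POLYMORPHIC_C", CHANNEL_RED),
    ("NON_POLYMORPHIC_G", CHANNEL_GREEN), ("NON_POLYMORPHIC_G", CHANNEL_RED),
    ("NON_POLYMORPHIC_T", CHANNEL_GREEN), ("NON_POLYMORPHIC_T", CHANNEL_RED),
    ("RESTORATION", CHANNEL_GREEN),
    ("NORM_A", CHANNEL_RED), ("NORM_T", CHANNEL_RED),
    ("NORM_C", CHANNEL_GREEN), ("NORM_G", CHANNEL_GREEN),
    ("NEGATIVE", CHANNEL_GREEN), ("NEGATIVE", CHANNEL_RED),
)
assert len(STANDARD_CONTROL_SCHEME) == 38

#: Names of the four out-of-band measures appended to every summary matrix.
OOB_MEASURE_NAMES = ["oob.green.mean", "oob.green.p01",
                     "oob.red.mean", "oob.red.p01"]


def load_scheme(path: str | Path) -> list[SummaryMeasure]:
    """Load an alternative control-summary scheme from YAML.

    The file is a list of mappings with keys ``name``, ``category``,
    ``channel`` and optionally ``statistic``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    scheme = []
    for entry in raw:
        scheme.append(SummaryMeasure(
            name=entry["name"], category=entry["category"],
            channel=entry["channel"], statistic=entry.get("statistic", "mean")))
    return scheme


@dataclasses.dataclass
class ControlSummaryMatrix:
    """Sample x measure summary values."""

    values: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def measures(self) -> list[str]:
        return list(self.values.columns)


def summarize_controls(channels: ChannelData,
                       manifest: ProbeManifest,
                       oob_green: np.ndarray,
                       oob_red: np.ndarray,
                       scheme: list[SummaryMeasure] | None = None,
                       require_all: bool = False) -> ControlSummaryMatrix:
    """Condense control probes and out-of-band values into summary measures.

    Scheme entries whose control category is absent from the manifest are
    dropped (their columns simply do not appear) unless ``require_all`` is
    set, in which case a missing category raises ``ConfigurationError``.
    """
    if scheme is None:
        scheme = STANDARD_CONTROL_SCHEME
    ctl = manifest.controls()
    present = set(ctl["control_category"])
    samples = channels.samples
    mats = {CHANNEL_GREEN: channels.green, CHANNEL_RED: channels.red}

    columns: dict[str, np.ndarray] = {}
    for measure in scheme:
        if measure.category not in present:
            if require_all:
                raise ConfigurationError(
                    f"control category {measure.category!r} declared in the "
                    "summary scheme has no probes in the manifest")
            continue
        if measure.statistic != "mean":
            raise ConfigurationError(
                f"unsupported statistic {measure.statistic!r}")
        sub = ctl[ctl["control_category"] == measure.category]
        mat = mats[measure.channel]
        pos = mat.index.get_indexer(sub["address_a"])
        if (pos < 0).any():
            raise ValidationError(
                f"control addresses for {measure.category!r} missing from channels")
        columns[measure.name] = np.log2(1.0 + mat.to_numpy()[pos]).mean(axis=0)
    if not columns:
        raise ConfigurationError("no scheme category present in the manifest")

    oob_green = np.asarray(oob_green, dtype=float)
    oob_red = np.asarray(oob_red, dtype=float)
    if oob_green.size == 0 or oob_red.size == 0:
        raise ConfigurationError("out-of-band intensities are required")
    lg = np.log2(1.0 + oob_green)
    lr = np.log2(1.0 + oob_red)
    columns["oob.green.mean"] = lg.mean(axis=0)
    columns["oob.green.p01"] = np.percentile(lg, 1, axis=0)
    columns["oob.red.mean"] = lr.mean(axis=0)
    columns["oob.red.p01"] = np.percentile(lr, 1, axis=0)

    values = pd.DataFrame(columns, index=pd.Index(samples, name="sample_id"))
    if not np.isfinite(values.to_numpy()).all():
        raise ValidationError("non-finite control summary values")
    return ControlSummaryMatrix(values)


@dataclasses.dataclass
class CovariateMatrix:
    """Principal-component scores of the standardized control summaries.

    ``Z`` has one mean-zero column per retained component; the centering and
    scaling applied to the summary columns are recorded for provenance.
    """

    Z: np.ndarray
    explained_variance_ratio: np.ndarray
    column_means: pd.Series
    column_sds: pd.Series
    kept_columns: list[str]

    @property
    def m(self) -> int:
        return self.Z.shape[1]


def control_covariates(summary: ControlSummaryMatrix, m: int = 2) -> CovariateMatrix:
    """First ``m`` principal-component score columns of the summary matrix.

    Columns are standardized (zero-variance columns dropped with a warning),
    scores are computed by SVD, and each component's sign is fixed so that
    its largest-magnitude loading is positive.
    """
    X = summary.values
    n = X.shape[0]
    if m < 0:
        raise ValidationError("m must be >= 0")
    if m >= n:
        raise ValidationError(f"m={m} must be smaller than the number of samples ({n})")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.any():
        raise ValidationError("all summary columns have zero variance")
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance summary column(s)")
    Xs = ((X.loc[:, keep] - means[keep]) / sds[keep]).to_numpy()
    if m == 0:
        return CovariateMatrix(np.zeros((n, 0)), np.zeros(0), means, sds,
                               list(X.columns[keep]))
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    scores = U[:, :m] * S[:m]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(scores.shape[1]):
        k = np.argmax(np.abs(Vt[j]))
        if Vt[j, k] < 0:
            scores[:, j] *= -1.0
    scores = scores - scores.mean(axis=0)
    total = (S ** 2).sum()
    evr = (S[:m] ** 2) / total if total > 0 else np.zeros(m)
    return CovariateMatrix(scores, evr, means, sds, list(X.columns[keep]))


@dataclasses.dataclass
class BatchAssociationReport:
    plate_means: pd.DataFrame   # plate x measure means
    pc_scores: pd.DataFrame     # sample, PC1, PC2, plate
    pc1_plate_r2: float
    notice: str | None = None


def _eta_squared(values: np.ndarray, labels: pd.Series) -> float:
    """Fraction of variance of a vector explained by a grouping factor."""
    values = np.asarray(values, dtype=float)
    grand = values.mean()
    ss_tot = ((values - grand) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    ss_within = 0.0
    for _, idx in pd.Series(range(len(values))).groupby(labels.to_numpy()):
        grp = values[idx.to_numpy()]
        ss_within += ((grp - grp.mean()) ** 2).sum()
    return 1.0 - ss_within / ss_tot


def batch_association_report(summary: ControlSummaryMatrix,
                             samplesheet: SampleSheet) -> BatchAssociationReport:
    """Per-plate summary means and the first two PC scores labeled by plate.

    This is the diagnostic showing whether control summaries cluster by
    processing plate, i.e. whether they can act as batch surrogates.
    """
    sheet = samplesheet.aligned_to(summary.samples)
    plates = sheet["plate"]
    plate_means = summary.values.groupby(plates.to_numpy()).mean()
    plate_means.index.name = "plate"
    cov = control_covariates(summary, m=min(2, len(summary.samples) - 1))
    Z = cov.Z
    pc_scores = pd.DataFrame({
        "sample_id": summary.samples,
        "PC1": Z[:, 0] if Z.shape[1] > 0 else np.zeros(len(summary.samples)),
        "PC2": Z[:, 1] if Z.shape[1] > 1 else np.zeros(len(summary.samples)),
        "plate": plates.to_numpy(),
    })
    r2 = _eta_squared(pc_scores["PC1"].to_numpy(), plates)
    notice = "single plate: no between-plate contrast" if plates.nunique() < 2 else None
    return BatchAssociationReport(plate_means, pc_scores, r2, notice)
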