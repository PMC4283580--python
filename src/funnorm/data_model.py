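"""Core data containers, plain-table I/O and raw channel-to-probe matching.

Two-color Infinium-style methylation arrays read every bead address in both a
green and a red channel.  A probe manifest maps addresses back to probes:

* type II probes use a single address, methylated signal in green and
  unmethylated in red;
* type I probes use two addresses (A = unmethylated, B = methylated) read in
  a single design channel (green or red).  The readings of type I probes in
  the *opposite* channel carry no target signal and are kept as out-of-band
  (oob) background measurements.

"Raw" preprocessing is nothing more than this relabeling; the methylation
proportion is estimated with the standard beta formula
``beta = M / (M + U + 100)``.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, FormatError, ValidationError

DESIGN_I_GREEN = "I_GREEN"
DESIGN_I_RED = "I_RED"
DESIGN_II = "II"
DESIGN_TYPES = (DESIGN_I_GREEN, DESIGN_I_RED, DESIGN_II)

SEX_MALE = "MALE"
SEX_FEMALE = "FEMALE"
SEX_UNKNOWN = "UNKNOWN"
SEXES = (SEX_MALE, SEX_FEMALE, SEX_UNKNOWN)

MANIFEST_COLUMNS = [
    "probe_id",
    "design_type",
    "chromosome",
    "is_control",
    "control_category",
    "address_a",
    "address_b",
]

SAMPLESHEET_COLUMNS = [
    "sample_id",
    "sex",
    "plate",
    "slide",
    "row",
    "column",
    "group",
    "replicate_of",
]

# consistent with a MAD-to-sd conversion under normality
MAD_SCALE = 1.4826


def _fail_rows(problems: list[str]) -> None:
    if problems:
        raise ValidationError("; ".join(problems))


@dataclasses.dataclass
class ProbeManifest:
    """Validated probe annotation table.

    The underlying table has one row per probe with columns
    ``probe_id, design_type, chromosome, is_control, control_category,
    address_a, address_b`` (``is_control`` is boolean, text columns hold
    empty strings rather than NaN).
    """

    table: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeManifest":
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"manifest missing required column(s): {missing}")
        df = df[MANIFEST_COLUMNS].copy()
        for col in ("probe_id", "design_type", "chromosome", "control_category",
                    "address_a", "address_b"):
            df[col] = df[col].fillna("").astype(str)
        if df["is_control"].dtype != bool:
            df["is_control"] = (
                df["is_control"].astype(str).str.strip().str.lower()
                .map({"1": True, "true": True, "0": False, "false": False})
            )
            if df["is_control"].isna().any():
                raise FormatError("is_control must be 0/1 or true/false")
            df["is_control"] = df["is_control"].astype(bool)

        dup = df["probe_id"][df["probe_id"].duplicated()].unique()
        if len(dup):
            raise ValidationError(f"duplicate probe_id(s): {list(dup[:5])}")

        problems: list[str] = []

        def bad(mask: pd.Series, what: str) -> None:
            rows = (np.flatnonzero(mask.to_numpy()) + 1).tolist()
            if rows:
                problems.append(f"{what} (rows {rows[:10]})")

        bad(~df["design_type"].isin(DESIGN_TYPES), "unknown design_type")
        bad((df["design_type"] == DESIGN_II) & (df["address_b"] != ""),
            "type II probe with address_b")
        bad((df["design_type"] != DESIGN_II) & (df["address_b"] == ""),
            "type I probe without address_b")
        bad(df["address_a"] == "", "missing address_a")
        ctl = df["is_control"]
        bad(ctl & (df["control_category"] == ""),
            "control probe without control_category")
        bad(ctl & (df["chromosome"] != ""), "control probe with chromosome")
        bad(~ctl & (df["chromosome"] == ""), "non-control probe without chromosome")
        bad(~ctl & (df["control_category"] != ""),
            "non-control probe with control_category")
        _fail_rows(problems)
        return cls(df.reset_index(drop=True))

    @property
    def probe_ids(self) -> pd.Series:
        return self.table["probe_id"]

    def non_control(self) -> pd.DataFrame:
        return self.table[~self.table["is_control"]].reset_index(drop=True)

    def controls(self) -> pd.DataFrame:
        return self.table[self.table["is_control"]].reset_index(drop=True)

    def control_categories(self) -> list[str]:
        return sorted(self.controls()["control_category"].unique())

    def all_addresses(self) -> pd.Series:
        t = self.table
        return pd.concat([t["address_a"], t.loc[t["address_b"] != "", "address_b"]],
                         ignore_index=True)


@dataclasses.dataclass
class SampleSheet:
    """Sample metadata: identity, sex, plate/slide/position layout and group."""

    table: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleSheet":
        missing = [c for c in SAMPLESHEET_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing required column(s): {missing}")
        df = df[SAMPLESHEET_COLUMNS].copy()
        for col in ("sample_id", "sex", "plate", "slide", "group", "replicate_of"):
            df[col] = df[col].fillna("").astype(str)
        df["row"] = pd.to_numeric(df["row"], errors="raise").astype(int)
        df["column"] = pd.to_numeric(df["column"], errors="raise").astype(int)
        dup = df["sample_id"][df["sample_id"].duplicated()].unique()
        if len(dup):
            raise ValidationError(f"duplicate sample_id(s): {list(dup[:5])}")
        problems: list[str] = []
        if (~df["sex"].isin(SEXES)).any():
            problems.append("sex must be MALE/FEMALE/UNKNOWN")
        if ((df["row"] < 1) | (df["row"] > 6)).any():
            problems.append("row must be in 1..6")
        if ((df["column"] < 1) | (df["column"] > 2)).any():
            problems.append("column must be in 1..2")
        _fail_rows(problems)
        return cls(df.reset_index(drop=True))

    @property
    def sample_ids(self) -> pd.Series:
        return self.table["sample_id"]

    def aligned_to(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        """Return rows reordered to a sample-id sequence (all must exist)."""
        t = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in t.index]
        if missing:
            raise ValidationError(f"sample sheet missing sample(s): {missing[:5]}")
        return t.loc[list(sample_ids)].reset_index()


@dataclasses.dataclass
class ChannelData:
    """Green/red intensity matrices indexed by bead address (rows) and
    sample id (columns)."""

    green: pd.DataFrame
    red: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.green.index.equals(self.red.index):
            raise ValidationError("green and red channels must share addresses")
        if list(self.green.columns) != list(self.red.columns):
            raise ValidationError("green and red channels must share sample order")
        for name, mat in (("green", self.green), ("red", self.red)):
            values = mat.to_numpy()
            if not np.isfinite(values).all():
                raise ValidationError(f"{name} channel contains non-finite values")
            if (values < 0).any():
                raise ValidationError(f"{name} channel contains negative values")

    @property
    def samples(self) -> list[str]:
        return list(self.green.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ChannelData":
        return ChannelData(self.green[list(sample_ids)], self.red[list(sample_ids)])


@dataclasses.dataclass
class MethylSet:
    """Methylated/unmethylated intensities per probe plus out-of-band values.

    ``M`` and ``U`` are probe x sample DataFrames in manifest probe order;
    ``oob_green``/``oob_red`` are value x sample arrays holding the type I
    probe readings from the opposite color channel.
    """

    M: pd.DataFrame
    U: pd.DataFrame
    oob_green: np.ndarray
    oob_red: np.ndarray

    def __post_init__(self) -> None:
        if self.M.shape != self.U.shape:
            raise ValidationError("M and U must have the same shape")
        if not (np.isfinite(self.M.to_numpy()).all()
                and np.isfinite(self.U.to_numpy()).all()):
            raise ValidationError("M/U contain non-finite values")

    @property
    def probes(self) -> pd.Index:
        return self.M.index

    @property
    def samples(self) -> list[str]:
        return list(self.M.columns)

    def copy(self) -> "MethylSet":
        return MethylSet(self.M.copy(), self.U.copy(),
                         self.oob_green.copy(), self.oob_red.copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylSet":
        cols = list(sample_ids)
        pos = [self.samples.index(s) for s in cols]
        return MethylSet(self.M[cols], self.U[cols],
                         self.oob_green[:, pos], self.oob_red[:, pos])


@dataclasses.dataclass
class BetaMatrix:
    """Beta values (methylation proportions) per probe and sample."""

    beta: pd.DataFrame
    offset: float = 100.0

    def __post_init__(self) -> None:
        values = self.beta.to_numpy()
        if ((values < 0) | (values > 1)).any() or not np.isfinite(values).all():
            raise ValidationError("beta values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Plain-table I/O
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> ProbeManifest:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return ProbeManifest.from_frame(df)


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    out = manifest.table.copy()
    out["is_control"] = out["is_control"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_samplesheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return SampleSheet.from_frame(df)


def write_samplesheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index=False)


def read_channels(green_path: str | Path, red_path: str | Path) -> ChannelData:
    """Read one wide TSV per channel (rows = addresses, columns = samples)."""
    green = pd.read_csv(green_path, sep="\t", index_col=0)
    red = pd.read_csv(red_path, sep="\t", index_col=0)
    green.index = green.index.astype(str)
    red.index = red.index.astype(str)
    return ChannelData(green.astype(float), red.astype(float))


def read_channels_long(path: str | Path) -> ChannelData:
    """Read a single long-format TSV with columns
    ``address, sample_id, green, red``."""
    df = pd.read_csv(path, sep="\t", dtype={"address": str, "sample_id": str})
    missing = [c for c in ("address", "sample_id", "green", "red")
               if c not in df.columns]
    if missing:
        raise FormatError(f"long channel table missing column(s): {missing}")
    green = df.pivot(index="address", columns="sample_id", values="green")
    red = df.pivot(index="address", columns="sample_id", values="red")
    return ChannelData(green.astype(float), red[green.columns].astype(float))


def write_channels(channels: ChannelData, green_path: str | Path,
                   red_path: str | Path) -> None:
    channels.green.to_csv(green_path, sep="\t", index_label="address")
    channels.red.to_csv(red_path, sep="\t", index_label="address")


# ---------------------------------------------------------------------------
# Raw preprocessing
# ---------------------------------------------------------------------------

def preprocess_raw(channels: ChannelData, manifest: ProbeManifest) -> MethylSet:
    """Match red and green channel readings to probes by array design.

    Pure relabeling: type II probes take M from green and U from red at their
    single address; type I probes take M from address B and U from address A,
    both in the design channel.  Type I readings in the opposite channel are
    collected as out-of-band background intensities.
    """
    gidx = channels.green.index
    gv = channels.green.to_numpy(dtype=float)
    rv = channels.red.to_numpy(dtype=float)

    def locate(addresses: pd.Series, probes: pd.Series) -> np.ndarray:
        pos = gidx.get_indexer(addresses)
        if (pos < 0).any():
            bad = probes[pos < 0].iloc[0]
            raise LookupError(
                f"address not present in channel data (first probe: {bad!r})")
        return pos

    table = manifest.table
    # verify every manifest address exists, controls included
    locate(table["address_a"], table["probe_id"])
    with_b = table[table["address_b"] != ""]
    locate(with_b["address_b"], with_b["probe_id"])

    ann = manifest.non_control()
    n_probes, n_samples = len(ann), gv.shape[1]
    M = np.empty((n_probes, n_samples))
    U = np.empty((n_probes, n_samples))

    pos_a = gidx.get_indexer(ann["address_a"])
    design = ann["design_type"].to_numpy()
    ii = design == DESIGN_II
    ig = design == DESIGN_I_GREEN
    ir = design == DESIGN_I_RED
    M[ii] = gv[pos_a[ii]]
    U[ii] = rv[pos_a[ii]]
    for mask, mat in ((ig, gv), (ir, rv)):
        if mask.any():
            pos_b = gidx.get_indexer(ann.loc[mask, "address_b"])
            M[mask] = mat[pos_b]
            U[mask] = mat[pos_a[mask]]

    # out-of-band: all type I probes (controls included) in the other channel
    t1g = table[table["design_type"] == DESIGN_I_GREEN]
    t1r = table[table["design_type"] == DESIGN_I_RED]

    def stack_oob(sub: pd.DataFrame, mat: np.ndarray) -> np.ndarray:
        if sub.empty:
            return np.empty((0, n_samples))
        pos = np.concatenate([gidx.get_indexer(sub["address_a"]),
                              gidx.get_indexer(sub["address_b"])])
        return mat[pos]

    oob_red = stack_oob(t1g, rv)    # green-design probes read in red
    oob_green = stack_oob(t1r, gv)  # red-design probes read in green

    probe_index = pd.Index(ann["probe_id"], name="probe_id")
    samples = channels.samples
    return MethylSet(
        pd.DataFrame(M, index=probe_index, columns=samples),
        pd.DataFrame(U, index=probe_index, columns=samples),
        oob_green, oob_red,
    )


def beta_values(mset: MethylSet, offset: float = 100.0) -> BetaMatrix:
    """Beta = M / (M + U + offset), elementwise."""
    if offset <= 0:
        raise ValidationError("offset must be positive")
    M = mset.M.to_numpy()
    U = mset.U.to_numpy()
    if (M < 0).any() or (U < 0).any():
        raise ValidationError("negative M or U intensity")
    beta = M / (M + U + offset)
    return BetaMatrix(pd.DataFrame(beta, index=mset.probes, columns=mset.samples),
                      offset=offset)


# ---------------------------------------------------------------------------
# Detection QC and locus filtering
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DetectionQC:
    p_values: pd.DataFrame       # probe x sample detection p-values
    fail_fraction: pd.Series     # per sample, fraction of undetected loci
    passes: pd.Series            # per sample pass/fail


def extract_negative_controls(channels: ChannelData,
                              manifest: ProbeManifest,
                              category: str = "NEGATIVE") -> tuple[np.ndarray, np.ndarray]:
    """Negative-control intensities per channel (value x sample arrays)."""
    ctl = manifest.controls()
    neg = ctl[ctl["control_category"] == category]
    if neg.empty:
        raise ConfigurationError(f"no control probes in category {category!r}")
    pos = channels.green.index.get_indexer(neg["address_a"])
    return (channels.green.to_numpy()[pos], channels.red.to_numpy()[pos])


def detection_qc(mset: MethylSet,
                 neg_green: np.ndarray,
                 neg_red: np.ndarray,
                 p_threshold: float = 0.01,
                 sample_fail_fraction: float = 0.10) -> DetectionQC:
    """Per-locus detection p-values against a negative-control background.

    The background of the total intensity M+U is modeled per sample as
    Normal with mean = sum of the per-channel negative-control medians and
    sd = sum of the per-channel MAD-based sds.  The detection p-value is the
    one-sided upper tail probability of the background at the observed total;
    a locus with p > ``p_threshold`` is undetected, and a sample fails when
    its undetected fraction exceeds ``sample_fail_fraction``.
    """
    neg_green = np.asarray(neg_green, dtype=float)
    neg_red = np.asarray(neg_red, dtype=float)
    if neg_green.shape[0] < 2 or neg_red.shape[0] < 2:
        raise ConfigurationError(
            "need at least 2 negative-control values per channel per sample")
    mu = np.median(neg_green, axis=0) + np.median(neg_red, axis=0)
    sd = (MAD_SCALE * stats.median_abs_deviation(neg_green, axis=0)
          + MAD_SCALE * stats.median_abs_deviation(neg_red, axis=0))
    sd = np.maximum(sd, 1e-6)
    total = mset.M.to_numpy() + mset.U.to_numpy()
    p = stats.norm.sf(total, loc=mu[np.newaxis, :], scale=sd[np.newaxis, :])
    p_df = pd.DataFrame(p, index=mset.probes, columns=mset.samples)
    frac = pd.Series((p > p_threshold).mean(axis=0), index=mset.samples,
                     name="fail_fraction")
    passes = pd.Series(frac.to_numpy() <= sample_fail_fraction,
                       index=mset.samples, name="passes")
    return DetectionQC(p_df, frac, passes)


@dataclasses.dataclass
class FilterReport:
    per_list_counts: list[int]
    unknown_counts: list[int]
    union_count: int
    n_before: int
    n_after: int


def filter_loci(obj: MethylSet | BetaMatrix,
                *drop_lists: Iterable[str]) -> tuple[MethylSet | BetaMatrix, FilterReport]:
    """Remove the union of one or more probe-id drop lists.

    Unknown probe ids are ignored (counted in the report); empty input lists
    leave the object unchanged.
    """
    probes = obj.beta.index if isinstance(obj, BetaMatrix) else obj.probes
    known = set(probes)
    per_list, unknown, union = [], [], set()
    for lst in drop_lists:
        ids = set(lst)
        hit = ids & known
        per_list.append(len(hit))
        unknown.append(len(ids - known))
        union |= hit
    if any(unknown):
        warnings.warn(f"ignored {sum(unknown)} unknown probe id(s) in drop lists")
    keep = ~probes.isin(union)
    report = FilterReport(per_list, unknown, len(union),
                          n_before=len(probes), n_after=int(keep.sum()))
    if isinstance(obj, BetaMatrix):
        return BetaMatrix(obj.beta.loc[keep], obj.offset), report
    return MethylSet(obj.M.loc[keep], obj.U.loc[keep],
                     obj.oob_green, obj.oob_red), report
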