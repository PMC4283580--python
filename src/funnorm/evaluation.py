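"""Differentially methylated position (DMP) calling and replication metrics.

DMPs are called probe-by-probe with an F-test for a group factor in a linear
model on beta values (optionally adjusting for a batch factor).  Method
robustness is judged by how well results replicate between separately
normalized discovery and validation cohorts: an ROC curve against the
discovery top-k taken as gold standard, and a concordance curve giving the
percentage overlap of the two top-k lists as k grows.  Technical-replicate
variance and effect-size distributions round out the benchmark suite, and a
balanced subsampling scheme measures how replication degrades with sample
size.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as _skmetrics

from .data_model import BetaMatrix
from .errors import ValidationError


def _design_matrix(factors: list[np.ndarray], n: int) -> np.ndarray:
    cols = [np.ones(n)]
    for values in factors:
        levels = pd.unique(values)
        for level in levels[1:]:  # first level absorbed by the intercept
            cols.append((values == level).astype(float))
    return np.column_stack(cols)


def find_dmps(beta: BetaMatrix | pd.DataFrame,
              groups: Sequence[str],
              batch: Sequence[str] | None = None) -> pd.DataFrame:
    """Probe-wise F-statistics for a group factor in a linear model on beta.

    Returns a table indexed by probe_id with columns ``F``, ``p``, ``rank``
    (1 = most significant, ties broken lexicographically by probe_id) and,
    for two groups, ``effect`` = mean(beta | first group) - mean(beta |
    second group) in sorted label order.
    """
    table = beta.beta if isinstance(beta, BetaMatrix) else beta
    Y = table.to_numpy().T  # samples x probes
    n = Y.shape[0]
    groups = np.asarray(groups)
    if groups.shape[0] != n:
        raise ValidationError("group labels must match the sample count")
    levels = sorted(pd.unique(groups))
    if len(levels) < 2:
        raise ValidationError("need at least two groups")
    counts = pd.Series(groups).value_counts()
    if (counts < 2).any():
        raise ValidationError("every group needs at least two samples")

    factors = [groups]
    null_factors: list[np.ndarray] = []
    if batch is not None:
        batch = np.asarray(batch)
        factors.append(batch)
        null_factors.append(batch)
    X1 = _design_matrix(factors, n)
    X0 = _design_matrix(null_factors, n)
    r1 = np.linalg.matrix_rank(X1)
    r0 = np.linalg.matrix_rank(X0)
    df_num = r1 - r0
    df_den = n - r1
    if df_den < 1:
        raise ValidationError("zero residual degrees of freedom")
    if df_num < 1:
        raise ValidationError("group factor is confounded with the batch factor")

    def rss(X: np.ndarray) -> np.ndarray:
        Q, _ = np.linalg.qr(X)
        resid = Y - Q @ (Q.T @ Y)
        return (resid ** 2).sum(axis=0)

    rss1 = rss(X1)
    rss0 = rss(X0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    F = np.where(rss1 <= 1e-300,
                 np.where(rss0 - rss1 > 1e-300, np.inf, 0.0), F)
    F = np.maximum(F, 0.0)
    p = stats.f.sf(F, df_num, df_den)

    out = pd.DataFrame({"F": F, "p": p}, index=table.index)
    # rank by F descending, ties broken lexicographically by probe id
    with np.errstate(invalid="ignore"):
        order = np.lexsort((table.index.to_numpy().astype(str), -F))
    ranks = np.empty(len(F), dtype=int)
    ranks[order] = np.arange(1, len(F) + 1)
    out["rank"] = ranks
    if len(levels) == 2:
        g1 = table.loc[:, groups == levels[0]].mean(axis=1)
        g2 = table.loc[:, groups == levels[1]].mean(axis=1)
        out["effect"] = g1 - g2
    return out


def ranking_from_dmps(dmps: pd.DataFrame) -> list[str]:
    """Probe ids ordered from most to least significant."""
    return list(dmps.sort_values("rank").index)


@dataclasses.dataclass
class CurveData:
    """Either an ROC curve (x = 1-specificity, y = sensitivity, with AUC)
    or a concordance curve (x = k, y = overlap %)."""

    kind: str
    x: np.ndarray
    y: np.ndarray
    auc: float | None = None


def roc_vs_gold(gold: Iterable[str],
                validation_ranking: Sequence[str],
                universe: Sequence[str] | None = None) -> CurveData:
    """ROC of a validation ranking against a gold-standard probe set.

    Probes are swept in validation rank order; sensitivity/specificity are
    computed against membership in the gold set within the universe
    (defaults to the ranked probes).  AUC is the trapezoidal area.
    """
    gold = set(gold)
    if not gold:
        raise ValidationError("gold standard set is empty")
    if universe is None:
        universe = list(validation_ranking)
    if not gold <= set(universe):
        raise ValidationError("gold set must be contained in the universe")
    pos = {pid: i for i, pid in enumerate(validation_ranking)}
    n = len(validation_ranking)
    labels = np.fromiter((pid in gold for pid in universe), dtype=bool,
                         count=len(universe))
    scores = np.fromiter((float(n - pos[pid]) if pid in pos else 0.0
                          for pid in universe), dtype=float, count=len(universe))
    fpr, tpr, _ = _skmetrics.roc_curve(labels, scores)
    return CurveData("roc", fpr, tpr, auc=float(_skmetrics.auc(fpr, tpr)))


def concordance_curve(rank1: Sequence[str],
                      rank2: Sequence[str],
                      k_values: Sequence[int] | None = None,
                      k_max: int | None = None) -> CurveData:
    """Percentage overlap of the two top-k lists for each k.

    Symmetric in its two rankings.  If explicit ``k_values`` are not given,
    a log-spaced grid up to ``k_max`` is used.
    """
    universe = min(len(rank1), len(rank2))
    if k_max is None:
        k_max = universe
    if k_max > universe:
        warnings.warn(f"k_max={k_max} clamped to the universe size {universe}")
        k_max = universe
    if k_values is None:
        k_values = np.unique(np.round(
            np.logspace(0, np.log10(k_max), num=30)).astype(int))
    ks = np.asarray(sorted({int(k) for k in k_values if 1 <= k <= k_max}))
    pos2 = {pid: i for i, pid in enumerate(rank2)}
    positions = np.fromiter((pos2.get(pid, np.iinfo(np.int64).max)
                             for pid in rank1), dtype=np.int64, count=len(rank1))
    overlap = np.array([np.count_nonzero(positions[:k] < k) for k in ks])
    return CurveData("concordance", ks, 100.0 * overlap / ks)


def replicate_variance(beta: BetaMatrix | pd.DataFrame,
                       replicate_groups: Mapping[str, Sequence[str]]) -> pd.Series:
    """Per-probe technical variance: within-group sample variance (ddof=1)
    averaged over replicate groups.  Singleton groups are excluded with a
    warning."""
    table = beta.beta if isinstance(beta, BetaMatrix) else beta
    usable = []
    for name, members in replicate_groups.items():
        members = list(members)
        if len(members) < 2:
            warnings.warn(f"replicate group {name!r} has fewer than 2 members; excluded")
            continue
        usable.append(members)
    if not usable:
        raise ValidationError("no replicate group with >= 2 members")
    variances = np.column_stack([
        table[members].var(axis=1, ddof=1).to_numpy() for members in usable])
    return pd.Series(variances.mean(axis=1), index=table.index,
                     name="replicate_variance")


def effect_sizes(beta: BetaMatrix | pd.DataFrame,
                 ranking: Sequence[str],
                 groups: Sequence[str],
                 k: int) -> pd.Series:
    """Group-mean beta differences for the top-k probes of a ranking
    (two groups, sorted label order: first minus second)."""
    table = beta.beta if isinstance(beta, BetaMatrix) else beta
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValidationError("effect sizes are defined for exactly two groups")
    top = [pid for pid in ranking[:k] if pid in table.index]
    sub = table.loc[top]
    diff = (sub.loc[:, groups == levels[0]].mean(axis=1)
            - sub.loc[:, groups == levels[1]].mean(axis=1))
    return diff.rename("effect")


@dataclasses.dataclass
class SubsampleRoc:
    """Pointwise mean ROC and percentile band for one subsample size."""

    size: int
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    lower_tpr: np.ndarray
    upper_tpr: np.ndarray
    aucs: np.ndarray


def subsample_roc(sample_ids: Sequence[str],
                  groups: Sequence[str],
                  gold: Iterable[str],
                  rank_subset: Callable[[list[str]], Sequence[str]],
                  sizes: Sequence[int] = (10, 20, 30, 50, 80),
                  B: int = 100,
                  seed: int = 0,
                  fpr_grid: np.ndarray | None = None) -> dict[int, SubsampleRoc]:
    """Balanced subsampling of the validation cohort.

    For each size n, draw n/2 samples per group B times; ``rank_subset``
    maps the drawn sample ids to a validation probe ranking (normalization +
    DMP calling on the subset), which is scored against the fixed gold set.
    Reports the pointwise mean ROC and the 0.025/0.975 percentile band on a
    common false-positive-rate grid.
    """
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    sample_ids = list(sample_ids)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValidationError("subsampling needs exactly two groups")
    by_group = {lvl: [s for s, g in zip(sample_ids, groups) if g == lvl]
                for lvl in levels}
    rng = np.random.default_rng(seed)
    out: dict[int, SubsampleRoc] = {}
    for size in sizes:
        half = size // 2
        if any(len(v) < half for v in by_group.values()):
            raise ValidationError(f"subsample size {size} exceeds group sizes")
        curves = np.empty((B, fpr_grid.size))
        aucs = np.empty(B)
        for b in range(B):
            chosen = sorted(
                [s for lvl in levels
                 for s in rng.choice(by_group[lvl], size=half, replace=False)])
            ranking = rank_subset(chosen)
            roc = roc_vs_gold(gold, ranking)
            # step-function interpolation of the ROC onto the common grid
            curves[b] = np.interp(fpr_grid, roc.x, roc.y)
            aucs[b] = roc.auc
        out[size] = SubsampleRoc(
            size=size, fpr_grid=fpr_grid,
            mean_tpr=curves.mean(axis=0),
            lower_tpr=np.percentile(curves, 2.5, axis=0),
            upper_tpr=np.percentile(curves, 97.5, axis=0),
            aucs=aucs)
    return out


def batch_r2(features: np.ndarray, labels: Sequence[str]) -> float:
    """Fraction of total (column-centered) variance of a samples x features
    matrix explained by a categorical label -- the batch-association R²."""
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    Xc = X - X.mean(axis=0)
    ss_tot = (Xc ** 2).sum()
    if ss_tot == 0:
        return 0.0
    ss_within = 0.0
    for level in pd.unique(labels):
        grp = X[labels == level]
        ss_within += ((grp - grp.mean(axis=0)) ** 2).sum()
    return float(1.0 - ss_within / ss_tot)
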