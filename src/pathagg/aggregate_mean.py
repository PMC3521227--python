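"""Mean-based pathway aggregation: all members, top 50% by |t|, and CORGs.

All three methods share the same transform — the arithmetic mean of the
selected member genes' z-scaled rows — and differ only in how the subset is
chosen on the training data:

* *mean_all*: every measured member.
* *mean_top50*: the ceil(m/2) members with the largest |t| (optionally the
  largest directional t, matching the CORG ordering).
* *mean_corgs*: the condition-responsive genes.  The pathway's net
  regulatory direction d is the sign of the mean member t-statistic;
  members are sorted with the most strongly d-regulated genes first, and
  the prefix is grown greedily while the absolute t-statistic of the
  prefix-mean profile strictly improves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pathagg.data_io import (
    DataError,
    ExpressionDataset,
    GeneSetCollection,
    PathwayExpression,
    warn_dropped,
)
from pathagg.preprocess import ScalingParams, gene_t_statistics, two_sample_t

MEAN_METHODS = ("mean_all", "mean_top50", "mean_corgs")


@dataclass
class PathwaySubset:
    genes: tuple[str, ...]
    direction: int = +1  # CORGs only; +1 on exact ties


@dataclass
class GeneSubsetModel:
    """Training-derived gene subsets per pathway for a mean-based method."""

    method: str
    scaling: ScalingParams
    pathways: dict[str, PathwaySubset] = field(default_factory=dict)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.pathways)


def _measured(sets: GeneSetCollection, zds: ExpressionDataset) -> dict[str, list[str]]:
    """Measured members per pathway; 0-member pathways dropped with warning."""
    out: dict[str, list[str]] = {}
    for gs in sets:
        measured = gs.measured_members(zds.gene_ids)
        if not measured:
            warn_dropped(gs.name, "no measured member genes")
            continue
        out[gs.name] = measured
    if not out:
        raise DataError("no pathway retains any measured member gene")
    return out


def fit_mean_all(zds: ExpressionDataset, sets: GeneSetCollection, scaling: ScalingParams) -> GeneSubsetModel:
    """Select every measured member of each pathway (catalogue order)."""
    model = GeneSubsetModel("mean_all", scaling)
    for name, measured in _measured(sets, zds).items():
        model.pathways[name] = PathwaySubset(tuple(measured))
    return model


def fit_mean_top50(
    zds: ExpressionDataset,
    sets: GeneSetCollection,
    scaling: ScalingParams,
    directional: bool = False,
) -> GeneSubsetModel:
    """Select the top half of members by t-statistic magnitude.

    With ``directional=True`` members are instead ordered by signed t in the
    pathway's net direction (the CORG ordering) before taking the top half.
    """
    gstats = gene_t_statistics(zds)
    model = GeneSubsetModel("mean_top50", scaling)
    for name, measured in _measured(sets, zds).items():
        t = gstats.t.loc[measured]
        if directional:
            d = _direction(t)
            order = _sort_members(t, d)
        else:
            order = sorted(measured, key=lambda g: (-abs(t.loc[g]), g))
        k = math.ceil(len(measured) / 2)
        model.pathways[name] = PathwaySubset(tuple(order[:k]))
    return model


def _direction(t: pd.Series) -> int:
    """Net pathway direction: sign of the mean member t; +1 on an exact tie."""
    m = float(t.mean())
    return -1 if m < 0 else +1


def _sort_members(t: pd.Series, direction: int) -> list[str]:
    """Members with the most strongly direction-regulated genes first."""
    return sorted(t.index, key=lambda g: (-direction * t.loc[g], g))


def fit_mean_corgs(zds: ExpressionDataset, sets: GeneSetCollection, scaling: ScalingParams) -> GeneSubsetModel:
    """Greedy condition-responsive gene search per pathway."""
    gstats = gene_t_statistics(zds)
    model = GeneSubsetModel("mean_corgs", scaling)
    for name, measured in _measured(sets, zds).items():
        d = _direction(gstats.t.loc[measured])
        order = _sort_members(gstats.t.loc[measured], d)
        k = corg_prefix_length(zds, order)
        model.pathways[name] = PathwaySubset(tuple(order[:k]), direction=d)
    return model


def corg_prefix_length(zds: ExpressionDataset, order: list[str]) -> int:
    """Length of the greedy CORG prefix of a direction-sorted member list.

    Extends the prefix while |t| of its mean profile strictly increases;
    stops at the first non-improvement.
    """
    z = zds.values.loc[order].to_numpy()
    running = np.zeros(z.shape[1])
    best = -np.inf
    best_k = 1
    for k in range(1, len(order) + 1):
        running = running + z[k - 1]
        profile = pd.DataFrame((running / k)[None, :], columns=zds.sample_ids)
        score = abs(float(two_sample_t(profile, zds.labels).t.iloc[0]))
        if score > best:
            best, best_k = score, k
        else:
            break
    return best_k


def transform_subset_mean(zds_target: ExpressionDataset, model: GeneSubsetModel) -> PathwayExpression:
    """Pathway profile = arithmetic mean of the selected genes' z rows."""
    rows = {}
    for name, sub in model.pathways.items():
        missing = [g for g in sub.genes if g not in zds_target.gene_ids]
        if missing:
            raise DataError(f"selected gene {missing[0]!r} absent from target ({name})")
        rows[name] = zds_target.values.loc[list(sub.genes)].mean(axis=0)
    return PathwayExpression(
        method=model.method,
        values=pd.DataFrame(rows).T.set_axis(zds_target.sample_ids, axis=1),
        provenance=model.scaling.fitted_on,
    )
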