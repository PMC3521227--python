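"""Unified fit/transform front-end over the six aggregation methods.

``fit_aggregator`` takes a raw (unscaled) labelled training dataset and
returns a :class:`FittedAggregator` whose ``transform`` maps any dataset
with the same genes to a pathways x samples activity matrix, reusing all
training-derived state (scaling parameters, gene subsets, projection
weights, densities) without refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from pathagg.data_io import ExpressionDataset, GeneSetCollection, PathwayExpression
from pathagg import aggregate_assess, aggregate_mean, aggregate_projection
from pathagg.preprocess import zscale_apply, zscale_fit

METHODS = ("mean_all", "mean_top50", "mean_corgs", "assess", "pca", "pls")


@dataclass
class FittedAggregator:
    method: str
    model: Any
    trained_on: str

    def transform(self, ds: ExpressionDataset) -> PathwayExpression:
        """Apply training-derived state to (possibly held-out) samples."""
        if self.method in aggregate_mean.MEAN_METHODS:
            zds = zscale_apply(ds, self.model.scaling)
            return aggregate_mean.transform_subset_mean(zds, self.model)
        if self.method in aggregate_projection.PROJECTION_METHODS:
            zds = zscale_apply(ds, self.model.scaling)
            return aggregate_projection.transform_projection(zds, self.model)
        lam = aggregate_assess.llr_matrix(ds, self.model["densities"])
        pe = aggregate_assess.assess_scores(lam, self.model["sets"], p=self.model["p"])
        pe.provenance = self.trained_on
        return pe

    @property
    def pathway_ids(self) -> list[str]:
        if self.method == "assess":
            # pathways retained at transform time; report catalogue order
            return self.model["sets"].names
        return self.model.pathway_ids


def fit_aggregator(
    ds_train: ExpressionDataset,
    sets: GeneSetCollection,
    method: str,
    top50_directional: bool = False,
    assess_p: float = 1.0,
) -> FittedAggregator:
    """Fit one of the six aggregation methods on a labelled training set."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if method == "assess":
        densities = aggregate_assess.fit_gene_densities(ds_train)
        return FittedAggregator(method, {"densities": densities, "sets": sets, "p": assess_p}, ds_train.name)
    scaling = zscale_fit(ds_train)
    zds = zscale_apply(ds_train, scaling)
    if method == "mean_all":
        model = aggregate_mean.fit_mean_all(zds, sets, scaling)
    elif method == "mean_top50":
        model = aggregate_mean.fit_mean_top50(zds, sets, scaling, directional=top50_directional)
    elif method == "mean_corgs":
        model = aggregate_mean.fit_mean_corgs(zds, sets, scaling)
    elif method == "pca":
        model = aggregate_projection.fit_pathway_pca(zds, sets, scaling)
    else:
        model = aggregate_projection.fit_pathway_pls(zds, sets, scaling)
    return FittedAggregator(method, model, ds_train.name)


def save_model_sidecar(agg: FittedAggregator, path: str | Path) -> None:
    """Serialize per-pathway fitted state as JSON lines."""
    with open(path, "w", encoding="utf-8") as fh:
        if agg.method == "assess":
            rec = {"method": "assess", "p": agg.model["p"], "trained_on": agg.trained_on}
            fh.write(json.dumps(rec) + "\n")
            return
        for name, state in agg.model.pathways.items():
            rec: dict[str, Any] = {"pathway": name, "method": agg.method}
            if agg.method in aggregate_mean.MEAN_METHODS:
                rec["genes"] = list(state.genes)
                rec["direction"] = state.direction
            else:
                rec["genes"] = list(state.genes)
                rec["weights"] = [float(w) for w in state.weights]
                rec["sign"] = state.sign
            fh.write(json.dumps(rec) + "\n")
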