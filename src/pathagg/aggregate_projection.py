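"""PCA and PLS pathway aggregation with sign correction.

Both methods project the z-scaled member-gene submatrix of a pathway onto
a unit-norm weight vector over genes:

* PCA: the first eigenvector of the member-gene correlation matrix
  (equivalently the first right singular direction of the samples x genes
  z-matrix).
* PLS: the first latent-component weight for a univariate class response,
  w = Z' y_c / ||Z' y_c|| with y_c the centered 0/1 class coding
  (0 = control, 1 = case).

Principal components and singular vectors carry an arbitrary orientation
("sign ambiguity"), and PLS scores inherit an arbitrary direction from the
class coding, so both sets of scores are flipped when necessary to
correlate positively with the pathway's mean member profile on the
training samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pathagg.data_io import (
    CASE,
    DataError,
    ExpressionDataset,
    GeneSetCollection,
    PathwayExpression,
    warn_dropped,
)
from pathagg.preprocess import ScalingParams

PROJECTION_METHODS = ("pca", "pls")


@dataclass
class PathwayProjection:
    genes: tuple[str, ...]
    weights: np.ndarray  # unit Euclidean norm, aligned with genes
    sign: int  # +1 or -1, from sign_correct


@dataclass
class ProjectionModel:
    method: str
    scaling: ScalingParams
    pathways: dict[str, PathwayProjection] = field(default_factory=dict)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.pathways)


def sign_correct(scores: np.ndarray, mean_profile: np.ndarray) -> int:
    """Orientation factor making scores correlate positively with the mean
    member profile; +1 on zero or undefined correlation."""
    if np.std(scores) == 0 or np.std(mean_profile) == 0:
        warnings.warn("sign correction undefined (constant vector); keeping +1", stacklevel=2)
        return +1
    r = float(np.corrcoef(scores, mean_profile)[0, 1])
    return -1 if r < 0 else +1


def _member_zmatrix(zds: ExpressionDataset, measured: list[str]) -> np.ndarray:
    """samples x genes z-matrix of the measured members."""
    return zds.values.loc[measured].to_numpy().T


def fit_pathway_pca(zds: ExpressionDataset, sets: GeneSetCollection, scaling: ScalingParams) -> ProjectionModel:
    """First principal component of each pathway's member correlation matrix."""
    if zds.n_samples < 3:
        raise DataError("PCA aggregation requires >= 3 samples")
    n = zds.n_samples
    model = ProjectionModel("pca", scaling)
    for gs in sets:
        measured = gs.measured_members(zds.gene_ids)
        if not measured:
            warn_dropped(gs.name, "no measured member genes")
            continue
        Z = _member_zmatrix(zds, measured)
        if not Z.any():
            warn_dropped(gs.name, "zero-variance member submatrix")
            continue
        if len(measured) == 1:
            w = np.array([1.0])
        else:
            corr = Z.T @ Z / (n - 1)  # rows are z-scaled, so this is the gene correlation matrix
            eigvals, eigvecs = np.linalg.eigh(corr)
            w = eigvecs[:, -1]
        scores = Z @ w
        c = sign_correct(scores, Z.mean(axis=1))
        model.pathways[gs.name] = PathwayProjection(tuple(measured), w, c)
    if not model.pathways:
        raise DataError("no pathway could be fitted by PCA")
    return model


def fit_pathway_pls(zds: ExpressionDataset, sets: GeneSetCollection, scaling: ScalingParams) -> ProjectionModel:
    """First PLS latent-component weights for the centered class response."""
    y = (zds.labels == CASE).to_numpy(dtype=float)
    if y.all() or not y.any():
        raise DataError("PLS aggregation requires both classes")
    y_c = y - y.mean()
    model = ProjectionModel("pls", scaling)
    for gs in sets:
        measured = gs.measured_members(zds.gene_ids)
        if not measured:
            warn_dropped(gs.name, "no measured member genes")
            continue
        Z = _member_zmatrix(zds, measured)
        w = Z.T @ y_c
        norm = np.linalg.norm(w)
        if norm == 0:
            warn_dropped(gs.name, "no member gene covaries with class")
            continue
        w = w / norm
        scores = Z @ w
        c = sign_correct(scores, Z.mean(axis=1))
        model.pathways[gs.name] = PathwayProjection(tuple(measured), w, c)
    if not model.pathways:
        raise DataError("no pathway could be fitted by PLS")
    return model


def transform_projection(zds_target: ExpressionDataset, model: ProjectionModel) -> PathwayExpression:
    """Pathway profile = c * (Z_target w) using training weights and sign."""
    rows = {}
    for name, proj in model.pathways.items():
        missing = [g for g in proj.genes if g not in zds_target.gene_ids]
        if missing:
            raise DataError(f"weighted gene {missing[0]!r} absent from target ({name})")
        Z = _member_zmatrix(zds_target, list(proj.genes))
        rows[name] = proj.sign * (Z @ proj.weights)
    return PathwayExpression(
        method=model.method,
        values=pd.DataFrame.from_dict(rows, orient="index", columns=zds_target.sample_ids),
        provenance=model.scaling.fitted_on,
    )
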