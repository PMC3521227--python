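"""ASSESS-style per-sample pathway enrichment scores.

Two stages, both fitted on raw (not z-scaled) training expression:

1. Per gene and class, a Gaussian kernel density over the class's training
   expression values gives class-conditional likelihoods; each (gene,
   sample) pair gets a log-likelihood ratio Lambda = log f_case(x) -
   log f_control(x), positive when the observation looks more like a case.
2. Per sample, genes are ranked by Lambda (case evidence first) and a
   weighted Kolmogorov-Smirnov-style random walk is run down the list:
   member genes step up proportionally to |Lambda|^p, non-members step
   down by 1/(N - m).  The enrichment score is the signed walk value at
   the maximum absolute deviation from zero, as in GSEA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pathagg.data_io import (
    CASE,
    CONTROL,
    DataError,
    ExpressionDataset,
    GeneSetCollection,
    PathwayExpression,
    warn_dropped,
)

#: Density floor keeping log-likelihood ratios finite far from all kernels.
DENSITY_FLOOR = 1e-12


@dataclass
class GeneDensityModel:
    """Per-gene, per-class kernel centers and bandwidths."""

    gene_ids: pd.Index
    centers_control: np.ndarray  # genes x n_control training values
    centers_case: np.ndarray  # genes x n_case
    bandwidth_control: np.ndarray  # per gene, > 0
    bandwidth_case: np.ndarray
    fitted_on: str


def _silverman(x: np.ndarray, full_range: np.ndarray) -> np.ndarray:
    """Silverman's rule per gene row, floored against degenerate classes.

    h = 0.9 * min(s, IQR/1.34) * n^(-1/5), with a floor of 1e-3 times the
    gene's overall training range (1e-8 if the range is itself zero).
    """
    n = x.shape[1]
    s = x.std(axis=1, ddof=1)
    q75, q25 = np.percentile(x, [75, 25], axis=1)
    spread = np.minimum(s, (q75 - q25) / 1.34)
    h = 0.9 * spread * n ** (-0.2)
    floor = np.where(full_range > 0, 1e-3 * full_range, 1e-8)
    return np.maximum(h, floor)


def fit_gene_densities(ds_train: ExpressionDataset) -> GeneDensityModel:
    """Fit Gaussian KDEs per (gene, class) on raw training expression."""
    m_ctrl = ds_train.class_mask(CONTROL)
    m_case = ds_train.class_mask(CASE)
    if m_ctrl.sum() < 2 or m_case.sum() < 2:
        raise DataError("density fitting requires >= 2 samples per class")
    x = ds_train.values.to_numpy()
    rng_range = x.max(axis=1) - x.min(axis=1)
    xc, xk = x[:, m_ctrl], x[:, m_case]
    return GeneDensityModel(
        gene_ids=ds_train.gene_ids,
        centers_control=xc,
        centers_case=xk,
        bandwidth_control=_silverman(xc, rng_range),
        bandwidth_case=_silverman(xk, rng_range),
        fitted_on=ds_train.name,
    )


def _kde_eval(x: np.ndarray, centers: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Evaluate per-gene Gaussian KDEs at a genes x samples matrix."""
    # x: genes x samples; centers: genes x n_class; h: genes
    d = x[:, :, None] - centers[:, None, :]
    hh = h[:, None, None]
    k = np.exp(-0.5 * (d / hh) ** 2) / (hh * np.sqrt(2.0 * np.pi))
    return k.mean(axis=2)


@dataclass
class LLRMatrix:
    """Genes x samples log-likelihood ratios; positive = case evidence."""

    values: pd.DataFrame


def llr_matrix(ds_target: ExpressionDataset, model: GeneDensityModel) -> LLRMatrix:
    missing = ds_target.gene_ids.difference(model.gene_ids)
    if len(missing):
        raise DataError(f"gene {missing[0]!r} missing from density model")
    idx = model.gene_ids.get_indexer(ds_target.gene_ids)
    x = ds_target.values.to_numpy()
    f_ctrl = _kde_eval(x, model.centers_control[idx], model.bandwidth_control[idx])
    f_case = _kde_eval(x, model.centers_case[idx], model.bandwidth_case[idx])
    lam = np.log(np.maximum(f_case, DENSITY_FLOOR)) - np.log(np.maximum(f_ctrl, DENSITY_FLOOR))
    return LLRMatrix(pd.DataFrame(lam, index=ds_target.gene_ids, columns=ds_target.sample_ids))


def enrichment_walk(lam_ranked: np.ndarray, member_mask: np.ndarray, p: float = 1.0) -> tuple[float, np.ndarray]:
    """Weighted KS walk over one ranked gene list.

    Returns (enrichment score, full walk).  The walk gains
    |Lambda|^p / sum_members |Lambda|^p at member positions and loses
    1/(N - m) elsewhere, so it always ends at 0; the score is the signed
    value at the maximum absolute deviation.
    """
    n = lam_ranked.size
    m = int(member_mask.sum())
    if m == 0 or m >= n:
        raise DataError("member count must satisfy 1 <= m < N")
    weights = np.abs(lam_ranked) ** p
    denom = weights[member_mask].sum()
    steps = np.full(n, -1.0 / (n - m))
    if denom == 0:
        return 0.0, np.zeros(n)
    steps[member_mask] = weights[member_mask] / denom
    walk = np.cumsum(steps)
    return float(walk[np.argmax(np.abs(walk))]), walk


def assess_scores(llr: LLRMatrix, sets: GeneSetCollection, p: float = 1.0) -> PathwayExpression:
    """Per-sample enrichment score of every pathway from an LLR matrix."""
    lam = llr.values.to_numpy()
    gene_ids = llr.values.index.to_numpy(dtype=object)
    n_genes, n_samples = lam.shape
    memberships: dict[str, np.ndarray] = {}
    for gs in sets:
        in_set = np.isin(gene_ids, list(gs.members))
        m = int(in_set.sum())
        if m == 0:
            warn_dropped(gs.name, "no measured member genes")
            continue
        if m == n_genes:
            raise DataError(f"gene set {gs.name!r} spans every measured gene")
        memberships[gs.name] = in_set
    if not memberships:
        raise DataError("no pathway retains any measured member gene")
    scores = np.zeros((len(memberships), n_samples))
    for s in range(n_samples):
        # rank by Lambda descending, stable ties by gene id ascending
        order = np.lexsort((gene_ids, -lam[:, s]))
        lam_ranked = lam[order, s]
        for i, mask in enumerate(memberships.values()):
            es, _ = enrichment_walk(lam_ranked, mask[order], p=p)
            scores[i, s] = es
    return PathwayExpression(
        method="assess",
        values=pd.DataFrame(scores, index=list(memberships), columns=llr.values.columns),
        provenance="",
    )
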