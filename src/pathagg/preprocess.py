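"""Per-gene z-scaling (fit/apply) and two-sample Student's t statistics.

Scaling parameters are always fitted on training samples and applied to
held-out samples, so that cross-validation and external validation never
leak information from the test portion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pathagg.data_io import CASE, CONTROL, DataError, ExpressionDataset

#: Variance floor used both for degenerate z-rows and for the pooled SD in t.
EPS = 1e-8


@dataclass
class ScalingParams:
    """Per-gene mean and sample standard deviation (ddof=1) of one dataset."""

    mean: pd.Series
    sd: pd.Series
    fitted_on: str


@dataclass
class GeneStats:
    """Per-feature pooled-variance t statistics (case minus control) and p."""

    t: pd.Series
    p: pd.Series
    df: int


def zscale_fit(ds: ExpressionDataset) -> ScalingParams:
    """Fit per-gene mean/SD across all samples (both classes pooled)."""
    if ds.n_samples < 2:
        raise DataError("z-scaling requires at least 2 samples")
    return ScalingParams(
        mean=ds.values.mean(axis=1),
        sd=ds.values.std(axis=1, ddof=1),
        fitted_on=ds.name,
    )


def zscale_apply(ds: ExpressionDataset, params: ScalingParams) -> ExpressionDataset:
    """Apply z = (x - mu)/s per gene; rows with s below the floor become 0."""
    missing = ds.gene_ids.difference(params.mean.index)
    if len(missing):
        raise DataError(f"gene {missing[0]!r} missing from scaling parameters")
    mu = params.mean.loc[ds.gene_ids].to_numpy()[:, None]
    sd = params.sd.loc[ds.gene_ids].to_numpy()[:, None]
    z = (ds.values.to_numpy() - mu) / np.where(sd < EPS, 1.0, sd)
    z[(sd < EPS).ravel(), :] = 0.0
    return ExpressionDataset(
        name=ds.name,
        values=pd.DataFrame(z, index=ds.gene_ids, columns=ds.sample_ids),
        labels=ds.labels.copy(),
    )


def two_sample_t(values: pd.DataFrame, labels: pd.Series) -> GeneStats:
    """Pooled-variance two-sample t per row, case minus control.

    Sign convention: t > 0 means the row mean is larger in case (class2)
    samples.  The pooled SD is floored at :data:`EPS` so t stays finite even
    for rows that are constant within both classes.
    """
    labels = labels.reindex(values.columns)
    m_ctrl = (labels == CONTROL).to_numpy()
    m_case = (labels == CASE).to_numpy()
    n1, n2 = int(m_ctrl.sum()), int(m_case.sum())
    if n1 < 2 or n2 < 2:
        raise DataError(f"t-test requires >= 2 samples per class (got {n1}, {n2})")
    x = values.to_numpy(dtype=float)
    x1, x2 = x[:, m_ctrl], x[:, m_case]
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / df)
    sp = np.maximum(sp, EPS)
    t = (mean2 - mean1) / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return GeneStats(
        t=pd.Series(t, index=values.index),
        p=pd.Series(p, index=values.index),
        df=df,
    )


def gene_t_statistics(zds: ExpressionDataset) -> GeneStats:
    """Gene-level Student's t on a (typically z-scaled) dataset."""
    return two_sample_t(zds.values, zds.labels)
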