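"""Between-dataset concordance of pathway differential-expression signatures.

A pathway signature is the vector of pathway-level Student's t statistics
of one dataset under one aggregation method (fitted and applied to the
whole dataset, no cross-validation).  Two related datasets are compared by
the Pearson correlation of their signatures; pathways whose t statistics
disagree in sign between the datasets (quadrants II/IV of the scatter) are
the discordant pathways.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pathagg.aggregate import fit_aggregator
from pathagg.data_io import DataError, ExpressionDataset, GeneSetCollection
from pathagg.preprocess import two_sample_t


@dataclass
class PathwaySignature:
    method: str
    dataset: str
    t: pd.Series  # per-pathway pooled-variance t, case minus control


@dataclass
class ConcordanceResult:
    method: str
    pair: tuple[str, str]
    points: pd.DataFrame  # columns: pathway, t_a, t_b, quadrant
    r: float

    @property
    def discordant(self) -> list[str]:
        mask = self.points.t_a * self.points.t_b < 0
        return self.points.loc[mask, "pathway"].tolist()

    def strongly_discordant(self, threshold: float = 2.0) -> list[str]:
        """Discordant pathways with |t| above ``threshold`` in both datasets."""
        mask = (
            (self.points.t_a * self.points.t_b < 0)
            & (self.points.t_a.abs() > threshold)
            & (self.points.t_b.abs() > threshold)
        )
        return self.points.loc[mask, "pathway"].tolist()


def _quadrant(ta: float, tb: float) -> str:
    if ta >= 0:
        return "I" if tb >= 0 else "IV"
    return "II" if tb >= 0 else "III"


def pathway_signature(
    ds: ExpressionDataset, sets: GeneSetCollection, method: str, assess_p: float = 1.0
) -> PathwaySignature:
    """Aggregate the full dataset and t-test every pathway row."""
    agg = fit_aggregator(ds, sets, method, assess_p=assess_p)
    pe = agg.transform(ds)
    st = two_sample_t(pe.values, ds.labels)
    return PathwaySignature(method=method, dataset=ds.name, t=st.t)


def correlate_signatures(a: PathwaySignature, b: PathwaySignature) -> ConcordanceResult:
    """Pearson correlation and discordant-pathway set over common pathways."""
    if a.method != b.method:
        raise DataError(f"method mismatch: {a.method!r} vs {b.method!r}")
    common = [pw for pw in a.t.index if pw in set(b.t.index)]
    if len(common) < 3:
        raise DataError("need >= 3 common pathways")
    ta = a.t.loc[common].to_numpy()
    tb = b.t.loc[common].to_numpy()
    if np.std(ta) == 0 or np.std(tb) == 0:
        raise DataError("zero-variance signature; correlation undefined")
    r = float(stats.pearsonr(ta, tb)[0])
    points = pd.DataFrame(
        {
            "pathway": common,
            "t_a": ta,
            "t_b": tb,
            "quadrant": [_quadrant(x, y) for x, y in zip(ta, tb)],
        }
    )
    return ConcordanceResult(method=a.method, pair=(a.dataset, b.dataset), points=points, r=r)


def pooled_concordance(results: list[ConcordanceResult]) -> tuple[pd.DataFrame, float]:
    """Concatenate the scatter points of several dataset pairs and correlate
    the pooled cloud (one point per pathway per pair)."""
    if not results:
        raise DataError("no concordance results to pool")
    pooled = pd.concat(
        [res.points.assign(pair="|".join(res.pair)) for res in results], ignore_index=True
    )
    r = float(stats.pearsonr(pooled.t_a, pooled.t_b)[0])
    return pooled, r
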