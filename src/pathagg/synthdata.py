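"""Synthetic two-class expression data with planted pathway regulation.

The generator emulates log-scale two-class expression: an i.i.d. Normal
background with additive class-conditional mean shifts planted into chosen
pathways.  A planted pathway has a *responsive* member subset (fraction
rho) shifted by +d*delta in case samples and, optionally, an *opposing*
("homeostatic") subset (fraction omega) shifted by -d*delta, so the
pathway's net direction is set by the balance of the two subsets.  Paired
datasets can force a pathway's net direction to flip between the pair by
exchanging the roles of the two subsets, while keeping the subsets
themselves — the mechanism behind between-dataset signature discordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from pathagg.data_io import (
    CASE,
    CONTROL,
    DataError,
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
)


@dataclass(frozen=True)
class PlantedPathway:
    """Regulation planted into one pathway.

    direction: net direction d of the responsive subset (+1 up in case).
    effect: shift delta in SD units of the background noise.
    responsive_fraction: fraction rho of members shifted by +d*delta.
    opposing_fraction: fraction omega shifted by -d*delta (homeostatic).
    """

    direction: int = +1
    effect: float = 2.0
    responsive_fraction: float = 1.0
    opposing_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if not 0 < self.responsive_fraction <= 1:
            raise ValueError("responsive_fraction must be in (0, 1]")
        if not 0 <= self.opposing_fraction < 1:
            raise ValueError("opposing_fraction must be in [0, 1)")
        if self.responsive_fraction + self.opposing_fraction > 1:
            raise ValueError("responsive + opposing fractions must be <= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset (or a related pair)."""

    n_genes: int = 1000
    n_sets: int = 40
    set_size_range: tuple[int, int] = (20, 60)
    overlap_fraction: float = 0.0
    n_control: int = 30
    n_case: int = 30
    planted: dict[str, PlantedPathway] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid set_size_range")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def set_name(i: int) -> str:
    return f"SET{i:03d}"


def standard_config(seed: int, planted: dict[str, PlantedPathway] | None = None) -> SimulationConfig:
    """The package's reference study conditions: 1,000 background genes,
    40 pathways of 20-60 members, 30 control + 30 case samples, unit noise."""
    return SimulationConfig(
        n_genes=1000,
        n_sets=40,
        set_size_range=(20, 60),
        n_control=30,
        n_case=30,
        noise_sd=1.0,
        planted=planted or {},
        seed=seed,
    )


#: Pathway flipped between the members of a homeostatic benchmark pair.
FLIP_PATHWAY = "SET005"


def flip_scenario_config(seed: int, effect: float = 2.0) -> SimulationConfig:
    """Homeostatic discordance scenario under the reference conditions.

    :data:`FLIP_PATHWAY` carries a dominant responsive subset (60% of
    members) and an opposing subset (30%); three other pathways are planted
    fully responsive and stay concordant.  Pass ``flip_set=(FLIP_PATHWAY,)``
    to :func:`simulate_pair` to exchange the subset roles in dataset B.
    """
    planted = {
        FLIP_PATHWAY: PlantedPathway(
            effect=effect, responsive_fraction=0.6, opposing_fraction=0.3
        ),
        "SET010": PlantedPathway(effect=effect),
        "SET015": PlantedPathway(effect=effect),
        "SET020": PlantedPathway(effect=effect),
    }
    return standard_config(seed, planted=planted)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


@dataclass
class _Plan:
    """Seed-derived layout shared between members of a dataset pair."""

    collection: GeneSetCollection
    responsive: dict[str, tuple[str, ...]]
    opposing: dict[str, tuple[str, ...]]


def _build_plan(cfg: SimulationConfig) -> _Plan:
    rng = np.random.default_rng(cfg.seed)
    genes = np.array(_gene_ids(cfg.n_genes), dtype=object)
    sets: list[GeneSet] = []
    prev_members: list[str] = []
    for i in range(cfg.n_sets):
        lo, hi = cfg.set_size_range
        size = int(rng.integers(lo, hi + 1))
        # each set is drawn without replacement within itself; sharing with
        # the *previous* set is pinned to overlap_fraction, sharing with
        # earlier sets is left to chance (as in real pathway catalogues)
        n_overlap = min(int(round(cfg.overlap_fraction * size)), len(prev_members))
        shared = list(rng.choice(np.array(prev_members, dtype=object), size=n_overlap, replace=False)) if n_overlap else []
        candidates = genes[~np.isin(genes, prev_members)]
        n_fresh = size - len(shared)
        if n_fresh > candidates.size:
            raise DataError(
                f"gene universe too small at set {i}: need {n_fresh} genes outside "
                f"the previous set, have {candidates.size}; increase n_genes"
            )
        fresh = list(rng.choice(candidates, size=n_fresh, replace=False))
        members = tuple(shared + fresh)
        sets.append(GeneSet(set_name(i), f"synthetic pathway {i}", members))
        prev_members = list(members)
    collection = GeneSetCollection.from_sets(sets)
    for name in cfg.planted:
        if name not in collection:
            raise DataError(f"planted pathway {name!r} not among generated sets")
    responsive: dict[str, tuple[str, ...]] = {}
    opposing: dict[str, tuple[str, ...]] = {}
    for name, plant in cfg.planted.items():
        members = collection[name].members
        order = rng.permutation(len(members))
        n_resp = max(1, int(round(plant.responsive_fraction * len(members))))
        n_opp = int(round(plant.opposing_fraction * len(members)))
        n_opp = min(n_opp, len(members) - n_resp)
        responsive[name] = tuple(members[j] for j in order[:n_resp])
        opposing[name] = tuple(members[j] for j in order[n_resp : n_resp + n_opp])
    return _Plan(collection, responsive, opposing)


def _realize(
    cfg: SimulationConfig,
    plan: _Plan,
    seed: int,
    name: str,
    flipped: frozenset[str] = frozenset(),
) -> tuple[ExpressionDataset, pd.DataFrame]:
    rng = np.random.default_rng(seed)
    genes = _gene_ids(cfg.n_genes)
    n = cfg.n_control + cfg.n_case
    x = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n))
    samples = [f"C{i:03d}" for i in range(cfg.n_control)] + [f"T{i:03d}" for i in range(cfg.n_case)]
    labels = pd.Series([CONTROL] * cfg.n_control + [CASE] * cfg.n_case, index=samples)
    gene_index = {g: i for i, g in enumerate(genes)}
    case_cols = np.arange(cfg.n_control, n)
    truth_rows = []
    for pw, plant in cfg.planted.items():
        flip = -1 if pw in flipped else +1
        for subset, base_sign in (("responsive", +1), ("opposing", -1)):
            members = plan.responsive[pw] if subset == "responsive" else plan.opposing[pw]
            applied = flip * base_sign * plant.direction
            for g in members:
                x[gene_index[g], case_cols] += applied * plant.effect
                truth_rows.append(
                    {
                        "gene": g,
                        "pathway": pw,
                        "subset": subset,
                        "direction": applied,
                        "effect": plant.effect,
                    }
                )
    truth = pd.DataFrame(truth_rows, columns=["gene", "pathway", "subset", "direction", "effect"])
    ds = ExpressionDataset(
        name=name,
        values=pd.DataFrame(x, index=genes, columns=samples),
        labels=labels,
    )
    return ds, truth


def simulate_dataset(cfg: SimulationConfig, name: str = "sim") -> tuple[ExpressionDataset, GeneSetCollection, pd.DataFrame]:
    """Generate one two-class dataset with planted pathway regulation.

    Returns (dataset, gene-set catalogue, truth table); the truth table
    lists every shifted gene with its pathway, subset and applied
    direction.  The same config always yields bit-identical output.
    """
    plan = _build_plan(cfg)
    ds, truth = _realize(cfg, plan, seed=(cfg.seed + 101) % (2**31), name=name)
    return ds, plan.collection, truth


def simulate_pair(
    cfg: SimulationConfig,
    flip_set: tuple[str, ...] = (),
    overrides_b: dict | None = None,
) -> tuple[
    tuple[ExpressionDataset, pd.DataFrame],
    tuple[ExpressionDataset, pd.DataFrame],
    GeneSetCollection,
]:
    """Generate two related datasets sharing one gene-set catalogue.

    Both draw independent noise from child seeds of ``cfg.seed``; pathways
    named in ``flip_set`` have their responsive and opposing subsets' shift
    signs exchanged in dataset B, flipping the net direction while a
    coherent strongly-shifted subset persists.
    """
    for pw in flip_set:
        if pw not in cfg.planted:
            raise DataError(f"flip_set names non-planted pathway {pw!r}")
    overrides_b = overrides_b or {}
    structural = {"n_genes", "n_sets", "set_size_range", "overlap_fraction", "seed"}
    if structural & overrides_b.keys():
        raise DataError(f"overrides_b may not change shared structure: {sorted(structural & overrides_b.keys())}")
    if "planted" in overrides_b and set(overrides_b["planted"]) != set(cfg.planted):
        raise DataError("overrides_b may change planted parameters but not the planted pathway set")
    plan = _build_plan(cfg)
    cfg_b = replace(cfg, **overrides_b)
    ds_a, truth_a = _realize(cfg, plan, seed=(cfg.seed + 101) % (2**31), name="simA")
    ds_b, truth_b = _realize(
        cfg_b, plan, seed=(cfg.seed + 202) % (2**31), name="simB", flipped=frozenset(flip_set)
    )
    return (ds_a, truth_a), (ds_b, truth_b), plan.collection
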