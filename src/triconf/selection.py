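"""Utility-maximizing condition selection.

Candidate stimulus conditions are ranked by how strongly the observer
models disagree about confidence there: at every grid point we compute the
pooled-SD Cohen's d between each pair of models' z-scored confidences and
sum |d| over the six pairs.  Points where the type-1 correct answer is
ambiguous (two or more components tied at the maximum) are excluded, the
permutation symmetry of the task collapses each triplet onto its sorted
representative, and the top-k surviving classes become the experimental
conditions.  Strength triplets translate to motion coherences through a
fixed scale factor, with an epsilon perturbation so that every condition
has a well-defined highest / second-best / lowest ordering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .models import MODELS, NoiseModel, SignalGrid
from .simulation import GridSimulation, simulate_all_models

MODEL_PAIRS = tuple(itertools.combinations(MODELS, 2))

CATEGORIES = ("lowest", "second", "highest")


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD Cohen's d, (mean(b) - mean(a)) / sqrt((var_a + var_b)/2)."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt((va + vb) / 2.0)
    if pooled == 0.0:
        return float("nan")
    return float((b.mean() - a.mean()) / pooled)


@dataclass
class EffectSizeTable:
    """Per-point pairwise effect sizes and their summed-|d| ranking.

    ``pairwise`` is a long table (c1, c2, c3, model_a, model_b, d);
    ``per_point`` aggregates summed |d| over the six pairs per triplet.
    """

    pairwise: pd.DataFrame
    per_point: pd.DataFrame
    n_trials: int


def cohens_d_map(sims: dict[str, GridSimulation]) -> EffectSizeTable:
    """Pairwise Cohen's d between models' z-scored confidence at each point."""
    models = list(sims)
    ref = sims[models[0]]
    for s in sims.values():
        if s.conf_z is None:
            raise ValueError("simulations must be z-scored before comparison")
        if s.n_trials != ref.n_trials or s.grid is not ref.grid and not np.array_equal(
            s.triplets, ref.triplets
        ):
            raise ValueError("simulations must share grid and n_trials")
    triplets = ref.triplets
    mu = {m: sims[m].conf_z.mean(axis=1) for m in models}
    var = {m: sims[m].conf_z.var(axis=1, ddof=1) for m in models}
    rows = []
    for a, b in itertools.combinations(models, 2):
        pooled = np.sqrt((var[a] + var[b]) / 2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(pooled > 0, (mu[b] - mu[a]) / pooled, np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "c1": triplets[:, 0],
                    "c2": triplets[:, 1],
                    "c3": triplets[:, 2],
                    "model_a": a,
                    "model_b": b,
                    "d": d,
                }
            )
        )
    pairwise = pd.concat(rows, ignore_index=True)
    per_point = (
        pairwise.assign(abs_d=pairwise["d"].abs())
        .groupby(["c1", "c2", "c3"], as_index=False)["abs_d"]
        .sum()
        .rename(columns={"abs_d": "summed_d"})
    )
    return EffectSizeTable(pairwise=pairwise, per_point=per_point, n_trials=ref.n_trials)


def pair_d(table: EffectSizeTable, model_a: str, model_b: str, triplet) -> float:
    """Look up d(model_a, model_b) at one triplet (antisymmetric in the pair)."""
    sign = 1.0
    if (model_a, model_b) not in list(
        table.pairwise[["model_a", "model_b"]].itertuples(index=False, name=None)
    ):
        model_a, model_b, sign = model_b, model_a, -1.0
    t = np.asarray(triplet, dtype=float)
    df = table.pairwise
    m = (
        (df["model_a"] == model_a)
        & (df["model_b"] == model_b)
        & np.isclose(df["c1"], t[0])
        & np.isclose(df["c2"], t[1])
        & np.isclose(df["c3"], t[2])
    )
    hit = df.loc[m, "d"]
    if len(hit) != 1:
        raise KeyError(f"no unique entry for ({model_a}, {model_b}) at {triplet}")
    return sign * float(hit.iloc[0])


# ---------------------------------------------------------------------------
# Ranking and selection
# ---------------------------------------------------------------------------


def is_ambiguous(triplet) -> bool:
    """True if the maximum strength is attained by two or more components."""
    t = np.asarray(triplet, dtype=float)
    return int((t == t.max()).sum()) >= 2


def class_ranking(table: EffectSizeTable, exclude_ambiguous: bool = True) -> pd.DataFrame:
    """Summed-|d| ranking over permutation-equivalence classes.

    The task is symmetric under permuting the three stimulus positions, so
    each triplet collapses onto its ascending-sorted representative; the
    class score is the mean summed |d| over its members.
    """
    pp = table.per_point.copy()
    key = np.sort(pp[["c1", "c2", "c3"]].to_numpy(), axis=1)
    pp["class"] = [tuple(row) for row in key]
    agg = pp.groupby("class", as_index=False)["summed_d"].mean()
    agg["ambiguous"] = [is_ambiguous(c) for c in agg["class"]]
    if exclude_ambiguous:
        agg = agg[~agg["ambiguous"]]
    agg = agg.sort_values("summed_d", ascending=False, ignore_index=True)
    agg["rank"] = np.arange(1, len(agg) + 1)
    return agg


def rank_and_select(
    table: EffectSizeTable, k: int = 3, exclude_ambiguous: bool = True
) -> list[np.ndarray]:
    """Top-k condition classes by summed |d| (ascending-sorted triplets)."""
    ranking = class_ranking(table, exclude_ambiguous=exclude_ambiguous)
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds the {len(ranking)} surviving classes")
    return [np.array(c, dtype=float) for c in ranking["class"].head(k)]


def robustness_check(
    grid: SignalGrid,
    noise_scales: list[float],
    n_trials: int = 2000,
    seed: int = 0,
    k: int = 3,
) -> dict:
    """Re-run selection at several covariance scales and compare rankings.

    Returns the per-scale rankings, Spearman correlations of the class
    summed-|d| scores against the first scale, and whether the top-k class
    set is identical across scales.
    """
    if any(s <= 0 for s in noise_scales):
        raise ValueError("noise scales must be positive")
    rankings: dict[float, pd.DataFrame] = {}
    for scale in noise_scales:
        sims = simulate_all_models(grid, NoiseModel(scale), n_trials=n_trials, seed=seed)
        rankings[scale] = class_ranking(cohens_d_map(sims))
    base_scale = noise_scales[0]
    base = rankings[base_scale].set_index("class")["summed_d"]
    correlations = {}
    topk_sets = {}
    for scale, r in rankings.items():
        cur = r.set_index("class")["summed_d"]
        joined = pd.concat([base, cur], axis=1, join="inner")
        rho = spearmanr(joined.iloc[:, 0], joined.iloc[:, 1]).statistic
        correlations[scale] = float(rho)
        topk_sets[scale] = set(r["class"].head(k))
    same_topk = all(topk_sets[s] == topk_sets[base_scale] for s in noise_scales)
    return {
        "rankings": rankings,
        "spearman_vs_first": correlations,
        "top_k_identical": same_topk,
        "top_k": {s: sorted(v) for s, v in topk_sets.items()},
    }


# ---------------------------------------------------------------------------
# Design translation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Condition:
    """One experimental condition: strengths and display coherences.

    Both vectors are stored ascending, so index 0 / 1 / 2 correspond to the
    lowest / second-best / highest stimulus.  Coherences are strictly
    increasing after the epsilon perturbation.
    """

    condition_id: str
    strengths: tuple[float, float, float]
    coherences: tuple[float, float, float]


@dataclass(frozen=True)
class ExperimentDesign:
    conditions: tuple[Condition, ...]
    coherence_scale: float = 0.16
    tie_epsilon: float = 1e-4

    def condition(self, condition_id: str) -> Condition:
        for c in self.conditions:
            if c.condition_id == condition_id:
                return c
        raise KeyError(condition_id)

    @property
    def condition_ids(self) -> tuple[str, ...]:
        return tuple(c.condition_id for c in self.conditions)


def strengths_to_design(
    triplets,
    coherence_scale: float = 0.16,
    tie_epsilon: float = 1e-4,
) -> ExperimentDesign:
    """Translate strength triplets into display coherences.

    Coherences are strengths times ``coherence_scale``; a condition whose
    two non-maximal strengths are tied gets ``tie_epsilon`` added to one of
    them in coherence space so that highest / second-best / lowest are
    well defined (e.g. strengths [0, 0, 3.5] become coherences
    [0, 0.0001, 0.56]).
    """
    conditions = []
    for i, t in enumerate(triplets):
        s = np.sort(np.asarray(t, dtype=float))
        if is_ambiguous(s):
            raise ValueError(
                f"triplet {tuple(s)} has a tied maximum; ambiguous conditions "
                "cannot be translated into an experiment"
            )
        coh = np.round(s * coherence_scale, 10)  # absorb binary float residue
        if coh.max() > 1.0:
            raise ValueError(f"coherence {coh.max():.3f} exceeds 1; reduce the scale")
        if coh[0] == coh[1]:
            coh = coh.copy()
            coh[1] += tie_epsilon
        if not (coh[0] < coh[1] < coh[2]):
            raise ValueError(f"coherences {coh} are not strictly ordered")
        conditions.append(
            Condition(
                condition_id=f"cond{i + 1}",
                strengths=tuple(float(x) for x in s),
                coherences=tuple(float(x) for x in coh),
            )
        )
    return ExperimentDesign(
        conditions=tuple(conditions),
        coherence_scale=coherence_scale,
        tie_epsilon=tie_epsilon,
    )


#: the three conditions used throughout fitting and recovery by default
DEFAULT_CONDITION_STRENGTHS = (
    (0.0, 0.0, 3.5),
    (3.5, 4.5, 5.0),
    (4.0, 4.5, 5.0),
)


def default_design() -> ExperimentDesign:
    return strengths_to_design(DEFAULT_CONDITION_STRENGTHS)
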