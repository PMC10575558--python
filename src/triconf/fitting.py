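"""Fitting observer models to 3AFC choice-and-confidence data.

The pipeline has two stages.  First the per-subject internal-noise scalar
sigma is fitted by minimizing the cross entropy between the subject's
type-1 choice-category distribution (highest / second-best / lowest
coherence chosen, per condition) and the model's simulated distribution
over a grid of candidate sigmas.  Because the full-grid, axis-aligned and
response-congruent-evidence observers make identical type-1 choices
(argmax of the evidence), a single shared sigma serves all of them; the
hierarchical observer's argmax-|d| rule is available for per-model fits.

Second, each model is re-simulated at the fitted sigma and its confidence
distribution, conditioned on (condition, choice category) and z-scored
within the three conditions, is compared to the subject's z-scored
confidences by cross entropy between Gaussian-KDE density estimates
evaluated on a shared grid.  Cross entropies may legitimately be +inf
when the subject produces confidences in regions the model never visits;
such results are flagged rather than floored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .models import MODELS, NoiseModel, SignalGrid, decide_batch
from .selection import CATEGORIES, ExperimentDesign

DEFAULT_SIGMA_GRID = np.round(np.arange(0.25, 6.0 + 1e-9, 0.05), 2)


# ---------------------------------------------------------------------------
# Subject data
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = [
    "subject_id",
    "trial_index",
    "condition_id",
    "coh_highest",
    "coh_second",
    "coh_lowest",
    "pos_highest",
    "pos_second",
    "pos_lowest",
    "choice_position",
    "choice_category",
    "confidence_raw",
    "rt_ms",
]


@dataclass
class SubjectData:
    """Trials for one subject with within-subject z-scored confidence."""

    subject_id: str
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.trials
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "rt_ms"]
        if missing:
            raise ValueError(f"subject {self.subject_id}: missing columns {missing}")
        n_cond = df["condition_id"].nunique()
        if n_cond != 3:
            raise ValueError(
                f"subject {self.subject_id}: expected 3 conditions, got {n_cond}"
            )
        raw = df["confidence_raw"].to_numpy(dtype=float)
        sd = raw.std()
        if sd == 0:
            raise ValueError(f"subject {self.subject_id}: constant confidence")
        self.trials = df.assign(confidence_z=(raw - raw.mean()) / sd)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def accuracy(self, condition_id: str | None = None) -> float:
        df = self.trials
        if condition_id is not None:
            df = df[df["condition_id"] == condition_id]
        return float((df["choice_category"] == "highest").mean())


def categorize_choice(coherences, arrangement: dict[str, int], choice_position: int) -> str:
    """Category (highest / second / lowest) of the chosen screen position.

    ``coherences`` are the condition's three coherence values;
    ``arrangement`` maps category name to screen position (1..3).
    """
    coh = np.asarray(coherences, dtype=float)
    if len(np.unique(coh)) != 3:
        raise ValueError(
            f"coherences {coherences} are not strictly orderable; apply the "
            "tie-epsilon perturbation to the design first"
        )
    for cat in CATEGORIES:
        if arrangement[cat] == choice_position:
            return cat
    raise ValueError(f"choice_position {choice_position} not in arrangement {arrangement}")


# ---------------------------------------------------------------------------
# Screening and behavioral summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreeningRules:
    """Attention-check exclusion rules applied before any model fitting."""

    min_overall_accuracy: float = 0.40
    easiest_condition_id: str | None = None
    require_easiest_best: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.min_overall_accuracy < 1.0):
            raise ValueError("min_overall_accuracy must lie in (0, 1)")


def easiest_condition(design: ExperimentDesign) -> str:
    """Condition with the largest highest-vs-second coherence gap."""
    gaps = {c.condition_id: c.coherences[2] - c.coherences[1] for c in design.conditions}
    return max(gaps, key=gaps.get)


def screen_subjects(
    subjects: list[SubjectData], rules: ScreeningRules
) -> tuple[list[SubjectData], list[tuple[SubjectData, str]]]:
    """Partition subjects into retained and (subject, reason) excluded."""
    retained, excluded = [], []
    for s in subjects:
        overall = s.accuracy()
        if overall < rules.min_overall_accuracy:
            excluded.append((s, f"overall accuracy {overall:.3f} below "
                                f"{rules.min_overall_accuracy:.2f}"))
            continue
        if rules.require_easiest_best:
            if rules.easiest_condition_id is None:
                raise ValueError("easiest_condition_id required when "
                                 "require_easiest_best is set")
            easiest = rules.easiest_condition_id
            acc = {c: s.accuracy(c) for c in s.trials["condition_id"].unique()}
            others = [a for c, a in acc.items() if c != easiest]
            if not all(acc[easiest] > a for a in others):
                excluded.append((s, "easiest condition accuracy "
                                    f"{acc[easiest]:.3f} does not surpass the others"))
                continue
        retained.append(s)
    return retained, excluded


def behavior_summary(subjects: list[SubjectData]) -> pd.DataFrame:
    """Per-condition grand means of accuracy, z-confidence and RT.

    Means are taken per subject first, then averaged across subjects.
    """
    rows = []
    for s in subjects:
        for cond, df in s.trials.groupby("condition_id"):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "condition_id": cond,
                    "accuracy": (df["choice_category"] == "highest").mean(),
                    "confidence_z": df["confidence_z"].mean(),
                    "rt_ms": df["rt_ms"].mean() if df["rt_ms"].notna().any() else np.nan,
                }
            )
    per_subject = pd.DataFrame(rows)
    return (
        per_subject.groupby("condition_id", as_index=False)[
            ["accuracy", "confidence_z", "rt_ms"]
        ].mean()
    )


# ---------------------------------------------------------------------------
# Type-1 cross entropy and sigma fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChoiceDistribution:
    """Per-condition probabilities over the three choice categories.

    Category order follows :data:`~triconf.selection.CATEGORIES`
    (lowest, second, highest).
    """

    condition_ids: tuple[str, ...]
    probs: np.ndarray  # (n_conditions, 3)
    counts: np.ndarray | None = None  # trials per condition


def subject_choice_distribution(subject: SubjectData, design: ExperimentDesign) -> ChoiceDistribution:
    probs, counts = [], []
    for cond in design.condition_ids:
        df = subject.trials[subject.trials["condition_id"] == cond]
        counts.append(len(df))
        p = np.array([(df["choice_category"] == cat).mean() for cat in CATEGORIES])
        probs.append(p)
    return ChoiceDistribution(
        condition_ids=design.condition_ids,
        probs=np.array(probs),
        counts=np.array(counts),
    )


def type1_cross_entropy(
    p: ChoiceDistribution, q: ChoiceDistribution, weights: np.ndarray | None = None
) -> float:
    """Choice cross entropy −Σ p log q, conditions weighted by trial counts.

    Weights are normalized to sum to one (equal condition sizes reduce to a
    plain average).  Returns +inf when the model assigns zero probability
    to a category the subject used.
    """
    if p.condition_ids != q.condition_ids:
        raise ValueError("choice distributions cover different conditions")
    if not np.allclose(p.probs.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("subject choice distribution is not normalized")
    if weights is None:
        weights = p.counts if p.counts is not None else np.ones(len(p.condition_ids))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    total = 0.0
    for wc, prow, qrow in zip(w, p.probs, q.probs):
        mask = prow > 0
        if np.any(qrow[mask] == 0):
            return float("inf")
        total += wc * float(-(prow[mask] * np.log(qrow[mask])).sum())
    return total


class SigmaFitter:
    """Grid search for sigma with cached, common-random-number simulations.

    For every candidate sigma the model's choice-category distribution at
    the design's three conditions is simulated once from a single frozen
    set of standard-normal draws (so the objective is deterministic and
    smooth in sigma) and cached; fitting any subject is then a cheap
    argmin over the candidate grid.  The ``maxd`` rule (argmax of the
    evidence) serves the full-grid, axis-aligned and heuristic observers;
    ``maxabsd`` serves the hierarchical observer.
    """

    def __init__(
        self,
        design: ExperimentDesign,
        sigma_grid: np.ndarray | None = None,
        sim_n: int = 2000,
        seed: int = 0,
    ) -> None:
        self.design = design
        self.sigma_grid = (
            DEFAULT_SIGMA_GRID.copy() if sigma_grid is None else np.asarray(sigma_grid, float)
        )
        if np.any(self.sigma_grid <= 0):
            raise ValueError("sigma grid must be positive")
        self.sim_n = sim_n
        strengths = np.array([c.strengths for c in design.conditions])  # (n_cond, 3)
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((len(strengths), sim_n, 3))
        self._q = {}
        for rule in ("maxd", "maxabsd"):
            q = np.empty((len(self.sigma_grid), len(strengths), 3))
            for k, sigma in enumerate(self.sigma_grid):
                d = strengths[:, None, :] + np.sqrt(sigma) * z
                scores = d if rule == "maxd" else d * d
                ch = np.argmax(scores, axis=-1)  # strengths ascending: index==category
                for j in range(len(strengths)):
                    q[k, j] = np.bincount(ch[j], minlength=3) / sim_n
            self._q[rule] = q

    @staticmethod
    def choice_rule(model_id: str) -> str:
        if model_id in ("plio", "aio", "rce", "shared"):
            return "maxd"
        if model_id == "plh":
            return "maxabsd"
        raise ValueError(f"unknown model {model_id!r}")

    def model_choice_distribution(self, model_id: str, sigma: float) -> ChoiceDistribution:
        k = int(np.argmin(np.abs(self.sigma_grid - sigma)))
        if abs(self.sigma_grid[k] - sigma) > 1e-9:
            raise KeyError(f"sigma {sigma} not on the fitter's grid")
        return ChoiceDistribution(
            condition_ids=self.design.condition_ids,
            probs=self._q[self.choice_rule(model_id)][k],
        )

    def fit(
        self, p: ChoiceDistribution, model_id: str = "shared"
    ) -> tuple[float, float, np.ndarray]:
        """Return (sigma_hat, CE1 at sigma_hat, full CE1 curve).

        Ties resolve to the smaller sigma (argmin on the ascending grid).
        """
        q = self._q[self.choice_rule(model_id)]
        curve = np.array(
            [
                type1_cross_entropy(
                    p,
                    ChoiceDistribution(self.design.condition_ids, q[k], None),
                )
                for k in range(len(self.sigma_grid))
            ]
        )
        k = int(np.argmin(curve))
        return float(self.sigma_grid[k]), float(curve[k]), curve


def fit_sigma(
    subject: SubjectData,
    model_id: str,
    design: ExperimentDesign,
    sigma_grid: np.ndarray | None = None,
    sim_n: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """One-shot sigma fit for one subject (thin wrapper over SigmaFitter)."""
    fitter = SigmaFitter(design, sigma_grid=sigma_grid, sim_n=sim_n, seed=seed)
    p = subject_choice_distribution(subject, design)
    sigma_hat, ce1, _ = fitter.fit(p, model_id)
    return sigma_hat, ce1


# ---------------------------------------------------------------------------
# Type-2 (confidence) cross entropy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KDESpec:
    """Kernel-density settings for confidence distributions.

    Within each (condition, category) cell both the subject and the model
    densities are smoothed with the *same* Gaussian bandwidth — Scott's
    rule evaluated on the subject's sample — and evaluated on one shared
    grid spanning every sample in the comparison, padded by
    ``pad_bandwidths`` bandwidths.  A common bandwidth and grid make the
    discretized cross entropies comparable across candidate models: with
    per-sample bandwidths a large simulated sample is smoothed far less
    than a 150-trial subject sample, which systematically favors models
    with slightly-too-wide confidence distributions, and per-model grids
    shift every entropy by the log of their bin width.  Densities are
    renormalized to discrete distributions on the grid; no flooring is
    applied, so an impossible subject observation yields an infinite
    cross entropy.
    """

    grid_points: int = 512
    pad_bandwidths: float = 3.0
    min_cell_count: int = 2


def _scott_bandwidth(x: np.ndarray) -> float:
    return float(len(x) ** (-0.2) * x.std(ddof=1))


def _kde_with_bandwidth(x: np.ndarray, h: float) -> gaussian_kde:
    return gaussian_kde(x, bw_method=h / x.std(ddof=1))


def confidence_cells(subject: SubjectData) -> dict[tuple[str, str], np.ndarray]:
    """Z-scored confidences grouped by (condition, choice category)."""
    return {
        (cond, cat): df["confidence_z"].to_numpy(dtype=float)
        for (cond, cat), df in subject.trials.groupby(
            ["condition_id", "choice_category"]
        )
    }


def model_confidence_cells(
    model_id: str,
    sigma: float,
    design: ExperimentDesign,
    grid: SignalGrid,
    sim_n: int = 2000,
    seed: int = 0,
) -> dict[tuple[str, str], np.ndarray]:
    """Simulate a model at sigma and return z-scored confidence per cell.

    Confidence is z-scored pooled across the design's three conditions
    (the scope observable in a three-condition experiment), then split by
    (condition, choice category).
    """
    noise = NoiseModel(sigma)
    rng = np.random.default_rng(seed)
    all_conf, all_choice, all_cond = [], [], []
    for cond in design.conditions:
        c = np.asarray(cond.strengths)
        d = c + noise.sd * rng.standard_normal((sim_n, 3))
        ch, cf = decide_batch(model_id, d, grid, noise)
        all_conf.append(cf)
        all_choice.append(ch)
        all_cond.append(np.full(sim_n, cond.condition_id, dtype=object))
    conf = np.concatenate(all_conf)
    choice = np.concatenate(all_choice)
    conds = np.concatenate(all_cond)
    sd = conf.std()
    if sd == 0:
        raise ValueError(f"model {model_id} produced constant confidence at sigma={sigma}")
    z = (conf - conf.mean()) / sd
    cells = {}
    for cond in design.condition_ids:
        for j, cat in enumerate(CATEGORIES):
            mask = (conds == cond) & (choice == j)  # ascending strengths: index==category
            cells[(cond, cat)] = z[mask]
    return cells


def type2_cross_entropy_joint(
    subject_cells: dict[tuple[str, str], np.ndarray],
    model_cells_by_model: dict[str, dict[tuple[str, str], np.ndarray]],
    kde: KDESpec = KDESpec(),
) -> tuple[dict[str, float], dict]:
    """Confidence cross entropy of each candidate model against one subject.

    Cells (condition x choice category) are weighted by the subject's
    empirical cell frequencies, normalized over the included cells.
    Subject cells below ``min_cell_count`` or with zero variance are
    skipped; within a cell all candidate models share one bandwidth (the
    subject sample's Scott bandwidth) and one evaluation grid spanning the
    subject's and every model's samples.  A model whose cell sample is
    missing or degenerate where the subject has real data scores +inf.
    Returns ({model: CE2}, info).
    """
    models = list(model_cells_by_model)
    included = {
        cell: arr
        for cell, arr in subject_cells.items()
        if len(arr) >= kde.min_cell_count and arr.std() > 0
    }
    skipped = [c for c in subject_cells if c not in included]
    if not included:
        return {m: float("inf") for m in models}, {
            "skipped_cells": skipped, "finite": {m: False for m in models}
        }
    total_n = sum(len(a) for a in included.values())
    ce = {m: 0.0 for m in models}
    for cell, p_sample in included.items():
        w = len(p_sample) / total_n
        h = _scott_bandwidth(p_sample)
        kp = _kde_with_bandwidth(p_sample, h)
        kq, lo, hi = {}, [p_sample.min()], [p_sample.max()]
        for m in models:
            q_sample = model_cells_by_model[m].get(cell, np.empty(0))
            if len(q_sample) < 2 or q_sample.std() == 0:
                kq[m] = None
                continue
            kq[m] = _kde_with_bandwidth(q_sample, h)
            lo.append(q_sample.min())
            hi.append(q_sample.max())
        xs = np.linspace(min(lo) - kde.pad_bandwidths * h,
                         max(hi) + kde.pad_bandwidths * h, kde.grid_points)
        p = kp(xs)
        p = p / p.sum()
        mask = p > 0
        for m in models:
            if not np.isfinite(ce[m]):
                continue
            if kq[m] is None:
                ce[m] = float("inf")
                continue
            q = kq[m](xs)
            qs = q.sum()
            if qs == 0 or np.any(q[mask] == 0):
                ce[m] = float("inf")
                continue
            q = q / qs
            ce[m] += w * float(-(p[mask] * np.log(q[mask])).sum())
    info = {"skipped_cells": skipped,
            "finite": {m: bool(np.isfinite(ce[m])) for m in models}}
    return ce, info


def type2_cross_entropy(
    subject_cells: dict[tuple[str, str], np.ndarray],
    model_cells: dict[tuple[str, str], np.ndarray],
    kde: KDESpec = KDESpec(),
) -> tuple[float, dict]:
    """Confidence cross entropy of one model against one subject.

    Single-model convenience wrapper over
    :func:`type2_cross_entropy_joint`; see there for the estimator's
    contract.  Returns (CE2, info); CE2 may be +inf (no flooring), which
    flags the subject/model pair rather than being an error.
    """
    ce, info = type2_cross_entropy_joint(subject_cells, {"model": model_cells}, kde)
    return ce["model"], {
        "skipped_cells": info["skipped_cells"],
        "finite": info["finite"]["model"],
    }


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------


class ModelConfCache:
    """Cache of z-scored model confidence cells keyed by (model, sigma).

    Candidate sigmas live on a discrete grid, so across a cohort the same
    (model, sigma) simulation is reused by every subject that fitted to
    that sigma.
    """

    def __init__(
        self,
        design: ExperimentDesign,
        grid: SignalGrid,
        sim_n: int = 2000,
        seed: int = 1,
    ) -> None:
        self.design = design
        self.grid = grid
        self.sim_n = sim_n
        self.seed = seed
        self._cache: dict[tuple[str, float], dict] = {}

    def get(self, model_id: str, sigma: float) -> dict[tuple[str, str], np.ndarray]:
        key = (model_id, round(float(sigma), 6))
        if key not in self._cache:
            self._cache[key] = model_confidence_cells(
                model_id, sigma, self.design, self.grid,
                sim_n=self.sim_n, seed=self.seed,
            )
        return self._cache[key]


@dataclass
class FitResult:
    """Per-subject fit: sigma, type-1 and type-2 cross entropies, winner."""

    subject_id: str
    fit_mode: str  # shared_sigma | per_model_sigma
    sigma_hat: dict[str, float]
    ce1: dict[str, float]
    ce2: dict[str, float]
    best_model: str | None
    excluded_nonfinite: bool
    tie: bool = False


def compare_models(
    subject: SubjectData,
    design: ExperimentDesign,
    fitter: SigmaFitter,
    conf_cache: ModelConfCache,
    kde: KDESpec = KDESpec(),
    fit_mode: str = "shared_sigma",
    models: tuple[str, ...] = MODELS,
) -> FitResult:
    """Fit sigma, score each model's confidence predictions, pick the winner.

    ``shared_sigma`` fits one sigma from the common argmax-evidence choice
    rule; ``per_model_sigma`` fits each model with its own type-1 rule.
    The best model minimizes finite CE2; ties within 1e-9 leave no winner.
    """
    if fit_mode not in ("shared_sigma", "per_model_sigma"):
        raise ValueError(f"unknown fit_mode {fit_mode!r}")
    p = subject_choice_distribution(subject, design)
    sigma_hat, ce1 = {}, {}
    if fit_mode == "shared_sigma":
        s, _, _ = fitter.fit(p, "shared")
        for m in models:
            sigma_hat[m] = s
            ce1[m] = type1_cross_entropy(p, fitter.model_choice_distribution(m, s))
    else:
        for m in models:
            s, c, _ = fitter.fit(p, m)
            sigma_hat[m], ce1[m] = s, c
    subj_cells = confidence_cells(subject)
    ce2, _ = type2_cross_entropy_joint(
        subj_cells, {m: conf_cache.get(m, sigma_hat[m]) for m in models}, kde
    )
    finite = {m: v for m, v in ce2.items() if np.isfinite(v)}
    if not finite:
        return FitResult(subject.subject_id, fit_mode, sigma_hat, ce1, ce2,
                         best_model=None, excluded_nonfinite=True)
    best = min(finite, key=finite.get)
    others = [v for m, v in finite.items() if m != best]
    tie = bool(others and min(others) - finite[best] <= 1e-9)
    return FitResult(
        subject.subject_id, fit_mode, sigma_hat, ce1, ce2,
        best_model=None if tie else best, excluded_nonfinite=False, tie=tie,
    )
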