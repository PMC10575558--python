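"""Model recovery: can the fitting pipeline identify the generating model?

Synthetic observers are generated from each of the four models at the
three experimental conditions (150 trials per condition by default) with
internal noise sigma drawn uniformly from [0.5, 5].  Each observer then
passes through the full fitting pipeline — shared-sigma type-1 fit, then
per-model type-2 cross entropy — using seeds independent of the ones that
generated the data.  The result is a confusion matrix of true versus
best-fitting model; observers for which every model's confidence cross
entropy is infinite (typically very large true sigma) are excluded, with
reasons logged.

This module doubles as the package's synthetic-data generator: cohorts
are written in the same trial schema as real data and are drop-in inputs
for the fitting tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import (
    FitResult,
    KDESpec,
    ModelConfCache,
    SigmaFitter,
    SubjectData,
    compare_models,
)
from .models import MODELS, NoiseModel, SignalGrid, decide_batch
from .selection import CATEGORIES, ExperimentDesign

SIGMA_RANGE = (0.5, 5.0)


def generate_observer(
    model_id: str,
    sigma: float,
    design: ExperimentDesign,
    n_trials_per_condition: int = 150,
    seed: int | np.random.SeedSequence = 0,
    grid: SignalGrid | None = None,
    subject_id: str | None = None,
) -> SubjectData:
    """Simulate one observer's full session at the design's conditions.

    Each trial randomly arranges the condition's three coherence levels on
    screen, draws a percept around the arranged true strengths, and applies
    the model's choice and confidence rules.  Confidence is the model's
    native output (posterior probability, or raw evidence for the
    heuristic); the SubjectData constructor z-scores it within the session,
    exactly as slider ratings would be.
    """
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}")
    if design is None or len(design.conditions) != 3:
        raise ValueError("design must have exactly 3 conditions")
    grid = grid or SignalGrid()
    noise = NoiseModel(sigma)
    rng = np.random.default_rng(seed)
    rows = []
    trial_index = 0
    for cond in design.conditions:
        strengths = np.asarray(cond.strengths)  # ascending: lowest, second, highest
        n = n_trials_per_condition
        # uniform random assignment of the three levels to screen positions
        arrangements = rng.permuted(
            np.tile(np.arange(3), (n, 1)), axis=1
        )  # arrangements[t, pos] = category index shown at screen position pos
        arranged_c = strengths[arrangements]  # (n, 3) true strength at each position
        d = arranged_c + noise.sd * rng.standard_normal((n, 3))
        pos_choice, conf = decide_batch(model_id, d, grid, noise)
        cat_choice = arrangements[np.arange(n), pos_choice]  # category index chosen
        # screen position (1-based) of each category, per trial
        pos_of_cat = np.argsort(arrangements, axis=1) + 1
        for t in range(n):
            rows.append(
                {
                    "subject_id": subject_id or f"{model_id}_sim",
                    "trial_index": trial_index,
                    "condition_id": cond.condition_id,
                    "coh_highest": cond.coherences[2],
                    "coh_second": cond.coherences[1],
                    "coh_lowest": cond.coherences[0],
                    "pos_highest": int(pos_of_cat[t, 2]),
                    "pos_second": int(pos_of_cat[t, 1]),
                    "pos_lowest": int(pos_of_cat[t, 0]),
                    "choice_position": int(pos_choice[t]) + 1,
                    "choice_category": CATEGORIES[cat_choice[t]],
                    "confidence_raw": float(conf[t]),
                    "rt_ms": np.nan,
                }
            )
            trial_index += 1
    return SubjectData(subject_id=rows[0]["subject_id"], trials=pd.DataFrame(rows))


@dataclass
class RecoveryResult:
    """Confusion matrix and accuracies from a model-recovery run."""

    confusion: pd.DataFrame  # rows: true model, cols: best-fit model (+ "tie")
    per_model_accuracy: dict[str, float]
    overall_accuracy: float
    excluded: list[tuple[str, str]]  # (observer id, reason)
    fits: list[FitResult]
    true_sigmas: dict[str, float]


def generate_cohort(
    design: ExperimentDesign,
    cohort_size_per_model: int,
    n_trials_per_condition: int = 150,
    master_seed: int = 0,
    grid: SignalGrid | None = None,
    models: tuple[str, ...] = MODELS,
) -> list[tuple[SubjectData, str, float]]:
    """Synthetic cohort: (subject, true model, true sigma) per observer.

    Sigma draws and trial noise come from independent child streams of the
    master seed, so any observer is reproducible in isolation.
    """
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(cohort_size_per_model * len(models))
    out = []
    k = 0
    for model_id in models:
        for i in range(cohort_size_per_model):
            child = children[k]
            k += 1
            sigma_stream = np.random.default_rng(child)
            sigma = float(sigma_stream.uniform(*SIGMA_RANGE))
            sid = f"{model_id}_{i:03d}"
            subj = generate_observer(
                model_id,
                sigma,
                design,
                n_trials_per_condition=n_trials_per_condition,
                seed=child.spawn(1)[0],
                grid=grid,
                subject_id=sid,
            )
            out.append((subj, model_id, sigma))
    return out


def run_recovery(
    cohort_size_per_model: int,
    design: ExperimentDesign,
    master_seed: int = 0,
    n_trials_per_condition: int = 150,
    sim_n: int = 2000,
    kde: KDESpec = KDESpec(),
    grid: SignalGrid | None = None,
    models: tuple[str, ...] = MODELS,
    fit_mode: str = "shared_sigma",
) -> RecoveryResult:
    """Full recovery study: generate, fit, classify, tabulate confusion.

    Fitting uses seeds derived independently of the generation streams.
    Observers whose confidence cross entropy is infinite for every model
    are excluded (logged); partial infinities only remove those models
    from the argmin.
    """
    grid = grid or SignalGrid()
    cohort = generate_cohort(
        design,
        cohort_size_per_model,
        n_trials_per_condition=n_trials_per_condition,
        master_seed=master_seed,
        grid=grid,
        models=models,
    )
    # fitting seeds deliberately unrelated to the generation streams
    fit_seed = (master_seed * 7919 + 101) % (2**31)
    fitter = SigmaFitter(design, sim_n=sim_n, seed=fit_seed)
    cache = ModelConfCache(design, grid, sim_n=sim_n, seed=fit_seed + 1)
    labels = list(models) + ["tie"]
    confusion = pd.DataFrame(0, index=list(models), columns=labels)
    excluded: list[tuple[str, str]] = []
    fits: list[FitResult] = []
    true_sigmas: dict[str, float] = {}
    for subj, true_model, sigma in cohort:
        true_sigmas[subj.subject_id] = sigma
        fit = compare_models(
            subj, design, fitter, cache, kde=kde, fit_mode=fit_mode, models=models
        )
        fits.append(fit)
        if fit.excluded_nonfinite:
            excluded.append(
                (subj.subject_id,
                 f"all models' CE2 non-finite (true sigma {sigma:.3f})")
            )
            continue
        confusion.loc[true_model, fit.best_model if fit.best_model else "tie"] += 1
    per_model = {}
    for m in models:
        row = confusion.loc[m]
        n = int(row.sum())
        per_model[m] = float(row[m] / n) if n else float("nan")
    diag = sum(int(confusion.loc[m, m]) for m in models)
    total = int(confusion.to_numpy().sum())
    overall = diag / total if total else float("nan")
    return RecoveryResult(
        confusion=confusion,
        per_model_accuracy=per_model,
        overall_accuracy=float(overall),
        excluded=excluded,
        fits=fits,
        true_sigmas=true_sigmas,
    )
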