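"""Monte-Carlo simulation of the observer models across the stimulus grid.

Each model is run at every strength triplet on the grid (11 x 11 x 11 =
1331 points by default), recording per-trial choices and native
confidences.  Percepts depend only on (seed, point, trial) — never on the
model — so running two models with the same seed evaluates them on a
common percept stream and any difference between their outputs is purely
decisional.

Confidence is z-scored within a model, pooled either over the whole grid
(for cross-model effect-size comparison) or over a listed subset of
conditions (mirroring what can be computed from a three-condition
experiment).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .models import MODELS, NoiseModel, SignalGrid, decide_batch

#: refuse grid simulations that would allocate more outcomes than this
MAX_OUTCOMES = 200_000_000

#: trials processed per vectorized block inside the full-grid posterior
_TRIAL_CHUNK = 4000


@dataclass(frozen=True)
class GridSimulation:
    """Choices and confidences for one model over every grid triplet.

    ``choices`` holds 1-based choices with shape (n_points, n_trials);
    ``conf_raw`` the native confidences; ``conf_z`` the z-scored
    confidences (None until :func:`zscore_confidence` runs).
    """

    model_id: str
    grid: SignalGrid
    sigma: float
    n_trials: int
    seed: int
    choices: np.ndarray
    conf_raw: np.ndarray
    conf_z: np.ndarray | None = None

    @property
    def triplets(self) -> np.ndarray:
        return self.grid.triplets


def simulate_grid(
    model_id: str,
    grid: SignalGrid,
    noise: NoiseModel,
    n_trials: int = 10_000,
    seed: int = 0,
) -> GridSimulation:
    """Simulate ``n_trials`` outcomes per grid triplet for one model.

    Deterministic given ``seed``; the percept stream is shared across
    models, so per-point type-1 behavior of choice-equivalent models is
    bit-identical under the same seed.
    """
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    triplets = grid.triplets
    total = triplets.shape[0] * n_trials
    if total > MAX_OUTCOMES:
        raise MemoryError(
            f"grid simulation of {total} outcomes exceeds the cap of "
            f"{MAX_OUTCOMES}; reduce n_trials or the grid"
        )
    rng = np.random.default_rng(seed)
    choices = np.empty((len(triplets), n_trials), dtype=np.int8)
    conf = np.empty((len(triplets), n_trials), dtype=np.float64)
    for i, c in enumerate(triplets):
        d = c + noise.sd * rng.standard_normal((n_trials, 3))
        # chunk the expensive full-grid posterior to bound memory
        for lo in range(0, n_trials, _TRIAL_CHUNK):
            hi = min(lo + _TRIAL_CHUNK, n_trials)
            ch, cf = decide_batch(model_id, d[lo:hi], grid, noise)
            choices[i, lo:hi] = ch + 1
            conf[i, lo:hi] = cf
    return GridSimulation(
        model_id=model_id,
        grid=grid,
        sigma=noise.sigma,
        n_trials=n_trials,
        seed=seed,
        choices=choices,
        conf_raw=conf,
    )


def zscore_confidence(
    sim: GridSimulation, scope: str | list | np.ndarray = "whole_grid"
) -> GridSimulation:
    """Z-score confidences against a pooled mean and SD.

    ``scope`` is either ``"whole_grid"`` (pool every simulated trial) or a
    sequence of point indices / strength triplets to pool over.  The same
    affine transform is applied to every trial, so relative ordering of
    per-point mean confidence is scope-invariant.
    """
    if isinstance(scope, str):
        if scope != "whole_grid":
            raise ValueError(f"unknown scope {scope!r}")
        pool = sim.conf_raw
    else:
        idx = _resolve_point_indices(sim, scope)
        pool = sim.conf_raw[idx]
    mean = float(pool.mean())
    sd = float(pool.std())
    if sd == 0.0:
        raise ValueError("pooled confidence SD is zero; degenerate simulation")
    return replace(sim, conf_z=(sim.conf_raw - mean) / sd)


def _resolve_point_indices(sim: GridSimulation, scope) -> np.ndarray:
    scope = np.asarray(scope)
    if scope.ndim == 1 and scope.dtype.kind in "iu":
        return scope
    if scope.ndim == 2 and scope.shape[1] == 3:
        triplets = sim.triplets
        idx = []
        for c in scope:
            hits = np.flatnonzero(np.all(np.isclose(triplets, c), axis=1))
            if len(hits) != 1:
                raise KeyError(f"triplet {c} not on the simulated grid")
            idx.append(hits[0])
        return np.array(idx)
    raise ValueError("scope must be 'whole_grid', point indices, or triplets")


def point_index(grid: SignalGrid, triplet) -> int:
    """Index of a strength triplet within ``grid.triplets``."""
    hits = np.flatnonzero(np.all(np.isclose(grid.triplets, np.asarray(triplet)), axis=1))
    if len(hits) != 1:
        raise KeyError(f"triplet {triplet} not on the grid")
    return int(hits[0])


def summarize_point(
    sim: GridSimulation, triplet, rng: np.random.Generator | None = None
) -> dict:
    """Accuracy and confidence summary at one grid point.

    Accuracy scores each choice against the argmax of the true triplet;
    when the maximum is tied the designated correct option is drawn
    uniformly among the tied components per trial (seeded via ``rng``).
    """
    i = point_index(sim.grid, triplet)
    c = sim.triplets[i]
    tied = np.flatnonzero(c == c.max())
    if len(tied) == 1:
        correct = np.full(sim.n_trials, tied[0] + 1)
    else:
        r = rng if rng is not None else np.random.default_rng(sim.seed)
        correct = r.choice(tied, size=sim.n_trials) + 1
    hits = sim.choices[i] == correct
    out = {"triplet": tuple(c), "accuracy": float(hits.mean())}
    conf = sim.conf_z[i] if sim.conf_z is not None else sim.conf_raw[i]
    for label, mask in (("correct", hits), ("incorrect", ~hits)):
        if mask.any():
            out[f"conf_mean_{label}"] = float(conf[mask].mean())
            out[f"conf_sd_{label}"] = float(conf[mask].std(ddof=1)) if mask.sum() > 1 else 0.0
        else:
            out[f"conf_mean_{label}"] = float("nan")
            out[f"conf_sd_{label}"] = float("nan")
    return out


def simulate_all_models(
    grid: SignalGrid,
    noise: NoiseModel,
    n_trials: int = 10_000,
    seed: int = 0,
    models: tuple[str, ...] = MODELS,
    zscore: bool = True,
) -> dict[str, GridSimulation]:
    """Run every model on the common percept stream; optionally z-score."""
    sims = {}
    for m in models:
        sim = simulate_grid(m, grid, noise, n_trials=n_trials, seed=seed)
        sims[m] = zscore_confidence(sim) if zscore else sim
    return sims
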