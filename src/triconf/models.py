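"""Generative observer models of 3AFC choice and confidence.

Four observers share a common front end: on each trial three stimuli with
true strengths ``c = (c1, c2, c3)`` produce a noisy internal sample
``d ~ N(c, sigma * I3)``.  They differ in how they turn ``d`` into a type-1
choice (which stimulus is strongest) and a type-2 confidence report:

``plio``
    Ideal observer marginalizing over the full 3-D grid of candidate
    strength triplets, partitioned by which component is largest.
    Confidence is the posterior probability of the chosen hypothesis.
``plh``
    Hierarchical observer that first projects each evidence component onto
    its own axis (point estimate ``c*_i = d_i``) and compares the resulting
    axis-aligned source hypotheses.  Equivalent to a softmax over
    ``d_i^2 / (2 sigma)``; its choice is ``argmax |d_i|``, which departs
    from the other models when a negative component has the largest
    magnitude.
``aio``
    Ideal observer restricted to axis-aligned sources with a single shared
    strength scalar, marginalized over the 1-D strength grid.
``rce``
    Response-congruent-evidence heuristic: choose ``argmax d_i``, report
    the raw evidence on the chosen dimension as confidence.

All posterior computations run in log space and are vectorized over
batches of percepts; public per-trial wrappers return small dataclasses.
Choices are 1-based (1, 2, 3) in public outputs and 0-based in the batch
helpers.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Literal

import numpy as np
from scipy.special import logsumexp

MODELS = ("plio", "plh", "aio", "rce")
MODEL_LABELS = {
    "plio": "P&L-IO",
    "plh": "P&L-H",
    "aio": "A-IO",
    "rce": "RCE",
}
BAYESIAN_MODELS = ("plio", "plh", "aio")

TieRule = Literal["share", "exclude"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalGrid:
    """Discrete grid of candidate stimulus strengths.

    The default grid spans 0 to 5 in steps of 0.5 (11 values); the full set
    of 3-way combinations (11^3 = 1331 triplets) enumerates every candidate
    source the ideal observer marginalizes over.
    """

    min_strength: float = 0.0
    max_strength: float = 5.0
    step: float = 0.5

    def __post_init__(self) -> None:
        if not (self.max_strength > self.min_strength):
            raise ValueError("max_strength must exceed min_strength")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @cached_property
    def values(self) -> np.ndarray:
        n = int(round((self.max_strength - self.min_strength) / self.step)) + 1
        vals = self.min_strength + self.step * np.arange(n)
        return vals

    @cached_property
    def triplets(self) -> np.ndarray:
        """All strength triplets, shape (len(values)**3, 3)."""
        v = self.values
        g = np.stack(np.meshgrid(v, v, v, indexing="ij"), axis=-1)
        return g.reshape(-1, 3)

    @property
    def n_points(self) -> int:
        return len(self.triplets)


@dataclass(frozen=True)
class NoiseModel:
    """Internal noise: isotropic Gaussian with covariance ``sigma * I3``.

    ``sigma`` scales the covariance entries directly, i.e. the
    per-component *variance* equals ``sigma`` (and the per-component
    standard deviation is ``sqrt(sigma)``).
    """

    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError(f"sigma must be a positive finite scalar, got {self.sigma}")

    @property
    def variance(self) -> float:
        return float(self.sigma)

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.sigma))

    @property
    def covariance(self) -> np.ndarray:
        return self.sigma * np.eye(3)


@dataclass(frozen=True)
class TrialOutcome:
    """Single simulated trial: model id, 1-based choice, native confidence.

    ``confidence_raw`` is a posterior probability in [0, 1] for the three
    Bayesian observers and the (unbounded) chosen-dimension evidence for
    the response-congruent-evidence heuristic.
    """

    model_id: str
    choice: int
    confidence_raw: float


def _check_percept(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.shape[-1] != 3:
        raise ValueError("percepts must have 3 components on the last axis")
    if not np.all(np.isfinite(d)):
        raise ValueError("percept contains non-finite values")
    return d


# ---------------------------------------------------------------------------
# Percept generation
# ---------------------------------------------------------------------------


def sample_percept(
    c: np.ndarray, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    """Draw one noisy internal sample ``d ~ N(c, sigma * I3)``."""
    c = np.asarray(c, dtype=float)
    if c.shape != (3,):
        raise ValueError("c must be a 3-vector")
    if not np.all(np.isfinite(c)):
        raise ValueError("c contains non-finite values")
    return c + noise.sd * rng.standard_normal(3)


def sample_percepts(
    c: np.ndarray, noise: NoiseModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` iid percepts around ``c``; shape (n, 3)."""
    c = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("c contains non-finite values")
    return c + noise.sd * rng.standard_normal((n,) + c.shape)


# ---------------------------------------------------------------------------
# Posterior readouts
# ---------------------------------------------------------------------------


def argmax_weights(triplets: np.ndarray, tie_rule: TieRule = "share") -> np.ndarray:
    """Hypothesis weights per candidate triplet, shape (n_triplets, 3).

    A triplet whose largest component sits on axis ``i`` supports the
    hypothesis "stimulus i is strongest".  Triplets with tied maxima either
    share their prior mass equally among the tied hypotheses (``share``) or
    are dropped (``exclude``).
    """
    t = np.asarray(triplets, dtype=float)
    is_max = t == t.max(axis=1, keepdims=True)
    n_tied = is_max.sum(axis=1, keepdims=True)
    if tie_rule == "share":
        return is_max / n_tied
    if tie_rule == "exclude":
        return np.where(n_tied == 1, is_max, 0.0).astype(float)
    raise ValueError(f"unknown tie_rule {tie_rule!r}")


def plio_posterior(
    d: np.ndarray,
    grid: SignalGrid,
    noise: NoiseModel,
    tie_rule: TieRule = "share",
) -> np.ndarray:
    """Full-grid ideal-observer posterior p(S_i | d).

    Marginalizes the Gaussian likelihood of ``d`` over every candidate
    strength triplet on the grid, partitioned by which component of the
    triplet is largest.  Accepts a single percept (shape (3,)) or a batch
    (..., 3); returns probabilities of matching shape.
    """
    d = _check_percept(d)
    single = d.ndim == 1
    db = d.reshape(-1, 3)
    t = grid.triplets  # (m, 3)
    w = argmax_weights(t, tie_rule)  # (m, 3)
    v = noise.variance
    # squared distances (n, m) without forming (n, m, 3)
    sq = (
        (db * db).sum(axis=1)[:, None]
        + (t * t).sum(axis=1)[None, :]
        - 2.0 * db @ t.T
    )
    scores = -sq / (2.0 * v)
    scores -= scores.max(axis=1, keepdims=True)  # log-space shift
    unnorm = np.exp(scores) @ w  # (n, 3)
    p = unnorm / unnorm.sum(axis=1, keepdims=True)
    return p[0] if single else p.reshape(d.shape)


def plh_posterior(d: np.ndarray, noise: NoiseModel) -> np.ndarray:
    """Hierarchical-observer posterior p(S_i | c*, d) with ``c*_i = d_i``.

    Each hypothesis i places the source at ``d_i`` on axis i and zero
    elsewhere, so the log-odds reduce to ``d_i^2 / (2 sigma)`` and the
    preferred option is the component with the largest magnitude.
    """
    d = _check_percept(d)
    scores = d * d / (2.0 * noise.variance)
    scores = scores - scores.max(axis=-1, keepdims=True)
    unnorm = np.exp(scores)
    return unnorm / unnorm.sum(axis=-1, keepdims=True)


def aio_posterior(
    d: np.ndarray, grid: SignalGrid, noise: NoiseModel
) -> np.ndarray:
    """Axis-aligned ideal-observer posterior p(S_i | d).

    Hypothesis i assumes the source is ``c * e_i`` for a single scalar
    strength ``c`` marginalized over the 1-D grid of values.
    """
    d = _check_percept(d)
    v = noise.variance
    c = grid.values  # (k,)
    # log sum_c exp(-(d_i - c)^2 / 2v), common factor exp(-(|d|^2-d_i^2)/2v)
    diff = d[..., None] - c  # (..., 3, k)
    scores = logsumexp(-(diff * diff) / (2.0 * v), axis=-1) + d * d / (2.0 * v)
    scores = scores - scores.max(axis=-1, keepdims=True)
    unnorm = np.exp(scores)
    return unnorm / unnorm.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Decision rules
# ---------------------------------------------------------------------------


def _argmax_tiebreak(x: np.ndarray, rng: np.random.Generator | None) -> int:
    """0-based argmax with uniform random tie-breaking (seeded stream)."""
    winners = np.flatnonzero(x == x.max())
    if len(winners) == 1 or rng is None:
        return int(winners[0])
    return int(rng.choice(winners))


def rce_decide(d: np.ndarray, rng: np.random.Generator | None = None) -> TrialOutcome:
    """Response-congruent-evidence rule: pick the largest evidence, report it."""
    d = _check_percept(d)
    if d.ndim != 1:
        raise ValueError("rce_decide expects a single percept")
    i = _argmax_tiebreak(d, rng)
    return TrialOutcome(model_id="rce", choice=i + 1, confidence_raw=float(d[i]))


def posterior_for(
    model_id: str, d: np.ndarray, grid: SignalGrid, noise: NoiseModel
) -> np.ndarray:
    if model_id == "plio":
        return plio_posterior(d, grid, noise)
    if model_id == "plh":
        return plh_posterior(d, noise)
    if model_id == "aio":
        return aio_posterior(d, grid, noise)
    raise ValueError(f"unknown Bayesian model {model_id!r}")


def decide_batch(
    model_id: str,
    d: np.ndarray,
    grid: SignalGrid,
    noise: NoiseModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized choices and native confidences for a batch of percepts.

    Returns 0-based choices (int array) and confidences.  Exact evidence
    ties resolve to the lowest index; they occur with probability zero for
    continuous percepts.
    """
    d = _check_percept(np.atleast_2d(d))
    if model_id == "rce":
        choices = np.argmax(d, axis=-1)
        conf = np.take_along_axis(d, choices[..., None], axis=-1)[..., 0]
        return choices, conf
    p = posterior_for(model_id, d, grid, noise)
    choices = np.argmax(p, axis=-1)
    conf = np.take_along_axis(p, choices[..., None], axis=-1)[..., 0]
    return choices, conf


def simulate_trial(
    model_id: str,
    c: np.ndarray,
    grid: SignalGrid,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> TrialOutcome:
    """One full trial: sample a percept, apply the model's decision rule."""
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}; expected one of {MODELS}")
    d = sample_percept(c, noise, rng)
    if model_id == "rce":
        return rce_decide(d, rng)
    p = posterior_for(model_id, d, grid, noise)
    i = _argmax_tiebreak(p, rng)
    return TrialOutcome(model_id=model_id, choice=i + 1, confidence_raw=float(p[i]))
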