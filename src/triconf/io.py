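"""File formats, run configuration and output metadata.

Trial data travel as flat CSV with one row per trial (schema below); the
experimental design and structured results are JSON.  Every file written
here embeds the schema version and a hash of the run configuration so
that outputs are traceable to the exact settings that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import TRIAL_COLUMNS, SubjectData, categorize_choice
from .selection import CATEGORIES, Condition, ExperimentDesign

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to/from YAML."""

    grid_min: float = 0.0
    grid_max: float = 5.0
    grid_step: float = 0.5
    sigma: float = 1.0
    n_trials_grid: int = 10_000
    selection_k: int = 3
    coherence_scale: float = 0.16
    tie_epsilon: float = 1e-4
    sigma_search_min: float = 0.25
    sigma_search_max: float = 6.0
    sigma_search_step: float = 0.05
    sim_n: int = 2000
    kde_grid_points: int = 512
    kde_pad_bandwidths: float = 3.0
    min_cell_count: int = 2
    cohort_size_per_model: int = 91
    n_trials_per_condition: int = 150
    fit_mode: str = "shared_sigma"
    master_seed: int = 0
    out_dir: str = "triconf_out"

    def __post_init__(self) -> None:
        checks = [
            (self.grid_max > self.grid_min, "grid_max must exceed grid_min"),
            (self.grid_step > 0, "grid_step must be positive"),
            (self.sigma > 0, "sigma must be positive"),
            (self.n_trials_grid >= 1, "n_trials_grid must be >= 1"),
            (self.selection_k >= 1, "selection_k must be >= 1"),
            (0 < self.coherence_scale <= 1, "coherence_scale must lie in (0, 1]"),
            (self.tie_epsilon > 0, "tie_epsilon must be positive"),
            (0 < self.sigma_search_min < self.sigma_search_max,
             "sigma search range must be positive and ordered"),
            (self.sigma_search_step > 0, "sigma_search_step must be positive"),
            (self.sim_n >= 1, "sim_n must be >= 1"),
            (self.kde_grid_points >= 16, "kde_grid_points must be >= 16"),
            (self.min_cell_count >= 2, "min_cell_count must be >= 2"),
            (self.cohort_size_per_model >= 1, "cohort size must be >= 1"),
            (self.n_trials_per_condition >= 1, "n_trials_per_condition must be >= 1"),
            (self.fit_mode in ("shared_sigma", "per_model_sigma"),
             f"unknown fit_mode {self.fit_mode!r}"),
            (self.master_seed >= 0, "master_seed must be non-negative"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid configuration: {msg}")

    @property
    def sigma_grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.sigma_search_min, self.sigma_search_max + 1e-9,
                      self.sigma_search_step),
            6,
        )

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _meta(config: RunConfig | None) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "config_hash": config.hash() if config is not None else None,
    }


# ---------------------------------------------------------------------------
# Trial CSV
# ---------------------------------------------------------------------------


def write_trials(
    subjects: list[SubjectData], path: str | Path, config: RunConfig | None = None
) -> None:
    """Write a cohort as trial CSV with a commented metadata header."""
    path = Path(path)
    frames = [s.trials[TRIAL_COLUMNS] for s in subjects]
    df = pd.concat(frames, ignore_index=True)
    meta = _meta(config)
    with open(path, "w") as fh:
        fh.write(
            f"# triconf trials schema_version={meta['schema_version']} "
            f"config_hash={meta['config_hash']}\n"
        )
        df.to_csv(fh, index=False)


def read_trials(path: str | Path) -> list[SubjectData]:
    """Read and validate a trial CSV; returns one SubjectData per subject.

    Malformed rows are rejected with their line numbers; the stored choice
    category is recomputed from the arrangement columns and must agree.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: schema mismatch, missing columns {missing}")
    # line numbers in the file: header + metadata comment precede the data
    offset = 3
    errors = []
    for i, row in df.iterrows():
        line = i + offset
        if row[["choice_position", "pos_highest", "pos_second", "pos_lowest"]].isna().any():
            errors.append(f"line {line}: missing position field")
            continue
        positions = {int(row[f"pos_{cat}"]) for cat in CATEGORIES}
        if positions != {1, 2, 3}:
            errors.append(f"line {line}: arrangement is not a permutation of 1..3")
            continue
        coh = [row["coh_lowest"], row["coh_second"], row["coh_highest"]]
        arrangement = {cat: int(row[f"pos_{cat}"]) for cat in CATEGORIES}
        try:
            cat = categorize_choice(coh, arrangement, int(row["choice_position"]))
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
            continue
        if cat != row["choice_category"]:
            errors.append(
                f"line {line}: stored category {row['choice_category']!r} conflicts "
                f"with arrangement (recomputed {cat!r}) for trial "
                f"{row['trial_index']} of subject {row['subject_id']}"
            )
    if errors:
        raise ValueError(f"{path}: invalid rows:\n" + "\n".join(errors))
    subjects = []
    for sid, sdf in df.groupby("subject_id", sort=False):
        subjects.append(SubjectData(subject_id=str(sid), trials=sdf.reset_index(drop=True)))
    return subjects


# ---------------------------------------------------------------------------
# Design and results JSON
# ---------------------------------------------------------------------------


def design_to_json(
    design: ExperimentDesign, path: str | Path, config: RunConfig | None = None
) -> None:
    payload = {
        **_meta(config),
        "coherence_scale": design.coherence_scale,
        "tie_epsilon": design.tie_epsilon,
        "conditions": [
            {
                "condition_id": c.condition_id,
                "strengths": list(c.strengths),
                "coherences": list(c.coherences),
            }
            for c in design.conditions
        ],
    }
    _atomic_write_json(payload, path)


def design_from_json(path: str | Path) -> ExperimentDesign:
    with open(path) as fh:
        data = json.load(fh)
    conditions = tuple(
        Condition(
            condition_id=c["condition_id"],
            strengths=tuple(c["strengths"]),
            coherences=tuple(c["coherences"]),
        )
        for c in data["conditions"]
    )
    return ExperimentDesign(
        conditions=conditions,
        coherence_scale=data["coherence_scale"],
        tie_epsilon=data["tie_epsilon"],
    )


def write_json(payload: dict, path: str | Path, config: RunConfig | None = None) -> None:
    _atomic_write_json({**_meta(config), **payload}, path)


def _atomic_write_json(payload: dict, path: str | Path) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")
    tmp.replace(path)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def write_effect_table(table, ranking: pd.DataFrame, path: str | Path,
                       config: RunConfig | None = None) -> None:
    """Effect-size CSV: per point and pair d, class summed d and rank."""
    path = Path(path)
    pw = table.pairwise.copy()
    pw["pair"] = pw["model_a"] + ":" + pw["model_b"]
    key = np.sort(pw[["c1", "c2", "c3"]].to_numpy(), axis=1)
    pw["class"] = [tuple(r) for r in key]
    rank_map = ranking.set_index("class")[["summed_d", "rank", "ambiguous"]]
    pw = pw.join(rank_map, on="class")
    ambiguous = pw["ambiguous"].isna() | (pw["ambiguous"] == True)  # noqa: E712
    pw["excluded_reason"] = np.where(ambiguous, "ambiguous_type1_maximum", "")
    out = pw[["c1", "c2", "c3", "pair", "d", "summed_d", "rank", "excluded_reason"]]
    meta = _meta(config)
    with open(path, "w") as fh:
        fh.write(
            f"# triconf effect sizes schema_version={meta['schema_version']} "
            f"config_hash={meta['config_hash']}\n"
        )
        out.to_csv(fh, index=False)
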