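"""File formats and provenance stamping.

Conventions, stated once and enforced by the validators here: tabular data
are CSV, structured objects are JSON, configurations are YAML; feature-space
coordinates are always in SD units and choices are always 0-based.  Floats
survive round trips exactly because Python's shortest-repr float formatting
is itself round-trip safe.

Trial/response CSV columns:
    trial_id, task, s1_x, s1_y, s2_x, s2_y, s3_x, s3_y, repeat_group, choice
with s3_* blank for familiarity trials, repeat_group blank for unrepeated
trials, and choice absent (or blank) in pure trial files.

Every writer embeds a provenance block (package version, seed, hash of the
configuration) — as a leading ``#`` comment line in CSV, as a top-level key
in JSON — so outputs are traceable to the exact inputs that produced them.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .comparison import DistanceMatrix
from .ideal_observer import FAMILIARITY, ODD_ONE_OUT, ObserverParams, Response, Trial
from .inference import PosteriorSamples, PriorConfig, SamplerSettings
from .prediction_eval import PredictionSet
from .subjective_model import FeatureSpace, GridDensity, SubjectiveDistribution

__all__ = [
    "provenance_block",
    "write_trials",
    "read_trials",
    "write_responses",
    "read_responses",
    "write_samples",
    "read_samples",
    "write_grid",
    "read_grid",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_predictions",
    "read_predictions",
]

def provenance_block(config: Optional[dict] = None, seed: Optional[int] = None) -> dict:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "package": "cogtomo",
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(payload.encode()).hexdigest()[:16],
    }


def _provenance_comment(config: Optional[dict], seed: Optional[int]) -> str:
    return "# provenance: " + json.dumps(provenance_block(config, seed), sort_keys=True)


# --------------------------------------------------------------------------
# Trials and responses
# --------------------------------------------------------------------------


def _trials_frame(trials: Sequence[Trial], choices: Optional[Sequence[int]] = None) -> pd.DataFrame:
    rows = []
    for i, t in enumerate(trials):
        s = t.stimuli
        row = {
            "trial_id": i,
            "task": t.task,
            "s1_x": s[0, 0],
            "s1_y": s[0, 1],
            "s2_x": s[1, 0],
            "s2_y": s[1, 1],
            "s3_x": s[2, 0] if t.task == ODD_ONE_OUT else None,
            "s3_y": s[2, 1] if t.task == ODD_ONE_OUT else None,
            "repeat_group": t.repeat_group,
        }
        if choices is not None:
            row["choice"] = choices[i]
        rows.append(row)
    return pd.DataFrame(rows)


def _write_frame(df: pd.DataFrame, path, config, seed) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_comment(config, seed) + "\n")
        df.to_csv(fh, index=False)


def write_trials(trials: Sequence[Trial], path, config: Optional[dict] = None, seed=None) -> None:
    _write_frame(_trials_frame(trials), path, config, seed)


def write_responses(responses: Sequence[Response], path, config: Optional[dict] = None, seed=None) -> None:
    trials = [r.trial for r in responses]
    choices = [r.choice for r in responses]
    _write_frame(_trials_frame(trials, choices), path, config, seed)


def _parse_trial_row(row, idx, space: FeatureSpace) -> Trial:
    task = row["task"]
    if task not in (FAMILIARITY, ODD_ONE_OUT):
        raise ValueError(f"row {idx}: unknown task {task!r}")
    try:
        if task == FAMILIARITY:
            stim = np.array(
                [[row["s1_x"], row["s1_y"]], [row["s2_x"], row["s2_y"]]], dtype=float
            )
            if not (pd.isna(row.get("s3_x")) and pd.isna(row.get("s3_y"))):
                raise ValueError("familiarity trials must leave s3 blank")
        else:
            stim = np.array(
                [
                    [row["s1_x"], row["s1_y"]],
                    [row["s2_x"], row["s2_y"]],
                    [row["s3_x"], row["s3_y"]],
                ],
                dtype=float,
            )
        if np.any(~np.isfinite(stim)):
            raise ValueError("missing or non-finite stimulus coordinate")
        rg = row.get("repeat_group")
        rg = None if pd.isna(rg) else int(rg)
        return Trial(task=task, stimuli=stim, space=space, repeat_group=rg)
    except ValueError as err:
        raise ValueError(f"row {idx}: {err}") from None


def read_trials(path, space: FeatureSpace = FeatureSpace()) -> list[Trial]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return [_parse_trial_row(row, i, space) for i, row in df.iterrows()]


def read_responses(path, space: FeatureSpace = FeatureSpace()) -> list[Response]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "choice" not in df.columns:
        raise ValueError("responses file must have a 'choice' column")
    out = []
    for i, row in df.iterrows():
        trial = _parse_trial_row(row, i, space)
        if pd.isna(row["choice"]):
            raise ValueError(f"row {i}: missing choice")
        try:
            out.append(Response(trial=trial, choice=int(row["choice"])))
        except ValueError as err:
            raise ValueError(f"row {i}: {err}") from None
    return out


# --------------------------------------------------------------------------
# Posterior samples
# --------------------------------------------------------------------------


def write_samples(samples: PosteriorSamples, path) -> None:
    doc = {
        "provenance": provenance_block(samples.config, samples.seed),
        "task": samples.task,
        "space": {"n_dims": samples.space.n_dims, "half_width": samples.space.half_width},
        "seed": samples.seed,
        "config": samples.config,
        "acceptance_rates": samples.acceptance_rates,
        "log_posterior_trace": samples.log_posterior_trace.tolist(),
        "draws": [
            {
                "p": p.to_dict(),
                "omega": {
                    "perceptual_sigma": params.perceptual_sigma,
                    "temperature": params.temperature,
                    "lapse": params.lapse,
                },
            }
            for p, params in samples.draws
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_samples(path) -> PosteriorSamples:
    with open(path) as fh:
        doc = json.load(fh)
    space = FeatureSpace(int(doc["space"]["n_dims"]), float(doc["space"]["half_width"]))
    draws = [
        (
            SubjectiveDistribution.from_dict(d["p"]),
            ObserverParams(**d["omega"]),
        )
        for d in doc["draws"]
    ]
    return PosteriorSamples(
        draws=draws,
        log_posterior_trace=np.asarray(doc["log_posterior_trace"], dtype=float),
        acceptance_rates=doc["acceptance_rates"],
        seed=doc["seed"],
        config=doc["config"],
        task=doc["task"],
        space=space,
    )


# --------------------------------------------------------------------------
# Grids, distance matrices, predictions
# --------------------------------------------------------------------------


def write_grid(grid: GridDensity, path, config: Optional[dict] = None, seed=None) -> None:
    _write_frame(grid.to_frame(), path, config, seed)


def read_grid(path, space: FeatureSpace = FeatureSpace()) -> GridDensity:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    n = len(df)
    resolution = int(round(n ** (1.0 / space.n_dims)))
    if resolution**space.n_dims != n:
        raise ValueError(f"{path}: {n} rows is not a square grid")
    masses = df["mass"].to_numpy(dtype=float).reshape((resolution,) * space.n_dims)
    return GridDensity(space, resolution, masses / masses.sum())


def _label_str(label) -> str:
    if isinstance(label, (tuple, list)):
        return "|".join(str(x) for x in label)
    return str(label)


def _label_parse(s: str):
    parts = s.split("|")
    return tuple(parts) if len(parts) > 1 else s


def write_distance_matrix(dm: DistanceMatrix, path, config=None, seed=None) -> None:
    rows = [
        {
            "label_a": _label_str(dm.labels[i]),
            "label_b": _label_str(dm.labels[j]),
            "distance": dm.values[i, j],
        }
        for i in range(dm.n)
        for j in range(i + 1, dm.n)
    ]
    df = pd.DataFrame(rows)
    df.attrs["metric"] = dm.metric
    with open(path, "w") as fh:
        fh.write(_provenance_comment(config, seed) + "\n")
        fh.write(f"# metric: {dm.metric}\n")
        df.to_csv(fh, index=False)


def read_distance_matrix(path) -> DistanceMatrix:
    metric = "js_bits"
    with open(path) as fh:
        for line in fh:
            if line.startswith("# metric:"):
                metric = line.split(":", 1)[1].strip()
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    labels = []
    for col in ("label_a", "label_b"):
        for s in df[col]:
            lbl = _label_parse(s)
            if lbl not in labels:
                labels.append(lbl)
    index = {lbl: i for i, lbl in enumerate(labels)}
    v = np.zeros((len(labels), len(labels)))
    for _, row in df.iterrows():
        i, j = index[_label_parse(row["label_a"])], index[_label_parse(row["label_b"])]
        v[i, j] = v[j, i] = float(row["distance"])
    return DistanceMatrix(labels=tuple(labels), values=v, metric=metric)


def write_predictions(pred: PredictionSet, path, config=None, seed=None) -> None:
    cols = {f"p{k + 1}": pred.probs[:, k] for k in range(pred.probs.shape[1])}
    df = pd.DataFrame({"trial_id": np.arange(pred.n_trials), **cols})
    df.insert(1, "task", pred.task)
    df.insert(2, "source_task", pred.source_task)
    _write_frame(df, path, config, seed)


def read_predictions(path) -> PredictionSet:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    pcols = [c for c in df.columns if c.startswith("p") and c[1:].isdigit()]
    probs = df[sorted(pcols, key=lambda c: int(c[1:]))].to_numpy(dtype=float)
    return PredictionSet(
        probs=probs, task=df["task"].iloc[0], source_task=df["source_task"].iloc[0]
    )


# --------------------------------------------------------------------------
# Configs
# --------------------------------------------------------------------------


def prior_from_dict(d: Optional[dict]) -> PriorConfig:
    return PriorConfig(**(d or {}))


def settings_from_dict(d: Optional[dict]) -> SamplerSettings:
    return SamplerSettings(**(d or {}))
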