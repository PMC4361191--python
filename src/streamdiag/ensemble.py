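"""Ensembles of replicate networks: training, prediction, validation error.

With only 32 training records and 9 inputs, a single network reaching the
loose MSE goal may latch onto any of several adequate input combinations;
its individual prediction is unstable. Training 50 replicate networks from
independent random initialisations and averaging their outputs gives a far
more stable stress estimate, summarised per record as mean +/- sample
standard deviation. A record is classified as high-stress (level 2) when
the ensemble mean is at or above 1.5.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ann
from .errors import InferenceError, TrainingError
from .prep import TrainingSplit

__all__ = [
    "Ensemble",
    "train_ensemble",
    "predict",
    "error_rate",
    "save_ensemble",
    "load_ensemble",
]

#: Stride between restart seeds of one member; keeps every derived seed
#: distinct from every other member/restart for base seeds below ~2e9.
_RESTART_STRIDE = 1_000_003


@dataclass(frozen=True)
class Ensemble:
    """A bag of converged replicate networks sharing one input layout."""

    target_name: str
    input_vars: tuple[str, ...]
    members: tuple[ann.Network, ...]
    member_seeds: tuple[int, ...]
    split: TrainingSplit | None
    goal: float
    member_epochs: tuple[int, ...] | None = None
    member_mse: tuple[float, ...] | None = None

    def __post_init__(self):
        if not self.members:
            raise TrainingError("ensemble has no members")
        n_in = len(self.input_vars)
        for m in self.members:
            if m.n_inputs != n_in:
                raise InferenceError("member input size does not match input_vars")


def _member_seed(base_seed: int, k: int, restart: int) -> int:
    return (base_seed + k + restart * _RESTART_STRIDE) % (2**31)


def train_ensemble(
    features: pd.DataFrame,
    target: pd.Series,
    split: TrainingSplit,
    target_name: str,
    input_vars,
    n_members: int = 50,
    base_seed: int = 0,
    goal: float = 0.2,
    max_epochs: int = 1000,
    max_restarts_per_member: int = 20,
    hidden: tuple[int, ...] = (6, 3),
    id_col: str = "record_id",
    log=None,
) -> Ensemble:
    """Train ``n_members`` converged networks on the training half.

    Member ``k`` starts from the seed ``base_seed + k``; if Levenberg-
    Marquardt fails to reach the MSE goal it is re-initialised from a fresh
    derived seed, up to ``max_restarts_per_member`` times, before raising.
    The whole ensemble is reproducible from ``base_seed``.
    """
    input_vars = tuple(input_vars)
    feat = features.set_index(id_col)
    train_ids = sorted(split.train_ids)
    X = feat.loc[train_ids, list(input_vars)].to_numpy(float)
    y = target.set_axis(features[id_col]).loc[train_ids].to_numpy(float)

    members, seeds, epochs, mses = [], [], [], []
    for k in range(n_members):
        state = None
        for restart in range(max_restarts_per_member + 1):
            seed = _member_seed(base_seed, k, restart)
            net = ann.init_network(seed, n_inputs=len(input_vars), hidden=hidden)
            net, state = ann.train(net, X, y, goal=goal, max_epochs=max_epochs)
            if state.converged:
                members.append(net)
                seeds.append(seed)
                epochs.append(state.epoch)
                mses.append(state.mse)
                if log is not None:
                    log.info(
                        "member %d/%d converged: seed=%d epochs=%d mse=%.4f",
                        k + 1, n_members, seed, state.epoch, state.mse,
                    )
                break
        else:
            raise TrainingError(
                f"member {k} failed to reach MSE <= {goal} after "
                f"{max_restarts_per_member} restarts (final MSE {state.mse:.4f})"
            )
    return Ensemble(
        target_name, input_vars, tuple(members), tuple(seeds), split, goal,
        member_epochs=tuple(epochs), member_mse=tuple(mses),
    )


def member_outputs(
    ens: Ensemble, features: pd.DataFrame, id_col: str = "record_id"
) -> np.ndarray:
    """Raw member outputs, shape (n_records, n_members)."""
    missing = [v for v in ens.input_vars if v not in features.columns]
    if missing:
        raise InferenceError(f"records are missing input variables {missing}")
    X = features[list(ens.input_vars)].to_numpy(float)
    return np.column_stack([ann.forward_batch(m, X) for m in ens.members])


def predict(
    ens: Ensemble,
    features: pd.DataFrame,
    id_col: str = "record_id",
    threshold: float = 1.5,
) -> pd.DataFrame:
    """Ensemble predictions per record: mean, sample SD, classified level.

    ``vote_fraction_high`` is the fraction of members whose individual
    output falls at or above the threshold — an alternative reading of the
    per-record "probability" that is reported alongside the mean.
    """
    outputs = member_outputs(ens, features, id_col)
    mean = outputs.mean(axis=1)
    sd = outputs.std(axis=1, ddof=1) if outputs.shape[1] > 1 else np.zeros(len(mean))
    return pd.DataFrame(
        {
            id_col: features[id_col].to_numpy(),
            "mean": mean,
            "sd": sd,
            "classified_level": np.where(mean >= threshold, 2, 1),
            "vote_fraction_high": (outputs >= threshold).mean(axis=1),
        }
    )


def error_rate(predicted_levels, true_levels) -> float:
    """Misclassification percentage, rounded to one decimal place."""
    pred = np.asarray(predicted_levels)
    truth = np.asarray(true_levels)
    if pred.size == 0:
        raise InferenceError("cannot compute an error rate on empty input")
    if pred.shape != truth.shape:
        raise InferenceError("prediction/truth length mismatch")
    if not set(np.unique(truth)) <= {1, 2}:
        raise InferenceError("true levels must be coded {1, 2}")
    rate = 100.0 * float(np.mean(pred != truth))
    # one-decimal rounding, half away from zero (2/32 -> 6.3, not 6.2)
    return math.floor(rate * 10.0 + 0.5) / 10.0


def _split_hash(split: TrainingSplit | None) -> str:
    if split is None:
        return ""
    doc = json.dumps(
        [sorted(map(str, split.train_ids)), sorted(map(str, split.validation_ids))]
    )
    return hashlib.sha256(doc.encode()).hexdigest()


def save_ensemble(ens: Ensemble, directory) -> None:
    """Write a manifest plus one JSON document per member network."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "target_name": ens.target_name,
        "input_vars": list(ens.input_vars),
        "goal": ens.goal,
        "n_members": len(ens.members),
        "member_seeds": list(ens.member_seeds),
        "split_hash": _split_hash(ens.split),
        "member_epochs": list(ens.member_epochs) if ens.member_epochs else None,
        "member_mse": list(ens.member_mse) if ens.member_mse else None,
        "train_ids": sorted(map(str, ens.split.train_ids)) if ens.split else None,
        "validation_ids": sorted(map(str, ens.split.validation_ids)) if ens.split else None,
        "priority_inputs": list(ens.split.priority_inputs) if ens.split else None,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    for i, m in enumerate(ens.members):
        (directory / f"member_{i:03d}.json").write_text(ann.network_to_json(m))


def load_ensemble(directory) -> Ensemble:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    members = tuple(
        ann.network_from_json((directory / f"member_{i:03d}.json").read_text())
        for i in range(manifest["n_members"])
    )
    split = None
    if manifest.get("train_ids") is not None:
        ids = manifest["train_ids"] + manifest["validation_ids"]
        cast = int if all(s.lstrip("-").isdigit() for s in ids) else str
        split = TrainingSplit(
            frozenset(cast(s) for s in manifest["train_ids"]),
            frozenset(cast(s) for s in manifest["validation_ids"]),
            tuple(manifest["priority_inputs"] or ()),
        )
    return Ensemble(
        target_name=manifest["target_name"],
        input_vars=tuple(manifest["input_vars"]),
        members=members,
        member_seeds=tuple(manifest["member_seeds"]),
        split=split,
        goal=manifest["goal"],
        member_epochs=tuple(manifest["member_epochs"]) if manifest.get("member_epochs") else None,
        member_mse=tuple(manifest["member_mse"]) if manifest.get("member_mse") else None,
    )
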