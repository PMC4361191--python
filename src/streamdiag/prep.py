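"""Standardization, integer coding, input screening and the train/validation split.

Raw biological responses are expressed relative to controls before any
pattern recognition: mesocosm records are divided by the mean of the
low-nutrient/low-sediment channels of the same year, survey sites by the
mean of the "field control" sites with <1 % grazing in their catchment. The
ratios are rounded to the nearest integer (half away from zero) and clipped
to the coding range [-2, +3].

Note on the coding range: a ratio of nonnegative responses can never be
negative, so under ratio standardization the codes -2 and -1 are
unreachable; they become reachable under the alternative z-score mode
(``mode="zscore"``). Both modes are provided; ratio is the default. See
docs/methods.md for the rationale.

Input screening drops the ``k`` variables least correlated (|Pearson r|)
with the target stress level, and the three strongest correlates become the
"priority inputs" that the split algorithm uses to make the training half
span the observed input levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .stats import pearson_r

__all__ = [
    "TrainingSplit",
    "mesocosm_control_ids",
    "survey_control_ids",
    "standardize",
    "discard_low_correlation",
    "rank_priority_inputs",
    "make_split",
    "CODE_MIN",
    "CODE_MAX",
]

CODE_MIN = -2
CODE_MAX = 3


@dataclass(frozen=True)
class TrainingSplit:
    """Disjoint, exhaustive partition of record ids into equal halves."""

    train_ids: frozenset
    validation_ids: frozenset
    priority_inputs: tuple[str, ...]

    def __post_init__(self):
        if self.train_ids & self.validation_ids:
            raise DataError("train and validation sets overlap")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def mesocosm_control_ids(df: pd.DataFrame) -> frozenset:
    """Ids of the experimental controls: low-nutrient, low-sediment channels."""
    mask = (df["nutrient_level"] == 1) & (df["sediment_level"] == 1)
    return frozenset(df.loc[mask, "record_id"])


def survey_control_ids(df: pd.DataFrame, grazing_cutoff: float = 0.01) -> frozenset:
    """Ids of field control sites: grazing below ``grazing_cutoff`` (default <1%)."""
    ids = frozenset(df.loc[df["grazing_proportion"] < grazing_cutoff, "site_id"])
    if len(ids) < 2:
        raise DataError(
            f"need at least 2 field control sites with grazing < {grazing_cutoff}, "
            f"found {len(ids)}"
        )
    return ids


def standardize(
    df: pd.DataFrame,
    control_ids,
    response_names,
    id_col: str = "record_id",
    mode: str = "ratio",
    by_year: bool | None = None,
) -> pd.DataFrame:
    """Standardize raw responses against controls and integer-code them.

    Parameters
    ----------
    df : table with an id column, the response columns, and optionally a
        ``year`` column.
    control_ids : ids of the control records/sites.
    mode : ``"ratio"`` — code = round(raw / control_mean); ``"zscore"`` —
        code = round((raw - control_mean) / control_sd). Codes are clipped
        to [-2, +3] in both modes; rounding is half away from zero.
    by_year : standardize within year (mesocosm rule: controls of the same
        year). Defaults to True when a ``year`` column is present.

    Returns a table with the id column and integer-coded feature columns.
    """
    if mode not in ("ratio", "zscore"):
        raise DataError(f"unknown standardization mode {mode!r}")
    control_ids = frozenset(control_ids)
    if not control_ids:
        raise DataError("control set is empty")
    missing = control_ids - set(df[id_col])
    if missing:
        raise DataError(f"control ids not present in table: {sorted(missing)[:5]}")
    if by_year is None:
        by_year = "year" in df.columns

    groups = df.groupby("year", sort=True) if by_year else [(None, df)]
    out_parts = []
    for _, g in groups:
        ctrl = g[g[id_col].isin(control_ids)]
        if ctrl.empty:
            raise DataError("a standardization group contains no control records")
        part = g[[id_col]].copy()
        for v in response_names:
            mean = float(ctrl[v].mean())
            if mode == "ratio":
                if mean == 0:
                    raise DataError(f"control mean of {v!r} is zero; ratio undefined")
                coded = g[v].to_numpy(float) / mean
            else:
                sd = float(ctrl[v].std(ddof=1))
                if sd == 0:
                    raise DataError(f"control sd of {v!r} is zero; z-score undefined")
                coded = (g[v].to_numpy(float) - mean) / sd
            part[v] = np.clip(_round_half_away(coded), CODE_MIN, CODE_MAX).astype(int)
        out_parts.append(part)
    out = pd.concat(out_parts).sort_index()
    return out.reset_index(drop=True)


def _abs_correlations(
    features: pd.DataFrame, target: np.ndarray, var_names
) -> dict[str, float]:
    target = np.asarray(target, dtype=float)
    out = {}
    for v in var_names:
        out[v] = abs(pearson_r(features[v].to_numpy(float), target))
    return out


def discard_low_correlation(
    features: pd.DataFrame, target, var_names, k: int = 2
) -> tuple[str, ...]:
    """Drop the ``k`` variables with the smallest |r| against the target level.

    ``var_names`` fixes the canonical order; ties in |r| are broken by that
    order (the earlier-listed variable is dropped first). A zero-variance
    feature has r defined as 0. Returns the retained names in canonical
    order.
    """
    var_names = tuple(var_names)
    if k < 0 or k > len(var_names):
        raise DataError(f"k must be in [0, {len(var_names)}], got {k}")
    if k == 0:
        return var_names
    target = np.asarray(target, dtype=float)
    if len(features) < 3:
        raise DataError("need at least 3 records to screen inputs")
    if np.all(target == target[0]):
        raise DataError("target levels are all equal; correlations undefined")
    r = _abs_correlations(features, target, var_names)
    order = sorted(var_names, key=lambda v: (r[v], var_names.index(v)))
    dropped = set(order[:k])
    return tuple(v for v in var_names if v not in dropped)


def rank_priority_inputs(
    features: pd.DataFrame, target, retained_vars, n_priority: int = 3
) -> tuple[str, ...]:
    """The ``n_priority`` retained variables with highest |r|, descending.

    Ties are broken by canonical (listed) order.
    """
    retained_vars = tuple(retained_vars)
    if len(retained_vars) < n_priority:
        raise DataError("fewer retained variables than requested priorities")
    r = _abs_correlations(features, np.asarray(target, dtype=float), retained_vars)
    order = sorted(retained_vars, key=lambda v: (-r[v], retained_vars.index(v)))
    return tuple(order[:n_priority])


def make_split(
    features: pd.DataFrame,
    target: pd.Series | np.ndarray,
    priority_inputs,
    id_col: str = "record_id",
) -> TrainingSplit:
    """Deterministic half/half train-validation split spanning input levels.

    Greedy coverage: iterate over the priority inputs in order and, for each
    observed integer level of each priority input (ascending), move the
    lowest-id not-yet-selected record exhibiting that level into the
    training set. Remaining training slots are filled alternating
    low-target/high-target records by ascending id. The remainder is the
    validation set. Both halves must contain both target levels.
    """
    n = len(features)
    if n < 8 or n % 2 != 0:
        raise DataError(f"split needs an even number of records >= 8, got {n}")
    ids = list(features[id_col])
    if len(set(ids)) != n:
        raise DataError("record ids are not unique")
    target = np.asarray(target)
    levels = dict(zip(ids, target))
    feat = features.set_index(id_col)
    order = sorted(ids)
    n_train = n // 2

    selected: list = []
    selected_set: set = set()

    def take(rid) -> None:
        selected.append(rid)
        selected_set.add(rid)

    for p in priority_inputs:
        if p not in feat.columns:
            raise DataError(f"priority input {p!r} missing from feature table")
        for level in sorted(feat[p].unique()):
            if len(selected) >= n_train:
                break
            for rid in order:
                if rid not in selected_set and feat.at[rid, p] == level:
                    take(rid)
                    break

    while len(selected) < n_train:
        # alternate low/high so the two target levels stay balanced,
        # counting what the coverage pass already selected; tie -> level 1
        c1 = sum(1 for rid in selected if levels[rid] == 1)
        want = 1 if c1 <= len(selected) - c1 else 2
        candidate = next(
            (rid for rid in order if rid not in selected_set and levels[rid] == want),
            None,
        )
        if candidate is None:
            candidate = next((rid for rid in order if rid not in selected_set), None)
        if candidate is None:
            break
        take(candidate)

    train = frozenset(selected)
    validation = frozenset(rid for rid in ids if rid not in train)
    for name, part in (("training", train), ("validation", validation)):
        part_levels = {levels[rid] for rid in part}
        if len(part_levels) < 2:
            raise DataError(f"{name} set does not contain both target levels")
    return TrainingSplit(train, validation, tuple(priority_inputs))


def write_features_csv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False)


def write_split_csv(split: TrainingSplit, path, id_col: str = "record_id") -> None:
    rows = [(rid, "train") for rid in sorted(split.train_ids)] + [
        (rid, "validation") for rid in sorted(split.validation_ids)
    ]
    pd.DataFrame(rows, columns=[id_col, "partition"]).to_csv(path, index=False)
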