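"""Standardization, integer coding, input screening and the 32/32 split."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from streamdiag import prep, synthdata
from streamdiag.errors import DataError
from streamdiag.synthdata import MesocosmConfig


def _table(values: dict, ids=None):
    ids = ids if ids is not None else list(range(1, len(next(iter(values.values()))) + 1))
    return pd.DataFrame({"record_id": ids, **values})


class TestStandardize:
    def test_ratio_codes_forced_by_round_and_clip(self):
        # controls are rows 1-2 with mean 10
        df = _table({"v": [10.0, 10.0, 10.0, 0.0, 36.0, 50.0, 14.9, 15.0]})
        out = prep.standardize(df, {1, 2}, ["v"])
        # 1.0->1, 0->0, 3.6->4 clip 3, 5.0->3 (clip), 1.49->1, 1.5->2
        assert out["v"].tolist() == [1, 1, 1, 0, 3, 3, 1, 2]

    def test_codes_bounded_and_integer(self, mesocosm_features, default_config):
        cols = list(default_config.mesocosm.response_names)
        vals = mesocosm_features[cols].to_numpy()
        assert vals.dtype.kind == "i"
        assert vals.min() >= prep.CODE_MIN and vals.max() <= prep.CODE_MAX

    def test_mesocosm_controls_are_per_year_low_low(self, mesocosm_table):
        ids = prep.mesocosm_control_ids(mesocosm_table)
        sub = mesocosm_table[mesocosm_table["record_id"].isin(ids)]
        assert len(sub) == 16
        assert (sub["nutrient_level"] == 1).all() and (sub["sediment_level"] == 1).all()
        assert set(sub["year"]) == {1, 2}

    def test_idempotent_when_control_mean_is_one(self):
        df = _table({"v": [1.0, 1.0, 2.0, 3.0, 0.0]})
        once = prep.standardize(df, {1, 2}, ["v"])
        again = prep.standardize(once.astype({"v": float}), {1, 2}, ["v"])
        assert once["v"].tolist() == again["v"].tolist()

    def test_zscore_mode_can_produce_negative_codes(self):
        df = _table({"v": [10.0, 12.0, 8.0, 2.0, 30.0]})
        out = prep.standardize(df, {1, 2, 3}, ["v"], mode="zscore")
        assert out["v"].min() < 0

    def test_zero_control_mean_names_the_variable(self):
        df = _table({"good": [1.0, 2.0, 3.0], "bad": [0.0, 0.0, 5.0]})
        with pytest.raises(DataError, match="bad"):
            prep.standardize(df, {1, 2}, ["good", "bad"])

    def test_empty_control_set_rejected(self):
        df = _table({"v": [1.0, 2.0]})
        with pytest.raises(DataError):
            prep.standardize(df, set(), ["v"])

    @given(st.lists(st.floats(0.0, 100.0), min_size=4, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_property_codes_always_in_range(self, raw):
        df = _table({"v": [10.0, 10.0] + raw})
        out = prep.standardize(df, {1, 2}, ["v"])
        assert out["v"].between(prep.CODE_MIN, prep.CODE_MAX).all()


class TestScreening:
    names = ("a", "b", "c", "d")

    def _features(self):
        return pd.DataFrame(
            {
                "record_id": range(1, 9),
                "a": [1, 1, 1, 1, 2, 2, 2, 2],  # perfect correlate
                "b": [1, 2, 1, 2, 2, 1, 2, 1],  # none
                "c": [0, 1, 0, 1, 1, 2, 2, 2],  # partial
                "d": [1, 1, 1, 1, 1, 1, 1, 1],  # zero variance -> r = 0
            }
        )

    target = np.array([1, 1, 1, 1, 2, 2, 2, 2])

    def test_k_zero_is_identity(self):
        f = self._features()
        assert prep.discard_low_correlation(f, self.target, self.names, k=0) == self.names

    def test_drops_weakest_and_keeps_canonical_order(self):
        f = self._features()
        retained = prep.discard_low_correlation(f, self.target, self.names, k=2)
        assert retained == ("a", "c")

    def test_perfect_correlate_ranks_first(self):
        f = self._features()
        pri = prep.rank_priority_inputs(f, self.target, self.names, n_priority=3)
        assert pri[0] == "a"

    def test_all_identical_features_tie_break_by_listed_order(self):
        f = pd.DataFrame({"record_id": range(1, 9), **{v: [1] * 8 for v in self.names}})
        pri = prep.rank_priority_inputs(f, self.target, self.names, n_priority=3)
        assert pri == ("a", "b", "c")

    def test_priorities_are_subset_of_retained(self, mesocosm_features, default_config):
        names = default_config.mesocosm.response_names
        for target_col in ("nutrient_level", "sediment_level"):
            target = mesocosm_features[target_col].to_numpy()
            retained = prep.discard_low_correlation(mesocosm_features, target, names, k=2)
            assert len(retained) == 9
            pri = prep.rank_priority_inputs(mesocosm_features, target, retained)
            assert set(pri) <= set(retained) and len(pri) == 3

    def test_pure_noise_variables_are_discarded(self):
        """Monte Carlo: with nine signal variables (x2.0 effect) and two pure
        noise variables, the screen drops both noise variables nearly always
        (oracle run: 100% of 200 seeds; assert >= 95%)."""
        base = MesocosmConfig.default()
        eff = {v: 2.0 for v in base.response_names}
        eff["Nousia"] = 1.0
        eff["Tanypodinae"] = 1.0
        cfg = dataclasses.replace(base, nutrient_effect=eff)
        hits = 0
        n = 100
        for seed in range(n):
            m = synthdata.generate_mesocosm(dataclasses.replace(cfg, seed=seed))
            f = prep.standardize(m, prep.mesocosm_control_ids(m), base.response_names)
            retained = prep.discard_low_correlation(
                f, m["nutrient_level"].to_numpy(), base.response_names, k=2
            )
            hits += ("Nousia" not in retained) and ("Tanypodinae" not in retained)
        assert hits / n >= 0.95


class TestSplit:
    def test_default_split_is_disjoint_exhaustive_32_32(self, mesocosm_features, default_config):
        from streamdiag.pipeline import select_and_split

        for target in ("nutrient", "sediment"):
            _, _, split = select_and_split(default_config, mesocosm_features, target)
            assert len(split.train_ids) == 32 and len(split.validation_ids) == 32
            assert split.train_ids | split.validation_ids == set(
                mesocosm_features["record_id"]
            )
            assert not split.train_ids & split.validation_ids

    def test_identical_records_select_lowest_ids_with_target_balance(self):
        f = pd.DataFrame({"record_id": range(1, 17), "a": [1] * 16})
        target = np.array([1, 2] * 8)
        split = prep.make_split(f, target, ("a",))
        assert split.train_ids == set(range(1, 9))

    def test_training_set_covers_all_repeated_priority_levels(self):
        """Brute-force coverage check on random integer tables."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = 64
            f = pd.DataFrame(
                {
                    "record_id": range(1, n + 1),
                    "p": rng.integers(-2, 4, n),
                    "q": rng.integers(-2, 4, n),
                    "r": rng.integers(-2, 4, n),
                }
            )
            target = np.array([1, 2] * (n // 2))
            split = prep.make_split(f, target, ("p", "q", "r"))
            fi = f.set_index("record_id")
            for col in ("p", "q", "r"):
                counts = fi[col].value_counts()
                for level, cnt in counts.items():
                    if cnt >= 2:
                        assert any(
                            fi.at[rid, col] == level for rid in split.train_ids
                        ), f"level {level} of {col} missing from training set"

    def test_both_partitions_contain_both_levels(self, mesocosm_features, default_config):
        from streamdiag.pipeline import select_and_split

        levels = mesocosm_features.set_index("record_id")["sediment_level"]
        _, _, split = select_and_split(default_config, mesocosm_features, "sediment")
        for part in (split.train_ids, split.validation_ids):
            assert {1, 2} == set(levels.loc[sorted(part)])

    def test_odd_or_tiny_inputs_rejected(self):
        f = pd.DataFrame({"record_id": range(1, 6), "a": [1] * 5})
        with pytest.raises(DataError):
            prep.make_split(f, np.array([1, 2, 1, 2, 1]), ("a",))
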