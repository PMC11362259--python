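"""Lumping, thresholding and missingness rules."""

import numpy as np
import pandas as pd
import pytest

import gesturemorphs as gm
from gesturemorphs.preprocess import (
    DegenerateActionError,
    LumpConflictError,
    consolidate_rare_levels,
    drop_incomplete_tokens,
    filter_actions_by_count,
    lump_presplit_actions,
    select_informative_modifiers,
)
from gesturemorphs.schema import (
    MISSING,
    NOT_VALID,
    OTHER,
    UNKNOWN,
    ActionLump,
    ModifierSchema,
    TokenTable,
)


def make_table(rows, modifiers=("repetition",)):
    levels = {
        "repetition": {"Yes", "No"},
        "body_part": {"Hand", "Foot", "Head", "Face"},
    }
    schema = ModifierSchema(
        modifiers={m: frozenset(levels[m]) for m in modifiers},
        action_lump_map={
            "Hitting": ActionLump("Hit", {"repetition": "Yes"}),
            "Hit": ActionLump("Hit", {"repetition": "No"}),
        },
    )
    df = pd.DataFrame(rows)
    df["token_id"] = [f"t{i}" for i in range(len(df))]
    for col, default in [("community", "Sonso"), ("signaller_id", "s1"),
                         ("goal", "Play")]:
        if col not in df:
            df[col] = default
    return TokenTable(df=df, schema=schema, provenance=["read"])


class TestLumpPresplit:
    def test_hit_hitting_lump(self):
        rows = [{"gesture_action": "Hit", "repetition": MISSING}] * 4 + \
               [{"gesture_action": "Hitting", "repetition": MISSING}] * 6
        out = lump_presplit_actions(make_table(rows))
        assert set(out.df["gesture_action"]) == {"Hit"}
        assert (out.df["repetition"] == "No").sum() == 4
        assert (out.df["repetition"] == "Yes").sum() == 6

    def test_identity_map_leaves_table_unchanged(self):
        rows = [{"gesture_action": "Shake", "repetition": "Yes"}] * 3
        table = make_table(rows)
        out = lump_presplit_actions(table, lump_map={})
        pd.testing.assert_frame_equal(out.df, table.df)

    def test_consistent_coded_value_is_kept(self):
        rows = [{"gesture_action": "Hitting", "repetition": "Yes"}] * 2
        out = lump_presplit_actions(make_table(rows))
        assert list(out.df["repetition"]) == ["Yes", "Yes"]

    def test_conflicting_coded_value_raises(self):
        rows = [{"gesture_action": "Hitting", "repetition": "No"}]
        with pytest.raises(LumpConflictError, match="repetition"):
            lump_presplit_actions(make_table(rows))

    def test_collapsing_three_actions_reduces_count_by_two(self):
        table = make_table(
            [{"gesture_action": a, "repetition": "Yes"} for a in "ABC"],
        )
        lump = {a: ActionLump("A", {}) for a in "ABC"}
        out = lump_presplit_actions(table, lump_map=lump)
        assert out.df["gesture_action"].nunique() == 1


class TestActionFilter:
    def test_threshold_keeps_only_frequent_actions(self):
        rows = ([{"gesture_action": "A", "repetition": "Yes"}] * 12
                + [{"gesture_action": "B", "repetition": "Yes"}] * 9
                + [{"gesture_action": "C", "repetition": "Yes"}] * 10)
        out = filter_actions_by_count(make_table(rows), min_n=10)
        assert set(out.df["gesture_action"]) == {"A", "C"}
        assert "removed 1 actions" in out.provenance[-1]

    def test_all_below_threshold_yields_empty_table(self):
        out = filter_actions_by_count(
            make_table([{"gesture_action": "A", "repetition": "Yes"}] * 3),
            min_n=10,
        )
        assert len(out) == 0
        assert any("removed" in p for p in out.provenance)

    def test_61_actions_19_rare_yields_42(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(61):
            n = int(rng.integers(1, 10)) if i < 19 else int(rng.integers(10, 90))
            rows += [{"gesture_action": f"A{i:02d}", "repetition": "Yes"}] * n
        out = filter_actions_by_count(make_table(rows), min_n=10)
        assert out.df["gesture_action"].nunique() == 42


class TestConsolidateRareLevels:
    def _df(self, counts):
        rows = []
        for lv, n in counts.items():
            rows += [{"gesture_action": "A", "body_part": lv}] * n
        return make_table(rows, modifiers=("body_part",)).df

    def test_rare_levels_pool_into_other(self):
        df = consolidate_rare_levels(
            self._df({"Hand": 20, "Head": 3, "Face": 2}), "body_part")
        counts = df["body_part"].value_counts()
        assert counts["Hand"] == 20 and counts[OTHER] == 5

    def test_undersized_other_becomes_missing(self):
        df = consolidate_rare_levels(self._df({"Hand": 20, "Head": 3}), "body_part")
        counts = df["body_part"].value_counts()
        assert counts["Hand"] == 20 and counts[MISSING] == 3
        assert OTHER not in counts

    def test_unknown_always_becomes_missing(self):
        df = consolidate_rare_levels(self._df({UNKNOWN: 4, "Hand": 6}), "body_part")
        assert (df["body_part"] == MISSING).sum() == 4

    def test_not_valid_is_a_regular_level(self):
        df = consolidate_rare_levels(
            self._df({NOT_VALID: 7, "Hand": 6}), "body_part")
        assert (df["body_part"] == NOT_VALID).sum() == 7


class TestModifierSelection:
    def test_two_sufficient_levels_retained(self):
        rows = [{"gesture_action": "A", "repetition": "Yes"}] * 6 + \
               [{"gesture_action": "A", "repetition": "No"}] * 5
        df = make_table(rows).df
        assert select_informative_modifiers(df, ["repetition"]) == ["repetition"]

    def test_single_qualifying_level_dropped(self):
        rows = [{"gesture_action": "A", "repetition": "Yes"}] * 30 + \
               [{"gesture_action": "A", "repetition": MISSING}] * 4
        df = make_table(rows).df
        assert select_informative_modifiers(df, ["repetition"]) == []

    def test_action_without_variation_is_single_morph(self):
        rows = [{"gesture_action": "Somersault", "repetition": "No",
                 "body_part": "Hand"}] * 40
        df = make_table(rows, modifiers=("repetition", "body_part")).df
        assert select_informative_modifiers(df, ["repetition", "body_part"]) == []

    def test_not_valid_counts_as_level(self):
        rows = [{"gesture_action": "A", "body_part": NOT_VALID}] * 6 + \
               [{"gesture_action": "A", "body_part": "Hand"}] * 7
        df = make_table(rows, modifiers=("body_part",)).df
        assert select_informative_modifiers(df, ["body_part"]) == ["body_part"]


class TestDropIncomplete:
    def test_missing_in_retained_modifier_removed(self):
        rows = [{"gesture_action": "A", "repetition": "Yes", "body_part": "Hand"}] * 5
        rows += [{"gesture_action": "A", "repetition": "No", "body_part": "Foot"}] * 3
        rows += [{"gesture_action": "A", "repetition": MISSING, "body_part": "Foot"}] * 2
        df = make_table(rows, modifiers=("repetition", "body_part")).df
        ds = drop_incomplete_tokens(df, "A", ["repetition"])
        assert len(ds.df) == 8
        assert ds.level_counts["repetition"] == {"Yes": 5, "No": 3}

    def test_missing_only_in_nonretained_modifier_kept(self):
        rows = [{"gesture_action": "A", "repetition": "Yes", "body_part": MISSING}]
        df = make_table(rows, modifiers=("repetition", "body_part")).df
        ds = drop_incomplete_tokens(df, "A", ["repetition"])
        assert len(ds.df) == 1

    def test_all_removed_is_degenerate(self):
        rows = [{"gesture_action": "A", "repetition": MISSING}] * 3
        df = make_table(rows).df
        with pytest.raises(DegenerateActionError):
            drop_incomplete_tokens(df, "A", ["repetition"])


class TestOneHot:
    def _dataset(self, rows, modifiers):
        df = make_table(rows, modifiers=modifiers).df
        return drop_incomplete_tokens(df, "A", list(modifiers))

    def test_block_structure_rows_sum_to_n_modifiers(self):
        rows = [
            {"gesture_action": "A", "repetition": "Yes", "body_part": "Hand"},
            {"gesture_action": "A", "repetition": "No", "body_part": "Foot"},
            {"gesture_action": "A", "repetition": "Yes", "body_part": "Foot"},
        ]
        X, labels = self._dataset(rows, ("repetition", "body_part")).one_hot()
        assert X.shape == (3, 4)
        assert (X.sum(axis=1) == 2).all()
        assert set(m for m, _ in labels) == {"repetition", "body_part"}

    def test_not_valid_gets_own_indicator(self):
        rows = [{"gesture_action": "A", "body_part": NOT_VALID}] * 2 + \
               [{"gesture_action": "A", "body_part": "Hand"}] * 2
        X, labels = self._dataset(rows, ("body_part",)).one_hot()
        assert ("body_part", NOT_VALID) in labels

    def test_single_modifier_rows_sum_to_one(self):
        rows = [{"gesture_action": "A", "body_part": bp}
                for bp in ["Hand", "Foot", "Head"]]
        X, labels = self._dataset(rows, ("body_part",)).one_hot()
        assert X.shape == (3, 3) and (X.sum(axis=1) == 1).all()

    def test_zero_retained_modifiers_is_error(self):
        rows = [{"gesture_action": "A", "body_part": "Hand"}] * 3
        df = make_table(rows, modifiers=("body_part",)).df
        ds = drop_incomplete_tokens(df, "A", [])
        with pytest.raises(ValueError, match="single-morph"):
            ds.one_hot()


class TestPipelineInvariants:
    def test_provenance_order_and_monotone_counts(self):
        table, _ = __import__("tests.conftest", fromlist=["planted_table"]) \
            .planted_table(k=2, n=60, seed=3, missing_rate=0.05)
        datasets, processed = gm.preprocess(table)
        assert processed.provenance[0] == "synthetic"
        assert any(p.startswith("lump_presplit") for p in processed.provenance)
        assert any(p.startswith("filter_actions") for p in processed.provenance)
        n_after = sum(len(d.df) for d in datasets.values())
        assert n_after <= len(table)

    def test_every_retained_level_has_min_support(self):
        table, _ = __import__("tests.conftest", fromlist=["planted_table"]) \
            .planted_table(k=3, n=200, seed=1, missing_rate=0.05)
        datasets, _ = gm.preprocess(table, min_level_n=5)
        for ds in datasets.values():
            for mod in ds.retained_modifiers:
                for lv, n in ds.level_counts[mod].items():
                    assert lv != MISSING
                    assert n >= 5 or lv == OTHER
                    if lv == OTHER:
                        assert n >= 5
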