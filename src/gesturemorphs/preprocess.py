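"""Lumping, thresholding and missingness rules producing analysis-ready
per-action datasets.

The pipeline order is fixed:

1. lump actions that were pre-split on modifiers of interest back together
   (inducing the modifier value the split encoded);
2. drop gesture actions with fewer than ``min_action_n`` (default 10) tokens;
3. within each action, recode unknown modifier values to missing and pool
   levels occurring fewer than ``min_level_n`` (default 5) times into an
   "other" category (itself set to missing if it stays below the threshold);
4. retain only modifiers with at least two levels each occurring at least
   ``min_level_n`` times (not-valid counts as a level, missing never does);
5. drop tokens with a missing value in a retained modifier.

Every step appends to the table's provenance log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import MISSING, OTHER, UNKNOWN, TokenTable


class LumpConflictError(ValueError):
    """An induced modifier value contradicts an explicitly coded one."""


class DegenerateActionError(ValueError):
    """Preprocessing removed every token of an action."""


@dataclass
class ActionDataset:
    """Analysis-ready tokens of one gesture action.

    Attributes
    ----------
    action : str
    df : DataFrame
        Tokens (rows) with modifier, goal, community columns.
    retained_modifiers : list of str
        Modifiers with sufficient variation for this action (possibly empty:
        a single-morph action, e.g. one that can only be done one way).
    level_counts : dict
        Per retained modifier, level -> count.
    combinations : list of tuple
        Per token, its level combination over retained modifiers.
    n_combinations : int
        Number of distinct observed combinations (>= 1).
    """

    action: str
    df: pd.DataFrame
    retained_modifiers: list[str]
    level_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            raise DegenerateActionError(self.action)

    @property
    def combinations(self) -> list[tuple[str, ...]]:
        if not self.retained_modifiers:
            return [() for _ in range(len(self.df))]
        return list(map(tuple, self.df[self.retained_modifiers].to_numpy()))

    @property
    def n_combinations(self) -> int:
        return max(1, len(set(self.combinations)))

    def one_hot(self) -> tuple[np.ndarray, list[tuple[str, str]]]:
        """One-hot encode retained modifier levels.

        Returns the binary matrix (tokens x indicator columns) and the
        (modifier, level) label of each column. Every level present after
        consolidation — including the pooled "other" and "not valid" —
        gets its own indicator; each row has exactly one 1 per modifier
        block.

        Raises
        ------
        ValueError
            If no modifier was retained (callers must treat the action as
            a single morph without running any clustering).
        """
        if not self.retained_modifiers:
            raise ValueError(
                f"action {self.action!r} has no retained modifiers; "
                "single-morph action, no encoding possible"
            )
        blocks = []
        labels: list[tuple[str, str]] = []
        for mod in self.retained_modifiers:
            col = self.df[mod]
            levels = sorted(col.unique())
            for lv in levels:
                blocks.append((col == lv).to_numpy(dtype=np.int8))
                labels.append((mod, lv))
        X = np.column_stack(blocks)
        return X, labels


def lump_presplit_actions(table: TokenTable,
                          lump_map: dict | None = None) -> TokenTable:
    """Merge actions pre-split on a modifier of interest.

    E.g. raw actions "Hit"/"Hitting" both become "Hit" with repetition
    no/yes. The induced value overwrites only a missing/unknown or
    consistent coded value; a contradictory explicit value raises
    :class:`LumpConflictError` listing the offending tokens.
    """
    if lump_map is None:
        lump_map = table.schema.action_lump_map
    if not lump_map:
        return table.derive(table.df, "lump_presplit: identity")
    df = table.df.copy()
    original_action = df["gesture_action"].copy()
    conflicts: list[str] = []
    n_renamed = 0
    for raw, lump in lump_map.items():
        mask = original_action == raw
        if not mask.any():
            continue
        for mod, value in lump.induced.items():
            current = df.loc[mask, mod]
            bad = current[~current.isin([value, MISSING, UNKNOWN])]
            if len(bad):
                conflicts.extend(
                    f"{tid}: {mod}={v!r} vs induced {value!r}"
                    for tid, v in zip(df.loc[bad.index, "token_id"], bad)
                )
                continue
            df.loc[mask, mod] = value
        if raw != lump.lumped_action:
            n_renamed += int(mask.sum())
        df.loc[mask, "gesture_action"] = lump.lumped_action
    if conflicts:
        raise LumpConflictError(
            "induced modifier values conflict with coded values: "
            + "; ".join(conflicts[:10])
        )
    return table.derive(df, f"lump_presplit: {n_renamed} tokens renamed")


def filter_actions_by_count(table: TokenTable, min_n: int = 10) -> TokenTable:
    """Drop gesture actions with fewer than ``min_n`` tokens."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    counts = table.df["gesture_action"].value_counts()
    keep = counts[counts >= min_n].index
    removed = sorted(set(counts.index) - set(keep))
    df = table.df[table.df["gesture_action"].isin(keep)]
    return table.derive(
        df,
        f"filter_actions(min_n={min_n}): removed {len(removed)} actions "
        f"({', '.join(removed) if removed else 'none'})",
    )


def consolidate_rare_levels(action_df: pd.DataFrame, modifier: str,
                            min_n: int = 5) -> pd.DataFrame:
    """Within one action, recode rare levels of one modifier.

    Unknown always becomes missing. Levels with fewer than ``min_n``
    occurrences are pooled into the "other" category; if the pooled
    category itself stays below ``min_n``, those cases become missing.
    The not-valid code is treated as a regular level throughout.
    """
    df = action_df.copy()
    col = df[modifier].replace({UNKNOWN: MISSING})
    counts = col[col != MISSING].value_counts()
    rare = counts[counts < min_n].index
    if len(rare):
        col = col.replace({lv: OTHER for lv in rare})
        if (col == OTHER).sum() < min_n:
            col = col.replace({OTHER: MISSING})
    df[modifier] = col
    return df


def select_informative_modifiers(action_df: pd.DataFrame,
                                 modifiers: list[str],
                                 min_n: int = 5) -> list[str]:
    """Modifiers with at least two levels occurring at least ``min_n`` times.

    Missing never counts as a level; not-valid does. An action with no
    variation in any modifier yields an empty list — a single-morph action
    (some actions can only be performed one way).
    """
    retained = []
    for mod in modifiers:
        col = action_df[mod]
        counts = col[col != MISSING].value_counts()
        if (counts >= min_n).sum() >= 2:
            retained.append(mod)
    return retained


def drop_incomplete_tokens(action_df: pd.DataFrame, action: str,
                           retained_modifiers: list[str]) -> ActionDataset:
    """Drop tokens missing a value in any retained modifier.

    Raises
    ------
    DegenerateActionError
        If every token is removed (the action reverts to excluded).
    """
    df = action_df
    if retained_modifiers:
        mask = np.ones(len(df), dtype=bool)
        for mod in retained_modifiers:
            mask &= (df[mod] != MISSING).to_numpy()
        df = df[mask]
    if len(df) == 0:
        raise DegenerateActionError(
            f"action {action!r}: all tokens removed by missingness filter"
        )
    level_counts = {
        mod: df[mod].value_counts().to_dict() for mod in retained_modifiers
    }
    return ActionDataset(
        action=action,
        df=df.reset_index(drop=True),
        retained_modifiers=retained_modifiers,
        level_counts=level_counts,
    )


def preprocess(table: TokenTable, min_action_n: int = 10,
               min_level_n: int = 5) -> tuple[dict[str, ActionDataset], TokenTable]:
    """Run the full preprocessing pipeline.

    Returns the per-action datasets (sorted by action name) and the
    intermediate filtered token table (with provenance). Actions whose
    tokens are all removed by the missingness filter are logged and
    skipped; they are not re-filtered against ``min_action_n`` after case
    removal.
    """
    table = lump_presplit_actions(table)
    table = filter_actions_by_count(table, min_n=min_action_n)
    datasets: dict[str, ActionDataset] = {}
    modifiers = table.schema.modifier_names
    for action in sorted(table.df["gesture_action"].unique()):
        adf = table.df[table.df["gesture_action"] == action]
        for mod in modifiers:
            adf = consolidate_rare_levels(adf, mod, min_n=min_level_n)
        retained = select_informative_modifiers(adf, modifiers, min_n=min_level_n)
        try:
            datasets[action] = drop_incomplete_tokens(adf, action, retained)
        except DegenerateActionError:
            table.log(f"preprocess: action {action!r} degenerate, excluded")
    table.log(
        f"preprocess: {len(datasets)} actions ready "
        f"(min_action_n={min_action_n}, min_level_n={min_level_n})"
    )
    return datasets, table
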