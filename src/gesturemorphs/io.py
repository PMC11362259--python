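"""Reading and writing gesture-token tables and morph-rule tables.

Token tables are delimited text (comma or tab, sniffed from the header)
with columns ``token_id, community, signaller_id, gesture_action,
<one per modifier>, goal``. Morph-rule tables have columns
``morph_name, count, <one per modifier>`` plus optional ``unexplained``,
``prediction_accuracy`` and ``note`` columns; modifier cells hold a level,
a ``|``-separated disjunction of levels, ``NV`` (the not-valid code), or
blank (unconstrained).
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .rules import Morph, MorphRuleset, RuleAlternative, RulesetError
from .schema import (
    MISSING,
    NOT_VALID,
    ModifierSchema,
    SchemaError,
    TokenTable,
    ValidationError,
)

REQUIRED_COLUMNS = ("token_id", "community", "signaller_id", "gesture_action", "goal")


def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return ","


def read_tokens(path, schema: ModifierSchema) -> TokenTable:
    """Read a gesture-token table, validating against the schema.

    Empty cells and the schema's configured spellings for unknown /
    not-valid map onto the reserved codes. Raises :class:`SchemaError` for
    missing columns and :class:`ValidationError` (listing offending rows)
    for undeclared levels.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, comment="#")
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    missing_cols += [m for m in schema.modifier_names if m not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {missing_cols}")

    bad: list[str] = []
    for mod in schema.modifier_names:
        vals = []
        for i, raw in enumerate(df[mod]):
            try:
                vals.append(schema.canonical_level(mod, raw))
            except ValidationError:
                bad.append(f"row {i}: {mod}={raw!r}")
                vals.append(raw)
        df[mod] = vals
    if bad:
        raise ValidationError(
            "cells outside schema: " + "; ".join(bad[:20])
            + ("" if len(bad) <= 20 else f" (+{len(bad) - 20} more)")
        )

    goal = [
        schema.canonical_code(g) or g.strip() for g in df["goal"]
    ]
    df["goal"] = goal
    if schema.goals:
        unknown_goals = sorted(
            {g for g in goal if g not in schema.goals and g not in (MISSING,)
             and schema.canonical_code(g) is None}
        )
        # canonical_code already applied; remaining strings must be declared
        unknown_goals = [g for g in unknown_goals if not g.startswith("<")]
        if unknown_goals:
            raise ValidationError(f"goals outside schema: {unknown_goals}")
    if schema.communities:
        bad_comm = sorted(set(df["community"]) - set(schema.communities))
        if bad_comm:
            raise ValidationError(f"communities outside schema: {bad_comm}")
    table = TokenTable(df=df, schema=schema, provenance=["read"])
    return table


def write_tokens(table: TokenTable, path, unknown_spelling: str = "unknown",
                 not_valid_spelling: str = "not_valid") -> None:
    """Write a token table as CSV, spelling reserved codes back out."""
    df = table.df.copy()
    mapping = {
        "<unknown>": unknown_spelling,
        "<not_valid>": not_valid_spelling,
        "<missing>": "",
        "<other>": "other",
    }
    for mod in table.schema.modifier_names:
        df[mod] = df[mod].map(lambda v: mapping.get(v, v))
    df["goal"] = df["goal"].map(lambda v: mapping.get(v, v))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# morph rule tables
# ---------------------------------------------------------------------------

_MORPH_NAME_RE = re.compile(r"^(?P<action>.+)\.(?P<index>\d+)$")


def _cell_to_levels(cell: str, modifier: str, schema: ModifierSchema) -> frozenset[str]:
    parts = [p.strip() for p in cell.split("|")]
    out = []
    for p in parts:
        code = schema.canonical_code(p)
        if code == NOT_VALID:
            out.append(NOT_VALID)
        elif code is not None:
            out.append(code)
        else:
            out.append(schema.canonical_level(modifier, p))
    return frozenset(out)


def parse_rule_table(path, schema: ModifierSchema) -> list[MorphRuleset]:
    """Parse a morph-rule table into per-action rulesets.

    Each row is one morph: named level cells are equality constraints,
    ``|``-separated cells membership constraints, ``NV`` the not-valid
    level, blanks unconstrained. A truthy ``unexplained`` column marks
    morphs without a defining rule ("all other cases" classes).

    Raises :class:`RulesetError` on duplicate morph names and
    :class:`ValidationError` on undeclared levels.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, comment="#")
    for col in ("morph_name", "count"):
        if col not in df.columns:
            raise SchemaError(f"rule table missing column {col!r}")
    modifiers = [m for m in schema.modifier_names if m in df.columns]

    by_action: dict[str, list[Morph]] = {}
    seen: set[str] = set()
    last: Morph | None = None
    for _, row in df.iterrows():
        name = row["morph_name"].strip()
        unexplained = str(row.get("unexplained", "")).strip() in {"1", "true", "True", "yes"}
        constraints: dict[str, frozenset[str]] = {}
        for mod in modifiers:
            cell = str(row[mod]).strip()
            if not cell:
                continue
            constraints[mod] = _cell_to_levels(cell, mod, schema)
        # a trailing "+" marks a continuation row: a further alternative
        # of the immediately preceding morph's disjunctive predicate
        if (name.endswith("+") and last is not None
                and name.rstrip("+") == last.name):
            last.alternatives.append(RuleAlternative(constraints))
            continue
        if name in seen:
            raise RulesetError(f"duplicate morph name {name!r}")
        seen.add(name)
        m = _MORPH_NAME_RE.match(name)
        action = m.group("action") if m else name
        morph = Morph(
            name=name,
            action=action,
            support=int(row["count"]),
            alternatives=[] if unexplained else [RuleAlternative(constraints)],
            explained=not unexplained,
            accuracy=(float(row["prediction_accuracy"])
                      if str(row.get("prediction_accuracy", "")).strip() else None),
            note=str(row.get("note", "")).strip(),
        )
        by_action.setdefault(action, []).append(morph)
        last = morph
    return [MorphRuleset(action=a, morphs=ms) for a, ms in by_action.items()]


def write_morph_table(rulesets: list[MorphRuleset], path,
                      schema: ModifierSchema) -> None:
    """Write rulesets in the row-per-morph layout parse_rule_table reads.

    Disjunctive predicates with several alternatives are expanded to the
    per-modifier union of their levels only when the alternatives differ on
    a single modifier (which rule minimisation guarantees); predicates that
    cannot be represented in one row are written as one row per alternative
    sharing the morph name suffix ``+``.
    """
    spell = {NOT_VALID: "NV"}
    rows = []
    for rs in sorted(rulesets, key=lambda r: r.action):
        for morph in rs.morphs:
            base = {
                "morph_name": morph.name,
                "count": morph.support,
                **{m: "" for m in schema.modifier_names},
                "unexplained": "" if morph.explained else "1",
                "prediction_accuracy": ""
                if morph.accuracy is None else repr(morph.accuracy),
                "note": morph.note,
            }
            if not morph.explained or not morph.alternatives:
                rows.append(base)
                continue
            if len(morph.alternatives) == 1:
                alt_rows = [morph.alternatives[0]]
            else:
                merged = _try_single_row(morph.alternatives)
                alt_rows = [merged] if merged is not None else morph.alternatives
            for i, alt in enumerate(alt_rows):
                row = dict(base)
                if i > 0:
                    row["morph_name"] = f"{morph.name}+"
                for mod, levels in alt.constraints.items():
                    row[mod] = "|".join(
                        sorted(spell.get(lv, lv) for lv in levels)
                    )
                rows.append(row)
    cols = ["morph_name", "count", *schema.modifier_names,
            "unexplained", "prediction_accuracy", "note"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def _try_single_row(alternatives: list[RuleAlternative]) -> RuleAlternative | None:
    """Merge alternatives differing on one modifier into a single row."""
    keys = {frozenset(a.constraints) for a in alternatives}
    if len(keys) != 1:
        return None
    mods = sorted(next(iter(keys)))
    diff = [m for m in mods
            if len({a.constraints[m] for a in alternatives}) > 1]
    if len(diff) != 1:
        return None
    m = diff[0]
    union = frozenset().union(*(a.constraints[m] for a in alternatives))
    merged = dict(alternatives[0].constraints)
    merged[m] = union
    return RuleAlternative(merged)


def read_rule_table_df(path) -> pd.DataFrame:
    """Raw rule-table rows as strings (for audit / fixtures)."""
    sep = _sniff_sep(path)
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, comment="#")


def default_table_path(name: str) -> Path:
    """Path of a data file shipped with the package."""
    return Path(__file__).parent / "data" / name
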