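"""Modifier schemas, reserved codes, and the gesture-token table container.

A gesture token is one observed instance of gesture use: a gesture action
(the defining bodily movement, e.g. "ObjectShake"), a set of categorical
modifiers describing how it was produced (body part, contact point,
rhythmic repetition, laterality), the apparent goal of the signaller, and
the community the signaller belongs to.

Modifier cells may hold, besides a regular level, one of four reserved
codes:

* ``UNKNOWN`` — the coder could not establish the level (treated as missing
  during analysis);
* ``NOT_VALID`` — the modifier does not apply given another modifier's
  value (e.g. laterality for head gestures); modelled as a level of its own;
* ``MISSING`` — no value; never modelled;
* ``OTHER`` — the pooled category rare levels are lumped into.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import yaml

# Canonical internal spellings of the reserved codes.  Angle brackets keep
# them disjoint from any plausible field-coded level name.
UNKNOWN = "<unknown>"
NOT_VALID = "<not_valid>"
MISSING = "<missing>"
OTHER = "<other>"
RESERVED_CODES = frozenset({UNKNOWN, NOT_VALID, MISSING, OTHER})

#: Label used for tokens no morph rule covers.
UNASSIGNED = "<unassigned>"

#: Goal label for cases where no apparently satisfactory outcome was coded.
UNKNOWN_GOAL = UNKNOWN


class SchemaError(ValueError):
    """A table does not conform to the declared modifier schema."""


class ValidationError(ValueError):
    """Cell values outside the schema's level sets / reserved codes."""


@dataclass(frozen=True)
class ActionLump:
    """Lumping rule for an action pre-split on a modifier of interest.

    e.g. raw action ``Hitting`` -> lumped action ``Hit`` with induced
    modifier value ``repetition=yes``.
    """

    lumped_action: str
    induced: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ModifierSchema:
    """Declared modifiers, their level sets, and code spellings.

    Parameters
    ----------
    modifiers
        Ordered mapping modifier name -> frozenset of regular levels.
    unknown_codes, not_valid_codes, missing_codes, other_codes
        Raw spellings (lower-cased for matching) mapped to each reserved
        code when reading tables.
    level_lump_map
        Per modifier, raw level -> analysis level (e.g. the laterality
        levels ``left``/``right`` both lumped to ``unimanual``).
    action_lump_map
        Raw action name -> :class:`ActionLump`.
    goals, communities
        Closed label sets; empty set = open (accept anything).
    """

    modifiers: dict[str, frozenset[str]]
    unknown_codes: frozenset[str] = frozenset({"unknown"})
    not_valid_codes: frozenset[str] = frozenset({"not_valid", "not valid", "nv"})
    missing_codes: frozenset[str] = frozenset({"", "na", "nan"})
    other_codes: frozenset[str] = frozenset({"other"})
    level_lump_map: dict[str, dict[str, str]] = field(default_factory=dict)
    action_lump_map: dict[str, ActionLump] = field(default_factory=dict)
    goals: frozenset[str] = frozenset()
    communities: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name, levels in self.modifiers.items():
            clash = set(levels) & RESERVED_CODES
            if clash:
                raise SchemaError(
                    f"modifier {name!r}: levels {sorted(clash)} collide with reserved codes"
                )
        for mod, lump in self.level_lump_map.items():
            if mod not in self.modifiers:
                raise SchemaError(f"level_lump_map names unknown modifier {mod!r}")
            missing = set(lump.values()) - self.modifiers[mod]
            if missing:
                raise SchemaError(
                    f"level_lump_map for {mod!r} targets undeclared levels {sorted(missing)}"
                )

    @property
    def modifier_names(self) -> list[str]:
        return list(self.modifiers)

    def canonical_code(self, raw: str) -> str | None:
        """Map a raw cell spelling to a reserved code, or None."""
        low = raw.strip().lower()
        if low in self.unknown_codes:
            return UNKNOWN
        if low in self.not_valid_codes:
            return NOT_VALID
        if low in self.missing_codes:
            return MISSING
        if low in self.other_codes:
            return OTHER
        return None

    def canonical_level(self, modifier: str, raw: str) -> str:
        """Resolve a raw cell to a declared level or a reserved code.

        Declared levels take precedence over reserved-code spellings (so a
        coded body-part level "Other" is not swallowed by the pooled-other
        code); matching is case-insensitive and lump maps apply first.

        Raises
        ------
        ValidationError
            If the cell is neither a declared level nor a reserved code.
        """
        val = raw.strip()
        if val in RESERVED_CODES:
            return val
        lump = self.level_lump_map.get(modifier, {})
        val = lump.get(val, lump.get(val.lower(), val))
        levels = self.modifiers[modifier]
        if val in levels:
            return val
        folded = {lv.lower(): lv for lv in levels}
        if val.lower() in folded:
            return folded[val.lower()]
        code = self.canonical_code(raw)
        if code is not None:
            return code
        raise ValidationError(
            f"level {raw!r} not declared for modifier {modifier!r}"
        )

    def with_modifier(self, name: str, levels: set[str]) -> "ModifierSchema":
        mods = dict(self.modifiers)
        mods[name] = frozenset(levels)
        return replace(self, modifiers=mods)


@dataclass(frozen=True)
class GestureToken:
    """One observed gesture: action, modifier values, goal, community."""

    token_id: str
    community: str
    signaller_id: str
    action: str
    modifiers: dict[str, str]
    goal: str

    @property
    def is_play(self) -> bool:
        return self.goal.lower() == "play"


@dataclass
class TokenTable:
    """A table of gesture tokens plus its schema and processing log.

    Internally the tokens live in a pandas DataFrame (one row per token,
    one column per modifier); ``tokens`` materialises GestureToken objects
    on demand.
    """

    df: "pandas.DataFrame"  # noqa: F821 - forward ref for typing only
    schema: ModifierSchema
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = self.df["token_id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise ValidationError(f"duplicate token_ids: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def tokens(self) -> list[GestureToken]:
        mods = self.schema.modifier_names
        out = []
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            out.append(
                GestureToken(
                    token_id=str(d["token_id"]),
                    community=str(d["community"]),
                    signaller_id=str(d["signaller_id"]),
                    action=str(d["gesture_action"]),
                    modifiers={m: str(d[m]) for m in mods},
                    goal=str(d["goal"]),
                )
            )
        return out

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def derive(self, df, message: str) -> "TokenTable":
        """New table with the same schema and an extended provenance."""
        return TokenTable(
            df=df.reset_index(drop=True),
            schema=self.schema,
            provenance=[*self.provenance, message],
        )

    def action_counts(self) -> dict[str, int]:
        return self.df["gesture_action"].value_counts().to_dict()


def default_chimp_schema() -> ModifierSchema:
    """Schema for the four standard chimpanzee gesture modifiers.

    Body part (signaller), body part (contact), rhythmic repetition, and
    laterality, with left/right-handed gestures lumped as unimanual.
    """
    return ModifierSchema(
        modifiers={
            "body_part_signaller": frozenset(
                {"Arm", "Back", "Body", "Bottom", "Face", "Fingers",
                 "Foot", "Hand", "Head", "Leg", "Other"}
            ),
            "body_part_contact": frozenset(
                {"Arm", "Back", "Body", "Bottom", "Face", "Genitals",
                 "Hand", "Head", "Leg", "None", "Other"}
            ),
            "repetition": frozenset({"Yes", "No"}),
            "laterality": frozenset({"Unimanual", "Both", "Alternating"}),
        },
        level_lump_map={
            "laterality": {"left": "Unimanual", "right": "Unimanual",
                           "Left": "Unimanual", "Right": "Unimanual"},
        },
        action_lump_map={
            "Hitting": ActionLump("Hit", {"repetition": "Yes"}),
            "Hit": ActionLump("Hit", {"repetition": "No"}),
        },
    )


def schema_from_yaml(path_or_stream) -> ModifierSchema:
    """Load a :class:`ModifierSchema` from a YAML config.

    Expected keys: ``modifiers`` (name -> list of levels); optional
    ``codes`` (unknown/not_valid/missing/other -> list of spellings),
    ``level_lumps`` (modifier -> {raw: level}), ``action_lumps``
    (raw action -> {action: ..., induced: {...}}), ``goals``,
    ``communities``.
    """
    if hasattr(path_or_stream, "read"):
        cfg = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    codes = cfg.get("codes", {})
    kwargs = {}
    for key, attr in [("unknown", "unknown_codes"), ("not_valid", "not_valid_codes"),
                      ("missing", "missing_codes"), ("other", "other_codes")]:
        if key in codes:
            kwargs[attr] = frozenset(str(c).lower() for c in codes[key])
    lumps = {}
    for raw, spec_ in cfg.get("action_lumps", {}).items():
        lumps[raw] = ActionLump(spec_["action"], dict(spec_.get("induced", {})))
    return ModifierSchema(
        modifiers={m: frozenset(lv) for m, lv in cfg["modifiers"].items()},
        level_lump_map={m: dict(d) for m, d in cfg.get("level_lumps", {}).items()},
        action_lump_map=lumps,
        goals=frozenset(cfg.get("goals", [])),
        communities=frozenset(cfg.get("communities", [])),
        **kwargs,
    )


def schema_to_yaml(schema: ModifierSchema) -> str:
    cfg = {
        "modifiers": {m: sorted(lv) for m, lv in schema.modifiers.items()},
        "codes": {
            "unknown": sorted(schema.unknown_codes),
            "not_valid": sorted(schema.not_valid_codes),
            "missing": sorted(schema.missing_codes),
            "other": sorted(schema.other_codes),
        },
        "level_lumps": {m: dict(d) for m, d in schema.level_lump_map.items()},
        "action_lumps": {
            raw: {"action": al.lumped_action, "induced": dict(al.induced)}
            for raw, al in schema.action_lump_map.items()
        },
        "goals": sorted(schema.goals),
        "communities": sorted(schema.communities),
    }
    buf = io.StringIO()
    yaml.safe_dump(cfg, buf, sort_keys=False)
    return buf.getvalue()
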