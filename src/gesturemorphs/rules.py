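"""Morph rulesets: turning accepted class solutions into assignment rules.

A *morph* is a sub-type of a gesture action defined by a combination of
modifier levels. An accepted latent-class solution for an action is
converted into a ruleset: for every class we look for modifier-level
combinations with probability 1 (the combination occurs in every case of
the class) and specificity 1 (it occurs in no other class). A single such
combination gives a simple rule; several jointly exhaustive ones give a
disjunctive rule; anything else leaves the morph "unexplained". Rules are
then minimised by dropping modifiers that do not discriminate the morph
from any other, giving the sparse rule tables field researchers publish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .schema import UNASSIGNED

Combination = tuple[str, ...]  # level per retained modifier, fixed order


@dataclass(frozen=True)
class RuleAlternative:
    """One conjunction of modifier constraints.

    ``constraints`` maps modifier name -> frozenset of admissible levels;
    a modifier absent from the map is unconstrained.
    """

    constraints: dict[str, frozenset[str]]

    def matches(self, modifiers: dict[str, str]) -> bool:
        return all(
            modifiers.get(mod) in levels for mod, levels in self.constraints.items()
        )

    def __hash__(self) -> int:
        return hash(frozenset((m, lv) for m, lv in self.constraints.items()))


@dataclass
class Morph:
    """A named morph with its defining predicate.

    The predicate is a list of alternatives (logical OR of conjunctions).
    Unexplained morphs have no usable predicate: they exist in the
    repertoire (and in entropy analyses) but capture no new tokens.
    """

    name: str
    action: str
    support: int
    alternatives: list[RuleAlternative] = field(default_factory=list)
    explained: bool = True
    combinations: list[dict[str, str]] = field(default_factory=list)
    accuracy: float | None = None
    note: str = ""

    def matches(self, modifiers: dict[str, str]) -> bool:
        if not self.explained:
            return False
        return any(alt.matches(modifiers) for alt in self.alternatives)

    def referenced_modifiers(self) -> set[str]:
        out: set[str] = set()
        for alt in self.alternatives:
            out.update(alt.constraints)
        return out


class RulesetError(ValueError):
    pass


@dataclass
class MorphRuleset:
    """All morphs of one gesture action, ordered by descending support."""

    action: str
    morphs: list[Morph] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for m in self.morphs:
            if m.name in seen:
                raise RulesetError(f"duplicate morph name {m.name!r}")
            seen.add(m.name)

    def __len__(self) -> int:
        return len(self.morphs)

    @property
    def explained(self) -> list[Morph]:
        return [m for m in self.morphs if m.explained]

    def referenced_modifiers(self) -> set[str]:
        out: set[str] = set()
        for m in self.explained:
            out.update(m.referenced_modifiers())
        return out


def assign_morph(ruleset: MorphRuleset, modifiers: dict[str, str],
                 action: str | None = None) -> str:
    """Assign a token's modifier values to the unique matching morph.

    Returns the morph name, or :data:`UNASSIGNED` when no explained morph
    matches (rare level, or a combination only an unexplained morph
    covers).

    Raises
    ------
    RulesetError
        If the token's action disagrees with the ruleset, or if two
        explained predicates both match (the ruleset invariant of mutual
        exclusivity over observed combinations is broken).
    """
    if action is not None and action != ruleset.action:
        raise RulesetError(
            f"token action {action!r} does not match ruleset for {ruleset.action!r}"
        )
    hits = [m.name for m in ruleset.morphs if m.matches(modifiers)]
    if len(hits) > 1:
        raise RulesetError(
            f"token matches multiple explained morphs {hits} in {ruleset.action!r}"
        )
    return hits[0] if hits else UNASSIGNED


# ---------------------------------------------------------------------------
# probability / specificity of combinations, rule extraction
# ---------------------------------------------------------------------------

def combination_support(assignments, combos: list[Combination]) -> pd.DataFrame:
    """Probability and specificity of each combination in each class.

    probability = share of the class's tokens carrying the combination;
    specificity = share of the combination's tokens falling in the class.

    Parameters
    ----------
    assignments
        Sequence of class indices, one per token.
    combos
        The token's modifier-level combination, aligned with assignments.

    Returns
    -------
    DataFrame with columns combination, class, n, probability, specificity.
    """
    df = pd.DataFrame({"combination": combos, "cls": list(assignments)})
    tab = df.groupby(["combination", "cls"], sort=True).size().rename("n").reset_index()
    class_n = df.groupby("cls").size()
    combo_n = df.groupby("combination").size()
    tab["probability"] = tab.apply(lambda r: r["n"] / class_n[r["cls"]], axis=1)
    tab["specificity"] = tab.apply(lambda r: r["n"] / combo_n[r["combination"]], axis=1)
    return tab.rename(columns={"cls": "class"})


def _combo_dict(combo: Combination, modifiers: list[str]) -> dict[str, str]:
    return dict(zip(modifiers, combo))


def _minimise(alternatives: list[dict[str, frozenset[str]]],
              own_combos: set[Combination],
              other_combos: set[Combination],
              modifiers: list[str]) -> list[RuleAlternative]:
    """Greedily drop modifiers whose value never discriminates this morph.

    A modifier is dropped from the whole rule only if, after projection,
    no observed combination of any *other* morph satisfies the relaxed
    predicate. The induced partition of observed tokens is thereby
    unchanged.
    """
    kept = list(modifiers)
    for mod in modifiers:
        trial = [m for m in kept if m != mod]
        relaxed = [
            {m: lv for m, lv in alt.items() if m in trial} for alt in alternatives
        ]
        leak = False
        for combo in other_combos:
            cd = _combo_dict(combo, modifiers)
            if any(all(cd[m] in lv for m, lv in alt.items()) for alt in relaxed):
                leak = True
                break
        if not leak:
            kept = trial
            alternatives = relaxed
    # merge alternatives that became identical, then merge single-modifier
    # differences into level disjunctions where possible
    uniq: list[dict[str, frozenset[str]]] = []
    for alt in alternatives:
        if alt not in uniq:
            uniq.append(alt)
    merged = _merge_disjunctions(uniq)
    return [RuleAlternative(alt) for alt in merged]


def _merge_disjunctions(alts: list[dict[str, frozenset[str]]]):
    """Merge alternatives differing on exactly one modifier into one
    alternative with a level disjunction (Face|Hand|Head-style cells)."""
    changed = True
    alts = [dict(a) for a in alts]
    while changed:
        changed = False
        out: list[dict[str, frozenset[str]]] = []
        used = [False] * len(alts)
        for i, a in enumerate(alts):
            if used[i]:
                continue
            for j in range(i + 1, len(alts)):
                if used[j]:
                    continue
                b = alts[j]
                if set(a) != set(b):
                    continue
                diff = [m for m in a if a[m] != b[m]]
                if len(diff) == 1:
                    m = diff[0]
                    a = {**a, m: a[m] | b[m]}
                    used[j] = True
                    changed = True
            out.append(a)
            used[i] = True
        alts = out
    return alts


def extract_ruleset(solution, dataset) -> MorphRuleset:
    """Convert an accepted class solution into a morph ruleset.

    Per class: a single combination with probability 1 and specificity 1
    becomes the defining rule; several combinations each with specificity 1
    and jointly with probability 1 become a disjunctive rule; otherwise the
    morph is left unexplained and only its raw combination list is kept.
    Morphs are named ``action.index`` with 1-based indices in order of
    descending support.

    Parameters
    ----------
    solution : SolutionChoice
        Accepted solution from :func:`gesturemorphs.lca.select_morph_solution`.
    dataset : ActionDataset
    """
    modifiers = dataset.retained_modifiers
    combos = dataset.combinations
    assignments = solution.assignments
    support_tab = combination_support(assignments, combos)

    classes = sorted(set(assignments))
    class_sizes = pd.Series(assignments).value_counts().to_dict()
    all_class_combos: dict[int, list[Combination]] = {
        k: sorted(
            support_tab.loc[support_tab["class"] == k, "combination"].tolist()
        )
        for k in classes
    }

    records = []
    for k in classes:
        sub = support_tab[support_tab["class"] == k]
        own = set(sub["combination"])
        perfect = sub[sub["specificity"] >= 1.0]
        prob_covered = perfect["probability"].sum()
        explained = bool(len(perfect) and prob_covered >= 1.0 - 1e-12)
        records.append((k, class_sizes[k], own, set(perfect["combination"]), explained))

    # descending support for naming
    records.sort(key=lambda r: (-r[1], r[0]))
    morphs = []
    for idx, (k, size, own, perfect_combos, explained) in enumerate(records, start=1):
        name = f"{dataset.action}.{idx}"
        if explained:
            other = set()
            for k2, _, own2, _, _ in records:
                if k2 != k:
                    other |= own2
            alts = [
                {m: frozenset([lv]) for m, lv in _combo_dict(c, modifiers).items()}
                for c in sorted(perfect_combos)
            ]
            alternatives = _minimise(alts, own, other, modifiers)
            morphs.append(
                Morph(
                    name=name, action=dataset.action, support=int(size),
                    alternatives=alternatives, explained=True,
                    combinations=[_combo_dict(c, modifiers) for c in sorted(own)],
                )
            )
        else:
            morphs.append(
                Morph(
                    name=name, action=dataset.action, support=int(size),
                    alternatives=[], explained=False,
                    combinations=[_combo_dict(c, modifiers) for c in sorted(own)],
                    note="All other cases",
                )
            )
    return MorphRuleset(action=dataset.action, morphs=morphs)


# ---------------------------------------------------------------------------
# repertoire summary
# ---------------------------------------------------------------------------

def ruleset_summary(rulesets: list[MorphRuleset]) -> dict:
    """Repertoire-level summary across all actions.

    Returns a dict with:

    * ``per_action`` — DataFrame: action, n_morphs, n_modifiers_referenced
    * ``total_morphs``, ``n_actions``, ``single_morph_actions``
    * ``morphs_per_action_hist`` — {morph count: number of actions}
    * ``modifier_share`` — share of morphs whose rule references each
      modifier (of morphs in split actions)
    * ``n_unexplained`` — morphs without a defining rule
    """
    rows = []
    hist: dict[int, int] = {}
    modifier_counts: dict[str, int] = {}
    total = 0
    unexplained = 0
    for rs in sorted(rulesets, key=lambda r: r.action):
        n = len(rs)
        total += n
        hist[n] = hist.get(n, 0) + 1
        mods = rs.referenced_modifiers()
        rows.append({
            "action": rs.action,
            "n_morphs": n,
            "n_modifiers_referenced": len(mods),
            "modifiers": "|".join(sorted(mods)),
        })
        for m in rs.morphs:
            if not m.explained:
                unexplained += 1
            for mod in m.referenced_modifiers():
                modifier_counts[mod] = modifier_counts.get(mod, 0) + 1
    per_action = pd.DataFrame(
        rows, columns=["action", "n_morphs", "n_modifiers_referenced", "modifiers"]
    )
    share = {m: c / total for m, c in sorted(modifier_counts.items())} if total else {}
    return {
        "per_action": per_action,
        "total_morphs": total,
        "n_actions": len(rows),
        "single_morph_actions": hist.get(1, 0),
        "morphs_per_action_hist": dict(sorted(hist.items())),
        "modifier_share": share,
        "n_unexplained": unexplained,
    }
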