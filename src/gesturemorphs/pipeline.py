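"""End-to-end morph discovery pipeline.

Sequences preprocessing, per-action constrained LCA, rule extraction,
the uncertainty-reduction analyses, and the action-vs-morph classifier
comparison from a single config, writing byte-stable outputs and a run
manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classifier import compare_predictors
from .infovalue import morph_value_report
from .io import write_morph_table
from .lca import select_morph_solution
from .preprocess import preprocess
from .rules import (
    Morph,
    MorphRuleset,
    RuleAlternative,
    assign_morph,
    extract_ruleset,
    ruleset_summary,
)
from .schema import UNASSIGNED, UNKNOWN, TokenTable


@dataclass
class RunConfig:
    """All knobs of a pipeline run.

    Thresholds mirror the field defaults: actions need >= 10 tokens,
    modifier levels and morphs >= 5 cases; LCA uses 10 restarts per
    candidate class count; the permutation null uses 1000 shuffles; the
    classifier 10 stratified folds.
    """

    out_dir: str
    master_seed: int = 0
    min_action_n: int = 10
    min_level_n: int = 5
    min_cluster_n: int = 5
    restarts: int = 10
    max_iter: int = 1000
    tol: float = 1e-6
    prior_strength: float = 1.01
    n_perm: int = 1000
    folds: int = 10
    upsample: bool = True
    max_classes: int | None = None

    def __post_init__(self) -> None:
        for name in ("min_action_n", "min_level_n", "min_cluster_n",
                     "restarts", "n_perm", "folds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class RunResult:
    rulesets: list[MorphRuleset]
    summary: dict
    assigned: pd.DataFrame
    value_report: object
    comparison: object | None
    candidate_log: pd.DataFrame
    n_tokens_preprocessed: int
    n_tokens_assignable: int


def discover_morphs(table: TokenTable, config: RunConfig):
    """Preprocess, per-action LCA, and rule extraction.

    Returns (rulesets, datasets, candidate_log_frame). Actions with no
    retained modifier become single-morph rulesets without any model fit.
    """
    datasets, processed = preprocess(
        table, min_action_n=config.min_action_n, min_level_n=config.min_level_n,
    )
    rulesets: list[MorphRuleset] = []
    log_rows = []
    for action in sorted(datasets):
        ds = datasets[action]
        if not ds.retained_modifiers:
            # single-morph action: one unconstrained rule matching all tokens
            rulesets.append(MorphRuleset(action=action, morphs=[Morph(
                name=f"{action}.1", action=action, support=len(ds.df),
                alternatives=[RuleAlternative(constraints={})],
                explained=True, note="single-morph action",
            )]))
            continue
        sol = select_morph_solution(
            ds, restarts=config.restarts, min_cluster_n=config.min_cluster_n,
            master_seed=config.master_seed, max_iter=config.max_iter,
            tol=config.tol, prior_strength=config.prior_strength,
            max_classes=config.max_classes,
        )
        for cand in sol.candidate_log:
            log_rows.append({
                "action": action, "K": cand.K, "restart": cand.restart,
                "seed": cand.seed, "loglik": cand.loglik, "bic": cand.bic,
                "eligible": cand.eligible,
                "rejection_reasons": "|".join(cand.rejection_reasons),
                "chosen": False,
            })
        rulesets.append(extract_ruleset(sol, ds))
    log = pd.DataFrame(
        log_rows, columns=["action", "K", "restart", "seed", "loglik",
                           "bic", "eligible", "rejection_reasons", "chosen"],
    )
    for rs in rulesets:
        k = len(rs)
        sel = (log["action"] == rs.action) & (log["K"] == k)
        log.loc[sel, "chosen"] = True
    return rulesets, datasets, processed, log


def _summary_text(summary: dict) -> str:
    lines = [
        "Morph repertoire summary",
        "========================",
        f"gesture actions analysed: {summary['n_actions']}",
        f"total morphs:             {summary['total_morphs']}",
        f"single-morph actions:     {summary['single_morph_actions']}",
        f"unexplained morphs:       {summary['n_unexplained']}",
        "",
        "morphs per action (count: actions):",
    ]
    for k, v in summary["morphs_per_action_hist"].items():
        lines.append(f"  {k}: {v}")
    lines.append("")
    lines.append("share of morphs whose rule uses each modifier:")
    for mod, share in summary["modifier_share"].items():
        lines.append(f"  {mod}: {share:.3f}")
    return "\n".join(lines) + "\n"


def assign_all(rulesets: list[MorphRuleset], datasets) -> pd.DataFrame:
    """Assign every preprocessed token to a morph (or UNASSIGNED)."""
    by_action = {rs.action: rs for rs in rulesets}
    frames = []
    for action, ds in sorted(datasets.items()):
        rs = by_action.get(action)
        if rs is None:
            continue
        df = ds.df.copy()
        mods = ds.retained_modifiers
        df["morph"] = [
            assign_morph(rs, {m: row[m] for m in mods})
            for _, row in df.iterrows()
        ]
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def run_pipeline(table: TokenTable, config: RunConfig) -> RunResult:
    """Full run; writes all output files under ``config.out_dir``.

    Outputs: morph_table.csv, summary.csv + summary.json (morph-count
    histogram, modifier-usage shares), morph_value.csv, classifier
    comparison CSVs, candidate_log.csv, manifest.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if len(table) == 0:
        raise ValueError("empty input table")

    rulesets, datasets, processed, cand_log = discover_morphs(table, config)
    if not rulesets:
        raise ValueError("no actions survived preprocessing")
    assigned = assign_all(rulesets, datasets)
    summary = ruleset_summary(rulesets)

    # support = observed assignment counts for audit
    write_morph_table(rulesets, out / "morph_table.csv", table.schema)
    summary["per_action"].to_csv(out / "summary.csv", index=False)
    (out / "summary.txt").write_text(_summary_text(summary), encoding="utf-8")
    cand_log.to_csv(out / "candidate_log.csv", index=False)

    usable = assigned[assigned["morph"] != UNASSIGNED]
    value = morph_value_report(
        usable, n_perm=config.n_perm, seed=config.master_seed,
    )
    value.rows.to_csv(out / "morph_value.csv", index=False)

    comparison = None
    known = usable[usable["goal"] != UNKNOWN]
    if len(known) >= config.folds and known["goal"].nunique() >= 2:
        comparison = compare_predictors(
            known, target="goal", folds=config.folds, seed=config.master_seed,
            upsample=config.upsample,
        )
        comparison.per_class.to_csv(out / "classifier_per_goal.csv", index=False)
        pd.DataFrame([{
            "predictor": "gesture_action",
            "token_accuracy": comparison.action.token_accuracy,
            "class_mean_accuracy": comparison.action.class_mean_accuracy,
            "chance_level": comparison.action.chance_level,
        }, {
            "predictor": "morph",
            "token_accuracy": comparison.morph.token_accuracy,
            "class_mean_accuracy": comparison.morph.class_mean_accuracy,
            "chance_level": comparison.morph.chance_level,
        }]).to_csv(out / "classifier_comparison.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "provenance": processed.provenance,
        "n_tokens_input": int(len(table)),
        "n_tokens_preprocessed": int(sum(len(d.df) for d in datasets.values())),
        "n_tokens_assignable": int(len(usable)),
        "n_actions": summary["n_actions"],
        "total_morphs": summary["total_morphs"],
        "single_morph_actions": summary["single_morph_actions"],
        "morphs_per_action_hist": {
            str(k): v for k, v in summary["morphs_per_action_hist"].items()
        },
        "modifier_share": summary["modifier_share"],
        "n_unexplained": summary["n_unexplained"],
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return RunResult(
        rulesets=rulesets, summary=summary, assigned=assigned,
        value_report=value, comparison=comparison, candidate_log=cand_log,
        n_tokens_preprocessed=manifest["n_tokens_preprocessed"],
        n_tokens_assignable=manifest["n_tokens_assignable"],
    )
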