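"""End-to-end orchestration of the two-level analysis.

Stages, mirroring the overall workflow:

1. **herb level** — build prescription transactions, mine herb -> phenotype
   rules, keep the best rule per phenotype, score each selected combination
   with per-herb interactome proximity, and summarise the top fraction of
   rules against the pooled permutation reference distribution;
2. **compound level** — mine compound -> phenotype rules, take the top-k by
   confidence, score the combination-related compounds by proximity, and
   intersect the two compound sets;
3. **structural reports** — hub/bottleneck rankings for each intersection
   compound and for each herbal combination.

All randomness flows from one master seed through deterministic child
seeds per (entity, phenotype), so a run is reproducible end to end and the
serialized outputs are byte-identical across repeated runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import child_seed
from .arm import (
    AssociationRule,
    TransactionSet,
    build_compound_transactions,
    build_herb_transactions,
    mine_rules,
    rules_to_frame,
    select_rules,
)
from .interactome import Interactome, prepare_graph
from .knowledge_base import KnowledgeBase, herb_targets, load_knowledge_base
from .proximity import (
    CombinationVerdict,
    ProximityResult,
    combination_proximity,
    compare_rule_z_to_reference,
    relative_proximity,
)
from .structural import StructuralReport, build_subnetwork, rank_hubs_bottlenecks

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable constants of the two-level analysis.

    Defaults follow the published analysis: herb-level minimum support
    0.0005, compound-level 0.0008, 1000 permutations, proximity threshold
    z <= -0.15, top 150 compound rules by confidence, top 5% of rules in
    the summary comparison.
    """

    kb_dir: str | None = None
    interactome_path: str | None = None
    herb_min_support: float = 0.0005
    compound_min_support: float = 0.0008
    n_perm: int = 1000
    z_threshold: float = -0.15
    top_k_compound_rules: int = 150
    top_fraction_for_summary: float = 0.05
    max_antecedent_size: int = 4
    master_seed: int = 0
    #: phenotype allow-list; None means every phenotype with >= 1 rule
    phenotypes: tuple[str, ...] | None = None
    majority_fraction: float = 0.5
    min_bin_size: int = 10
    structural_k: int = 3
    #: cap on rules entering the per-phenotype summary comparison
    max_summary_rules: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.herb_min_support <= 1 or not 0 < self.compound_min_support <= 1:
            raise ValueError("min supports must be in (0, 1]")
        if not 0 < self.top_fraction_for_summary <= 1:
            raise ValueError("top_fraction_for_summary must be in (0, 1]")
        if self.n_perm < 2 or self.top_k_compound_rules < 1 or self.max_antecedent_size < 1:
            raise ValueError("invalid count parameter")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class PhenotypeSummary:
    """Mean rule z vs pooled reference, with the group-comparison test."""

    phenotype_id: str
    n_rules: int
    #: mean z per top-fraction rule (one value per combination)
    rule_mean_z: list[float]
    #: per-herb z values pooled over the top-fraction rules
    herb_z: list[float]
    reference_mean: float
    rule_mean: float
    statistic: float
    p_value: float
    method: str


@dataclass
class HerbLevelResult:
    transactions_n: int
    rules: list[AssociationRule]
    best_rules: dict[str, AssociationRule]
    verdicts: dict[str, CombinationVerdict]
    summaries: dict[str, PhenotypeSummary]
    phenotypes_without_rules: list[str]


@dataclass
class CandidateSet:
    """Per-phenotype compound candidates from the two-route intersection."""

    phenotype_id: str
    herbal_combination: tuple[str, ...]
    rule: AssociationRule
    herb_proximity: CombinationVerdict
    combination_compounds: frozenset[str]
    arm_compounds: frozenset[str]
    proximal_compounds: frozenset[str]
    compound_results: list[ProximityResult]
    intersection: frozenset[str]
    literature_supported: frozenset[str] = frozenset()

    def validate(self) -> None:
        assert self.intersection <= self.arm_compounds
        assert self.intersection <= self.proximal_compounds
        assert self.proximal_compounds <= self.combination_compounds


def run_herb_level(
    kb: KnowledgeBase, g: Interactome, cfg: PipelineConfig
) -> HerbLevelResult:
    """Herb-level ARM, per-phenotype rule selection and proximity verdicts."""
    ts = build_herb_transactions(kb)
    universe = set(cfg.phenotypes) if cfg.phenotypes else ts.phenotype_universe()
    if not universe:
        logger.warning("no labelled prescriptions: empty rule set")
        return HerbLevelResult(ts.n, [], {}, {}, {}, [])
    rules = mine_rules(
        ts, cfg.herb_min_support, universe, max_antecedent_size=cfg.max_antecedent_size
    )
    no_rules = sorted(universe - {r.consequent for r in rules})
    if not rules:
        return HerbLevelResult(ts.n, [], {}, {}, {}, no_rules)
    best = {r.consequent: r for r in select_rules(rules, "per-phenotype-best")}
    verdicts: dict[str, CombinationVerdict] = {}
    summaries: dict[str, PhenotypeSummary] = {}
    for ph in sorted(best):
        if ph not in kb.phenotype_genes:
            logger.warning("phenotype %s has no gene annotations; proximity skipped", ph)
            continue
        verdicts[ph] = combination_proximity(
            g, kb, best[ph].antecedent, ph, cfg.n_perm, cfg.master_seed,
            threshold=cfg.z_threshold, majority_fraction=cfg.majority_fraction,
            min_bin_size=cfg.min_bin_size,
        )
        summaries[ph] = _summarise_phenotype(kb, g, cfg, ph, [r for r in rules if r.consequent == ph])
    return HerbLevelResult(ts.n, rules, best, verdicts, summaries, no_rules)


def _summarise_phenotype(
    kb: KnowledgeBase,
    g: Interactome,
    cfg: PipelineConfig,
    phenotype: str,
    rules_ph: Sequence[AssociationRule],
) -> PhenotypeSummary:
    """Mean per-rule z for the top fraction of rules vs the pooled reference.

    The reference distribution is the pooled standardized permutation-null
    distances gathered while scoring the rules (mean ~ 0 by construction),
    standing in for distances between randomly selected gene groups.
    """
    top = select_rules(rules_ph, "top-fraction-by-confidence", fraction=cfg.top_fraction_for_summary)
    top = top[: cfg.max_summary_rules]
    rule_mean_z: list[float] = []
    herb_z: list[float] = []
    pooled: list[np.ndarray] = []
    for rule in top:
        verdict = combination_proximity(
            g, kb, rule.antecedent, phenotype, cfg.n_perm, cfg.master_seed,
            threshold=cfg.z_threshold, majority_fraction=cfg.majority_fraction,
            min_bin_size=cfg.min_bin_size, keep_null=True,
        )
        zs = [r.z for r in verdict.results if not r.degenerate]
        if zs:
            rule_mean_z.append(float(np.mean(zs)))
            herb_z.extend(zs)
        for r in verdict.results:
            if r.null_z is not None:
                pooled.append(r.null_z)
    reference = np.concatenate(pooled) if pooled else np.array([0.0])
    # the group contrast pools the per-herb z values of the selected rules
    # against the standardized reference distances
    stat, p, method = compare_rule_z_to_reference(herb_z, reference)
    return PhenotypeSummary(
        phenotype_id=phenotype,
        n_rules=len(top),
        rule_mean_z=rule_mean_z,
        herb_z=herb_z,
        reference_mean=float(reference.mean()),
        rule_mean=float(np.mean(rule_mean_z)),
        statistic=stat,
        p_value=p,
        method=method,
    )


def run_compound_level(
    kb: KnowledgeBase,
    g: Interactome,
    cfg: PipelineConfig,
    herb_result: HerbLevelResult,
    *,
    evidence: Mapping[tuple[str, str], str] | None = None,
) -> dict[str, CandidateSet]:
    """Compound-level ARM, proximity scoring and the two-route intersection."""
    cts = build_compound_transactions(kb)
    phenotypes = sorted(set(herb_result.best_rules) & set(kb.phenotype_genes))
    if not phenotypes:
        return {}
    crules = mine_rules(
        cts, cfg.compound_min_support, phenotypes, max_antecedent_size=cfg.max_antecedent_size
    )
    candidates: dict[str, CandidateSet] = {}
    for ph in phenotypes:
        rule = herb_result.best_rules[ph]
        rules_ph = [r for r in crules if r.consequent == ph]
        if rules_ph:
            top = select_rules(rules_ph, "top-k-by-confidence", k=cfg.top_k_compound_rules)
            arm_compounds = frozenset().union(*(r.antecedent for r in top))
        else:
            arm_compounds = frozenset()
        combination = tuple(sorted(rule.antecedent))
        combination_compounds: set[str] = set()
        for h in combination:
            combination_compounds.update(kb.herb_compounds.get(h, ()))
        P = set(kb.phenotype_genes[ph]) & g.nodes
        compound_results: list[ProximityResult] = []
        proximal: set[str] = set()
        n_untargeted = 0
        for c in sorted(combination_compounds):
            targets = set(kb.compound_targets.get(c, ())) & g.nodes
            if not targets:
                n_untargeted += 1
                continue
            res = relative_proximity(
                g, P, targets, cfg.n_perm, child_seed(cfg.master_seed, c, ph),
                min_bin_size=cfg.min_bin_size, entity_id=c, phenotype_id=ph,
            )
            compound_results.append(res)
            if not res.degenerate and res.z <= cfg.z_threshold:
                proximal.add(c)
        if n_untargeted:
            logger.warning(
                "%s: %d combination compounds without usable targets", ph, n_untargeted
            )
        intersection = arm_compounds & proximal
        supported = frozenset(
            c for c in intersection if evidence and (c, ph) in evidence
        )
        cand = CandidateSet(
            phenotype_id=ph,
            herbal_combination=combination,
            rule=rule,
            herb_proximity=herb_result.verdicts.get(ph),  # type: ignore[arg-type]
            combination_compounds=frozenset(combination_compounds),
            arm_compounds=arm_compounds,
            proximal_compounds=frozenset(proximal),
            compound_results=compound_results,
            intersection=frozenset(intersection),
            literature_supported=supported,
        )
        cand.validate()
        candidates[ph] = cand
    return candidates


def run_structural_reports(
    kb: KnowledgeBase,
    g: Interactome,
    cfg: PipelineConfig,
    candidates: Mapping[str, CandidateSet],
) -> dict[str, dict[str, StructuralReport]]:
    """One report per intersection compound and one per herbal combination.

    Keys of the inner mapping are compound ids plus the special key
    ``combination``, whose report uses the union of herb targets.
    """
    reports: dict[str, dict[str, StructuralReport]] = {}
    for ph, cand in sorted(candidates.items()):
        P = kb.phenotype_genes[ph]
        per_ph: dict[str, StructuralReport] = {}
        for c in sorted(cand.intersection):
            sub = build_subnetwork(g, kb.compound_targets.get(c, frozenset()), P)
            per_ph[c] = rank_hubs_bottlenecks(sub, cfg.structural_k)
        combo_targets: set[str] = set()
        for h in cand.herbal_combination:
            combo_targets.update(herb_targets(kb, h).genes)
        sub = build_subnetwork(g, combo_targets, P)
        per_ph["combination"] = rank_hubs_bottlenecks(sub, cfg.structural_k)
        reports[ph] = per_ph
    return reports


def load_evidence(path: str | Path) -> dict[tuple[str, str], str]:
    """Read a literature-evidence TSV (compound_id, phenotype_id, reference)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["compound_id", "phenotype_id", "reference"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"{path}: expected header {expected}")
    return {
        (row.compound_id, row.phenotype_id): row.reference
        for row in df.itertuples()
    }


@dataclass
class PipelineRun:
    config: PipelineConfig
    herb_level: HerbLevelResult
    candidates: dict[str, CandidateSet]
    structural: dict[str, dict[str, StructuralReport]]


def run_all(
    cfg: PipelineConfig,
    *,
    kb: KnowledgeBase | None = None,
    g: Interactome | None = None,
    evidence: Mapping[tuple[str, str], str] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineRun:
    """Run all three stages; optionally serialize everything under ``out_dir``."""
    if kb is None:
        if cfg.kb_dir is None:
            raise ValueError("provide kb or cfg.kb_dir")
        kb, _ = load_knowledge_base(cfg.kb_dir)
    if g is None:
        if cfg.interactome_path is None:
            raise ValueError("provide g or cfg.interactome_path")
        g = prepare_graph(cfg.interactome_path)
    herb_level = run_herb_level(kb, g, cfg)
    candidates = run_compound_level(kb, g, cfg, herb_level, evidence=evidence)
    structural = run_structural_reports(kb, g, cfg, candidates)
    run = PipelineRun(cfg, herb_level, candidates, structural)
    if out_dir is not None:
        write_run(run, out_dir)
    return run


def proximity_results_frame(results: Sequence[ProximityResult], threshold: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "entity_id": [r.entity_id for r in results],
            "phenotype_id": [r.phenotype_id for r in results],
            "observed_d": [r.observed_d for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_sd": [r.null_sd for r in results],
            "z": [r.z for r in results],
            "n_perm": [r.n_permutations for r in results],
            "seed": [r.seed for r in results],
            "n_targets_used": [r.n_targets_used for r in results],
            "n_phenotype_genes_used": [r.n_phenotype_genes_used for r in results],
            "proximal_flag": [
                (not r.degenerate and r.z <= threshold) for r in results
            ],
        }
    )


def write_run(run: PipelineRun, out_dir: str | Path) -> None:
    """Serialize a run: config snapshot, rule tables, proximity tables, reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(run.config.to_json() + "\n", encoding="utf-8")
    rules_to_frame(run.herb_level.rules).to_csv(
        out / "herb_rules.tsv", sep="\t", index=False, float_format="%.10g"
    )
    best = [run.herb_level.best_rules[ph] for ph in sorted(run.herb_level.best_rules)]
    rules_to_frame(best).to_csv(
        out / "herb_best_rules.tsv", sep="\t", index=False, float_format="%.10g"
    )
    herb_prox: list[ProximityResult] = []
    for ph in sorted(run.herb_level.verdicts):
        herb_prox.extend(run.herb_level.verdicts[ph].results)
    proximity_results_frame(herb_prox, run.config.z_threshold).to_csv(
        out / "herb_proximity.tsv", sep="\t", index=False, float_format="%.10g"
    )
    summaries = {
        ph: {
            "n_rules": s.n_rules,
            "rule_mean_z": [round(v, 10) for v in s.rule_mean_z],
            "herb_z": [round(v, 10) for v in s.herb_z],
            "rule_mean": round(s.rule_mean, 10),
            "reference_mean": round(s.reference_mean, 10),
            "statistic": round(s.statistic, 10),
            "p_value": float(f"{s.p_value:.6g}"),
            "method": s.method,
        }
        for ph, s in sorted(run.herb_level.summaries.items())
    }
    (out / "herb_summary.json").write_text(
        json.dumps(summaries, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    comp_prox: list[ProximityResult] = []
    cand_json: dict[str, dict] = {}
    for ph, cand in sorted(run.candidates.items()):
        comp_prox.extend(cand.compound_results)
        cand_json[ph] = {
            "herbal_combination": list(cand.herbal_combination),
            "rule_confidence": round(cand.rule.confidence, 10),
            "rule_lift": round(cand.rule.lift, 10),
            "rule_support": round(cand.rule.support, 10),
            "combination_proximal": cand.herb_proximity.proximal if cand.herb_proximity else None,
            "combination_compounds": sorted(cand.combination_compounds),
            "arm_compounds": sorted(cand.arm_compounds),
            "proximal_compounds": sorted(cand.proximal_compounds),
            "intersection": sorted(cand.intersection),
            "literature_supported": sorted(cand.literature_supported),
        }
    proximity_results_frame(comp_prox, run.config.z_threshold).to_csv(
        out / "compound_proximity.tsv", sep="\t", index=False, float_format="%.10g"
    )
    (out / "candidates.json").write_text(
        json.dumps(cand_json, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    structural_json = {
        ph: {key: rep.to_dict() for key, rep in sorted(reports.items())}
        for ph, reports in sorted(run.structural.items())
    }
    (out / "structural_reports.json").write_text(
        json.dumps(structural_json, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
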