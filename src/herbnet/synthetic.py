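"""Synthetic knowledge bases and interactomes with planted ground truth.

Every downstream stage of the pipeline (rule mining, proximity, structural
analysis) is exercised against data whose generating process is known, so
recovery can be tested without any database downloads. The generator
emulates the statistical structure the real analysis assumes:

* prescriptions are herb itemsets; a planted high-confidence rule places a
  fixed herb combination into a block of "carrier" prescriptions that are
  labelled with the rule's phenotype at the target confidence rate
  (rejection-free: each carrier is labelled independently with probability
  equal to the confidence target, which is unbiased by construction);
* background prescriptions draw herbs and phenotype labels independently
  (``noise`` is the per-herb background co-prescription rate);
* herbs fan out to compounds and compounds to target genes; each planted
  rule owns a small pool of *effective compounds* shared across the rule's
  herbs, mirroring how active constituents recur across the herbs of a
  formula;
* the interactome is a preferential-attachment (Barabasi-Albert) graph —
  heavy-tailed degree, single component — and each phenotype owns a
  connected gene module grown by breadth-first search;
* targets of effective compounds are drawn from within distance 1 of the
  rule's phenotype module at rate ``proximity_planting``; all other
  targets are uniform over the gene universe.

Ground truth (planted rules, effective compounds, modules, seed) is
emitted as a separate JSON record, never merged into the knowledge-base
tables, so the pipeline cannot accidentally read it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

from .interactome import Interactome, write_edge_list
from .knowledge_base import KnowledgeBase, write_knowledge_base


def herb_id(i: int) -> str:
    return f"H{i:03d}"


def compound_id(i: int) -> str:
    return f"C{i:04d}"


def gene_id(i: int) -> str:
    return f"G{i:05d}"


def phenotype_id(i: int) -> str:
    return f"PH{i:02d}"


def prescription_id(i: int) -> str:
    return f"RX{i:05d}"


@dataclass(frozen=True)
class PlantedRule:
    """A ground-truth herb-combination -> phenotype rule to be planted."""

    herbs: tuple[str, ...]
    phenotype: str
    confidence: float = 0.8
    support: float = 0.15

    def __post_init__(self) -> None:
        if len(self.herbs) < 2:
            raise ValueError("planted combination must have >= 2 herbs")
        if not 0 < self.confidence <= 1:
            raise ValueError("confidence target must be in (0, 1]")
        if not 0 < self.support < 1:
            raise ValueError("support target must be in (0, 1)")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic knowledge base + interactome."""

    n_prescriptions: int = 2000
    n_herbs: int = 120
    n_compounds: int = 300
    n_genes: int = 1000
    n_phenotypes: int = 8
    planted_rules: tuple[PlantedRule, ...] = ()
    #: Barabasi-Albert attachment parameter (edges per new node)
    attachment: int = 3
    #: genes per phenotype module
    module_size: int = 20
    #: fraction of effective-compound targets placed within distance 1 of the module
    proximity_planting: float = 0.8
    #: background per-herb co-prescription rate
    noise: float = 0.18
    #: background per-phenotype labelling rate per prescription
    label_rate: float = 0.003
    compounds_per_herb: int = 5
    targets_per_compound: int = 3
    #: effective compounds owned by each planted rule
    effective_pool_size: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_prescriptions", "n_herbs", "n_compounds", "n_genes", "n_phenotypes",
            "attachment", "module_size", "compounds_per_herb", "targets_per_compound",
            "effective_pool_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.proximity_planting <= 1:
            raise ValueError("proximity_planting must be in [0, 1]")
        herb_universe = {herb_id(i) for i in range(self.n_herbs)}
        phen_universe = {phenotype_id(i) for i in range(self.n_phenotypes)}
        seen: set[str] = set()
        for rule in self.planted_rules:
            if not set(rule.herbs) <= herb_universe:
                raise ValueError(f"planted herbs outside the herb universe: {rule.herbs}")
            if rule.phenotype not in phen_universe:
                raise ValueError(f"planted phenotype outside the universe: {rule.phenotype}")
            if seen & set(rule.herbs):
                raise ValueError("planted rules must not share herbs")
            seen.update(rule.herbs)
        needed = len(self.planted_rules) * self.effective_pool_size
        if needed > self.n_compounds:
            raise ValueError("not enough compounds for the planted effective pools")


def default_study_spec(seed: int = 0, *, planted: bool = True) -> SyntheticSpec:
    """The canonical desk-scale study conditions used throughout the tests.

    One planted 4-herb rule at confidence 0.8 and support 0.15 over 2000
    prescriptions (when ``planted``), on a 1000-gene interactome.
    """
    rules = (
        (PlantedRule(herbs=(herb_id(0), herb_id(1), herb_id(2), herb_id(3)),
                     phenotype=phenotype_id(0)),)
        if planted else ()
    )
    return SyntheticSpec(planted_rules=rules, seed=seed)


@dataclass
class GroundTruth:
    """Planted structure, for recovery tests only — never fed to the pipeline."""

    seed: int
    planted: list[dict] = field(default_factory=list)
    modules: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "planted": self.planted, "modules": self.modules},
            indent=1, sort_keys=True,
        )


def generate_interactome(spec: SyntheticSpec) -> Interactome:
    """Degree-heterogeneous connected interactome, deterministic given the seed."""
    if spec.n_genes < 50:
        raise ValueError("interactome needs at least 50 nodes")
    g = nx.barabasi_albert_graph(spec.n_genes, spec.attachment, seed=spec.seed)
    g = nx.relabel_nodes(g, {i: gene_id(i) for i in g.nodes})
    inter = Interactome(graph=g)
    if not nx.is_connected(g):  # cannot happen for Barabasi-Albert, kept as a guard
        from .interactome import prepare_graph

        inter = prepare_graph(list(g.edges))
    return inter


def _grow_module(g: Interactome, start: str, size: int) -> list[str]:
    """Connected module: the first ``size`` nodes in deterministic BFS order."""
    adj = g.graph.adj
    seen = [start]
    seen_set = {start}
    frontier = [start]
    while frontier and len(seen) < size:
        nxt: list[str] = []
        for u in frontier:
            for v in sorted(adj[u]):
                if v not in seen_set:
                    seen.append(v)
                    seen_set.add(v)
                    nxt.append(v)
                    if len(seen) >= size:
                        return seen
        frontier = nxt
    return seen


def generate_knowledge_base(
    spec: SyntheticSpec,
) -> tuple[KnowledgeBase, GroundTruth, Interactome]:
    """Generate the knowledge base, ground-truth record and interactome.

    Carrier prescriptions for each planted rule contain the full herb
    combination plus sparse extra herbs (rate ``noise/10``); they carry the
    rule's phenotype label with probability equal to the confidence target.
    Background prescriptions include each herb independently at rate
    ``noise`` and each phenotype label at rate ``label_rate``. An error is
    raised when background co-occurrence of the full combination would
    materially dilute the planted confidence (infeasible target).
    """
    inter = generate_interactome(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 2077]))
    genes = sorted(inter.nodes)
    phenotypes = [phenotype_id(i) for i in range(spec.n_phenotypes)]
    herbs = [herb_id(i) for i in range(spec.n_herbs)]
    compounds = [compound_id(i) for i in range(spec.n_compounds)]

    # phenotype gene modules: connected BFS neighbourhoods
    modules: dict[str, list[str]] = {}
    for ph in phenotypes:
        start = genes[int(rng.integers(len(genes)))]
        modules[ph] = sorted(_grow_module(inter, start, spec.module_size))

    # herb -> compounds; planted herbs draw from their rule's effective pool
    pool = spec.effective_pool_size
    effective_of_rule: list[list[str]] = [
        compounds[j * pool:(j + 1) * pool] for j in range(len(spec.planted_rules))
    ]
    herb_rule: dict[str, int] = {}
    for j, rule in enumerate(spec.planted_rules):
        for h in rule.herbs:
            herb_rule[h] = j
    herb_compounds: dict[str, frozenset[str]] = {}
    for h in herbs:
        if h in herb_rule:
            src = effective_of_rule[herb_rule[h]]
        else:
            src = compounds
        k = min(spec.compounds_per_herb, len(src))
        picked = rng.choice(len(src), size=k, replace=False)
        herb_compounds[h] = frozenset(src[i] for i in sorted(picked))

    # compound -> target genes
    effective_phenotype: dict[str, str] = {}
    for j, rule in enumerate(spec.planted_rules):
        for c in effective_of_rule[j]:
            effective_phenotype[c] = rule.phenotype
    near_pool: dict[str, list[str]] = {}
    for ph in phenotypes:
        near = set(modules[ph])
        for m in modules[ph]:
            near.update(inter.graph.adj[m])
        near_pool[ph] = sorted(near)
    compound_targets: dict[str, frozenset[str]] = {}
    for c in compounds:
        targets: set[str] = set()
        ph = effective_phenotype.get(c)
        for _ in range(spec.targets_per_compound):
            if ph is not None and rng.random() < spec.proximity_planting:
                src = near_pool[ph]
            else:
                src = genes
            targets.add(src[int(rng.integers(len(src)))])
        compound_targets[c] = frozenset(targets)

    # prescriptions: carriers per planted rule, then background
    prescriptions: dict[str, frozenset[str]] = {}
    indications: dict[str, frozenset[str]] = {}
    truth = GroundTruth(seed=spec.seed, modules=modules)
    pid = 0
    herb_arr = np.array(herbs)
    phen_arr = np.array(phenotypes)
    for j, rule in enumerate(spec.planted_rules):
        n_carriers = int(round(rule.support * spec.n_prescriptions))
        if n_carriers < 1:
            raise ValueError(f"support target {rule.support} yields zero carriers")
        n_bg = spec.n_prescriptions - sum(
            int(round(r.support * spec.n_prescriptions)) for r in spec.planted_rules
        )
        expected_bg_combo = n_bg * spec.noise ** len(rule.herbs)
        if expected_bg_combo > 0.5 * n_carriers:
            raise ValueError(
                f"support/confidence targets infeasible: expected {expected_bg_combo:.1f} "
                f"background occurrences of the combination would swamp {n_carriers} carriers"
            )
        combo = set(rule.herbs)
        extras_rate = spec.noise / 10.0
        for _ in range(n_carriers):
            extras = herb_arr[rng.random(spec.n_herbs) < extras_rate]
            items = combo | (set(extras.tolist()) - combo)
            labels: set[str] = set()
            if rng.random() < rule.confidence:
                labels.add(rule.phenotype)
            bg_labels = phen_arr[rng.random(spec.n_phenotypes) < spec.label_rate]
            labels.update(p for p in bg_labels.tolist() if p != rule.phenotype)
            prescriptions[prescription_id(pid)] = frozenset(items)
            indications[prescription_id(pid)] = frozenset(labels)
            pid += 1
        truth.planted.append(
            {
                "herbs": sorted(rule.herbs),
                "phenotype": rule.phenotype,
                "confidence_target": rule.confidence,
                "support_target": rule.support,
                "n_carriers": n_carriers,
                "effective_compounds": sorted(effective_of_rule[j]),
            }
        )
    while pid < spec.n_prescriptions:
        items_mask = rng.random(spec.n_herbs) < spec.noise
        items = set(herb_arr[items_mask].tolist())
        if not items:
            items = {herbs[int(rng.integers(spec.n_herbs))]}
        labels = set(phen_arr[rng.random(spec.n_phenotypes) < spec.label_rate].tolist())
        # every prescription containing a planted combination is labelled at
        # the rule's confidence rate, carriers and background alike
        for rule in spec.planted_rules:
            if set(rule.herbs) <= items:
                if rng.random() < rule.confidence:
                    labels.add(rule.phenotype)
                else:
                    labels.discard(rule.phenotype)
        prescriptions[prescription_id(pid)] = frozenset(items)
        indications[prescription_id(pid)] = frozenset(labels)
        pid += 1

    kb = KnowledgeBase(
        prescriptions=prescriptions,
        indications={p: l for p, l in indications.items() if l},
        herb_compounds=herb_compounds,
        compound_targets=compound_targets,
        phenotype_genes={ph: frozenset(m) for ph, m in modules.items()},
    )
    kb.validate()
    return kb, truth, inter


def write_synthetic_study(spec: SyntheticSpec, directory: str | Path) -> None:
    """Write the five KB tables, the interactome edge list and ground_truth.json.

    Outputs are sorted and byte-stable: the same spec and seed always
    produce identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    kb, truth, inter = generate_knowledge_base(spec)
    write_knowledge_base(kb, directory)
    write_edge_list(inter, directory / "interactome.tsv")
    with open(directory / "ground_truth.json", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(truth.to_json())
        fh.write("\n")
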