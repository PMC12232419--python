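"""Transaction construction and Apriori association-rule mining.

Two transaction levels are supported:

* **herb level** — one transaction per prescription; the itemset is the
  prescription's herbs and the consequents are its indicated phenotypes
  (rule form ``herb A, herb B, ... -> phenotype``);
* **compound level** — one transaction per herbal material; the itemset is
  the herb's compounds and the consequents are the union of phenotypes
  over prescriptions containing the herb (rule form ``compound -> phenotype``).

Rules are evaluated with support, confidence and lift. ``min_support`` is
interpreted on the joint itemset (antecedent plus consequent): a rule
qualifies when the fraction of transactions containing both the antecedent
itemset and the consequent label reaches the threshold. Consequents are
phenotype labels only and never enter the item universe, so no herb->herb
or compound->compound rules are produced.

The miner is a level-wise Apriori over transaction-id posting lists. It is
exact: the emitted rule set equals exhaustive enumeration of all antecedent
subsets up to ``max_antecedent_size`` (the test suite asserts this against
a brute-force oracle).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .knowledge_base import KnowledgeBase

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class Transaction:
    items: frozenset[str]
    consequents: frozenset[str]


@dataclass
class TransactionSet:
    level: Literal["herb", "compound"]
    transactions: list[Transaction]
    #: per-construction accounting: entities skipped for having empty itemsets
    n_skipped_empty: int = 0

    @property
    def n(self) -> int:
        return len(self.transactions)

    def phenotype_universe(self) -> set[str]:
        out: set[str] = set()
        for t in self.transactions:
            out.update(t.consequents)
        return out


@dataclass(frozen=True)
class AssociationRule:
    """One mined rule ``antecedent -> consequent`` with exact counts.

    Invariants (checked by :meth:`validate`):
    ``support = joint_count / n``, ``confidence = joint_count / antecedent_count``,
    ``lift = confidence / (consequent_count / n)`` and
    ``joint_count <= min(antecedent_count, consequent_count)``.
    """

    antecedent: frozenset[str]
    consequent: str
    support: float
    confidence: float
    lift: float
    antecedent_count: int
    joint_count: int
    consequent_count: int
    n: int

    def validate(self) -> None:
        assert self.joint_count <= min(self.antecedent_count, self.consequent_count)
        assert math.isclose(self.support, self.joint_count / self.n)
        assert math.isclose(self.confidence, self.joint_count / self.antecedent_count)
        assert math.isclose(self.lift, self.confidence / (self.consequent_count / self.n))

    def sort_key(self):
        return (-self.confidence, -self.lift, tuple(sorted(self.antecedent)), self.consequent)


def min_joint_count(min_support: float, n: int) -> int:
    """Smallest transaction count whose support reaches ``min_support``.

    ``ceil(min_support * n)`` with a floating-point guard, floored at 1.
    E.g. a 0.0005 threshold over 16 260 transactions demands 9 transactions
    (more than floor(0.0005 * 16260) = 8), and 0.0008 over 5187 demands 5.
    """
    if not 0 < min_support <= 1:
        raise ValueError("min_support must be in (0, 1]")
    return max(1, math.ceil(min_support * n - _EPS))


def build_herb_transactions(kb: KnowledgeBase) -> TransactionSet:
    """One transaction per prescription: its herbs, labelled by its indications."""
    transactions: list[Transaction] = []
    skipped = 0
    for pid in sorted(kb.prescriptions):
        herbs = kb.prescriptions[pid]
        if not herbs:
            skipped += 1
            continue
        transactions.append(
            Transaction(items=herbs, consequents=kb.indications.get(pid, frozenset()))
        )
    if skipped:
        logger.warning("skipped %d prescriptions with zero herbs", skipped)
    return TransactionSet(level="herb", transactions=transactions, n_skipped_empty=skipped)


def build_compound_transactions(kb: KnowledgeBase) -> TransactionSet:
    """One transaction per herbal material: its compounds, labelled by the
    union of phenotypes over prescriptions containing the herb."""
    herb_phenotypes: dict[str, set[str]] = {}
    for pid, herbs in kb.prescriptions.items():
        labels = kb.indications.get(pid, frozenset())
        for h in herbs:
            herb_phenotypes.setdefault(h, set()).update(labels)
    transactions: list[Transaction] = []
    skipped = 0
    for herb in sorted(kb.herb_compounds):
        compounds = kb.herb_compounds[herb]
        if not compounds:
            skipped += 1
            continue
        transactions.append(
            Transaction(
                items=compounds,
                consequents=frozenset(herb_phenotypes.get(herb, ())),
            )
        )
    if skipped:
        logger.warning("skipped %d herbs with zero compounds", skipped)
    return TransactionSet(level="compound", transactions=transactions, n_skipped_empty=skipped)


def _postings(transactions: Sequence[Transaction]) -> dict[str, set[int]]:
    idx: dict[str, set[int]] = {}
    for i, t in enumerate(transactions):
        for item in t.items:
            idx.setdefault(item, set()).add(i)
    return idx


def _apriori_frequent(
    postings: dict[str, set[int]],
    universe_ids: set[int],
    min_count: int,
    max_size: int,
) -> dict[frozenset[str], set[int]]:
    """Frequent itemsets (by count within ``universe_ids``) via level-wise join."""
    frequent: dict[frozenset[str], set[int]] = {}
    level: dict[tuple[str, ...], set[int]] = {}
    for item in sorted(postings):
        ids = postings[item] & universe_ids
        if len(ids) >= min_count:
            level[(item,)] = ids
    frequent.update({frozenset(k): v for k, v in level.items()})
    k = 1
    while level and k < max_size:
        keys = sorted(level)
        next_level: dict[tuple[str, ...], set[int]] = {}
        # classic prefix join: two sorted k-itemsets sharing the first k-1 items
        by_prefix: dict[tuple[str, ...], list[tuple[str, ...]]] = {}
        for key in keys:
            by_prefix.setdefault(key[:-1], []).append(key)
        for prefix, group in by_prefix.items():
            for a, b in combinations(group, 2):
                candidate = a + (b[-1],)
                # anti-monotonic prune: every k-subset must be frequent
                if any(
                    candidate[:i] + candidate[i + 1:] not in level
                    for i in range(len(candidate) - 2)
                ):
                    continue
                ids = level[a] & level[b]
                if len(ids) >= min_count:
                    next_level[candidate] = ids
        frequent.update({frozenset(k_): v for k_, v in next_level.items()})
        level = next_level
        k += 1
    return frequent


def mine_rules(
    ts: TransactionSet,
    min_support: float,
    consequent_universe: Iterable[str] | None = None,
    *,
    max_antecedent_size: int = 4,
) -> list[AssociationRule]:
    """Mine all rules ``antecedent -> phenotype`` with joint support >= threshold.

    Parameters
    ----------
    ts
        Transaction set (herb or compound level).
    min_support
        Joint-support threshold in (0, 1], applied to the fraction of
        transactions containing both antecedent and consequent.
    consequent_universe
        Phenotypes eligible as consequents; defaults to every phenotype
        observed in the transactions. An explicitly empty universe raises.
    max_antecedent_size
        Cap on antecedent itemset size (default 4).

    Returns rules in deterministic order: descending confidence, then
    descending lift, then lexicographic antecedent, then consequent.
    """
    n = ts.n
    if n == 0:
        raise ValueError("empty transaction set")
    if consequent_universe is None:
        consequent_universe = ts.phenotype_universe()
    else:
        consequent_universe = set(consequent_universe)
        if not consequent_universe:
            raise ValueError("empty consequent universe")
    if min_support < 1 / n:
        logger.warning(
            "min_support %.3g is below 1/n (n=%d); equivalent to joint count >= 1",
            min_support, n,
        )
    min_count = min_joint_count(min_support, n)
    postings = _postings(ts.transactions)
    rules: list[AssociationRule] = []
    for phenotype in sorted(consequent_universe):
        ph_ids = {i for i, t in enumerate(ts.transactions) if phenotype in t.consequents}
        consequent_count = len(ph_ids)
        if consequent_count < min_count:
            continue
        frequent = _apriori_frequent(postings, ph_ids, min_count, max_antecedent_size)
        for antecedent, joint_ids in frequent.items():
            ant_ids: set[int] | None = None
            for item in antecedent:
                ant_ids = postings[item] if ant_ids is None else ant_ids & postings[item]
            assert ant_ids is not None
            antecedent_count = len(ant_ids)
            joint_count = len(joint_ids)
            confidence = joint_count / antecedent_count
            rules.append(
                AssociationRule(
                    antecedent=antecedent,
                    consequent=phenotype,
                    support=joint_count / n,
                    confidence=confidence,
                    lift=confidence / (consequent_count / n),
                    antecedent_count=antecedent_count,
                    joint_count=joint_count,
                    consequent_count=consequent_count,
                    n=n,
                )
            )
    rules.sort(key=AssociationRule.sort_key)
    return rules


def select_rules(
    rules: Sequence[AssociationRule],
    policy: Literal["per-phenotype-best", "top-k-by-confidence", "top-fraction-by-confidence"],
    *,
    k: int = 150,
    fraction: float = 0.05,
) -> list[AssociationRule]:
    """Deterministic rule-selection policies.

    * ``per-phenotype-best`` — for each phenotype, the rule with maximal
      confidence (ties broken by lift, then lexicographic antecedent);
    * ``top-k-by-confidence`` — the first ``k`` rules in the canonical
      order (default 150); if fewer rules exist, all are returned with a
      warning;
    * ``top-fraction-by-confidence`` — the top ``fraction`` of rules
      (default 5%), at least one.
    """
    if not rules:
        raise ValueError("empty rule list")
    ordered = sorted(rules, key=AssociationRule.sort_key)
    if policy == "per-phenotype-best":
        best: dict[str, AssociationRule] = {}
        for r in ordered:
            best.setdefault(r.consequent, r)
        return [best[ph] for ph in sorted(best)]
    if policy == "top-k-by-confidence":
        if k > len(ordered):
            logger.warning("k=%d exceeds rule count %d; returning all", k, len(ordered))
        return ordered[:k]
    if policy == "top-fraction-by-confidence":
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        m = max(1, math.ceil(fraction * len(ordered)))
        return ordered[:m]
    raise ValueError(f"unknown policy: {policy!r}")


def rules_to_frame(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    """Tabulate rules; antecedents are semicolon-joined in sorted order."""
    return pd.DataFrame(
        {
            "antecedent": [";".join(sorted(r.antecedent)) for r in rules],
            "consequent": [r.consequent for r in rules],
            "support": [r.support for r in rules],
            "confidence": [r.confidence for r in rules],
            "lift": [r.lift for r in rules],
            "antecedent_count": [r.antecedent_count for r in rules],
            "joint_count": [r.joint_count for r in rules],
            "consequent_count": [r.consequent_count for r in rules],
        }
    )


def write_rules_tsv(rules: Sequence[AssociationRule], path: str | Path) -> None:
    rules_to_frame(rules).to_csv(path, sep="\t", index=False, float_format="%.10g")
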