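"""Relative network proximity between target sets and phenotype gene modules.

The observed statistic is the closest distance ``d(P, S)`` between a
phenotype gene module ``P`` and a target set ``S``. Its significance is a
z-score against a degree-preserving permutation null: in each of
``n_perm`` permutations (default 1000) *both* ``P`` and ``S`` are replaced
by degree-matched random node sets of the same sizes and the closest
distance is recomputed. With null mean ``mu_d`` and standard deviation
``sigma_d`` (sample SD, ``n-1`` denominator by default),

    z = (d(P, S) - mu_d) / sigma_d.

A target set is called *proximal* to the phenotype when ``z <= -0.15``,
a threshold established in earlier interactome-proximity screens for its
balance of coverage and false positives. A herbal combination is called
proximal when a configurable fraction of its herbs (default: strict
majority) pass the per-herb threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from ._rng import child_seed, rng_from
from .interactome import (
    Interactome,
    _closest_distance_idx,
    _filter_to_nodes,
    closest_distance,
    degree_matched_sample,
)
from .knowledge_base import KnowledgeBase, herb_targets

logger = logging.getLogger(__name__)

Z_THRESHOLD_DEFAULT = -0.15


@dataclass
class ProximityResult:
    """Observed closest distance, permutation-null summary and z-score."""

    entity_id: str
    phenotype_id: str
    observed_d: float
    null_mean: float
    null_sd: float
    z: float  # NaN when degenerate
    n_permutations: int
    seed: int
    n_targets_used: int
    n_phenotype_genes_used: int
    degenerate: bool = False
    #: standardized null draws ((d_k - mean) / sd), kept only on request
    null_z: np.ndarray | None = field(default=None, repr=False)


def relative_proximity(
    g: Interactome,
    P: Iterable[str],
    S: Iterable[str],
    n_perm: int = 1000,
    rng: int | np.random.Generator = 0,
    *,
    min_bin_size: int = 10,
    ddof: int = 1,
    entity_id: str = "S",
    phenotype_id: str = "P",
    keep_null: bool = False,
) -> ProximityResult:
    """Relative proximity z-score of target set ``S`` to gene module ``P``.

    Both sets are restricted to interactome nodes (dropped genes are
    logged). Each permutation replaces both sets with degree-matched
    samples and recomputes the closest distance; the z-score standardises
    the observed distance against the resulting reference distribution.
    A zero null SD flags the result degenerate (``z`` is NaN, never
    +/-inf).
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    seed = int(rng) if not isinstance(rng, np.random.Generator) else -1
    rng = rng_from(rng)
    P_kept = _filter_to_nodes(g, P, "P")
    S_kept = _filter_to_nodes(g, S, "S")
    observed = closest_distance(g, P_kept, S_kept)
    dmat = g.distance_matrix()
    null = np.empty(n_perm)
    for k in range(n_perm):
        P_rand = degree_matched_sample(g, P_kept, rng, min_bin_size=min_bin_size)
        S_rand = degree_matched_sample(g, S_kept, rng, min_bin_size=min_bin_size)
        if dmat is not None:
            null[k] = _closest_distance_idx(dmat, g.indices(P_rand), g.indices(S_rand))
        else:
            null[k] = closest_distance(g, P_rand, S_rand)
    mu = float(null.mean())
    sd = float(null.std(ddof=ddof))
    degenerate = sd == 0.0
    if degenerate:
        logger.warning("degenerate null (sd=0) for %s vs %s", entity_id, phenotype_id)
    z = float("nan") if degenerate else (observed - mu) / sd
    return ProximityResult(
        entity_id=entity_id,
        phenotype_id=phenotype_id,
        observed_d=observed,
        null_mean=mu,
        null_sd=sd,
        z=z,
        n_permutations=n_perm,
        seed=seed,
        n_targets_used=len(S_kept),
        n_phenotype_genes_used=len(P_kept),
        degenerate=degenerate,
        null_z=((null - mu) / sd if (keep_null and not degenerate) else None),
    )


def is_proximal(r: ProximityResult, threshold: float = Z_THRESHOLD_DEFAULT) -> bool:
    """True iff ``z <= threshold`` (boundary inclusive). Degenerate raises."""
    if r.degenerate:
        raise ValueError(
            f"degenerate proximity result for {r.entity_id} vs {r.phenotype_id}: z undefined"
        )
    return bool(r.z <= threshold)


@dataclass
class CombinationVerdict:
    combination: tuple[str, ...]
    phenotype_id: str
    results: list[ProximityResult]
    unresolved: list[str]
    proximal: bool
    n_pass: int
    n_evaluated: int


def combination_proximity(
    g: Interactome,
    kb: KnowledgeBase,
    combination: Iterable[str],
    phenotype: str,
    n_perm: int = 1000,
    master_seed: int = 0,
    *,
    threshold: float = Z_THRESHOLD_DEFAULT,
    majority_fraction: float = 0.5,
    min_bin_size: int = 10,
    keep_null: bool = False,
) -> CombinationVerdict:
    """Per-herb proximity of a herbal combination to a phenotype module.

    Every herb is resolved to its target set (union over its compounds) and
    scored by :func:`relative_proximity` with a child seed derived from the
    master seed and the (herb, phenotype) labels. Herbs whose usable target
    set is empty are reported unresolved and excluded from the verdict
    denominator. The verdict is proximal when the passing fraction strictly
    exceeds ``majority_fraction`` (default: strict majority).
    """
    combination = tuple(sorted(set(combination)))
    if phenotype not in kb.phenotype_genes:
        raise KeyError(f"phenotype {phenotype!r} has no gene annotations")
    P = set(kb.phenotype_genes[phenotype]) & g.nodes
    results: list[ProximityResult] = []
    unresolved: list[str] = []
    for herb in combination:
        targets = set(herb_targets(kb, herb).genes) & g.nodes
        if not targets:
            logger.warning("herb %s has no usable targets in the interactome", herb)
            unresolved.append(herb)
            continue
        seed = child_seed(master_seed, herb, phenotype)
        results.append(
            relative_proximity(
                g, P, targets, n_perm, seed,
                min_bin_size=min_bin_size,
                entity_id=herb, phenotype_id=phenotype,
                keep_null=keep_null,
            )
        )
    n_pass = sum(1 for r in results if not r.degenerate and is_proximal(r, threshold))
    n_eval = len(results)
    proximal = n_eval > 0 and n_pass > majority_fraction * n_eval
    return CombinationVerdict(
        combination=combination,
        phenotype_id=phenotype,
        results=results,
        unresolved=unresolved,
        proximal=proximal,
        n_pass=n_pass,
        n_evaluated=n_eval,
    )


def compare_rule_z_to_reference(
    rule_z: Sequence[float],
    reference: Sequence[float],
    method: Literal["auto", "t", "mannwhitney"] = "auto",
    *,
    min_n_for_t: int = 5,
) -> tuple[float, float, str]:
    """Two-sided comparison of rule z-scores against reference distances.

    ``auto`` uses a two-sample Student t-test unless the rule group has
    fewer than ``min_n_for_t`` members, in which case the Mann-Whitney U
    test is used (small rule sets do not support the t-test's normality
    assumptions). Returns ``(statistic, p_value, method_used)``.
    """
    rule_z = np.asarray(rule_z, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if rule_z.size == 0 or reference.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        method = "t" if rule_z.size >= min_n_for_t else "mannwhitney"
    if method == "t":
        if rule_z.size < 2 or reference.size < 2:
            raise ValueError("t-test requires >= 2 observations per group; use mannwhitney")
        stat, p = stats.ttest_ind(rule_z, reference, equal_var=True)
        return float(stat), float(p), "t"
    if method == "mannwhitney":
        res = stats.mannwhitneyu(rule_z, reference, alternative="two-sided")
        return float(res.statistic), float(res.pvalue), "mannwhitney"
    raise ValueError(f"unknown method: {method!r}")
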