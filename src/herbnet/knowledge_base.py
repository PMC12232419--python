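"""Data model and I/O for the traditional-medicine knowledge graph.

The knowledge base links five entity types through four association tables
plus one indication table, all stored as two-column TSV files:

========================  =========================================
table                     columns
========================  =========================================
``prescriptions.tsv``     prescription_id, herb_id
``indications.tsv``       prescription_id, phenotype_id
``herb_compounds.tsv``    herb_id, compound_id
``compound_targets.tsv``  compound_id, gene_id
``phenotype_genes.tsv``   phenotype_id, gene_id
========================  =========================================

Identifiers are opaque strings; no ontology mapping is attempted.
Unresolved cross-references (a prescription herb with no compound row, a
compound with no target row) are retained and reported, never dropped, so
rule-mining counts are unaffected by target sparsity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: table name -> (parent column, child column)
TABLE_SCHEMAS: dict[str, tuple[str, str]] = {
    "prescriptions": ("prescription_id", "herb_id"),
    "indications": ("prescription_id", "phenotype_id"),
    "herb_compounds": ("herb_id", "compound_id"),
    "compound_targets": ("compound_id", "gene_id"),
    "phenotype_genes": ("phenotype_id", "gene_id"),
}

#: tables that must contain at least one usable row; ``indications`` may be
#: empty (unlabeled prescriptions are retained and contribute no consequents)
REQUIRED_TABLES = ("prescriptions", "herb_compounds", "compound_targets", "phenotype_genes")


@dataclass
class LoadReport:
    """Per-table row accounting produced by :func:`load_knowledge_base`."""

    row_counts: dict[str, int] = field(default_factory=dict)
    duplicate_counts: dict[str, int] = field(default_factory=dict)
    malformed_counts: dict[str, int] = field(default_factory=dict)
    #: herb ids referenced by prescriptions but absent from herb_compounds
    unresolved_herbs: set[str] = field(default_factory=set)
    #: compound ids referenced by herbs but absent from compound_targets
    unresolved_compounds: set[str] = field(default_factory=set)

    def summary(self) -> str:
        lines = []
        for table in TABLE_SCHEMAS:
            lines.append(
                f"{table}: {self.row_counts.get(table, 0)} rows "
                f"({self.duplicate_counts.get(table, 0)} duplicates, "
                f"{self.malformed_counts.get(table, 0)} malformed skipped)"
            )
        lines.append(f"unresolved herbs: {len(self.unresolved_herbs)}")
        lines.append(f"unresolved compounds: {len(self.unresolved_compounds)}")
        return "\n".join(lines)


@dataclass
class KnowledgeBase:
    """In-memory knowledge base: five maps from parent id to a child id set."""

    prescriptions: dict[str, frozenset[str]]
    indications: dict[str, frozenset[str]]
    herb_compounds: dict[str, frozenset[str]]
    compound_targets: dict[str, frozenset[str]]
    phenotype_genes: dict[str, frozenset[str]]

    @property
    def herbs(self) -> set[str]:
        out: set[str] = set(self.herb_compounds)
        for members in self.prescriptions.values():
            out.update(members)
        return out

    @property
    def phenotypes(self) -> set[str]:
        out: set[str] = set(self.phenotype_genes)
        for labels in self.indications.values():
            out.update(labels)
        return out

    def validate(self) -> None:
        for name in TABLE_SCHEMAS:
            mapping: Mapping[str, frozenset[str]] = getattr(self, name)
            for parent, children in mapping.items():
                if parent == "":
                    raise ValueError(f"empty-string parent id in {name}")
                if any(c == "" for c in children):
                    raise ValueError(f"empty-string child id in {name}[{parent}]")


@dataclass(frozen=True)
class HerbTargetSet:
    """The target-gene set of one herbal material.

    Defined as the union of the target sets of every compound contained in
    the herb; intersect with interactome nodes before any proximity use.
    """

    herb: str
    genes: frozenset[str]


def _read_table(path: Path, table: str, report: LoadReport) -> dict[str, frozenset[str]]:
    parent_col, child_col = TABLE_SCHEMAS[table]
    if not path.exists():
        raise FileNotFoundError(f"knowledge-base table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != [parent_col, child_col]:
        raise ValueError(
            f"{path}: expected header '{parent_col}\\t{child_col}', got {list(df.columns)}"
        )
    malformed = (df[parent_col] == "") | (df[child_col] == "")
    n_malformed = int(malformed.sum())
    if n_malformed:
        logger.warning("%s: skipped %d malformed rows", path, n_malformed)
        df = df[~malformed]
    n_dup = int(df.duplicated(subset=[parent_col, child_col]).sum())
    df = df.drop_duplicates(subset=[parent_col, child_col])
    report.row_counts[table] = len(df)
    report.duplicate_counts[table] = n_dup
    report.malformed_counts[table] = n_malformed
    out: dict[str, frozenset[str]] = {
        parent: frozenset(group) for parent, group in df.groupby(parent_col)[child_col]
    }
    return out


def load_knowledge_base(
    directory: str | Path | None = None,
    *,
    paths: Mapping[str, str | Path] | None = None,
) -> tuple[KnowledgeBase, LoadReport]:
    """Load a knowledge base from five TSV tables.

    Parameters
    ----------
    directory
        Directory holding ``<table>.tsv`` for each table in
        :data:`TABLE_SCHEMAS`. Mutually exclusive with ``paths``.
    paths
        Explicit per-table file locations, keyed by table name.

    Returns
    -------
    (KnowledgeBase, LoadReport)
        The deduplicated maps plus row accounting. A missing file or an
        empty required table is fatal; malformed rows are skipped and
        counted; duplicate pairs are collapsed and counted.
    """
    if (directory is None) == (paths is None):
        raise ValueError("pass exactly one of 'directory' or 'paths'")
    if directory is not None:
        paths = {t: Path(directory) / f"{t}.tsv" for t in TABLE_SCHEMAS}
    assert paths is not None
    report = LoadReport()
    tables: dict[str, dict[str, frozenset[str]]] = {}
    for table in TABLE_SCHEMAS:
        tables[table] = _read_table(Path(paths[table]), table, report)
    for table in REQUIRED_TABLES:
        if report.row_counts.get(table, 0) == 0:
            raise ValueError(f"required table '{table}' has zero usable rows")
    kb = KnowledgeBase(**tables)
    kb.validate()
    for members in kb.prescriptions.values():
        report.unresolved_herbs.update(h for h in members if h not in kb.herb_compounds)
    for compounds in kb.herb_compounds.values():
        report.unresolved_compounds.update(
            c for c in compounds if c not in kb.compound_targets
        )
    if report.unresolved_herbs:
        logger.info("%d herbs lack compound rows", len(report.unresolved_herbs))
    if report.unresolved_compounds:
        logger.info("%d compounds lack target rows", len(report.unresolved_compounds))
    return kb, report


def write_knowledge_base(kb: KnowledgeBase, directory: str | Path) -> None:
    """Write the five TSV tables with rows sorted, so output is byte-stable."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for table, (parent_col, child_col) in TABLE_SCHEMAS.items():
        mapping: Mapping[str, frozenset[str]] = getattr(kb, table)
        rows = sorted(
            (parent, child) for parent, children in mapping.items() for child in children
        )
        with open(directory / f"{table}.tsv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"{parent_col}\t{child_col}\n")
            for parent, child in rows:
                fh.write(f"{parent}\t{child}\n")


def herb_targets(kb: KnowledgeBase, herb: str) -> HerbTargetSet:
    """Union of target genes over all compounds of ``herb``.

    Raises ``KeyError`` naming the id for an unknown herb; a herb whose
    compounds all lack target rows yields an empty set with a warning.
    """
    if herb not in kb.herb_compounds:
        raise KeyError(f"unknown herb id: {herb!r}")
    genes: set[str] = set()
    for compound in kb.herb_compounds[herb]:
        genes.update(kb.compound_targets.get(compound, ()))
    if not genes:
        logger.warning("herb %s has no targeted compounds", herb)
    return HerbTargetSet(herb=herb, genes=frozenset(genes))


def compound_targets_of(kb: KnowledgeBase, compounds: Iterable[str]) -> dict[str, frozenset[str]]:
    """Target sets for a collection of compounds (missing ones map to empty)."""
    return {c: kb.compound_targets.get(c, frozenset()) for c in compounds}
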