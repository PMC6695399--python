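"""Target-coverage prediction and cross-compartment candidate integration.

Because miRNAs repress their targets, a set of downregulated miRNAs predicts
*up*regulated mRNAs and vice versa (direction inversion).  The prediction is
coverage-filtered: a gene qualifies only if it is targeted by more than a
stated fraction (default: more than 50%) of the source miRNA set.

Two integration strategies are provided:

* ``common_mirna_first`` (default): intersect the cell and exosome DE miRNA
  sets per direction first, predict target genes from each common set, then
  intersect with the observed mRNA DE sets.
* ``per_compartment``: predict target genes separately from the cell and the
  exosome DE miRNA sets, then take the three-way intersection with the
  observed mRNA DE sets.

All gene-level intersections are computed in Entrez ID space; symbols that
the supplied ID map cannot resolve drop out before intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .datamodel import ConfigError, GeneIdMap, TargetTable, normalize_gene_id, normalize_mirna_id
from .diffexpr import DEResult

STRATEGIES = ("common_mirna_first", "per_compartment")


@dataclass
class CoverageSet:
    """Coverage-filtered target prediction from one miRNA set.

    ``predicted_genes`` maps each targeted gene symbol to the number of
    source miRNAs that list it; ``qualifying_genes`` are those with
    count / |source_mirnas| strictly greater than ``min_fraction``.
    """

    source_mirnas: frozenset[str]
    source_direction: str
    predicted_genes: dict[str, int]
    min_fraction: float
    qualifying_genes: frozenset[str]
    denominator: int

    @property
    def predicted_direction(self) -> str:
        return {"up": "down", "down": "up"}[self.source_direction]


@dataclass
class CandidateSet:
    """Integrated biomarker candidates with full per-gene provenance.

    ``provenance`` has one row per candidate gene: symbol, Entrez ID,
    direction, and the membership/coverage evidence from each contributing
    set.  ``cardinalities`` records every intermediate set size (the Venn
    numbers of the integration graph).
    """

    up_genes: frozenset[str]
    down_genes: frozenset[str]
    provenance: pd.DataFrame
    strategy: str
    cardinalities: dict[str, int]
    id_map: GeneIdMap | None = None

    def __post_init__(self) -> None:
        if self.up_genes & self.down_genes:
            raise ValueError("a gene cannot be both an up and a down candidate")

    @property
    def n_candidates(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


def common_mirnas(cell_de: DEResult, exo_de: DEResult) -> tuple[frozenset[str], frozenset[str]]:
    """Direction-stratified intersection of cell and exosome DE miRNA sets."""

    def norm(ids: Iterable[str]) -> frozenset[str]:
        return frozenset(normalize_mirna_id(i) for i in ids)

    common_up = norm(cell_de.up_set) & norm(exo_de.up_set)
    common_down = norm(cell_de.down_set) & norm(exo_de.down_set)
    return common_up, common_down


def coverage_targets(
    mirna_set: Iterable[str],
    direction: str,
    table: TargetTable,
    min_fraction: float = 0.5,
    *,
    arm_fallback: bool = False,
    denominator: str = "all",
    union_mode: bool = False,
) -> CoverageSet:
    """Predict genes targeted by more than ``min_fraction`` of ``mirna_set``.

    ``denominator='all'`` counts every source miRNA (one absent from the
    target table simply targets nothing); ``'in_table'`` restricts the
    denominator to miRNAs with at least one table entry.  ``union_mode``
    disables the coverage filter and returns every targeted gene.
    """
    if direction not in ("up", "down"):
        raise ConfigError(f"direction must be 'up' or 'down', got {direction!r}")
    if not (0 <= min_fraction <= 1):
        raise ConfigError("min_fraction must be in [0, 1]")
    if denominator not in ("all", "in_table"):
        raise ConfigError(f"unknown denominator policy {denominator!r}")
    mirnas = frozenset(normalize_mirna_id(m) for m in mirna_set)
    if not mirnas:
        raise ConfigError("coverage_targets requires a nonempty miRNA set (undefined denominator)")

    counts: dict[str, int] = {}
    n_in_table = 0
    for m in sorted(mirnas):
        targets = table.targets_of(m, arm_fallback=arm_fallback)
        if targets:
            n_in_table += 1
        for g in targets:
            counts[g] = counts.get(g, 0) + 1
    denom = len(mirnas) if denominator == "all" else n_in_table
    if union_mode:
        qualifying = frozenset(counts)
    elif denom == 0:
        qualifying = frozenset()
    else:
        qualifying = frozenset(g for g, c in counts.items() if c / denom > min_fraction)
    return CoverageSet(
        source_mirnas=mirnas,
        source_direction=direction,
        predicted_genes=counts,
        min_fraction=min_fraction,
        qualifying_genes=qualifying,
        denominator=denom,
    )


def map_ids(genes: Iterable[str], id_map: GeneIdMap) -> tuple[dict[str, int], list[str]]:
    """Resolve gene symbols to Entrez IDs; unmapped symbols are reported separately."""
    mapped: dict[str, int] = {}
    unmapped: list[str] = []
    for g in sorted(normalize_gene_id(x) for x in genes):
        eid = id_map.get(g)
        if eid is None:
            unmapped.append(g)
        else:
            mapped[g] = eid
    return mapped, unmapped


def _empty_coverage(direction: str, min_fraction: float) -> CoverageSet:
    return CoverageSet(
        source_mirnas=frozenset(),
        source_direction=direction,
        predicted_genes={},
        min_fraction=min_fraction,
        qualifying_genes=frozenset(),
        denominator=0,
    )


def _coverage_or_empty(mirnas, direction, table, min_fraction, **kw) -> CoverageSet:
    if not mirnas:
        return _empty_coverage(direction, min_fraction)
    return coverage_targets(mirnas, direction, table, min_fraction, **kw)


def integrate_candidates(
    mrna_de: DEResult,
    cell_mirna_de: DEResult,
    exo_mirna_de: DEResult,
    table: TargetTable,
    id_map: GeneIdMap,
    strategy: str = "common_mirna_first",
    *,
    min_fraction: float = 0.5,
    arm_fallback: bool = False,
    denominator: str = "all",
    union_mode: bool = False,
) -> CandidateSet:
    """Run the full integration graph and return the candidate biomarker genes."""
    if strategy not in STRATEGIES:
        raise ConfigError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    cov_kw = dict(arm_fallback=arm_fallback, denominator=denominator, union_mode=union_mode)

    mrna_up = frozenset(normalize_gene_id(g) for g in mrna_de.up_set)
    mrna_down = frozenset(normalize_gene_id(g) for g in mrna_de.down_set)
    mrna_up_ids, mrna_up_unmapped = map_ids(mrna_up, id_map)
    mrna_down_ids, mrna_down_unmapped = map_ids(mrna_down, id_map)

    cards: dict[str, int] = {
        "mrna_up": len(mrna_up),
        "mrna_down": len(mrna_down),
        "mrna_up_mapped": len(mrna_up_ids),
        "mrna_down_mapped": len(mrna_down_ids),
        "mirna_cell_up": len(cell_mirna_de.up_set),
        "mirna_cell_down": len(cell_mirna_de.down_set),
        "mirna_exo_up": len(exo_mirna_de.up_set),
        "mirna_exo_down": len(exo_mirna_de.down_set),
    }

    # coverage sets contributing to each candidate direction, keyed by label
    contrib_up: dict[str, CoverageSet] = {}
    contrib_down: dict[str, CoverageSet] = {}

    if strategy == "common_mirna_first":
        common_up, common_down = common_mirnas(cell_mirna_de, exo_mirna_de)
        cards["mirna_common_up"] = len(common_up)
        cards["mirna_common_down"] = len(common_down)
        contrib_up["common_down_mirnas"] = _coverage_or_empty(common_down, "down", table, min_fraction, **cov_kw)
        contrib_down["common_up_mirnas"] = _coverage_or_empty(common_up, "up", table, min_fraction, **cov_kw)
    else:
        contrib_up["cell_down_mirnas"] = _coverage_or_empty(cell_mirna_de.down_set, "down", table, min_fraction, **cov_kw)
        contrib_up["exo_down_mirnas"] = _coverage_or_empty(exo_mirna_de.down_set, "down", table, min_fraction, **cov_kw)
        contrib_down["cell_up_mirnas"] = _coverage_or_empty(cell_mirna_de.up_set, "up", table, min_fraction, **cov_kw)
        contrib_down["exo_up_mirnas"] = _coverage_or_empty(exo_mirna_de.up_set, "up", table, min_fraction, **cov_kw)

    def finish(direction: str, observed_ids: dict[str, int], contribs: dict[str, CoverageSet]):
        id_sets = [frozenset(observed_ids.values())]
        for label, cov in contribs.items():
            mapped, _ = map_ids(cov.qualifying_genes, id_map)
            cards[f"predicted_{direction}_{label}"] = len(cov.qualifying_genes)
            cards[f"predicted_{direction}_{label}_mapped"] = len(mapped)
            id_sets.append(frozenset(mapped.values()))
        common_ids = frozenset.intersection(*id_sets)
        genes = frozenset(g for g, i in observed_ids.items() if i in common_ids)
        cards[f"candidates_{direction}"] = len(genes)
        return genes

    up_genes = finish("up", mrna_up_ids, contrib_up)
    down_genes = finish("down", mrna_down_ids, contrib_down)

    rows = []
    for direction, genes, observed_ids, contribs in (
        ("up", up_genes, mrna_up_ids, contrib_up),
        ("down", down_genes, mrna_down_ids, contrib_down),
    ):
        for g in sorted(genes):
            row: dict[str, object] = {
                "gene": g,
                "entrez_id": observed_ids[g],
                "direction": direction,
                "in_mrna_de": True,
            }
            for label, cov in contribs.items():
                row[f"count_{label}"] = cov.predicted_genes.get(g, 0)
                row[f"denominator_{label}"] = cov.denominator
            rows.append(row)
    provenance = pd.DataFrame(rows)

    cards["unmapped_mrna_up"] = len(mrna_up_unmapped)
    cards["unmapped_mrna_down"] = len(mrna_down_unmapped)
    return CandidateSet(
        up_genes=up_genes,
        down_genes=down_genes,
        provenance=provenance,
        strategy=strategy,
        cardinalities=cards,
        id_map=id_map,
    )
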