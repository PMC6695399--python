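"""qPCR ddCt relative quantification and biomarker confirmation.

Relative expression follows the standard ddCt model with amplification
efficiency fixed at 2: dCt = Ct(gene) - Ct(reference) per replicate, relative
expression = 2^-dCt, and the between-group fold change is
2^(mean dCt_group1 - mean dCt_group2), so fold > 1 means higher expression
in substate 2.

A candidate is *confirmed* when its fold change passes the 1.5-fold filter in
the candidate's direction and an unpaired two-tailed t-test on per-replicate
relative expression gives p < 0.05.  Significance tiers (p < 0.1, < 0.05,
< 0.01) are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GROUP_1, GROUP_2, ConfigError, QpcrDataset, normalize_gene_id

if True:  # local import kept at bottom of dependency chain
    from .integration import CandidateSet


def delta_ct(data: QpcrDataset) -> dict[str, pd.DataFrame]:
    """Per-group genes x replicates dCt table: Ct(gene) - Ct(reference)."""
    out = {}
    for group, table in data.ct.items():
        ref = table.loc[data.reference_gene]
        out[group] = table - ref
    return out


def qpcr_fold_changes(dct: dict[str, pd.DataFrame]) -> pd.Series:
    """Per-gene fold change substate2 vs substate1: 2^(mean dCt_s1 - mean dCt_s2)."""
    for g in (GROUP_1, GROUP_2):
        if g not in dct:
            raise ConfigError(f"group {g!r} missing from dCt tables")
    m1 = dct[GROUP_1].mean(axis=1)
    m2 = dct[GROUP_2].mean(axis=1)
    fold = np.power(2.0, m1 - m2)
    fold.name = "fold"
    return fold


@dataclass
class QpcrResult:
    """Per-gene ddCt quantification and significance table.

    Columns: mean_dct_s1, mean_dct_s2, fold, log2_fold, p, tier.
    ``rel_expr[group]`` keeps the per-replicate relative expression (2^-dCt)
    the t-test was computed on.
    """

    table: pd.DataFrame
    rel_expr: dict[str, pd.DataFrame]
    reference_gene: str
    test_scale: str = "expression"


def quantify(data: QpcrDataset, *, test_scale: str = "expression", tiers=(0.1, 0.05, 0.01)) -> QpcrResult:
    """ddCt quantification plus an unpaired two-tailed t-test per gene.

    ``test_scale='expression'`` (default) tests per-replicate 2^-dCt values;
    ``'dct'`` tests the dCt values directly.
    """
    if test_scale not in ("expression", "dct"):
        raise ConfigError(f"unknown test_scale {test_scale!r}")
    tiers = tuple(sorted(tiers, reverse=True))
    dct = delta_ct(data)
    rel = {g: np.power(2.0, -t) for g, t in dct.items()}
    fold = qpcr_fold_changes(dct)

    rows = {}
    for gene in dct[GROUP_1].index:
        a = (rel if test_scale == "expression" else dct)[GROUP_1].loc[gene].to_numpy(dtype=float)
        b = (rel if test_scale == "expression" else dct)[GROUP_2].loc[gene].to_numpy(dtype=float)
        if gene == data.reference_gene or (np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]):
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        rows[gene] = p
    p_series = pd.Series(rows, name="p")

    def tier_of(p: float) -> str:
        label = "ns"
        for cut in tiers:
            if p < cut:
                label = f"p<{cut:g}"
        return label

    table = pd.DataFrame(
        {
            "mean_dct_s1": dct[GROUP_1].mean(axis=1),
            "mean_dct_s2": dct[GROUP_2].mean(axis=1),
            "fold": fold,
            "log2_fold": np.log2(fold),
            "p": p_series,
            "tier": p_series.map(tier_of),
        }
    )
    table = table.drop(index=data.reference_gene)
    return QpcrResult(table=table, rel_expr=rel, reference_gene=data.reference_gene, test_scale=test_scale)


def confirm_candidates(
    result: QpcrResult,
    candidates: "CandidateSet",
    fold_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Confirmation table for each candidate gene.

    A candidate is confirmed when |log2 fold| >= log2(fold_threshold) with the
    fold in the candidate's direction AND p < p_threshold.  Candidates without
    qPCR measurements are flagged ``untested`` rather than failed.
    """
    if fold_threshold < 1:
        raise ConfigError("fold_threshold must be >= 1")
    cut = np.log2(fold_threshold)
    rows = []
    for direction, genes in (("up", candidates.up_genes), ("down", candidates.down_genes)):
        for gene in sorted(normalize_gene_id(g) for g in genes):
            if gene not in result.table.index:
                rows.append(
                    {
                        "gene": gene,
                        "direction": direction,
                        "fold": np.nan,
                        "p": np.nan,
                        "tier": "untested",
                        "status": "untested",
                        "confirmed": False,
                    }
                )
                continue
            rec = result.table.loc[gene]
            direction_ok = rec["log2_fold"] >= cut if direction == "up" else rec["log2_fold"] <= -cut
            confirmed = bool(direction_ok and rec["p"] < p_threshold)
            rows.append(
                {
                    "gene": gene,
                    "direction": direction,
                    "fold": float(rec["fold"]),
                    "p": float(rec["p"]),
                    "tier": rec["tier"],
                    "status": "tested",
                    "confirmed": confirmed,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene", "direction", "fold", "p", "tier", "status", "confirmed"]
    )
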