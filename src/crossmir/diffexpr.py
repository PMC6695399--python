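"""Differential expression: Z-score selection for mRNA, fold + paired-t + FDR for miRNA.

Two deliberately different procedures, matching common microarray practice
for the two assays:

* mRNA chips (one chip per group in the motivating design) are compared by
  the Z-score of the per-feature log2 fold change against the distribution
  of log2 fold changes across all features: z_i = (fc_i - mean(fc)) / sd(fc),
  with features called up/down at |z| >= z_threshold (default 2).

* miRNA chips (paired replicates) are first filtered to features with at
  least a 2-fold mean difference, then tested with a two-sided paired t-test
  on log2 signals, with Benjamini-Hochberg correction applied within the
  fold-passing subset; features are called at q < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import GROUP_1, GROUP_2, ConfigError, ExpressionMatrix, StateError


@dataclass
class DEResult:
    """Per-feature differential-expression table plus the thresholds used.

    ``table`` columns: mean_log2_s1, mean_log2_s2, log2fc, and depending on
    the branch z (mRNA) or t_stat/p/q (miRNA); ``call`` is up/down/neither.
    """

    table: pd.DataFrame
    thresholds: dict = field(default_factory=dict)
    assay: str = "mRNA"

    def __post_init__(self) -> None:
        if not self.table["call"].isin(["up", "down", "neither"]).all():
            raise ValueError("invalid call values")

    @property
    def up_set(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["call"] == "up"].astype(str))

    @property
    def down_set(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["call"] == "down"].astype(str))

    def summary(self) -> dict:
        return {
            "assay": self.assay,
            "n_features": int(len(self.table)),
            "n_up": len(self.up_set),
            "n_down": len(self.down_set),
            **{k: (v if not isinstance(v, float) else float(v)) for k, v in self.thresholds.items()},
        }


def group_mean_log2(matrix: ExpressionMatrix, group: str) -> pd.Series:
    if not matrix.is_log2:
        raise StateError("expected a normalized (log2) matrix")
    return matrix.group_signals(group).mean(axis=1)


def log2_fold_changes(matrix: ExpressionMatrix) -> pd.Series:
    """Per-feature log2 fold change, substate 2 minus substate 1 (log2 units)."""
    m1 = group_mean_log2(matrix, GROUP_1)
    m2 = group_mean_log2(matrix, GROUP_2)
    fc = m2 - m1
    fc.name = "log2fc"
    return fc


def zscore_select(
    log2fcs: pd.Series,
    z_threshold: float = 2.0,
    *,
    centered: bool = True,
    group_means: tuple[pd.Series, pd.Series] | None = None,
    assay: str = "mRNA",
) -> DEResult:
    """Call features whose standardized log2 fold change exceeds ``z_threshold``.

    z_i = (fc_i - mean(fc)) / sd(fc) with the sample standard deviation
    (n-1 denominator); ``centered=False`` skips the mean subtraction.
    """
    fc = np.asarray(log2fcs, dtype=float)
    if fc.size < 3:
        raise ConfigError("Z-score selection needs at least 3 features")
    if not np.isfinite(fc).all():
        raise ConfigError("non-finite log2 fold changes")
    if z_threshold <= 0:
        raise ConfigError("z_threshold must be > 0")
    center = fc.mean() if centered else 0.0
    sd = fc.std(ddof=1)
    if sd == 0:
        raise StateError("log2 fold-change distribution is degenerate (sd = 0)")
    z = (fc - center) / sd
    call = np.where(z >= z_threshold, "up", np.where(z <= -z_threshold, "down", "neither"))
    table = pd.DataFrame({"log2fc": fc, "z": z, "call": call}, index=log2fcs.index)
    if group_means is not None:
        table.insert(0, "mean_log2_s1", group_means[0])
        table.insert(1, "mean_log2_s2", group_means[1])
    thresholds = {
        "z_threshold": float(z_threshold),
        "centered": centered,
        "fc_mean": float(center),
        "fc_sd": float(sd),
    }
    return DEResult(table=table, thresholds=thresholds, assay=assay)


def mrna_de(matrix: ExpressionMatrix, z_threshold: float = 2.0, *, centered: bool = True) -> DEResult:
    """Z-score differential expression on a normalized mRNA matrix."""
    m1 = group_mean_log2(matrix, GROUP_1)
    m2 = group_mean_log2(matrix, GROUP_2)
    return zscore_select(
        m2 - m1, z_threshold, centered=centered, group_means=(m1, m2), assay="mRNA"
    )


def paired_ttest(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Two-sided paired t-test per feature on log2 signals (substate2 - substate1).

    Degenerate features are handled explicitly: all-zero differences give
    p = 1; zero-variance nonzero-mean differences give a p = 0 sentinel with
    a warning (the statistic is infinite).
    """
    pairs = matrix.paired_columns()
    if len(pairs) < 2:
        raise StateError("paired t-test needs at least 2 replicate pairs")
    s1 = matrix.signals[[a for a, _ in pairs]].to_numpy(dtype=float)
    s2 = matrix.signals[[b for _, b in pairs]].to_numpy(dtype=float)
    diffs = s2 - s1
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    t = np.full(len(mean), np.nan)
    p = np.ones(len(mean))
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    degenerate = (~ok) & (mean != 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) with zero-variance nonzero-mean paired "
            "differences; reporting p = 0 sentinel",
            RuntimeWarning,
            stacklevel=2,
        )
        t[degenerate] = np.inf * np.sign(mean[degenerate])
        p[degenerate] = 0.0
    return pd.DataFrame({"t_stat": t, "p": p}, index=matrix.signals.index)


def bh_fdr(p_values, *, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, in [0, 1]).

    ``method='bonferroni'`` switches to Bonferroni-adjusted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ConfigError("p-values must lie in [0, 1]")
    if method not in ("fdr_bh", "bonferroni"):
        raise ConfigError(f"unknown correction method {method!r}")
    return multipletests(p, method=method)[1]


def mirna_de(
    matrix: ExpressionMatrix,
    fold_threshold: float = 2.0,
    q_threshold: float = 0.05,
    *,
    fdr_scope: str = "subset",
    correction: str = "fdr_bh",
    assay: str = "miRNA",
) -> DEResult:
    """Fold-change + paired-t + FDR differential expression for miRNA chips.

    Features with |log2FC| >= log2(fold_threshold) enter testing; the paired
    t-test and the multiple-testing correction are applied within that subset
    (``fdr_scope='all'`` corrects over all features instead).  Calls require
    q < q_threshold with the sign of the fold change.
    """
    if fold_threshold < 1:
        raise ConfigError("fold_threshold must be >= 1")
    if not (0 < q_threshold < 1):
        raise ConfigError("q_threshold must be in (0, 1)")
    if fdr_scope not in ("subset", "all"):
        raise ConfigError(f"unknown fdr_scope {fdr_scope!r}")
    m1 = group_mean_log2(matrix, GROUP_1)
    m2 = group_mean_log2(matrix, GROUP_2)
    fc = m2 - m1
    cut = np.log2(fold_threshold)
    passing = fc.abs() >= cut

    table = pd.DataFrame(
        {
            "mean_log2_s1": m1,
            "mean_log2_s2": m2,
            "log2fc": fc,
            "t_stat": np.nan,
            "p": np.nan,
            "q": np.nan,
            "call": "neither",
        }
    )
    if fdr_scope == "all":
        tt = paired_ttest(matrix)
        table["t_stat"], table["p"] = tt["t_stat"], tt["p"]
        table["q"] = bh_fdr(table["p"].to_numpy(), method=correction)
    elif passing.any():
        sub = matrix.with_signals(matrix.signals.loc[passing])
        tt = paired_ttest(sub)
        table.loc[passing, "t_stat"] = tt["t_stat"]
        table.loc[passing, "p"] = tt["p"]
        table.loc[passing, "q"] = bh_fdr(tt["p"].to_numpy(), method=correction)
    else:
        warnings.warn("no features pass the fold-change filter", RuntimeWarning, stacklevel=2)

    sig = passing & (table["q"] < q_threshold)
    table.loc[sig & (fc > 0), "call"] = "up"
    table.loc[sig & (fc < 0), "call"] = "down"
    thresholds = {
        "fold_threshold": float(fold_threshold),
        "q_threshold": float(q_threshold),
        "fdr_scope": fdr_scope,
        "correction": correction,
    }
    return DEResult(table=table, thresholds=thresholds, assay=assay)
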