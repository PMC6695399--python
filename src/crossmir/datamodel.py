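"""Domain types shared by every stage of the pipeline.

Expression data live in an :class:`ExpressionMatrix` (a features x samples
:class:`pandas.DataFrame` plus per-sample metadata).  miRNA target
predictions, gene-symbol -> Entrez mappings, and qPCR Ct tables get small
dedicated containers with validation at construction time.

Identifier hygiene is centralized here: gene symbols are upper-cased and
miRNA identifiers are lower-cased with the conventional ``miR`` capitalization
restored, so that set operations over lists produced by different tools never
miss on case.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GROUP_1 = "substate1"
GROUP_2 = "substate2"
GROUPS = (GROUP_1, GROUP_2)
COMPARTMENTS = ("cell", "exosome", "none")
ASSAYS = ("mRNA", "miRNA")


class PipelineError(Exception):
    """Base class for all errors raised by crossmir."""


class FormatError(PipelineError):
    """An input table violates its documented format."""


class StateError(PipelineError):
    """An operation was applied to data in the wrong state (e.g. re-normalization)."""


class ConfigError(PipelineError):
    """A configuration value is missing, contradictory, or infeasible."""


def normalize_gene_id(symbol: str) -> str:
    """Case-normalize a gene symbol (upper case, stripped)."""
    return symbol.strip().upper()


_MIR_SEG = re.compile(r"(^|-)mir(?=-|$)")


def normalize_mirna_id(mirna: str) -> str:
    """Case-normalize a miRNA identifier.

    Lower-cases the identifier and restores the conventional ``miR``
    capitalization of the mature-miRNA segment (``let`` stays lower case),
    so ``HSA-MIR-21-5P`` and ``hsa-miR-21-5p`` compare equal.
    """
    low = mirna.strip().lower()
    return _MIR_SEG.sub(lambda m: m.group(1) + "miR", low)


def strip_arm_suffix(mirna: str) -> str:
    """Drop a trailing ``-5p``/``-3p`` arm suffix if present."""
    return re.sub(r"-[35]p$", "", mirna)


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for a single array (chip) or qPCR sample."""

    name: str
    group: str
    replicate_index: int
    compartment: str = "none"
    assay: str = "mRNA"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.compartment not in COMPARTMENTS:
            raise ConfigError(f"unknown compartment {self.compartment!r}")
        if self.assay not in ASSAYS:
            raise ConfigError(f"unknown assay {self.assay!r}")
        if self.replicate_index < 1:
            raise ConfigError("replicate_index must be a positive integer")


@dataclass
class ExpressionMatrix:
    """A features x samples signal table with per-sample metadata.

    ``signals`` is linear-scale fluorescence unless ``is_log2`` is set.
    Column order of ``signals`` matches the order of ``samples``.
    """

    signals: pd.DataFrame
    samples: list[SampleInfo]
    is_log2: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.signals.shape[1] != len(self.samples):
            raise FormatError(
                f"signal table has {self.signals.shape[1]} columns but "
                f"{len(self.samples)} sample records"
            )
        names = [s.name for s in self.samples]
        if list(self.signals.columns) != names:
            raise FormatError("signal columns do not match sample metadata order")
        if len(set(names)) != len(names):
            raise FormatError("duplicate sample names")
        norm_ids = [str(f).strip().upper() for f in self.signals.index]
        dup = _first_duplicate(norm_ids)
        if dup is not None:
            raise FormatError(f"duplicate feature ID {dup!r} (after case normalization)")
        if self.signals.shape[0] == 0:
            raise FormatError("no features")
        values = self.signals.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric signal values")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise FormatError(
                f"missing value at feature {self.signals.index[r]!r}, "
                f"sample {self.signals.columns[c]!r} (imputation is not supported)"
            )
        if not self.is_log2 and (values < 0).any():
            raise FormatError("negative signals in a linear-scale matrix")
        for group in self.groups():
            idx = [s.replicate_index for s in self.samples if s.group == group]
            if len(set(idx)) != len(idx):
                raise FormatError(f"replicate indices within group {group!r} are not unique")

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.signals.index]

    @property
    def n_features(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def sample_names(self, group: str | None = None) -> list[str]:
        return [s.name for s in self.samples if group is None or s.group == group]

    def group_signals(self, group: str) -> pd.DataFrame:
        cols = self.sample_names(group)
        if not cols:
            raise StateError(f"group {group!r} has no samples")
        return self.signals[cols]

    def paired_columns(self) -> list[tuple[str, str]]:
        """(substate1, substate2) sample-name pairs matched on replicate_index."""
        by_rep: dict[str, dict[int, str]] = {g: {} for g in GROUPS}
        for s in self.samples:
            by_rep[s.group][s.replicate_index] = s.name
        if set(by_rep[GROUP_1]) != set(by_rep[GROUP_2]):
            raise StateError(
                "samples are not pairable: replicate indices differ between groups "
                f"({sorted(by_rep[GROUP_1])} vs {sorted(by_rep[GROUP_2])})"
            )
        return [(by_rep[GROUP_1][i], by_rep[GROUP_2][i]) for i in sorted(by_rep[GROUP_1])]

    def with_signals(self, signals: pd.DataFrame, **flags) -> "ExpressionMatrix":
        kw = dict(is_log2=self.is_log2, normalized=self.normalized)
        kw.update(flags)
        return ExpressionMatrix(signals=signals, samples=list(self.samples), **kw)

    def swap_groups(self) -> "ExpressionMatrix":
        """Relabel substate1 <-> substate2 (used for symmetry checks)."""
        flip = {GROUP_1: GROUP_2, GROUP_2: GROUP_1}
        samples = [
            SampleInfo(s.name, flip[s.group], s.replicate_index, s.compartment, s.assay)
            for s in self.samples
        ]
        out = ExpressionMatrix.__new__(ExpressionMatrix)
        out.signals = self.signals
        out.samples = samples
        out.is_log2 = self.is_log2
        out.normalized = self.normalized
        out.validate()
        return out


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


@dataclass
class TargetTable:
    """Mapping miRNA identifier -> set of predicted target gene symbols."""

    entries: dict[str, frozenset[str]]
    dialect: str = "two_column"

    def __post_init__(self) -> None:
        norm: dict[str, frozenset[str]] = {}
        for mirna, genes in self.entries.items():
            key = normalize_mirna_id(mirna)
            gset = frozenset(normalize_gene_id(g) for g in genes)
            if not gset:
                raise FormatError(f"miRNA {mirna!r} has an empty target set")
            if key in norm:
                gset = norm[key] | gset
            norm[key] = gset
        self.entries = norm

    def targets_of(self, mirna: str, *, arm_fallback: bool = False) -> frozenset[str]:
        """Target set for ``mirna`` (empty if absent from the table).

        With ``arm_fallback`` the ``-5p``/``-3p`` suffix is stripped and
        retried when the exact normalized identifier has no entry.
        """
        key = normalize_mirna_id(mirna)
        if key in self.entries:
            return self.entries[key]
        if arm_fallback:
            stem = strip_arm_suffix(key)
            if stem != key and stem in self.entries:
                return self.entries[stem]
        return frozenset()

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class GeneIdMap:
    """Gene symbol -> Entrez ID mapping with an explicit unmapped set."""

    entries: dict[str, int]
    unmapped: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        norm: dict[str, int] = {}
        for sym, eid in self.entries.items():
            key = normalize_gene_id(sym)
            eid = int(eid)
            if eid <= 0:
                raise FormatError(f"Entrez ID for {sym!r} must be a positive integer, got {eid}")
            if key in norm and norm[key] != eid:
                raise FormatError(f"gene symbol {sym!r} maps to two distinct IDs ({norm[key]}, {eid})")
            norm[key] = eid
        self.entries = norm
        self.unmapped = frozenset(normalize_gene_id(s) for s in self.unmapped) - set(norm)

    def get(self, symbol: str) -> int | None:
        return self.entries.get(normalize_gene_id(symbol))

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class QpcrDataset:
    """Ct values (cycles) per gene, replicate, and group, plus the reference gene.

    ``ct[group]`` is a genes x replicates DataFrame; the reference gene
    (GAPDH in the motivating study) must be present in every group.
    """

    ct: Mapping[str, pd.DataFrame]
    reference_gene: str

    def __post_init__(self) -> None:
        self.reference_gene = normalize_gene_id(self.reference_gene)
        ct = {}
        for group, table in self.ct.items():
            if group not in GROUPS:
                raise ConfigError(f"unknown qPCR group {group!r}")
            table = table.copy()
            table.index = [normalize_gene_id(str(g)) for g in table.index]
            vals = table.to_numpy(dtype=float)
            if np.isnan(vals).any() or np.isinf(vals).any():
                raise FormatError(f"non-finite Ct value in group {group!r}")
            if (vals <= 0).any() or (vals > 45).any():
                raise FormatError(f"Ct values in group {group!r} outside (0, 45]")
            if self.reference_gene not in table.index:
                raise FormatError(
                    f"reference gene {self.reference_gene!r} missing from group {group!r}"
                )
            ct[group] = table
        if set(ct) != set(GROUPS):
            raise ConfigError(f"qPCR dataset must contain both groups {GROUPS}")
        self.ct = ct

    @property
    def genes(self) -> list[str]:
        return [g for g in self.ct[GROUP_1].index if g != self.reference_gene]
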