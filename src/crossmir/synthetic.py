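"""Synthetic two-substate microarray studies with recorded planted truth.

The generator emulates the statistical structure the analysis assumes:

* log-normal chip signals — per-feature baseline log2 levels drawn from a
  normal distribution, per-replicate log2 noise, and a hard detection floor
  once signals are linearized;
* paired replicate chips — replicate i of substate 1 shares a per-pair,
  per-feature batch offset with replicate i of substate 2, which a paired
  test removes and an unpaired test pays for as extra variance;
* planted two-fold (or larger) effects on chosen subsets of mRNAs and
  miRNAs, with the substate-2 group shifted by +/- ``effect_log2fc``;
* partial sharing of DE miRNAs between the cell and exosome compartments;
* a target table in which the planted *down* miRNAs collectively cover each
  planted biomarker *up* gene above the coverage threshold (and symmetrically
  for down biomarkers), while decoy miRNAs spread random targets over
  non-DE genes so the coverage filter has something to reject;
* a qPCR panel over the planted biomarker genes whose dCt values encode the
  same planted effects, against a constant reference gene.

All randomness flows from one integer seed through a single
``numpy.random.Generator`` (PCG64), so a given configuration is bit-identical
across runs and platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    GROUP_1,
    GROUP_2,
    ConfigError,
    ExpressionMatrix,
    GeneIdMap,
    QpcrDataset,
    SampleInfo,
    TargetTable,
)

REFERENCE_GENE = "GAPDH"


@dataclass(frozen=True)
class SyntheticConfig:
    """Data-generating parameters for one synthetic study.

    Defaults describe a realistic small two-colorless (single-channel) design:
    2000 genes and 300 miRNAs on 3 paired chips per substate, four-fold
    dynamic-range baseline spread, 2-fold planted effects, and quarter-log2
    replicate noise.
    """

    n_genes: int = 2000
    n_mirnas: int = 300
    replicates_per_group: int = 3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    noise_sd: float = 0.25
    effect_log2fc: float = 2.0
    n_de_genes_up: int = 100
    n_de_genes_down: int = 100
    n_de_mirnas_up: int = 30
    n_de_mirnas_down: int = 30
    compartment_share_fraction: float = 0.5
    targets_per_mirna: int = 25
    biomarker_coverage: float = 0.6
    n_biomarkers_up: int = 14
    n_biomarkers_down: int = 1
    qpcr_ct_sd: float = 0.15
    seed: int = 0
    generator: str = "PCG64"

    def validate(self) -> None:
        c = self
        if min(c.n_genes, c.n_mirnas, c.replicates_per_group) < 1:
            raise ConfigError("n_genes, n_mirnas and replicates_per_group must be >= 1")
        if c.noise_sd <= 0 or c.qpcr_ct_sd <= 0:
            raise ConfigError("noise_sd and qpcr_ct_sd must be > 0")
        if c.n_de_genes_up + c.n_de_genes_down > c.n_genes:
            raise ConfigError("planted DE genes exceed n_genes")
        if c.n_de_mirnas_up + c.n_de_mirnas_down > c.n_mirnas:
            raise ConfigError("planted DE miRNAs exceed n_mirnas")
        if not (0 <= c.compartment_share_fraction <= 1):
            raise ConfigError("compartment_share_fraction must be in [0, 1]")
        if not (0 <= c.biomarker_coverage <= 1):
            raise ConfigError("biomarker_coverage must be in [0, 1]")
        if c.n_biomarkers_up > c.n_de_genes_up or c.n_biomarkers_down > c.n_de_genes_down:
            raise ConfigError("biomarker genes must be a subset of planted DE genes")
        if c.n_biomarkers_up > 0 and c.n_de_mirnas_down == 0:
            raise ConfigError("up biomarkers need planted down miRNAs to be targeted by")
        if c.n_biomarkers_down > 0 and c.n_de_mirnas_up == 0:
            raise ConfigError("down biomarkers need planted up miRNAs to be targeted by")
        n_decoy_genes = c.n_genes - c.n_de_genes_up - c.n_de_genes_down
        if c.targets_per_mirna > max(n_decoy_genes, 0):
            raise ConfigError(
                "targets_per_mirna exceeds the number of non-DE genes available as decoy targets"
            )


@dataclass(frozen=True)
class SyntheticTruth:
    """The planted features a recovery experiment is scored against."""

    de_genes_up: frozenset[str]
    de_genes_down: frozenset[str]
    de_mirnas_up: dict[str, frozenset[str]]  # per compartment
    de_mirnas_down: dict[str, frozenset[str]]
    biomarker_genes_up: frozenset[str]
    biomarker_genes_down: frozenset[str]
    seed: int
    generator: str = "PCG64"

    def validate(self) -> None:
        if not self.biomarker_genes_up <= self.de_genes_up:
            raise ConfigError("biomarker up genes must be planted DE up genes")
        if not self.biomarker_genes_down <= self.de_genes_down:
            raise ConfigError("biomarker down genes must be planted DE down genes")


def _gene_names(n: int) -> list[str]:
    return [f"GENE{i + 1:04d}" for i in range(n)]


def _mirna_names(n: int) -> list[str]:
    # alternate mature arms, as real miRBase lists do
    return [f"hsa-miR-{5000 + i}-{'5p' if i % 2 == 0 else '3p'}" for i in range(n)]


def _split_shared(ids: list[str], fraction: float) -> tuple[list[str], list[str], list[str]]:
    """Split a planted DE miRNA list into (shared, cell-private, exosome-private)."""
    n_shared = round(fraction * len(ids))
    shared = ids[:n_shared]
    rest = ids[n_shared:]
    half = (len(rest) + 1) // 2
    return shared, rest[:half], rest[half:]


def _expression_matrix(
    rng: np.random.Generator,
    features: list[str],
    effects: dict[str, float],
    cfg: SyntheticConfig,
    compartment: str,
    assay: str,
) -> ExpressionMatrix:
    n_feat, n_rep = len(features), cfg.replicates_per_group
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n_feat)
    eff = np.array([effects.get(f, 0.0) for f in features])
    # Percentile-shift normalization assumes the chip's upper tail is stable
    # between groups: the anchor percentile is carried by invariant
    # high-expressed features.  DE features are therefore drawn from the
    # central bulk (baseline truncated at +1 sd) so a planted shift never
    # displaces the anchor, mirroring real arrays where differential miRNAs
    # are mid-abundance rather than the top-expressed species.
    de_mask = eff != 0.0
    if de_mask.any():
        from scipy.stats import norm

        u = rng.uniform(0.0, norm.cdf(1.0), size=int(de_mask.sum()))
        baseline[de_mask] = cfg.baseline_log2_mean + cfg.baseline_log2_sd * norm.ppf(u)
    pair_offset = rng.normal(0.0, cfg.noise_sd, size=(n_feat, n_rep))

    log2 = np.empty((n_feat, 2 * n_rep))
    samples = []
    col = 0
    for group in (GROUP_1, GROUP_2):
        for rep in range(n_rep):
            noise = rng.normal(0.0, cfg.noise_sd, size=n_feat)
            shift = eff if group == GROUP_2 else 0.0
            log2[:, col] = baseline + pair_offset[:, rep] + shift + noise
            samples.append(
                SampleInfo(
                    name=f"{compartment}_{assay}_{group}_r{rep + 1}",
                    group=group,
                    replicate_index=rep + 1,
                    compartment=compartment,
                    assay=assay,
                )
            )
            col += 1
    signals = pd.DataFrame(
        np.power(2.0, log2), index=pd.Index(features, name="feature"), columns=[s.name for s in samples]
    )
    return ExpressionMatrix(signals=signals, samples=samples, is_log2=False)


def _stratified_pick(rng: np.random.Generator, strata: list[list[str]], fraction: float) -> list[str]:
    """Pick >= fraction of each stratum (ceil), randomly within the stratum."""
    chosen: list[str] = []
    for stratum in strata:
        if not stratum:
            continue
        k = min(len(stratum), math.ceil(fraction * len(stratum)))
        idx = rng.choice(len(stratum), size=k, replace=False)
        chosen.extend(stratum[i] for i in sorted(idx))
    return chosen


def _build_target_table(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    mirnas: list[str],
    genes: list[str],
    up_strata: list[list[str]],
    down_strata: list[list[str]],
    biomarkers_up: list[str],
    biomarkers_down: list[str],
    decoy_genes: list[str],
) -> TargetTable:
    """Targets: planted coverage of biomarkers + random decoy targets.

    Each biomarker-up gene is targeted by at least ``biomarker_coverage`` of
    every stratum (shared / cell-private / exosome-private) of the planted
    *down* miRNAs, so its coverage clears the filter whichever miRNA set the
    integration strategy predicts from.  Symmetric for biomarker-down genes
    and the planted *up* miRNAs.  Every miRNA is then padded with random
    non-DE decoy genes up to ``targets_per_mirna``.
    """
    targets: dict[str, set[str]] = {m: set() for m in mirnas}
    for gene, strata in [(g, down_strata) for g in biomarkers_up] + [
        (g, up_strata) for g in biomarkers_down
    ]:
        for m in _stratified_pick(rng, strata, cfg.biomarker_coverage):
            targets[m].add(gene)
    decoys = np.array(decoy_genes)
    for m in mirnas:
        need = cfg.targets_per_mirna - len(targets[m])
        if need > 0 and len(decoys):
            idx = rng.choice(len(decoys), size=min(need, len(decoys)), replace=False)
            targets[m].update(decoys[i] for i in sorted(idx))
    entries = {m: frozenset(t) for m, t in targets.items() if t}
    return TargetTable(entries=entries, dialect="two_column")


def _build_qpcr(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    panel: list[str],
    effects: dict[str, float],
) -> QpcrDataset:
    """Ct tables whose dCt shifts encode the planted log2 effects.

    A gene with planted effect e has its substate-2 Ct lowered by e cycles
    (one cycle per doubling at efficiency 2); the reference gene is stable.
    """
    genes = panel + [REFERENCE_GENE]
    n_rep = cfg.replicates_per_group
    base_ct = {g: rng.uniform(22.0, 28.0) for g in panel}
    base_ct[REFERENCE_GENE] = 18.0
    ct = {}
    for group in (GROUP_1, GROUP_2):
        values = np.empty((len(genes), n_rep))
        for i, g in enumerate(genes):
            shift = -effects.get(g, 0.0) if group == GROUP_2 else 0.0
            values[i] = base_ct[g] + shift + rng.normal(0.0, cfg.qpcr_ct_sd, size=n_rep)
        ct[group] = pd.DataFrame(
            np.clip(values, 1.0, 45.0),
            index=genes,
            columns=[f"{group}_r{r + 1}" for r in range(n_rep)],
        )
    return QpcrDataset(ct=ct, reference_gene=REFERENCE_GENE)


def generate_study(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix, TargetTable, GeneIdMap, QpcrDataset, SyntheticTruth]:
    """Generate one synthetic study.

    Returns (mRNA cell matrix, miRNA cell matrix, miRNA exosome matrix,
    target table, gene ID map, qPCR dataset, planted truth).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _gene_names(config.n_genes)
    mirnas = _mirna_names(config.n_mirnas)

    genes_up = genes[: config.n_de_genes_up]
    genes_down = genes[config.n_de_genes_up : config.n_de_genes_up + config.n_de_genes_down]
    decoy_genes = genes[config.n_de_genes_up + config.n_de_genes_down :]
    biomarkers_up = genes_up[: config.n_biomarkers_up]
    biomarkers_down = genes_down[: config.n_biomarkers_down]

    mirnas_up = mirnas[: config.n_de_mirnas_up]
    mirnas_down = mirnas[config.n_de_mirnas_up : config.n_de_mirnas_up + config.n_de_mirnas_down]
    up_shared, up_cell, up_exo = _split_shared(mirnas_up, config.compartment_share_fraction)
    down_shared, down_cell, down_exo = _split_shared(mirnas_down, config.compartment_share_fraction)

    e = config.effect_log2fc
    gene_effects = {g: e for g in genes_up} | {g: -e for g in genes_down}
    mirna_effects = {
        "cell": {m: e for m in up_shared + up_cell} | {m: -e for m in down_shared + down_cell},
        "exosome": {m: e for m in up_shared + up_exo} | {m: -e for m in down_shared + down_exo},
    }

    mrna_cell = _expression_matrix(rng, genes, gene_effects, config, "cell", "mRNA")
    mirna_cell = _expression_matrix(rng, mirnas, mirna_effects["cell"], config, "cell", "miRNA")
    mirna_exo = _expression_matrix(rng, mirnas, mirna_effects["exosome"], config, "exosome", "miRNA")

    table = _build_target_table(
        rng,
        config,
        mirnas,
        genes,
        up_strata=[up_shared, up_cell, up_exo],
        down_strata=[down_shared, down_cell, down_exo],
        biomarkers_up=biomarkers_up,
        biomarkers_down=biomarkers_down,
        decoy_genes=decoy_genes,
    )
    id_map = GeneIdMap(entries={g: 100000 + i for i, g in enumerate(genes)})
    qpcr = _build_qpcr(rng, config, biomarkers_up + biomarkers_down, gene_effects)

    truth = SyntheticTruth(
        de_genes_up=frozenset(genes_up),
        de_genes_down=frozenset(genes_down),
        de_mirnas_up={
            "cell": frozenset(up_shared + up_cell),
            "exosome": frozenset(up_shared + up_exo),
        },
        de_mirnas_down={
            "cell": frozenset(down_shared + down_cell),
            "exosome": frozenset(down_shared + down_exo),
        },
        biomarker_genes_up=frozenset(biomarkers_up),
        biomarker_genes_down=frozenset(biomarkers_down),
        seed=config.seed,
        generator=config.generator,
    )
    truth.validate()
    return mrna_cell, mirna_cell, mirna_exo, table, id_map, qpcr, truth


def generate_null_study(config: SyntheticConfig):
    """A study with all effect sizes forced to zero and empty truth sets.

    The same number of features, chips, and target-table rows are produced
    (targets become pure decoys), so downstream error rates are measured
    under the null without changing the data layout.
    """
    config.validate()
    null_cfg = replace(
        config,
        effect_log2fc=0.0,
        n_de_genes_up=0,
        n_de_genes_down=0,
        n_de_mirnas_up=0,
        n_de_mirnas_down=0,
        n_biomarkers_up=0,
        n_biomarkers_down=0,
        targets_per_mirna=min(config.targets_per_mirna, config.n_genes),
    )
    return generate_study(null_cfg)
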