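"""Coverage-filtered target prediction and cross-compartment integration."""

import numpy as np
import pandas as pd
import pytest

from crossmir.datamodel import ConfigError, GeneIdMap, TargetTable
from crossmir.diffexpr import DEResult
from crossmir.integration import (
    CandidateSet,
    common_mirnas,
    coverage_targets,
    integrate_candidates,
    map_ids,
)


def de_from_sets(up=(), down=(), universe=None, assay="miRNA"):
    """Build a minimal DEResult with the given up/down calls."""
    universe = list(universe) if universe else sorted(set(up) | set(down))
    call = ["up" if f in set(up) else "down" if f in set(down) else "neither" for f in universe]
    table = pd.DataFrame({"log2fc": 0.0, "call": call}, index=universe)
    return DEResult(table=table, thresholds={}, assay=assay)


class TestCommonMirnas:
    def test_direction_stratified_intersection(self):
        cell = de_from_sets(up=["miR-a", "miR-b", "miR-c"], down=["miR-x"])
        exo = de_from_sets(up=["miR-b", "miR-c", "miR-d"], down=["miR-y"])
        up, down = common_mirnas(cell, exo)
        assert up == {"miR-b", "miR-c"} and down == frozenset()

    def test_disjoint_sets_empty(self):
        up, down = common_mirnas(de_from_sets(up=["miR-a"]), de_from_sets(up=["miR-b"]))
        assert up == frozenset() and down == frozenset()

    def test_opposite_directions_never_common(self):
        cell = de_from_sets(up=["miR-a"])
        exo = de_from_sets(down=["miR-a"])
        up, down = common_mirnas(cell, exo)
        assert up == frozenset() and down == frozenset()

    def test_case_normalization_applied(self):
        up, _ = common_mirnas(de_from_sets(up=["HSA-MIR-21-5P"]), de_from_sets(up=["hsa-miR-21-5p"]))
        assert up == {"hsa-miR-21-5p"}


class TestCoverageTargets:
    def test_two_of_three_qualifies(self):
        t = TargetTable(entries={"miR-1": {"G"}, "miR-2": {"G"}, "miR-3": {"H"}})
        cov = coverage_targets(["miR-1", "miR-2", "miR-3"], "down", t)
        assert "G" in cov.qualifying_genes and "H" not in cov.qualifying_genes
        assert cov.predicted_direction == "up"

    def test_exactly_half_excluded_strict_boundary(self):
        t = TargetTable(entries={"miR-1": {"H"}, "miR-2": {"H"}, "miR-3": {"X"}, "miR-4": {"X"}})
        cov = coverage_targets(["miR-1", "miR-2", "miR-3", "miR-4"], "up", t)
        assert cov.qualifying_genes == frozenset()  # 2/4 = 0.5 is not > 0.5

    def test_empty_mirna_set_rejected(self):
        with pytest.raises(ConfigError, match="nonempty"):
            coverage_targets([], "down", TargetTable(entries={"m": {"G"}}))

    def test_absent_mirna_counts_in_denominator(self):
        t = TargetTable(entries={"miR-1": {"G"}, "miR-2": {"G"}})
        strict = coverage_targets(["miR-1", "miR-2", "miR-3", "miR-4"], "down", t)
        assert strict.qualifying_genes == frozenset()  # 2/4
        lenient = coverage_targets(["miR-1", "miR-2", "miR-3", "miR-4"], "down", t, denominator="in_table")
        assert lenient.qualifying_genes == {"G"}  # 2/2

    def test_union_mode_returns_all_targets(self):
        t = TargetTable(entries={"miR-1": {"G"}, "miR-2": {"H"}})
        cov = coverage_targets(["miR-1", "miR-2", "miR-3"], "down", t, union_mode=True)
        assert cov.qualifying_genes == {"G", "H"}

    def test_synthetic_biomarkers_qualify_against_shared_down(self, default_study):
        _, _, _, table, _, _, truth = default_study
        shared_down = truth.de_mirnas_down["cell"] & truth.de_mirnas_down["exosome"]
        cov = coverage_targets(shared_down, "down", table)
        assert truth.biomarker_genes_up <= cov.qualifying_genes
        # brute-force recount
        for gene in truth.biomarker_genes_up:
            count = sum(1 for m in shared_down if gene in table.targets_of(m))
            assert count == cov.predicted_genes[gene]
            assert count / len(shared_down) > 0.5


class TestMapIds:
    def test_mapped_and_unmapped_split(self):
        m = GeneIdMap(entries={"GBX2": 2637, "TLR4": 7099})
        mapped, unmapped = map_ids(["GBX2", "NOVELX"], m)
        assert mapped == {"GBX2": 2637} and unmapped == ["NOVELX"]

    def test_empty_input(self):
        mapped, unmapped = map_ids([], GeneIdMap(entries={"A": 1}))
        assert mapped == {} and unmapped == []


def toy_inputs():
    mrna = de_from_sets(up=["G1", "G2", "G3"], down=["G9"], assay="mRNA")
    # cell and exosome agree on down miRNAs miR-1..miR-3 (targets of G2/G3/G4)
    cell = de_from_sets(down=["miR-1", "miR-2", "miR-3"], up=["miR-9"])
    exo = de_from_sets(down=["miR-1", "miR-2", "miR-3"], up=["miR-9"])
    table = TargetTable(
        entries={
            "miR-1": {"G2", "G3", "G4"},
            "miR-2": {"G2", "G3", "G4"},
            "miR-3": {"G4"},
            "miR-9": {"G9"},
        }
    )
    id_map = GeneIdMap(entries={f"G{i}": 100 + i for i in range(1, 10)})
    return mrna, cell, exo, table, id_map


class TestIntegrateCandidates:
    def test_toy_intersection_common_first(self):
        # G2/G3 covered by 2/3 of the common down miRNAs (> 0.5); G4 qualifies
        # too but is not mRNA-up; G1 is mRNA-up but untargeted
        cand = integrate_candidates(*toy_inputs(), strategy="common_mirna_first")
        assert cand.up_genes == {"G2", "G3"}
        assert cand.cardinalities["mirna_common_down"] == 3
        assert cand.cardinalities["candidates_up"] == 2

    def test_toy_down_candidate_from_up_mirnas(self):
        # miR-9 is the single common up miRNA and targets G9 (1/1 > 0.5),
        # which is also mRNA-down -> down candidate
        cand = integrate_candidates(*toy_inputs(), strategy="common_mirna_first")
        assert cand.cardinalities["mirna_common_up"] == 1
        assert cand.down_genes == {"G9"}

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ConfigError, match="strategy"):
            integrate_candidates(*toy_inputs(), strategy="bogus")

    def test_per_compartment_empty_prediction_absorbs(self):
        mrna, cell, exo, table, id_map = toy_inputs()
        exo_empty = de_from_sets(universe=["miR-1"], assay="miRNA")  # no calls
        cand = integrate_candidates(mrna, cell, exo_empty, table, id_map, strategy="per_compartment")
        assert cand.up_genes == frozenset() and cand.down_genes == frozenset()
        assert cand.cardinalities["candidates_up"] == 0

    def test_unmapped_symbols_drop_before_intersection(self):
        mrna, cell, exo, table, _ = toy_inputs()
        id_map = GeneIdMap(entries={"G3": 103, "G9": 109})  # G2 has no Entrez ID
        cand = integrate_candidates(mrna, cell, exo, table, id_map)
        assert cand.up_genes == {"G3"}
        assert cand.cardinalities["unmapped_mrna_up"] == 2  # G1, G2

    def test_candidates_bounded_by_every_intersected_set(self, default_study):
        from crossmir.normalization import NormalizationSpec, normalize_chips
        from crossmir.diffexpr import mirna_de, mrna_de

        mrna, mir_cell, mir_exo, table, id_map, _, _ = default_study
        mrna_res = mrna_de(normalize_chips(mrna, NormalizationSpec(percentile=75)))
        cell_res = mirna_de(normalize_chips(mir_cell, NormalizationSpec(percentile=99)))
        exo_res = mirna_de(normalize_chips(mir_exo, NormalizationSpec(percentile=99)))
        for strategy in ("common_mirna_first", "per_compartment"):
            cand = integrate_candidates(mrna_res, cell_res, exo_res, table, id_map, strategy=strategy)
            c = cand.cardinalities
            assert c["candidates_up"] <= min(c["mrna_up_mapped"], *(v for k, v in c.items() if k.startswith("predicted_up")))
            assert cand.n_candidates == c["candidates_up"] + c["candidates_down"]

    def test_provenance_complete_for_every_candidate(self):
        cand = integrate_candidates(*toy_inputs())
        assert set(cand.provenance["gene"]) == cand.up_genes | cand.down_genes
        assert cand.provenance["entrez_id"].notna().all()
        up_rows = cand.provenance[cand.provenance["direction"] == "up"]
        assert (up_rows["count_common_down_mirnas"] >= 0).all()
        down_rows = cand.provenance[cand.provenance["direction"] == "down"]
        assert (down_rows["count_common_up_mirnas"] >= 0).all()

    def test_up_down_disjoint_enforced(self):
        with pytest.raises(ValueError):
            CandidateSet(
                up_genes=frozenset({"A"}),
                down_genes=frozenset({"A"}),
                provenance=pd.DataFrame(),
                strategy="common_mirna_first",
                cardinalities={},
            )


def brute_force_candidates(mrna, cell, exo, table, id_map, strategy, min_fraction=0.5):
    """Enumerate genes and check the membership predicates directly."""

    def covered(gene, mirnas):
        if not mirnas:
            return False
        n = sum(1 for m in mirnas if gene in table.targets_of(m))
        return n / len(mirnas) > min_fraction

    out = {}
    for direction in ("up", "down"):
        observed = mrna.up_set if direction == "up" else mrna.down_set
        source = "down" if direction == "up" else "up"
        cell_src = getattr(cell, f"{source}_set")
        exo_src = getattr(exo, f"{source}_set")
        result = set()
        for gene in observed:
            if id_map.get(gene) is None:
                continue
            if strategy == "common_mirna_first":
                ok = covered(gene, cell_src & exo_src)
            else:
                ok = covered(gene, cell_src) and covered(gene, exo_src)
            if ok:
                result.add(gene)
        out[direction] = result
    return out


@pytest.mark.parametrize("strategy", ["common_mirna_first", "per_compartment"])
@pytest.mark.parametrize("seed", range(8))
def test_brute_force_oracle_equivalence(strategy, seed):
    """Random small studies: the integration graph equals direct predicate checks."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(30)]
    mirnas = [f"miR-{i}" for i in range(15)]
    id_map = GeneIdMap(entries={g: 1000 + i for i, g in enumerate(genes) if rng.random() > 0.1})
    table = TargetTable(
        entries={
            m: frozenset(rng.choice(genes, size=rng.integers(1, 10), replace=False))
            for m in mirnas
            if rng.random() > 0.2
        }
    )

    def random_de(ids, assay):
        call = rng.choice(["up", "down", "neither"], size=len(ids), p=[0.3, 0.3, 0.4])
        return DEResult(pd.DataFrame({"log2fc": 0.0, "call": call}, index=ids), {}, assay)

    mrna = random_de(genes, "mRNA")
    cell = random_de(mirnas, "miRNA")
    exo = random_de(mirnas, "miRNA")
    cand = integrate_candidates(mrna, cell, exo, table, id_map, strategy=strategy)
    expected = brute_force_candidates(mrna, cell, exo, table, id_map, strategy)
    assert cand.up_genes == expected["up"]
    assert cand.down_genes == expected["down"]


def test_swapping_substates_swaps_candidates(small_config):
    """Relabeling the groups end-to-end exactly swaps up and down candidates."""
    from crossmir.normalization import NormalizationSpec, normalize_chips
    from crossmir.diffexpr import mirna_de, mrna_de
    from crossmir.synthetic import generate_study

    mrna, mir_cell, mir_exo, table, id_map, _, _ = generate_study(small_config)

    def run(swap):
        ms = [mrna, mir_cell, mir_exo]
        if swap:
            ms = [m.swap_groups() for m in ms]
        mrna_res = mrna_de(normalize_chips(ms[0], NormalizationSpec(percentile=75)))
        cell_res = mirna_de(normalize_chips(ms[1], NormalizationSpec(percentile=99)))
        exo_res = mirna_de(normalize_chips(ms[2], NormalizationSpec(percentile=99)))
        return integrate_candidates(mrna_res, cell_res, exo_res, table, id_map)

    a, b = run(False), run(True)
    assert a.up_genes == b.down_genes
    assert a.down_genes == b.up_genes
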