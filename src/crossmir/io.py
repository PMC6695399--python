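"""Readers and writers for every external table the pipeline touches.

Supported inputs: plain tab-delimited expression tables (first column =
feature ID, one header row of sample names), the GEO series-matrix dialect
(metadata lines prefixed ``!`` with the data block between the
``!series_matrix_table_begin`` / ``!series_matrix_table_end`` sentinels),
TargetScan-style predicted-target flat files plus a simplified two-column
dialect, and two-column gene-symbol -> Entrez ID maps.  Outputs: the
candidate report (TSV + cardinality summary + JSON run metadata).

Missing values are rejected, never imputed: single-channel array exports are
dense, and a hole in the table is evidence of a malformed file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    ExpressionMatrix,
    FormatError,
    GeneIdMap,
    QpcrDataset,
    SampleInfo,
    TargetTable,
)
from .diffexpr import DEResult
from .integration import CandidateSet

HUMAN_TAX_ID = "9606"
GEO_BEGIN = "!series_matrix_table_begin"
GEO_END = "!series_matrix_table_end"

# accepted header spellings in TargetScan-style flat files
_TS_MIRNA_COLS = ("miRNA", "miR Family", "miR_Family")
_TS_GENE_COLS = ("Gene Symbol", "Gene_Symbol")
_TS_SPECIES_COLS = ("Species ID", "Species_ID", "Tax ID", "Tax_ID")


def _as_lines(stream: IO[str] | str | Path) -> list[str]:
    if isinstance(stream, (str, Path)):
        text = Path(stream).read_text()
    else:
        text = stream.read()
    return text.splitlines()


def _build_samples(names: list[str], sample_meta_spec: Mapping[str, Mapping | SampleInfo]) -> list[SampleInfo]:
    samples = []
    for name in names:
        if name not in sample_meta_spec:
            raise FormatError(f"sample {name!r} in header is missing from the sample spec")
        meta = sample_meta_spec[name]
        if isinstance(meta, SampleInfo):
            if meta.name != name:
                meta = SampleInfo(name, meta.group, meta.replicate_index, meta.compartment, meta.assay)
            samples.append(meta)
        else:
            samples.append(SampleInfo(name=name, **dict(meta)))
    return samples


def _parse_data_block(
    lines: list[str],
    sample_meta_spec: Mapping,
    *,
    is_log2: bool,
    strip_quotes: bool = False,
) -> ExpressionMatrix:
    rows = [ln for ln in lines if ln.strip()]
    if not rows:
        raise FormatError("empty table")
    header = rows[0].split("\t")
    names = [_unquote(c) if strip_quotes else c for c in header[1:]]
    if not names:
        raise FormatError("header has no sample columns")
    samples = _build_samples(names, sample_meta_spec)
    data_rows = rows[1:]
    if not data_rows:
        raise FormatError("no features")
    feature_ids: list[str] = []
    values = np.empty((len(data_rows), len(names)))
    for r, line in enumerate(data_rows):
        cells = line.split("\t")
        if len(cells) != len(names) + 1:
            raise FormatError(
                f"ragged row {r + 2}: expected {len(names) + 1} columns, got {len(cells)}"
            )
        fid = _unquote(cells[0]) if strip_quotes else cells[0]
        feature_ids.append(fid.strip())
        for c, cell in enumerate(cells[1:]):
            try:
                values[r, c] = float(cell)
            except ValueError:
                raise FormatError(
                    f"non-numeric value {cell!r} at feature {fid!r}, sample {names[c]!r}"
                ) from None
    signals = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature"), columns=names)
    return ExpressionMatrix(signals=signals, samples=samples, is_log2=is_log2)


def _unquote(s: str) -> str:
    s = s.strip()
    if len(s) >= 2 and s[0] == s[-1] and s[0] in "\"'":
        return s[1:-1]
    return s


def read_expression_table(
    stream: IO[str] | str | Path,
    sample_meta_spec: Mapping,
    *,
    is_log2: bool = False,
) -> ExpressionMatrix:
    """Read a plain tab-delimited features x samples expression table."""
    return _parse_data_block(_as_lines(stream), sample_meta_spec, is_log2=is_log2)


def read_geo_series_matrix(
    stream: IO[str] | str | Path,
    sample_meta_spec: Mapping,
    *,
    is_log2: bool = False,
) -> ExpressionMatrix:
    """Read the data block of a GEO series-matrix file.

    Metadata lines (``!``-prefixed) are ignored; the table between the begin
    and end sentinels is parsed like a plain expression table.  GEO quotes
    identifiers; quotes are stripped.
    """
    lines = _as_lines(stream)
    try:
        start = next(i for i, ln in enumerate(lines) if ln.strip().lower() == GEO_BEGIN)
    except StopIteration:
        raise FormatError(f"missing {GEO_BEGIN!r} sentinel") from None
    try:
        end = next(i for i, ln in enumerate(lines) if ln.strip().lower() == GEO_END)
    except StopIteration:
        raise FormatError(f"missing {GEO_END!r} sentinel") from None
    if end <= start:
        raise FormatError("series-matrix sentinels out of order")
    return _parse_data_block(
        lines[start + 1 : end], sample_meta_spec, is_log2=is_log2, strip_quotes=True
    )


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix back to the plain tab-delimited dialect (full precision)."""
    df = matrix.signals.copy()
    df.index.name = "feature"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_target_table(stream: IO[str] | str | Path, dialect: str = "two_column") -> TargetTable:
    """Read a miRNA -> target-gene table.

    ``two_column``: header + (miRNA, gene symbol) rows.  ``targetscan7``:
    tab-delimited with named miRNA/gene-symbol/species columns; rows are
    filtered to human (tax ID 9606).
    """
    lines = [ln for ln in _as_lines(stream) if ln.strip()]
    if not lines:
        raise FormatError("empty target table")
    entries: dict[str, set[str]] = {}
    if dialect == "two_column":
        for ln in lines[1:]:
            cells = ln.split("\t")
            if len(cells) < 2:
                raise FormatError(f"two_column row with fewer than 2 fields: {ln!r}")
            entries.setdefault(cells[0].strip(), set()).add(cells[1].strip())
    elif dialect == "targetscan7":
        header = [c.strip() for c in lines[0].split("\t")]

        def col(cands: tuple[str, ...], what: str) -> int:
            for cand in cands:
                if cand in header:
                    return header.index(cand)
            raise FormatError(f"targetscan7 table lacks a {what} column (looked for {cands})")

        i_mir = col(_TS_MIRNA_COLS, "miRNA")
        i_gene = col(_TS_GENE_COLS, "gene symbol")
        i_tax = col(_TS_SPECIES_COLS, "species tax ID")
        for ln in lines[1:]:
            cells = ln.split("\t")
            if len(cells) <= max(i_mir, i_gene, i_tax):
                raise FormatError(f"short targetscan7 row: {ln!r}")
            if cells[i_tax].strip() != HUMAN_TAX_ID:
                continue
            entries.setdefault(cells[i_mir].strip(), set()).add(cells[i_gene].strip())
    else:
        raise FormatError(f"unknown target-table dialect {dialect!r}")
    return TargetTable(entries={m: frozenset(g) for m, g in entries.items()}, dialect=dialect)


def read_gene_id_map(stream: IO[str] | str | Path) -> GeneIdMap:
    """Read a two-column (gene symbol, Entrez ID) map.

    A header row is auto-detected by a non-numeric second field.  Rows with
    an empty ID are recorded as unmapped; a symbol mapped to two distinct IDs
    is an error.
    """
    lines = [ln for ln in _as_lines(stream) if ln.strip()]
    if not lines:
        raise FormatError("empty ID map")
    start = 0
    first = lines[0].split("\t")
    if len(first) >= 2 and first[1].strip() and not first[1].strip().isdigit():
        start = 1  # header row
    entries: dict[str, int] = {}
    unmapped: set[str] = set()
    for ln in lines[start:]:
        cells = ln.split("\t")
        if len(cells) < 2 or not cells[1].strip():
            sym = cells[0].strip()
            if sym:
                unmapped.add(sym)
            continue
        sym, raw = cells[0].strip(), cells[1].strip()
        try:
            eid = int(raw)
        except ValueError:
            raise FormatError(f"non-integer Entrez ID {raw!r} for symbol {sym!r}") from None
        key = sym.upper()
        if key in entries and entries[key] != eid:
            raise FormatError(f"gene symbol {sym!r} maps to two distinct IDs ({entries[key]}, {eid})")
        entries[key] = eid
    return GeneIdMap(entries=entries, unmapped=frozenset(unmapped))


def write_de_table(result: DEResult, path: str | Path) -> None:
    """Serialize a DEResult to TSV (feature, fold change, statistic, p, q, call)."""
    df = result.table.copy()
    df.index.name = "feature"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_de_table(path: str | Path, assay: str = "mRNA") -> DEResult:
    """Read back a DE table written by :func:`write_de_table`."""
    df = pd.read_csv(path, sep="\t", index_col="feature")
    if "call" not in df.columns or "log2fc" not in df.columns:
        raise FormatError("DE table needs 'log2fc' and 'call' columns")
    bad = set(df["call"].unique()) - {"up", "down", "neither"}
    if bad:
        raise FormatError(f"invalid call values {sorted(bad)}")
    return DEResult(table=df, thresholds={}, assay=assay)


def read_candidates(path: str | Path) -> CandidateSet:
    """Read back a candidate table written by :func:`write_candidate_report`."""
    df = pd.read_csv(path, sep="\t")
    if df.empty and "direction" not in df.columns:
        df = pd.DataFrame(columns=["gene", "entrez_id", "direction", "in_mrna_de"])
    up = frozenset(df.loc[df["direction"] == "up", "gene"].astype(str))
    down = frozenset(df.loc[df["direction"] == "down", "gene"].astype(str))
    return CandidateSet(
        up_genes=up,
        down_genes=down,
        provenance=df,
        strategy="loaded",
        cardinalities={"candidates_up": len(up), "candidates_down": len(down)},
    )


def write_candidate_report(
    candidates: CandidateSet,
    de_summaries: Mapping[str, DEResult] | None,
    out_dir: str | Path,
    *,
    metadata: Mapping | None = None,
) -> dict[str, Path]:
    """Write the candidate table, the cardinality summary, and run metadata.

    Creates ``candidates.tsv`` (one row per candidate with provenance
    columns), ``summary.txt`` (all intersection cardinalities), and
    ``run_metadata.json`` (config echo, seed, versions, cardinalities).
    Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table_path = out / "candidates.tsv"
    prov = candidates.provenance
    if prov.empty:
        prov = pd.DataFrame(columns=["gene", "entrez_id", "direction", "in_mrna_de"])
    prov.to_csv(table_path, sep="\t", index=False)

    summary_path = out / "summary.txt"
    lines = [
        f"integration strategy: {candidates.strategy}",
        f"up candidates: {len(candidates.up_genes)}",
        f"down candidates: {len(candidates.down_genes)}",
        "",
        "cardinalities:",
    ]
    for key in sorted(candidates.cardinalities):
        lines.append(f"  {key}: {candidates.cardinalities[key]}")
    if de_summaries:
        lines.append("")
        lines.append("differential expression:")
        for name, de in de_summaries.items():
            s = de.summary()
            lines.append(f"  {name}: {s['n_up']} up, {s['n_down']} down of {s['n_features']}")
    summary_path.write_text("\n".join(lines) + "\n")

    meta_path = out / "run_metadata.json"
    meta = {
        "strategy": candidates.strategy,
        "cardinalities": candidates.cardinalities,
        "up_genes": sorted(candidates.up_genes),
        "down_genes": sorted(candidates.down_genes),
    }
    if de_summaries:
        meta["de_summaries"] = {k: v.summary() for k, v in de_summaries.items()}
    if metadata:
        meta["run"] = dict(metadata)
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    return {"candidates": table_path, "summary": summary_path, "metadata": meta_path}


def write_qpcr_table(confirmation: pd.DataFrame, path: str | Path) -> None:
    confirmation.to_csv(path, sep="\t", index=False)


def write_target_table(table: TargetTable, path: str | Path) -> None:
    """Write a TargetTable in the simplified two-column dialect."""
    with open(path, "w") as fh:
        fh.write("miRNA\tGene Symbol\n")
        for mirna in sorted(table.entries):
            for gene in sorted(table.entries[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


def write_gene_id_map(id_map: GeneIdMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("Gene symbol\tNCBI gene ID\n")
        for sym in sorted(id_map.entries):
            fh.write(f"{sym}\t{id_map.entries[sym]}\n")
        for sym in sorted(id_map.unmapped):
            fh.write(f"{sym}\t\n")


def write_qpcr_dataset(data: QpcrDataset, path: str | Path) -> None:
    """Write Ct tables as one long-format TSV (group, gene, replicate, ct)."""
    rows = []
    for group, table in data.ct.items():
        for gene in table.index:
            for rep, col in enumerate(table.columns, start=1):
                rows.append((group, gene, rep, table.loc[gene, col]))
    df = pd.DataFrame(rows, columns=["group", "gene", "replicate", "ct"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_qpcr_dataset(path: str | Path, reference_gene: str) -> QpcrDataset:
    """Read the long-format qPCR TSV written by :func:`write_qpcr_dataset`."""
    df = pd.read_csv(path, sep="\t")
    required = {"group", "gene", "replicate", "ct"}
    if not required <= set(df.columns):
        raise FormatError(f"qPCR table needs columns {sorted(required)}")
    ct = {}
    for group, sub in df.groupby("group"):
        wide = sub.pivot(index="gene", columns="replicate", values="ct")
        wide.columns = [f"{group}_r{int(c)}" for c in wide.columns]
        ct[str(group)] = wide
    return QpcrDataset(ct=ct, reference_gene=reference_gene)
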