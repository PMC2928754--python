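"""Readers and writers for every file format the pipeline touches.

All tabular files are UTF-8 TSV.  Gene sets use the standard GMT
interchange format (set name, description, tab-separated members).
Readers validate strictly and raise :class:`~popvar.errors.FormatError`
instead of coercing; writers serialize floats with Python's shortest
round-trip repr so write -> read reproduces values bit-exactly.

Result writers prepend ``#``-prefixed header comments recording the
configuration hash and master seed of the run, which readers skip.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, ProbeFlagTable, SnpTable
from .errors import FormatError

__all__ = [
    "read_expression",
    "write_expression",
    "read_snp_table",
    "write_snp_table",
    "read_gene_sets",
    "write_gene_sets",
    "read_probe_flags",
    "write_probe_flags",
    "read_table",
    "write_results",
    "config_hash",
]


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc


def read_population_map(path) -> pd.Series:
    """Read a two-column (sample_id, population) TSV into a Series."""
    df = _read_tsv(path)
    if list(df.columns[:2]) != ["sample_id", "population"]:
        raise FormatError(
            f"{path}: expected columns 'sample_id' and 'population', "
            f"got {list(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample ids {dupes[:5]}")
    return pd.Series(
        df["population"].to_numpy(), index=pd.Index(df["sample_id"]), name="population"
    )


def read_expression(path, population_map_path) -> list[ExpressionMatrix]:
    """Read an expression TSV and split it into per-population matrices.

    The TSV has a header row of sample ids with gene ids in the first
    column.  Every sample must appear in the population map; the returned
    matrices are ordered by population label.
    """
    raw = _read_tsv(path)
    gene_col = raw.columns[0]
    gene_ids = pd.Index(raw[gene_col], name="gene_id")
    if gene_ids.has_duplicates:
        dupes = gene_ids[gene_ids.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene id {dupes[0]!r}")
    values = raw.drop(columns=[gene_col])
    def _to_float(cell):
        try:
            return float(cell)
        except (TypeError, ValueError):
            return None

    for col in values.columns:
        converted = values[col].map(_to_float)  # exact strtod round-trip
        bad = converted.isna() | values[col].isna()
        if bad.any():
            row = gene_ids[bad.to_numpy()][0]
            raise FormatError(
                f"{path}: non-numeric or missing cell at gene {row!r}, "
                f"sample {col!r}"
            )
        values[col] = converted.astype(float)
    values.index = gene_ids

    pop_map = read_population_map(population_map_path)
    unmapped = [s for s in values.columns if s not in pop_map.index]
    if unmapped:
        raise FormatError(
            f"{path}: samples missing from population map: {unmapped[:5]}"
        )
    matrices = []
    for pop in sorted(pop_map.unique()):
        samples = [s for s in values.columns if pop_map[s] == pop]
        if samples:
            matrices.append(ExpressionMatrix(values[samples].copy(), pop))
    return matrices


def write_expression(matrices: Iterable[ExpressionMatrix], path, population_map_path) -> None:
    """Write per-population matrices as one joined TSV plus a population map."""
    matrices = list(matrices)
    joined = pd.concat([m.values for m in matrices], axis=1)
    joined.index.name = "gene_id"
    joined.to_csv(path, sep="\t")
    rows = [
        {"sample_id": s, "population": m.population}
        for m in matrices
        for s in m.sample_ids
    ]
    pd.DataFrame(rows).to_csv(population_map_path, sep="\t", index=False)


def read_snp_table(path, populations: tuple[str, str] = ("popA", "popB")) -> SnpTable:
    """Read the 5-column SNP TSV (snp_id, gene_id, region, maf_a, maf_b)."""
    df = _read_tsv(path)
    missing = [c for c in SnpTable.REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: SNP table missing columns {missing}")
    for col in ("maf_a", "maf_b"):
        try:
            converted = df[col].map(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric value in {col}: {exc}") from exc
        df[col] = converted
    return SnpTable(df, populations)


def write_snp_table(table: SnpTable, path, **meta) -> None:
    header = _header_comment(
        populations=",".join(table.populations), **meta
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        table.df.to_csv(fh, sep="\t", index=False)


def read_gene_sets(path, codes_path=None) -> GeneSetCollection:
    """Read a GMT file and, optionally, a (gene_id, category_code) TSV."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: malformed GMT line "
                    "(need set name, description and at least one member)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    codes = None
    if codes_path is not None:
        cdf = _read_tsv(codes_path)
        if list(cdf.columns[:2]) != ["gene_id", "category_code"]:
            raise FormatError(
                f"{codes_path}: expected columns 'gene_id' and 'category_code'"
            )
        codes = pd.Series(
            cdf["category_code"].to_numpy(),
            index=pd.Index(cdf["gene_id"]),
            name="category_code",
        )
    return GeneSetCollection(sets, codes=codes, descriptions=descriptions)


def write_gene_sets(collection: GeneSetCollection, path, codes_path=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
    if codes_path is not None and collection.codes is not None:
        df = collection.codes.rename_axis("gene_id").reset_index()
        df.to_csv(codes_path, sep="\t", index=False)


def read_probe_flags(path) -> ProbeFlagTable:
    """Read a (gene_id, probe_snp_overlap) TSV; values must be 0/1 or true/false."""
    df = _read_tsv(path)
    if list(df.columns[:2]) != ["gene_id", "probe_snp_overlap"]:
        raise FormatError(
            f"{path}: expected columns 'gene_id' and 'probe_snp_overlap'"
        )
    mapping = {"0": False, "1": True, "true": True, "false": False}
    raw = df["probe_snp_overlap"].astype(str).str.lower()
    bad = ~raw.isin(mapping)
    if bad.any():
        raise FormatError(
            f"{path}: non-boolean probe flags {df.loc[bad, 'probe_snp_overlap'].tolist()[:5]}"
        )
    flags = pd.Series(raw.map(mapping).to_numpy(), index=pd.Index(df["gene_id"]))
    return ProbeFlagTable(flags)


def write_probe_flags(table: ProbeFlagTable, path) -> None:
    df = table.flags.astype(int).rename("probe_snp_overlap").rename_axis("gene_id")
    df.reset_index().to_csv(path, sep="\t", index=False)


def config_hash(config: Mapping) -> str:
    """Deterministic short hash of a flat configuration mapping."""
    canon = "\n".join(f"{k}={config[k]}" for k in sorted(map(str, config)))
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:12]


def _header_comment(**meta) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_results(tables: Mapping[str, pd.DataFrame], out_dir, **meta) -> list[Path]:
    """Write each result table as ``<out_dir>/<name>.tsv``.

    Keyword arguments (typically ``config_hash=...`` and ``seed=...``) are
    recorded as ``#`` header comments.  Column order is the DataFrame's
    column order, which callers keep fixed; floats use full-precision repr
    so the tables round-trip losslessly through :func:`read_table`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    header = _header_comment(**meta)
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)
        written.append(path)
    return written


def read_table(path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty results table")
    return df
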