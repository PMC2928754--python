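"""Core in-memory containers shared across the pipeline.

The canonical layout for expression data is a pandas DataFrame with gene
identifiers on the index and sample identifiers on the columns, wrapped in
:class:`ExpressionMatrix` together with the population label.  SNP tables,
gene-set collections and probe flags are thin validated wrappers around the
corresponding tabular objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

#: Closed vocabulary of cis-regions a SNP may be assigned to.
SNP_REGIONS = ("promoter", "utr5", "utr3")


@dataclass
class ExpressionMatrix:
    """Positive expression intensities for one population.

    Parameters
    ----------
    values
        genes x samples DataFrame of strictly positive intensities.
    population
        Population label (e.g. ``"CEU"``); purely a tag, any pair of labels
        can be compared downstream.
    """

    values: pd.DataFrame
    population: str

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dupes[:5]}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise FormatError("expression values must be finite")
        if np.any(arr <= 0):
            bad = idx[np.any(arr <= 0, axis=1)].tolist()
            raise FormatError(
                f"non-positive expression values for genes: {bad[:5]}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[gene_ids], self.population)


@dataclass
class SnpTable:
    """Per-SNP minor-allele frequencies in two populations.

    ``df`` columns: ``snp_id``, ``gene_id``, ``region`` (one of
    :data:`SNP_REGIONS`), ``maf_a``, ``maf_b`` with MAFs folded into
    ``[0, 0.5]``.  ``populations`` records which labels the ``a``/``b``
    columns refer to.
    """

    df: pd.DataFrame
    populations: tuple[str, str]

    REQUIRED_COLUMNS = ("snp_id", "gene_id", "region", "maf_a", "maf_b")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"SNP table missing columns: {missing}")
        if self.df["snp_id"].duplicated().any():
            dupes = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"]
            raise FormatError(f"duplicate snp ids: {dupes.tolist()[:5]}")
        bad_region = ~self.df["region"].isin(SNP_REGIONS)
        if bad_region.any():
            tokens = self.df.loc[bad_region, "region"].unique().tolist()
            raise FormatError(f"unknown region tokens: {tokens[:5]}")
        for col in ("maf_a", "maf_b"):
            maf = self.df[col].to_numpy(dtype=float)
            if np.any(~np.isfinite(maf)) or np.any(maf < 0) or np.any(maf > 0.5):
                bad = self.df.loc[
                    ~np.isfinite(maf) | (maf < 0) | (maf > 0.5), "snp_id"
                ]
                raise FormatError(
                    f"MAF outside [0, 0.5] in {col} for SNPs: "
                    f"{bad.tolist()[:5]}"
                )

    def __len__(self) -> int:
        return len(self.df)

    def for_region(self, region: str) -> pd.DataFrame:
        if region not in SNP_REGIONS:
            raise FormatError(f"unknown region {region!r}")
        return self.df[self.df["region"] == region]


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional per-gene most-specific category code.

    ``sets`` maps set name -> list of member gene ids.  ``codes`` (optional)
    assigns every annotated gene exactly one category code, used for
    annotation-matched null-set construction.
    """

    sets: dict[str, list[str]]
    codes: pd.Series | None = None
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.codes is not None and self.codes.index.has_duplicates:
            raise FormatError("category code table has duplicate gene ids")

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def validate_universe(self, universe) -> None:
        """Check every set member is a known gene id."""
        known = set(universe)
        for name, members in self.sets.items():
            unknown = [g for g in members if g not in known]
            if unknown:
                raise FormatError(
                    f"set {name!r} references unknown gene ids: {unknown[:5]}"
                )


@dataclass
class ProbeFlagTable:
    """gene_id -> bool flag marking probes that overlap an annotated SNP.

    Genes absent from the table are treated as unflagged, so the table is
    total over any gene universe.
    """

    flags: pd.Series

    def __post_init__(self) -> None:
        if self.flags.index.has_duplicates:
            raise FormatError("probe flag table has duplicate gene ids")
        self.flags = self.flags.astype(bool)

    def is_flagged(self, gene_ids) -> pd.Series:
        out = self.flags.reindex(pd.Index(gene_ids), fill_value=False)
        return out.astype(bool)

    def flagged_genes(self) -> list:
        return self.flags[self.flags].index.tolist()
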