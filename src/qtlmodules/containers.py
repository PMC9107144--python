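"""Core in-memory containers: genotypes, expression, summary statistics.

The containers are thin wrappers around :class:`pandas.DataFrame` so that
the rest of the package can rely on consistent orientation (samples in
rows) and metadata without inventing a new data model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .io import read_tsv, write_tsv

VARIANT_COLUMNS = ["chrom", "pos", "effect_allele", "other_allele", "maf"]
GENE_COLUMNS = ["chrom", "tss"]


@dataclass
class GenotypeMatrix:
    """Sample x variant allele-dosage matrix plus per-variant metadata.

    ``dosages`` holds counts of the effect allele in {0, 1, 2}; ``variants``
    is indexed by variant_id with columns chrom, pos (1-based),
    effect_allele, other_allele and maf (empirical effect-allele frequency
    folded to the minor side).
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise InputError(f"variant metadata lacks columns {missing}")
        if list(self.dosages.columns) != list(self.variants.index):
            raise InputError("dosage columns and variant metadata index disagree")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def variant_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def dosage(self, variant_id: str) -> np.ndarray:
        if variant_id not in self.dosages.columns:
            raise InputError(f"variant {variant_id!r} not in genotype matrix")
        return self.dosages[variant_id].to_numpy(dtype=float)

    def write(self, dosage_path: str | Path, variants_path: str | Path) -> None:
        out = self.dosages.copy()
        out.insert(0, "sample_id", out.index)
        write_tsv(out, dosage_path)
        meta = self.variants.copy()
        meta.insert(0, "variant_id", meta.index)
        write_tsv(meta, variants_path)

    @classmethod
    def read(cls, dosage_path: str | Path, variants_path: str | Path) -> "GenotypeMatrix":
        dosages = read_tsv(dosage_path).set_index("sample_id")
        dosages.index.name = None
        variants = read_tsv(variants_path).set_index("variant_id")
        variants.index.name = None
        return cls(dosages=dosages, variants=variants)


@dataclass
class ExpressionMatrix:
    """Sample x gene normalized expression for one tissue."""

    values: pd.DataFrame
    tissue_id: str

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "sample_id", out.index)
        write_tsv(out, path)

    @classmethod
    def read(cls, path: str | Path, tissue_id: str) -> "ExpressionMatrix":
        values = read_tsv(path).set_index("sample_id")
        values.index.name = None
        return cls(values=values, tissue_id=tissue_id)


SUMMARY_COLUMNS = ["variant_id", "beta", "se", "p", "n", "maf"]


@dataclass
class SummaryStatSet:
    """Per-variant association summary statistics for one trait.

    The table carries variant_id, beta, se, p, n and maf; optional
    effect_allele / other_allele columns enable allele alignment in
    colocalization.
    """

    trait_id: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in SUMMARY_COLUMNS if c not in self.table.columns]
        if missing:
            raise InputError(f"summary statistics lack columns {missing}")
        if self.table["variant_id"].duplicated().any():
            raise InputError("duplicate variant_id in summary statistics")
        if (self.table["se"] <= 0).any():
            raise InputError("summary statistics contain se <= 0")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table["variant_id"])

    def write(self, path: str | Path) -> None:
        write_tsv(self.table, path)

    @classmethod
    def read(cls, path: str | Path, trait_id: str) -> "SummaryStatSet":
        return cls(trait_id=trait_id, table=read_tsv(path))


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Gene annotation table indexed by gene_id with chrom and tss columns."""
    genes = read_tsv(path).set_index("gene_id")
    genes.index.name = None
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise InputError(f"gene annotation lacks columns {missing}")
    return genes


def write_gene_annotation(genes: pd.DataFrame, path: str | Path) -> None:
    out = genes.copy()
    out.insert(0, "gene_id", out.index)
    write_tsv(out, path)
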