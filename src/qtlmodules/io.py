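"""Readers and writers for the plain-text formats the pipeline exchanges.

All tables are tab-separated with a header row, UTF-8, ``.`` decimal and
``NA`` for missing values.  Genomic coordinates in variant/gene tables are
1-based; BEDPE interaction files follow the BEDPE convention of 0-based,
half-open intervals.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ParseError

NA_REP = "NA"


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, na_rep=NA_REP)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=[NA_REP])


def read_bedpe(path: str | Path) -> pd.DataFrame:
    """Parse a BEDPE file of pairwise chromatin interactions.

    Returns a frame with columns chrom1, start1, end1, chrom2, start2, end2
    (0-based, half-open).  Extra columns are ignored; malformed lines raise
    :class:`ParseError` with the 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"BEDPE line has {len(fields)} fields, expected >= 6", lineno
                )
            try:
                rec = (
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    fields[3],
                    int(fields[4]),
                    int(fields[5]),
                )
            except ValueError as exc:
                raise ParseError(f"non-integer BEDPE coordinate: {exc}", lineno)
            if rec[1] > rec[2] or rec[4] > rec[5]:
                raise ParseError("BEDPE interval start exceeds end", lineno)
            rows.append(rec)
    return pd.DataFrame(
        rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    )


def write_bedpe(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set catalog: name <TAB> description <TAB> genes..."""
    catalog: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("GMT line needs name, description and >= 1 gene", lineno)
            name = fields[0]
            if name in catalog:
                raise ParseError(f"duplicate gene-set name {name!r}", lineno)
            catalog[name] = [g for g in fields[2:] if g]
    return catalog


def write_gmt(catalog: dict[str, list[str]], path: str | Path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in catalog.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")
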