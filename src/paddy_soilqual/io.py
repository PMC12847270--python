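"""Reading, validating and writing the pipeline's tabular formats.

All tidy tables are UTF-8 CSV with one header row, '.' decimal separator;
TSV is accepted via ``sep="\\t"``. Expected columns per schema:

``sieve``
    sample_id, treatment, depth, replicate, class_gt2, class_1_2,
    class_05_1, class_025_05, class_0053_025, class_lt0053  (grams)
``chem``
    sample_id, treatment, depth, replicate, SOM, TN, TP, AN, AP, pH
``copies``
    sample_id, treatment, depth, replicate, bacterial_copies, fungal_copies

Unknown extra columns are preserved and passed through untouched. The count
table (``counts.tsv``) is a dense matrix, by default taxa as rows and samples
as columns with the first column named ``taxon_id``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    SIEVE_CLASS_COLUMNS,
    ChemProfile,
    CopyNumbers,
    PlotSample,
    SieveFractions,
    TaxonCountTable,
    check_unique_design,
)
from .errors import ParseError, SchemaError, ValidationError

__all__ = [
    "SCHEMAS",
    "read_tidy_table",
    "write_tidy_table",
    "to_records",
    "read_count_table",
    "write_count_table",
]

_ID_COLUMNS = ("sample_id", "treatment", "depth", "replicate")

#: Required columns per table kind; numeric ones exclude the id block.
SCHEMAS: dict[str, tuple[str, ...]] = {
    "sieve": _ID_COLUMNS + SIEVE_CLASS_COLUMNS,
    "chem": _ID_COLUMNS + ("SOM", "TN", "TP", "AN", "AP", "pH"),
    "copies": _ID_COLUMNS + ("bacterial_copies", "fungal_copies"),
}

Schema = Literal["sieve", "chem", "copies"]


def _numeric_columns(schema: Schema) -> tuple[str, ...]:
    return tuple(c for c in SCHEMAS[schema] if c not in ("sample_id", "treatment", "depth"))


def read_tidy_table(
    path: str | Path,
    schema: Schema,
    sep: str = ",",
    custom_design: bool = False,
) -> pd.DataFrame:
    """Read and validate one tidy sample table.

    Returns the table with row order preserved and extra columns untouched.
    Raises :class:`SchemaError` for missing columns, :class:`ParseError` for
    non-numeric cells and :class:`ValidationError` for invariant violations
    (naming the offending sample).
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing column(s) {', '.join(missing)} "
            f"required by schema {schema!r}"
        )
    out = df.copy()
    for col in _numeric_columns(schema):
        parsed = pd.to_numeric(out[col], errors="coerce")
        bad = parsed.isna() & (out[col] != "")
        bad |= out[col] == ""
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ParseError(
                f"{path.name}: non-numeric value {df[col].iloc[row]!r} in "
                f"column {col!r} at data row {row}"
            )
        # float() is correctly rounded, so read -> write -> read is exact
        out[col] = np.array([float(v) for v in out[col]], dtype=float)
    out["replicate"] = out["replicate"].astype(int)
    # validation happens record-by-record so errors name the sample
    to_records(out, schema, custom_design=custom_design)
    return out


def write_tidy_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a tidy table; inverse of :func:`read_tidy_table`.

    Floats are written with 17 significant digits so every value survives a
    write -> read -> write cycle bit-for-bit.
    """
    df.to_csv(path, sep=sep, index=False, float_format=lambda v: format(v, ".17g"))


def _plot_sample(row: pd.Series, custom_design: bool) -> PlotSample:
    return PlotSample(
        sample_id=str(row["sample_id"]),
        treatment=str(row["treatment"]),
        depth=str(row["depth"]),
        replicate=int(row["replicate"]),
        custom_design=custom_design,
    )


def to_records(
    df: pd.DataFrame, schema: Schema, custom_design: bool = False
) -> list[SieveFractions] | list[ChemProfile] | list[CopyNumbers]:
    """Convert a validated tidy table into typed records (row order kept)."""
    records: list = []
    for _, row in df.iterrows():
        sample = _plot_sample(row, custom_design)
        if schema == "sieve":
            masses = tuple(float(row[c]) for c in SIEVE_CLASS_COLUMNS)
            records.append(SieveFractions(sample=sample, mass_g=masses))
        elif schema == "chem":
            records.append(
                ChemProfile(
                    sample=sample,
                    **{k: float(row[k]) for k in ("SOM", "TN", "TP", "AN", "AP", "pH")},
                )
            )
        elif schema == "copies":
            records.append(
                CopyNumbers(
                    sample=sample,
                    bacterial_copies=float(row["bacterial_copies"]),
                    fungal_copies=float(row["fungal_copies"]),
                )
            )
        else:  # pragma: no cover
            raise SchemaError(f"unknown schema {schema!r}")
    check_unique_design([r.sample for r in records])
    return records


def read_count_table(
    path: str | Path,
    sep: str = "\t",
    orientation: Literal["taxa_rows", "samples_rows"] = "taxa_rows",
) -> TaxonCountTable:
    """Read a dense taxon count matrix, normalizing to samples x taxa.

    ``orientation`` declares the on-disk layout; the default matches
    ``counts.tsv`` with one taxon per row, the first column ``taxon_id``
    and one column per sample.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty or df.shape[1] == 0:
        raise ValidationError(f"{path.name}: empty count matrix")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values), rtol=0, atol=0):
            frac = np.argwhere(values != np.round(values))[0]
            raise ValidationError(
                f"{path.name}: fractional count {values[tuple(frac)]} at "
                f"row {df.index[frac[0]]!r}; counts must be integers"
            )
        values = np.round(values).astype(np.int64)
    if orientation == "taxa_rows":
        return TaxonCountTable(
            sample_ids=[str(c) for c in df.columns],
            taxon_ids=[str(i) for i in df.index],
            counts=values.T,
        )
    return TaxonCountTable(
        sample_ids=[str(i) for i in df.index],
        taxon_ids=[str(c) for c in df.columns],
        counts=values,
    )


def write_count_table(
    table: TaxonCountTable,
    path: str | Path,
    sep: str = "\t",
    orientation: Literal["taxa_rows", "samples_rows"] = "taxa_rows",
) -> None:
    """Write a count table; inverse of :func:`read_count_table`."""
    if orientation == "taxa_rows":
        df = pd.DataFrame(
            table.counts.T, index=pd.Index(table.taxon_ids, name="taxon_id"),
            columns=table.sample_ids,
        )
    else:
        df = pd.DataFrame(
            table.counts, index=pd.Index(table.sample_ids, name="sample_id"),
            columns=table.taxon_ids,
        )
    df.to_csv(path, sep=sep)
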