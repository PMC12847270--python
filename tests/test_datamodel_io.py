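"""Tidy-table and count-table I/O: round-trips, schema and invariant checks."""

import numpy as np
import pandas as pd
import pytest

from paddy_soilqual.datamodel import PlotSample, SieveFractions, TaxonCountTable
from paddy_soilqual.errors import ParseError, SchemaError, ValidationError
from paddy_soilqual.io import (
    read_count_table,
    read_tidy_table,
    to_records,
    write_count_table,
    write_tidy_table,
)
from paddy_soilqual.synth import write_dataset


@pytest.mark.parametrize("kind", ["sieve", "chem", "copies"])
def test_tidy_round_trip_is_identity(default_dataset, tmp_path, kind):
    """read(write(df)) reproduces every cell of a generated table."""
    _, data = default_dataset
    path = tmp_path / f"{kind}.csv"
    write_tidy_table(data[kind], path)
    back = read_tidy_table(path, kind)
    pd.testing.assert_frame_equal(
        back, data[kind], check_exact=False, rtol=0, atol=1e-12
    )
    # and a second write produces byte-identical files
    path2 = tmp_path / f"{kind}2.csv"
    write_tidy_table(back, path2)
    assert path.read_bytes() == path2.read_bytes()


def test_sieve_table_parses_to_typed_records(default_dataset, tmp_path):
    _, data = default_dataset
    path = tmp_path / "sieve.csv"
    write_tidy_table(data["sieve"], path)
    records = to_records(read_tidy_table(path, "sieve"), "sieve")
    assert len(records) == 30
    assert all(isinstance(r, SieveFractions) for r in records)
    assert records[0].sample.sample_id == data["sieve"]["sample_id"].iloc[0]


def test_negative_mass_names_offending_sample(default_dataset, tmp_path):
    _, data = default_dataset
    bad = data["sieve"].copy()
    bad.loc[3, "class_1_2"] = -1.0
    path = tmp_path / "sieve.csv"
    write_tidy_table(bad, path)
    with pytest.raises(ValidationError, match=str(bad.loc[3, "sample_id"])):
        read_tidy_table(path, "sieve")


def test_missing_column_names_the_column(default_dataset, tmp_path):
    _, data = default_dataset
    path = tmp_path / "chem.csv"
    write_tidy_table(data["chem"].drop(columns=["AP"]), path)
    with pytest.raises(SchemaError, match="AP"):
        read_tidy_table(path, "chem")


def test_non_numeric_cell_reports_row(default_dataset, tmp_path):
    _, data = default_dataset
    bad = data["copies"].copy().astype({"bacterial_copies": object})
    bad.loc[5, "bacterial_copies"] = "twelve"
    path = tmp_path / "copies.csv"
    write_tidy_table(bad, path)
    with pytest.raises(ParseError, match="row 5"):
        read_tidy_table(path, "copies")


def test_extra_columns_pass_through(default_dataset, tmp_path):
    _, data = default_dataset
    df = data["chem"].copy()
    df["block"] = ["B1"] * len(df)
    path = tmp_path / "chem.csv"
    write_tidy_table(df, path)
    back = read_tidy_table(path, "chem")
    assert list(back["block"]) == ["B1"] * len(df)


def test_duplicate_design_cell_rejected(default_dataset, tmp_path):
    _, data = default_dataset
    dup = data["chem"].copy()
    dup.loc[1, ["treatment", "depth", "replicate"]] = dup.loc[
        0, ["treatment", "depth", "replicate"]
    ].values
    path = tmp_path / "chem.csv"
    write_tidy_table(dup, path)
    with pytest.raises(ValidationError, match="duplicate design cell"):
        read_tidy_table(path, "chem")


def test_unknown_treatment_requires_custom_design():
    with pytest.raises(ValidationError, match="unknown treatment"):
        PlotSample("s1", "CONTROL", "D0_20", 1)
    s = PlotSample("s1", "CONTROL", "LAYER_A", 1, custom_design=True)
    assert s.treatment == "CONTROL"


def test_count_table_orientation_normalized(tmp_path):
    """A 3-taxon x 2-sample file yields a (2, 3) samples-x-taxa table."""
    path = tmp_path / "counts.tsv"
    path.write_text("taxon_id\ts1\ts2\nt1\t4\t0\nt2\t5\t1\nt3\t6\t2\n")
    table = read_count_table(path)
    assert table.shape == (2, 3)
    assert table.sample_ids == ["s1", "s2"]
    np.testing.assert_array_equal(table.counts, [[4, 5, 6], [0, 1, 2]])


def test_count_round_trip(default_dataset, tmp_path):
    _, data = default_dataset
    path = tmp_path / "counts.tsv"
    write_count_table(data["counts"], path)
    back = read_count_table(path)
    assert back.sample_ids == data["counts"].sample_ids
    assert back.taxon_ids == data["counts"].taxon_ids
    np.testing.assert_array_equal(back.counts, data["counts"].counts)


def test_fractional_and_empty_counts_rejected(tmp_path):
    frac = tmp_path / "frac.tsv"
    frac.write_text("taxon_id\ts1\ts2\nt1\t2.5\t1\n")
    with pytest.raises(ValidationError, match="integer"):
        read_count_table(frac)
    empty = tmp_path / "empty.tsv"
    empty.write_text("taxon_id\n")
    with pytest.raises(ValidationError):
        read_count_table(empty)


def test_all_zero_sample_rejected():
    with pytest.raises(ValidationError, match="s2"):
        TaxonCountTable(
            sample_ids=["s1", "s2"],
            taxon_ids=["t1", "t2"],
            counts=np.array([[1, 2], [0, 0]]),
        )


def test_write_dataset_emits_provenance(default_dataset, tmp_path):
    cfg, data = default_dataset
    written = write_dataset(data, tmp_path / "out", cfg)
    names = {p.name for p in written}
    assert names == {"sieve.csv", "chem.csv", "copies.csv", "counts.tsv",
                     "provenance.json"}
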