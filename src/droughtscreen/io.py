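"""Delimited-table readers/writers and the packaged field-ranking fixture.

The whole pipeline exchanges small comma-separated tables with a header row
("." decimal, UTF-8).  Each table kind has a schema: required columns, their
types, and optional key columns that must be unique.  Validation errors are
structured — they name the offending column and 1-based data row numbers —
because silent coercion of a screening table is how wrong genotypes get
selected.

The packaged fixture ``table1_sts.csv`` is the transcription of the field
study's published per-genotype STS scores and ranks for all 114 wild barley
genotypes; it ships with a sha256 so a corrupted copy is detected at load
time rather than propagating into a ranking.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import DuplicateKeyError, FixtureError, SchemaError

__all__ = ["TableSchema", "SCHEMAS", "read_table", "write_table", "load_table1_fixture"]

TABLE1_SHA256 = "e9ef0173696db7818f21d4ed88426c4b138117a29803c3e03b85f1b3e02a4bfe"


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple  # (column, kind) pairs; kind in {"num", "int", "str"}
    key: tuple = ()  # columns whose combination must be unique

    @property
    def column_names(self) -> tuple:
        return tuple(c for c, _ in self.columns)


SCHEMAS: dict[str, TableSchema] = {
    s.name: s
    for s in (
        TableSchema(
            "yields",
            (("genotype", "str"), ("yp", "num"), ("ys", "num")),
            key=("genotype",),
        ),
        TableSchema(
            "ct",
            (
                ("genotype", "str"),
                ("treatment", "str"),
                ("gene", "str"),
                ("bio_rep", "int"),
                ("tech_rep", "int"),
                ("ct", "num"),
            ),
            key=("genotype", "treatment", "gene", "bio_rep", "tech_rep"),
        ),
        TableSchema(
            "absorbances",
            (
                ("sample_id", "str"),
                ("a663", "num"),
                ("a646", "num"),
                ("a470", "num"),
            ),
            key=("sample_id",),
        ),
        TableSchema(
            "traits",
            (
                ("genotype", "str"),
                ("stress_level", "str"),
                ("replicate", "int"),
                ("trait", "str"),
                ("value", "num"),
            ),
            key=("genotype", "stress_level", "replicate", "trait"),
        ),
        TableSchema(
            "table1",
            (("genotype", "int"), ("sts", "num"), ("rank", "int")),
            key=("genotype",),
        ),
    )
}


def _coerce(df: pd.DataFrame, schema: TableSchema, source: str) -> pd.DataFrame:
    for col, kind in schema.columns:
        if kind == "str":
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = (df.index[bad] + 1).tolist()
            raise SchemaError(
                f"{source}: non-numeric value(s) in column {col!r} at data "
                f"row(s) {rows}"
            )
        if coerced.isna().any():
            rows = (df.index[coerced.isna()] + 1).tolist()
            raise SchemaError(
                f"{source}: missing value(s) in column {col!r} at data row(s) {rows}"
            )
        if kind == "int":
            if not (coerced == coerced.round()).all():
                raise SchemaError(f"{source}: column {col!r} must be integer-valued")
            coerced = coerced.astype(int)
        df[col] = coerced
    return df


def read_table(path, schema: str | TableSchema) -> pd.DataFrame:
    """Read and validate a delimited table against a named schema.

    Extra columns are preserved; missing or malformed required columns raise
    :class:`SchemaError`, duplicated keys :class:`DuplicateKeyError`.
    """
    if isinstance(schema, str):
        try:
            schema = SCHEMAS[schema]
        except KeyError:
            raise SchemaError(f"unknown table schema {schema!r}") from None
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in schema.column_names if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing} for a "
            f"{schema.name!r} table (found: {list(df.columns)})"
        )
    df = _coerce(df, schema, str(path))
    if schema.key:
        dup = df.duplicated(subset=list(schema.key))
        if dup.any():
            rows = (df.index[dup] + 1).tolist()
            raise DuplicateKeyError(
                f"{path}: duplicate {schema.key} key(s) at data row(s) {rows}"
            )
    return df


def write_table(table: pd.DataFrame, path) -> Path:
    """Write a table as comma-separated text with a header row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def load_table1_fixture() -> pd.DataFrame:
    """The published field ranking: genotype (1..114), sts, rank.

    Verifies the packaged file's sha256 and its basic shape before
    returning, so downstream ranking checks run against an intact
    transcription.
    """
    ref = resources.files("droughtscreen.data") / "table1_sts.csv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise FixtureError(
            "packaged field-ranking fixture failed its checksum "
            f"(got {digest[:12]}..., expected {TABLE1_SHA256[:12]}...)"
        )
    df = pd.read_csv(pd.io.common.BytesIO(raw))
    if len(df) != 114 or sorted(df["genotype"]) != list(range(1, 115)):
        raise FixtureError("fixture must contain genotypes 1..114 exactly once")
    return df
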