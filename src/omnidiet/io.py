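"""Readers and writers for the package's tabular formats.

Formats are deliberately minimal: delimited text with the delimiter chosen by
extension (``.tsv`` tab, ``.csv`` comma), headers always present.  The ASV
table layout is one row per ASV with taxonomy columns followed by one count
column per sample:

    asv_id, phylum, order, family, genus, species, <sample 1>, <sample 2>, ...
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .datatypes import (
    ISOTOPE_COLUMNS,
    TAXONOMY_RANKS,
    AnnotatedASVTable,
    RunConfig,
    ValidationError,
    validate_isotopes,
    validate_metadata,
)


def _sep(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() == ".tsv" else ","


def read_asv_table(path: str | Path, marker: str) -> AnnotatedASVTable:
    """Read an annotated ASV read-count table.

    Raises :class:`ValidationError` naming the offending row/column on
    missing taxonomy columns, negative or non-integer counts, or duplicate
    identifiers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    if "asv_id" not in df.columns:
        raise ValidationError(f"{path.name}: missing 'asv_id' column")
    missing = [r for r in TAXONOMY_RANKS if r not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing taxonomy column(s) {missing}")
    sample_cols = [c for c in df.columns if c not in ("asv_id", *TAXONOMY_RANKS)]
    if not sample_cols:
        raise ValidationError(f"{path.name}: no sample count columns found")
    taxonomy = df.set_index("asv_id")[list(TAXONOMY_RANKS)]
    counts = df.set_index("asv_id")[sample_cols]
    for col in sample_cols:
        num = pd.to_numeric(counts[col], errors="coerce")
        bad = num.isna() | (num % 1 != 0) | (num < 0)
        if bad.any():
            asv = counts.index[bad][0]
            raise ValidationError(
                f"{path.name}: invalid count {counts.loc[asv, col]!r} "
                f"at ASV {asv!r}, sample {col!r}"
            )
        counts[col] = num.astype(int)
    counts = counts.T
    counts = counts.rename_axis(index=None, columns=None)
    taxonomy = taxonomy.rename_axis(index=None)
    return AnnotatedASVTable(counts=counts, taxonomy=taxonomy, marker=marker)


def write_asv_table(table: AnnotatedASVTable, path: str | Path) -> None:
    path = Path(path)
    df = table.taxonomy.copy()
    df = pd.concat([df, table.counts.T], axis=1)
    df.index.name = "asv_id"
    df.to_csv(path, sep=_sep(path))


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample_id, habitat, session, sex, age)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path.name}: missing 'sample_id' column")
    return validate_metadata(df.set_index("sample_id"))


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=_sep(path))


def read_isotopes(path: str | Path) -> pd.DataFrame:
    """Read consumer/source isotope measurements."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    return validate_isotopes(df).reset_index(drop=True)[list(ISOTOPE_COLUMNS)]


def write_isotopes(records: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    records[list(ISOTOPE_COLUMNS)].to_csv(path, sep=_sep(path), index=False)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; ``None`` yields the defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
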