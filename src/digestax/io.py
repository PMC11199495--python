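"""Readers and writers for the plain-text formats used by the pipeline.

FASTA for sequences, a two-column TSV sidecar for taxonomies
(accession <TAB> semicolon-delimited seven-rank string), TSV/CSV for
count tables and sample metadata.  TSV is the canonical tabular
dialect (tab-separated, UTF-8, '.' decimal); CSV is accepted on read.
Writers are deterministic so identical inputs reproduce byte-identical
outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .errors import InvalidInputError
from .refdb import ReferenceRecord
from .taxonomy import TaxonomyPath, format_taxonomy, parse_taxonomy

logger = logging.getLogger("digestax")

#: Closed metadata vocabularies; out-of-vocabulary values fall back to
#: the last entry ("Other"/"unknown") with a logged warning.
METADATA_VOCABULARY = {
    "substrate": ("Wastewater sludge", "Industrial", "Food waste",
                  "Manure", "Other"),
    "temperature": ("Mesophilic", "Thermophilic", "unknown"),
    "technology": ("CSTR", "TSAD", "UASB", "Other"),
    "primer_set": ("V1-V3", "V4", "V3-V5"),
}


def read_fasta(path: str | Path,
               taxonomy: Mapping[str, TaxonomyPath] | None = None,
               source: str = "existing") -> list[ReferenceRecord]:
    """Read FASTA records (wrapped or unwrapped), uppercasing sequences.

    Duplicate identifiers are an error listing the offenders; an empty
    file yields an empty list with a warning.
    """
    records = []
    seen = set()
    dupes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            dupes.append(rec.id)
            continue
        seen.add(rec.id)
        tax = taxonomy.get(rec.id) if taxonomy else None
        records.append(ReferenceRecord(rec.id, str(rec.seq).upper(),
                                       tax, source))
    if dupes:
        raise InvalidInputError(f"duplicate FASTA ids: {dupes}")
    if not records:
        logger.warning("empty FASTA file: %s", path)
    return records


def write_fasta(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    """Write records unwrapped, one sequence per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n{rec.sequence}\n")


def read_taxonomy_table(path: str | Path) -> dict[str, TaxonomyPath]:
    """Read an accession<TAB>taxonomy sidecar file."""
    out: dict[str, TaxonomyPath] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InvalidInputError(
                    f"{path}:{line_no}: expected 2 tab-separated fields")
            acc, tax = parts
            if acc in out:
                raise InvalidInputError(
                    f"{path}:{line_no}: duplicate accession {acc!r}")
            out[acc] = parse_taxonomy(tax)
    return out


def write_taxonomy_table(taxonomy: Mapping[str, TaxonomyPath],
                         path: str | Path, prefixed: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for acc in taxonomy:
            fh.write(f"{acc}\t{format_taxonomy(taxonomy[acc], prefixed)}\n")


def _read_delimited(path: str | Path, **kwargs) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, **kwargs)


def read_counts(path: str | Path, orientation: str = "features",
                ) -> pd.DataFrame:
    """Read a count table as samples x features.

    ``orientation="features"`` expects the conventional layout with
    features in rows and samples in columns (transposed on read);
    ``"samples"`` reads rows as samples directly.  Counts must be
    non-negative integers.
    """
    df = _read_delimited(path, index_col=0)
    if orientation == "features":
        df = df.T
    elif orientation != "samples":
        raise InvalidInputError(f"unknown orientation {orientation!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        raise InvalidInputError(f"non-numeric counts in {path}") from None
    if (values < 0).any():
        raise InvalidInputError(f"negative counts in {path}")
    if (values != values.round()).any():
        raise InvalidInputError(f"non-integer counts in {path}")
    out = df.astype("int64")
    for axis, what in ((out.index, "sample"), (out.columns, "feature")):
        if axis.duplicated().any():
            raise InvalidInputError(
                f"duplicate {what} ids in {path}: "
                f"{list(axis[axis.duplicated()])}")
    return out


def write_table(df: pd.DataFrame, path: str | Path,
                index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_metadata(path: str | Path,
                  samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Read per-sample metadata, validating category vocabularies.

    Values outside a closed vocabulary are coerced to its fallback
    ("Other" or "unknown") with a warning.  When *samples* is given,
    every one of them must have a metadata row.
    """
    df = _read_delimited(path, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise InvalidInputError(
            f"duplicate sample ids in {path}: "
            f"{list(df.index[df.index.duplicated()])}")
    if samples is not None:
        missing = [s for s in samples if s not in df.index]
        if missing:
            raise InvalidInputError(
                f"samples present in table but not metadata: {missing}")
    for field, vocab in METADATA_VOCABULARY.items():
        if field not in df.columns:
            continue
        fallback = vocab[-1]
        bad = ~df[field].isin(vocab) | df[field].isna()
        if bad.any():
            logger.warning("%s: %d value(s) in %r outside %s; "
                           "coerced to %r", path, int(bad.sum()),
                           field, list(vocab), fallback)
            df.loc[bad, field] = fallback
    return df


def write_config(config: Mapping, path: str | Path) -> None:
    """Serialise the resolved run configuration next to the outputs."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


def read_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}
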