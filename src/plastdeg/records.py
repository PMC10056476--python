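"""Record schema I/O and taxonomic lineage handling.

A degradation record is one literature report linking a taxon (by NCBI-style
taxonomy id) to a plastic type. Tables are exchanged as UTF-8 TSV/CSV with
header columns ``tax_id, organism, lineage, plastic, reference``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

#: Default rank template used to pair positional lineage tokens with ranks.
DEFAULT_RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

REQUIRED_COLUMNS = ("tax_id", "organism", "lineage", "plastic", "reference")


class SchemaError(ValueError):
    """Input table does not conform to the record schema."""


class RecordParseError(ValueError):
    """A data row could not be parsed; carries the offending row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass(frozen=True)
class RankedLineage:
    """Ordered (rank, name) pairs from domain toward species.

    Ranks are lower-cased and unique; lookup by rank returns at most one name.
    """

    entries: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        ranks = [r for r, _ in self.entries]
        if len(ranks) != len(set(ranks)):
            raise ValueError(f"duplicate ranks in lineage: {ranks}")

    def get(self, rank: str) -> Optional[str]:
        rank = rank.lower()
        for r, name in self.entries:
            if r == rank:
                return name
        return None

    @property
    def genus(self) -> Optional[str]:
        return self.get("genus")

    def serialize(self, ranks: Sequence[str] = DEFAULT_RANKS) -> str:
        """Positional serialization against a rank template (absent ranks empty)."""
        by_rank = dict(self.entries)
        return ";".join(by_rank.get(r.lower(), "") for r in ranks)


@dataclass(frozen=True)
class DegradationRecord:
    """One literature report that a taxon degrades a plastic type."""

    tax_id: int
    organism: str
    lineage: RankedLineage
    plastic: str
    reference: str

    def __post_init__(self) -> None:
        if self.tax_id <= 0:
            raise ValueError(f"tax_id must be positive, got {self.tax_id}")
        if not self.plastic.strip():
            raise ValueError("plastic token is empty")


def _clean_plastic(token: str) -> str:
    # Trim and collapse internal whitespace; case and spelling are preserved
    # deliberately (plastic-type names are never merged as synonyms).
    return " ".join(token.split())


def parse_lineage(
    text: str, ranks: Sequence[str] = DEFAULT_RANKS
) -> RankedLineage:
    """Parse a semicolon- or pipe-delimited lineage string.

    Tokens are paired positionally with the rank template; empty (unnamed)
    ranks are skipped. Tokens beyond the template are ignored. Degenerate
    input yields an empty lineage rather than an error.
    """
    if text is None:
        return RankedLineage()
    text = text.strip()
    if not text:
        return RankedLineage()
    delim = "|" if ("|" in text and ";" not in text) else ";"
    tokens = [t.strip() for t in text.split(delim)]
    entries = tuple(
        (rank.lower(), name)
        for rank, name in zip(ranks, tokens)
        if name
    )
    return RankedLineage(entries)


def extract_genus(record: DegradationRecord) -> Optional[str]:
    """Genus-rank name from the record's lineage, or None.

    The genus is taken only from the lineage; the free-text organism name is
    never consulted (so "Bacillus sp." with a genus-less lineage yields None).
    """
    return record.lineage.genus


def read_records(
    path: str | Path,
    dialect: str = "tsv",
    ranks: Sequence[str] = DEFAULT_RANKS,
) -> list[DegradationRecord]:
    """Read a record table from TSV or CSV.

    The header must name the five schema columns (order-insensitive; extra
    columns are ignored). Fields are whitespace-trimmed and row order is
    preserved.

    Raises
    ------
    SchemaError
        if a required column is missing.
    RecordParseError
        if a row's tax_id is not a positive integer (cites the row index,
        0-based over data rows).
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'csv')")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records: list[DegradationRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = getattr(row, "tax_id").strip()
        try:
            tax_id = int(raw)
            if tax_id <= 0:
                raise ValueError
        except ValueError:
            raise RecordParseError(i, f"unparseable tax_id {raw!r}") from None
        records.append(
            DegradationRecord(
                tax_id=tax_id,
                organism=getattr(row, "organism").strip(),
                lineage=parse_lineage(getattr(row, "lineage"), ranks),
                plastic=_clean_plastic(getattr(row, "plastic")),
                reference=getattr(row, "reference").strip(),
            )
        )
    return records


def records_to_frame(
    records: Iterable[DegradationRecord], ranks: Sequence[str] = DEFAULT_RANKS
) -> pd.DataFrame:
    recs = list(records)
    return pd.DataFrame(
        {
            "tax_id": [r.tax_id for r in recs],
            "organism": [r.organism for r in recs],
            "lineage": [r.lineage.serialize(ranks) for r in recs],
            "plastic": [r.plastic for r in recs],
            "reference": [r.reference for r in recs],
        }
    )


def write_records(
    records: Sequence[DegradationRecord],
    path: str | Path,
    ranks: Sequence[str] = DEFAULT_RANKS,
) -> None:
    """Write records as TSV in the schema column order."""
    records_to_frame(list(records), ranks).to_csv(path, sep="\t", index=False)
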