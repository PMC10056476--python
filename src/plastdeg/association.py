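"""Binary genus x plastic association matrix and the C-C / C-X group scheme.

Plastic types split chemically into two backbone families: C-C plastics
(all-carbon backbone: PE, HDPE, LDPE, PP, PS, PVC, PVA) whose chains offer no
hydrolyzable linkage, and C-X plastics (heteroatoms in the backbone —
polyesters, polyamides, polyurethanes) that enzymes can cleave
hydrolytically. The association matrix records, per genus and plastic type,
whether at least one degradation report exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .curation import CuratedTable
from .records import DegradationRecord, extract_genus

CC = "CC"
CX = "CX"

#: All-carbon-backbone plastic types.
DEFAULT_CC_PLASTICS = ("PE", "HDPE", "LDPE", "PVC", "PVA", "PP", "PS")
#: Heteroatom-backbone (hydrolyzable) plastic types.
DEFAULT_CX_PLASTICS = (
    "PHB", "PHA", "PHBH", "PCL", "PU", "PES", "PBS",
    "PLA", "PHBV", "Nylon", "PBSA", "PET", "PBAT",
)

DEFAULT_MIN_PLASTICS = 4  # genus selection threshold: reported for >= 4 plastics


@dataclass(frozen=True)
class GroupScheme:
    """Mapping of plastic-type tokens to the CC or CX backbone group."""

    membership: Mapping[str, str]

    def __post_init__(self) -> None:
        groups = set(self.membership.values())
        bad = groups - {CC, CX}
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")
        if groups != {CC, CX}:
            raise ValueError("both CC and CX groups must be non-empty")

    def group_of(self, plastic: str) -> Optional[str]:
        return self.membership.get(plastic)

    @property
    def cc(self) -> tuple[str, ...]:
        return tuple(p for p, g in self.membership.items() if g == CC)

    @property
    def cx(self) -> tuple[str, ...]:
        return tuple(p for p, g in self.membership.items() if g == CX)

    def swapped(self) -> "GroupScheme":
        """Scheme with the CC/CX labels exchanged (useful for symmetry checks)."""
        return GroupScheme({p: CX if g == CC else CC for p, g in self.membership.items()})

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.membership.items()), columns=["plastic", "group"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroupScheme":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if list(df.columns) != ["plastic", "group"]:
            raise ValueError("scheme TSV must have columns: plastic, group")
        return cls(dict(zip(df["plastic"], df["group"])))


def default_group_scheme() -> GroupScheme:
    """The shipped backbone-chemistry scheme: 7 CC types and 13 CX types."""
    membership = {p: CC for p in DEFAULT_CC_PLASTICS}
    membership.update({p: CX for p in DEFAULT_CX_PLASTICS})
    return GroupScheme(membership)


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary incidence matrix: rows are genera, columns plastic types."""

    data: pd.DataFrame  # int 0/1, index=genera, columns=plastics

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("association matrix cells must be 0 or 1")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("genus and plastic labels must be unique")

    @property
    def genera(self) -> list[str]:
        return list(self.data.index)

    @property
    def plastics(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="genus")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AssociationMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="genus"))


def build_association_matrix(
    table: CuratedTable | Sequence[DegradationRecord],
) -> AssociationMatrix:
    """Incidence matrix with cell(g, p) = 1 iff >= 1 record pairs genus g with plastic p.

    Rows and columns are sorted lexicographically for determinism. Repeated
    reports of a pair do not change the cell (incidence, not counts).
    """
    records = table.records if isinstance(table, CuratedTable) else list(table)
    if not records:
        raise ValueError("cannot build an association matrix from an empty table")
    pairs = []
    for r in records:
        g = extract_genus(r)
        if g is None:
            raise ValueError(f"record tax_id={r.tax_id} lacks a genus in its lineage")
        pairs.append((g, r.plastic))
    df = pd.DataFrame(pairs, columns=["genus", "plastic"])
    mat = (pd.crosstab(df["genus"], df["plastic"]) > 0).astype(int)
    mat = mat.sort_index(axis=0).sort_index(axis=1)
    mat.index.name = None
    mat.columns.name = None
    return AssociationMatrix(mat)


def select_genera(
    matrix: AssociationMatrix, min_plastics: int = DEFAULT_MIN_PLASTICS
) -> AssociationMatrix:
    """Keep genera reported for at least ``min_plastics`` plastic types."""
    if min_plastics < 1:
        raise ValueError(f"min_plastics must be positive, got {min_plastics}")
    keep = matrix.data.sum(axis=1) >= min_plastics
    if not keep.any():
        raise ValueError(
            f"no genus is reported for >= {min_plastics} plastic types"
        )
    return AssociationMatrix(matrix.data.loc[keep])


@dataclass(frozen=True)
class SchemeReport:
    """Coverage report of a group scheme against a matrix's plastic columns."""

    unmapped_plastics: tuple[str, ...]  # matrix columns absent from the scheme
    unused_scheme_plastics: tuple[str, ...]  # scheme tokens absent from the matrix

    @property
    def ok(self) -> bool:
        return not self.unmapped_plastics


def validate_group_scheme(
    scheme: GroupScheme, matrix: AssociationMatrix
) -> SchemeReport:
    cols = set(matrix.plastics)
    mapped = set(scheme.membership)
    return SchemeReport(
        unmapped_plastics=tuple(sorted(cols - mapped)),
        unused_scheme_plastics=tuple(sorted(mapped - cols)),
    )
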