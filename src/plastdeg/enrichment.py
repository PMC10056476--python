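"""Per-genus group-proportion enrichment and the twofold tendency rule.

For each selected genus, the statistic is the fraction of each backbone
group's plastic types the genus is reported to degrade — e.g. a genus
reported for 2 of the 7 C-C types and 2 of the 13 C-X types scores
(2/7, 2/13). A genus is assigned a group tendency when one group's
proportion is at least twofold the other's; otherwise it is left
unassigned. Comparisons are made on exact fractions, never on the
2-decimal display values, because rounding first would flip boundary
cases (0.30 vs 2 x 0.15 is an exact tie that rounded values can break).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import pandas as pd

from .association import CC, CX, AssociationMatrix, GroupScheme
from .records import DegradationRecord, extract_genus

DEFAULT_FOLD = 2.0


@dataclass(frozen=True)
class EnrichmentRow:
    """Group counts, exact proportions, and tendency assignment for one genus."""

    genus: str
    taxon_class: str
    n_cc: int
    n_cx: int
    prop_cc: Fraction
    prop_cx: Fraction
    assignment: Optional[str]  # CC, CX, or None

    def swapped(self) -> "EnrichmentRow":
        return replace(
            self,
            n_cc=self.n_cx,
            n_cx=self.n_cc,
            prop_cc=self.prop_cx,
            prop_cx=self.prop_cc,
            assignment={CC: CX, CX: CC}.get(self.assignment),
        )


def assign_tendency(
    prop_cc: Fraction | float,
    prop_cx: Fraction | float,
    fold: float = DEFAULT_FOLD,
    strict: bool = False,
) -> Optional[str]:
    """Twofold rule: label toward the group whose proportion dominates.

    CC if prop_cc >= fold * prop_cx (and prop_cc > 0); CX symmetrically;
    otherwise None. ``strict=True`` uses > instead of >= at the boundary.
    A positive proportion against a zero one is always assigned (the fold
    ratio is infinite); zero against zero is never assigned.
    """
    if fold <= 1:
        raise ValueError(f"fold must exceed 1, got {fold}")
    if isinstance(fold, float) and fold.is_integer():
        fold = int(fold)  # keep Fraction comparisons exact for integer folds
    dominates = (lambda x, y: x > fold * y) if strict else (lambda x, y: x >= fold * y)
    if prop_cc > 0 and dominates(prop_cc, prop_cx):
        return CC
    if prop_cx > 0 and dominates(prop_cx, prop_cc):
        return CX
    return None


def class_lookup_from_records(
    records: Sequence[DegradationRecord],
) -> dict[str, str]:
    """Genus -> class-rank name, from the record lineages.

    If records of one genus disagree on the class, the most frequent name
    wins (ties broken lexicographically).
    """
    votes: dict[str, dict[str, int]] = {}
    for r in records:
        g = extract_genus(r)
        cls = r.lineage.get("class")
        if g is not None and cls is not None:
            votes.setdefault(g, {}).setdefault(cls, 0)
            votes[g][cls] += 1
    return {
        g: min(cnt, key=lambda c: (-cnt[c], c))
        for g, cnt in votes.items()
    }


def group_proportions(
    matrix: AssociationMatrix,
    scheme: GroupScheme,
    class_lookup: Optional[Mapping[str, str]] = None,
    fold: float = DEFAULT_FOLD,
    strict: bool = False,
    allow_unmapped: bool = False,
) -> list[EnrichmentRow]:
    """Per-genus group counts, exact proportions, and tendency assignments.

    Denominators are the number of scheme-mapped plastic columns per group
    (with the shipped scheme and all 20 retained plastic types present:
    7 for C-C, 13 for C-X). Unmapped matrix columns raise unless
    ``allow_unmapped``, in which case they are excluded from both groups.
    """
    class_lookup = class_lookup or {}
    cols_cc = [p for p in matrix.plastics if scheme.group_of(p) == CC]
    cols_cx = [p for p in matrix.plastics if scheme.group_of(p) == CX]
    unmapped = [p for p in matrix.plastics if scheme.group_of(p) is None]
    if unmapped and not allow_unmapped:
        raise ValueError(
            f"plastic column(s) not mapped by the group scheme: {', '.join(unmapped)}"
        )
    if not cols_cc or not cols_cx:
        raise ValueError("matrix must contain at least one plastic from each group")
    rows = []
    for genus in matrix.genera:
        profile = matrix.data.loc[genus]
        n_cc = int(profile[cols_cc].sum())
        n_cx = int(profile[cols_cx].sum())
        prop_cc = Fraction(n_cc, len(cols_cc))
        prop_cx = Fraction(n_cx, len(cols_cx))
        rows.append(
            EnrichmentRow(
                genus=genus,
                taxon_class=class_lookup.get(genus, ""),
                n_cc=n_cc,
                n_cx=n_cx,
                prop_cc=prop_cc,
                prop_cx=prop_cx,
                assignment=assign_tendency(prop_cc, prop_cx, fold=fold, strict=strict),
            )
        )
    return rows


def order_rows(
    rows: Sequence[EnrichmentRow], tree: Optional[str] = None
) -> list[EnrichmentRow]:
    """Order rows for display: by a phylogeny's leaf order if given, else by
    (class, genus) lexicographically.

    ``tree`` is a newick string (or path to one) whose leaves must cover every
    genus; extra leaves are ignored.
    """
    if tree is None:
        return sorted(rows, key=lambda r: (r.taxon_class, r.genus))
    text = tree
    p = Path(tree)
    if not text.lstrip().startswith("(") and p.exists():
        text = p.read_text()
    t = dendropy.Tree.get(data=text, schema="newick")
    leaf_order = [leaf.taxon.label.replace(" ", "_") for leaf in t.leaf_node_iter()]
    rank = {name: i for i, name in enumerate(leaf_order)}
    missing = sorted(r.genus for r in rows if r.genus not in rank)
    if missing:
        raise ValueError(f"tree is missing genus leaves: {', '.join(missing)}")
    return sorted(rows, key=lambda r: rank[r.genus])


def heatmap_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Tabular form of the enrichment heatmap (proportions shown to 2 decimals)."""
    return pd.DataFrame(
        {
            "genus": [r.genus for r in rows],
            "class": [r.taxon_class for r in rows],
            "prop_cc": [f"{float(r.prop_cc):.2f}" for r in rows],
            "prop_cx": [f"{float(r.prop_cx):.2f}" for r in rows],
            "assignment": [r.assignment or "" for r in rows],
        }
    )


def export_heatmap_table(
    rows: Sequence[EnrichmentRow], path: Optional[str | Path] = None
) -> str:
    """Write (or return) the ordered heatmap table as TSV."""
    buf = io.StringIO()
    heatmap_frame(rows).to_csv(buf, sep="\t", index=False)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def per_plastic_table(
    matrix: AssociationMatrix,
    scheme: GroupScheme,
    rows: Optional[Sequence[EnrichmentRow]] = None,
) -> pd.DataFrame:
    """Extended table listing each reported plastic token per genus, by group."""
    genera = [r.genus for r in rows] if rows is not None else matrix.genera
    out = []
    for genus in genera:
        profile = matrix.data.loc[genus]
        reported = [p for p in matrix.plastics if profile[p] == 1]
        out.append(
            {
                "genus": genus,
                "cc_plastics": ",".join(p for p in reported if scheme.group_of(p) == CC),
                "cx_plastics": ",".join(p for p in reported if scheme.group_of(p) == CX),
            }
        )
    return pd.DataFrame(out)
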