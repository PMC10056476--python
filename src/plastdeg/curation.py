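"""Record-curation funnel and report-frequency summaries.

The funnel applies four filters in a fixed order — exact-duplicate removal,
uncultured-organism removal, genus requirement, rare-plastic removal — and
logs per-stage counts so a run can be compared side by side with any other
corpus curated the same way. Stage order matters (the rare-plastic counts
depend on what earlier stages dropped), so the composed funnel always uses
this order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .records import DegradationRecord, extract_genus

logger = logging.getLogger(__name__)

DEFAULT_MIN_TAXA = 10  # plastics reported by fewer distinct tax_ids are dropped


@dataclass(frozen=True)
class FunnelStage:
    name: str
    n_in: int
    n_dropped: int
    n_out: int

    def __post_init__(self) -> None:
        if self.n_in != self.n_dropped + self.n_out:
            raise ValueError(
                f"stage {self.name}: n_in ({self.n_in}) != "
                f"n_dropped ({self.n_dropped}) + n_out ({self.n_out})"
            )


@dataclass
class CuratedTable:
    """Records surviving the funnel plus per-stage drop counters."""

    records: list[DegradationRecord]
    funnel: list[FunnelStage] = field(default_factory=list)
    retained_plastics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for prev, cur in zip(self.funnel, self.funnel[1:]):
            if prev.n_out != cur.n_in:
                raise ValueError(
                    f"funnel stages do not chain: {prev.name} n_out={prev.n_out} "
                    f"but {cur.name} n_in={cur.n_in}"
                )

    def funnel_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.n_in, s.n_dropped, s.n_out) for s in self.funnel],
            columns=["stage", "n_in", "n_dropped", "n_out"],
        )

    def write_funnel(self, path: str | Path) -> None:
        self.funnel_frame().to_csv(path, sep="\t", index=False)


def _stage(
    name: str,
    records: Sequence[DegradationRecord],
    keep: Callable[[DegradationRecord], bool],
) -> CuratedTable:
    kept = [r for r in records if keep(r)]
    stage = FunnelStage(name, len(records), len(records) - len(kept), len(kept))
    logger.info(
        "curation stage %s: %d in, %d dropped, %d out",
        stage.name, stage.n_in, stage.n_dropped, stage.n_out,
    )
    return CuratedTable(kept, [stage])


def drop_duplicates(records: Sequence[DegradationRecord]) -> CuratedTable:
    """Collapse rows identical on (tax_id, organism, plastic, reference).

    The first occurrence is kept; two reports of the same taxon+plastic from
    distinct references are NOT duplicates.
    """
    seen: set[tuple] = set()

    def keep(r: DegradationRecord) -> bool:
        key = (r.tax_id, r.organism, r.plastic, r.reference)
        if key in seen:
            return False
        seen.add(key)
        return True

    return _stage("duplicates", records, keep)


def is_uncultured(organism: str) -> bool:
    """Case-insensitive 'uncultured' substring predicate on the organism name."""
    return "uncultured" in organism.lower()


def drop_uncultured(records: Sequence[DegradationRecord]) -> CuratedTable:
    return _stage("uncultured", records, lambda r: not is_uncultured(r.organism))


def require_genus(records: Sequence[DegradationRecord]) -> CuratedTable:
    """Keep only records whose lineage carries a genus-rank name."""
    return _stage("genus", records, lambda r: extract_genus(r) is not None)


def filter_rare_plastics(
    records: Sequence[DegradationRecord], min_taxa: int = DEFAULT_MIN_TAXA
) -> CuratedTable:
    """Drop plastic types reported by fewer than ``min_taxa`` distinct tax_ids.

    Counting uses distinct taxonomy ids (not raw rows) so repeated reports of
    one organism cannot carry a plastic over the threshold; the rule is
    inclusive (exactly ``min_taxa`` distinct ids is retained).
    """
    if min_taxa < 1:
        raise ValueError(f"min_taxa must be positive, got {min_taxa}")
    taxa_per_plastic: dict[str, set[int]] = {}
    for r in records:
        taxa_per_plastic.setdefault(r.plastic, set()).add(r.tax_id)
    retained = {p for p, taxa in taxa_per_plastic.items() if len(taxa) >= min_taxa}
    table = _stage("rare_plastic", records, lambda r: r.plastic in retained)
    table.retained_plastics = sorted(retained)
    return table


def curation_funnel(
    records: Sequence[DegradationRecord], min_taxa: int = DEFAULT_MIN_TAXA
) -> CuratedTable:
    """Apply the full funnel: duplicates -> uncultured -> genus -> rare plastic."""
    t1 = drop_duplicates(records)
    t2 = drop_uncultured(t1.records)
    t3 = require_genus(t2.records)
    t4 = filter_rare_plastics(t3.records, min_taxa=min_taxa)
    return CuratedTable(
        t4.records,
        t1.funnel + t2.funnel + t3.funnel + t4.funnel,
        t4.retained_plastics,
    )


@dataclass(frozen=True)
class ECDCurve:
    """Empirical cumulative distribution of per-taxon report counts.

    ``support`` holds the sorted distinct report counts and
    ``cumulative_fraction`` the fraction of taxa reported at most that many
    times; the final fraction is 1.
    """

    level: str
    support: tuple[int, ...]
    cumulative_fraction: tuple[float, ...]

    def __post_init__(self) -> None:
        fracs = np.asarray(self.cumulative_fraction)
        if len(fracs) and (np.any(np.diff(fracs) < 0) or not np.isclose(fracs[-1], 1.0)):
            raise ValueError("cumulative fractions must be non-decreasing and end at 1")

    @property
    def singleton_fraction(self) -> float:
        """Fraction of taxa reported exactly once."""
        if not self.support:
            return float("nan")
        return self.cumulative_fraction[0] if self.support[0] == 1 else 0.0

    def fraction_at_most(self, count: int) -> float:
        frac = 0.0
        for s, f in zip(self.support, self.cumulative_fraction):
            if s <= count:
                frac = f
        return frac

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reports": self.support, "cumulative_fraction": self.cumulative_fraction}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def report_frequency_ecd(
    records: Sequence[DegradationRecord], level: str = "species"
) -> ECDCurve:
    """ECD of report counts per distinct taxon at species (tax_id) or genus level."""
    if level == "species":
        keys = [r.tax_id for r in records]
    elif level == "genus":
        keys = []
        for r in records:
            g = extract_genus(r)
            if g is None:
                raise ValueError(
                    f"genus-level ECD requires genus in every lineage "
                    f"(tax_id {r.tax_id} has none)"
                )
            keys.append(g)
    else:
        raise ValueError(f"level must be 'species' or 'genus', got {level!r}")
    counts = pd.Series(keys).value_counts()
    dist = counts.value_counts().sort_index()  # reports -> n taxa
    cum = dist.cumsum() / dist.sum()
    return ECDCurve(
        level=level,
        support=tuple(int(s) for s in dist.index),
        cumulative_fraction=tuple(float(f) for f in cum),
    )
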