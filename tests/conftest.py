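import pandas as pd
import pytest

from plastdeg.association import AssociationMatrix, default_group_scheme
from plastdeg.records import DegradationRecord, RankedLineage, parse_lineage


def make_record(
    tax_id=1,
    organism="Pseudomonas putida",
    genus="Pseudomonas",
    taxon_class="Gammaproteobacteria",
    plastic="PET",
    reference="ref1",
    with_genus=True,
):
    entries = [
        ("domain", "Bacteria"),
        ("class", taxon_class),
        ("family", f"{genus}aceae"),
    ]
    if with_genus:
        entries.append(("genus", genus))
    return DegradationRecord(
        tax_id=tax_id,
        organism=organism,
        lineage=RankedLineage(tuple(entries)),
        plastic=plastic,
        reference=reference,
    )


@pytest.fixture
def toy_records():
    """8-record corpus exercising every funnel stage at min_taxa=2.

    One exact duplicate, one uncultured organism, one genus-less lineage, and
    one plastic (PLA) reported by a single taxonomy id. Hand-traced funnel:
    8 -> 7 (duplicate) -> 6 (uncultured) -> 5 (no genus) -> 4 (rare plastic).
    """
    r1 = make_record(tax_id=1, reference="refA")
    return [
        r1,
        r1,  # exact duplicate of r1
        make_record(tax_id=1, reference="refB"),  # same pair, new reference: kept
        make_record(tax_id=99, organism="uncultured bacterium", genus="X",
                    reference="refC"),
        make_record(tax_id=2, organism="Bacillus subtilis", genus="Bacillus",
                    taxon_class="Bacilli", reference="refD"),
        make_record(tax_id=3, organism="Bacillaceae bacterium", with_genus=False,
                    genus="Bacillus", taxon_class="Bacilli", reference="refE"),
        make_record(tax_id=4, organism="Aspergillus niger", genus="Aspergillus",
                    taxon_class="Eurotiomycetes", plastic="PLA", reference="refF"),
        make_record(tax_id=5, organism="Penicillium sp.", genus="Penicillium",
                    taxon_class="Eurotiomycetes", reference="refG"),
    ]


@pytest.fixture
def scheme():
    return default_group_scheme()


@pytest.fixture
def worked_matrix(scheme):
    """Matrix over all 20 scheme plastics with a Staphylococcus-like genus
    reported for 2 C-C (PE, PS) and 2 C-X (PET, PLA) types, plus a genus
    reported for everything (so no column is all-zero)."""
    plastics = sorted(scheme.membership)
    staph = {p: 0 for p in plastics}
    for p in ("PE", "PS", "PET", "PLA"):
        staph[p] = 1
    data = pd.DataFrame(
        [staph, {p: 1 for p in plastics}],
        index=["Staphylococcus", "Pseudomonas"],
    )[plastics]
    return AssociationMatrix(data)
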