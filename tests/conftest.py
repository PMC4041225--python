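"""Shared fixtures: a tiny handcrafted reference and the default synthetic one."""

from __future__ import annotations

import pytest

from itsclade.refdb import ReferenceDB, ReferenceRecord, RegionSpec, TaxonomyPath
from itsclade.synth import CladeModel, generate_reference


def taxon(clade: str, subcluster: str = "SC5.1",
          genus: str = "Synechococcus") -> TaxonomyPath:
    return TaxonomyPath(("Cyanobacteria", genus, subcluster, clade))


@pytest.fixture
def tiny_db() -> ReferenceDB:
    """Three clades x two members, 20 columns, with gaps; fully handcrafted."""
    rows = [
        ("II_a",  "ACGTACGTAC--GTACGTAC", "II"),
        ("II_b",  "ACGTACGTAC--GTACGTAC", "II"),
        ("IV_a",  "ACGTTTTTAC--GTACGAAC", "IV"),
        ("IV_b",  "ACGTTTTTAC--GTACGAAC", "IV"),
        ("CRD1_a", "TTTTACGTACGGGTACGTTT", "CRD1"),
        ("CRD1_b", "TTTTACGTACGGGTACGTTT", "CRD1"),
    ]
    records = [ReferenceRecord(i, s, taxon(c)) for i, s, c in rows]
    return ReferenceDB(records, 20)


@pytest.fixture(scope="session")
def default_reference():
    """The default synthetic fixture: 18 clades x 4 members, fixed seed."""
    db, truth, region = generate_reference(CladeModel(seed=2024))
    return db, truth, region
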