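"""Shared fixtures: fragment geometry and small hand-built count tables."""

from __future__ import annotations

import numpy as np
import pytest

from mthet import GenomeCoords, RegionMap, SampleProfile, StrandCountTable
from mthet.calling import BASES, HeteroplasmyCall
from mthet.coords import default_coords


@pytest.fixture(scope="session")
def coords() -> GenomeCoords:
    return default_coords()


@pytest.fixture(scope="session")
def region_map(coords) -> RegionMap:
    return RegionMap(coords=coords)


def counts_vec(**bases: int) -> list[int]:
    """(A, C, G, T) count vector from keyword arguments."""
    vec = [0, 0, 0, 0]
    for b, n in bases.items():
        vec[BASES.index(b)] = n
    return vec


@pytest.fixture
def make_table(coords):
    """Factory: StrandCountTable with given per-site (plus, minus) counts and a
    uniform background depth of major-allele reads everywhere else."""

    def _make(
        sample_id: str = "S1",
        per_site: dict[int, tuple[list[int], list[int]]] | None = None,
        background_depth: int = 0,
    ) -> StrandCountTable:
        n = coords.fragment_length
        plus = np.zeros((n, 4), dtype=np.int64)
        minus = np.zeros((n, 4), dtype=np.int64)
        if background_depth:
            plus[:, 0] = background_depth  # all-A background
            minus[:, 0] = background_depth
        for site, (p, m) in (per_site or {}).items():
            idx = coords.require(site)
            plus[idx] = p
            minus[idx] = m
        return StrandCountTable(sample_id, plus, minus, coords)

    return _make


@pytest.fixture
def make_profile():
    """Factory: QC-passing SampleProfile from a site -> MAF mapping."""

    def _make(
        sample_id: str,
        group: str = "CENT",
        family_id: str | None = None,
        maf_by_site: dict[int, float] | None = None,
        age: float = 70.0,
    ) -> SampleProfile:
        calls = tuple(
            HeteroplasmyCall(site=s, major_allele="A", minor_allele="G",
                             maf=m, depth=50_000, ds_validated=True)
            for s, m in sorted((maf_by_site or {}).items())
        )
        return SampleProfile(
            sample_id=sample_id, group=group, family_id=family_id, age=age,
            mean_coverage=50_000.0, qc_pass=True, calls=calls,
        )

    return _make
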