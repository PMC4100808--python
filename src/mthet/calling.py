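"""Heteroplasmy calling from strand-resolved allele counts.

The pipeline enters here: per-sample tables of post-alignment,
post-quality-filter base counts (A/C/G/T) per fragment position and strand.
A site is called heteroplasmic in a sample when

* its combined-strand minor allele frequency (MAF) is at or above the
  detection threshold (default 0.2%, i.e. ``maf >= 0.002``), and
* the *same* minor allele reaches the per-strand threshold independently on
  the plus and the minus strand (double-strand validation, which suppresses
  strand-specific sequencing artefacts).

The minor allele is defined per sample relative to that sample's own major
allele, not the rCRS reference base: heteroplasmy is intra-individual
variation, so a homoplasmic difference from the reference is not a call.
Ties in counts are broken alphabetically (A < C < G < T), deterministically.

Samples whose mean combined-strand coverage over the 853 fragment positions
falls below the coverage floor (default 10,000x; exactly 10,000 passes) are
excluded from heteroplasmy analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .coords import GenomeCoords, default_coords
from .errors import ParameterError, SchemaError

__all__ = [
    "BASES",
    "StrandCountTable",
    "HeteroplasmyCall",
    "SampleProfile",
    "SiteSummary",
    "site_allele_summary",
    "double_strand_validate",
    "call_sample",
    "sample_qc",
    "build_profile",
]

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_THRESHOLD = 0.002
DEFAULT_COVERAGE_FLOOR = 10_000.0


def _as_count_vector(counts: Mapping[str, int] | Sequence[int] | np.ndarray) -> np.ndarray:
    if isinstance(counts, Mapping):
        vec = np.zeros(4, dtype=np.int64)
        for base, n in counts.items():
            if base not in _BASE_INDEX:
                raise SchemaError(f"unknown base {base!r}; only A/C/G/T are supported")
            vec[_BASE_INDEX[base]] = int(n)
    else:
        vec = np.asarray(counts, dtype=np.int64)
        if vec.shape != (4,):
            raise SchemaError(f"expected 4 base counts (A,C,G,T), got shape {vec.shape}")
    if (vec < 0).any():
        raise SchemaError("negative base count")
    return vec


@dataclass
class StrandCountTable:
    """Dense per-sample strand-resolved counts over the fragment.

    ``plus`` and ``minus`` are (n_positions, 4) integer arrays in fragment
    order with columns A, C, G, T; positions with no sequencing data hold
    zeros.  At most one input row per (site, strand) is accepted when
    building from records.
    """

    sample_id: str
    plus: np.ndarray
    minus: np.ndarray
    coords: GenomeCoords = field(default_factory=GenomeCoords)

    def __post_init__(self) -> None:
        n = self.coords.fragment_length
        self.plus = np.asarray(self.plus, dtype=np.int64)
        self.minus = np.asarray(self.minus, dtype=np.int64)
        for name, arr in (("plus", self.plus), ("minus", self.minus)):
            if arr.shape != (n, 4):
                raise SchemaError(
                    f"{name} counts must have shape ({n}, 4), got {arr.shape}"
                )
            if (arr < 0).any():
                raise SchemaError(f"negative count in {name}-strand table")

    @classmethod
    def empty(cls, sample_id: str, coords: GenomeCoords | None = None) -> "StrandCountTable":
        coords = coords or default_coords()
        n = coords.fragment_length
        return cls(sample_id, np.zeros((n, 4), np.int64), np.zeros((n, 4), np.int64), coords)

    @classmethod
    def from_records(
        cls,
        sample_id: str,
        records: Iterable[tuple[int, str, Sequence[int]]],
        coords: GenomeCoords | None = None,
    ) -> "StrandCountTable":
        """Build from (site, strand, (A,C,G,T)) records; strand is '+' or '-'."""
        table = cls.empty(sample_id, coords)
        seen: set[tuple[int, str]] = set()
        for site, strand, counts in records:
            if strand not in ("+", "-"):
                raise SchemaError(f"unknown strand symbol {strand!r}")
            idx = table.coords.require(int(site))
            key = (int(site), strand)
            if key in seen:
                raise SchemaError(f"duplicate row for site {site} strand {strand}")
            seen.add(key)
            vec = _as_count_vector(counts)
            if strand == "+":
                table.plus[idx] = vec
            else:
                table.minus[idx] = vec
        return table

    @property
    def combined(self) -> np.ndarray:
        return self.plus + self.minus

    @property
    def depth(self) -> np.ndarray:
        """Combined-strand depth per fragment position."""
        return self.combined.sum(axis=1)

    def swap_strands(self) -> "StrandCountTable":
        return StrandCountTable(self.sample_id, self.minus.copy(), self.plus.copy(), self.coords)


@dataclass(frozen=True)
class HeteroplasmyCall:
    """One validated heteroplasmic site in one sample."""

    site: int
    major_allele: str
    minor_allele: str
    maf: float
    depth: int
    ds_validated: bool

    def __post_init__(self) -> None:
        if self.major_allele == self.minor_allele:
            raise ParameterError("major and minor allele must differ")
        if not 0.0 <= self.maf <= 0.5:
            raise ParameterError(f"MAF {self.maf} outside [0, 0.5]")
        if self.depth <= 0:
            raise ParameterError("depth must be positive")


@dataclass(frozen=True)
class SiteSummary:
    """Combined-strand allele summary for one site."""

    major: str
    minor: str
    maf: float
    depth: int
    minor_freq_plus: float
    minor_freq_minus: float


def _rank_alleles(combined: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of major and minor allele per site, alphabetical tie-break.

    A stable descending sort on counts keeps the original (alphabetical)
    column order among ties, which makes the tie-break deterministic.
    """
    order = np.argsort(-combined, axis=-1, kind="stable")
    return order[..., 0], order[..., 1]


def site_allele_summary(
    plus_counts: Mapping[str, int] | Sequence[int] | np.ndarray,
    minus_counts: Mapping[str, int] | Sequence[int] | np.ndarray,
) -> SiteSummary:
    """Summarise one site: major/minor allele, combined MAF, per-strand minor freqs.

    Raises :class:`ParameterError` on zero combined depth (the caller should
    skip and log such sites).
    """
    plus = _as_count_vector(plus_counts)
    minus = _as_count_vector(minus_counts)
    combined = plus + minus
    depth = int(combined.sum())
    if depth == 0:
        raise ParameterError("site has zero combined depth")
    major_i, minor_i = _rank_alleles(combined)
    major_i, minor_i = int(major_i), int(minor_i)
    maf = combined[minor_i] / depth
    pdep, mdep = plus.sum(), minus.sum()
    return SiteSummary(
        major=BASES[major_i],
        minor=BASES[minor_i],
        maf=float(maf),
        depth=depth,
        minor_freq_plus=float(plus[minor_i] / pdep) if pdep > 0 else 0.0,
        minor_freq_minus=float(minus[minor_i] / mdep) if mdep > 0 else 0.0,
    )


def double_strand_validate(
    minor_freq_plus: float,
    minor_freq_minus: float,
    threshold: float,
    same_minor_allele: bool = True,
    plus_depth: int = 1,
    minus_depth: int = 1,
) -> bool:
    """True iff the same minor allele reaches ``threshold`` on both strands.

    A strand with zero depth fails validation (logged as strand dropout).
    """
    if plus_depth <= 0 or minus_depth <= 0:
        logger.warning("double-strand validation failed: strand dropout (zero depth)")
        return False
    if not same_minor_allele:
        return False
    return minor_freq_plus >= threshold and minor_freq_minus >= threshold


def call_sample(
    table: StrandCountTable,
    threshold: float = DEFAULT_THRESHOLD,
    per_strand_multiplier: float = 1.0,
    require_double_strand: bool = True,
) -> tuple[HeteroplasmyCall, ...]:
    """Call heteroplasmic sites in one sample.

    Returns one call per site whose combined MAF is >= ``threshold`` (sites
    exactly at threshold are called) and which passes double-strand
    validation at ``threshold * per_strand_multiplier`` per strand.  With
    ``require_double_strand=False`` the strand check only annotates
    ``ds_validated`` instead of filtering.
    """
    if not 0.0 < threshold <= 0.5:
        raise ParameterError(f"threshold {threshold} outside (0, 0.5]")
    combined = table.combined
    depth = combined.sum(axis=1)
    covered = depth > 0
    if not covered.any():
        logger.warning("sample %s: empty count table, no calls", table.sample_id)
        return ()
    n_uncovered = int((~covered).sum())
    if n_uncovered:
        logger.debug("sample %s: %d sites with zero depth skipped", table.sample_id, n_uncovered)

    major_i, minor_i = _rank_alleles(combined)
    rows = np.arange(combined.shape[0])
    minor_count = combined[rows, minor_i]
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(covered, minor_count / np.maximum(depth, 1), 0.0)

    pdep = table.plus.sum(axis=1)
    mdep = table.minus.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_plus = np.where(pdep > 0, table.plus[rows, minor_i] / np.maximum(pdep, 1), 0.0)
        minor_minus = np.where(mdep > 0, table.minus[rows, minor_i] / np.maximum(mdep, 1), 0.0)

    strand_thr = threshold * per_strand_multiplier
    # the minor allele on each strand must be the combined minor allele; a
    # strand whose reads for that base reach the threshold supports it by
    # construction, so identity is enforced through the shared minor_i index
    ds_ok = (pdep > 0) & (mdep > 0) & (minor_plus >= strand_thr) & (minor_minus >= strand_thr)

    passing = covered & (maf >= threshold)
    if require_double_strand:
        passing &= ds_ok

    calls = []
    positions = table.coords.positions
    for idx in np.nonzero(passing)[0]:
        calls.append(
            HeteroplasmyCall(
                site=int(positions[idx]),
                major_allele=BASES[int(major_i[idx])],
                minor_allele=BASES[int(minor_i[idx])],
                maf=float(maf[idx]),
                depth=int(depth[idx]),
                ds_validated=bool(ds_ok[idx]),
            )
        )
    return tuple(calls)


def sample_qc(
    table: StrandCountTable, floor: float = DEFAULT_COVERAGE_FLOOR
) -> tuple[float, bool]:
    """Mean combined coverage over all fragment positions, and QC verdict.

    Positions with no data count as zero depth.  Mean coverage exactly at the
    floor passes (only strictly lower coverage is excluded).
    """
    mean_cov = float(table.depth.mean())
    return mean_cov, mean_cov >= floor


@dataclass(frozen=True)
class SampleProfile:
    """A sample's metadata, QC status and validated calls."""

    sample_id: str
    group: str
    family_id: str | None
    age: float
    mean_coverage: float
    qc_pass: bool
    calls: tuple[HeteroplasmyCall, ...] = ()

    def __post_init__(self) -> None:
        if not self.qc_pass and self.calls:
            raise ParameterError("QC-failed sample must carry no calls")

    @property
    def sites(self) -> frozenset[int]:
        return frozenset(c.site for c in self.calls)

    @property
    def maf_by_site(self) -> dict[int, float]:
        return {c.site: c.maf for c in self.calls}


GROUPS = ("CENT", "CO", "ONLL")


def build_profile(
    table: StrandCountTable,
    group: str,
    family_id: str | None = None,
    age: float = float("nan"),
    threshold: float = DEFAULT_THRESHOLD,
    coverage_floor: float = DEFAULT_COVERAGE_FLOOR,
    per_strand_multiplier: float = 1.0,
) -> SampleProfile:
    """QC a sample and, if it passes, call its heteroplasmies."""
    if group not in GROUPS:
        raise ParameterError(f"group must be one of {GROUPS}, got {group!r}")
    mean_cov, qc_pass = sample_qc(table, coverage_floor)
    calls: tuple[HeteroplasmyCall, ...] = ()
    if qc_pass:
        calls = call_sample(table, threshold, per_strand_multiplier)
    else:
        logger.info(
            "sample %s excluded: mean coverage %.1f < %.1f",
            table.sample_id, mean_cov, coverage_floor,
        )
    return SampleProfile(
        sample_id=table.sample_id,
        group=group,
        family_id=family_id,
        age=age,
        mean_coverage=mean_cov,
        qc_pass=qc_pass,
        calls=calls,
    )
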