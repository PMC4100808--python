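"""Circular rCRS coordinate arithmetic and control-region geometry.

All coordinates are 1-based positions on the 16,569-bp revised Cambridge
Reference Sequence (rCRS, GenBank NC_012920) and all intervals are closed.
The analysed fragment is the 853-bp stretch of the mtDNA control region
running from position 15978 across the origin of the circular genome to
position 261.  Circularity is handled by explicit arc enumeration (never
modular arithmetic on offsets) so that region boundaries stay auditable.

Region conventions::

    HV1           15978 .. 16364   (hypervariable segment 1, 387 bp)
    INTERMEDIATE  16365 .. 72      (origin-crossing stretch, 277 bp)
    HV2           73 .. 261        (part of hypervariable segment 2, 189 bp)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np

from .errors import CoordinateError, ParameterError, SchemaError

__all__ = [
    "GenomeCoords",
    "RegionMap",
    "circular_interval_length",
    "fragment_positions",
    "assign_region",
    "region_sizes",
]

RCRS_LENGTH = 16569
FRAGMENT_START = 15978
FRAGMENT_END = 261

DEFAULT_REGIONS: tuple[tuple[str, int, int], ...] = (
    ("HV1", 15978, 16364),
    ("INTERMEDIATE", 16365, 72),
    ("HV2", 73, 261),
)


def circular_interval_length(start: int, end: int, genome_length: int = RCRS_LENGTH) -> int:
    """Length in bp of the closed circular interval ``[start, end]``.

    When ``start <= end`` this is the ordinary ``end - start + 1``; when the
    interval crosses the origin it is the length of the arc running forward
    from ``start`` through the origin to ``end``.
    """
    if genome_length < 1:
        raise CoordinateError(f"genome length must be positive, got {genome_length}")
    for pos in (start, end):
        if not 1 <= pos <= genome_length:
            raise CoordinateError(
                f"position {pos} outside [1, {genome_length}]"
            )
    if start <= end:
        return end - start + 1
    return (genome_length - start + 1) + end


def _arc_positions(start: int, end: int, genome_length: int) -> np.ndarray:
    """Explicitly enumerate the 1-based positions of a circular arc, in order."""
    if start <= end:
        return np.arange(start, end + 1, dtype=np.int64)
    return np.concatenate(
        [
            np.arange(start, genome_length + 1, dtype=np.int64),
            np.arange(1, end + 1, dtype=np.int64),
        ]
    )


@dataclass(frozen=True)
class GenomeCoords:
    """The circular genome and the fragment under analysis (1-based, closed)."""

    genome_length: int = RCRS_LENGTH
    fragment_start: int = FRAGMENT_START
    fragment_end: int = FRAGMENT_END

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise CoordinateError("genome_length must be >= 1")
        for pos in (self.fragment_start, self.fragment_end):
            if not 1 <= pos <= self.genome_length:
                raise CoordinateError(
                    f"fragment bound {pos} outside [1, {self.genome_length}]"
                )

    @property
    def fragment_length(self) -> int:
        return circular_interval_length(
            self.fragment_start, self.fragment_end, self.genome_length
        )

    @cached_property
    def positions(self) -> np.ndarray:
        """Fragment positions in fragment order (read-only array)."""
        arc = _arc_positions(self.fragment_start, self.fragment_end, self.genome_length)
        arc.setflags(write=False)
        return arc

    @cached_property
    def position_index(self) -> dict[int, int]:
        """Map rCRS position -> 0-based column index in fragment order."""
        return {int(p): i for i, p in enumerate(self.positions)}

    def contains(self, pos: int) -> bool:
        return pos in self.position_index

    def require(self, pos: int) -> int:
        """Return the fragment index of ``pos`` or raise :class:`CoordinateError`."""
        try:
            return self.position_index[pos]
        except KeyError:
            raise CoordinateError(f"position {pos} outside the analysed fragment") from None


_DEFAULT_COORDS: GenomeCoords | None = None


def default_coords() -> GenomeCoords:
    """Shared default rCRS fragment geometry (caches the position index once)."""
    global _DEFAULT_COORDS
    if _DEFAULT_COORDS is None:
        _DEFAULT_COORDS = GenomeCoords()
    return _DEFAULT_COORDS


def fragment_positions(coords: GenomeCoords | None = None) -> np.ndarray:
    """Canonical ordered fragment positions (15978..16569 then 1..261 by default)."""
    return (coords or default_coords()).positions


@dataclass(frozen=True)
class RegionMap:
    """Named, disjoint circular intervals that partition the fragment."""

    intervals: tuple[tuple[str, int, int], ...] = DEFAULT_REGIONS
    coords: GenomeCoords = field(default_factory=GenomeCoords)

    def __post_init__(self) -> None:
        seen: dict[int, str] = {}
        for name, start, end in self.intervals:
            for pos in _arc_positions(start, end, self.coords.genome_length):
                pos = int(pos)
                if pos in seen:
                    raise CoordinateError(
                        f"position {pos} assigned to both {seen[pos]} and {name}"
                    )
                seen[pos] = name
        fragment = set(int(p) for p in self.coords.positions)
        if set(seen) != fragment:
            missing = sorted(fragment - set(seen))[:5]
            extra = sorted(set(seen) - fragment)[:5]
            raise CoordinateError(
                f"regions do not partition the fragment (missing {missing}, extra {extra})"
            )
        object.__setattr__(self, "_lookup", seen)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.intervals)

    def assign(self, pos: int) -> str:
        """Region label of a fragment position."""
        try:
            return self._lookup[int(pos)]  # type: ignore[attr-defined]
        except KeyError:
            raise CoordinateError(f"position {pos} outside the analysed fragment") from None

    def sizes(self) -> dict[str, int]:
        """Region name -> size in bp (sizes sum to the fragment length)."""
        return {
            name: circular_interval_length(start, end, self.coords.genome_length)
            for name, start, end in self.intervals
        }

    def positions(self, name: str) -> np.ndarray:
        """Ordered positions of one region."""
        for rname, start, end in self.intervals:
            if rname == name:
                return _arc_positions(start, end, self.coords.genome_length)
        raise ParameterError(f"unknown region {name!r}")

    def to_tsv(self, path: str | Path) -> None:
        """Serialise as a 3-column tab-separated file: name, start, end."""
        with open(path, "w") as fh:
            fh.write("# 1-based closed rCRS intervals; circular arcs cross the origin\n")
            for name, start, end in self.intervals:
                fh.write(f"{name}\t{start}\t{end}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, coords: GenomeCoords | None = None) -> "RegionMap":
        intervals = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise SchemaError(f"{path}: line {lineno}: expected 3 tab-separated fields")
                try:
                    intervals.append((parts[0], int(parts[1]), int(parts[2])))
                except ValueError:
                    raise SchemaError(
                        f"{path}: line {lineno}: start/end must be integers"
                    ) from None
        return cls(intervals=tuple(intervals), coords=coords or default_coords())


def assign_region(pos: int, region_map: RegionMap | None = None) -> str:
    """Region label (HV1 / INTERMEDIATE / HV2 by default) of a fragment position."""
    return (region_map or RegionMap()).assign(pos)


def region_sizes(region_map: RegionMap | None = None) -> dict[str, int]:
    """Region -> bp sizes; always sums to the fragment length."""
    return (region_map or RegionMap()).sizes()
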