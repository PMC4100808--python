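"""Tab-separated file formats and configuration I/O.

Everything is plain TSV with a header line; coordinates are 1-based rCRS
positions throughout.  Formats:

* count table      ``sample_id site strand A C G T``   (strand is ``+``/``-``)
* call table       ``sample_id site major minor maf depth ds_validated``
                   (MAF with 6 decimal places; add a leading ``replicate``
                   column for replicate call tables)
* metadata         ``sample_id group family_id age``   (family_id may be ``.``)
* rate table       ``site rate``
* truth table      ``sample_id site true_maf``

Malformed rows are rejected with their line number.  Writing a count table
omits all-zero rows; a write -> read round trip reproduces every count.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .calling import BASES, HeteroplasmyCall, StrandCountTable
from .coords import GenomeCoords, default_coords
from .errors import CoordinateError, SchemaError
from .simulate import GeneratorConfig, TruthCohort

__all__ = [
    "read_count_table",
    "write_count_tables",
    "write_calls",
    "read_calls",
    "read_replicate_calls",
    "write_metadata",
    "read_metadata",
    "write_rate_table",
    "read_rate_table",
    "write_truth",
    "load_config",
    "dump_config",
    "config_hash",
]

COUNT_HEADER = ["sample_id", "site", "strand", "A", "C", "G", "T"]
CALL_HEADER = ["sample_id", "site", "major", "minor", "maf", "depth", "ds_validated"]


def read_count_table(
    path: str | Path, coords: GenomeCoords | None = None
) -> dict[str, StrandCountTable]:
    """Parse a count-table TSV into dense per-sample tables.

    Sites absent from the file hold zero counts.  Schema violations
    (unknown strand, negative or non-integer counts, out-of-fragment sites,
    duplicate rows) raise :class:`SchemaError` naming the line.
    """
    coords = coords or default_coords()
    tables: dict[str, StrandCountTable] = {}
    seen: set[tuple[str, int, str]] = set()
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        if header != COUNT_HEADER:
            raise SchemaError(
                f"{path}: line 1: expected header {' '.join(COUNT_HEADER)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 7:
                raise SchemaError(f"{path}: line {lineno}: expected 7 fields, got {len(row)}")
            sample, site_s, strand = row[0], row[1], row[2]
            if strand not in ("+", "-"):
                raise SchemaError(f"{path}: line {lineno}: unknown strand symbol {strand!r}")
            try:
                site = int(site_s)
            except ValueError:
                raise SchemaError(f"{path}: line {lineno}: site {site_s!r} is not an integer") from None
            try:
                counts = [int(x) for x in row[3:7]]
            except ValueError:
                raise SchemaError(f"{path}: line {lineno}: counts must be integers") from None
            if any(c < 0 for c in counts):
                raise SchemaError(f"{path}: line {lineno}: negative count")
            if sample not in tables:
                tables[sample] = StrandCountTable.empty(sample, coords)
            try:
                idx = coords.require(site)
            except CoordinateError:
                raise SchemaError(
                    f"{path}: line {lineno}: site {site} outside the analysed fragment"
                ) from None
            key = (sample, site, strand)
            if key in seen:
                raise SchemaError(
                    f"{path}: line {lineno}: duplicate row for {sample} site {site} strand {strand}"
                )
            seen.add(key)
            target = tables[sample].plus if strand == "+" else tables[sample].minus
            target[idx] = counts
    return tables


def write_count_tables(
    tables: Iterable[StrandCountTable], path: str | Path
) -> None:
    """Write count tables as TSV, omitting rows where all four counts are 0."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COUNT_HEADER)
        for table in tables:
            positions = table.coords.positions
            for strand, arr in (("+", table.plus), ("-", table.minus)):
                nz = np.nonzero(arr.sum(axis=1) > 0)[0]
                for idx in nz:
                    writer.writerow(
                        [table.sample_id, int(positions[idx]), strand, *arr[idx].tolist()]
                    )


def write_calls(
    calls_by_sample: Mapping[str, Iterable[HeteroplasmyCall]],
    path: str | Path,
    replicate_by_sample: Mapping[str, int] | None = None,
) -> None:
    """Write a call table; MAF printed with 6 decimal places."""
    header = CALL_HEADER if replicate_by_sample is None else ["sample_id", "replicate", *CALL_HEADER[1:]]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for sample in sorted(calls_by_sample):
            for c in sorted(calls_by_sample[sample], key=lambda c: c.site):
                row = [
                    sample,
                    c.site,
                    c.major_allele,
                    c.minor_allele,
                    f"{c.maf:.6f}",
                    c.depth,
                    int(c.ds_validated),
                ]
                if replicate_by_sample is not None:
                    row.insert(1, replicate_by_sample[sample])
                writer.writerow(row)


def _parse_call_row(row: list[str], lineno: int, path, offset: int = 0) -> tuple[str, HeteroplasmyCall]:
    try:
        call = HeteroplasmyCall(
            site=int(row[1 + offset]),
            major_allele=row[2 + offset],
            minor_allele=row[3 + offset],
            maf=float(row[4 + offset]),
            depth=int(row[5 + offset]),
            ds_validated=bool(int(row[6 + offset])),
        )
    except (ValueError, IndexError):
        raise SchemaError(f"{path}: line {lineno}: malformed call row") from None
    for b in (call.major_allele, call.minor_allele):
        if b not in BASES:
            raise SchemaError(f"{path}: line {lineno}: unknown base {b!r}")
    return row[0], call


def read_calls(path: str | Path) -> dict[str, tuple[HeteroplasmyCall, ...]]:
    out: dict[str, list[HeteroplasmyCall]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != CALL_HEADER:
            raise SchemaError(f"{path}: line 1: expected header {' '.join(CALL_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            sample, call = _parse_call_row(row, lineno, path)
            out.setdefault(sample, []).append(call)
    return {s: tuple(calls) for s, calls in out.items()}


def read_replicate_calls(path: str | Path) -> dict[str, dict[int, tuple[HeteroplasmyCall, ...]]]:
    """Call table with a replicate column -> sample -> replicate -> calls."""
    expected = ["sample_id", "replicate", *CALL_HEADER[1:]]
    out: dict[str, dict[int, list[HeteroplasmyCall]]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != expected:
            raise SchemaError(f"{path}: line 1: expected header {' '.join(expected)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                rep = int(row[1])
            except ValueError:
                raise SchemaError(f"{path}: line {lineno}: replicate must be an integer") from None
            sample, call = _parse_call_row(row, lineno, path, offset=1)
            out.setdefault(sample, {}).setdefault(rep, []).append(call)
    return {s: {r: tuple(c) for r, c in reps.items()} for s, reps in out.items()}


def write_metadata(cohort_or_rows, path: str | Path) -> None:
    rows = (
        [
            {"sample_id": p.sample_id, "group": p.group,
             "family_id": p.family_id or ".", "age": f"{p.age:.1f}"}
            for p in cohort_or_rows.profiles
        ]
        if isinstance(cohort_or_rows, TruthCohort)
        else list(cohort_or_rows)
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str, "family_id": str})
    required = {"sample_id", "group", "family_id", "age"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: metadata needs columns {sorted(required)}")
    df["family_id"] = df["family_id"].replace(".", np.nan)
    return df.set_index("sample_id")


def write_rate_table(rates: pd.Series, path: str | Path) -> None:
    rates.rename("rate").rename_axis("site").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_rate_table(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["site", "rate"]:
        raise SchemaError(f"{path}: expected columns 'site' and 'rate'")
    if (df["rate"] < 0).any():
        raise SchemaError(f"{path}: negative mutation rate")
    return pd.Series(df["rate"].to_numpy(), index=df["site"].astype(int), name="rate")


def write_truth(cohort: TruthCohort, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "site", "true_maf"])
        for p in cohort.profiles:
            for site in sorted(p.maf):
                writer.writerow([p.sample_id, site, f"{p.maf[site]:.6f}"])


def load_config(path: str | Path) -> GeneratorConfig:
    """Generator configuration from a YAML key-value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a key-value mapping")
    known = set(GeneratorConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    if "public_sites" in data:
        data["public_sites"] = tuple(int(s) for s in data["public_sites"])
    return GeneratorConfig(**data)


def dump_config(config: GeneratorConfig, path: str | Path | None = None) -> str:
    data = asdict(config)
    data["public_sites"] = list(data["public_sites"])
    text = yaml.safe_dump(data, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(config: GeneratorConfig) -> str:
    return hashlib.sha256(dump_config(config).encode()).hexdigest()[:16]


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
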