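"""Readers and writers for every on-disk artifact of the pipeline.

Formats are deliberately plain:

* amplicon targets as BED6 (0-based half-open) plus a tab-separated config
  listing each region's CpG offsets within the amplicon read;
* fragment pattern tables, per-CpG profiles and sample metadata as
  tab-separated tables whose comment lines start with ``#`` (every writer
  emits a ``# generated-by`` provenance line);
* synthetic reads as FASTQ (see :mod:`epiallele.synthetic_data`).

Readers validate and reject malformed records instead of coercing them;
missing values are written as ``NA`` and parsed back to NaN, never to 0.
"""

from __future__ import annotations

import dataclasses
import math
import os
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .epiallele_core import PATTERN_ALPHABET, EpialleleTable

__all__ = [
    "AmpliconSpec",
    "SampleMetadata",
    "read_amplicon_spec",
    "read_pattern_table",
    "write_pattern_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "metadata_to_frame",
    "read_table",
    "write_table",
    "write_summary_tables",
]

GROUPS = ("control", "ALS")
TISSUES = ("motor_cortex", "occipital_cortex", "cerebellum", "liver")

NA = "NA"
_FLOAT_FMT = "%.6g"


def _provenance() -> str:
    from . import __version__

    return f"# generated-by: epiallele {__version__}"


@dataclasses.dataclass(frozen=True)
class AmpliconSpec:
    """One bisulfite amplicon target and its ordered CpG sites.

    Coordinates follow the BED convention (0-based, half-open); offsets are
    0-based positions of the CpG cytosines within the amplicon read.
    Amplicons are modelled on the bisulfite top strand; minus-strand BED
    records are normalised to top-strand offsets at load time.
    """

    region_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cpg_positions: tuple[int, ...]
    cpg_offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cpg_positions", tuple(int(p) for p in self.cpg_positions))
        object.__setattr__(self, "cpg_offsets", tuple(int(o) for o in self.cpg_offsets))
        if self.end <= self.start:
            raise ValueError(f"region {self.region_id}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"region {self.region_id}: strand must be + or -")
        if len(self.cpg_positions) != len(self.cpg_offsets) or not self.cpg_positions:
            raise ValueError(
                f"region {self.region_id}: positions and offsets must be non-empty "
                "and of equal length"
            )
        prev = None
        for pos, off in zip(self.cpg_positions, self.cpg_offsets):
            if prev is not None and pos <= prev:
                raise ValueError(f"region {self.region_id}: CpG positions must strictly increase")
            prev = pos
            if not (self.start <= pos < self.end):
                raise ValueError(
                    f"region {self.region_id}: CpG position {pos} outside "
                    f"[{self.start}, {self.end})"
                )
            if pos - self.start != off:
                raise ValueError(
                    f"region {self.region_id}: offset {off} inconsistent with position {pos}"
                )

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class SampleMetadata:
    """One donor: group, tissue and ages in years.

    ``age_at_onset`` and ``disease_duration`` are present only for ALS
    donors; for controls they are NaN.
    """

    sample_id: str
    group: str
    tissue: str
    age_at_autopsy: float
    age_at_onset: float = math.nan
    disease_duration: float = math.nan

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"sample {self.sample_id}: group must be one of {GROUPS}")
        if self.tissue not in TISSUES:
            raise ValueError(f"sample {self.sample_id}: tissue must be one of {TISSUES}")
        if not self.age_at_autopsy > 0:
            raise ValueError(f"sample {self.sample_id}: age_at_autopsy must be positive")
        has_onset = not math.isnan(self.age_at_onset)
        has_duration = not math.isnan(self.disease_duration)
        if self.group == "control" and (has_onset or has_duration):
            raise ValueError(
                f"sample {self.sample_id}: onset/duration only valid for ALS donors"
            )
        if has_onset and not (0 < self.age_at_onset <= self.age_at_autopsy):
            raise ValueError(
                f"sample {self.sample_id}: age_at_onset must lie in (0, age_at_autopsy]"
            )
        if has_duration and self.disease_duration < 0:
            raise ValueError(f"sample {self.sample_id}: disease_duration must be >= 0")


def _data_lines(path) -> Iterable[list[str]]:
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield line.split("\t")


def read_amplicon_spec(bed_path, config_path) -> list[AmpliconSpec]:
    """Load amplicon intervals (BED6) and per-region CpG offsets (TSV config).

    The config has columns ``region_id`` and ``cpg_offsets`` (comma-separated
    0-based offsets).  Offsets outside the amplicon or duplicated region ids
    raise a validation error naming the offender.
    """
    offsets_by_region: dict[str, list[int]] = {}
    for fields in _data_lines(config_path):
        if len(fields) < 2:
            raise ValueError(f"malformed config line: {fields!r}")
        region_id = fields[0]
        if region_id == "region_id":  # plain header line
            continue
        if region_id in offsets_by_region:
            raise ValueError(f"duplicate region_id {region_id!r} in config")
        try:
            offsets = [int(x) for x in fields[1].split(",") if x != ""]
        except ValueError as exc:
            raise ValueError(f"region {region_id}: non-integer offset in config") from exc
        offsets_by_region[region_id] = offsets

    specs: list[AmpliconSpec] = []
    seen: set[str] = set()
    for fields in _data_lines(bed_path):
        if len(fields) < 4:
            raise ValueError(f"BED record needs at least 4 columns: {fields!r}")
        chrom, start_s, end_s, region_id = fields[:4]
        strand = fields[5] if len(fields) >= 6 else "+"
        start, end = int(start_s), int(end_s)
        if region_id in seen:
            raise ValueError(f"duplicate region_id {region_id!r} in BED")
        seen.add(region_id)
        if region_id not in offsets_by_region:
            raise ValueError(f"region {region_id!r} has no CpG offsets in config")
        offsets = offsets_by_region[region_id]
        length = end - start
        for off in offsets:
            if not (0 <= off < length):
                raise ValueError(
                    f"region {region_id}: CpG offset {off} outside amplicon of length {length}"
                )
        if strand == "-":
            # Normalise to the bisulfite top strand: offsets were given
            # relative to the reverse-strand read start (the BED end).
            positions = sorted(end - 1 - off for off in offsets)
            offsets = [pos - start for pos in positions]
        else:
            positions = [start + off for off in offsets]
            offsets = sorted(offsets)
            positions = sorted(positions)
        specs.append(
            AmpliconSpec(
                region_id=region_id,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                cpg_positions=tuple(positions),
                cpg_offsets=tuple(offsets),
            )
        )
    return specs


def read_pattern_table(path, specs: Mapping[str, AmpliconSpec] | None = None) -> list[EpialleleTable]:
    """Read a fragment-pattern TSV into per-(sample, region) tables.

    Columns: ``sample_id``, ``region_id``, ``pattern``, ``count``.
    Duplicate rows are aggregated by summing counts.  Illegal pattern
    characters and negative counts are rejected.  When ``specs`` is given,
    pattern lengths are checked against the region's CpG count.
    """
    agg: dict[tuple[str, str], dict[str, int]] = {}
    for fields in _data_lines(path):
        if fields[0] == "sample_id":
            continue
        if len(fields) != 4:
            raise ValueError(f"pattern table rows need 4 columns, got {fields!r}")
        sample_id, region_id, pattern, count_s = fields
        if not set(pattern) <= PATTERN_ALPHABET:
            bad = sorted(set(pattern) - PATTERN_ALPHABET)
            raise ValueError(f"pattern {pattern!r} contains illegal characters {bad}")
        count = int(count_s)
        if count < 0:
            raise ValueError(f"negative count {count} for pattern {pattern!r}")
        if specs is not None:
            spec = specs.get(region_id)
            if spec is not None and len(pattern) != spec.n_cpgs:
                raise ValueError(
                    f"pattern {pattern!r} has length {len(pattern)} but region "
                    f"{region_id} defines {spec.n_cpgs} CpGs"
                )
        key = (sample_id, region_id)
        bucket = agg.setdefault(key, {})
        bucket[pattern] = bucket.get(pattern, 0) + count
    tables = []
    for (sample_id, region_id), patterns in sorted(agg.items()):
        n_cpgs = len(next(iter(patterns)))
        if any(len(p) != n_cpgs for p in patterns):
            raise ValueError(
                f"inconsistent pattern lengths for {sample_id}/{region_id}"
            )
        tables.append(EpialleleTable(sample_id, region_id, n_cpgs, patterns))
    return tables


def write_pattern_table(tables: Iterable[EpialleleTable], path) -> None:
    """Write tables as a deterministic 4-column TSV with provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance() + "\n")
        fh.write("sample_id\tregion_id\tpattern\tcount\n")
        for table in sorted(tables, key=lambda t: (t.sample_id, t.region_id)):
            for pat in sorted(table.patterns):
                fh.write(f"{table.sample_id}\t{table.region_id}\t{pat}\t{table.patterns[pat]}\n")


_META_COLUMNS = [
    "sample_id",
    "group",
    "tissue",
    "age_at_autopsy",
    "age_at_onset",
    "disease_duration",
]


def metadata_to_frame(metadata: Sequence[SampleMetadata]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(m) for m in metadata], columns=_META_COLUMNS)


def write_sample_metadata(metadata: Sequence[SampleMetadata], path) -> None:
    write_table(metadata_to_frame(metadata), path)


def read_sample_metadata(path) -> list[SampleMetadata]:
    df = read_table(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                tissue=str(row["tissue"]),
                age_at_autopsy=float(row["age_at_autopsy"]),
                age_at_onset=float(row["age_at_onset"]) if pd.notna(row["age_at_onset"]) else math.nan,
                disease_duration=float(row["disease_duration"])
                if pd.notna(row["disease_duration"])
                else math.nan,
            )
        )
    return out


def read_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (``#`` comments, NA markers)."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=[NA], keep_default_na=False)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a DataFrame as TSV: provenance header, 6-significant-digit
    floats, NaN serialized as ``NA``."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance() + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=NA, float_format=_FLOAT_FMT)


def write_summary_tables(results: Mapping[str, pd.DataFrame], out_dir) -> dict[str, Path]:
    """Write every result DataFrame as ``<name>.tsv`` under ``out_dir``.

    Round-tripping through :func:`read_table` preserves values to the
    6-significant-digit serialization precision.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and not os.access(out_dir, os.W_OK):
        raise PermissionError(f"output directory {out_dir} is not writable")
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in sorted(results):
        p = out_dir / f"{name}.tsv"
        write_table(results[name], p)
        paths[name] = p
    return paths
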