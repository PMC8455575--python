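"""Fragment-level methylation statistics for targeted bisulfite amplicons.

In targeted (amplicon) bisulfite sequencing every read starts at a known
position, so the methylation state of each CpG in the target region can be
read off at a fixed offset within the read: an unconverted cytosine (``C``)
means the CpG was methylated, a converted one (``T``) unmethylated.  The
joint state of one sequenced fragment across all CpGs of the region is its
*epiallele* (e.g. ``MMUUMM``), and the distribution of epiallele frequencies
within a sample carries information that per-site averages do not:

* **epipolymorphism** ``E = 1 - sum_i p_i**2`` measures within-sample
  pattern heterogeneity (0 for a monoclonal population);
* the **methylation linkage** matrix holds the pairwise correlation of the
  binary methylation state of every CpG pair across fragments — high when
  demethylation hits whole alleles as a block, near zero when it acts
  per-site and stochastically;
* the **count spectrum** classifies fragments by how many of the region's
  CpGs are methylated.

This module implements pattern calling from reads, per-CpG methylation
percentages, and all of the above epiallele-level statistics, plus a
Gaussian kernel-density estimate of local CpG density along the genome.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EpialleleTable",
    "MethylationProfile",
    "CountSpectrum",
    "EpipolymorphismScore",
    "LinkageMatrix",
    "DensityTrack",
    "PatternCallResult",
    "table_from_fragment_matrix",
    "call_patterns",
    "methylation_percent",
    "count_spectrum",
    "epipolymorphism",
    "linkage_matrix",
    "cpg_density",
    "interindividual_variability",
    "cohort_summary",
]

#: Per-fragment pattern alphabet: M = methylated (C retained through
#: bisulfite conversion), U = unmethylated (C read as T), N = uncallable.
PATTERN_ALPHABET = frozenset("MUN")

DEFAULT_MIN_FRAGMENTS = 10
DEFAULT_BANDWIDTH = 10.73


class InsufficientFragmentsError(ValueError):
    """Raised when a statistic is requested on fewer complete fragments
    than the configured minimum."""


@dataclasses.dataclass(frozen=True)
class EpialleleTable:
    """Counts of fragment-level methylation patterns for one sample/region.

    ``patterns`` maps pattern strings over ``{M, U, N}`` (one character per
    CpG of the region, in genomic order) to non-negative fragment counts.
    Patterns containing ``N`` still contribute their callable sites to
    per-CpG percentages, but are excluded from epiallele-level statistics
    (spectrum, epipolymorphism, linkage) so that epiallele frequencies
    remain a proper probability distribution.
    """

    sample_id: str
    region_id: str
    n_cpgs: int
    patterns: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.n_cpgs <= 0:
            raise ValueError("n_cpgs must be positive")
        for pat, count in self.patterns.items():
            if len(pat) != self.n_cpgs:
                raise ValueError(
                    f"pattern {pat!r} has length {len(pat)}, expected {self.n_cpgs}"
                )
            if not set(pat) <= PATTERN_ALPHABET:
                bad = sorted(set(pat) - PATTERN_ALPHABET)
                raise ValueError(f"pattern {pat!r} contains illegal characters {bad}")
            if count < 0:
                raise ValueError(f"negative count {count} for pattern {pat!r}")
        object.__setattr__(self, "patterns", dict(self.patterns))

    @property
    def total_fragments(self) -> int:
        return int(sum(self.patterns.values()))

    def complete_patterns(self) -> dict[str, int]:
        """Patterns with every site callable (no ``N``), with their counts."""
        return {p: c for p, c in self.patterns.items() if "N" not in p and c > 0}

    @property
    def n_complete(self) -> int:
        return int(sum(self.complete_patterns().values()))

    def indicator_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Complete patterns as a 0/1 matrix plus their count vector.

        Returns ``(counts, X)`` where ``X`` has one row per distinct
        complete pattern and one column per CpG (1 = methylated).
        """
        complete = self.complete_patterns()
        if not complete:
            return np.zeros(0, dtype=np.int64), np.zeros((0, self.n_cpgs))
        pats = sorted(complete)
        counts = np.array([complete[p] for p in pats], dtype=np.int64)
        X = np.array([[1.0 if ch == "M" else 0.0 for ch in p] for p in pats])
        return counts, X


def table_from_fragment_matrix(
    sample_id: str, region_id: str, fragments: np.ndarray
) -> EpialleleTable:
    """Collapse a boolean fragment × CpG methylation matrix into a table."""
    frag = np.asarray(fragments)
    if frag.ndim != 2 or frag.shape[0] == 0:
        raise ValueError("fragments must be a non-empty 2-D array")
    chars = np.where(frag.astype(bool), ord("M"), ord("U")).astype(np.uint8)
    rows = np.ascontiguousarray(chars).view(f"S{frag.shape[1]}").ravel()
    uniq, counts = np.unique(rows, return_counts=True)
    patterns = {u.decode(): int(c) for u, c in zip(uniq, counts)}
    return EpialleleTable(sample_id, region_id, frag.shape[1], patterns)


@dataclasses.dataclass(frozen=True)
class MethylationProfile:
    """Per-CpG percent methylation with callable coverage.

    ``percent[j]`` is ``100 * #M / (#M + #U)`` at site ``j`` over all
    fragments whose site ``j`` was callable; ``NaN`` when no fragment was
    callable there (never silently 0).
    """

    sample_id: str
    region_id: str
    percent: np.ndarray
    coverage: np.ndarray

    @property
    def mean(self) -> float:
        """Unweighted mean of defined per-site percentages."""
        return float(np.nanmean(self.percent)) if np.any(np.isfinite(self.percent)) else math.nan


@dataclasses.dataclass(frozen=True)
class CountSpectrum:
    """Proportions of complete fragments carrying k methylated CpGs, k=0..n."""

    proportions: np.ndarray
    n_complete: int


@dataclasses.dataclass(frozen=True)
class EpipolymorphismScore:
    score: float
    n_complete_fragments: int


@dataclasses.dataclass(frozen=True)
class LinkageMatrix:
    """Pairwise phi correlation of binary methylation states across fragments.

    Entries are NaN where either site is constant across the complete
    fragments (the correlation is undefined; it is never imputed as 0).
    ``mean_pairwise`` averages the defined off-diagonal entries.
    """

    r: np.ndarray
    mean_pairwise: float
    n_complete: int


@dataclasses.dataclass(frozen=True)
class DensityTrack:
    density: np.ndarray
    bandwidth: float


@dataclasses.dataclass(frozen=True)
class PatternCallResult:
    table: EpialleleTable
    n_reads: int
    n_dropped: int


def _read_records(reads, fastq_format: str = "fastq"):
    """Yield ``(sequence, qualities)`` from SeqRecords, tuples or a FASTQ path."""
    if isinstance(reads, (str, Path)):
        from Bio import SeqIO

        reads = SeqIO.parse(str(reads), fastq_format)
    for rec in reads:
        if isinstance(rec, tuple):
            seq, quals = rec
        else:
            seq = str(rec.seq)
            quals = rec.letter_annotations.get("phred_quality")
        yield seq.upper(), quals


def call_patterns(
    reads,
    spec,
    min_base_quality: int = 20,
    sample_id: str | None = None,
) -> PatternCallResult:
    """Call one methylation pattern per read by offset lookup.

    ``reads`` may be a FASTQ path, an iterable of Bio.SeqRecord, or an
    iterable of ``(sequence, qualities)`` tuples (qualities may be None).
    At each CpG offset of ``spec``: C -> M, T -> U, anything else -> N;
    a base below ``min_base_quality`` is also N.  Reads shorter than the
    last CpG offset are skipped and counted in ``n_dropped``.
    """
    offsets = list(spec.cpg_offsets)
    max_off = max(offsets)
    counts: dict[str, int] = {}
    n_reads = 0
    n_dropped = 0
    for seq, quals in _read_records(reads):
        n_reads += 1
        if len(seq) <= max_off:
            n_dropped += 1
            continue
        chars = []
        for off in offsets:
            base = seq[off]
            if quals is not None and quals[off] < min_base_quality:
                chars.append("N")
            elif base == "C":
                chars.append("M")
            elif base == "T":
                chars.append("U")
            else:
                chars.append("N")
        pat = "".join(chars)
        counts[pat] = counts.get(pat, 0) + 1
    table = EpialleleTable(
        sample_id if sample_id is not None else "sample",
        spec.region_id,
        len(offsets),
        counts,
    )
    return PatternCallResult(table=table, n_reads=n_reads, n_dropped=n_dropped)


def methylation_percent(table: EpialleleTable) -> MethylationProfile:
    """Per-CpG percent methylation over callable fragments.

    N calls are excluded from numerator and denominator at their site only;
    the rest of the fragment still counts at its callable sites.
    """
    k = table.n_cpgs
    n_meth = np.zeros(k, dtype=np.int64)
    n_call = np.zeros(k, dtype=np.int64)
    for pat, count in table.patterns.items():
        for j, ch in enumerate(pat):
            if ch == "M":
                n_meth[j] += count
                n_call[j] += count
            elif ch == "U":
                n_call[j] += count
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(n_call > 0, 100.0 * n_meth / np.maximum(n_call, 1), np.nan)
    return MethylationProfile(table.sample_id, table.region_id, percent, n_call)


def count_spectrum(table: EpialleleTable) -> CountSpectrum:
    """Distribution of methylated-CpG counts among complete fragments."""
    complete = table.complete_patterns()
    total = sum(complete.values())
    if total == 0:
        raise InsufficientFragmentsError(
            f"no complete (N-free) pattern in {table.sample_id}/{table.region_id}"
        )
    props = np.zeros(table.n_cpgs + 1)
    for pat, count in complete.items():
        props[pat.count("M")] += count
    props /= total
    return CountSpectrum(proportions=props, n_complete=total)


def epipolymorphism(
    table: EpialleleTable, min_fragments: int = DEFAULT_MIN_FRAGMENTS
) -> EpipolymorphismScore:
    """Epipolymorphism ``E = 1 - sum_i p_i**2`` over complete-pattern frequencies."""
    complete = table.complete_patterns()
    total = sum(complete.values())
    if total < min_fragments:
        raise InsufficientFragmentsError(
            f"{total} complete fragments in {table.sample_id}/{table.region_id}, "
            f"need at least min_fragments={min_fragments}"
        )
    freqs = np.array(list(complete.values()), dtype=float) / total
    return EpipolymorphismScore(score=float(1.0 - np.sum(freqs**2)), n_complete_fragments=total)


def linkage_matrix(
    table: EpialleleTable, min_fragments: int = DEFAULT_MIN_FRAGMENTS
) -> LinkageMatrix:
    """Pairwise Pearson (phi) correlation of CpG methylation indicators.

    Computed across complete fragments with pattern counts as weights.
    Pairs involving a constant site are NaN and excluded from the mean.
    """
    counts, X = table.indicator_matrix()
    total = int(counts.sum())
    if total < min_fragments:
        raise InsufficientFragmentsError(
            f"{total} complete fragments in {table.sample_id}/{table.region_id}, "
            f"need at least min_fragments={min_fragments}"
        )
    w = counts / total
    mean = w @ X
    centered = X - mean
    cov = (centered * w[:, None]).T @ centered
    var = np.diag(cov).copy()
    k = table.n_cpgs
    r = np.full((k, k), np.nan)
    nonconst = var > 0
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_all = cov / denom
    mask = np.outer(nonconst, nonconst)
    r[mask] = r_all[mask]
    r[np.ix_(nonconst, nonconst)] = np.clip(r[np.ix_(nonconst, nonconst)], -1.0, 1.0)
    off = ~np.eye(k, dtype=bool)
    defined = off & np.isfinite(r)
    mean_pairwise = float(np.mean(r[defined])) if defined.any() else math.nan
    return LinkageMatrix(r=r, mean_pairwise=mean_pairwise, n_complete=total)


def cpg_density(spec_or_positions, bandwidth: float = DEFAULT_BANDWIDTH) -> DensityTrack:
    """Gaussian kernel-density estimate of CpG density at each CpG site.

    ``d_j = (1/(n*h)) * sum_i K((x_j - x_i)/h)`` with K the standard normal
    kernel, evaluated at every CpG position (self-inclusive), so the
    density integrates to 1 over the point set.  Translation-invariant.
    """
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    positions = np.asarray(
        getattr(spec_or_positions, "cpg_positions", spec_or_positions), dtype=float
    )
    if positions.size == 0:
        raise ValueError("at least one CpG position required")
    z = (positions[:, None] - positions[None, :]) / bandwidth
    kernel = np.exp(-0.5 * z**2) / math.sqrt(2.0 * math.pi)
    density = kernel.sum(axis=1) / (positions.size * bandwidth)
    return DensityTrack(density=density, bandwidth=float(bandwidth))


def interindividual_variability(profiles: Sequence[MethylationProfile]) -> np.ndarray:
    """Per-CpG sample standard deviation (n-1 denominator) across donors.

    Sites with fewer than two defined values are NaN.
    """
    if not profiles:
        raise ValueError("no profiles given")
    mat = np.vstack([p.percent for p in profiles])
    n_def = np.sum(np.isfinite(mat), axis=0)
    out = np.full(mat.shape[1], np.nan)
    enough = n_def >= 2
    if enough.any():
        cols = np.where(enough)[0]
        for j in cols:
            vals = mat[np.isfinite(mat[:, j]), j]
            out[j] = np.std(vals, ddof=1)
    return out


def cohort_summary(
    tables: Iterable[EpialleleTable],
    specs: Mapping[str, object] | Sequence,
    min_fragments: int = DEFAULT_MIN_FRAGMENTS,
) -> dict[str, pd.DataFrame]:
    """Tidy per-sample, per-region summaries over a collection of tables.

    Returns DataFrames:

    - ``profiles``: one row per sample x region x CpG with percent and
      callable coverage;
    - ``summary``: one row per sample x region with mean methylation,
      epipolymorphism, mean pairwise linkage, fragment counts and a
      ``qc_pass`` flag (complete fragments >= ``min_fragments``);
    - ``spectra``: methylated-count spectrum rows (complete fragments);
    - ``linkage``: long-format pairwise correlations (upper triangle).

    Epiallele-level statistics are NaN for samples failing the fragment
    threshold; they are flagged, never silently computed.
    """
    if not isinstance(specs, Mapping):
        specs = {s.region_id: s for s in specs}
    prof_rows, summ_rows, spec_rows, link_rows = [], [], [], []
    for table in tables:
        spec = specs.get(table.region_id)
        if spec is not None and spec.n_cpgs != table.n_cpgs:
            raise ValueError(
                f"table {table.sample_id}/{table.region_id} has {table.n_cpgs} CpGs "
                f"but spec defines {spec.n_cpgs}"
            )
        prof = methylation_percent(table)
        positions = list(spec.cpg_positions) if spec is not None else [None] * table.n_cpgs
        for j in range(table.n_cpgs):
            prof_rows.append(
                {
                    "sample_id": table.sample_id,
                    "region_id": table.region_id,
                    "site_index": j + 1,
                    "position": positions[j],
                    "percent_methylation": prof.percent[j],
                    "coverage": int(prof.coverage[j]),
                }
            )
        n_complete = table.n_complete
        qc_pass = n_complete >= min_fragments
        epi = math.nan
        mean_r = math.nan
        if qc_pass:
            epi = epipolymorphism(table, min_fragments).score
            link = linkage_matrix(table, min_fragments)
            mean_r = link.mean_pairwise
            iu = np.triu_indices(table.n_cpgs, k=1)
            for a, b in zip(*iu):
                link_rows.append(
                    {
                        "sample_id": table.sample_id,
                        "region_id": table.region_id,
                        "site_i": int(a) + 1,
                        "site_j": int(b) + 1,
                        "r": link.r[a, b],
                    }
                )
            spectrum = count_spectrum(table)
            for k_meth, pi in enumerate(spectrum.proportions):
                spec_rows.append(
                    {
                        "sample_id": table.sample_id,
                        "region_id": table.region_id,
                        "n_methylated": k_meth,
                        "proportion": pi,
                    }
                )
        summ_rows.append(
            {
                "sample_id": table.sample_id,
                "region_id": table.region_id,
                "mean_methylation": prof.mean,
                "epipolymorphism": epi,
                "mean_pairwise_r": mean_r,
                "n_fragments": table.total_fragments,
                "n_complete": n_complete,
                "min_fragments": min_fragments,
                "qc_pass": qc_pass,
            }
        )
    sort = ["sample_id", "region_id"]
    return {
        "profiles": pd.DataFrame(prof_rows).sort_values(sort + ["site_index"]).reset_index(drop=True)
        if prof_rows
        else pd.DataFrame(
            columns=["sample_id", "region_id", "site_index", "position", "percent_methylation", "coverage"]
        ),
        "summary": pd.DataFrame(summ_rows).sort_values(sort).reset_index(drop=True)
        if summ_rows
        else pd.DataFrame(
            columns=[
                "sample_id", "region_id", "mean_methylation", "epipolymorphism",
                "mean_pairwise_r", "n_fragments", "n_complete", "min_fragments", "qc_pass",
            ]
        ),
        "spectra": pd.DataFrame(spec_rows).sort_values(sort + ["n_methylated"]).reset_index(drop=True)
        if spec_rows
        else pd.DataFrame(columns=["sample_id", "region_id", "n_methylated", "proportion"]),
        "linkage": pd.DataFrame(link_rows).sort_values(sort + ["site_i", "site_j"]).reset_index(drop=True)
        if link_rows
        else pd.DataFrame(columns=["sample_id", "region_id", "site_i", "site_j", "r"]),
    }
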