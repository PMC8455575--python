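"""Synthetic bisulfite-amplicon data with controllable epiallele structure.

Generates fragment populations, bisulfite reads, and donor cohorts that
carry the statistical structure the epiallele analysis is designed to
detect, under explicit mechanistic models:

* ``clustered`` — whole alleles lose methylation as a block (the signature
  of targeted enzymatic demethylation): high methylation linkage, and for a
  two-allele mix with event probability q, epipolymorphism 2q(1-q);
* ``site_independent`` — every CpG is demethylated independently: linkage
  near zero;
* ``drift`` — a clustered backbone with per-site stochastic demethylation
  on top.  Raising the per-site rate drives epipolymorphism up and mean
  pairwise linkage down, the signature of stochastic epiallele drift
  with aging.

The cohort generator emulates two donor groups over a shared pair of
amplicon regions: controls whose mean methylation declines linearly with
age, and cases whose methylation sits at an age-flat depressed level, plus
donor-level biological noise, bisulfite-conversion failure and sequencing
error.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
import zlib
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np

from .epiallele_core import EpialleleTable, table_from_fragment_matrix
from .io_formats import AmpliconSpec, SampleMetadata, read_amplicon_spec

__all__ = [
    "EpialleleModel",
    "CohortConfig",
    "simulate_epiallele_population",
    "synthetic_reference",
    "emit_reads",
    "write_fastq",
    "simulate_cohort",
    "default_amplicons",
]

MODELS = ("clustered", "site_independent", "drift")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclasses.dataclass(frozen=True)
class EpialleleModel:
    """Mechanistic generator for one fragment population.

    ``baseline_methylation`` is the per-CpG probability a site starts
    methylated.  ``allele_event_prob`` is the probability an entire allele
    is demethylated as a block (clustered and drift models);
    ``site_event_prob`` is the per-CpG independent demethylation
    probability (site_independent and drift models).
    """

    model: str
    n_cpgs: int
    baseline_methylation: float = 1.0
    allele_event_prob: float = 0.0
    site_event_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.n_cpgs <= 0:
            raise ValueError("n_cpgs must be positive")
        for name in ("baseline_methylation", "allele_event_prob", "site_event_prob"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {val}")


def simulate_epiallele_population(
    model: EpialleleModel,
    n_fragments: int,
    seed: int,
    sample_id: str = "sim",
    region_id: str = "region",
) -> EpialleleTable:
    """Draw a fragment population and collapse it to a pattern table.

    Identical seeds give identical tables; pattern counts always sum to
    ``n_fragments``.
    """
    if n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    rng = np.random.default_rng(seed)
    frag = rng.random((n_fragments, model.n_cpgs)) < model.baseline_methylation
    if model.model in ("clustered", "drift"):
        block = rng.random(n_fragments) < model.allele_event_prob
        frag[block] = False
    if model.model in ("site_independent", "drift"):
        site_events = rng.random((n_fragments, model.n_cpgs)) < model.site_event_prob
        frag &= ~site_events
    return table_from_fragment_matrix(sample_id, region_id, frag)


def synthetic_reference(spec: AmpliconSpec, seed: int | None = None) -> str:
    """Deterministic amplicon reference with CpGs exactly at the spec offsets.

    Built from the region id (or an explicit seed) so repeated calls agree.
    ``CG`` dinucleotides occur only at the declared CpG offsets; non-CpG
    cytosines are present so conversion failure is observable.
    """
    if seed is None:
        seed = zlib.crc32(spec.region_id.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    length = spec.length
    seq = np.zeros(length, dtype=np.uint8)
    fixed = np.zeros(length, dtype=bool)
    for off in spec.cpg_offsets:
        if off + 1 >= length:
            raise ValueError(
                f"region {spec.region_id}: CpG offset {off} leaves no room for the G"
            )
        seq[off] = ord("C")
        seq[off + 1] = ord("G")
        fixed[off] = fixed[off + 1] = True
    for i in range(length):
        if fixed[i]:
            continue
        choices = list(_BASES)
        if i > 0 and seq[i - 1] == ord("C"):
            choices.remove(ord("G"))  # avoid creating an undeclared CpG
        if i + 1 < length and fixed[i + 1] and seq[i + 1] == ord("G"):
            choices.remove(ord("C"))
        seq[i] = choices[rng.integers(len(choices))]
    return seq.tobytes().decode()


def _bisulfite_read(
    ref: np.ndarray,
    pattern: str,
    offsets: Sequence[int],
    conversion_failure_rate: float,
    sequencing_error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    read = ref.copy()
    is_cpg = np.zeros(read.size, dtype=bool)
    for off in offsets:
        is_cpg[off] = True
    non_cpg_c = (read == ord("C")) & ~is_cpg
    converted = non_cpg_c.copy()
    if conversion_failure_rate > 0:
        converted &= rng.random(read.size) >= conversion_failure_rate
    read[converted] = ord("T")
    qual = np.full(read.size, 40, dtype=np.int8)
    for off, state in zip(offsets, pattern):
        if state == "M":
            read[off] = ord("C")
        elif state == "U":
            read[off] = ord("T")
        else:
            read[off] = ord("N")
            qual[off] = 2
    if sequencing_error_rate > 0:
        errs = np.where(rng.random(read.size) < sequencing_error_rate)[0]
        for i in errs:
            alternatives = _BASES[_BASES != read[i]]
            read[i] = alternatives[rng.integers(alternatives.size)]
    return read, qual


def emit_reads(
    table: EpialleleTable,
    spec: AmpliconSpec,
    conversion_failure_rate: float = 0.0,
    sequencing_error_rate: float = 0.0,
    seed: int = 0,
    reference: str | None = None,
):
    """Render every fragment of ``table`` as one merged amplicon-length read.

    CpG offsets carry C for M and T for U (N sites become an ``N`` base at
    quality 2); non-CpG cytosines convert to T except with probability
    ``conversion_failure_rate``; every base is substituted with probability
    ``sequencing_error_rate``.  Returns a list of Bio.SeqRecord.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if table.region_id != spec.region_id:
        raise ValueError(
            f"table region {table.region_id!r} does not match spec {spec.region_id!r}"
        )
    if table.n_cpgs != spec.n_cpgs:
        raise ValueError(
            f"table has {table.n_cpgs} CpGs but spec defines {spec.n_cpgs}"
        )
    for rate, name in (
        (conversion_failure_rate, "conversion_failure_rate"),
        (sequencing_error_rate, "sequencing_error_rate"),
    ):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    ref = np.frombuffer(
        (reference if reference is not None else synthetic_reference(spec)).encode(),
        dtype=np.uint8,
    ).copy()
    if ref.size != spec.length:
        raise ValueError("reference length does not match the amplicon interval")
    rng = np.random.default_rng(seed)
    records = []
    idx = 0
    for pattern in sorted(table.patterns):
        for _ in range(table.patterns[pattern]):
            read, qual = _bisulfite_read(
                ref, pattern, spec.cpg_offsets,
                conversion_failure_rate, sequencing_error_rate, rng,
            )
            rec = SeqRecord(
                Seq(read.tobytes().decode()),
                id=f"{table.sample_id}|{table.region_id}|{idx}",
                description="",
            )
            rec.letter_annotations["phred_quality"] = qual.tolist()
            records.append(rec)
            idx += 1
    return records


def write_fastq(records, path) -> None:
    from Bio import SeqIO

    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def _parse_pair(text: str) -> tuple[float, float]:
    a, b = (float(x) for x in text.split(","))
    return a, b


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for a two-group synthetic cohort.

    Controls follow ``mean methylation = intercept + slope * age`` (percent,
    percent/year); cases sit at the age-flat ``als_level``.  Donor-level
    biological noise (percent points, between donors) is added to the
    target before fragment sampling; ``allele_linkage`` sets the expected
    pairwise CpG correlation within a donor's fragment population via an
    allele-block/independent-site mixture.  Numeric defaults live in the
    packaged ``motor-cortex`` preset file, not in code.
    """

    n_controls: int
    n_cases: int
    age_range: tuple[float, float]
    control_trend: tuple[float, float]
    als_level: float
    biological_noise_sd: float
    allele_linkage: float
    n_fragments_per_sample: int
    conversion_failure_rate: float
    sequencing_error_rate: float
    seed: int
    case_age_range: tuple[float, float] | None = None
    tissue: str = "motor_cortex"
    control_ages: tuple[float, ...] | None = None
    case_ages: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_controls <= 0 or self.n_cases <= 0:
            raise ValueError("n_controls and n_cases must be positive")
        if self.n_fragments_per_sample <= 0:
            raise ValueError("n_fragments_per_sample must be positive")
        if not (0.0 <= self.allele_linkage <= 1.0):
            raise ValueError("allele_linkage must be in [0, 1]")
        for rate in (self.conversion_failure_rate, self.sequencing_error_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("error rates must be in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be (min, max) with min < max")

    @classmethod
    def from_config_file(cls, path, seed: int, **overrides) -> "CohortConfig":
        """Parse a flat ``key = value`` config file (``#`` comments allowed)."""
        raw: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                raw[key.strip()] = value.strip()
        kwargs = dict(
            n_controls=int(raw["n_controls"]),
            n_cases=int(raw["n_cases"]),
            age_range=_parse_pair(raw["age_range"]),
            control_trend=_parse_pair(raw["control_trend"]),
            als_level=float(raw["als_level"]),
            biological_noise_sd=float(raw["biological_noise_sd"]),
            allele_linkage=float(raw["allele_linkage"]),
            n_fragments_per_sample=int(raw["n_fragments_per_sample"]),
            conversion_failure_rate=float(raw["conversion_failure_rate"]),
            sequencing_error_rate=float(raw["sequencing_error_rate"]),
            tissue=raw.get("tissue", "motor_cortex"),
        )
        if "case_age_range" in raw:
            kwargs["case_age_range"] = _parse_pair(raw["case_age_range"])
        kwargs.update(overrides)
        return cls(seed=seed, **kwargs)

    @classmethod
    def motor_cortex_preset(cls, seed: int, **overrides) -> "CohortConfig":
        """The packaged motor-cortex default cohort: 11 controls (ages 45-90) whose
        region mean falls 1 percent/year through 80% at 55 and 50% at 85,
        and 10 age-flat cases at 65%."""
        res = importlib.resources.files("epiallele") / "presets" / "motor_cortex_cohort.cfg"
        with importlib.resources.as_file(res) as path:
            return cls.from_config_file(path, seed=seed, **overrides)


def default_amplicons() -> list[AmpliconSpec]:
    """The packaged two-region amplicon panel: a 9-CpG region followed by a
    denser 6-CpG region (placeholder coordinates, realistic spacing)."""
    pkg = importlib.resources.files("epiallele") / "presets"
    with importlib.resources.as_file(pkg / "tardbp_3utr.bed") as bed:
        with importlib.resources.as_file(pkg / "tardbp_3utr_cpgs.tsv") as cfg:
            return read_amplicon_spec(bed, cfg)


def _sample_donor_fragments(
    level: float,
    linkage: float,
    n_fragments: int,
    n_cpgs: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fragments with per-site methylation probability ``level`` and expected
    pairwise correlation ``linkage``.

    A fraction ``linkage`` of fragments is all-or-none (whole allele
    Bernoulli(level)); the rest have independent per-site states.  Both
    components share the marginal mean, so the mixture weight directly sets
    the expected phi correlation.
    """
    block = rng.random(n_fragments) < linkage
    allele_state = rng.random(n_fragments) < level
    independent = rng.random((n_fragments, n_cpgs)) < level
    frag = np.where(block[:, None], allele_state[:, None], independent)
    return frag


def simulate_cohort(
    config: CohortConfig, specs: Sequence[AmpliconSpec] | Mapping[str, AmpliconSpec]
) -> tuple[list[EpialleleTable], list[SampleMetadata]]:
    """Generate pattern tables and metadata for a full two-group cohort.

    One metadata row per donor and one pattern table per donor per region.
    Donor ages are uniform over the group's age range (unless explicit ages
    are supplied); the donor's target mean methylation is the group model
    evaluated at that age plus Normal(0, biological_noise_sd), clipped to
    [0, 100].  Identical seeds give identical cohorts.
    """
    if isinstance(specs, Mapping):
        specs = list(specs.values())
    rng = np.random.default_rng(config.seed)
    intercept, slope = config.control_trend
    tables: list[EpialleleTable] = []
    metadata: list[SampleMetadata] = []

    def _ages(n: int, rng_: np.random.Generator, rng_range, explicit) -> np.ndarray:
        if explicit is not None:
            ages = np.asarray(explicit, dtype=float)
            if ages.size != n:
                raise ValueError("explicit age list length does not match group size")
            return ages
        lo, hi = rng_range
        return np.round(rng_.uniform(lo, hi, n), 1)

    control_ages = _ages(config.n_controls, rng, config.age_range, config.control_ages)
    case_range = config.case_age_range if config.case_age_range is not None else config.age_range
    case_ages = _ages(config.n_cases, rng, case_range, config.case_ages)

    for i, age in enumerate(control_ages, start=1):
        sample_id = f"control_{i:02d}"
        target = intercept + slope * float(age) + rng.normal(0.0, config.biological_noise_sd)
        level = float(np.clip(target, 0.0, 100.0)) / 100.0
        metadata.append(
            SampleMetadata(sample_id, "control", config.tissue, float(age))
        )
        for spec in specs:
            frag = _sample_donor_fragments(
                level, config.allele_linkage, config.n_fragments_per_sample,
                spec.n_cpgs, rng,
            )
            tables.append(table_from_fragment_matrix(sample_id, spec.region_id, frag))

    for i, age in enumerate(case_ages, start=1):
        sample_id = f"als_{i:02d}"
        target = config.als_level + rng.normal(0.0, config.biological_noise_sd)
        level = float(np.clip(target, 0.0, 100.0)) / 100.0
        duration = float(np.round(rng.uniform(1.0, 5.0), 1))
        duration = min(duration, float(age) - 0.1)
        onset = float(np.round(float(age) - duration, 1))
        metadata.append(
            SampleMetadata(
                sample_id, "ALS", config.tissue, float(age),
                age_at_onset=onset, disease_duration=duration,
            )
        )
        for spec in specs:
            frag = _sample_donor_fragments(
                level, config.allele_linkage, config.n_fragments_per_sample,
                spec.n_cpgs, rng,
            )
            tables.append(table_from_fragment_matrix(sample_id, spec.region_id, frag))

    return tables, metadata
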