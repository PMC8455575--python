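import numpy as np
import pytest

from epiallele import AmpliconSpec, EpialleleTable, default_amplicons


@pytest.fixture(scope="session")
def amplicons():
    return default_amplicons()


@pytest.fixture(scope="session")
def region_b(amplicons):
    """The packaged 6-CpG region."""
    return next(s for s in amplicons if s.n_cpgs == 6)


@pytest.fixture
def tiny_spec():
    """A 10-bp amplicon with 3 CpGs at offsets 1, 4, 7."""
    return AmpliconSpec(
        region_id="tiny",
        chrom="chr1",
        start=100,
        end=110,
        strand="+",
        cpg_positions=(101, 104, 107),
        cpg_offsets=(1, 4, 7),
    )


def random_table(rng: np.random.Generator, max_cpgs: int = 3, max_fragments: int = 20,
                 allow_n: bool = True) -> EpialleleTable:
    """A random pattern table with at least one complete fragment."""
    k = int(rng.integers(1, max_cpgs + 1))
    n = int(rng.integers(1, max_fragments + 1))
    alphabet = "MUN" if allow_n else "MU"
    patterns: dict[str, int] = {}
    for _ in range(n):
        pat = "".join(rng.choice(list(alphabet)) for _ in range(k))
        patterns[pat] = patterns.get(pat, 0) + 1
    if all("N" in p for p in patterns):
        pat = "M" * k
        patterns[pat] = patterns.get(pat, 0) + 1
    return EpialleleTable("rand", "rand_region", k, patterns)
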