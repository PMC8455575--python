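import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epiallele import (
    EpialleleTable,
    call_patterns,
    count_spectrum,
    cpg_density,
    epipolymorphism,
    interindividual_variability,
    linkage_matrix,
    methylation_percent,
)
from epiallele.epiallele_core import InsufficientFragmentsError

from _oracles import oracle_epipolymorphism, oracle_linkage, oracle_spectrum
from conftest import random_table


def table(patterns, n_cpgs=None, sample="s", region="r"):
    if n_cpgs is None:
        n_cpgs = len(next(iter(patterns)))
    return EpialleleTable(sample, region, n_cpgs, patterns)


class TestMethylationPercent:
    def test_all_methylated(self):
        prof = methylation_percent(table({"MMM": 10}))
        assert prof.percent.tolist() == [100.0, 100.0, 100.0]
        assert prof.coverage.tolist() == [10, 10, 10]

    def test_site_wise_arithmetic(self):
        prof = methylation_percent(table({"MMU": 2, "MUU": 2}))
        assert prof.percent.tolist() == [100.0, 50.0, 0.0]

    def test_n_excluded_from_site_only(self):
        # N rows leave the site's denominator, not the whole fragment
        prof = methylation_percent(table({"MNM": 5, "MUM": 5}))
        assert prof.percent[1] == 0.0
        assert prof.coverage.tolist() == [10, 5, 10]

    def test_uncovered_site_is_missing_not_zero(self):
        prof = methylation_percent(table({"MNM": 4}))
        assert math.isnan(prof.percent[1]) and prof.coverage[1] == 0


class TestCountSpectrum:
    def test_monoclonal(self):
        spec = count_spectrum(table({"MMMMMM": 100}))
        assert spec.proportions[6] == 1.0 and spec.proportions[:6].sum() == 0.0

    def test_two_pattern_split(self):
        spec = count_spectrum(table({"MMMUUU": 50, "UUUUUU": 50}))
        assert spec.proportions[3] == 0.5 and spec.proportions[0] == 0.5

    def test_incomplete_fragments_excluded(self):
        spec = count_spectrum(table({"MMMMMN": 10, "MMMMMM": 10}))
        assert spec.n_complete == 10 and spec.proportions[6] == 1.0

    def test_no_complete_pattern_errors(self):
        with pytest.raises(InsufficientFragmentsError):
            count_spectrum(table({"MNM": 3}))


class TestEpipolymorphism:
    @pytest.mark.parametrize(
        "patterns, expected",
        [
            ({"MMMMMM": 100}, 0.0),
            ({"MMMMMM": 50, "UUUUUU": 50}, 0.5),
        ],
    )
    def test_closed_forms(self, patterns, expected):
        assert epipolymorphism(table(patterns)).score == pytest.approx(expected, abs=1e-12)

    def test_uniform_64_patterns(self):
        pats = {"".join("M" if (i >> j) & 1 else "U" for j in range(6)): 1 for i in range(64)}
        score = epipolymorphism(table(pats, n_cpgs=6)).score
        assert score == pytest.approx(1 - 1 / 64, abs=1e-12)

    def test_min_fragments_threshold_named_in_error(self):
        with pytest.raises(InsufficientFragmentsError, match="min_fragments=10"):
            epipolymorphism(table({"MMM": 5}))


class TestLinkage:
    def test_perfect_linkage(self):
        link = linkage_matrix(table({"MMMMMM": 50, "UUUUUU": 50}))
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(link.r[off], 1.0)
        assert link.mean_pairwise == pytest.approx(1.0)

    def test_constant_sites_give_missing_never_zero(self):
        link = linkage_matrix(table({"MMMMMM": 100}))
        assert np.isnan(link.r).all()
        assert math.isnan(link.mean_pairwise)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(5)
        t = random_table(rng, max_cpgs=3, max_fragments=20, allow_n=False)
        link = linkage_matrix(t, min_fragments=1)
        assert np.allclose(link.r, link.r.T, equal_nan=True)
        for j in range(t.n_cpgs):
            if not math.isnan(link.r[j, j]):
                assert link.r[j, j] == pytest.approx(1.0)


def test_statistics_match_brute_force_enumeration():
    rng = np.random.default_rng(20210921)
    for _ in range(100):
        t = random_table(rng)
        assert epipolymorphism(t, min_fragments=1).score == pytest.approx(
            oracle_epipolymorphism(t), abs=1e-12
        )
        assert np.allclose(count_spectrum(t).proportions, oracle_spectrum(t), atol=1e-12)
        link = linkage_matrix(t, min_fragments=1)
        oracle_r, oracle_mean = oracle_linkage(t)
        assert np.allclose(link.r, oracle_r, atol=1e-9, equal_nan=True)
        assert link.mean_pairwise == pytest.approx(oracle_mean, abs=1e-9, nan_ok=True)


class TestCallPatterns:
    def _reads(self, seqs, qual=40):
        return [(s, [qual] * len(s)) for s in seqs]

    def test_c_and_t_calls(self, tiny_spec):
        #          0123456789   offsets 1,4,7
        res = call_patterns(self._reads(["ACGTCGTCGA"]), tiny_spec)
        assert res.table.patterns == {"MMM": 1}
        res = call_patterns(self._reads(["ATGTTGTTGA"]), tiny_spec)
        assert res.table.patterns == {"UUU": 1}

    def test_mixed_and_error_base(self, tiny_spec):
        res = call_patterns(self._reads(["ATGTCGTGGA"]), tiny_spec)
        assert res.table.patterns == {"UMN": 1}

    def test_low_quality_masked(self, tiny_spec):
        quals = [40] * 10
        quals[4] = 5
        res = call_patterns([("ACGTCGTCGA", quals)], tiny_spec)
        assert res.table.patterns == {"MNM": 1}

    def test_short_reads_dropped_and_tallied(self, tiny_spec):
        res = call_patterns(self._reads(["ACGT", "ACGTCGTCGA"]), tiny_spec)
        assert res.n_dropped == 1
        assert res.table.total_fragments == 1

    def test_empty_input_gives_empty_table(self, tiny_spec):
        res = call_patterns([], tiny_spec)
        assert res.table.total_fragments == 0 and res.n_reads == 0


class TestCpgDensity:
    def test_single_site_analytic(self):
        d = cpg_density([1000.0], bandwidth=10.73)
        assert d.density[0] == pytest.approx(1 / (10.73 * math.sqrt(2 * math.pi)), rel=1e-9)

    def test_two_distant_sites_halve(self):
        h = 10.73
        d = cpg_density([0.0, 100 * h], bandwidth=h)
        assert np.allclose(d.density, 1 / (2 * h * math.sqrt(2 * math.pi)), rtol=0.01)

    def test_translation_invariance(self, region_b):
        base = cpg_density(region_b)
        shifted = cpg_density(np.array(region_b.cpg_positions) + 1000)
        assert np.allclose(base.density, shifted.density)

    def test_denser_sites_have_higher_density(self, amplicons):
        sparse, dense = amplicons[0], amplicons[1]
        assert cpg_density(dense).density.mean() > cpg_density(sparse).density.mean()

    def test_bad_bandwidth(self):
        with pytest.raises(ValueError, match="bandwidth"):
            cpg_density([1.0, 2.0], bandwidth=0)


class TestInterindividualVariability:
    def _profiles(self, rows):
        return [
            methylation_percent(table(p)) if isinstance(p, dict) else p for p in rows
        ]

    def test_identical_profiles_sd_zero(self):
        profs = self._profiles([{"MMU": 10}, {"MMU": 10}, {"MMU": 10}])
        assert np.allclose(interindividual_variability(profs), 0.0)

    def test_two_sample_arithmetic(self):
        profs = self._profiles([{"MMMUU": 2, "UUUUU": 3}, {"MMMUU": 3, "UUUUU": 2}])
        # site 1: 40% vs 60% -> SD = sqrt(200)
        sd = interindividual_variability(profs)
        assert sd[0] == pytest.approx(math.sqrt(200), rel=1e-12)

    def test_single_sample_all_missing(self):
        sd = interindividual_variability(self._profiles([{"MMM": 5}]))
        assert np.isnan(sd).all()


@st.composite
def pattern_tables(draw):
    k = draw(st.integers(1, 4))
    pats = draw(
        st.dictionaries(
            st.text(alphabet="MU", min_size=k, max_size=k),
            st.integers(1, 50),
            min_size=1,
            max_size=8,
        )
    )
    return EpialleleTable("h", "r", k, pats)


@given(pattern_tables())
@settings(max_examples=60, derandomize=True, deadline=None)
def test_epiallele_invariants(t):
    """Spectrum sums to 1; E within [0, 1 - 1/#patterns]; linkage in [-1, 1]."""
    spec = count_spectrum(t)
    assert spec.proportions.sum() == pytest.approx(1.0, abs=1e-9)
    e = epipolymorphism(t, min_fragments=1).score
    assert 0.0 <= e <= 1.0 - 1.0 / len(t.complete_patterns()) + 1e-12
    link = linkage_matrix(t, min_fragments=1)
    finite = link.r[np.isfinite(link.r)]
    assert ((finite >= -1 - 1e-9) & (finite <= 1 + 1e-9)).all()
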