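"""Log-ratio computation, quartile scheme, bin distributions, sample size."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orgfid import (
    bin_index,
    fit_bin_scheme,
    least_bin_frequency,
    log2_ratio,
    make_distribution,
    min_sections,
)
from orgfid.binning import BinDistribution, BinScheme, LogRatioRecord
from orgfid.errors import (
    ConfigurationError,
    EmptyConditionError,
    InsufficientReferenceError,
    NoTissueError,
)
from orgfid.image_quant import SectionQuant


def _quant(k8, k14, tissue=None):
    tissue = (k8 + k14) if tissue is None else tissue
    area = max(1, 4 * (k8 + k14), tissue)
    return SectionQuant(
        section_id="s", patient_id="p", subtype="synthetic", condition="c",
        source_kind="ST", image_area_px=area, tissue_area_px=tissue,
        k8_area_px=k8, k14_area_px=k14,
    )


def _recs(values):
    return [
        LogRatioRecord(section_id=f"s{i}", patient_id="p", subtype="synthetic",
                       condition="c", source_kind="ST", log2_ratio=v)
        for i, v in enumerate(values)
    ]


class TestLog2Ratio:
    @pytest.mark.parametrize("k8,k14,expected", [(100, 100, 0.0), (400, 100, 2.0)])
    def test_plain_ratio(self, k8, k14, expected):
        rec = log2_ratio(_quant(k8, k14))
        assert rec.log2_ratio == expected
        assert not rec.pseudocount_applied

    def test_pseudocount_on_zero_area(self):
        rec = log2_ratio(_quant(400, 0), pseudocount_px=1)
        assert rec.log2_ratio == pytest.approx(math.log2(401), abs=1e-12)
        assert rec.pseudocount_applied

    def test_no_tissue_rejected(self):
        with pytest.raises(NoTissueError):
            log2_ratio(_quant(0, 0, tissue=0))


class TestFitBinScheme:
    def test_symmetric_odd_sample(self):
        scheme = fit_bin_scheme(_recs([-2, -1, 0, 1, 2]))
        assert scheme.boundaries == (-1.0, 0.0, 1.0)
        assert scheme.n_reference == 5

    def test_constant_sample_degenerate_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            scheme = fit_bin_scheme(_recs([0.5] * 8))
        assert scheme.boundaries == (0.5, 0.5, 0.5)

    def test_standard_normal_quartiles(self, rng):
        scheme = fit_bin_scheme(_recs(rng.standard_normal(1000)))
        expected = (-0.6744897501, 0.0, 0.6744897501)
        for got, want in zip(scheme.boundaries, expected):
            assert abs(got - want) < 0.1

    def test_too_few_records(self):
        with pytest.raises(InsufficientReferenceError):
            fit_bin_scheme(_recs([0, 1, 2]))


class TestBinIndex:
    def test_boundary_closures(self, symmetric_scheme):
        s = symmetric_scheme
        assert bin_index(s.q25, s) == 1  # boundary belongs to the left bin
        assert bin_index(s.q25 + 1e-9, s) == 2
        assert bin_index(s.q50, s) == 2
        assert bin_index(s.q75, s) == 3
        assert bin_index(s.q75 + 0.001, s) == 4
        assert bin_index(s.q25 - 5.0, s) == 1

    @given(value=st.floats(-50, 50), shift=st.floats(-10, 10))
    @settings(max_examples=200, deadline=None)
    def test_shift_equivariance(self, value, shift):
        """Shifting values and boundaries together never changes the bin."""
        s1 = BinScheme(q25=-1.0, q50=0.25, q75=2.0)
        s2 = BinScheme(q25=-1.0 + shift, q50=0.25 + shift, q75=2.0 + shift)
        assert bin_index(value, s1) == bin_index(value + shift, s2)


class TestMakeDistribution:
    def test_degenerate_all_bin1(self, symmetric_scheme):
        d = make_distribution(_recs([-5, -6, -7]), symmetric_scheme, "x")
        assert d.probs == (1.0, 0.0, 0.0, 0.0)

    def test_exact_counts(self, symmetric_scheme):
        values = [-2, -1.5, -0.5, -0.2, 0.3, 0.9, 1.5, 2.0]
        d = make_distribution(_recs(values), symmetric_scheme, "x")
        assert d.counts == (2, 2, 2, 2)
        assert d.probs == (0.25, 0.25, 0.25, 0.25)

    def test_probs_sum_exactly_one(self, symmetric_scheme, rng):
        d = make_distribution(_recs(rng.normal(0, 2, 37)), symmetric_scheme, "x")
        assert sum(d.probs) == 1.0
        assert d.n_sections == 37

    def test_empty_condition(self, symmetric_scheme):
        with pytest.raises(EmptyConditionError):
            make_distribution([], symmetric_scheme, "x")

    def test_undersampling_warns(self, symmetric_scheme):
        spec = min_sections(0.08, 0.85)
        with pytest.warns(UserWarning, match="below the minimum"):
            make_distribution(_recs([0.1] * 5), symmetric_scheme, "x",
                              sample_size=spec)

    @pytest.mark.parametrize("n", [5, 8, 23, 97, 100])
    def test_self_quartile_property(self, n, rng):
        """A cohort binned by its own scheme fills all bins ~equally."""
        values = rng.normal(0.4, 1.7, n)
        recs = _recs(values)
        scheme = fit_bin_scheme(recs)
        d = make_distribution(recs, scheme, "self")
        assert all(abs(p - 0.25) <= 2.0 / n + 1e-12 for p in d.probs)


class TestMinSections:
    @pytest.mark.parametrize("f,c,expected", [
        (0.08, 0.85, 23),   # the least-bin frequency and confidence in use
        (1.0, 0.5, 1),
        (1.0, 0.0, 1),
        (0.1, 0.9, 22),     # frozen from direct iteration over N
    ])
    def test_known_values(self, f, c, expected):
        assert min_sections(f, c).n_min == expected

    def test_definition_holds_at_and_below_n_min(self):
        spec = min_sections(0.08, 0.85)
        n = spec.n_min
        assert 1 - 0.92**n >= 0.85
        assert 1 - 0.92 ** (n - 1) < 0.85

    @given(
        f=st.floats(0.01, 0.99), c=st.floats(0.0, 0.99),
        df=st.floats(0.0, 0.5), dc=st.floats(0.0, 0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotonicity(self, f, c, df, dc):
        """n_min never increases with f, never decreases with c."""
        base = min_sections(f, c).n_min
        assert min_sections(min(f + df, 1.0), c).n_min <= base
        assert min_sections(f, min(c + dc, 0.999)).n_min >= base

    @pytest.mark.parametrize("f,c", [(0.0, 0.5), (-0.1, 0.5), (0.1, 1.0)])
    def test_invalid_inputs(self, f, c):
        with pytest.raises(ConfigurationError):
            min_sections(f, c)


class TestLeastBinFrequency:
    def test_examples(self):
        d1 = BinDistribution("a", (7, 1, 1, 1))
        assert least_bin_frequency([d1]) == pytest.approx(0.1)
        d2 = BinDistribution("b", (30, 15, 12, 3))  # min prob 0.05
        d3 = BinDistribution("c", (20, 22, 24, 14))  # min prob 0.175
        assert least_bin_frequency([d2, d3]) == pytest.approx((0.05 + 0.175) / 2)
        uniform = BinDistribution("u", (5, 5, 5, 5))
        assert least_bin_frequency([uniform]) == 0.25
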