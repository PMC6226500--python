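"""Sample coverage, accumulation curves and the curvilinearity completeness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latgaps import (
    BandGrid,
    accumulation_curve,
    band_completeness,
    band_incidences,
    completeness_table,
    exact_accumulation_curve,
    sac_completeness,
    sample_coverage,
)

from conftest import make_records

# three sampling events recording species sets {A,B}, {B}, {C}
THREE_EVENTS = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 1]], dtype=bool)


class TestSampleCoverage:
    def test_direct_evaluation(self):
        # 1 - (2/10) * (9*2 / (9*2 + 2)) = 1 - 0.2 * 0.9
        assert sample_coverage(10, 2, 1) == pytest.approx(0.82)

    def test_no_singletons_full_coverage(self):
        assert sample_coverage(7, 0, 3) == 1.0

    def test_all_singletons_zero_coverage(self):
        assert sample_coverage(5, 5, 0) == 0.0

    def test_degenerate_sizes(self):
        assert math.isnan(sample_coverage(0, 0, 0))
        assert sample_coverage(1, 1, 0) == 0.0

    def test_precondition_errors(self):
        with pytest.raises(ValueError):
            sample_coverage(3, 2, 1)  # f1 + 2 f2 > n
        with pytest.raises(ValueError):
            sample_coverage(-1, 0, 0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(2, 500), st.data())
    def test_monotone_in_singletons(self, n, data):
        """At fixed n and f2, more singletons never increase coverage."""
        f2 = data.draw(st.integers(0, n // 2))
        f1_max = n - 2 * f2
        f1 = data.draw(st.integers(1, max(1, f1_max)))
        if f1 + 2 * f2 > n:
            return
        c_hi = sample_coverage(n, f1, f2)
        c_lo = sample_coverage(n, f1 - 1, f2)
        assert c_lo >= c_hi - 1e-12

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(2, 500), st.data())
    def test_duplicating_a_singleton_never_decreases_coverage(self, n, data):
        f2 = data.draw(st.integers(0, n // 3))
        f1 = data.draw(st.integers(1, max(1, n - 2 * f2)))
        if f1 + 2 * f2 > n:
            return
        before = sample_coverage(n, f1, f2)
        after = sample_coverage(n + 1, f1 - 1, f2 + 1)
        assert after >= before - 1e-12


class TestAccumulationCurve:
    def test_every_event_has_all_species(self):
        M = np.ones((6, 4), dtype=bool)
        assert np.allclose(accumulation_curve(M, n_perm=10, seed=0), 4.0)

    def test_each_event_one_novel_species(self):
        M = np.eye(5, dtype=bool)
        assert np.allclose(accumulation_curve(M, n_perm=10, seed=0), np.arange(1, 6))

    def test_exact_three_event_curve(self):
        """Exhaustive average over all 6 orderings of {AB},{B},{C}:
        ((2+2+1+1+1+1)/6, (2+3+2+2+3+2)/6, 3) = (4/3, 7/3, 3)."""
        curve = exact_accumulation_curve(THREE_EVENTS)
        assert np.allclose(curve, [4 / 3, 7 / 3, 3.0])

    def test_monte_carlo_reproducible_and_converging(self):
        a = accumulation_curve(THREE_EVENTS, n_perm=500, seed=11)
        b = accumulation_curve(THREE_EVENTS, n_perm=500, seed=11)
        assert np.array_equal(a, b)  # bit-for-bit at the same seed
        c = accumulation_curve(THREE_EVENTS, n_perm=500, seed=12)
        assert not np.array_equal(a, c)

    def test_curve_non_decreasing_and_ends_at_total(self):
        rng = np.random.default_rng(3)
        M = rng.random((15, 20)) < 0.2
        M[0, 0] = True
        curve = accumulation_curve(M, n_perm=50, seed=4)
        assert (np.diff(curve) >= -1e-12).all()
        assert curve[-1] == pytest.approx(M.any(axis=0).sum())

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            accumulation_curve(np.zeros((0, 3), dtype=bool))
        with pytest.raises(ValueError):
            exact_accumulation_curve(np.zeros((9, 2), dtype=bool))  # > 8 events


class TestSacCompleteness:
    def test_flat_tail_is_complete(self):
        curve = np.minimum(np.arange(1, 101), 30.0)
        assert sac_completeness(curve) == 1.0

    def test_linear_curve_is_incomplete(self):
        assert sac_completeness(np.arange(1.0, 101.0)) == 0.0

    def test_event_threshold_is_strict(self):
        assert math.isnan(sac_completeness(np.arange(1.0, 41.0)))  # 40 events
        assert not math.isnan(sac_completeness(np.arange(1.0, 42.0)))  # 41 events

    def test_tail_window(self):
        # 100 events: last 10 events; half a species per event in the tail
        curve = np.concatenate([np.arange(1.0, 91.0), 90 + 0.5 * np.arange(1, 11)])
        assert sac_completeness(curve) == pytest.approx(0.5)


class TestBandCompleteness:
    def test_zero_record_band_undefined(self):
        est = band_completeness(None)
        assert math.isnan(est.coverage) and math.isnan(est.sac)

    def test_saturated_band(self, grid):
        rec = make_records(
            [
                (f"Genus sp{s}", 1.0 + 0.01 * e, 2.0, "2000-01-01")
                for e in range(50)
                for s in range(3)
            ]
        )
        inc = band_incidences(rec, grid)[16]
        assert inc.n_events == 50
        est = band_completeness(inc, n_perm=50, seed=0)
        assert est.coverage == 1.0
        assert est.sac == 1.0

    def test_heavy_singleton_band_low_coverage(self, grid):
        # 6 singletons among 10 records: coverage below 0.5
        rows = [(f"Genus sp{s}", 1.0, 2.0 + s, "2000-01-01") for s in range(6)]
        rows += [("Genus sp40", 1.0, 50.0 + e, "2000-01-01") for e in range(4)]
        inc = band_incidences(make_records(rows), grid)[16]
        assert (inc.f1, inc.n_records) == (6, 10)
        est = band_completeness(inc, n_perm=10, seed=0)
        assert est.coverage < 0.5
        assert math.isnan(est.sac)  # only 10 events

    def test_completeness_table_shape_and_reproducibility(self, grid):
        rec = make_records(
            [(f"Genus sp{s}", -30.0 + s, 2.0 + e, "2000-01-01")
             for s in range(5) for e in range(10)]
        )
        a = completeness_table(rec, grid, n_perm=20, seed=9)
        b = completeness_table(rec, grid, n_perm=20, seed=9)
        assert len(a) == grid.n_bands
        assert a.equals(b)
        empty = a[a.n_records == 0]
        assert empty["coverage"].isna().all() and empty["sac"].isna().all()
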