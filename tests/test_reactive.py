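"""Reactive-geometry classification and summary statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from loxmd.errors import InputError
from loxmd.reactive import (
    GeometrySummary,
    ReactiveDistances,
    classify,
    classify_frame,
    compare_summaries,
    compute_reactive_distances,
    summarize,
)
from loxmd.refdata import load_reference_geometry
from loxmd.synth import gen_reactive_frames


def rd(d_c, d_hs, d_hr, i=0):
    return ReactiveDistances(i, 0.0, d_c, d_hs, d_hr)


class TestClassifyFrame:
    def test_both_criteria_met(self):
        c = classify_frame(rd(3.7, 2.5, 5.0))
        assert c.well_oriented_S and c.precatalytic_S
        assert c.well_oriented_any and c.precatalytic_any

    def test_oriented_but_beyond_cutoff(self):
        c = classify_frame(rd(3.7, 3.5, 5.0))
        assert c.well_oriented_S and not c.precatalytic_S

    def test_close_but_misoriented(self):
        c = classify_frame(rd(2.5, 2.9, 5.0))
        assert not c.well_oriented_S and not c.precatalytic_S

    def test_cutoff_boundary_is_inclusive(self):
        c = classify_frame(rd(3.7, 3.0, 5.0))
        assert c.precatalytic_S

    def test_orientation_boundary_is_strict(self):
        c = classify_frame(rd(3.0, 3.0, 5.0))
        assert not c.well_oriented_S


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    d_c=st.floats(0.5, 10.0),
    d_hs=st.floats(0.5, 10.0),
    d_hr=st.floats(0.5, 10.0),
    cutoff=st.floats(1.0, 6.0),
)
def test_precatalytic_implies_well_oriented(d_c, d_hs, d_hr, cutoff):
    c = classify_frame(rd(d_c, d_hs, d_hr), cutoff=cutoff)
    assert not c.precatalytic_S or c.well_oriented_S
    assert not c.precatalytic_R or c.well_oriented_R
    assert c.precatalytic_any == (c.precatalytic_S or c.precatalytic_R)
    assert c.well_oriented_any == (c.well_oriented_S or c.well_oriented_R)
    # independent brute-force re-evaluation of the two inequalities
    assert c.precatalytic_S == (d_hs <= cutoff and d_hs < d_c)
    assert c.precatalytic_R == (d_hr <= cutoff and d_hr < d_c)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(seed=st.integers(0, 1000))
def test_precatalytic_pct_monotone_in_cutoff(seed):
    traj, _ = gen_reactive_frames(200, 3.8, 0.6, 15.0, seed=seed)
    rds = compute_reactive_distances(traj)
    pcts = []
    for cutoff in (2.0, 3.0, 4.0, np.inf):
        s = summarize(rds, classify(rds, cutoff=cutoff))
        pcts.append(s.pct_precatalytic)
    assert pcts == sorted(pcts)
    s_inf = summarize(rds, classify(rds, cutoff=np.inf))
    assert s_inf.pct_precatalytic == pytest.approx(s_inf.pct_well_oriented)


class TestComputeDistances:
    def test_simple_frame_distance(self):
        traj, _ = gen_reactive_frames(1, 3.7, 0.0, 0.0, seed=0)
        r = compute_reactive_distances(traj)[0]
        assert r.d_C_OH == pytest.approx(3.7)
        # hydrogen on the C->O segment at 1.09 Å from C
        assert r.d_HproS_OH == pytest.approx(3.7 - 1.09)

    def test_matches_generator_ground_truth(self):
        traj, spec = gen_reactive_frames(500, 3.5, 0.5, 25.0, seed=11)
        rds = compute_reactive_distances(traj)
        np.testing.assert_allclose(
            [r.d_C_OH for r in rds], spec.ground_truth["d_C_OH"], atol=1e-9
        )
        np.testing.assert_allclose(
            [r.d_HproS_OH for r in rds], spec.ground_truth["d_H_OH"], atol=1e-9
        )
        np.testing.assert_allclose(
            [r.d_HproR_OH for r in rds], spec.ground_truth["d_H_OH"], atol=1e-9
        )


class TestSummarize:
    def test_percentages(self):
        rds = [rd(3.7, 2.5, 5.0, i) for i in range(2)] + [rd(3.7, 5.0, 5.0, i + 2) for i in range(2)]
        s = summarize(rds, classify(rds))
        assert s.pct_precatalytic == pytest.approx(50.0)
        assert s.n_frames == 4

    def test_identical_frames_mean_is_frame_value(self):
        rds = [rd(4.2, 3.1, 5.0, i) for i in range(10)]
        s = summarize(rds, classify(rds))
        assert s.mean_d_C_OH == pytest.approx(4.2)
        assert s.mean_d_HproS_OH == pytest.approx(3.1)

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            summarize([], [])

    def test_large_sample_matches_analytic_fraction(self):
        """Empirical pre-catalytic % within the 99% binomial CI of the
        truncated-normal closed form."""
        n = 10_000
        traj, spec = gen_reactive_frames(n, 3.5, 0.5, 0.0, seed=42)
        rds = compute_reactive_distances(traj)
        s = summarize(rds, classify(rds))
        p = spec.ground_truth["expected"]["precatalytic"]
        half_width = 100 * norm.ppf(0.995) * np.sqrt(p * (1 - p) / n)
        assert abs(s.pct_precatalytic - 100 * p) <= half_width


class TestCompareSummaries:
    @staticmethod
    def _summary(pct_pc, pct_wo=99.0, mean_c=4.0):
        return GeometrySummary(
            n_frames=1, mean_d_C_OH=mean_c, mean_d_HproS_OH=4.0, mean_d_HproR_OH=4.0,
            pct_well_oriented=pct_wo, pct_precatalytic=pct_pc,
        )

    def test_large_fold_displays_as_integer(self):
        cmp = compare_summaries(self._summary(55.69), self._summary(3.40))
        assert cmp.fold_precatalytic == pytest.approx(55.69 / 3.40)
        assert cmp.display_fold_precatalytic == 16

    def test_small_fold_displays_one_decimal(self):
        cmp = compare_summaries(self._summary(22.65), self._summary(14.40))
        assert cmp.display_fold_precatalytic == pytest.approx(1.6)

    def test_distance_shift(self):
        cmp = compare_summaries(
            self._summary(50.0, mean_c=3.70), self._summary(5.0, mean_c=5.19)
        )
        assert cmp.delta_mean_d_C_OH == pytest.approx(1.49)
        assert cmp.display_delta_mean_d_C_OH == pytest.approx(1.5)

    def test_zero_reference_rejected(self):
        with pytest.raises(Exception):
            compare_summaries(self._summary(10.0), self._summary(0.0))


def test_reference_summaries_reproduce_published_contrasts():
    """The shipped literature summaries give the published fold changes."""
    ref = load_reference_geometry()
    aa = compare_summaries(ref[("Trp181Glu", "AA")], ref[("WT", "AA")])
    assert aa.display_fold_precatalytic == 16
    assert aa.display_delta_mean_d_C_OH == pytest.approx(1.5)
    la = compare_summaries(ref[("Trp181Glu", "LA")], ref[("WT", "LA")])
    assert la.display_fold_precatalytic == pytest.approx(1.6)
    assert la.display_delta_mean_d_C_OH == pytest.approx(0.3)
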