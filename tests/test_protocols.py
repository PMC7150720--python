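"""Unit tests for pacing protocols, APD measurement, restitution and
alternans detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiolab import protocols as pr
from cardiolab.exceptions import (
    CaptureError,
    ConfigurationError,
    InsufficientDataError,
    UnrepolarizedBeatError,
)
from conftest import triangle_ap


class TestAPDMeasurement:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(duration=st.floats(60.0, 400.0))
    def test_triangle_apd_matches_analytic_value(self, duration):
        """For a linear-repolarization triangle the 90% crossing sits at
        0.9 x (full repolarization time), to interpolation accuracy."""
        t, v = triangle_ap(duration=duration)
        apd = pr.apd_from_series(t, v)
        assert apd == pytest.approx(0.9 * duration, abs=0.2)

    def test_unrepolarized_beat_raises(self):
        t = np.arange(0.0, 300.0, 0.1)
        v = np.where(t < 10.0, -85.0, 20.0)   # upstroke, never repolarizes
        with pytest.raises(UnrepolarizedBeatError):
            pr.apd_from_series(t, v)

    def test_no_upstroke_raises(self):
        t = np.arange(0.0, 100.0, 0.1)
        with pytest.raises(CaptureError):
            pr.apd_from_series(t, np.full_like(t, -85.0))

    def test_resampling_stability(self):
        """APD from a 10x coarser output grid agrees within 0.1 ms
        (interpolated crossings, dense-grid oracle)."""
        tr = pr.pace_to_steady_state("epi", "E299V", n_beats=6,
                                     record_beats=1, record_stride=1)
        apd_dense = pr.measure_apd(tr, -1)
        sub = pr.PacedTrace(
            t=tr.t[::10], V=tr.V[::10], Ca_i=tr.Ca_i[::10],
            I_K1=tr.I_K1[::10], stim_times=tr.stim_times, BCL=tr.BCL,
            n_beats=tr.n_beats, dt=tr.dt * 10)
        assert pr.measure_apd(sub, -1) == pytest.approx(apd_dense, abs=0.1)


class TestPacing:
    def test_two_beat_bookkeeping(self):
        """n_beats=2: two upstrokes; DI of beat 2 = BCL - APD of beat 1."""
        tr = pr.pace_to_steady_state("endo", "WT_E299V", n_beats=2,
                                     record_beats=2)
        assert tr.n_recorded_beats == 2
        apd1 = pr.measure_apd(tr, 0)
        di = tr.BCL - apd1
        assert di > 0
        assert pr._count_upstrokes(tr.t, tr.V) == 2

    def test_loss_of_capture_raises(self):
        """A BCL far below the APD cannot hold 1:1 capture."""
        with pytest.raises(CaptureError):
            pr.pace_to_steady_state("endo", "WT", BCL=60.0, n_beats=6,
                                    record_beats=6)

    def test_trace_invariants(self):
        tr = pr.pace_to_steady_state("epi", "E299V", n_beats=4,
                                     record_beats=3)
        assert len(tr.t) == len(tr.V) == len(tr.Ca_i)
        assert np.all(np.diff(tr.stim_times) == tr.BCL)

    def test_bad_config_rejected(self):
        with pytest.raises(ConfigurationError):
            pr.pace_to_steady_state("endo", "WT", n_beats=1)


class TestRestitutionCurve:
    def _linear_curve(self, slope=0.5, n=15):
        bcl = np.linspace(400.0, 260.0, n)
        apd = np.empty(n)
        di = np.empty(n)
        # self-consistent dynamic protocol: DI = BCL - APD(previous step);
        # for the synthetic check simply impose APD = 100 + slope*DI
        for i, b in enumerate(bcl):
            di[i] = (b - 100.0) / (1.0 + slope)
            apd[i] = 100.0 + slope * di[i]
        return pr.RestitutionCurve(bcl=bcl, di=di, apd=apd)

    def test_linear_curve_slope_recovered(self):
        """APD(DI) = 100 + 0.5 DI yields slope 0.5 everywhere."""
        curve = self._linear_curve(0.5)
        assert np.allclose(curve.slopes(), 0.5, atol=1e-9)

    def test_slopes_match_spline_oracle(self):
        """Central differences vs an independent cubic-spline derivative
        agree within 5% on a smooth curved restitution."""
        from scipy.interpolate import CubicSpline
        di = np.linspace(40.0, 300.0, 25)
        apd = 300.0 - 160.0 * np.exp(-di / 80.0)
        bcl = di + apd
        curve = pr.RestitutionCurve(bcl=bcl, di=di, apd=apd)
        slopes = curve.slopes()[::-1]          # ascending DI order
        oracle = CubicSpline(di, apd)(di, 1)
        interior = slice(1, -1)
        rel = np.abs(slopes[interior] - oracle[interior]) / \
            np.abs(oracle[interior])
        assert np.max(rel) < 0.05

    def test_di_identity_on_scan(self, restitution_scans):
        """DI = BCL - preceding APD >= 0 on every captured record."""
        curve = restitution_scans[("E299V", "endo")]
        assert np.all(curve.di >= 0)
        assert np.all(np.diff(np.unique(curve.bcl)) > 0)

    def test_too_few_levels(self):
        c = pr.RestitutionCurve(bcl=np.array([400.0, 390.0]),
                                di=np.array([100.0, 95.0]),
                                apd=np.array([300.0, 295.0]))
        with pytest.raises(InsufficientDataError):
            c.slopes()


class TestAlternansDetection:
    def test_constant_sequence_none(self):
        assert pr.detect_alternans({300.0: np.full(8, 210.0)}) is None

    def test_constructed_alternans_detected(self):
        seqs = {300.0: np.array([200.0, 180.0, 200.0, 180.0])}
        assert pr.detect_alternans(seqs, threshold=5.0) == 300.0

    def test_largest_bcl_reported(self):
        alt = np.array([200.0, 180.0, 200.0, 180.0])
        seqs = {280.0: alt, 320.0: alt, 300.0: np.full(4, 200.0)}
        assert pr.detect_alternans(seqs) == 320.0

    def test_invariant_to_discarding_equilibrated_beats(self):
        """Prepending already-equilibrated beats does not change the call."""
        base = {260.0: np.array([190.0, 170.0, 190.0, 170.0])}
        padded = {260.0: np.concatenate([[190.0, 170.0] * 3,
                                         base[260.0]])}
        assert pr.detect_alternans(base) == pr.detect_alternans(padded)

    def test_short_sequence_raises(self):
        with pytest.raises(InsufficientDataError):
            pr.detect_alternans({300.0: np.array([200.0, 180.0])})

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(1.0, 50.0), st.floats(150.0, 250.0))
    def test_alternating_above_threshold_always_flagged(self, delta, base):
        """Any strict alternation with |difference| > threshold is found."""
        seq = np.array([base + delta, base - delta] * 3)
        got = pr.detect_alternans({250.0: seq}, threshold=delta * 0.99)
        assert got == 250.0

    def test_monotone_apd_along_curve(self, restitution_scans):
        """Mean APD is non-increasing as BCL decreases until truncation."""
        curve = restitution_scans[("WT_E299V", "epi")]
        bcl_u = np.unique(curve.bcl)[::-1]
        apd_m = np.array([curve.apd[curve.bcl == b].mean() for b in bcl_u])
        assert np.all(np.diff(apd_m) < 1.0)   # tiny tolerance for noise
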