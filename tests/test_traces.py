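"""Trace processing: background subtraction, FRET computation, bleach
detection and histogram construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from g4fold import (
    IntensityTrajectory,
    TwoStateModel,
    background_correct,
    build_histogram,
    compute_fret,
    detect_photobleach,
    molecule_fret_value,
    simulate_ensemble,
    simulate_two_state_trajectory,
)
from g4fold.traces import FretTrace, estimate_background_post_bleach


def make_traj(donor, acceptor, dt=0.1, mol="m"):
    donor = np.asarray(donor, dtype=float)
    return IntensityTrajectory(
        molecule_id=mol, time=np.arange(len(donor)) * dt,
        donor=donor, acceptor=np.asarray(acceptor, dtype=float), frame_interval=dt,
    )


class TestBackgroundAndFret:
    def test_constant_subtraction(self):
        traj = make_traj([300, 300], [200, 200])
        out = background_correct(traj, 100, 50)
        np.testing.assert_array_equal(out.donor, [200, 200])
        np.testing.assert_array_equal(out.acceptor, [150, 150])

    def test_zero_background_is_identity(self):
        traj = make_traj([300, 310], [200, 190])
        out = background_correct(traj, 0, 0)
        np.testing.assert_array_equal(out.donor, traj.donor)

    def test_post_bleach_median_recovers_background(self):
        model = TwoStateModel(tau_bleach_donor=15.0, bg_donor=50, bg_acceptor=50,
                              n_frames=600, seed=8)
        for traj, truth in simulate_ensemble(model, 20):
            if truth.donor_bleach_frame is not None and truth.donor_bleach_frame < 400:
                d, a = estimate_background_post_bleach(traj, truth.donor_bleach_frame)
                assert d == pytest.approx(50, abs=2)
                assert a == pytest.approx(50, abs=2)
                return
        pytest.fail("no donor-bleached molecule in fixture")

    @pytest.mark.parametrize("acceptor,donor,expected", [
        (50, 50, 0.5), (0, 100, 0.0), (85, 15, 0.85),
    ])
    def test_fret_arithmetic(self, acceptor, donor, expected):
        traj = make_traj([donor] * 20, [acceptor] * 20)
        trace = compute_fret(traj, min_total=10)
        assert trace.efficiency[0] == pytest.approx(expected)

    def test_all_frames_below_threshold_raises(self):
        traj = make_traj([1] * 20, [1] * 20)
        with pytest.raises(ValueError, match="below min_total"):
            compute_fret(traj, min_total=100)

    def test_noiseless_fret_equals_state_means(self, noiseless_model):
        traj, truth = simulate_two_state_trajectory(noiseless_model)
        trace = compute_fret(traj, min_total=1)
        expected = np.where(truth.state_path == 1,
                            noiseless_model.e_high, noiseless_model.e_low)
        np.testing.assert_allclose(trace.efficiency, expected, rtol=1e-12)


class TestPhotobleachDetection:
    def test_constructed_acceptor_step(self):
        acc = np.r_[np.full(120, 500.0), np.full(80, 50.0)]
        don = np.r_[np.full(120, 300.0), np.full(80, 750.0)]
        rng = np.random.default_rng(0)
        traj = make_traj(don + rng.normal(0, 5, 200), acc + rng.normal(0, 5, 200))
        a, d = detect_photobleach(traj)
        assert a == 120
        assert d is None

    def test_flat_trace_no_bleach(self):
        rng = np.random.default_rng(1)
        traj = make_traj(300 + rng.normal(0, 10, 200), 500 + rng.normal(0, 10, 200))
        assert detect_photobleach(traj) == (None, None)

    def test_short_trace_rejected(self):
        traj = make_traj([1] * 5, [1] * 5)
        with pytest.raises(ValueError):
            detect_photobleach(traj)

    def test_state_transition_not_mistaken_for_bleach(self):
        """A high->low unfolding step is anticorrelated but leaves the
        acceptor at the low-state level, so it must not be called a bleach."""
        acc = np.r_[np.full(100, 850.0), np.full(100, 490.0)]
        don = np.r_[np.full(100, 150.0), np.full(100, 510.0)]
        rng = np.random.default_rng(2)
        traj = make_traj(don + rng.normal(0, 8, 200), acc + rng.normal(0, 8, 200))
        a, d = detect_photobleach(traj)
        assert a is None and d is None

    def test_donor_bleach_total_collapse(self):
        don = np.r_[np.full(150, 600.0), np.full(50, 20.0)]
        acc = np.r_[np.full(150, 400.0), np.full(50, 30.0)]
        rng = np.random.default_rng(3)
        traj = make_traj(don + rng.normal(0, 5, 200), acc + rng.normal(0, 5, 200))
        a, d = detect_photobleach(traj)
        assert d == 150

    def test_bleach_lifetime_recovery(self):
        """Detected bleach times on a simulated ensemble reproduce the
        generating exponential lifetime (window long enough that
        truncation is negligible)."""
        model = TwoStateModel(tau_bleach_acceptor=30.0, n_frames=1000, seed=13)
        times = []
        for traj, truth in simulate_ensemble(model, 300):
            a, d = detect_photobleach(traj)
            if a is not None:
                times.append(a * model.frame_interval)
        assert len(times) > 250
        assert np.mean(times) == pytest.approx(30.0, abs=3.0)

    def test_truncation_idempotent(self, small_ensemble):
        """Re-running detection on a bleach-truncated trace finds nothing."""
        model = TwoStateModel(tau_bleach_acceptor=40.0, n_frames=600, seed=19)
        for traj, _ in simulate_ensemble(model, 10):
            a, d = detect_photobleach(traj)
            cut = min(f for f in (a, d, traj.n_frames) if f is not None)
            if cut >= 10:
                sub = make_traj(traj.donor[:cut], traj.acceptor[:cut],
                                dt=traj.frame_interval)
                a2, _ = detect_photobleach(sub)
                assert a2 is None


class TestMoleculeValueAndHistogram:
    def test_constant_trace_mean(self):
        trace = FretTrace("m", np.arange(20) * 0.1, np.full(20, 0.41), 20, 0.1)
        assert molecule_fret_value(trace) == pytest.approx(0.41)

    def test_insufficient_frames_excluded(self):
        trace = FretTrace("m", np.arange(14) * 0.1, np.full(14, 0.5), 14, 0.1)
        assert molecule_fret_value(trace, n_first_frames=15) is None

    def test_ensemble_mean_recovery(self):
        """Per-molecule early-frame averages center on the state mean."""
        model = TwoStateModel(e_low=0.40, e_high=0.41, k_lh=100.0, k_hl=1e-9,
                              p_init_high=1.0, sigma_e_high=0.05, seed=23,
                              n_frames=20, bg_donor=0, bg_acceptor=0,
                              sigma_channel=0)
        values = []
        for traj, _ in simulate_ensemble(model, 150):
            trace = compute_fret(traj, min_total=10)
            v = molecule_fret_value(trace)
            assert v is not None
            values.append(v)
        assert np.mean(values) == pytest.approx(0.41, abs=0.01)

    def test_all_identical_values_single_bin(self):
        hist = build_histogram([0.5] * 50)
        assert np.count_nonzero(hist.counts) == 1
        assert hist.counts.sum() == 50

    def test_too_few_molecules(self):
        with pytest.raises(ValueError, match="at least 10"):
            build_histogram([0.5] * 9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        bin_width=st.floats(0.01, 0.05),
        n=st.integers(10, 400),
        seed=st.integers(0, 1000),
    )
    def test_histogram_conserves_counts(self, bin_width, n, seed):
        values = np.random.default_rng(seed).normal(0.6, 0.3, n)  # tails beyond range
        hist = build_histogram(values, bin_width=bin_width)
        assert hist.counts.sum() == n

    def test_bimodal_histogram_modes(self, bimodal_values):
        hist = build_histogram(bimodal_values)
        centers = hist.bin_centers
        lo = centers[(centers > 0.3) & (centers < 0.65)]
        hi = centers[(centers > 0.65) & (centers < 1.0)]
        mode_lo = lo[np.argmax(hist.counts[(centers > 0.3) & (centers < 0.65)])]
        mode_hi = hi[np.argmax(hist.counts[(centers > 0.65) & (centers < 1.0)])]
        assert mode_lo == pytest.approx(0.49, abs=0.03)
        assert mode_hi == pytest.approx(0.81, abs=0.03)
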