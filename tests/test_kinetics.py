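"""Dwell-time extraction and rate estimation, including recovery at the
slow-folding regime where censoring dominates."""

import numpy as np
import pandas as pd
import pytest

from g4fold import (
    TwoStateModel,
    assign_states,
    background_correct,
    compute_fret,
    extract_dwells,
    fit_dwell_rate,
    folding_energetics,
    per_molecule_mean_dwells,
    simulate_ensemble,
    simulate_two_state_trajectory,
)
from g4fold.kinetics import DwellTable, StateSequence
from g4fold.traces import FretTrace


def trace_from_e(e_values, dt=0.3, mol="m"):
    e = np.asarray(e_values, dtype=float)
    return FretTrace(mol, np.arange(len(e)) * dt, e, len(e), dt)


def dwell_table_from_durations(durations, state="low", dt=0.3):
    """All complete dwells of one state, as if pooled across molecules."""
    rows = [
        {"molecule_id": f"m{i}", "state": state, "duration_s": d,
         "censored": False, "ends_at_trace_end": False}
        for i, d in enumerate(durations)
    ]
    return DwellTable(table=pd.DataFrame(rows), frame_interval=dt)


class TestStateAssignment:
    def test_constructed_threshold(self):
        e = [0.4] * 10 + [0.85] * 5 + [0.4] * 10
        seq = assign_states(trace_from_e(e), threshold=0.6, median_filter=False)
        np.testing.assert_array_equal(seq.states, [0] * 10 + [1] * 5 + [0] * 10)

    def test_all_above_threshold_single_dwell(self):
        seq = assign_states(trace_from_e([0.9] * 20), threshold=0.6)
        table = extract_dwells(seq).table
        assert len(table) == 1
        assert table.iloc[0]["state"] == "high"

    def test_noiseless_roundtrip_matches_ground_truth(self, noiseless_model):
        traj, truth = simulate_two_state_trajectory(noiseless_model)
        trace = compute_fret(traj, min_total=1)
        mid = 0.5 * (noiseless_model.e_low + noiseless_model.e_high)
        seq = assign_states(trace, threshold=mid, median_filter=False)
        np.testing.assert_array_equal(seq.states, truth.state_path)

    def test_requires_threshold_or_two_components(self):
        with pytest.raises(ValueError, match="two-component"):
            assign_states(trace_from_e([0.5] * 10))

    def test_noisy_misassignment_rate(self):
        """sigma_e=0.05 with dmu=0.3: <1% misassigned frames with filter."""
        model = TwoStateModel(e_low=0.5, e_high=0.8, k_lh=0.05, k_hl=0.05,
                              sigma_e_low=0.05, sigma_e_high=0.05,
                              bg_donor=0, bg_acceptor=0, sigma_channel=0,
                              n_frames=2000, seed=6)
        mis = []
        for traj, truth in simulate_ensemble(model, 10):
            trace = compute_fret(background_correct(traj, 0, 0), 10)
            seq = assign_states(trace, threshold=0.65, median_filter=True)
            mis.append(np.mean(seq.states != truth.state_path))
        assert np.mean(mis) < 0.01


class TestDwellExtraction:
    def test_run_lengths_and_censoring(self):
        e = [0.4] * 10 + [0.85] * 5 + [0.4] * 10
        table = extract_dwells(assign_states(trace_from_e(e), threshold=0.6,
                                             median_filter=False)).table
        complete = table[~table["censored"]]
        assert len(complete) == 1
        assert complete.iloc[0]["state"] == "high"
        assert complete.iloc[0]["duration_s"] == pytest.approx(1.5)
        assert table["censored"].iloc[0] and table["censored"].iloc[-1]

    def test_constant_trace_no_complete_dwells(self):
        table = extract_dwells(assign_states(trace_from_e([0.4] * 30),
                                             threshold=0.6)).table
        assert (~table["censored"]).sum() == 0

    def test_matches_ground_truth_runs(self, noiseless_model):
        traj, truth = simulate_two_state_trajectory(noiseless_model)
        trace = compute_fret(traj, min_total=1)
        seq = assign_states(trace, threshold=0.65, median_filter=False)
        table = extract_dwells(seq).table
        # durations sum to the trace duration
        assert table["duration_s"].sum() == pytest.approx(
            noiseless_model.n_frames * noiseless_model.frame_interval
        )
        change = np.flatnonzero(np.diff(truth.state_path)).size
        assert len(table) == change + 1

    def test_per_molecule_means(self):
        rows = [
            {"molecule_id": "m1", "state": "high", "duration_s": 1.5,
             "censored": False, "ends_at_trace_end": False},
            {"molecule_id": "m1", "state": "high", "duration_s": 2.5,
             "censored": False, "ends_at_trace_end": False},
            {"molecule_id": "m1", "state": "low", "duration_s": 9.0,
             "censored": True, "ends_at_trace_end": True},
        ]
        table = DwellTable(pd.DataFrame(rows), 0.3)
        means = per_molecule_mean_dwells(table)
        assert means.loc["m1", "mean_high_dwell_s"] == pytest.approx(2.0)
        assert np.isnan(means.loc["m1", "mean_low_dwell_s"])

    def test_mean_high_dwell_matches_rate(self):
        """Mean per-molecule high dwell ~ 1/k_hl = 20 s on long traces."""
        model = TwoStateModel(k_lh=0.05, k_hl=0.05, n_frames=3000, seed=29,
                              sigma_e_low=0.02, sigma_e_high=0.02,
                              bg_donor=0, bg_acceptor=0, sigma_channel=0)
        seqs = []
        for traj, _ in simulate_ensemble(model, 100):
            trace = compute_fret(traj, min_total=10)
            seqs.append(assign_states(trace, threshold=0.65))
        means = per_molecule_mean_dwells(extract_dwells(seqs))
        grand = means["mean_high_dwell_s"].mean()
        assert grand == pytest.approx(20.0, rel=0.15)


class TestRateFits:
    def test_mle_on_exponential_draws(self):
        rng = np.random.default_rng(0)
        d = rng.exponential(20.0, 500)  # k = 0.05
        est = fit_dwell_rate(dwell_table_from_durations(d), "low->high", method="mle")
        assert est.rate == pytest.approx(0.05, abs=0.005)
        assert est.uncertainty == pytest.approx(est.rate / np.sqrt(500))

    def test_mle_single_dwell_is_reciprocal_mean(self):
        est = fit_dwell_rate(dwell_table_from_durations([10.0]), "low->high",
                             method="mle", min_dwells=1)
        assert est.rate == pytest.approx(0.1)

    def test_histogram_agrees_with_mle(self):
        """On uncensored exponential fixtures the two estimators agree
        within 2 combined SE."""
        rng = np.random.default_rng(4)
        d = rng.exponential(20.0, 600)
        table = dwell_table_from_durations(d)
        h = fit_dwell_rate(table, "low->high", method="histogram", bin_width_s=0.6)
        m = fit_dwell_rate(table, "low->high", method="mle")
        combined_se = np.hypot(h.uncertainty, m.uncertainty)
        assert abs(h.rate - m.rate) < 2 * combined_se

    def test_too_few_dwells_reports_count(self):
        with pytest.raises(ValueError, match="only 3"):
            fit_dwell_rate(dwell_table_from_durations([1.0, 2.0, 3.0]), "low->high",
                           method="mle")

    def test_rate_recovery_at_slow_folding_regime(self):
        """Median relative error <= 20% over seeds at k=0.011/0.050,
        dt=0.3 s, 200 molecules x 300 frames (censoring-aware method)."""
        errs_lh, errs_hl = [], []
        for seed in range(10):
            model = TwoStateModel(k_lh=0.011, k_hl=0.050, seed=200 + seed,
                                  sigma_e_low=0.02, sigma_e_high=0.02,
                                  bg_donor=0, bg_acceptor=0, sigma_channel=0)
            seqs = []
            for traj, _ in simulate_ensemble(model, 200):
                trace = compute_fret(traj, min_total=10)
                seqs.append(assign_states(trace, threshold=0.67))
            table = extract_dwells(seqs)
            k_lh = fit_dwell_rate(table, "low->high", method="occupancy").rate
            k_hl = fit_dwell_rate(table, "high->low", method="occupancy").rate
            errs_lh.append(abs(k_lh - 0.011) / 0.011)
            errs_hl.append(abs(k_hl - 0.050) / 0.050)
        assert np.median(errs_lh) <= 0.20
        assert np.median(errs_hl) <= 0.20


class TestEnergetics:
    def test_symmetric_cases_zero_dg(self):
        e = folding_energetics(fractions=(50.0, 50.0))
        assert e.dg_fractions_kJ_mol == pytest.approx(0.0)
        e = folding_energetics(rates=(0.02, 0.02))
        assert e.dg_rates_kJ_mol == pytest.approx(0.0)
        assert e.k_eq_rates == pytest.approx(1.0)

    def test_hand_value_63_37(self):
        """37/63 at 293.15 K: dG = -RT ln(63/37) = -1.30 kJ/mol."""
        e = folding_energetics(fractions=(37.0, 63.0), temperature_K=293.15)
        assert e.dg_fractions_kJ_mol == pytest.approx(-1.30, abs=0.005)

    def test_degenerate_fraction_infinite_dg(self):
        e = folding_energetics(fractions=(0.0, 100.0))
        assert np.isinf(e.dg_fractions_kJ_mol)

    def test_consistency_ratio(self):
        e = folding_energetics(fractions=(50.0, 50.0), rates=(0.02, 0.01))
        assert e.consistency_ratio == pytest.approx(2.0)
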