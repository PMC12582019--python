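"""End-to-end analysis workflows.

``run_smfret_workflow`` chains trace processing -> population histogram ->
Gaussian decomposition -> state assignment -> dwell extraction -> rate
estimation -> equilibrium energetics, and returns one structured report.
``run_cd_workflow`` bundles topology classification, exponential kinetic
fits and melting fits. Both are deterministic given a seed and a config.
"""

from __future__ import annotations

import logging

import numpy as np

from . import kinetics, populations, traces
from .cd import CDKineticTrace, CDSpectrum, MeltingCurve, classify_topology, fit_exponential, fit_melting
from .io import AnalysisConfig
from .simulate import TwoStateModel, simulate_ensemble
from .traces import IntensityTrajectory

__all__ = ["run_smfret_workflow", "run_cd_workflow", "process_trajectories"]

logger = logging.getLogger(__name__)


def _stage(name):
    """Re-raise stage failures with the stage name attached."""
    import contextlib

    @contextlib.contextmanager
    def cm():
        try:
            yield
        except Exception as exc:
            raise RuntimeError(f"smFRET workflow failed at stage '{name}': {exc}") from exc

    return cm()


def process_trajectories(
    trajectories: list[IntensityTrajectory],
    config: AnalysisConfig,
    bg_donor: float | None = None,
    bg_acceptor: float | None = None,
) -> tuple[list[traces.FretTrace], dict]:
    """Background-correct, bleach-truncate and convert to FRET traces.

    Backgrounds default to post-donor-bleach channel medians pooled over
    molecules whose donor bleaches; zero if none do.
    """
    bleach = {t.molecule_id: traces.detect_photobleach(t, step_sigma=config.bleach_step_sigma)
              for t in trajectories}
    if bg_donor is None or bg_acceptor is None:
        est_d, est_a = [], []
        for t in trajectories:
            _, d_frame = bleach[t.molecule_id]
            if d_frame is not None and d_frame < t.n_frames - 1:
                d, a = traces.estimate_background_post_bleach(t, d_frame)
                est_d.append(d)
                est_a.append(a)
        bg_donor = float(np.median(est_d)) if est_d else 0.0 if bg_donor is None else bg_donor
        bg_acceptor = float(np.median(est_a)) if est_a else 0.0 if bg_acceptor is None else bg_acceptor
        logger.info("estimated backgrounds: donor %.1f, acceptor %.1f (from %d bleached molecules)",
                    bg_donor, bg_acceptor, len(est_d))

    corrected = [traces.background_correct(t, bg_donor, bg_acceptor) for t in trajectories]
    median_total = float(np.median(np.concatenate([t.total for t in corrected])))
    min_total = config.min_total_frac * median_total

    fret_traces = []
    for t in corrected:
        a_frame, d_frame = bleach[t.molecule_id]
        cand = [f for f in (a_frame, d_frame) if f is not None]
        valid_until = min(cand) if cand else t.n_frames
        if valid_until == 0:
            continue
        try:
            fret_traces.append(traces.compute_fret(t, min_total, valid_until=valid_until))
        except ValueError:
            logger.info("%s dropped: no frames above intensity threshold", t.molecule_id)
    info = {
        "bg_donor": bg_donor,
        "bg_acceptor": bg_acceptor,
        "min_total": min_total,
        "n_input": len(trajectories),
        "n_traces": len(fret_traces),
    }
    return fret_traces, info


def run_smfret_workflow(
    trajectories: list[IntensityTrajectory] | None = None,
    model: TwoStateModel | None = None,
    n_molecules: int | None = None,
    config: AnalysisConfig | None = None,
    bg_donor: float | None = None,
    bg_acceptor: float | None = None,
) -> dict:
    """Full smFRET analysis from raw trajectories (or a simulation spec).

    Returns a nested report: processing stats, histogram summary, mixture
    fit with percent populations, dwell/rate estimates for both
    transitions (all three estimators where computable, the configured
    one as headline) and folding energetics.
    """
    config = config or AnalysisConfig()
    if trajectories is None:
        if model is None or n_molecules is None:
            raise ValueError("give trajectories, or a model plus n_molecules")
        with _stage("simulate"):
            trajectories = [traj for traj, _ in simulate_ensemble(model, n_molecules)]
        if bg_donor is None:
            bg_donor, bg_acceptor = model.bg_donor, model.bg_acceptor

    with _stage("trace_processing"):
        fret_traces, proc_info = process_trajectories(
            trajectories, config, bg_donor=bg_donor, bg_acceptor=bg_acceptor
        )

    with _stage("histogram"):
        values = [traces.molecule_fret_value(t, config.first_frames) for t in fret_traces]
        values = [v for v in values if v is not None]
        hist = traces.build_histogram(values, bin_width=config.bin_width, range_=config.hist_range)

    with _stage("population_fit"):
        if config.components == "auto":
            n_comp = populations.select_n_components(hist, alpha=config.f_test_alpha)
        else:
            n_comp = int(config.components)
        mixture = populations.fit_gaussian_mixture(hist, n_comp)

    report: dict = {
        "processing": proc_info,
        "histogram": {"n_molecules": hist.n_molecules, "bin_width": hist.bin_width},
        "populations": {
            "n_components": mixture.n_components,
            "means": mixture.means.tolist(),
            "sds": mixture.sds.tolist(),
            "fractions_percent": mixture.fractions.tolist(),
            "converged": mixture.converged,
        },
    }

    if n_comp == 2:
        with _stage("dwell_kinetics"):
            seqs = []
            for t in fret_traces:
                try:
                    seqs.append(kinetics.assign_states(t, mixture, median_filter=config.median_filter))
                except ValueError:
                    continue
            table = kinetics.extract_dwells(seqs)
            rates: dict = {}
            for transition in ("low->high", "high->low"):
                rates[transition] = {}
                for method in ("occupancy", "histogram", "mle"):
                    try:
                        est = kinetics.fit_dwell_rate(
                            table,
                            transition,
                            method=method,
                            bin_width_s=config.dwell_bin_frames * table.frame_interval,
                            min_dwells=config.min_dwells,
                        )
                        rates[transition][method] = {
                            "rate_per_s": est.rate,
                            "se_per_s": est.uncertainty,
                            "n_dwells": est.n_dwells,
                        }
                    except ValueError as exc:
                        rates[transition][method] = {"error": str(exc)}
            report["dwells"] = {
                "n_molecules": len(seqs),
                "n_dwells_total": len(table.table),
                "threshold": seqs[0].threshold if seqs else None,
            }
            report["rates"] = rates
            report["rate_method"] = config.rate_method

            headline = {
                tr: rates[tr][config.rate_method].get("rate_per_s") for tr in rates
            }
            if all(v is not None for v in headline.values()):
                energetics = kinetics.folding_energetics(
                    fractions=(mixture.fractions[0], mixture.fractions[1]),
                    rates=(headline["low->high"], headline["high->low"]),
                    temperature_K=config.temperature_K,
                )
                report["energetics"] = {
                    "k_eq_fractions": energetics.k_eq_fractions,
                    "k_eq_rates": energetics.k_eq_rates,
                    "dG_fractions_kJ_mol": energetics.dg_fractions_kJ_mol,
                    "dG_rates_kJ_mol": energetics.dg_rates_kJ_mol,
                    "consistency_ratio": energetics.consistency_ratio,
                    "temperature_K": config.temperature_K,
                }
    return report


def run_cd_workflow(
    spectrum: CDSpectrum | None = None,
    kinetic_traces: list[CDKineticTrace] | None = None,
    melting_curves: list[MeltingCurve] | None = None,
    config: AnalysisConfig | None = None,
) -> dict:
    """CD analysis bundle: topology, folding kinetics, thermal stability.

    When two melting curves are given (e.g. without and with a
    stabilizing ligand) the report includes their midpoint difference
    delta_tm_C = tm[1] - tm[0].
    """
    config = config or AnalysisConfig()
    if spectrum is None and not kinetic_traces and not melting_curves:
        raise ValueError("give at least one of: spectrum, kinetic_traces, melting_curves")
    report: dict = {}
    if spectrum is not None:
        call = classify_topology(spectrum, window_points=config.sg_window)
        report["topology"] = {
            "label": call.label,
            "extrema_nm_mdeg": call.extrema,
            "ratio_295_265": call.ratio_295_265,
        }
    if kinetic_traces:
        fits = []
        for trace in kinetic_traces:
            fit = fit_exponential(trace, alpha=config.f_test_alpha)
            entry = {
                "wavelength_nm": trace.wavelength_nm,
                "model": fit.model,
                "a": fit.a,
                f"b_per_{fit.time_unit}": fit.b,
            }
            if fit.model == "bi":
                entry["c"] = fit.c
                entry[f"d_per_{fit.time_unit}"] = fit.d
            fits.append(entry)
        report["kinetics"] = fits
    if melting_curves:
        melts = []
        for curve in melting_curves:
            fit = fit_melting(curve)
            melts.append({"tm_C": fit.tm, "width_C": fit.width, "tm_se_C": fit.tm_se,
                          "converged": fit.converged})
        report["melting"] = melts
        if len(melts) == 2:
            report["delta_tm_C"] = melts[1]["tm_C"] - melts[0]["tm_C"]
    return report
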