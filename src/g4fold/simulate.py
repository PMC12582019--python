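"""Synthetic-data generators for every measurement the pipeline consumes.

All generators retain ground truth so downstream estimators can be tested
by parameter recovery: two-state Markov FRET trajectories with single-step
photobleaching, per-molecule Gaussian FRET populations, mono/bi-exponential
CD folding kinetics, Boltzmann melting curves, single-site binding
titrations with ligand depletion, and rule-based G4 CD topology spectra.

Every generator takes an integer seed (or an explicit ``numpy`` Generator)
and is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .binding import TitrationSeries, fraction_bound
from .cd import (
    CDKineticTrace,
    CDSpectrum,
    MeltingCurve,
    bi_exponential,
    boltzmann_sigmoid,
    mono_exponential,
)
from .traces import IntensityTrajectory

__all__ = [
    "TwoStateModel",
    "GroundTruth",
    "CDKineticTrace",
    "MeltingCurve",
    "TitrationSeries",
    "CDSpectrum",
    "simulate_two_state_trajectory",
    "simulate_ensemble",
    "simulate_fret_population",
    "simulate_cd_kinetic_trace",
    "simulate_melting_curve",
    "simulate_titration",
    "simulate_cd_spectrum",
    "TOPOLOGY_BANDS",
]


class TwoStateModel(BaseModel):
    """Ground-truth parameters of a two-state (compacted/folded) FRET system.

    The folded G-quadruplex is the high-FRET state; the unfolded or
    compacted conformer is the low-FRET state. Transitions follow a
    continuous-time two-state Markov process sampled at the camera frame
    interval, so the per-frame switching probability is 1 - exp(-k*dt).

    Parameters
    ----------
    e_low, e_high
        Mean apparent FRET efficiency of the low/high state (0-1).
    sigma_e_low, sigma_e_high
        Per-frame FRET noise SD within each state.
    k_lh, k_hl
        Low-to-high (folding) and high-to-low (unfolding) rates, 1/s.
    i_total
        Mean total photon counts per frame shared between the channels.
    sigma_channel
        Additive Gaussian read-noise SD per channel, counts.
    bg_donor, bg_acceptor
        Background count means added to each channel.
    frame_interval
        Camera integration time, s (100 or 300 ms in typical experiments).
    n_frames
        Frames per molecule.
    tau_bleach_acceptor, tau_bleach_donor
        Exponential photobleach lifetimes, s; ``inf`` disables bleaching.
    p_init_high
        Probability that a molecule starts in the high state. Defaults to
        the stationary occupancy k_lh/(k_lh+k_hl); exposed because samples
        refolded in situ can start far from equilibrium.
    seed
        Seed of the ensemble random stream.
    """

    e_low: float = 0.49
    e_high: float = 0.85
    sigma_e_low: float = 0.05
    sigma_e_high: float = 0.05
    k_lh: float = Field(0.011, description="low->high folding rate, 1/s")
    k_hl: float = Field(0.050, description="high->low unfolding rate, 1/s")
    i_total: float = 1000.0
    sigma_channel: float = 20.0
    bg_donor: float = 50.0
    bg_acceptor: float = 50.0
    frame_interval: float = 0.3
    n_frames: int = 300
    tau_bleach_acceptor: float = math.inf
    tau_bleach_donor: float = math.inf
    p_init_high: float | None = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "TwoStateModel":
        if not self.k_lh > 0:
            raise ValueError("k_lh must be > 0")
        if not self.k_hl > 0:
            raise ValueError("k_hl must be > 0")
        if not (0.0 <= self.e_low < self.e_high <= 1.0):
            raise ValueError("require 0 <= e_low < e_high <= 1")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.sigma_e_low < 0 or self.sigma_e_high < 0:
            raise ValueError("sigma_e_low/sigma_e_high must be >= 0")
        if self.sigma_channel < 0:
            raise ValueError("sigma_channel must be >= 0")
        if self.tau_bleach_acceptor <= 0 or self.tau_bleach_donor <= 0:
            raise ValueError("bleach lifetimes must be > 0 (use inf to disable)")
        if self.p_init_high is not None and not (0.0 <= self.p_init_high <= 1.0):
            raise ValueError("p_init_high must be in [0, 1]")
        return self

    @property
    def stationary_p_high(self) -> float:
        """Equilibrium occupancy of the high-FRET state, k_lh/(k_lh+k_hl)."""
        return self.k_lh / (self.k_lh + self.k_hl)

    @property
    def initial_p_high(self) -> float:
        return self.stationary_p_high if self.p_init_high is None else self.p_init_high


@dataclass
class GroundTruth:
    """Per-molecule truth retained by the simulator for recovery tests."""

    molecule_id: str
    state_path: np.ndarray  # 0 = low, 1 = high, length n_frames
    acceptor_bleach_frame: int | None
    donor_bleach_frame: int | None
    model: TwoStateModel


def _sample_state_path(model: TwoStateModel, rng: np.random.Generator) -> np.ndarray:
    dt = model.frame_interval
    p_lh = 1.0 - math.exp(-model.k_lh * dt)
    p_hl = 1.0 - math.exp(-model.k_hl * dt)
    u = rng.random(model.n_frames)
    path = np.empty(model.n_frames, dtype=np.int8)
    path[0] = 1 if u[0] < model.initial_p_high else 0
    # sequential dependence; loop is fine at desk scale
    for i in range(1, model.n_frames):
        if path[i - 1] == 0:
            path[i] = 1 if u[i] < p_lh else 0
        else:
            path[i] = 0 if u[i] < p_hl else 1
    return path


def _sample_bleach_frame(tau: float, model: TwoStateModel, rng: np.random.Generator) -> int | None:
    """Frame index at which the fluorophore goes dark, or None if it survives."""
    if math.isinf(tau):
        # keep the stream aligned whether or not bleaching is enabled
        rng.exponential(1.0)
        return None
    t = rng.exponential(tau)
    frame = int(t // model.frame_interval)
    return frame if frame < model.n_frames else None


def simulate_two_state_trajectory(
    model: TwoStateModel,
    molecule_id: str = "mol_0",
    rng: np.random.Generator | None = None,
) -> tuple[IntensityTrajectory, GroundTruth]:
    """Simulate one donor/acceptor intensity trajectory.

    Per frame, the apparent FRET efficiency is the state mean plus state
    noise; the donor receives (1-E)*i_total and the acceptor E*i_total on
    top of their backgrounds, plus channel read noise. Acceptor bleaching
    is the classic anticorrelated step: the acceptor collapses to
    background and the donor gains the full i_total. Donor bleaching
    collapses both channels to background.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    path = _sample_state_path(model, rng)
    a_bleach = _sample_bleach_frame(model.tau_bleach_acceptor, model, rng)
    d_bleach = _sample_bleach_frame(model.tau_bleach_donor, model, rng)

    n = model.n_frames
    e_mean = np.where(path == 1, model.e_high, model.e_low)
    e_sd = np.where(path == 1, model.sigma_e_high, model.sigma_e_low)
    e = e_mean + e_sd * rng.standard_normal(n)

    donor = model.bg_donor + (1.0 - e) * model.i_total
    acceptor = model.bg_acceptor + e * model.i_total

    if a_bleach is not None:
        donor[a_bleach:] = model.bg_donor + model.i_total
        acceptor[a_bleach:] = model.bg_acceptor
    if d_bleach is not None:
        donor[d_bleach:] = model.bg_donor
        acceptor[d_bleach:] = model.bg_acceptor
        if a_bleach is not None and a_bleach > d_bleach:
            a_bleach = None  # acceptor step can no longer be observed

    donor = donor + model.sigma_channel * rng.standard_normal(n)
    acceptor = acceptor + model.sigma_channel * rng.standard_normal(n)

    time = np.arange(n) * model.frame_interval
    traj = IntensityTrajectory(
        molecule_id=molecule_id,
        time=time,
        donor=donor,
        acceptor=acceptor,
        frame_interval=model.frame_interval,
    )
    truth = GroundTruth(
        molecule_id=molecule_id,
        state_path=path,
        acceptor_bleach_frame=a_bleach,
        donor_bleach_frame=d_bleach,
        model=model,
    )
    return traj, truth


def simulate_ensemble(
    model: TwoStateModel, n_molecules: int
) -> list[tuple[IntensityTrajectory, GroundTruth]]:
    """Simulate independent molecules from one seeded stream."""
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(model.seed)
    return [
        simulate_two_state_trajectory(model, molecule_id=f"mol_{i}", rng=rng)
        for i in range(n_molecules)
    ]


def simulate_fret_population(
    means: Sequence[float],
    sds: Sequence[float],
    weights: Sequence[float],
    n_molecules: int,
    seed: int = 0,
) -> np.ndarray:
    """Draw per-molecule FRET values from a 1- or 2-component Gaussian mixture.

    Emulates the one-value-per-molecule histograms built from early-frame
    FRET averages, without simulating full trajectories.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not (len(means) == len(sds) == len(weights)):
        raise ValueError("means, sds and weights must have equal length")
    if np.any(sds <= 0) or np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("sds must be > 0 and weights non-negative")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(means), size=n_molecules, p=weights / weights.sum())
    return rng.normal(means[comp], sds[comp])


def simulate_cd_kinetic_trace(
    a: float,
    b: float,
    t_grid: Sequence[float],
    c: float | None = None,
    d: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    time_unit: str = "min",
    wavelength_nm: float = 295.0,
) -> CDKineticTrace:
    """Generate a mono- or bi-exponential folding trace with Gaussian noise."""
    t = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if b <= 0:
        raise ValueError("b must be > 0")
    if (c is None) != (d is None):
        raise ValueError("c and d must be given together")
    if c is not None:
        if d is None or d <= 0:
            raise ValueError("d must be > 0 for the bi-exponential form")
        y = bi_exponential(t, a, b, c, d)
    else:
        y = mono_exponential(t, a, b)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.shape)
    return CDKineticTrace(time=t, signal=y, time_unit=time_unit, wavelength_nm=wavelength_nm)


def simulate_melting_curve(
    tm: float,
    width: float,
    theta_folded: float = 10.0,
    theta_unfolded: float = 0.0,
    t_range: tuple[float, float] = (25.0, 95.0),
    step: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MeltingCurve:
    """Generate a Boltzmann melting curve on a uniform temperature grid."""
    if width <= 0:
        raise ValueError("width must be > 0")
    lo, hi = t_range
    if lo < 0 or hi > 110 or hi <= lo:
        raise ValueError("t_range must be increasing and within [0, 110] degC")
    n = int(round((hi - lo) / step)) + 1
    temp = lo + step * np.arange(n)
    y = boltzmann_sigmoid(temp, theta_folded, theta_unfolded, tm, width)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return MeltingCurve(temperature=temp, signal=y)


def simulate_titration(
    k_d: float,
    dna_total: float = 0.02,
    top_conc: float = 200.0,
    n_points: int = 16,
    dilution_factor: float = 2.0,
    r_free: float = 850.0,
    r_bound: float = 890.0,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """Generate a serial-dilution titration from the 1:1 depletion isotherm.

    Defaults reproduce a 16-point 1:1 dilution from 200 µM with 20 nM
    labeled DNA. ``noise_frac`` is the Gaussian noise SD as a fraction of
    the response amplitude |r_bound - r_free|.
    """
    if k_d <= 0 or dna_total <= 0 or top_conc <= 0:
        raise ValueError("k_d, dna_total and top_conc must be > 0")
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must be > 1")
    conc = top_conc / dilution_factor ** np.arange(n_points)
    f = np.array([fraction_bound(p, dna_total, k_d) for p in conc])
    y = r_free + (r_bound - r_free) * f
    if noise_frac > 0:
        amp = abs(r_bound - r_free)
        y = y + np.random.default_rng(seed).normal(0.0, noise_frac * amp, size=n_points)
    return TitrationSeries(ligand_total=conc, response=y, dna_total=dna_total)


# Gaussian band positions (nm), signs and relative amplitudes realizing the
# canonical G4 CD signatures: parallel +~264/-240; antiparallel +295/+240/-260;
# hybrid shows both positive ~264 and ~290 bands.
TOPOLOGY_BANDS: dict[str, list[tuple[float, float, float]]] = {
    "parallel": [(264.0, 1.0, 9.0), (240.0, -0.55, 7.0)],
    "antiparallel": [(295.0, 1.0, 9.0), (240.0, 0.6, 7.0), (260.0, -0.5, 8.0)],
    "hybrid": [(264.0, 0.9, 8.0), (290.0, 0.8, 8.0), (240.0, -0.45, 7.0)],
}


def simulate_cd_spectrum(
    topology_label: Literal["parallel", "antiparallel", "hybrid"],
    amplitude: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    wavelength: np.ndarray | None = None,
) -> CDSpectrum:
    """Generate a synthetic G4 CD spectrum as a sum of Gaussian bands."""
    if topology_label not in TOPOLOGY_BANDS:
        raise ValueError(
            f"unknown topology {topology_label!r}; expected one of {sorted(TOPOLOGY_BANDS)}"
        )
    if wavelength is None:
        wavelength = np.arange(200.0, 320.5, 0.5)
    wl = np.asarray(wavelength, dtype=float)
    y = np.zeros_like(wl)
    for center, rel_amp, sd in TOPOLOGY_BANDS[topology_label]:
        y += amplitude * rel_amp * np.exp(-0.5 * ((wl - center) / sd) ** 2)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=wl.shape)
    return CDSpectrum(wavelength=wl, signal=y)
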