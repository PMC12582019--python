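"""Per-frame intensity trajectories -> FRET traces and per-molecule values.

Implements the standard smFRET preprocessing chain: background
subtraction, apparent FRET efficiency E = I_A/(I_A + I_D), single-step
photobleach detection with truncation, early-frame per-molecule FRET
averaging and histogram construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "IntensityTrajectory",
    "FretTrace",
    "FretHistogram",
    "background_correct",
    "estimate_background_post_bleach",
    "compute_fret",
    "detect_photobleach",
    "molecule_fret_value",
    "build_histogram",
]

logger = logging.getLogger(__name__)

_TIME_TOL = 1e-6


@dataclass
class IntensityTrajectory:
    """Donor/acceptor counts per frame for one immobilized molecule."""

    molecule_id: str
    time: np.ndarray  # s, uniform spacing
    donor: np.ndarray  # counts
    acceptor: np.ndarray  # counts
    frame_interval: float  # s

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        n = len(self.time)
        if len(self.donor) != n or len(self.acceptor) != n:
            raise ValueError("time, donor and acceptor must have equal length")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.max(np.abs(dt - self.frame_interval)) > _TIME_TOL:
                raise ValueError("time spacing must equal frame_interval")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor


@dataclass
class FretTrace:
    """Apparent per-frame FRET efficiency with a validity horizon.

    ``efficiency`` is NaN on frames whose background-corrected total
    intensity fell below the validity threshold; ``valid_until`` is the
    index of the first frame NOT analyzable (photobleach or trace end),
    so frames [0, valid_until) are the analysis window.
    """

    molecule_id: str
    time: np.ndarray
    efficiency: np.ndarray
    valid_until: int
    frame_interval: float

    def __post_init__(self) -> None:
        if not (0 <= self.valid_until <= len(self.time)):
            raise ValueError("valid_until out of range")

    def valid_efficiencies(self) -> np.ndarray:
        e = self.efficiency[: self.valid_until]
        return e[np.isfinite(e)]


@dataclass
class FretHistogram:
    """Histogram of one-value-per-molecule FRET efficiencies."""

    bin_edges: np.ndarray
    counts: np.ndarray
    per_molecule_values: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_molecules(self) -> int:
        return len(self.per_molecule_values)


def background_correct(
    traj: IntensityTrajectory, bg_donor: float, bg_acceptor: float
) -> IntensityTrajectory:
    """Subtract constant backgrounds channel-wise.

    Negative corrected counts are permitted (read noise around zero);
    clipping them would bias downstream Gaussian fits. A background above
    the 95th percentile of its channel almost certainly means the wrong
    constant was supplied, and is logged as a warning.
    """
    if not (np.isfinite(bg_donor) and np.isfinite(bg_acceptor)):
        raise ValueError("backgrounds must be finite")
    for name, bg, chan in (
        ("donor", bg_donor, traj.donor),
        ("acceptor", bg_acceptor, traj.acceptor),
    ):
        if bg > np.percentile(chan, 95):
            logger.warning(
                "%s: %s background %.1f exceeds the channel 95th percentile",
                traj.molecule_id, name, bg,
            )
    return replace(traj, donor=traj.donor - bg_donor, acceptor=traj.acceptor - bg_acceptor)


def estimate_background_post_bleach(
    traj: IntensityTrajectory, donor_bleach_frame: int
) -> tuple[float, float]:
    """Estimate per-channel backgrounds as post-donor-bleach medians."""
    if donor_bleach_frame >= traj.n_frames - 1:
        raise ValueError("no post-bleach frames to estimate background from")
    return (
        float(np.median(traj.donor[donor_bleach_frame + 1 :])),
        float(np.median(traj.acceptor[donor_bleach_frame + 1 :])),
    )


def compute_fret(
    traj: IntensityTrajectory,
    min_total: float,
    valid_until: int | None = None,
) -> FretTrace:
    """Apparent FRET efficiency E = I_A / (I_A + I_D) per frame.

    ``traj`` should already be background-corrected. Frames whose total
    intensity is below ``min_total`` are marked invalid (NaN).
    """
    total = traj.total
    ok = total >= min_total
    if not np.any(ok):
        raise ValueError(f"{traj.molecule_id}: all frames below min_total={min_total}")
    e = np.full(traj.n_frames, np.nan)
    e[ok] = traj.acceptor[ok] / total[ok]
    if valid_until is None:
        valid_until = traj.n_frames
    return FretTrace(
        molecule_id=traj.molecule_id,
        time=traj.time,
        efficiency=e,
        valid_until=valid_until,
        frame_interval=traj.frame_interval,
    )


def _robust_step_sd(x: np.ndarray) -> float:
    """Frame-to-frame noise SD from the MAD of first differences."""
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    # 1.4826 converts MAD to SD; differences carry sqrt(2) of the per-frame noise
    return float(max(1.4826 * mad / np.sqrt(2.0), 1e-12))


def detect_photobleach(
    traj: IntensityTrajectory,
    step_sigma: float = 5.0,
    anticorrelation_frac: float = 0.5,
    collapse_frac: float = 0.25,
) -> tuple[int | None, int | None]:
    """Locate single-step acceptor and/or donor photobleaching.

    Acceptor (Cy5) bleaching is the anticorrelated step: the largest
    single-frame acceptor drop exceeding ``step_sigma`` times the robust
    frame noise, accompanied within +/-1 frame by a donor rise of at least
    ``anticorrelation_frac`` of its magnitude, after which the acceptor
    stays collapsed near background (below ``collapse_frac`` of its
    pre-step median). The collapse condition separates bleaching from
    high-to-low conformational transitions, which show the same
    anticorrelated step but leave the acceptor at the low-state level.

    Donor (Cy3) bleaching collapses the total intensity: the largest
    single-frame total drop exceeding the threshold after which the mean
    total stays below ``collapse_frac`` of its pre-step median.

    Returns (acceptor_bleach_frame, donor_bleach_frame), each the index of
    the first dark frame or None.
    """
    if traj.n_frames < 10:
        raise ValueError("photobleach detection needs at least 10 frames")

    total = traj.total
    donor_bleach: int | None = None
    sd_tot = _robust_step_sd(total)
    d_tot = np.diff(total)
    candidates = np.flatnonzero(-d_tot > step_sigma * sd_tot)
    if candidates.size:
        # deepest qualifying collapse wins
        for i in candidates[np.argsort(d_tot[candidates])]:
            pre = np.median(total[: i + 1])
            post = float(np.mean(total[i + 1 :]))
            if pre > 0 and post < collapse_frac * pre:
                donor_bleach = int(i + 1)
                break

    horizon = donor_bleach if donor_bleach is not None else traj.n_frames
    acc = traj.acceptor[:horizon]
    don = traj.donor[:horizon]
    acceptor_bleach: int | None = None
    if len(acc) >= 3:
        sd_a = _robust_step_sd(acc)
        d_acc = np.diff(acc)
        drops = np.flatnonzero(-d_acc > step_sigma * sd_a)
        if drops.size:
            d_don = np.diff(don)
            for i in drops[np.argsort(d_acc[drops])]:
                lo, hi = max(i - 1, 0), min(i + 2, len(d_don))
                rise = np.max(d_don[lo:hi]) if hi > lo else -np.inf
                if rise < anticorrelation_frac * (-d_acc[i]):
                    continue
                pre = float(np.median(acc[: i + 1]))
                post = float(np.median(acc[i + 1 :])) if i + 1 < len(acc) else 0.0
                if pre > 0 and post < collapse_frac * pre:
                    acceptor_bleach = int(i + 1)
                    break
    return acceptor_bleach, donor_bleach


def molecule_fret_value(trace: FretTrace, n_first_frames: int = 15) -> float | None:
    """Mean apparent FRET of the first ``n_first_frames`` valid frames.

    Population histograms are built from early-frame averages so that
    molecules bleaching later do not weight the histogram unevenly.
    Returns None (exclusion, logged) when fewer valid frames are
    available.
    """
    e = trace.valid_efficiencies()
    if len(e) < n_first_frames:
        logger.info(
            "%s excluded from histogram: %d valid frames < %d required",
            trace.molecule_id, len(e), n_first_frames,
        )
        return None
    return float(np.mean(e[:n_first_frames]))


def build_histogram(
    values,
    bin_width: float = 0.02,
    range_: tuple[float, float] = (-0.1, 1.1),
) -> FretHistogram:
    """Bin per-molecule FRET values on a fixed E-axis grid.

    The range extends beyond [0, 1] so noise tails remain visible; counts
    always conserve the number of molecules (values outside the range are
    clipped into the edge bins rather than dropped).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError(
            f"only {len(values)} molecules; at least 10 are needed for a histogram"
        )
    lo, hi = range_
    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-9))
    edges = lo + bin_width * np.arange(n_bins + 1)
    clipped = np.clip(values, lo, np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    return FretHistogram(bin_edges=edges, counts=counts, per_molecule_values=values)
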