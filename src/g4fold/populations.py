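"""Gaussian decomposition of per-molecule FRET histograms.

A one- or two-Gaussian model is fitted to the histogram counts by least
squares (as population histograms are conventionally analyzed), and the
relative contribution of each population is reported as its percent area,
a_i*sigma_i / sum_j a_j*sigma_j * 100. A value-space maximum-likelihood
mixture fit (scikit-learn) is kept as an independent cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from lmfit.models import GaussianModel
from scipy import stats
from scipy.signal import find_peaks

from .traces import FretHistogram

__all__ = [
    "GaussianMixtureFit",
    "fit_gaussian_mixture",
    "select_n_components",
    "population_shift",
    "PopulationShift",
    "fit_value_mixture",
]

logger = logging.getLogger(__name__)


@dataclass
class GaussianMixtureFit:
    """Result of a 1- or 2-Gaussian histogram fit.

    ``fractions`` are percent areas summing to 100; components are sorted
    by ascending mean.
    """

    n_components: int
    means: np.ndarray
    sds: np.ndarray
    amplitudes: np.ndarray  # peak heights in count units
    fractions: np.ndarray  # percent area per component
    residual_norm: float
    converged: bool
    rss: float = field(default=np.nan)
    n_points: int = field(default=0)
    n_params: int = field(default=0)

    def __post_init__(self) -> None:
        order = np.argsort(self.means)
        for name in ("means", "sds", "amplitudes", "fractions"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float)[order])
        if self.converged and abs(self.fractions.sum() - 100.0) > 1e-6:
            raise ValueError("fractions must sum to 100")


def _peak_init(hist: FretHistogram, n_components: int) -> list[tuple[float, float, float]]:
    """Peak-based initialization: the largest well-separated local maxima
    of the lightly smoothed histogram (smoothing stops single noisy bins
    from outranking a genuine minority mode)."""
    x, y = hist.bin_centers, hist.counts.astype(float)
    ys = np.convolve(y, np.ones(3) / 3.0, mode="same")
    min_sep = max(3, int(0.15 / hist.bin_width))
    peaks, props = find_peaks(ys, distance=min_sep, height=0.5)
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(ys))])
        props = {"peak_heights": ys[peaks]}
    order = np.argsort(props["peak_heights"])[::-1]
    chosen = list(peaks[order[:n_components]])
    while len(chosen) < n_components:
        # fall back: split around the global mode
        chosen.append(int(np.clip(chosen[-1] + min_sep, 0, len(x) - 1)))
    sigma0 = max(4 * hist.bin_width, 0.03)
    return [(float(x[i]), sigma0, float(max(y[i], 1.0))) for i in sorted(chosen)]


def _quantile_init(hist: FretHistogram, n_components: int) -> list[tuple[float, float, float]]:
    """Quantile-based initialization from the raw per-molecule values."""
    v = np.asarray(hist.per_molecule_values, dtype=float)
    qs = np.linspace(0, 1, 2 * n_components + 1)[1::2]  # 0.5 or 0.25/0.75
    centers = np.quantile(v, qs)
    sigma0 = max(float(np.std(v)) / (2 * n_components - 1), hist.bin_width)
    height0 = max(float(hist.counts.max()) / n_components, 1.0)
    return [(float(c), sigma0, height0) for c in centers]


def fit_gaussian_mixture(
    hist: FretHistogram,
    n_components: int,
    init: list[tuple[float, float, float]] | None = None,
) -> GaussianMixtureFit:
    """Least-squares fit of a sum of Gaussians to histogram counts.

    ``init`` optionally supplies (mean, sd, height) triples; otherwise the
    fit is multi-started deterministically from peak-based and
    quantile-based guesses and the lowest-residual solution kept (local
    optima that park both components on one mode are common for minority
    populations). Component SDs are bounded below by half the bin width
    to avoid degenerate spikes.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    occupied = int(np.count_nonzero(hist.counts))
    if occupied < 5:
        raise ValueError(f"histogram has {occupied} occupied bins; at least 5 required")

    if init is not None:
        if len(init) != n_components:
            raise ValueError("init must provide one (mean, sd, height) per component")
        starts = [init]
    else:
        starts = [_peak_init(hist, n_components), _quantile_init(hist, n_components)]

    best: GaussianMixtureFit | None = None
    for start in starts:
        fit = _fit_once(hist, n_components, start)
        if best is None or (fit.converged, -fit.rss) > (best.converged, -best.rss):
            best = fit
    assert best is not None
    if not best.converged:
        logger.warning("gaussian mixture fit did not converge")
    return best


def _fit_once(
    hist: FretHistogram,
    n_components: int,
    init: list[tuple[float, float, float]],
) -> GaussianMixtureFit:
    x, y = hist.bin_centers, hist.counts.astype(float)
    model = None
    params = None
    sigma_floor = hist.bin_width / 2.0
    for i, (mu0, sd0, height0) in enumerate(init):
        g = GaussianModel(prefix=f"g{i}_")
        p = g.make_params()
        p[f"g{i}_center"].set(value=mu0, min=x[0], max=x[-1])
        p[f"g{i}_sigma"].set(value=max(sd0, sigma_floor), min=sigma_floor, max=(x[-1] - x[0]))
        # lmfit's gaussian amplitude is the area; area = height * sigma * sqrt(2*pi)
        p[f"g{i}_amplitude"].set(value=height0 * sd0 * np.sqrt(2 * np.pi), min=0.0)
        model = g if model is None else model + g
        params = p if params is None else params.update(p) or params

    result = model.fit(y, params, x=x)
    means = np.array([result.params[f"g{i}_center"].value for i in range(n_components)])
    sds = np.array([result.params[f"g{i}_sigma"].value for i in range(n_components)])
    areas = np.array([result.params[f"g{i}_amplitude"].value for i in range(n_components)])
    heights = areas / (sds * np.sqrt(2 * np.pi))
    total_area = areas.sum()
    if total_area <= 0:
        fractions = np.full(n_components, 100.0 / n_components)
        converged = False
    else:
        fractions = 100.0 * areas / total_area
        converged = bool(result.success)
    rss = float(np.sum(result.residual**2))
    return GaussianMixtureFit(
        n_components=n_components,
        means=means,
        sds=sds,
        amplitudes=heights,
        fractions=fractions,
        residual_norm=float(np.sqrt(rss)),
        converged=converged,
        rss=rss,
        n_points=len(x),
        n_params=3 * n_components,
    )


def select_n_components(
    hist: FretHistogram, alpha: float = 0.01, min_fraction: float = 5.0
) -> int:
    """Choose 1 vs 2 components by a nested-model F-test.

    Two components are reported only when the extra-parameter F-test is
    significant at ``alpha`` AND the fitted means are separated by more
    than the wider component SD AND both populations carry at least
    ``min_fraction`` percent of the area (small enough to keep genuine
    minority populations, such as a few-percent folded state). The last two guards reject the
    degenerate solutions overlapping Gaussians admit (a narrow spike on
    one noisy bin, or two components sharing one peak).
    """
    fit1 = fit_gaussian_mixture(hist, 1)
    try:
        fit2 = fit_gaussian_mixture(hist, 2)
    except ValueError:
        return 1
    if not fit2.converged:
        return 1
    df1 = fit1.n_points - fit1.n_params
    df2 = fit2.n_points - fit2.n_params
    if df2 <= 0 or fit2.rss <= 0:
        return 1
    f = ((fit1.rss - fit2.rss) / (df1 - df2)) / (fit2.rss / df2)
    p = stats.f.sf(f, df1 - df2, df2)
    separated = abs(fit2.means[1] - fit2.means[0]) > max(fit2.sds)
    substantial = bool(np.min(fit2.fractions) >= min_fraction)
    return 2 if (p < alpha and separated and substantial) else 1


@dataclass
class PopulationShift:
    """Component-matched change between two mixture fits."""

    fraction_delta: np.ndarray  # percent points, after - before
    mean_shift: np.ndarray  # E units, after - before
    matched: list[tuple[int, int]]
    landscape_change: bool  # component counts differ


def population_shift(
    fit_before: GaussianMixtureFit, fit_after: GaussianMixtureFit
) -> PopulationShift:
    """Per-component fraction and mean changes, matching by nearest mean.

    A component-count mismatch is reported as a refolded landscape rather
    than raised, because appearing/vanishing populations are a real
    observation, not an analysis failure.
    """
    if not (fit_before.converged and fit_after.converged):
        raise ValueError("both fits must have converged")
    if fit_before.n_components != fit_after.n_components:
        return PopulationShift(
            fraction_delta=np.array([]),
            mean_shift=np.array([]),
            matched=[],
            landscape_change=True,
        )
    n = fit_before.n_components
    used: set[int] = set()
    matched: list[tuple[int, int]] = []
    for i in range(n):
        dists = [
            (abs(fit_after.means[j] - fit_before.means[i]), j)
            for j in range(n)
            if j not in used
        ]
        # ties break toward preserving component order (lower j first)
        _, j = min(dists)
        used.add(j)
        matched.append((i, j))
    fraction_delta = np.array(
        [fit_after.fractions[j] - fit_before.fractions[i] for i, j in matched]
    )
    mean_shift = np.array([fit_after.means[j] - fit_before.means[i] for i, j in matched])
    return PopulationShift(
        fraction_delta=fraction_delta,
        mean_shift=mean_shift,
        matched=matched,
        landscape_change=False,
    )


def fit_value_mixture(values, n_components: int, seed: int = 0) -> GaussianMixtureFit:
    """Maximum-likelihood Gaussian mixture on the raw per-molecule values.

    Independent cross-check for the histogram-space fit; fractions here
    are mixture weights (equal to percent areas for Gaussian components).
    """
    from sklearn.mixture import GaussianMixture

    values = np.asarray(values, dtype=float).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=n_components, covariance_type="full", n_init=5, random_state=seed
    )
    gm.fit(values)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    return GaussianMixtureFit(
        n_components=n_components,
        means=means,
        sds=sds,
        amplitudes=weights / (sds * np.sqrt(2 * np.pi)),
        fractions=100.0 * weights / weights.sum(),
        residual_norm=float("nan"),
        converged=bool(gm.converged_),
        n_points=len(values),
        n_params=3 * n_components - 1,
    )
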