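"""Burst-wise smFRET efficiencies, histograms and Gaussian decomposition.

The apparent FRET efficiency of a burst is E_app = I_A / (I_D + I_A),
the acceptor fraction of the detected photons. Histograms of E_app over
many bursts resolve conformational or binding subpopulations as peaks;
the peaks are decomposed as a sum of Gaussians and subpopulations are
selected by closed efficiency windows for downstream
subpopulation-selective FCS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import lmfit

from .exceptions import (
    DegenerateInputError,
    FitFailureError,
    InvalidArgumentError,
    UndefinedEfficiencyError,
)
from .trace import Burst

__all__ = [
    "FretHistogram",
    "GaussianPeak",
    "fret_efficiency",
    "fret_histogram",
    "choose_n_components",
    "select_by_efficiency",
    "subpopulation_fractions",
]

DEFAULT_RANGE = (-0.2, 1.2)
DEFAULT_BIN_WIDTH = 0.02


@dataclass(frozen=True)
class FretHistogram:
    """Histogram of apparent FRET efficiencies (or any scalar burst
    observable, e.g. direct-excitation acceptor counts)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if len(counts) != len(edges) - 1:
            raise InvalidArgumentError("counts must have one entry per bin")
        if np.any(np.diff(edges) <= 0):
            raise InvalidArgumentError("bin_edges must be strictly increasing")
        if counts.size and counts.min() < 0:
            raise InvalidArgumentError("counts must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def normalize(self) -> "FretHistogram":
        """Unit-area copy (density normalization)."""
        widths = np.diff(self.bin_edges)
        total = float((self.counts * widths).sum())
        if total == 0:
            raise DegenerateInputError("cannot normalize an empty histogram")
        return FretHistogram(self.bin_edges, self.counts / total, normalized=True)


@dataclass(frozen=True)
class GaussianPeak:
    """One fitted Gaussian component: amplitude * exp(-(x-mean)^2/2 sigma^2)."""

    mean: float
    sigma: float
    amplitude: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise InvalidArgumentError("sigma must be > 0")
        if self.amplitude < 0:
            raise InvalidArgumentError("amplitude must be >= 0")

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * np.sqrt(2 * np.pi)


def fret_efficiency(donor_sum: float, acceptor_sum: float) -> float:
    """Apparent FRET efficiency E_app = acceptor / (donor + acceptor).

    Raises :class:`UndefinedEfficiencyError` when the total is not
    positive (an empty burst after background correction has no defined
    efficiency).
    """
    total = donor_sum + acceptor_sum
    if total <= 0:
        raise UndefinedEfficiencyError("total photon count must be positive")
    return acceptor_sum / total


def _values_from(bursts_or_values) -> np.ndarray:
    items = list(bursts_or_values)
    if items and isinstance(items[0], Burst):
        vals = np.array([b.e_app for b in items], dtype=float)
    else:
        vals = np.asarray(items, dtype=float)
    return vals[np.isfinite(vals)]


def _multi_gaussian(x, params, n):
    y = np.zeros_like(x, dtype=float)
    for i in range(n):
        a = params[f"a{i}"]
        mu = params[f"mu{i}"]
        sig = params[f"sig{i}"]
        y = y + a * np.exp(-0.5 * ((x - mu) / sig) ** 2)
    return y


def _initial_means(centers, counts, n):
    """Seed component means at the highest local maxima of the smoothed
    histogram, falling back to count-weighted quantiles."""
    from scipy.signal import find_peaks

    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    idx, props = find_peaks(smooth, height=0)
    if len(idx) >= n:
        order = np.argsort(props["peak_heights"])[::-1][:n]
        return np.sort(centers[idx[order]])
    total = counts.sum()
    if total == 0:
        return np.linspace(centers[0], centers[-1], n + 2)[1:-1]
    cdf = np.cumsum(counts) / total
    qs = (np.arange(n) + 0.5) / n
    return np.interp(qs, cdf, centers)


def fit_gaussian_mixture(
    centers: np.ndarray,
    counts: np.ndarray,
    n_components: int,
    mean_bounds: tuple[float, float] | None = None,
) -> list[GaussianPeak]:
    """Unweighted least-squares fit of a sum of Gaussians to histogram
    counts; peaks returned sorted by mean."""
    centers = np.asarray(centers, float)
    counts = np.asarray(counts, float)
    if n_components < 1:
        raise InvalidArgumentError("n_components must be >= 1")
    span = centers[-1] - centers[0]
    lo, hi = mean_bounds if mean_bounds else (centers[0], centers[-1])
    means0 = _initial_means(centers, counts, n_components)
    amax = max(counts.max(), 1.0)
    params = lmfit.Parameters()
    for i in range(n_components):
        params.add(f"a{i}", value=0.8 * amax, min=0)
        params.add(f"mu{i}", value=float(np.clip(means0[i], lo, hi)), min=lo, max=hi)
        params.add(f"sig{i}", value=span / (6 * n_components), min=span * 1e-4, max=span)

    def residual(p):
        return _multi_gaussian(centers, p.valuesdict(), n_components) - counts

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise FitFailureError(
            f"Gaussian decomposition did not converge: {result.message}",
            best_values=dict(result.params.valuesdict()),
            residual_norm=float(np.linalg.norm(result.residual)),
        )
    v = result.params.valuesdict()
    peaks = [
        GaussianPeak(mean=v[f"mu{i}"], sigma=v[f"sig{i}"], amplitude=v[f"a{i}"])
        for i in range(n_components)
    ]
    return sorted(peaks, key=lambda p: p.mean)


def fret_histogram(
    bursts_or_values,
    bin_width_e: float = DEFAULT_BIN_WIDTH,
    n_components: int | None = None,
    hist_range: tuple[float, float] = DEFAULT_RANGE,
) -> tuple[FretHistogram, list[GaussianPeak]]:
    """Histogram burst efficiencies (or any scalar collection) and
    optionally decompose the histogram into ``n_components`` Gaussians.

    Returns ``(histogram, peaks)``; ``peaks`` is empty when
    ``n_components`` is None. Non-finite efficiencies (bursts with no
    defined E_app after correction) are dropped.
    """
    values = _values_from(bursts_or_values)
    if values.size == 0:
        raise DegenerateInputError("no finite values to histogram")
    lo, hi = hist_range
    n_bins = max(1, int(round((hi - lo) / bin_width_e)))
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    hist = FretHistogram(edges, counts)
    peaks: list[GaussianPeak] = []
    if n_components is not None:
        if np.allclose(np.std(values), 0):
            # degenerate: all mass in one bin; report it directly
            peaks = [
                GaussianPeak(mean=float(values[0]), sigma=bin_width_e / 2, amplitude=float(counts.max()))
            ]
        else:
            peaks = fit_gaussian_mixture(hist.centers, counts, n_components, mean_bounds=(lo, hi))
    return hist, peaks


def choose_n_components(
    bursts_or_values,
    max_components: int = 4,
    bin_width_e: float = DEFAULT_BIN_WIDTH,
    hist_range: tuple[float, float] = DEFAULT_RANGE,
) -> int:
    """Pick the number of Gaussian components by the Bayesian
    information criterion on the histogram residuals.

    Off by default everywhere — the component count is normally chosen
    per experiment by the analyst; this helper exists for exploratory
    use. Returns the count in [1, max_components] minimizing the
    Poisson-weighted (Pearson) chi-square plus a 3k·ln(n) complexity
    penalty over the histogram bins.
    """
    values = _values_from(bursts_or_values)
    if values.size == 0:
        raise DegenerateInputError("no finite values")
    lo, hi = hist_range
    n_bins = max(1, int(round((hi - lo) / bin_width_e)))
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    n = len(counts)
    best_k, best_bic = 1, np.inf
    for k in range(1, max_components + 1):
        try:
            peaks = fit_gaussian_mixture(centers, counts, k, mean_bounds=(lo, hi))
        except FitFailureError:
            continue
        model = np.zeros_like(centers)
        for p in peaks:
            model += p.amplitude * np.exp(-0.5 * ((centers - p.mean) / p.sigma) ** 2)
        chi2 = float((((counts - model) ** 2) / np.maximum(counts, 1.0)).sum())
        bic = chi2 + 3 * k * np.log(n)
        if bic < best_bic:
            best_k, best_bic = k, bic
    return best_k


def select_by_efficiency(bursts: Iterable[Burst], e_min: float, e_max: float) -> list[Burst]:
    """Bursts whose apparent efficiency lies in the closed window
    [e_min, e_max]; order preserved, NaN efficiencies excluded."""
    if not e_min < e_max:
        raise InvalidArgumentError("e_min must be < e_max")
    return [b for b in bursts if np.isfinite(b.e_app) and e_min <= b.e_app <= e_max]


def subpopulation_fractions(
    peaks: Sequence[GaussianPeak], labels: Mapping[int, str] | Sequence[str]
) -> dict[str, float]:
    """Area fractions of labelled peaks.

    ``labels`` maps peak index to species name (or is a sequence aligned
    with ``peaks``). Peaks the caller wants disregarded — e.g. the
    zero-efficiency donor-only peak — are simply left unlabelled.
    Fractions sum to one over the labelled peaks.
    """
    if isinstance(labels, Mapping):
        pairs = [(peaks[i], name) for i, name in labels.items()]
    else:
        pairs = list(zip(peaks, labels))
    if not pairs:
        raise InvalidArgumentError("at least one labelled peak required")
    areas = {}
    for peak, name in pairs:
        areas[name] = areas.get(name, 0.0) + peak.area
    total = sum(areas.values())
    if total == 0:
        raise DegenerateInputError("all labelled peak areas are zero")
    return {name: a / total for name, a in areas.items()}
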