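"""Amplitude histograms, Gaussian-mixture fits, and i-V conductance.

All-points current histograms are fitted with sums of Gaussians to
estimate the unitary current ``i`` of each open level and the fraction
of time spent at each level; single-channel conductance ``gamma`` is the
slope of the single-channel current-voltage relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.stats import linregress

from .errors import ConvergenceError, ValidationError

__all__ = ["AmplitudeHistogram", "AmplitudeFit", "IVFit",
           "amplitude_histogram", "fit_gaussian_mixture",
           "level_occupancy_from_fit", "fit_iv"]


@dataclass
class AmplitudeHistogram:
    bin_edges_pa: np.ndarray
    counts: np.ndarray

    @property
    def centers_pa(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_pa[:-1] + self.bin_edges_pa[1:])

    @property
    def bin_width_pa(self) -> float:
        return float(self.bin_edges_pa[1] - self.bin_edges_pa[0])


@dataclass
class AmplitudeFit:
    """Gaussian-mixture fit of an all-points amplitude histogram.

    Components are sorted by absolute deflection from baseline (the
    component nearest zero deflection first); ``weights`` are area
    fractions summing to 1; ``i_pa`` holds the unitary current of each
    open level (component mean minus baseline mean).
    """

    means_pa: np.ndarray
    sds_pa: np.ndarray
    weights: np.ndarray
    baseline_mean_pa: float
    r: float                     # correlation of fit vs observed counts
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.sds_pa <= 0):
            raise ValidationError("component SDs must be positive")
        if np.any(self.weights <= 0) or abs(self.weights.sum() - 1) > 1e-9:
            raise ValidationError("weights must be in (0,1] and sum to 1")

    @property
    def i_pa(self) -> np.ndarray:
        """Unitary current per open level: component mean - baseline mean."""
        return self.means_pa[1:] - self.baseline_mean_pa


@dataclass
class IVFit:
    voltages_mv: np.ndarray
    currents_pa: np.ndarray
    gamma_ps: float
    slope_pa_per_mv: float
    intercept_pa: float
    r_squared: float


def amplitude_histogram(trace: np.ndarray, bin_width_pa: float = 0.02,
                        window_s: float | None = None,
                        sampling_rate_hz: float | None = None) -> AmplitudeHistogram:
    """All-points histogram; counts sum to the number of samples analysed.

    ``window_s`` restricts the analysis to the leading window of the
    record (the convention is 10-s windows of 50 Hz-filtered data).
    """
    x = np.asarray(trace, float)
    if x.size == 0:
        raise ValidationError("empty trace")
    if bin_width_pa <= 0:
        raise ValidationError("bin width must be positive")
    if window_s is not None:
        if sampling_rate_hz is None:
            raise ValidationError("window_s requires sampling_rate_hz")
        x = x[: int(round(window_s * sampling_rate_hz))]
    lo = np.floor(x.min() / bin_width_pa) * bin_width_pa
    hi = np.ceil(x.max() / bin_width_pa) * bin_width_pa
    nbins = max(int(round((hi - lo) / bin_width_pa)), 1)
    counts, edges = np.histogram(x, bins=nbins, range=(lo, lo + nbins * bin_width_pa))
    return AmplitudeHistogram(edges, counts)


def _gauss_sum(x, *params):
    y = np.zeros_like(x)
    for amp, mu, sd in zip(params[0::3], params[1::3], params[2::3]):
        y = y + amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return y


def _initial_means(hist: AmplitudeHistogram, n: int) -> np.ndarray:
    smoothed = np.convolve(hist.counts, np.ones(3) / 3.0, mode="same")
    peaks, props = find_peaks(smoothed, prominence=smoothed.max() * 0.01)
    centers = hist.centers_pa
    if len(peaks) >= n:
        order = np.argsort(props["prominences"])[::-1][:n]
        return np.sort(centers[peaks[order]])
    # fall back to weighted quantiles of the distribution
    cdf = np.cumsum(hist.counts) / hist.counts.sum()
    qs = (np.arange(n) + 0.5) / n
    return np.interp(qs, cdf, centers)


def fit_gaussian_mixture(hist: AmplitudeHistogram, n_components: int,
                         init_means_pa=None,
                         baseline_mean_pa: float | None = None) -> AmplitudeFit:
    """Least-squares fit of ``n_components`` Gaussians to binned counts.

    On non-convergence a flagged (``converged=False``) result carrying
    diagnostics is returned rather than failing silently.  The baseline
    component defaults to the fitted component nearest zero deflection.
    """
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    nonempty = int((hist.counts > 0).sum())
    if nonempty < 3 * n_components:
        raise ValidationError(
            f"histogram has {nonempty} nonempty bins; need >= {3 * n_components}")
    x, y = hist.centers_pa, hist.counts.astype(float)
    mus = (np.sort(np.asarray(init_means_pa, float)) if init_means_pa is not None
           else _initial_means(hist, n_components))
    span = x.max() - x.min()
    sd0 = max(span / (6.0 * n_components), hist.bin_width_pa)
    p0 = []
    for mu in mus:
        k = int(np.argmin(np.abs(x - mu)))
        p0 += [max(y[k], 1.0), mu, sd0]
    lb = [0.0, x.min() - span, hist.bin_width_pa * 0.1] * n_components
    ub = [y.max() * 10 + 10, x.max() + span, span + hist.bin_width_pa] * n_components
    try:
        popt, _ = curve_fit(_gauss_sum, x, y, p0=p0, bounds=(lb, ub), maxfev=20000)
        converged = True
        diag = {}
    except RuntimeError as exc:
        popt = np.array(p0, float)
        converged = False
        diag = {"error": str(exc)}
    amps = np.array(popt[0::3])
    means = np.array(popt[1::3])
    sds = np.array(popt[2::3])
    areas = amps * sds                      # proportional to component area
    weights = areas / areas.sum()
    if baseline_mean_pa is None:
        base_idx = int(np.argmin(np.abs(means)))
    else:
        base_idx = int(np.argmin(np.abs(means - baseline_mean_pa)))
    order = np.argsort(np.abs(means - means[base_idx]))
    means, sds, weights = means[order], sds[order], weights[order]
    weights = weights / weights.sum()
    fitted = _gauss_sum(x, *popt)
    denom = np.std(fitted) * np.std(y)
    r = float(np.corrcoef(fitted, y)[0, 1]) if denom > 0 else 0.0
    return AmplitudeFit(means, sds, weights, float(means[0]), r,
                        converged=converged, diagnostics=diag)


def level_occupancy_from_fit(fit: AmplitudeFit, expected_i_pa,
                             tolerance_pa: float | None = None) -> np.ndarray:
    """Map mixture components to conductance levels; P(k) = component weight.

    ``expected_i_pa`` lists the expected deflection of each open level
    from baseline (e.g. [i_sc, i_sc + i_wtl] need not be multiples).  A
    component whose deflection matches no expected level within the
    tolerance (default a quarter of the largest |expected| deflection)
    raises, naming the offending component.
    """
    expected = np.concatenate(([0.0], np.asarray(expected_i_pa, float)))
    if tolerance_pa is None:
        tolerance_pa = 0.25 * np.max(np.abs(expected))
    occ = np.zeros(len(expected))
    defl = fit.means_pa - fit.baseline_mean_pa
    for j, (d, w) in enumerate(zip(defl, fit.weights)):
        dist = np.abs(expected - d)
        k = int(np.argmin(dist))
        if dist[k] > tolerance_pa:
            raise ValidationError(
                f"component {j} (deflection {d:.3f} pA) matches no expected level "
                f"within {tolerance_pa:.3f} pA")
        occ[k] += w
    return occ / occ.sum()


def fit_iv(voltages_mv, currents_pa) -> IVFit:
    """Ordinary least-squares line through (V, i) points; gamma = |slope| in pS.

    With i in pA and V in mV the slope is in nS, hence gamma (pS) is the
    slope magnitude times 1000.  The slope — and therefore the
    conductance — is unchanged by any constant offset of the voltage
    axis, so driving-force versus absolute-voltage bookkeeping does not
    affect gamma.
    """
    v = np.asarray(voltages_mv, float)
    i = np.asarray(currents_pa, float)
    if len(np.unique(v)) < 2:
        raise ValidationError("need at least 2 distinct voltages")
    res = linregress(v, i)
    return IVFit(v, i, gamma_ps=abs(res.slope) * 1e3,
                 slope_pa_per_mv=float(res.slope),
                 intercept_pa=float(res.intercept),
                 r_squared=float(res.rvalue ** 2))
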