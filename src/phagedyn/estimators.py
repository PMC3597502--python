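"""Parameter-estimation routines for growth curves and plating assays.

These operate on plain time/value tables — real measurements or the
package's own simulated fixtures — and return the quantities the simulator
consumes: maximum growth rate, latent period, burst size, escape-mutant
frequency, and a density-to-OD conversion for comparing simulations with
turbidity data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import DomainError

__all__ = [
    "EstimationError",
    "GrowthCurve",
    "OneStepDesign",
    "CalibrationCurve",
    "GrowthRateEstimate",
    "OneStepEstimate",
    "CemFrequencyEstimate",
    "estimate_growth_rate",
    "analyze_one_step",
    "cem_frequency",
    "density_to_od",
]


class EstimationError(ValueError):
    """The data do not support the requested estimate."""


@dataclass
class GrowthCurve:
    """A growth time series: OD readings or direct cell densities."""

    times: np.ndarray
    readings: np.ndarray
    kind: str = "od"  # "od" | "density"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        if self.times.shape != self.readings.shape:
            raise DomainError("times and readings must have equal length")
        if len(self.times) and (np.diff(self.times) <= 0).any():
            raise DomainError("times must be strictly increasing")
        if (self.readings < 0).any():
            raise DomainError("readings must be non-negative")
        if self.kind not in ("od", "density"):
            raise DomainError("kind must be 'od' or 'density'")


@dataclass(frozen=True)
class OneStepDesign:
    """Windows and threshold for analysing a one-step growth experiment.

    The pre-burst window is half-open ``[pre_start, pre_end)`` so a sample
    taken exactly at its upper edge — where the first bursts may already have
    occurred — does not contaminate the pre-burst mean.  The post-burst
    window is closed.
    """

    pre_window: tuple[float, float] = (15 / 60, 25 / 60)
    post_window: tuple[float, float] = (40 / 60, 60 / 60)
    rise_threshold: float = 1.5

    def __post_init__(self) -> None:
        if not (self.pre_window[0] < self.pre_window[1] <= self.post_window[0] < self.post_window[1]):
            raise DomainError("windows must be ordered and disjoint (pre before post)")
        if self.rise_threshold <= 1:
            raise DomainError("rise_threshold must exceed 1")


@dataclass
class CalibrationCurve:
    """Polynomial mapping from cell density to optical density.

    Fitted on paired (density, OD) calibration points; conversions clamp to
    the calibrated density range and never return below ``od_floor`` — ODs
    around the floor are an artifact and densities mapping there are
    operationally indistinguishable.
    """

    densities: np.ndarray
    ods: np.ndarray
    degree: int = 3
    od_floor: float = 0.005
    _poly: np.polynomial.Polynomial | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.ods = np.asarray(self.ods, dtype=float)
        if len(self.densities) < self.degree + 1:
            raise EstimationError("not enough calibration points for the polynomial degree")

    def fit(self) -> "CalibrationCurve":
        self._poly = np.polynomial.Polynomial.fit(self.densities, self.ods, self.degree)
        grid = np.linspace(self.densities.min(), self.densities.max(), 512)
        vals = self._poly(grid)
        if (np.diff(vals) < -1e-12 * max(1.0, float(np.abs(vals).max()))).any():
            raise EstimationError(
                "fitted calibration polynomial is not monotone over the "
                "calibrated range; lower the degree"
            )
        return self

    @property
    def fitted(self) -> bool:
        return self._poly is not None

    def convert(self, densities: np.ndarray) -> np.ndarray:
        if self._poly is None:
            raise EstimationError("calibration curve has not been fitted")
        d = np.clip(np.asarray(densities, dtype=float), self.densities.min(), self.densities.max())
        return np.maximum(self._poly(d), self.od_floor)


@dataclass(frozen=True)
class GrowthRateEstimate:
    rate: float  # per hour
    ci95_half_width: float
    n_points: int


@dataclass(frozen=True)
class OneStepEstimate:
    latent_period: float  # hours
    burst_size: float  # phage per infected cell
    pre_mean: float
    post_mean: float


@dataclass(frozen=True)
class CemFrequencyEstimate:
    frequency: float
    upper_bound: float | None = None  # set when zero plaques were observed


def estimate_growth_rate(
    curve: GrowthCurve, window: tuple[float, float]
) -> GrowthRateEstimate:
    """OLS slope of ln(reading) against time over a window, with 95% CI.

    Works identically for OD and density readings (any positive linear
    rescaling leaves the log-slope unchanged).
    """
    lo, hi = window
    mask = (curve.times >= lo) & (curve.times <= hi)
    t = curve.times[mask]
    y = curve.readings[mask]
    if len(t) < 3:
        raise EstimationError("need at least 3 points in the regression window")
    if (y <= 0).any():
        raise EstimationError("all readings in the window must be positive")
    res = stats.linregress(t, np.log(y))
    tcrit = stats.t.ppf(0.975, len(t) - 2)
    half = float(tcrit * res.stderr) if math.isfinite(res.stderr) else 0.0
    return GrowthRateEstimate(float(res.slope), half, len(t))


def analyze_one_step(
    times: np.ndarray,
    pfu: np.ndarray,
    design: OneStepDesign = OneStepDesign(),
) -> OneStepEstimate:
    """Latent period and burst size from a one-step growth PFU series.

    The latent period is the earliest sampling time at which PFU exceeds
    ``rise_threshold`` times the mean pre-burst PFU; the burst size is the
    ratio of the post-window mean to the pre-window mean (pre-burst PFU
    approximates the number of infective centers, so the ratio is in
    particles per infected cell).
    """
    times = np.asarray(times, dtype=float)
    pfu = np.asarray(pfu, dtype=float)
    if times.shape != pfu.shape:
        raise EstimationError("times and pfu must have equal length")
    pre = (times >= design.pre_window[0]) & (times < design.pre_window[1])
    post = (times >= design.post_window[0]) & (times <= design.post_window[1])
    if pre.sum() < 2:
        raise EstimationError("need at least two pre-burst samples")
    if not post.any():
        raise EstimationError("pfu series does not cover the post-burst window")
    pre_mean = float(pfu[pre].mean())
    post_mean = float(pfu[post].mean())
    if pre_mean <= 0:
        raise EstimationError("pre-burst mean PFU is zero; burst size undefined")

    threshold = design.rise_threshold * pre_mean
    eligible = times >= design.pre_window[0]
    crossed = eligible & (pfu > threshold)
    if not crossed.any():
        raise EstimationError("no burst detected: PFU never exceeds the rise threshold")
    latent = float(times[crossed][0])
    return OneStepEstimate(latent, post_mean / pre_mean, pre_mean, post_mean)


def cem_frequency(
    plaques_on_bim: int,
    dilution_bim: float,
    plaques_on_wt: int,
    dilution_wt: float,
) -> CemFrequencyEstimate:
    """Escape-mutant frequency from a two-lawn plating assay.

    Ratio of the estimated phage density titered on an immune-host lawn
    (only escape mutants plaque) to that on a wild-type lawn (all phage
    plaque).  Zero plaques on the immune lawn yields frequency 0 with an
    upper bound computed as if one plaque had been seen.
    """
    if plaques_on_wt <= 0:
        raise EstimationError(
            "zero plaques on the wild-type lawn: total titer undefined"
        )
    if min(dilution_bim, dilution_wt) < 1:
        raise DomainError("dilution factors must be >= 1")
    if plaques_on_bim < 0:
        raise DomainError("plaque counts must be non-negative")
    wt_titer = plaques_on_wt * dilution_wt
    if plaques_on_bim == 0:
        return CemFrequencyEstimate(0.0, upper_bound=dilution_bim / wt_titer)
    return CemFrequencyEstimate(plaques_on_bim * dilution_bim / wt_titer)


def density_to_od(cal: CalibrationCurve, densities: np.ndarray) -> np.ndarray:
    """Convert simulated cell densities to predicted OD readings."""
    return cal.convert(densities)
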