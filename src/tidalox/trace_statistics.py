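"""Measurement rules for sampled PaO2 traces.

Implements the analysis conventions of the breath-hold / tidal-breathing
protocol: per-breath oscillation mean and amplitude over a 2-min
steady-state window, the steepest 5-s decline with exclusion of samples
below 100 mmHg (where haemoglobin desaturation invalidates the linear
model), steady-state detection (mean PaO2 changing by no more than
5 mmHg/min), and Bland-Altman agreement statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal, stats

from .errors import InvalidParameterError
from .gas_exchange import PO2Trace

__all__ = [
    "SampledTrace",
    "OscillationStats",
    "DeclineResult",
    "BlandAltmanResult",
    "SteadyStateResult",
    "segment_breaths",
    "oscillation_stats",
    "steepest_decline",
    "is_steady_state",
    "bland_altman",
    "normalize_decline",
]


@dataclass
class SampledTrace:
    """Uniformly sampled PaO2 (mmHg), optionally with airway pressure."""

    t: np.ndarray
    pao2: np.ndarray
    paw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pao2 = np.asarray(self.pao2, dtype=float)
        if len(self.t) != len(self.pao2):
            raise InvalidParameterError("t and pao2 must have equal length")
        if len(self.t) >= 2:
            dts = np.diff(self.t)
            if dts.min() <= 0 or not np.allclose(dts, dts[0], rtol=1e-6):
                raise InvalidParameterError("time grid must be uniform, increasing")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @classmethod
    def from_po2trace(cls, trace: PO2Trace, channel: str = "art") -> "SampledTrace":
        y = trace.pao2_art if channel == "art" else trace.pao2_alv
        return cls(t=np.asarray(trace.t), pao2=np.asarray(y),
                   paw=np.asarray(trace.paw_cmh2o))


@dataclass
class OscillationStats:
    window_start: float
    window_end: float
    mean_pao2: float
    amplitude_mean: float     # mean per-breath peak-to-trough, mmHg
    amplitude_max: float
    n_breaths: int
    mean_paw: float | None = None


@dataclass
class DeclineResult:
    rate: float               # mmHg/s, magnitude of steepest decline
    window_start: float
    excluded_below_floor: bool
    valid: bool = True


@dataclass
class SteadyStateResult:
    steady: bool
    window_starts: np.ndarray   # start times (s) of qualifying 2-min windows
    threshold: float


@dataclass
class BlandAltmanResult:
    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_bias: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]


def segment_breaths(
    trace: SampledTrace, rr_hint: float
) -> list[tuple[int, int]]:
    """Split a trace into per-breath windows (index pairs, end exclusive).

    With an airway-pressure channel, breaths are cut at inspiratory onsets
    (airway-pressure troughs at end-expiration).  Without one, PaO2
    troughs with >= 1 mmHg prominence are used.  Minimum spacing between
    cuts is half the expected period.  Returns an empty list (with a
    warning) when no cycles are detected.
    """
    if rr_hint <= 0:
        raise InvalidParameterError("rr_hint must be > 0")
    period = 60.0 / rr_hint
    if trace.duration < 2 * period:
        raise InvalidParameterError("trace must span at least 2 breaths")
    distance = max(1, int(round(0.5 * period / trace.dt)))
    if trace.paw is not None and np.ptp(trace.paw) > 1e-9:
        onsets, _ = signal.find_peaks(
            -np.asarray(trace.paw), distance=distance,
            prominence=0.25 * np.ptp(trace.paw),
        )
    else:
        onsets, _ = signal.find_peaks(
            -trace.pao2, distance=distance, prominence=1.0
        )
    if len(onsets) < 2:
        warnings.warn("no respiratory cycles detected", RuntimeWarning,
                      stacklevel=2)
        return []
    return [(int(a), int(b)) for a, b in zip(onsets[:-1], onsets[1:])]


def oscillation_stats(
    trace: SampledTrace, rr_hint: float, window: float = 120.0
) -> OscillationStats:
    """Mean PaO2 and per-breath peak-to-trough amplitudes over the final
    ``window`` seconds of the trace (assumed at steady state)."""
    if trace.duration + trace.dt < window:
        raise InvalidParameterError(
            f"trace shorter than requested {window} s window"
        )
    i0 = int(np.searchsorted(trace.t, trace.t[-1] - window + 0.5 * trace.dt))
    sub = SampledTrace(
        t=trace.t[i0:], pao2=trace.pao2[i0:],
        paw=None if trace.paw is None else trace.paw[i0:],
    )
    breaths = segment_breaths(sub, rr_hint)
    if len(breaths) < 2:
        raise InvalidParameterError("analysis window holds fewer than 2 breaths")
    amps = np.array(
        [np.ptp(sub.pao2[a:b]) for a, b in breaths]
    )
    return OscillationStats(
        window_start=float(sub.t[0]),
        window_end=float(sub.t[-1]),
        mean_pao2=float(np.mean(sub.pao2)),
        amplitude_mean=float(np.mean(amps)),
        amplitude_max=float(np.max(amps)),
        n_breaths=len(breaths),
        mean_paw=None if sub.paw is None else float(np.mean(sub.paw)),
    )


def steepest_decline(
    trace: SampledTrace, window: float = 5.0, floor: float = 100.0
) -> DeclineResult:
    """Steepest decline: the largest-magnitude negative least-squares slope
    over every sliding window of length ``window`` s (step = one sample).

    Windows containing any sample below ``floor`` mmHg are excluded.
    Returns a ``valid=False`` result when every window is excluded.
    """
    w = int(round(window / trace.dt)) + 1
    if w > len(trace.pao2):
        raise InvalidParameterError("trace shorter than the slope window")
    views = sliding_window_view(trace.pao2, w)
    tc = (np.arange(w) - (w - 1) / 2.0) * trace.dt
    slopes = views @ tc / np.sum(tc * tc)
    ok = np.min(views, axis=1) >= floor
    any_excluded = bool(not ok.all())
    if not ok.any():
        return DeclineResult(
            rate=float("nan"), window_start=float("nan"),
            excluded_below_floor=any_excluded, valid=False,
        )
    slopes = np.where(ok, slopes, np.inf)
    i = int(np.argmin(slopes))
    rate = max(0.0, -float(slopes[i]))
    return DeclineResult(
        rate=rate,
        window_start=float(trace.t[i]),
        excluded_below_floor=any_excluded,
    )


def is_steady_state(
    trace: SampledTrace, threshold: float = 5.0
) -> SteadyStateResult:
    """Steady state: consecutive non-overlapping 60-s means differing by no
    more than ``threshold`` mmHg (i.e. mmHg per minute)."""
    n60 = int(round(60.0 / trace.dt))
    if len(trace.pao2) < 2 * n60:
        raise InvalidParameterError("steady-state test needs >= 2 min of data")
    csum = np.concatenate([[0.0], np.cumsum(trace.pao2)])
    means = (csum[n60:] - csum[:-n60]) / n60   # mean over [i, i+n60)
    n_start = len(trace.pao2) - 2 * n60 + 1
    diffs = np.abs(means[n60:n60 + n_start] - means[:n_start])
    starts = trace.t[:n_start][diffs <= threshold]
    return SteadyStateResult(
        steady=bool(len(starts) > 0),
        window_starts=np.asarray(starts, dtype=float),
        threshold=threshold,
    )


def bland_altman(a, b=None) -> BlandAltmanResult:
    """Bland-Altman agreement between paired measurements.

    Accepts either a sequence of ``(a, b)`` pairs or two equal-length
    arrays.  Bias is the mean difference ``a - b``; limits of agreement are
    ``bias +/- 1.96 * SD``; the bias CI uses ``t(n-1) * SD / sqrt(n)`` and
    each limit's CI the standard ``t(n-1) * SD * sqrt(3/n)`` approximation.
    """
    if b is None:
        arr = np.asarray(a, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise InvalidParameterError("expected pairs of measurements")
        a, b = arr[:, 0], arr[:, 1]
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = len(d)
    if n < 3:
        raise InvalidParameterError("Bland-Altman needs n >= 3 pairs")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    tcrit = float(stats.t.ppf(0.975, n - 1))
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    return BlandAltmanResult(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        ci_bias=(bias - tcrit * se_bias, bias + tcrit * se_bias),
        ci_loa_low=(loa_low - tcrit * se_loa, loa_low + tcrit * se_loa),
        ci_loa_high=(loa_high - tcrit * se_loa, loa_high + tcrit * se_loa),
    )


def normalize_decline(
    rate: float,
    mass: float,
    reference_mass: float = 29.0,
    rule: str = "linear",
) -> float:
    """Normalise a decline rate for body mass.

    The decline scales as VO2/VA and both scale roughly with mass, so the
    default ``linear`` rule rescales by ``mass / reference_mass``;
    ``none`` returns the rate unchanged.
    """
    if mass <= 0 or reference_mass <= 0:
        raise InvalidParameterError("masses must be > 0")
    if rule == "linear":
        return rate * mass / reference_mass
    if rule == "none":
        return rate
    raise InvalidParameterError(f"unknown normalisation rule {rule!r}")
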