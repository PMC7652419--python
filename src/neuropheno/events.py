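"""Spontaneous postsynaptic-current event detection and distribution tests.

Detects spontaneous/miniature postsynaptic currents (sPSC/sEPSC/sIPSC and
their miniature counterparts) in voltage-clamp holding-current traces,
summarises their amplitudes and inter-event intervals, and compares
distributions between groups with the two-sample Kolmogorov–Smirnov test on
the empirical cumulative distributions (significance conventionally at
p < 0.001 for these large event samples).

The detector is deliberately simple and fully parameterised: the rectified
trace is smoothed with a short moving average, candidate peaks above an
amplitude threshold are found with a minimum-separation rule (peaks closer
than ``min_separation_ms`` merge into one compound event scored at the
compound peak), the local baseline is the median of a pre-onset window, and
the event onset is the last sub-threshold-fraction crossing before the peak.
Inward currents at a −70 mV holding potential are negative deflections;
amplitudes are reported as positive magnitudes with polarity configured per
condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks
from scipy.stats import ks_2samp

__all__ = [
    "EventSeries",
    "DetectionParams",
    "detect_events",
    "ecdf",
    "ks_two_sample",
    "tail_fraction",
    "enforce_event_protocol",
    "match_events",
]


@dataclass
class EventSeries:
    """Detected events for one cell: onset times (s) and amplitudes (pA)."""

    onsets: np.ndarray
    amplitudes: np.ndarray
    cell_id: str = ""
    condition: str = "sPSC"
    duration: float | None = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.onsets.size != self.amplitudes.size:
            raise ValueError("onsets and amplitudes must have equal length")
        if self.onsets.size > 1 and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return self.onsets.size

    @property
    def iei_ms(self) -> np.ndarray:
        """Inter-event intervals in ms (length n − 1)."""
        return np.diff(self.onsets) * 1000.0


@dataclass(frozen=True)
class DetectionParams:
    """Tunable detector parameters (times in ms, amplitudes in pA).

    ``rise_ms``/``decay_ms`` describe the expected event time course (the
    detection template); the amplitude readout divides out the known
    attenuation of its smoothing window on that template, so amplitudes
    are unbiased for template-shaped events.
    """

    threshold: float = 15.0
    min_separation_ms: float = 5.0
    smooth_ms: float = 2.0  # moving-average width for peak finding
    amp_smooth_ms: float = 1.0  # amplitude-readout smoothing
    baseline_ms: float = 20.0  # pre-onset window for the local baseline
    onset_frac: float = 0.2  # rising-phase fraction defining the onset
    rise_ms: float = 1.5  # template rise time constant
    decay_ms: float = 6.0  # template decay time constant
    polarity: str = "negative"  # inward events deflect negative

    def __post_init__(self) -> None:
        for name in ("threshold", "min_separation_ms", "smooth_ms", "amp_smooth_ms",
                     "baseline_ms", "rise_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.decay_ms <= self.rise_ms:
            raise ValueError("template decay must exceed rise")
        if self.polarity not in ("negative", "positive"):
            raise ValueError("polarity must be 'negative' or 'positive'")

    def smoothing_attenuation(self, fs: float) -> float:
        """Peak attenuation of the amplitude-smoothing window on the
        difference-of-exponentials template (1 means none)."""
        tr, td = self.rise_ms / 1000.0, self.decay_ms / 1000.0
        t = np.arange(int(round(8 * td * fs))) / fs
        k = np.exp(-t / td) - np.exp(-t / tr)
        k /= k.max()
        w = max(int(round(self.amp_smooth_ms / 1000.0 * fs)), 1)
        return float(uniform_filter1d(k, size=w, mode="nearest").max())


def _smooth(y: np.ndarray, width_samples: int) -> np.ndarray:
    return uniform_filter1d(y, size=max(width_samples, 1), mode="nearest")


def detect_events(
    trace: np.ndarray,
    fs: float,
    params: DetectionParams | None = None,
    cell_id: str = "",
    condition: str = "sPSC",
    noise_sd: float | None = None,
) -> EventSeries:
    """Detect postsynaptic-current events in a holding-current trace.

    ``noise_sd``, when given, is only used to warn if the threshold sits
    below three standard deviations of the baseline noise.
    """
    params = params or DetectionParams()
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        return EventSeries(np.array([]), np.array([]), cell_id, condition, 0.0)
    y = -trace if params.polarity == "negative" else trace.copy()
    w_det = int(round(params.smooth_ms / 1000.0 * fs))
    if noise_sd is not None:
        # detection runs on the smoothed trace, whose noise floor is reduced
        # by roughly sqrt(window) relative to the raw noise SD
        floor = noise_sd / np.sqrt(max(w_det, 1))
        if params.threshold < 5.0 * floor:
            warnings.warn(
                "detection threshold is below 5x the smoothed noise floor; "
                "expect false positives",
                UserWarning,
                stacklevel=2,
            )
    w_amp = int(round(params.amp_smooth_ms / 1000.0 * fs))
    y_det = _smooth(y, w_det)
    y_amp = _smooth(y, w_amp)

    distance = max(int(round(params.min_separation_ms / 1000.0 * fs)), 1)
    # The detection pass runs on the heavily smoothed trace, which attenuates
    # sharp peaks; use a fraction of the amplitude threshold here and confirm
    # against the lightly smoothed amplitude below.
    peaks, _ = find_peaks(y_det, height=0.5 * params.threshold, distance=distance)

    n_base = int(round(params.baseline_ms / 1000.0 * fs))
    atten = params.smoothing_attenuation(fs)
    w_loc = max(w_amp, 1)  # narrow refinement window around the detection peak
    onsets, amps = [], []
    for p in peaks:
        # refine the peak location on the amplitude trace
        lo = max(p - w_loc, 0)
        hi = min(p + w_loc + 1, y.size)
        p_amp = lo + int(np.argmax(y_amp[lo:hi]))
        b0 = max(p_amp - n_base, 0)
        baseline = float(np.median(y_amp[b0:p_amp])) if p_amp > b0 else 0.0
        amp = float(y_amp[p_amp] - baseline) / atten
        if amp < params.threshold:
            continue
        # onset: last crossing of baseline + onset_frac * amp before the peak
        level = baseline + params.onset_frac * amp * atten
        seg = y_amp[b0:p_amp]
        below = np.nonzero(seg < level)[0]
        onset_idx = b0 + below[-1] + 1 if below.size else b0
        onsets.append(onset_idx / fs)
        amps.append(amp)

    onsets_arr = np.asarray(onsets)
    amps_arr = np.asarray(amps)
    # merging by `distance` can still leave duplicate onsets from distinct
    # detection peaks resolving to one amplitude peak
    if onsets_arr.size > 1:
        keep = np.ones(onsets_arr.size, dtype=bool)
        keep[1:] = np.diff(onsets_arr) > 0
        onsets_arr, amps_arr = onsets_arr[keep], amps_arr[keep]
    return EventSeries(onsets_arr, amps_arr, cell_id, condition, trace.size / fs)


def ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF as (sorted values, cumulative probabilities).

    Right-continuous and nondecreasing, reaching exactly 1 at the largest
    observation.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("ecdf of an empty sample is undefined")
    x = np.sort(v)
    y = np.arange(1, x.size + 1) / x.size
    return x, y


def ks_two_sample(a: np.ndarray, b: np.ndarray, method: str = "auto") -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov comparison: (D, p).

    D = sup |ECDF_a − ECDF_b|.  ``method`` follows scipy's convention
    ('auto' selects the exact distribution for small samples and the
    asymptotic one for the large event counts typical here).
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def tail_fraction(
    amplitudes: np.ndarray, cutoffs: tuple[float, ...] = (100.0, 250.0)
) -> dict[float, float]:
    """Percent of events exceeding each amplitude cutoff.

    Mirrors the reporting of large-amplitude (long-tail) event frequencies,
    e.g. the share of events above 100 pA and above 250 pA out of the total
    analysed.
    """
    a = np.asarray(amplitudes, dtype=float)
    if a.size == 0:
        raise ValueError("amplitudes must be nonempty")
    return {float(c): float(100.0 * np.mean(a > c)) for c in cutoffs}


def enforce_event_protocol(
    series: list[EventSeries],
    n_min: int = 200,
    bin_window: tuple[float, float] | None = None,
) -> tuple[list[EventSeries], dict[str, int]]:
    """Keep cells with at least ``n_min`` events inside a common temporal bin.

    Implements the "at least 200 events from identical temporal bins" rule:
    every cell is scored on the same ``bin_window`` (whole recording when
    None) and cells below ``n_min`` are excluded.  Returns the retained
    series and a per-cell event-count report for logging.
    """
    report: dict[str, int] = {}
    kept: list[EventSeries] = []
    for s in series:
        if bin_window is None:
            count = len(s)
        else:
            t0, t1 = bin_window
            if s.duration is not None and t1 > s.duration:
                raise ValueError(
                    f"bin window extends past the recording of cell {s.cell_id!r}"
                )
            count = int(np.sum((s.onsets >= t0) & (s.onsets < t1)))
        report[s.cell_id] = count
        if count >= n_min:
            kept.append(s)
    return kept, report


def match_events(
    detected: EventSeries,
    truth_onsets: np.ndarray,
    truth_amplitudes: np.ndarray | None = None,
    tol_ms: float = 2.0,
) -> dict[str, float]:
    """Score a detection against ground truth by greedy onset matching.

    Events match when onsets agree within ``tol_ms``.  Returns recall,
    precision, and (when truth amplitudes are given) the mean absolute
    relative amplitude error over matched pairs.
    """
    tol = tol_ms / 1000.0
    t_truth = np.asarray(truth_onsets, dtype=float)
    used = np.zeros(t_truth.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for i, t in enumerate(detected.onsets):
        j = int(np.argmin(np.abs(t_truth - t))) if t_truth.size else -1
        if j >= 0 and not used[j] and abs(t_truth[j] - t) <= tol:
            used[j] = True
            pairs.append((i, j))
    n_match = len(pairs)
    out = {
        "recall": n_match / t_truth.size if t_truth.size else np.nan,
        "precision": n_match / len(detected) if len(detected) else np.nan,
        "n_matched": float(n_match),
    }
    if truth_amplitudes is not None and pairs:
        ta = np.asarray(truth_amplitudes, dtype=float)
        rel = [
            abs(detected.amplitudes[i] - ta[j]) / ta[j] for i, j in pairs if ta[j] > 0
        ]
        out["amplitude_mae_rel"] = float(np.mean(rel))
    return out
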