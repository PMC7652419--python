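"""Intrinsic membrane properties from current-step voltage sweeps.

Implements the standard single-electrode current-clamp workflow: resting
membrane potential from the pre-step baseline, input resistance by Ohm's law
from the steady-state deflection of a −100 pA step, membrane time constant by
a single-exponential fit of the charging transient, sag voltage as the peak
negative-going voltage minus the steady-state voltage, spike detection by
threshold crossing, the accommodation index as max ISI (including last spike
to step end) over first ISI, and input–output (current → spike count) curves
compared between groups by linear regression followed by ANCOVA.

Window conventions (configurable on every function): baseline is the 100 ms
preceding step onset, the steady state is the last 20% of the step, and the
sag peak is searched in the first 40% of the step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.optimize import curve_fit
from statsmodels.stats.anova import anova_lm

__all__ = [
    "StepProtocol",
    "SweepSet",
    "IntrinsicProperties",
    "AncovaResult",
    "measure_rmp",
    "input_resistance",
    "fit_tau",
    "sag_measures",
    "detect_spikes",
    "accommodation_index",
    "measure_intrinsic",
    "io_curve",
    "compare_io",
]

# Shared window defaults (fractions of the step, seconds for baseline).
BASELINE_S = 0.1
SS_FRAC = 0.2
PEAK_FRAC = 0.4


@dataclass(frozen=True)
class StepProtocol:
    """A stepped current-injection protocol.

    ``currents`` are the per-sweep injected currents in pA; the step runs
    from ``step_start`` for ``step_dur`` seconds inside a sweep of
    ``sweep_dur`` seconds.
    """

    currents: tuple[float, ...] = (-100.0, -60.0, -20.0, 20.0, 60.0, 120.0, 180.0)
    step_start: float = 0.2
    step_dur: float = 0.5
    sweep_dur: float = 1.0

    def __post_init__(self) -> None:
        if self.step_dur <= 0:
            raise ValueError("protocol steps must have positive duration")
        if not (0 < self.step_start and self.step_start + self.step_dur < self.sweep_dur):
            raise ValueError("step window must lie strictly inside the sweep")


@dataclass
class SweepSet:
    """Voltage sweeps (mV) under a stepped current protocol.

    ``sweeps`` has shape (n_sweeps, n_samples) and row i corresponds to
    ``protocol.currents[i]``.  ``spike_times`` optionally carries
    ground-truth spike times per sweep (synthetic data only).
    """

    sweeps: np.ndarray
    protocol: StepProtocol
    fs: float
    spike_times: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        if self.sweeps.ndim != 2:
            raise ValueError("sweeps must be a 2-D (n_sweeps, n_samples) array")
        if self.sweeps.shape[0] != len(self.protocol.currents):
            raise ValueError("one sweep per protocol current is required")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.sweeps.shape[1]) / self.fs

    def sweep_at(self, current: float) -> np.ndarray:
        idx = [i for i, c in enumerate(self.protocol.currents) if c == current]
        if not idx:
            raise KeyError(f"no sweep at {current} pA")
        return self.sweeps[idx[0]]


@dataclass
class IntrinsicProperties:
    """Per-cell summary matching the reported property panel."""

    rmp: float  # mV
    input_resistance: float  # MΩ
    tau: float  # ms
    sag_voltage: float  # mV, <= 0
    sag_percent: float  # %
    accommodation_index: float | None  # dimensionless, None if < 2 spikes


def _step_slice(fs: float, start: float, dur: float, frac0: float, frac1: float) -> slice:
    i0 = int(round((start + frac0 * dur) * fs))
    i1 = int(round((start + frac1 * dur) * fs))
    return slice(i0, i1)


def measure_rmp(
    sweep: np.ndarray, fs: float, step_start: float, baseline_s: float = BASELINE_S
) -> float:
    """Resting membrane potential: mean voltage over the pre-step baseline."""
    i1 = int(round(step_start * fs))
    i0 = i1 - int(round(baseline_s * fs))
    if i0 < 0 or i1 <= i0:
        raise ValueError("baseline window must be nonempty and precede step onset")
    return float(np.mean(sweep[i0:i1]))


def input_resistance(
    sweep: np.ndarray,
    fs: float,
    current_pa: float,
    step_start: float,
    step_dur: float,
    rmp: float | None = None,
    ss_frac: float = SS_FRAC,
) -> float:
    """Input resistance in MΩ by Ohm's law, R = V/I.

    V is the steady-state deflection (mean over the last ``ss_frac`` of the
    step) relative to the resting potential; I is the injected current
    (−100 pA in the standard protocol).  Reported positive.
    """
    if current_pa == 0:
        raise ValueError("injected current must be nonzero")
    if rmp is None:
        rmp = measure_rmp(sweep, fs, step_start)
    ss = sweep[_step_slice(fs, step_start, step_dur, 1.0 - ss_frac, 1.0)]
    v_ss = float(np.mean(ss))
    # mV / pA = GΩ, hence the factor 1000 to MΩ.
    return abs((v_ss - rmp) / current_pa) * 1000.0


def fit_tau(
    sweep: np.ndarray,
    fs: float,
    step_start: float,
    fit_dur: float = 0.1,
    min_deflection_mv: float = 0.5,
) -> float:
    """Membrane time constant (ms) by a single-exponential fit A·e^(−t/τ).

    The charging transient from step onset over ``fit_dur`` seconds is fit
    to V(t) = V∞ − A·e^(−t/τ) by nonlinear least squares; the initial τ
    guess comes from the 63% crossing time.
    """
    i0 = int(round(step_start * fs))
    i1 = i0 + int(round(fit_dur * fs))
    seg = sweep[i0:i1]
    t = np.arange(seg.size) / fs
    v0, v_inf = seg[0], float(np.mean(seg[-max(seg.size // 10, 1):]))
    if abs(v_inf - v0) < min_deflection_mv:
        raise ValueError("no charging transient to fit (flat trace)")
    # 63% crossing for the initial guess
    target = v0 + 0.632 * (v_inf - v0)
    crossed = np.nonzero((seg - target) * np.sign(v_inf - v0) >= 0)[0]
    tau0 = t[crossed[0]] if crossed.size else fit_dur / 5.0
    tau0 = max(tau0, 2.0 / fs)

    def model(t, v_inf, a, tau):
        return v_inf - a * np.exp(-t / tau)

    p0 = (v_inf, v_inf - v0, tau0)
    popt, _ = curve_fit(model, t, seg, p0=p0, maxfev=10000)
    tau = popt[2]
    if not np.isfinite(tau) or tau <= 0:
        raise RuntimeError("exponential fit did not converge to a positive tau")
    return float(tau * 1000.0)


def sag_measures(
    sweep: np.ndarray,
    fs: float,
    step_start: float,
    step_dur: float,
    rmp: float | None = None,
    peak_frac: float = PEAK_FRAC,
    ss_frac: float = SS_FRAC,
) -> tuple[float, float]:
    """Sag voltage (mV, ≤ 0) and sag percent for a hyperpolarizing step.

    sag_voltage = V_peak − V_ss where V_peak is the most negative voltage in
    the first ``peak_frac`` of the step and V_ss the steady-state mean;
    sag_percent expresses |sag| relative to the peak deflection from rest.
    """
    if rmp is None:
        rmp = measure_rmp(sweep, fs, step_start)
    ss = sweep[_step_slice(fs, step_start, step_dur, 1.0 - ss_frac, 1.0)]
    v_ss = float(np.mean(ss))
    if v_ss >= rmp:
        raise ValueError("sag is defined on hyperpolarizing sweeps only")
    peak_win = sweep[_step_slice(fs, step_start, step_dur, 0.0, peak_frac)]
    v_peak = float(np.min(peak_win))
    sag_v = min(v_peak - v_ss, 0.0)
    denom = abs(v_peak - rmp)
    sag_pct = 100.0 * abs(sag_v) / denom if denom > 0 else 0.0
    return sag_v, sag_pct


def detect_spikes(
    sweep: np.ndarray,
    fs: float,
    threshold: float = 0.0,
    refractory_ms: float = 2.0,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Spike times (s) as upward threshold crossings with a refractory period.

    ``window`` optionally restricts detection to (t0, t1) seconds.
    """
    if refractory_ms <= 0:
        raise ValueError("refractory period must be > 0")
    v = np.asarray(sweep, dtype=float)
    above = v >= threshold
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    times = crossings / fs
    if window is not None:
        times = times[(times >= window[0]) & (times < window[1])]
    kept: list[float] = []
    refr = refractory_ms / 1000.0
    for t in times:
        if not kept or t - kept[-1] >= refr:
            kept.append(float(t))
    return np.array(kept)


def accommodation_index(spike_times: np.ndarray, step_end: float) -> float | None:
    """max ISI (including last spike → step end) over the first ISI.

    Returns None with fewer than two spikes (the property is undefined, not
    zero).  Note the printed definition implies values ≥ 1 whenever the
    terminal interval or any later ISI exceeds the first; empirically
    reported values below 1 are inconsistent with this formula — the formula
    is implemented as stated and the discrepancy is documented rather than
    silently inverted.
    """
    st = np.sort(np.asarray(spike_times, dtype=float))
    if st.size < 2:
        return None
    isis = np.diff(st)
    if isis[0] <= 0:
        raise ValueError("coincident spikes: first inter-spike interval is zero")
    intervals = np.append(isis, step_end - st[-1])
    return float(np.max(intervals) / isis[0])


def measure_intrinsic(
    ss: SweepSet,
    r_current: float = -100.0,
    spike_threshold: float = 0.0,
) -> IntrinsicProperties:
    """Full property panel for one cell from its sweep set.

    R_N, τ and sag come from the ``r_current`` (−100 pA) sweep; the
    accommodation index from the highest-current suprathreshold sweep.
    """
    p = ss.protocol
    hyp = ss.sweep_at(r_current)
    rmp = measure_rmp(hyp, ss.fs, p.step_start)
    r_n = input_resistance(hyp, ss.fs, r_current, p.step_start, p.step_dur, rmp=rmp)
    tau = fit_tau(hyp, ss.fs, p.step_start)
    sag_v, sag_pct = sag_measures(hyp, ss.fs, p.step_start, p.step_dur, rmp=rmp)
    acc = None
    step_window = (p.step_start, p.step_start + p.step_dur)
    for i in np.argsort(p.currents)[::-1]:
        spikes = detect_spikes(ss.sweeps[i], ss.fs, spike_threshold, window=step_window)
        if spikes.size >= 2:
            acc = accommodation_index(spikes, step_window[1])
            break
    return IntrinsicProperties(rmp, r_n, tau, sag_v, sag_pct, acc)


def io_curve(ss: SweepSet, spike_threshold: float = 0.0) -> pd.DataFrame:
    """Spike count per injected current for one cell."""
    p = ss.protocol
    win = (p.step_start, p.step_start + p.step_dur)
    rows = [
        {
            "current": c,
            "n_spikes": detect_spikes(ss.sweeps[i], ss.fs, spike_threshold, window=win).size,
        }
        for i, c in enumerate(p.currents)
    ]
    return pd.DataFrame(rows)


@dataclass
class AncovaResult:
    """Slope-then-intercept comparison of two input–output curves."""

    f_slope: float
    p_slope: float
    f_intercept: float
    p_intercept: float
    slopes: dict = field(default_factory=dict)
    alpha: float = 0.05

    @property
    def slopes_differ(self) -> bool:
        return self.p_slope < self.alpha


def compare_io(
    group_a: pd.DataFrame, group_b: pd.DataFrame, alpha: float = 0.05
) -> AncovaResult:
    """Linear regression followed by ANCOVA on two groups of I-O curves.

    Each input frame holds columns ``cell, current, n_spikes`` for ≥ 2 cells
    on a shared current grid.  Slopes are compared first (current × group
    interaction F-test); given parallel slopes, intercepts are compared by
    the group main effect in the additive model.
    """
    for name, g in (("a", group_a), ("b", group_b)):
        if g["cell"].nunique() < 2:
            raise ValueError(f"group {name} needs >= 2 cells")
        if g["current"].nunique() < 2:
            raise ValueError("current grid must contain >= 2 levels")
    grid_a, grid_b = set(group_a["current"]), set(group_b["current"])
    if not grid_a & grid_b:
        raise ValueError("groups have disjoint current grids")
    df = pd.concat(
        [group_a.assign(group="a"), group_b.assign(group="b")], ignore_index=True
    )
    df = df[df["current"].isin(grid_a & grid_b)]
    full = smf.ols("n_spikes ~ current * C(group)", data=df).fit()
    add = smf.ols("n_spikes ~ current + C(group)", data=df).fit()
    tab_full = anova_lm(full, typ=2)
    tab_add = anova_lm(add, typ=2)
    inter = tab_full.loc["current:C(group)"]
    grp = tab_add.loc["C(group)"]
    slopes = {
        "a": full.params["current"],
        "b": full.params["current"] + full.params["current:C(group)[T.b]"],
    }
    return AncovaResult(
        f_slope=float(inter["F"]),
        p_slope=float(inter["PR(>F)"]),
        f_intercept=float(grp["F"]),
        p_intercept=float(grp["PR(>F)"]),
        slopes=slopes,
        alpha=alpha,
    )
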