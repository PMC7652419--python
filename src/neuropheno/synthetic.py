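"""Ground-truth synthetic data for every stage of the pipeline.

Each generator emulates one input class of the study — isotopomer panels,
current-step voltage sweeps, shot-noise postsynaptic-current traces,
startle trial tables, arena trajectories, and qPCR Ct tables — from a
single :class:`GroundTruth` parameter set, so that every downstream
analysis can be validated against known programmed values:

* at zero noise, each generator composed with its matched analysis
  operation recovers the programmed parameters exactly (to numerical
  tolerance);
* under noise, recovery is unbiased and tightens as n grows;
* a fixed seed reproduces every dataset bit-identically.  A single global
  seed expands into independent per-generator substreams through fixed
  stream offsets.

Default parameter values are chosen to mirror the measured scales of the
study system (adult CA1 pyramidal neurons, hippocampal metabolite pools,
rodent startle and open-field behaviour); see docs/methods.md for the
provenance of each default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import intrinsic as intr
from .events import EventSeries
from .flux import ENRICH_POSITIONS, FLUX_CONSTANTS, IsotopomerSample

__all__ = [
    "FluxTargets",
    "CellParams",
    "EventParams",
    "PpiParams",
    "TrackParams",
    "QpcrParams",
    "GroundTruth",
    "gen_isotopomer_dataset",
    "gen_step_sweeps",
    "gen_psc_trace",
    "gen_startle_trials",
    "gen_track",
    "gen_qpcr",
    "DEFAULT_TEMPLATE",
]

# Fixed substream offsets: one independent random stream per generator.
_STREAMS = {
    "isotopomer": 0,
    "sweeps": 1,
    "psc": 2,
    "startle": 3,
    "track": 4,
    "qpcr": 5,
}


@dataclass(frozen=True)
class FluxTargets:
    """Programmed glucose-oxidation rates and the fixed sample context.

    The default rates are the worked-example values produced by the
    printed formulas on hippocampal vehicle-condition pool concentrations
    (Glu 13.5, GABA 3.6, Gln 5.0, Asp 2.3 µmol/g) with a 50% plasma
    glucose-C1 enrichment.
    """

    mr_glu: float = 0.347556
    mr_gaba: float = 0.117156
    mr_total: float = 0.5854
    conc: dict = field(
        default_factory=lambda: {"glu": 13.5, "gaba": 3.6, "asp": 2.3, "gln": 5.0}
    )
    glc_c1: float = 50.0

    def __post_init__(self) -> None:
        for name in ("mr_glu", "mr_gaba", "mr_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative target flux {name}")
        if self.glc_c1 <= 0:
            raise ValueError("glc_c1 must be > 0")


@dataclass(frozen=True)
class CellParams:
    """Intrinsic-property ground truth (adult CA1 pyramidal scale)."""

    rmp_mv: float = -62.3
    r_n_mohm: float = 195.0
    tau_ms: float = 19.0
    sag_mv: float = 4.3  # magnitude of peak-minus-steady-state at −100 pA
    accommodation: float = 1.3  # geometric ISI growth ratio, >= 1
    rheobase_pa: float = 50.0
    sag_onset_s: float = 0.12  # sag component delay after step onset
    sag_tau_s: float = 0.06  # sag relaxation time constant

    def __post_init__(self) -> None:
        if self.r_n_mohm <= 0 or self.tau_ms <= 0:
            raise ValueError("resistance and time constant must be > 0")
        if self.sag_mv < 0 or self.accommodation < 1:
            raise ValueError("sag must be >= 0 and accommodation ratio >= 1")


@dataclass(frozen=True)
class EventParams:
    """Spontaneous-event ground truth: Poisson rate, log-normal amplitude
    body, heavy-tail mixture, and difference-of-exponentials kernel."""

    rate_hz: float = 2.0
    amp_median_pa: float = 30.0
    amp_sigma: float = 0.35  # log-normal shape
    tail_frac: float = 0.02  # mixture weight of the large-amplitude tail
    tail_cutoff_pa: float = 100.0  # tail support starts here
    tail_scale_pa: float = 50.0  # exponential excess above the cutoff
    rise_ms: float = 1.5
    decay_ms: float = 6.0

    def __post_init__(self) -> None:
        if not 0 <= self.tail_frac <= 1:
            raise ValueError("tail_frac must lie in [0, 1]")
        if self.decay_ms <= self.rise_ms:
            raise ValueError("kernel decay must exceed rise")
        if min(self.rate_hz, self.amp_median_pa, self.rise_ms) <= 0:
            raise ValueError("rate, amplitude and kernel times must be > 0")


@dataclass(frozen=True)
class PpiParams:
    """Basal startle mean and per-prepulse-level attenuation fractions."""

    basal: float = 100.0
    attenuation: dict = field(default_factory=lambda: {4: 0.30, 8: 0.45, 16: 0.60})

    def __post_init__(self) -> None:
        if self.basal < 0:
            raise ValueError("basal startle mean must be >= 0")
        for lvl, a in self.attenuation.items():
            if not 0 <= a <= 1:
                raise ValueError(f"attenuation at +{lvl} dB must lie in [0, 1]")


@dataclass(frozen=True)
class TrackParams:
    """Correlated-random-walk parameters (cm, per-sample)."""

    step_scale_cm: float = 0.25  # Rayleigh scale of per-sample step length
    persistence: float = 0.6  # 0 = isotropic, → 1 = straight-line
    avoidance_weight: float = 1.0  # Metropolis penalty inside the anxiogenic zone

    def __post_init__(self) -> None:
        if self.step_scale_cm <= 0 or not 0 <= self.persistence < 1:
            raise ValueError("step scale must be > 0 and persistence in [0, 1)")


_DEFAULT_PANEL = {
    "Bdnf": 0.8, "Gad1": 0.0, "Gad2": 0.0, "Pvalb": -0.6, "Sst": -0.4,
    "Npy": 0.0, "Calb1": 0.0, "Calb2": 0.0, "Grin1": 0.0, "Grin2a": 0.0,
    "Grin2b": 0.0, "Gria1": 0.0, "Camk2a": 0.0, "Creb1": 0.0, "Crh": 0.0,
    "Crhr1": 0.5, "Nr3c1": 0.0,
}


@dataclass(frozen=True)
class QpcrParams:
    """Per-gene log₂ fold changes and Ct noise levels."""

    log2_fc: dict = field(default_factory=lambda: dict(_DEFAULT_PANEL))
    housekeeping: str = "Gapdh"
    ct_sd: float = 0.3
    subject_sd: float = 0.2  # per-subject global Ct offset (pipetting)
    base_ct: float = 24.0
    housekeeping_ct: float = 18.0

    def __post_init__(self) -> None:
        if self.ct_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.housekeeping in self.log2_fc and self.log2_fc[self.housekeeping] != 0:
            raise ValueError("housekeeping gene must have zero programmed effect")


@dataclass(frozen=True)
class GroundTruth:
    """The full programmed parameter set plus the global seed."""

    flux: FluxTargets = field(default_factory=FluxTargets)
    cell: CellParams = field(default_factory=CellParams)
    events: EventParams = field(default_factory=EventParams)
    ppi: PpiParams = field(default_factory=PpiParams)
    track: TrackParams = field(default_factory=TrackParams)
    qpcr: QpcrParams = field(default_factory=QpcrParams)
    seed: int = 0

    def rng(self, stream: str) -> np.random.Generator:
        """Independent substream for one generator (fixed offsets)."""
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def with_seed(self, seed: int) -> "GroundTruth":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# isotopomer panels

#: Relative position weights before scaling (percent-scale magnitudes).
DEFAULT_TEMPLATE = {
    "glu_c4": 20.0, "glu_c3": 5.0, "gaba_c2": 10.0,
    "gaba_c4": 8.0, "asp_c3": 8.0, "gln_c4": 10.0,
}


def _solve_enrichments(targets: FluxTargets, template: dict) -> dict[str, float]:
    """Scale the template per metabolite group so the three linear rate
    formulas hit the programmed targets exactly.

    The glutamate and aspartate positions share one scale fixed by MR_Glu;
    the GABA positions then absorb MR_GABA and the glutamine position
    MR_Total.  Raises when no nonnegative scaling exists.
    """
    w = {p: float(template.get(p, 0.0)) for p in ENRICH_POSITIONS}
    if any(v < 0 for v in w.values()):
        raise ValueError("template weights must be nonnegative")
    if all(v == 0 for v in w.values()):
        raise ValueError("template is all-zero: no scaling can reach the targets")
    c = targets.conc
    k = FLUX_CONSTANTS.prefactor * FLUX_CONSTANTS.scale / targets.glc_c1
    g0 = c["glu"] * (w["glu_c4"] + 2 * w["glu_c3"])
    a0 = c["asp"] * 2 * w["asp_c3"]
    b0 = c["gaba"] * (w["gaba_c2"] + 2 * w["gaba_c4"])
    q0 = c["gln"] * w["gln_c4"]

    denom = FLUX_CONSTANTS.glu_coeff_in_glu * g0 + FLUX_CONSTANTS.asp_coeff * a0
    if targets.mr_glu > 0 and denom == 0:
        raise ValueError("template has no Glu/Asp weight but MR_Glu > 0")
    s1 = targets.mr_glu / (k * denom) if denom > 0 else 0.0
    g, a = s1 * g0, s1 * a0

    b_needed = targets.mr_gaba / k - FLUX_CONSTANTS.glu_coeff_in_gaba * g \
        - FLUX_CONSTANTS.asp_coeff * a
    if b_needed < -1e-9:
        raise ValueError("targets infeasible: MR_GABA below its Glu/Asp floor")
    if b_needed > 1e-12 and b0 == 0:
        raise ValueError("template has no GABA weight but MR_GABA requires it")
    s2 = max(b_needed, 0.0) / b0 if b0 > 0 else 0.0
    b = s2 * b0

    q_needed = targets.mr_total / k - g - b - a
    if q_needed < -1e-9:
        raise ValueError("targets infeasible: MR_Total below MR_Glu/MR_GABA floor")
    if q_needed > 1e-12 and q0 == 0:
        raise ValueError("template has no Gln weight but MR_Total requires it")
    s3 = max(q_needed, 0.0) / q0 if q0 > 0 else 0.0

    scale = {"glu_c4": s1, "glu_c3": s1, "asp_c3": s1,
             "gaba_c2": s2, "gaba_c4": s2, "gln_c4": s3}
    enrich = {p: w[p] * scale[p] for p in ENRICH_POSITIONS}
    bad = {p: v for p, v in enrich.items() if v > 100.0}
    if bad:
        raise ValueError(f"solved enrichments exceed 100 percent: {bad}")
    return enrich


def gen_isotopomer_dataset(
    truth: GroundTruth,
    template: dict | None = None,
    noise_cv: float = 0.0,
    n: int = 1,
    tissue: str = "hippocampus",
) -> list[IsotopomerSample]:
    """Samples whose flux formulas return the programmed targets.

    The template's relative position weights are scaled (per metabolite
    group) so the linear rate formulas evaluate exactly to
    ``truth.flux``; with ``noise_cv > 0`` each position then receives
    independent multiplicative Gaussian noise (mean 1, CV ``noise_cv``),
    leaving the recovered fluxes unbiased.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    base = _solve_enrichments(truth.flux, template or DEFAULT_TEMPLATE)
    rng = truth.rng("isotopomer")
    out = []
    for i in range(n):
        if noise_cv > 0:
            e = {
                p: float(np.clip(v * (1 + noise_cv * rng.standard_normal()), 0, 100))
                for p, v in base.items()
            }
        else:
            e = dict(base)
        out.append(
            IsotopomerSample(
                conc=dict(truth.flux.conc),
                enrich=e,
                glc_c1=truth.flux.glc_c1,
                tissue=tissue,
                subject=f"s{i:03d}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# current-step sweeps


def _sag_shape(t: np.ndarray, cell: CellParams) -> np.ndarray:
    """Unit sag relaxation: delayed opposing slow exponential.

    Zero until ``sag_onset_s`` after step onset, then saturating with
    ``sag_tau_s``.  The delay (placed after the fast charging transient
    has settled) keeps the charging phase a pure single exponential, so
    the membrane time constant remains identifiable from the same sweep.
    """
    s = np.zeros_like(t)
    m = t > cell.sag_onset_s
    s[m] = 1.0 - np.exp(-(t[m] - cell.sag_onset_s) / cell.sag_tau_s)
    return s


def _calibrate_sag(
    cell: CellParams, protocol: intr.StepProtocol, fs: float, i_ref: float
) -> tuple[float, float]:
    """Deflection and sag-component amplitudes (mV) at the reference current.

    Solves for (D_fast, A_sag) such that, on the exact sample grid with the
    standard measurement windows, the steady-state deflection yields the
    programmed input resistance and peak-minus-steady-state equals the
    programmed sag voltage.
    """
    n_step = int(round(protocol.step_dur * fs))
    t = np.arange(n_step) / fs
    fast = 1.0 - np.exp(-t / (cell.tau_ms / 1000.0))
    sagsh = _sag_shape(t, cell)
    ss_lo = int(round((1.0 - intr.SS_FRAC) * n_step))
    pk_hi = int(round(intr.PEAK_FRAC * n_step))
    target_ss = i_ref * cell.r_n_mohm / 1000.0  # mV, negative for I < 0
    target_sag = cell.sag_mv  # |peak - ss|

    a = 0.0 if target_sag == 0 else target_sag  # initial guess
    d = target_ss
    for _ in range(60):
        dev = d * fast + a * sagsh
        ss = float(np.mean(dev[ss_lo:]))
        peak = float(np.min(dev[:pk_hi]))
        sag_meas = ss - peak  # positive magnitude
        # linear corrections: ss depends on both amplitudes
        d_new = d + (target_ss - ss)
        if target_sag == 0:
            a_new = 0.0
        else:
            a_new = a + (target_sag - sag_meas)
        if abs(d_new - d) < 1e-12 and abs(a_new - a) < 1e-12:
            d, a = d_new, a_new
            break
        d, a = d_new, a_new
    return d, a


def _spike_template(fs: float) -> np.ndarray:
    """Stereotyped spike: one-sample rise to +30 mV above a −70 base,
    fast decay, small afterhyperpolarization recovering over 20 ms."""
    n_decay = int(round(0.0015 * fs))
    n_ahp = int(round(0.02 * fs))
    peak = 95.0  # mV above baseline: clears a 0 mV threshold from rest
    decay = peak * np.exp(-np.arange(n_decay) / (0.0004 * fs))
    ahp = -4.0 * (1 - np.arange(n_ahp) / n_ahp)
    return np.concatenate([decay, ahp])


def _spike_times_for(cell: CellParams, protocol: intr.StepProtocol, current: float) -> np.ndarray:
    """Programmed spike times: geometric ISI growth within the step."""
    if current < cell.rheobase_pa:
        return np.array([])
    overdrive = current - cell.rheobase_pa + 10.0
    isi0 = 2.0 / overdrive  # s; 2000 ms·pA drive constant
    t = protocol.step_start + 0.02
    end = protocol.step_start + protocol.step_dur
    times = []
    isi = isi0
    while t < end - 0.002:
        times.append(t)
        t += isi
        isi *= cell.accommodation
    return np.array(times)


def gen_step_sweeps(
    truth: GroundTruth,
    protocol: intr.StepProtocol | None = None,
    fs: float = 20000.0,
    noise_sd: float = 0.0,
) -> intr.SweepSet:
    """Voltage sweeps under the stepped protocol, with ground-truth spikes.

    Subthreshold responses follow RMP + I·R_N·(1 − e^(−t/τ)); the −100 pA
    class of hyperpolarizing sweeps additionally carries an opposing,
    delayed slow-exponential sag component calibrated so that the standard
    measurement windows recover the programmed R_N and sag voltage
    exactly.  Suprathreshold sweeps superimpose stereotyped spikes at
    programmed times whose inter-spike intervals grow geometrically by the
    accommodation ratio; the programmed times are returned in
    ``SweepSet.spike_times``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if fs < 10000:
        raise ValueError("sampling rate must be >= 10 kHz")
    protocol = protocol or intr.StepProtocol()
    cell = truth.cell
    rng = truth.rng("sweeps")
    n = int(round(protocol.sweep_dur * fs))
    n_step = int(round(protocol.step_dur * fs))
    i0 = int(round(protocol.step_start * fs))
    t_step = np.arange(n_step) / fs
    fast = 1.0 - np.exp(-t_step / (cell.tau_ms / 1000.0))
    sagsh = _sag_shape(t_step, cell)
    i_ref = min(protocol.currents)  # the −100 pA reference sweep
    d_ref, a_ref = _calibrate_sag(cell, protocol, fs, i_ref)

    template = _spike_template(fs)
    sweeps = np.full((len(protocol.currents), n), cell.rmp_mv)
    all_spikes: list[np.ndarray] = []
    for k, current in enumerate(protocol.currents):
        dev = np.zeros(n_step)
        spikes = np.array([])
        if current < 0:
            # scale the calibrated reference waveform linearly with current
            scale = current / i_ref
            dev = scale * (d_ref * fast + a_ref * sagsh)
        elif current < cell.rheobase_pa:
            dev = current * cell.r_n_mohm / 1000.0 * fast
        else:
            depol = min(current * cell.r_n_mohm / 1000.0, 15.0)
            dev = depol * fast
            spikes = _spike_times_for(cell, protocol, current)
        sweeps[k, i0:i0 + n_step] += dev
        # after-step relaxation back to rest
        tail = np.arange(n - i0 - n_step) / fs
        sweeps[k, i0 + n_step:] += dev[-1] * np.exp(-tail / (cell.tau_ms / 1000.0))
        for st in spikes:
            j = int(round(st * fs))
            seg = template[: n - j]
            sweeps[k, j:j + seg.size] += seg
        all_spikes.append(spikes)
    if noise_sd > 0:
        sweeps = sweeps + rng.normal(0.0, noise_sd, sweeps.shape)
    return intr.SweepSet(sweeps, protocol, fs, spike_times=all_spikes)


# ---------------------------------------------------------------------------
# postsynaptic-current traces


def _psc_kernel(ev: EventParams, fs: float) -> np.ndarray:
    """Difference-of-exponentials kernel normalised to unit peak."""
    tr, td = ev.rise_ms / 1000.0, ev.decay_ms / 1000.0
    n = int(round(8 * td * fs))
    t = np.arange(n) / fs
    k = np.exp(-t / td) - np.exp(-t / tr)
    return k / k.max()


def _draw_amplitude(ev: EventParams, rng: np.random.Generator) -> float:
    if rng.random() < ev.tail_frac:
        return ev.tail_cutoff_pa + rng.exponential(ev.tail_scale_pa)
    return float(ev.amp_median_pa * np.exp(ev.amp_sigma * rng.standard_normal()))


def gen_psc_trace(
    truth: GroundTruth,
    duration: float = 150.0,
    fs: float = 20000.0,
    noise_sd: float = 5.0,
    compound_prob: float = 0.0,
) -> tuple[np.ndarray, EventSeries]:
    """Inward shot-noise current trace plus its ground-truth event list.

    Events arrive as a Poisson train; each deflects the holding current
    negative with a difference-of-exponentials time course.  Amplitudes
    come from a log-normal body mixed (with probability ``tail_frac``)
    with a heavy tail supported above ``tail_cutoff_pa``.  With
    probability ``compound_prob`` an event is a compound burst of several
    summed sub-events, recorded in the ground truth as a single event at
    the compound peak — matching how compound negative peaks are counted
    in amplitude distributions.
    """
    ev = truth.events
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if fs * ev.rise_ms / 1000.0 < 5:
        raise ValueError("sampling rate resolves < 5 samples per kernel rise")
    expected = duration * ev.rate_hz
    if expected < 200:
        warnings.warn(
            f"expected event count {expected:.0f} < 200: too short for the "
            "event-count protocol rule",
            UserWarning,
            stacklevel=2,
        )
    rng = truth.rng("psc")
    n = int(round(duration * fs))
    kernel = _psc_kernel(ev, fs)
    trace = np.zeros(n)

    # Poisson onsets
    gaps = rng.exponential(1.0 / ev.rate_hz, size=int(expected * 2 + 50))
    onsets = np.cumsum(gaps)
    onsets = onsets[onsets < duration - 10 * ev.decay_ms / 1000.0]

    truth_onsets: list[float] = []
    truth_amps: list[float] = []
    for t0 in onsets:
        if compound_prob > 0 and rng.random() < compound_prob:
            n_sub = 2 + rng.poisson(1.0)
            offsets = np.concatenate([[0.0], np.sort(rng.uniform(0.001, 0.012, n_sub - 1))])
        else:
            offsets = np.array([0.0])
        amps = np.array([_draw_amplitude(ev, rng) for _ in offsets])
        # clean burst waveform for the ground-truth compound amplitude
        burst_n = kernel.size + int(round(offsets[-1] * fs))
        burst = np.zeros(burst_n)
        for off, a in zip(offsets, amps):
            j = int(round(off * fs))
            seg = kernel[: burst_n - j]
            burst[j:j + seg.size] += a * seg
        i0 = int(round(t0 * fs))
        seg = burst[: n - i0]
        trace[i0:i0 + seg.size] -= seg
        truth_onsets.append(i0 / fs)
        truth_amps.append(float(burst.max()))
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, n)

    t_arr = np.asarray(truth_onsets)
    a_arr = np.asarray(truth_amps)
    keep = np.ones(t_arr.size, dtype=bool)
    keep[1:] = np.diff(t_arr) > 0
    return trace, EventSeries(t_arr[keep], a_arr[keep], condition="sPSC",
                              duration=duration)


# ---------------------------------------------------------------------------
# startle trials


def gen_startle_trials(
    truth: GroundTruth,
    n_tone: int = 10,
    n_prepulse: int = 5,
    cv: float = 0.1,
) -> pd.DataFrame:
    """Two-block startle trial table with programmed attenuation.

    Block 1: ``n_tone`` tone-only pulses (basal startle).  Block 2:
    ``n_tone`` tone-only trials interleaved with ``n_prepulse`` trials per
    prepulse level, attenuated by the programmed per-level fraction.
    Multiplicative Gaussian noise with coefficient of variation ``cv``
    (amplitudes floored at zero).
    """
    if n_tone < 1 or n_prepulse < 1:
        raise ValueError("trial counts must be >= 1")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    p = truth.ppi
    rng = truth.rng("startle")

    def noisy(mean: float, size: int) -> np.ndarray:
        if cv == 0:
            return np.full(size, mean)
        return np.maximum(mean * (1 + cv * rng.standard_normal(size)), 0.0)

    rows = []
    for amp in noisy(p.basal, n_tone):
        rows.append({"condition": bhv.TONE_ONLY, "amplitude": amp, "block": 1})
    for amp in noisy(p.basal, n_tone):
        rows.append({"condition": bhv.TONE_ONLY, "amplitude": amp, "block": 2})
    for level, atten in p.attenuation.items():
        for amp in noisy(p.basal * (1 - atten), n_prepulse):
            rows.append(
                {"condition": bhv.prepulse_condition(level), "amplitude": amp, "block": 2}
            )
    df = pd.DataFrame(rows)
    df.insert(0, "trial", np.arange(len(df)))
    return df


# ---------------------------------------------------------------------------
# arena trajectories

_ANXIOGENIC_ZONE = {"open_field": "center", "plus_maze": "open_arms",
                    "light_dark": "light"}
_MAX_AVOIDANCE = 50.0


def gen_track(
    truth: GroundTruth,
    arena: bhv.Arena | None = None,
    duration: float = 600.0,
    fs: float = 25.0,
) -> bhv.Track:
    """Correlated random walk confined to the arena.

    Per-sample steps have Rayleigh lengths and von-Mises-like heading
    persistence; proposals leaving the arena are rejected (the animal
    stays), and proposals entering the arena's anxiogenic zone are
    accepted with probability e^(−w) where w is the avoidance weight
    (clamped at 50, effectively never entering).  With zero avoidance and
    zero persistence this is a Metropolis sampler of the uniform
    distribution on the arena, so long-run zone occupancy equals the zone
    area fraction.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    arena = arena or bhv.open_field_arena()
    if arena.boundary.area <= 0:
        raise ValueError("zero-area arena")
    p = truth.track
    w = min(p.avoidance_weight, _MAX_AVOIDANCE)
    zone_name = _ANXIOGENIC_ZONE.get(arena.name)
    zone = arena.zones.get(zone_name) if zone_name else None
    rng = truth.rng("track")
    n = int(round(duration * fs))

    # start uniformly in the arena (outside the avoided zone when w > 0)
    minx, miny, maxx, maxy = arena.boundary.bounds
    import shapely as _shp

    while True:
        x0 = rng.uniform(minx, maxx)
        y0 = rng.uniform(miny, maxy)
        if not _shp.contains_xy(arena.boundary, x0, y0):
            continue
        if w > 0 and zone is not None and _shp.contains_xy(zone, x0, y0):
            continue
        break

    lengths = rng.rayleigh(p.step_scale_cm, n)
    if p.persistence == 0:
        # fresh uniform headings: a symmetric proposal, so the Metropolis
        # chain has the exactly uniform stationary law on the arena
        turns = rng.uniform(-np.pi, np.pi, n)
    else:
        turns = rng.normal(0.0, (1.0 - p.persistence) * np.pi, n)
    accept_u = rng.random(n)
    xs = np.empty(n)
    ys = np.empty(n)
    x, y = x0, y0
    theta = rng.uniform(0, 2 * np.pi)
    in_zone = bool(zone is not None and _shp.contains_xy(zone, x, y))
    for i in range(n):
        theta = theta + turns[i]
        px = x + lengths[i] * np.cos(theta)
        py = y + lengths[i] * np.sin(theta)
        if _shp.contains_xy(arena.boundary, px, py):
            p_in = bool(zone is not None and _shp.contains_xy(zone, px, py))
            du = w * (int(p_in) - int(in_zone))
            if du <= 0 or accept_u[i] < np.exp(-du):
                x, y, in_zone = px, py, p_in
        xs[i] = x
        ys[i] = y
    t = np.arange(n) / fs
    return bhv.Track(t, xs, ys, fs, arena)


# ---------------------------------------------------------------------------
# qPCR Ct tables


def gen_qpcr(
    truth: GroundTruth,
    genes: list[str] | None = None,
    n_per_group: int = 11,
    groups: tuple[str, str] = ("vehicle", "treated"),
) -> pd.DataFrame:
    """Ct table with programmed log₂ fold changes in the treated group.

    Ct = gene baseline − log₂(fold change)·[treated] + per-subject offset
    + Gaussian noise.  The housekeeping gene is always included with zero
    programmed effect and shares each subject's global offset, so ΔΔCt
    analysis of a noise-free table returns the programmed fold changes
    exactly.
    """
    q = truth.qpcr
    if genes is None:
        genes = list(q.log2_fc)
    else:
        if q.housekeeping in genes:
            genes = [g for g in genes if g != q.housekeeping]
        missing = [g for g in genes if g not in q.log2_fc]
        if missing:
            raise ValueError(f"no programmed fold change for genes: {missing}")
    if not genes:
        raise ValueError("need at least one target gene besides housekeeping")
    rng = truth.rng("qpcr")
    rows = []
    for gi, group in enumerate(groups):
        treated = gi == 1
        for s in range(n_per_group):
            subject = f"{group}_{s:02d}"
            offset = rng.normal(0.0, q.subject_sd) if q.subject_sd > 0 else 0.0
            for gene in [q.housekeeping] + genes:
                base = q.housekeeping_ct if gene == q.housekeeping else q.base_ct
                effect = q.log2_fc.get(gene, 0.0) if gene != q.housekeeping else 0.0
                ct = base - effect * treated + offset
                if q.ct_sd > 0:
                    ct += rng.normal(0.0, q.ct_sd)
                rows.append(
                    {"subject": subject, "group": group, "gene": gene, "ct": ct}
                )
    return pd.DataFrame(rows)
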