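# Methods

This note records the models, parameter choices and numerical decisions
behind each module, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Flux model

The three glucose-oxidation rates are fixed linear combinations of pool
concentrations and position-specific ¹³C enrichments (see README for the
formulas). They are evaluated verbatim, with three points fixed by design:

* **Units.** Enrichments and Glc_C1 enter in percent; because the formulas
  divide by Glc_C1, feeding fraction-scaled enrichments with percent Glc_C1
  silently rescales every rate by 100. `IsotopomerSample` therefore warns
  when all enrichments are below 1. Output is reported as
  µmol·g⁻¹·min⁻¹; the dimensional role of the 1/10 prefactor is carried
  as printed and not re-derived.
* **Natural abundance.** The 1.1% ¹³C natural abundance is subtracted from
  tissue enrichments (floored at zero) when samples are built from tables
  (`samples_from_table(correct_na=True)`), and never from plasma Glc_C1,
  whose satellite-area measurement already isolates the ¹³C-coupled signal.
  The switch is exposed because the source procedure is ambiguous on this
  point.
* **The glutamine term** of MR_Total is [Gln]·Gln_C4 (the bracketing in the
  printed formula is ambiguous; no alternative reading is supported), and
  the aspartate term of MR_Total carries no 0.42 coefficient. Together with
  0.82 + 0.02 < 1 this guarantees MR_Total ≥ MR_Glu + MR_GABA on
  nonnegative inputs, which the tests assert on randomized samples.
* `conc_from_reference` exposes an explicit `proton_ratio` (metabolite
  protons at the integrated resonance relative to glycine's, default 1)
  because per-proton normalisation is not stated in the source procedure;
  the default makes the assumption visible and overridable.

The matching generator inverts the linear system: given target rates, the
enrichment template (relative weights per labelled position) is scaled per
metabolite group — glutamate/aspartate positions by MR_Glu, then GABA
positions by the MR_GABA residual, then Gln_C4 by the MR_Total residual —
so zero-noise panels reproduce the targets to machine precision.
Infeasible target triples (e.g. MR_Total below the floor implied by the
component rates) are rejected rather than clipped. Multiplicative Gaussian
noise (mean 1) per position keeps noisy recovery unbiased because the
formulas are linear in the enrichments.

## Current-step sweeps and intrinsic properties

Measurement conventions (all configurable): baseline = 100 ms before step
onset; steady state = last 20% of the step; sag peak search = first 40% of
the step; τ fit window = 100 ms from onset with a free-asymptote single
exponential, initial guess from the 63% crossing; spike threshold 0 mV with
a 2 ms refractory. The sag-percent denominator is the peak deflection from
rest (the reported "Sag (%)" is not defined in the source; the alternative
steady-state denominator is available via the function arguments).

The generator's subthreshold response is RMP + I·R_N·(1 − e^(−t/τ)). The
sag of hyperpolarizing sweeps is an additive opposing slow exponential
(relaxation time constant 60 ms) whose onset is *delayed* to 120 ms after
step onset — i.e. after the fast charging transient has settled. The delay
is a deliberate modelling choice: with a sag component active from t = 0
the charging phase is no longer a single exponential and the membrane time
constant cannot be recovered within 1% from the same −100 pA sweep that the
measurement procedure prescribes; physiologically, h-current activation is
indeed slow relative to the membrane charge. The two amplitudes (fast
deflection, sag component) are calibrated by fixed-point iteration on the
exact sample grid so that the standard windows return the programmed R_N
and sag voltage to machine precision; other hyperpolarizing currents scale
this calibrated waveform linearly.

Suprathreshold sweeps superimpose stereotyped spikes (one-sample rise, fast
decay, small AHP) at programmed times: the first ISI shrinks with drive
(isi₀ = 2 s·pA/(I − rheobase + 10 pA)) and successive ISIs grow
geometrically by the accommodation ratio (default 1.3), so spike counts
rise with current and the accommodation index has a closed-form expected
value. The spike waveform is a marker, not a conductance model — spike
*shape* analytics are out of scope.

The printed accommodation-index formula (max ISI including the terminal
interval, over the first ISI) implies values ≥ 1 for adapting trains,
whereas empirical panels report 0.3–0.5; the formula is implemented as
printed and the discrepancy surfaced here rather than silently inverted.
With fewer than two spikes the index is reported missing (None), not zero.

Input–output curves are compared by OLS with a current × group interaction
(statsmodels): slopes first (interaction F), then intercepts from the
additive model given parallel slopes, at α = 0.05.

## Event detection and distribution comparison

The detector rectifies the trace per the configured polarity (inward
events at −70 mV holding are negative), smooths with a 2 ms moving average
for peak finding, enforces a 5 ms minimum separation (closer peaks merge
into one compound event scored at the compound peak, matching how compound
negative peaks are counted in amplitude distributions), takes the local
baseline as the median of the 20 ms before the peak, and reads the
amplitude from a 1 ms-smoothed trace divided by the known attenuation of
that window on the expected difference-of-exponentials event shape
(rise 1.5 ms, decay 6 ms) — this keeps amplitudes unbiased for
template-shaped events while suppressing the noise-inflated-maximum bias of
reading raw peaks. The onset is the last 20%-of-amplitude crossing before
the peak. These defaults are documented choices, not reconstructions of any
commercial tool's internals.

The generator produces a Poisson event train convolved with the same
kernel family plus Gaussian noise. Amplitudes are a two-component mixture:
a log-normal body (median 30 pA, σ = 0.35) and, with probability
`tail_frac`, a heavy tail supported strictly above the 100 pA cutoff
(cutoff + exponential excess, scale 50 pA). Placing the tail's support
above the cutoff makes the fraction of amplitudes exceeding the cutoff an
exact binomial quantity, which is what the tail-fraction validation
measures; the exponential excess also reproduces the rare > 250 pA events
at realistic frequency. Compound bursts (probability `compound_prob`) sum
2–4 sub-events within ~12 ms and enter the ground truth as a single event
at the compound peak. Defaults (2 Hz, SNR 5 at the default noise level)
reflect spontaneous PSC recordings in CA1 pyramidal neurons.

ECDFs are computed directly (right-continuous, reaching 1); the two-sample
K-S test is scipy's, exact for small samples and asymptotic for the large
event counts the protocol requires. The "at least 200 events from identical
temporal bins" rule is a hard filter with a per-cell count report. The
K-S normality screen uses parameters estimated from the same sample, which
is anti-conservative; this fidelity-to-procedure choice is logged, not
corrected.

## Behavioural scoring

Percent PPI uses tone-only trials from the block containing the prepulse
trials (configurable to all tone-only trials); basal startle is the
first-block tone-only mean. Negative PPI (facilitation) is allowed.

Arenas are shapely polygons: 40×40 cm open field with a 20×20 cm centre;
plus maze with 30×5 cm arms around a 5×5 cm centre square that belongs to
neither arm class; 25×25 / 15×25 cm light–dark box. Zone membership is by
the tracked centre point; an entry requires 2 consecutive samples on the
new side (debounce, configurable), and a track that starts inside a zone
counts an initial entry. Distance is the summed step length, with each
step assigned to the zone of its starting sample.

The track generator is a Metropolis-style correlated random walk: Rayleigh
step lengths, heading persistence, proposals leaving the arena rejected
(the animal stays), and proposals entering the arena's anxiogenic zone
(centre / open arms / light chamber) accepted with probability e^(−w).
With zero persistence the headings are drawn fresh and uniform, making the
proposal symmetric, so the chain's stationary law is exactly uniform on
the arena — zone occupancy then equals the zone's area fraction (25% for
the open-field centre), which anchors the occupancy validation; with
w → ∞ (clamped at 50) the zone is never entered. With persistence > 0 the
uniform law is only approximate, which is why the validation runs the
isotropic case. The generator emulates centroid tracking only: no body
orientation, rearing, grooming or velocity modulation, so passing tests
say nothing about pose-dependent measures.

## Statistics

t tests are scipy's (pooled df = n₁ + n₂ − 2; Welch–Satterthwaite df when
flagged, mirroring the reporting convention of applying Welch only where
noted). Both groups constant and equal gives t = 0, p = 1 by logged
convention. The two-stage FDR procedure is hand-implemented: BH at
q′ = q/(1+q), null count m₀ = m − r₁, then BH at q′·m/m₀, with the no-/all-
discovery edge cases short-circuited; the tests verify exact agreement
with an independently coded reference and with statsmodels'
two-stage implementation on random p-vectors, plus monotonicity in q and
all-null FDP control. ΔΔCt aggregates per-subject ΔCt by arithmetic mean
(geometric mean of relative quantities, the standard convention for the
method); fold change = 2^(−ΔΔCt). Per-subject ΔCt values are exposed for
downstream t tests, and per-subject global Ct shifts cancel exactly.

The qPCR generator programs Ct = baseline − log₂(fold)·[treated] +
subject offset + noise over a 17-gene hippocampal panel plus GAPDH
(zero programmed effect, required present); the subject offset is shared
across genes, exercising the housekeeping normalisation.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: 1000 randomized
samples for formula-oracle equivalence; n = 100 panels at 5% noise for
flux recovery; 50 seeds at 0.5 mV noise for τ; a 150 s, 20 kHz trace at
2 Hz and SNR 5 for detection scoring (±2 ms onset matching); ~5000 events
for the tail binomial; 2000 replicates (n = 50 per sample) for the K-S
null calibration; 200 one-minute tracks at 25 Hz for centre occupancy;
1000 random p-vectors for the FDR reference comparison. These sizes give
the Monte-Carlo intervals quoted in the tests while keeping the whole
suite inside a few minutes on one core.

## Limitations

* The pipeline starts from peak areas and trial tables: raw NMR FID
  processing, video tracking, densitometry and manual behavioural scoring
  are out of scope.
* Generators are phenomenological (threshold-marker spikes, additive sag,
  mixture amplitudes, Metropolis walks); they validate the *analysis*
  operations, not biophysical realism. Passing round trips demonstrate
  correctness of the measurement code under the generator's assumptions,
  not robustness to every artefact of real recordings (electrode drift,
  series-resistance changes, seal instability).
* The amplitude-distribution family of real spontaneous events is unknown;
  the log-normal + shifted-tail mixture is an artifact decision, flagged
  as such.
* Dynamic flux fitting of labelling time courses (and astrocytic V_cyc
  estimation) is not attempted; only the printed linear formulas are
  implemented.
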