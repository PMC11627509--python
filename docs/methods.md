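# Methods

## The pitch-class circle

All stimuli are Shepard tones: sums of equal-amplitude, octave-spaced
sinusoids with per-trial random phases and 5 ms sinusoidal gates, rendered
over a configurable audible band (default 30 Hz–16 kHz). A tone is labelled
by its pitch class φ ∈ [0, 12) semitones relative to the 440 Hz anchor;
pitch class 12 is identical to 0, so every comparison is circular and goes
through `shepadapt.circular`. Signed steps live in (−6, +6]; the half-octave
boundary is reported as +6 by a fixed convention that no percept label
depends on (percept labels are derived from the bias side, never from this
sign).

## Stimulus paradigms

**Biased pair.** Each condition crosses 4 base pitch classes {0, 3, 6, 9} ×
2 randomizations × bias lengths {5, 10} × bias direction {up, down}, giving
32 distinct bias sequences with 240 distinct bias tones. Bias pitch classes
are drawn uniformly and continuously from a 5 st range centered 3 st above
(up) or below (down) the first test tone, i.e. offsets in [0.5, 5.5] st on
the bias side. Tones last 0.1 s at a 0.15 s onset asynchrony; the ambiguous
pair (6 st separation) follows after a silent gap of 0.05, 0.2 or 0.5 s.
One `ToneSequence` is emitted per (bias sequence × gap): the same bias draw
is reused across gaps so that gap effects are measured on matched sequences.

**Biased tuning.** 154-tone sequences open with 15 lead-in tones from one of
four bias regions ([0–5], [3–8], [6–11], [9–2] st), then repeat groups of
5 bias tones plus one probe tone from the full octave discretized to 24
positions (0.5 st). The printed sequence arithmetic does not decompose
exactly into such groups, so sequences are truncated/padded to the
configured length and probe coverage is balanced across a region's sequence
set (every grid position occurs floor-or-ceil equally often). Both layout
parameters are configuration keys.

**Spectrogram.** Model stimuli are time × pitch-bin grids at 20 Hz (50 ms
frames) with 24 circular bins per octave — finer than a 12-bin
representation so that 0.5 st probes occupy distinct bins; the mid-level
sum normalizes by 1/n_bins accordingly. Each tone contributes amplitude 1 in
its nearest circular bin for the frames overlapping its on-time.

## Encoding models

**Tuning.** Each unit is a period-12 von Mises curve with best pitch class
φᵢ and width σᵢ (semitones), normalized to unit area (idealized non-dynamic
models) or unit peak (dynamic model layers). For σ = 1 st the half-height
halfwidth is ≈ 2.4 st.

**Non-dynamic adaptation variants** act on an idealized population (100
cells, equally spaced, area-one tuning) and an idealized bias profile
S_bias(φ) ∈ [0, 1] (5 st boxcar):

- *local*: R(S) = (1 − A₀·S_bias(S))·M(S). The whole population is scaled
  identically for a given test stimulus, so decoded pitch is exactly
  unchanged.
- *global*: per-cell scaling by the tuning/bias overlap. The printed overlap
  normalization (1/12 ∫ S_bias·M dφ) does not keep the coefficient within
  [0, A₀] for area-one curves, so the package uses the tuning-weighted mean
  of the bias profile, A = A₀·(∫S_bias·M / ∫M), which does exactly.
- *spread*: local depression at the synapses of a distributed mid-level
  layer; the cortical response integrates mid-level activity through
  connection strengths with per-connection adaptation. This variant both
  reduces tuning curves locally and repels decoding — the combination the
  other two variants each lack.

A₀ defaults to 0.8. Decoded shifts of the variants are always measured
against the *unadapted* decode of the same population, which removes the
population-vector decoder's small discretization bias (≈ 0.013 st for 100
cells) from the contrast.

**Dynamic model.** A two-layer rate model at 20 Hz: mid-level units
(J = 48, peak-one von Mises, width σ_mid = 0.85 st) read the spectrogram,
T_j(t) = (1/n_bins) Σ_φ M_j(φ)·S(t, φ); cortical cells filter the mid-level
trace through an SSTRF (5 lags × J) whose lag-0/1 columns carry the cell's
tuning over mid-unit best pitch classes (width σ_cortical, default 0.5 st;
cohort widths are lognormal with median ≈ 0.4 st so that measured Shepard
tuning halfwidths have a median of ~2.7 st, inside the narrow 2–3 st range
of well-tuned units). Directional cells add a late von Mises lobe (peak
0.25, width 1 st) at lags 3–4 (150–250 ms), centered 3 st below the best
pitch class for upward-preferring cells and above it for downward-preferring
ones (the offset is a configuration key; only "relatively higher/lower" is
constrained a priori).

Per-synapse depression follows

    A_ij ← clip( (A_ij + F_A·d_ij·(1 − A_ij)) · (1 − F_R), 0, A_max )

with drive d_ij the max-normalized SSTRF weight times the peak-normalized
mid-level activity, summed over lags (peak normalization keeps F_A a
meaningful fraction in [0, 1]). A literal reading of the update as
A·(1 − F_A·d)·(1 − F_R) can never grow from A = 0; the accumulation form
above reproduces the described behavior — drive pushes A toward saturation,
silence relaxes it geometrically with time constant 1/(20·F_R) s — and
reduces to pure recovery when d = 0. The literal variant is available behind
the `printed_update` flag for comparison. Rates are clipped at zero.

Spontaneous activity is transmitted through the same depressing synapses:
the baseline rate (2 Hz) is scaled by the weighted mean synaptic efficacy,
so spontaneous rates dip after a bias sequence and recover with the model's
recovery time constant — the basis of the recovery-fit analysis.

**Calibration.** F_R is fixed in closed form by the target recovery time
constant (1.2 s → F_R = 1 − e^(−1/24) ≈ 0.0408 per frame). The adaptation
gain F_A and the depression ceiling A_max are then jointly tuned so that the
population onset response over an L = 10 bias train decays with
τ ≈ 3.9 stimuli to a plateau ≈ 13% below the initial response. Both targets
cannot be met with a single gain: an uncapped depression that equilibrates
in ~4 stimuli is far deeper than 13%, so the ceiling (a typed model
parameter bounding A_ij) carries the depth target while the gain carries the
speed. The shipped defaults (F_A = 0.0624, A_max = 0.335) come from a
Nelder–Mead search against a deterministic reference simulation (662-cell
cohort marginals, 16-randomization L = 10 design, two independent stimulus
draws averaged) minimizing squared log-errors; `pipeline.calibrate`
re-derives them.

The build-up fit always excludes the first tone: it is the only tone without
a preceding stimulus, so the late SSTRF lobes of directional cells
contribute to every onset response except the first, producing an initial
buildup before the adaptive decay (recorded population PSTHs show the same
feature).

## Synthetic cohorts and trial noise

`emulate_recorded_cohort` draws 662 units by default: best pitch classes
equally spaced with jitter, lognormal widths and peak rates (median ≈ 20 Hz),
direction classes in thirds, and a Bernoulli 91% adapting flag
(non-adapting cells have their adaptation gain zeroed). Per-cell rate gains
scale model units so a cell's preferred isolated tone evokes its drawn peak
rate. Trial noise is Poisson on 50 ms bins, 10 repetitions; a rate mode
stores the noiseless rates for model-level analyses. Unit selection keeps
units that are auditory-driven (one-sided Wilcoxon of driven vs spontaneous
per-trial means) and Shepard-tuned (Kruskal–Wallis across 1 st pitch-class
groups, p < 0.05); both thresholds are deliberately uncritical. The cohort
generator emits the *selected* population directly; emulating a larger
recorded pool with sub-threshold units is out of scope.

What the generator does **not** emulate: inter-neuron noise correlations,
facilitating response types (the non-adapting 9% are flat, not
facilitating), spike-sorting artifacts, per-animal random effects, and
onset/sustained/offset response-shape diversity. Passing tests therefore
demonstrate internal consistency of the analysis chain and parameter
recovery under the modeled conditions, not quantitative agreement with any
recorded dataset; all effect sizes measured on recordings (decoded shifts
up to 0.8 st, 33–40% in-bias reductions, 88–95% percept-prediction
accuracies) are data-bound and serve only as calibration anchors or
sign/ordering constraints here.

## Decoding

The PCA circle decoder mean-centers the (stimuli × neurons) training matrix
and selects, among the top five principal components, the pair maximizing a
circular-fit score (resultant length of the angle-vs-pitch relation, both
orientations) — robust to a large component encoding sequence position.
Orientation is fixed so pitch increases counterclockwise. A coarse circle of
24 anchors is built from rank-ordered bins of n/24 training stimuli (exactly
10 for the 240-tone design, ties broken by stimulus index) and linearly
interpolated to a closed polyline at 0.05 st; a test response is projected
(centered with the *training* mean, scale not normalized) and takes the
pitch label of the nearest polyline point. The decoder is deliberately not
cross-validated: it is a reference frame for held-out test tones. The
population-vector decoder weights each neuron's unit complex vector by its
max-normalized rate and the inverse occurrence frequency of best pitch
classes (12-bin histogram with add-one smoothing); a near-zero resultant is
flagged undefined.

Bias-induced shifts are the signed circular deviation of decoded from true
pitch class, sign-flipped so positive points away from the bias center.
Decoding analyses of the *pair* run on the plain (nondirectional) model
cohort with deterministic rates: the repulsion, its growth with bias length
and its monotone decay across the gaps are model properties, and the
directional extension exists for the percept analyses, not the pitch
decoding.

## Directionality

SSTRFs are estimated by reverse correlation: ridge regression (leave-one-out
generalized cross-validation over a log-spaced grid) of 50 ms-binned
trial-mean responses on the z-normalized lagged one-hot stimulus history,
restricted to during-stimulus response bins. The DI sums the
previous-stimulus columns (lags 3–4; the pause lag between current and
previous tone is excluded, as is the half-octave tie bin) of the
max-normalized filter below minus above the lag-0 best pitch class; positive
DI marks upward-preferring cells. The unweighted sum is used, following the
printed formula rather than a distance-weighted variant.

The directional decoder weights each cell's activity by its DI and a
period-12 von Mises kernel (width 1.5 st, a configuration key with a
sensitivity sweep in the test suite) of the distance between the cell's
SSTRF center of mass and the tone. Percept labels are fixed rules: the first
tone's step is heard away from the bias side, the second tone's step bridges
the bias.

**Differential map and near-tone test.** For matched up/down-bias conditions
the per-cell difference "bias locally above the tone minus below" is binned
by DI and by the cell's pitch-class distance to the tone (both test tones
contribute). First-tone samples whose preceding bias tone started within the
SSTRF's 250 ms span (gap 0.05 s) are excluded: there the difference contains
a residual sensory transient through the late SSTRF lobes rather than the
adaptation state (the second tone is immune — its predecessor is the first
test tone, identical in both conditions). The near-tone test compares
per-cell mean differentials of ascending- vs descending-preferring cells
(|distance| ≤ 1.5 st) with a one-way ANOVA; a DI-binned variant is
available. The ablation contrast (full model vs no-adaptation vs
no-directional) runs on the symmetric 500-cell thirds population with
deterministic rates and the constructed directionality: without adaptation
the matched-condition differential is identically zero and the test is
undefined (reported as "no dependence"), which is the model's exact
statement, not a statistical accident.

## Adaptation analyses

Onset/sustained/offset windows are the three 50 ms bins tiling the 150 ms
onset asynchrony (0–50, 50–100, 100–150 ms re tone onset; the placement
within the stated 50 ms granularity is the package's choice). Response types
come from an exponential fit r(k) = a + b·e^(−k/τ) over bias position with
endpoint-derived initialization; adapting ⇔ asymptote below initial, with a
2%-of-initial tie-break to "flat" and an endpoint fallback when the fit does
not converge. The three windows are averaged into one label per cell.

Recovery fits use silent frames ≥ 0.3 s after the last tone (beyond the
SSTRF span) against r(t) = base − c·e^(−t/τ), flagged degenerate when the
recovered depth is below 2% of baseline; reliable τ estimation needs the
post-sequence window to span ≈ 3 time constants (the study-scale measurement
uses 4.5 s tails).

Biased tuning curves: adapted curves per region from the probe tones
(0.5 st grid); the unadapted baseline pools the first five stimuli of every
sequence across conditions (together the four regions cover the octave) at
1 st resolution, circularly interpolated to the probe grid. Difference and
ratio profiles are re-centered on each region's bias center before
averaging. Because the "unadapted" baseline is itself partially adapted
(adaptation builds within ~4 stimuli) and synaptic depression is capped by
the calibrated ceiling, the measured fractional reduction inside the bias
(≈ 8–10%) is necessarily far below reductions reported for recordings; the
*locality* contrast (inside ≫ outside) is the model-testable property.

The tuning halfwidth interprets the half-height threshold as
f_min + (f_max − f_min)/2 (the literal printed expression would place the
threshold below f_min for positive curves; that variant is a flag), walks
circularly from the minimum to the nearest crossings, and returns the octave
minus the below-threshold arc — conservative for weakly modulated cells, and
exactly invariant under affine rate transforms. Flat curves return 12 st
with a degenerate flag.

## Measurement problem sizes

Study-design sizes (32 bias sequences, 240 bias tones, 662 cells, 10
repetitions) are used wherever they are statistically adequate. Three
measurements are limited by stimulus-sampling noise rather than trial noise
— the exponential build-up fit, per-cell response-type labels, and the
bias-length effect of the directional decoder — and use expanded
randomization sets (16 randomizations with up to 3 independent draws for
the fits; an 8-randomization deterministic design restricted to gaps
≥ 0.2 s for the length effect), chosen once as the package's reference
conditions and stated in the relevant function docstrings.

## Known limitations

- The depression ceiling makes the build-up non-exponential near
  saturation; the fitted τ is an effective constant of a mixture.
- The directional decoder's second-tone predictions are weaker than the
  first-tone ones (as in perception), and at the shortest gap the
  first-tone score is dominated by the residual sensory transient rather
  than the adaptation state.
- The per-cell response-type classification under the original 2-randomization
  design is dominated by stimulus-sampling noise for sharply tuned cells;
  the reference measurement therefore uses the expanded design.
- Nonlinear embedders (e.g. tSNE) are deliberately excluded from the
  decoder for determinism; the MEG-timing stimulus variant exists as a
  paradigm flag but no MEG-specific analysis is implemented.
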