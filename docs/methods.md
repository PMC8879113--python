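# Methods

## Scope and model

The package quantifies resting eyes-open EEG at the central strip into
per-band amplitude profiles and evaluates them against the normative
amplitude-relationship rules used in neurotherapeutic practice, with a
screening pattern for generalized anxiety disorder (GAD) layered on top.
The unit of exchange is the **amplitude profile**: one value in µV per
(channel, band), for the six bands delta, theta, alpha, SMR, beta1, beta2.

### Band amplitude

"Amplitude" is defined as the equivalent-sine peak amplitude
`sqrt(2 * band power)`, where band power is the integral of a one-sided
Welch power spectral density over the half-open interval `[f_lo, f_hi)`.
This convention makes a pure in-band sinusoid of peak amplitude A yield a
band amplitude of exactly A, so the estimates are commensurate with the
µV ceilings of the normative tables. Half-open intervals prevent a shared
edge frequency from being counted in two bands.

Estimator defaults: Hann window, 4 s segments (0.25 Hz resolution), 50%
overlap, per-segment mean removal, density scaling (summing PSD × bin
width over all frequencies recovers the signal variance). These are a
standard bias/variance compromise for 60 s resting recordings; both are
configurable. No artifact rejection is applied by default, since profiles
are meant to summarise whole resting recordings; an optional
peak-threshold epoch-rejection switch exists for contaminated data.

### Band edges

The band-edge convention (delta 0.5–4, theta 4–8, alpha 8–12, SMR 12–15,
beta1 15–20, beta2 20–30 Hz) follows common neurofeedback practice over
C3/Cz/C4. Acquisition systems differ here; every `BandScheme` therefore
carries a `scheme_id` that is stamped into profiles computed under it, and
custom edges can be supplied via configuration. All fixture-derived
results use printed amplitudes directly and are insensitive to this
choice.

### Montage

Profiles are computed from a referential Cz montage (each channel minus
the vertex electrode). Re-referencing is idempotent through the
recording's reference label, and quantification re-references
automatically when a Cz channel is present.

## Normative rules

Eleven rule families, each producing explicit pass/violation/informational
findings with the observed values attached:

| rule | statement | strictness |
|---|---|---|
| ABS_LIMIT | δ < 20, θ < 15, α < 10 µV; SMR/β1/β2 in [4, 10] µV | ceiling inclusive-violation (≥), range closed |
| ORDER_DELTA_THETA / THETA_ALPHA / ALPHA_SMR | δ > θ > α > SMR | strict |
| ORDER_SMR_BETA1 / BETA2 | SMR ≥ β1, SMR ≥ β2 | non-strict |
| SMR_HALF_THETA | SMR ≥ θ/2 | non-strict |
| ALPHA_GE_BETA2 | α ≥ β2 | non-strict |
| CALM_BETA_HALF_THETA | β1, β2 ≤ θ/2 in a calm resting state | non-strict |
| ASYMMETRY | C3/C4 index ≤ 20% per band | tie at threshold passes |
| DOMINANCE | fast waves ≤ 50% higher on the dominant side | see below |

The **asymmetry index** is `|L − R| / min(L, R) × 100`: symmetric,
scale-invariant, zero only at equality. The smaller-denominator
convention is a deliberate design choice — with it, exactly the four
fixture patients described as asymmetric (AD alpha 39.8%, GG beta1 23.6%,
SK SMR/β1/β2 46–74%, GP delta 23.2%) cross the 20% line while TD
(max 18.8%) does not; a larger-denominator convention would miss two of
them.

**Dominance** defaults to a left-dominant (C3) assumption, configurable,
since handedness is rarely reported with amplitude tables. Fast-wave
excess on the dominant side beyond 50% is a violation; fast-wave excess
on the non-dominant side, and slow-wave excess on the dominant side, are
contrary to expectation but not stated pathologies, so they are emitted
as informational findings and never counted in `n_violations`. SMR is
treated as a slow wave for dominance expectations but shares the fast-wave
4–10 µV absolute range.

For a two-channel six-band profile an evaluation emits exactly
12 + 18 + 6 + 6 = 42 findings in deterministic (rule, channel, band)
order.

## GAD signature and cohort relations

Per channel: `low_smr` ⇔ SMR < β2 (the SMR ≥ β2 norm inverted), and
`beta2_ge_alpha` ⇔ β2 ≥ (1 − tol)·α. A subject is positive when both
components hold in both hemispheres; positivity is monotone in `tol`.

The default tolerance **tol = 0.10** encodes the clinical reading that
beta2 "equalised" with alpha already signals anxiety-range activity
rather than requiring strict exceedance. On the embedded fixture the
tolerance matters: at tol = 0 exactly AD, SK and TD are positive (the
three patients with β2 strictly above α in both hemispheres); at 0.10,
GG joins; GP's C4 β2/α ratio is 0.8915, so GP is negative at the default
and joins only at tol ≥ 0.109. The default is a screening choice on a
five-subject, no-control case series — not a validated diagnostic
threshold — and is exposed as a parameter everywhere it is used.

Cohort relations (β2 > α, θ > δ, α > θ) use strict inequalities and
require both hemispheres; this convention reproduces all four published
cohort counts (3, 2, 2 and 4 of 5) simultaneously.

## Neurofeedback planning

Contributions are amplitude shares of the six-band sum per channel
(summing to 100%). The planner amplifies alpha toward a 16% contribution
and SMR toward 12% when currently below those targets (a contribution
exactly at target is left alone), and inhibits beta1/beta2 when they
exceed the calm-state ceiling of half the theta amplitude. Practice
guidance also leaves a small residual beta share untouched when
amplifying; the planner records this as a note and applies no arithmetic
adjustment, because no well-defined formula exists for it.

## Synthetic generator

The generator emulates a resting recording whose band amplitudes are
known by construction: per (channel, band), three equal-power sinusoids
at seeded random frequencies strictly inside the band (≥ 0.5 Hz from the
edges so Hann-window leakage stays inside the half-open interval, and
≥ 0.25 Hz apart so no pair beats slower than the analysis window and adds
coherently), scaled so the band's equivalent-sine amplitude equals the
target; plus per-channel 1/f noise of prescribed RMS (default 1 µV,
exponent 1.0) and a noise-only Cz channel so the montage applies.
Substreams are derived from (seed, channel, band), so adding a channel
never perturbs existing ones. A filtered-noise carrier mode exists for
more EEG-like waveforms at the cost of realisation variance.

What the generator does **not** emulate: eye-blink/EMG artifacts,
non-stationarity, volume-conduction correlations between electrodes, or
realistic spectral peak shapes. Passing round-trip tests therefore
demonstrates estimator correctness and pipeline integrity, not robustness
to real-world contamination.

### Round-trip fidelity

With the default conditions (60 s, 250 Hz, 1 µV background, 20 seeds) the
quantifier recovers every fixture amplitude within 10% (typically < 6%,
< 5% noise-free), and the violated-rule set of a regenerated recording
matches the direct fixture evaluation for patients AD, GG, SK and TD in
at least 19 of 20 seeds. Patient GP is the exception by construction:
the published C4 SMR and beta1 amplitudes are exactly equal (4.24 µV), a
tie sitting on the non-strict SMR ≥ β1 boundary. Any re-estimate perturbs
the two bands independently by a few tenths of a percent, so the tie's
verdict is a coin flip per realisation and GP's rule set cannot be stably
reproduced. Widening the rule comparisons enough to absorb the tie
(~1–2% equivalence) would erase genuinely narrated findings with small
margins (GG's α > θ at 2.2%), so the engine keeps exact comparisons and
the limitation is documented instead.

## Numerical choices and degenerate inputs

* EDF writing quantises to 16 bits over a symmetric per-channel physical
  range; worst-case round-trip error is one quantisation step. Non-finite
  samples are refused.
* All-zero (or otherwise power-free) channels make amplitude profiles
  invalid — every rule divides or compares by amplitudes, so strictly
  positive finite values are enforced at construction.
* Validation oracles in the test suite take an independent time-domain
  route: √2 × RMS of a zero-phase FIR band-passed copy (1025 taps, one
  filter length trimmed per end to discard filtfilt padding transients).
* Problem sizes throughout (60 s recordings, 20-seed repetitions) keep
  every stage at desk scale; the full pipeline on all five patients runs
  in seconds.

## Known limitations

* n = 5, one diagnosis, no controls: counts and the signature are
  descriptive, with no sensitivity/specificity claims.
* Published amplitudes are taken as printed ("mV" read as µV); the
  original recordings' duration, epoching and artifact handling are
  unknown, so the fixture bypasses acquisition entirely.
* Band edges and the asymmetry-denominator convention of the original
  acquisition software are undocumented; defaults are stated above and
  configurable.
* The rule set is an adult resting eyes-open norm; no age- or
  sex-stratified normative database is included.
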