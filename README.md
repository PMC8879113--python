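# qeegkit

Quantitative EEG (QEEG) band-amplitude analysis at the central electrodes
(C3, Cz, C4), for clinicians and researchers working with resting
eyes-open recordings — in particular the amplitude-relationship norms used
in neurofeedback practice and a screening pattern reported in adults with
generalized anxiety disorder (GAD).

## What it computes

For each channel the package reduces the EEG to six **band amplitudes** in
microvolts — delta (0.5–4 Hz), theta (4–8), alpha (8–12), SMR (12–15),
beta1 (15–20), beta2 (20–30 Hz) — defined as the *equivalent-sine peak
amplitude*

&nbsp;&nbsp;&nbsp;&nbsp;A_b = √(2 ∫_b P(f) df),

where P(f) is a Hann-windowed Welch power spectral density of the
Cz-referenced signal. A pure sinusoid of peak amplitude A inside band *b*
yields A_b = A, which ties the estimates to the µV values used in
normative tables.

On top of the amplitudes sit three layers:

* **Normative rules** — absolute ceilings (δ < 20, θ < 15, α < 10 µV, fast
  waves within 4–10 µV), the slow-to-fast ordering δ > θ > α > SMR ≥ β1, β2,
  ratio rules (SMR ≥ ½θ, α ≥ β2, calm-state β ≤ ½θ), inter-hemispheric
  asymmetry |C3 − C4| / min(C3, C4) × 100 ≤ 20%, and hemispheric-dominance
  margins.
* **GAD signature** — per channel: SMR below beta2 (depressed sensorimotor
  rhythm) *and* β2 ≥ (1 − tol)·α with a 10% default equivalence tolerance;
  positive when both hold in both hemispheres. Cohort-level relation
  counts accompany it.
* **Neurofeedback planning** — amplify alpha toward a 16% contribution of
  the six-band sum and SMR toward 12%, inhibit beta above the calm-state
  ceiling.

A five-patient amplitude fixture (the published GAD case series this
implementation follows) is embedded, and a synthetic generator produces
EEG-like recordings with prescribed band amplitudes over 1/f background
noise so the whole pipeline runs with no external data.

## Worked example

```
$ python analysis/02_cohort_relations.py
## Cohort summary

- patients: 5
- beta2 > alpha in both hemispheres: 3
- theta > delta in both hemispheres: 2
- alpha > theta in both hemispheres: 2
- >=1 band with supra-threshold C3/C4 asymmetry: 4
- signature-positive: 4

signature-positive at tol=0.00: AD, SK, TD
signature-positive at tol=0.10: AD, GG, SK, TD
signature-positive at tol=0.11: AD, GG, GP, SK, TD
```

Reading: of the five patients, three (AD, SK, TD) have beta2 amplitudes
strictly above alpha in both hemispheres; two show theta above delta
(a slow-wave ordering reversal); two show alpha above theta; four have at
least one band whose left–right amplitude difference exceeds 20% — e.g.
patient AD's alpha pair (7.94 µV at C3 vs 11.1 µV at C4) gives an
asymmetry index of 39.8%. At the default 10% equivalence tolerance four
of five patients carry the full low-SMR/high-beta2 signature; patient
GP's C4 beta2/alpha ratio (5.75/6.45 = 0.89) sits just below the cut and
joins at an 11% tolerance.

The same pipeline runs on raw data:

```
qeegkit simulate --spec spec.yaml --out synth.edf   # or any EDF recording
qeegkit quantify --edf synth.edf --out profile.csv
qeegkit evaluate --profiles profile.csv --out rules.json
qeegkit cohort   --profiles profile.csv --out summary.json
```

The numbered scripts under `analysis/` re-derive the per-patient rule
reports, cohort relations, neurofeedback plans and a synthetic end-to-end
validation, writing their tables under `results/`.

## Caveats

The underlying case series has five subjects and no control group; the
signature is a descriptive pattern, not a validated diagnostic
classifier. The published amplitude tables label values "mV"; scalp EEG
amplitudes are physiologically microvolts and are treated as µV
throughout. See `docs/methods.md` for the model, parameter defaults and
known limitations.
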