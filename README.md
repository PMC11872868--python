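# sleepvol

Volatility analysis of sleep-transition neural dynamics from multimodal
polysomnography (EEG, EOG, EMG), built around a synthetic sleep-telemetry
generator so every stage of the analysis is testable without downloading
recordings.

## Who this is for

Sleep and aging researchers who want to quantify how *unstable* neural
signals are around sleep-stage transitions — and how that instability
differs between age groups and between a sedative night and a placebo
night — using conditional-heteroskedasticity modeling rather than mean
band power alone.

## The model

For a per-epoch feature series `y_t` (by default the stage-centered log
wavelet energy of the delta band), volatility is modeled as GARCH(1,1):

    y_t     = μ + ε_t,     ε_t = σ_t z_t,   z_t ~ iid N(0, 1)
    σ²_t    = α₀ + α₁ ε²_{t−1} + β₁ σ²_{t−1}

fitted by constrained Gaussian quasi-maximum likelihood (α₀ > 0,
α₁, β₁ ≥ 0, α₁ + β₁ < 1).  The fitted conditional variances σ²_t are the
per-epoch volatility; their average over time and recordings per
(age group × condition × stage) cell is the **mean conditional volatility
(MCV)**.  Directed influence between channels is measured by plug-in
**transfer entropy** on quantile-binned envelope series,

    T_{X→Y} = Σ p(y_{t+1}, y_t, x_t) log [ p(y_{t+1}|y_t,x_t) / p(y_{t+1}|y_t) ]

and the **causality index (CI)** of a (band, stage, age-group) cell is
the mean of per-window transfer entropies.  Upstream, signals pass
through equiripple FIR band-pass filtering, Welch PSDs and band powers,
ICA-based ocular artifact removal, a 5-axis tensor (subject × modality ×
band × bin × time), Morlet-CWT features (energy / mean / entropy, Eq.-style
importance weights), and SVM-RFE stage-pair feature selection.  See
`docs/methods.md` for the full account.

The synthetic generator injects *known* GARCH amplitude volatility
(placebo α₁ = 0.25; the drug night halves α₁), age-dependent declines in
delta/SWA/spindle amplitude, and a lagged frontal→occipital delta
coupling during stage 3 — so parameter recovery, the drug-effect
direction, and the coupling direction are all checkable against ground
truth.

## Worked example

```python
import sleepvol as sv
from sleepvol import pipeline

spec = sv.CohortSpec(n_subjects=8, duration_hours=2.0, seed=0)
recordings = sv.generate_cohort(spec)          # 16 subject-nights

print(pipeline.drug_effect_by_group(recordings))
fwd, rev = pipeline.cohort_causality(recordings)
print(f"CI frontal->occipital {fwd:.3f}  reverse {rev:.3f}")
```

Output:

```
condition age_group      drug   placebo  drug_lower
0             18-29  0.622709  1.691572        True
1             30-49  0.506891  1.854722        True
2             50-66  0.876543  1.817230        True
CI frontal->occipital 0.253  reverse 0.189
```

Reading the numbers: each row is an age group's mean conditional
volatility of the delta-band log wavelet energy under drug and placebo
nights; `drug_lower=True` in every row says the generator's built-in
volatility reduction on drug nights was recovered by the full pipeline.
The causality indices show the planted frontal→occipital delta coupling
in stage 3: the forward direction carries more directed information than
the reverse.

The same analysis runs from the shell, stage by stage with checksummed
artifacts on disk:

```
sleepvol run-all --subjects 4 --hours 1 --seed 1 --out out/
```

(subcommands: simulate, preprocess, tensorize, features, select, garch,
causality, stats, run-all).  Recordings are written as EDF plus a sidecar
CSV hypnogram; real Sleep-EDF-style telemetry files with a compatible
channel set can be substituted through `sleepvol.io.read_recording`.

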