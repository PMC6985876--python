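# cardioresp

Cardiorespiratory signal analysis for conscious-rodent whole-body
plethysmography and arterial blood-pressure telemetry, plus a synthetic
recording generator that provides exact ground truth for every analysis
stage.

## What it does

- **core_io** — domain types (`SignalTrace`, `AnnotationTable`,
  `GasProtocol`, `RecordingBundle`) and CSV/YAML readers and writers.
  Time in seconds, rates in Hz, half-open windows.
- **synth** — coupled respiratory-flow (half-sine inspiration,
  exponential expiration) and 500-Hz pulse-pressure recordings with
  programmable breath-interval AR(1) variability, Poisson-inserted
  apneas/hypopneas/sighs, an exact E2/E1 shape target, LF/HF heart-rate
  modulation, a tunable VT→SBP coupling gain, and first-order
  ventilatory responses to FIO2/FICO2 steps. Deterministic given a seed.
- **breath** — breath segmentation from flow (hysteresis zero-crossing
  detection), ventilation summaries (VT per 100 g, Rf, V̇e = VT×Rf),
  scoring of apneas (≥3 local breathing cycles), hypopneas (VT ≤50 % of
  the 3 preceding normal breaths), sighs (≥150 %), post-sigh apneas, and
  Poincaré SD1/SD2 + VT coefficient of variation.
- **expiration** — E2/E1 late/early expiratory area ratio over randomly
  chosen event-free segments (3 × 20 cycles by default).
- **hemo** — beat detection at dP/dt maxima, per-cycle SBP/DBP/MAP/PP,
  local-level Kalman RR smoothing, Teichholz left-ventricular volumes.
- **hrv** — RR tachogram (cubic interpolation, 10 Hz), Welch-style
  Hann-tapered Burg AR spectra, rat LF (0.04–0.6 Hz) / HF (0.6–2.4 Hz)
  band powers, normalized units and LF/HF ratio, time-varying spectra.
- **coupling** — magnitude-squared coherence between per-breath VT and
  per-beat SBP over a 0.1-Hz band centered at the VT spectral peak, with
  the analytic Welch significance level.
- **chemoreflex** — episodic hypercapnic stimulation schedules, HCVR
  (FICO2 0.03→7 %) and HVR (FIO2 21→10 %) slopes, post-stimulation
  ventilation deltas.
- **pipeline / cli** — end-to-end simulate → analyze → report runs with
  byte-stable outputs.

## CLI

```bash
cardioresp simulate --seed 1 --duration 600 --out run/          # flow + pressure + truth
cardioresp breaths   run/flow.csv                               # VT / Rf / VE summary
cardioresp events    run/flow.csv --out run/events.csv          # AHI etc.
cardioresp expiration run/flow.csv                              # E2/E1
cardioresp beats     run/pressure.csv                           # dP/dt beat detection
cardioresp hrv       run/pressure.csv                           # LF/HF spectra
cardioresp coupling  run/flow.csv run/pressure.csv              # VT-SBP coherence
cardioresp chemoreflex --mode hcvr --gain 5.5 --seed 1          # gain recovery
cardioresp report --seed 1 --out report/                        # full pipeline
cardioresp demo   --seed 1 --out demo/                          # Sham-like vs HF-like
```

## Notes

- Inspiration is positive flow by convention; VT is the integral of
  inspiratory flow.
- Poincaré SD1/SD2 use population (1/n) variances:
  SD1² = Var(Δx)/2, SD2² = 2·Var(x) − SD1².
- The Teichholz volume is V(D) = 7 D³/(2.4 + D) (D in cm, reported µL).
- All detection thresholds (hysteresis fraction, minimum breath
  duration, apnea cycle multiple, band edges, Welch segmenting, AR
  order) are keyword-exposed on the respective functions.
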