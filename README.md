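# ripplelock

Event-locked analysis of neocortical **fast ripples** (FRs, 200–550 Hz
pathological high-frequency oscillations) and the large-scale **3–5 Hz
slow oscillation** that constrains them, for multichannel extracellular
recordings from epileptic networks (hippocampi + frontal cortex).

In unilateral hippocampal epilepsy, fast ripples appear in the frontal
cortex far from the focus. They are not isolated events: they ride on
trains of interictal discharges (IEDs, 20–30 Hz) whose amplitude is
coupled to the phase of a slow oscillation, neuronal firing is
phase-locked to that oscillation, and the oscillation itself builds up
in the hippocampi before reaching the cortex. `ripplelock` implements
the full analysis chain needed to establish that picture:

* **Detection** — FRs (≥ 4 oscillations above 3× the ±250 ms baseline
  SD of the 200–550 Hz band-passed trace) and multiunit spikes
  (threshold `4·median(|x|)/0.6745` on the 300–6000 Hz band).
* **Time–frequency** — Stockwell-transform spectrograms z-scored
  against randomly sampled event-free baselines, IED association
  (z > 2 in 20–30 Hz) and band-onset estimation (z > 5).
* **Circular statistics** — phase locking of events and spikes
  (Rayleigh test; von Mises mean μ and concentration κ),
  Watson–Williams and equal-concentration tests, the across-event
  phase-locking factor with a phase-randomized control, and
  inter-regional phase-difference synchrony scans.
* **Phase–amplitude coupling** — comodulograms of the Kullback–Leibler
  modulation index, `MI = KL(p ‖ uniform)/log 18 ∈ [0, 1]`, where p is
  the normalized mean-amplitude-per-phase-bin distribution.
* **Directed connectivity** — Kalman-filtered time-varying
  autoregressive models, adaptive partial directed coherence
  `APDC_ij(f,t)² = |A_ij(f,t)|² / Σ_k |A_ik(f,t)|²`, its band-integrated
  form iAPDC over [f1, f2], and band-limited cross-correlation lags
  (negative lag = second signal delayed).
* **Peri-event spiking** — PSTHs, laminar down-state/FR firing ratios,
  laminar MUA-onset chronology, and FR precedence across regions.
* **Synthetic recordings** — a ground-truth generator
  (`ripplelock.simulate`) reproducing the study conditions (three
  regions, 16 kHz, phase-coupled IED bursts, phase-locked FRs and MUA,
  64/52 ms hippocampus→cortex lags, causal slow-band drive), used by
  the test suite to validate every stage by parameter recovery.

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.

## Worked example

Run the pipeline on a synthetic desk-scale recording (90 s, 12 epileptic
complexes at 4 kHz) and inspect the headline quantities:

```python
from ripplelock.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=7, stages=("detect", "locking", "pac"))
bundle = run_pipeline(cfg)

fr = bundle.catalog.of_type("fast_ripple", "FC")
print(f"frontal cortex fast ripples: {len(fr)}")
lock = bundle.locking["fr_onset"]
print(f"FR onset locking to 3-5 Hz phase: mean angle {lock['mu']:.2f} rad, "
      f"kappa {lock['kappa']:.2f}, Rayleigh p {lock['p']:.2e}")
mua = bundle.locking["mua"]
print(f"MUA locking: POI kappa {mua['kappa_poi']:.2f} vs baseline "
      f"{mua['kappa_baseline']:.2f} (equal-kappa p {mua['p_kappa']:.1e})")
print(f"PAC peak (phase, amplitude): {bundle.pac['poi_peak']} Hz, "
      f"MI ratio at peak {bundle.pac['peak_ratio']:.2f}")
```

prints

```
frontal cortex fast ripples: 12
FR onset locking to 3-5 Hz phase: mean angle 1.32 rad, kappa 6.90, Rayleigh p 1.40e-06
MUA locking: POI kappa 0.58 vs baseline 0.19 (equal-kappa p 4.2e-11)
PAC peak (phase, amplitude): (4.5, 27.0) Hz, MI ratio at peak 3.25
```

All 12 generated FRs are found; their onsets are locked near the
generated slow-oscillation phase (1.57 rad); multiunit firing is more
concentrated on the slow phase during the periods of interest than at
baseline; and the comodulogram peak recovers the generated coupling
(4.5 Hz phase × 27 Hz amplitude), elevated ~3× over baseline.

The same stages are available from the shell:

```sh
ripplelock simulate --seed 7 --out sim/       # recording + ground truth
ripplelock all --seed 7 --out results/        # full pipeline
```

Exit codes: 0 ok, 2 configuration error, 3 stage failure.

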