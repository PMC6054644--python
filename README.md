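# myostep

Simulation and analysis of processive molecular-motor stepping under
load, built around the single-molecule phenotype of myosin-5B: a
plus-end-directed actin motor that walks in ~36-nm steps, stalls near
2 pN of resistive load, and detaches much faster under assistive load.

The package is for single-molecule biophysicists who need a tested,
reproducible version of the standard analysis chain for two assays:

* **Ultrafast force-clamp (three-bead dumbbell) records** — attachment
  event detection from the dumbbell velocity, bidirectional step
  detection inside processive runs, run assembly, and per-force-bin
  statistics (run length, duration, detachment rate k = 1/⟨τ⟩ with
  σ_k = σ_τ⟨τ⟩⁻², step counts and forward/backward ratio).
* **Unloaded TIRF motility movies** — 2-D Gaussian PSF localization of
  quantum-dot labels, nearest-neighbor tracking, interpolated run
  length, change-point step detection, Michaelis–Menten velocity fits.

On top sit the models fitted to those statistics:

* Bell-type force dependence, `y(F) = y₀ · exp(±|F|·d / kBT)`, for run
  length, detachment rate, stepping rates and the forward/backward
  step-count ratio, with the stall force `F* = (kBT/d)·ln R₀` where the
  fitted ratio model crosses one;
* Michaelis–Menten kinetics `v = v_max·[ATP]/(K_app + [ATP])`;
* the finite-oscillation-window correction for assistive-load run
  lengths: with exponential true run length (mean L) and uniform
  attachment inside a window of width D, the measured mean is
  `<Lm> = (1/D)[L²(e^(−D/L) − 1) + L·D]`, which the package inverts
  numerically to recover L from censored data.

A full stochastic simulator (Gillespie stepping kinetics, dumbbell
oscillation/truncation geometry, TIRF image stacks with Poisson shot
noise) generates every input the chain consumes, with bit-for-bit seed
reproducibility, so each detector and fit can be validated against
ground truth.

## Worked example

Simulate ~750 runs on the resistive branch from the reference
run-length model (L₀ = 890 nm, d_L = 6.3 nm), refit blind, and compute
the stall force and a censoring round trip:

```python
from myostep import experiments, models

fit = experiments.recover_runlength_bell(seed=1)
print(f"L0 = {fit.amplitude0:.0f} +/- {fit.amplitude0_se:.0f} nm, "
      f"d_L = {fit.distance:.2f} +/- {fit.distance_se:.2f} nm")

print(f"stall force = {models.stall_force(54.0, 8.2):.2f} pN")

Lm = models.expected_measured_runlength(148.0, 400.0)
print(f"<Lm>(L=148, D=400) = {Lm:.1f} nm -> corrected back: "
      f"{models.correct_run_length(Lm, 400.0):.1f} nm")
```

prints

```
L0 = 853 +/- 35 nm, d_L = 6.24 +/- 0.09 nm
stall force = 2.00 pN
<Lm>(L=148, D=400) = 96.9 nm -> corrected back: 148.0 nm
```

The refitted zero-force run length (853 ± 35 nm) and distance parameter
(6.24 ± 0.09 nm) recover the generating values within sampling error;
the ratio-model parameters R₀ = 54, d = 8.2 nm place stall at 2.0 pN;
and inverting the window-censoring expectation returns the true 148-nm
mean from a measured 96.9-nm mean exactly.

## Command line

A thin CLI wraps the library:

```bash
myostep simulate clamp --force 1.5 --range 400 --seed 1 --out rec.h5
myostep clamp rec.h5 --bins -3,-2,-1,0,1,2,3 --out runs.csv
myostep fit bell table.csv --sign decay --branch resistive
myostep fit correct-runlength --lm 96.9 --d 400
myostep pipeline --seed 1 --out demo_out
```

`myostep pipeline` runs simulate → detect → bin → fit → correct end to
end from a YAML config and writes CSV/JSON artifacts stamped with the
config hash; the same config and seed reproduce the outputs
byte-for-byte.

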