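# hydrokin

Confined-water diffusion kinetics: mean-squared-displacement (MSD)
estimation of self-diffusion coefficients, deformed (super-)Arrhenius
fitting of their temperature dependence, and enzyme-channel hydration
profiling — with seeded synthetic generators so every stage can be
validated against known ground truth.

## The scientific problem

Water inside the nano-channels of a folded enzyme does not diffuse like
bulk water.  In the tetramer of phosphofructokinase-1 (PFK-1, the
rate-limiting glycolytic enzyme), channel-confined water hops between
local potential minima over barriers of tens of kJ/mol, and its
diffusion coefficient D(T) over the physiological range 270–340 K bends
away from the straight Arrhenius line: the apparent activation energy
*decreases* as temperature rises (super-Arrhenius behavior).  The same
signature appears in whole-cell respiration rates, which makes the
channel-water kinetics a candidate molecular explanation.

This package implements the full desk-side analysis chain for that
problem, for computational biophysicists who have (or simulate)
particle trajectories and temperature-indexed rate/diffusion tables:

1. **trajectory → MSD → D** — ensemble MSD with multiple time origins
   (exact FFT algorithm), periodic-boundary unwrapping, and the
   directed-motion fit MSD(t) = 4Dt + (Vt)² (or the dimensionally
   explicit 2·n·Dt form);
2. **D(T) → deformed Arrhenius law** — ordinary least squares of
   ln D (or ln k) on x = 1/RT:

       ln D(T) = ln D₀ + B/RT + C/(RT)²,
       Eₐ(T)   = −d ln D / d(1/RT) = −B − 2C/RT,

   with R = 8.314 J K⁻¹ mol⁻¹; C < 0 ⇔ super-Arrhenius (Eₐ falls with
   T), C = 0 recovers the classical law with Eₐ = −B;
3. **channel hydration** — centerline geometry (arc length, bottleneck
   radius/width), Kyte–Doolittle hydropathy profiles normalized to
   [−1, 1], and per-frame counts of waters within a cutoff (default
   3 Å) of the channel centerline;
4. **synthetic ground truth** — Brownian bulk water, barrier-limited
   channel hopping with an optional temperature-growing release of
   trapped tracers to bulk-like diffusion (the population-thinning
   mechanism that produces C < 0), forward-model rate series, and
   channel fixtures with exactly known water labels.

## Worked example

Fit a temperature series generated from the published transient-channel
parameters (ln D₀ = −33.77, B = 9.98×10⁴ J/mol, C = −1.58×10⁸ J²/mol²):

```sh
hydrokin simulate-rates --ln-pre -33.77 --b 99800 --c -1.58e8 \
    --temperatures 270,280,290,300,310,320,330,340 --out rates.csv
hydrokin fit --rates rates.csv --out fit.json
```

`fit.json` then contains (abridged):

```json
"super_arrhenius": {
  "ln_pre": -33.77, "B_J_per_mol": 99800.0,
  "C_J2_per_mol2": -1.58e8, "r_squared": 1.0,
  "Ea_kJ_per_mol": {"290": 31.26, "300": 26.89, "310": 22.81}
},
"classification": "super"
```

The zero-noise refit returns the generator parameters exactly, and the
derived activation energy falls from 31.3 kJ/mol at 290 K to
22.8 kJ/mol at 310 K — water that must climb substantial barriers when
cold diffuses almost freely when warm.  The same chain runs from raw
trajectories: `hydrokin pipeline --config cfg.yaml` simulates (or
loads) one trajectory per temperature, computes MSD and D per
temperature, fits both laws and writes a JSON report.

The `analysis/` directory holds the numbered study drivers
(01 activation energies, 02 bulk reference, 03 channel sweeps,
04 hydration profiles, 05 estimator calibration); each writes its
tables under `results/` and prints what it found.

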