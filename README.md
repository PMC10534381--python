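# depsep

Finite-element simulation of dielectrophoretic cell separation in a
two-stage Y-channel lab-on-chip.

## What it is for

Isolating circulating tumor cells (CTCs) from blood is a key step in
liquid biopsy: CTCs are rare (1–10 per mL), so a preparative microfluidic
stage that splits an RBC-depleted sample into clean CTC, white-blood-cell
(WBC) and platelet (PLT) fractions is valuable for diagnosis and
treatment monitoring. `depsep` is a self-contained simulator for one such
device: a 919 µm × 440 µm planar chip in which a fast buffer stream
pinches the sample against an electrode-bearing wall and negative
dielectrophoresis (nDEP) deflects each cell species by a different
amount, so two cascaded Y-splits sort them into three outlets. It is
aimed at microfluidic-device designers who want to explore this design
space (channel width, electrode count and voltage, inlet speeds) without
a commercial multiphysics package.

## Model

Three sequentially coupled physics on a shared unstructured triangle
mesh, all implemented in-package on numpy/scipy:

* **Creeping flow** — Stokes equations 0 = −∇p + µ∇²u, ∇·u = 0
  (Taylor–Hood elements), plug velocity inlets, 0 Pa outlets, no-slip
  walls.
* **Electric currents** — ∇·(σ∇V) = 0 with alternating ±V_a on the
  electrode faces (quadratic elements); the dielectrophoretic drive
  ∇|E|² is reconstructed from an L2 projection of |E|² onto the
  continuous quadratic space.
* **Cell tracing** — overdamped point particles,
  dx/dt = u + F_DEP/(6πµR_p), with the time-averaged DEP force

      F_DEP = 2π ε_m R_p³ Re[K(ω)] ∇|E_rms|²,

  where Re[K] is the real Clausius–Mossotti factor of the single-shell
  cell model (cytoplasm sphere + thin membrane, homogenised to one
  complex permittivity ε* = ε − jσ/ω).

Separation efficiency (per species) and purity (per outlet) are counted
per the usual definitions: η = 100 × isolated/injected, purity = 100 ×
targeted/(targeted + unwanted). See `docs/methods.md` for assumptions,
the operating-point calibration and numerical details.

## Worked example

```bash
python examples/run_optimum_design.py
```

runs the proposed design — four electrodes at ±2.0 V, 40 µm channel
width, buffer 850 µm/s, cells 134 µm/s, 20 cells per species — and
prints:

```
separation efficiency (% of injected cells at the designated outlet):
  CTC: 100.00%
  PLT: 100.00%
  WBC: 100.00%
outlet purity (% of arriving cells that are the intended species):
  outlet_CTC: 100.00%
  outlet_PLT: 100.00%
  outlet_WBC: 100.00%
lost cells: 0 of 60
outlet throughput (nL/min):
  outlet_CTC: 64.1
  outlet_PLT: 58.6
  outlet_WBC: 113.5
complete separation: True
```

Every platelet leaves through the upper outlet (they feel the weakest
DEP force and stay nearest the electrodes), every WBC through the lower
outlet (strongest force, deflected furthest), and every CTC through the
middle outlet — 100% efficiency and purity, i.e. complete separation at
only ±2 V. The throughputs sum to the injected (850+134) µm/s × 40 µm ×
100 µm flow rate.

Other examples: `cmf_spectra.py` (Clausius–Mossotti spectra and the
force ordering |F_WBC| > |F_CTC| > |F_PLT| behind the routing),
`build_geometry_and_mesh.py` (parametric geometry and mesh export),
`voltage_and_buffer_effects.py` (how voltage and buffer speed move the
cell streams).

There is also a thin CLI:

```bash
depsep simulate --mesh-level fine              # shipped optimum design
depsep sweep --widths 40,50 --voltages 2.0,2.5 # parametric design sweep
depsep convergence                             # grid-independence study
depsep export-catalog                          # cell property table
```

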