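# Methods

`depsep` simulates a planar, two-stage lab-on-chip that separates
circulating tumor cells (CTCs), white blood cells (WBCs) and platelets
(PLTs) from an RBC-depleted blood sample by combining hydrodynamic flow
focusing with negative dielectrophoresis (nDEP). This note records the
model, its assumptions, the numerical choices and the limits of what the
simulations demonstrate.

## Device and model overview

The device is a 2D channel network: an upper blood inlet and a lower,
faster buffer inlet merge at 90° into a main channel whose upper wall
carries 2 or 4 rectangular electrodes protruding into the flow; a first
Y-split diverts the lower stream to the WBC outlet, and a second split
divides the remaining stream between the CTC (middle) and PLT (upper)
outlets. The faster buffer pinches the sample against the electrode-side
wall, so every cell enters the non-uniform field region; the DEP force
then displaces each species across the channel in proportion to its
polarisability and size, and the two splits read that displacement out
as outlet routing.

Three one-way coupled physics are solved sequentially on the same mesh:

1. **Creeping flow.** Steady incompressible Stokes equations
   (0 = −∇p + µ∇²u, ∇·u = 0) with no-slip walls, velocity inlets and
   0 Pa (traction-free) outlets. Inertia is neglected: Re ≈ 10⁻² at
   the operating speeds.
2. **Electric currents.** The quasi-static potential ∇·(σ∇V) = 0 with
   Dirichlet values ±Va on the three exposed faces of each electrode
   (polarity alternating along the array) and insulating walls. The AC
   frequency does not change the field shape; it enters only through
   the Clausius–Mossotti factor.
3. **Particle tracing.** Point particles advected by the fluid and the
   time-averaged DEP force
   F = 2π ε_m R³ Re[K(ω)] ∇|E_rms|², with ∇|E_rms|² = ∇|E|²/2 for the
   amplitude field returned by the potential solve. Default dynamics is
   overdamped (dx/dt = u + F/6πµR); the Stokes relaxation time of a
   ≤15 µm cell in water is ~10⁻⁵ s, negligible against the transit.
   An inertial mode (m dv/dt = 6πµR(u−v) + F, cell density 1050 kg/m³)
   exists for sensitivity checks and reproduces the overdamped routing.

Cell–cell interactions, two-way momentum coupling, Brownian motion,
deformation and lift forces are excluded.

## Cell dielectrics

Each species is a single-shell sphere: cytoplasm (σ_cyt, ε_cyt) wrapped
in a thin membrane (thickness t, σ_mem, ε_mem). The shell is homogenised
into one complex permittivity

    ε*_eff = ε*_mem (γ³ + 2Δ)/(γ³ − Δ),  γ = R/(R−t),
    Δ = (ε*_cyt − ε*_mem)/(ε*_cyt + 2ε*_mem),   ε* = ε − jσ/ω,

and the real Clausius–Mossotti factor is
Re[K] = Re[(ε*_p − ε*_m)/(ε*_p + 2ε*_m)] ∈ [−½, 1]. At ω = 0 a
conductivity-only branch replaces the complex expression (never a
division by ω). The shipped catalog (`data/cells.json`):

| property | CTC | WBC | PLT |
|---|---|---|---|
| diameter (µm) | 15 | 12 | 1.8 |
| membrane thickness (nm) | 7 | 7 | 8 |
| cytoplasm conductivity (S/m) | 1.0 | 0.18 | 0.25 |
| membrane conductivity (S/m) | 9·10⁻⁷ | 9·10⁻⁶ | 1·10⁻⁶ |
| cytoplasm rel. permittivity | 50 | 80 | 50 |
| membrane rel. permittivity | 12.5 | 10 | 6 |

## Operating-point calibration

The buffer conductivity, permittivity and signal frequency are free
design parameters of the separator. The defaults are σ_m = 55 mS/m
(low-conductivity DEP buffer), ε_m,r = 80 (aqueous) and **f = 96 kHz**,
chosen so that, at the operating point,

    Re[K] = −0.033 (CTC), −0.182 (WBC), −0.496 (PLT).

All three species experience nDEP (pushed away from the electrodes) and
the force magnitudes order |F_WBC| > |F_CTC| > |F_PLT| — the WBC force
wins over the larger CTC because 96 kHz sits just below the CTC's
crossover frequency, where its polarisation contrast nearly vanishes
while the WBC's is still substantial. The DEP deflection mobilities
(∝ |K| R²) then order WBC : CTC : PLT ≈ 7.6 : 2.2 : 0.5, which is what
routes WBCs furthest from the electrodes, CTCs to the middle outlet and
PLTs (barely deflected) to the upper outlet. A configuration that breaks
this ordering triggers a logged warning. With these defaults the package
reproduces complete separation at the published operating points
(4 electrodes/±2 V/40 µm/850 µm·s⁻¹; 2 electrodes/±4 V/50 µm;
4 electrodes/±2.5 V/1350 µm·s⁻¹) and the published failure at a buffer
speed of 350 µm/s.

The frequency is deliberately *not* 100 kHz: there Re[K]_CTC = −0.008,
which makes the CTC mobility indistinguishable from the platelet's and
no frequency-independent tuning can then split CTCs from PLTs.

## Geometry and meshing

All lengths are micrometres; x runs along the main channel, origin at
the lower-left of the bounding box. Branch angles are 90° between the
two arms of every Y (each arm at 45° to the local axis). Branch widths
are uniform (= CW). The electrode array (width e = 40, gap d = 40,
protrusion 16) ends half a channel width upstream of the first split,
leaving the upstream main channel electrode-free for flow focusing.
The stage-2 outlet lengths carry fixed trim extensions (+38.08 µm CTC,
+59.08 µm PLT) calibrated once so the assembled default device matches
the published 919 µm × 440 µm footprint exactly; the nominal port length
(190 µm) is otherwise used for all ports.

Meshing is Delaunay-based: the polygon boundary is resampled under a
graded size field, interior points come from structured grids filtered
to the interior, and missing boundary edges are recovered by midpoint
insertion, so the kept triangles tile the polygon exactly (area defect
~10⁻¹⁶). Levels: coarse h = 8 µm, normal 4 µm, fine 2 µm, with 6× local
refinement in a band along the electrode faces and the wall segments
between them (grading slope 0.25). The band, rather than corner-only,
refinement is what makes the traced cell speeds grid-converge below the
1% criterion between the normal and fine meshes.

## Discretisation

* **Stokes:** Taylor–Hood (quadratic velocity / linear pressure),
  direct sparse solve. Inlets impose a plug profile with a fixed-width
  (10% of the face) linear rolloff at the corners — mesh-independent,
  no-slip compatible — rescaled so the discrete influx equals the
  nominal mean speed × width exactly; a parabolic profile is available.
  Outlets are traction-free, which pins p ≈ 0 there. Mass balance
  between inlets and outlets holds to <0.1% on the fine mesh.
* **Potential:** quadratic continuous Galerkin; σ is uniform and drops
  out of the field shape.
* **DEP drive:** |E|² (piecewise quadratic, discontinuous) is
  L2-projected onto the continuous quadratic space; its element-wise
  gradient is recovered to vertices by area-weighted averaging, giving
  a continuous piecewise-linear ∇|E|². The projection step converges
  roughly one order faster along the cell paths than elementwise
  recovery (required for the grid criterion), and the continuity keeps
  the particle integrator's adaptive steps well-behaved.
* **Tracing:** one adaptive RK45 system over all cells (rtol 10⁻⁷,
  atol 10⁻⁵ µm, max step 10 ms); terminated cells are masked. The
  inertial mode instead uses a midpoint exponential integrator — the
  linear drag relaxation (τ ≈ 10⁻⁵ s, brutally stiff for explicit
  steppers) is integrated exactly per step with the fields evaluated at
  the step midpoint, stepping ~1 µm at a time. Exits are detected by
  segment/port-face intersection; wall contact freezes a cell when its
  centre comes within 0.1 µm of a wall. The finite radius
  enters only the force and drag laws: with the sample focused into the
  top few micrometres of the channel, a centre-distance-R contact rule
  would freeze every large cell on release, contradicting the device's
  observed operation; centre contact matches standard point-particle
  tracing. At zero voltage the tracer reproduces independent streamline
  integrations to <0.1 µm.

## Metrics

Separation efficiency (per species) is 100 × (cells at the designated
outlet)/(cells injected); lost cells (frozen, unresolved, washed back)
count against the denominator. Purity (per outlet) is 100 × targeted /
(targeted + unwanted) among arrivals only; empty outlets and uninjected
species are reported as absent rather than 0%. Throughput is the
outlet-face flux integral × channel depth (100 µm). The grid study
compares the mean cell speed at each species' designated outlet across
refinement levels (ε = |v_fine − v_coarser|/v_fine); the verdict uses
the finest pair against a 1% criterion.

## Synthetic ensembles

Each run releases `n_per_species` (default 20) cells of every species
across the blood-inlet cross-section, 6 µm inside the inlet face, with a
10% margin at each wall. The uniform grid interleaves all species at
identical stations, so any routing difference between species is
attributable purely to their size and dielectric properties. Release is
simultaneous (t = 0). Physiological abundances (CTCs are ~1–10 per mL)
are deliberately not emulated — equal counts give equal statistical
power per species; an abundance-weighted mode exists for realism
studies. 20 cells/species gives 5% efficiency granularity, enough to
certify 100%-vs-not outcomes. What passing tests show is therefore the
*deterministic routing* of isolated, spherical, point-like cells; they
do not probe crowding, cell-size dispersion within a species, or
stochastic arrival times of a real sample.

## Problem sizes and runtime

The shipped configurations solve ~10⁴ (normal) to ~3.5·10⁴ (fine)
triangles, i.e. ~2·10⁵ Taylor–Hood unknowns at the fine level, and trace
60 cells; one fine-mesh pipeline run takes ~15 s on one core, so the
full acceptance recomputation (three fine runs plus one normal run) and
the test suite each stay within a few minutes.

## Known limitations

* The exposure time of cells to the field is set by the transit time
  implied by the stated inlet speeds (~0.5 s through the active stage).
  Published force-versus-time plots for this class of device suggest a
  much longer residence; that timing is not reproduced here and is not
  used as a target.
* The complete-separation *map* over the full design grid is reproduced
  only partially: at 40 µm/850 µm·s⁻¹ this calibration separates fully
  at ±2.0 V but not ±2.5 V (CTCs overshoot into the WBC outlet). The
  qualitative trends — higher voltage pushes every species further from
  the electrodes, faster buffer pulls them closer, wider channels need
  more voltage, fewer electrodes need more voltage — all hold.
* 2D planar model: the 100 µm depth enters only the volumetric
  throughput; top/bottom-wall effects on drag and field are absent.
* Electrode polarisation, double-layer screening, AC electro-osmosis
  and electrothermal flow are not modelled; at ±2–4 V and ~100 kHz in a
  55 mS/m buffer these are small but not strictly zero.
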