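# Methods

## Model structure

`mapskin` simulates drug disposition after application of a dissolvable
microarray patch (MAP) as a linear compartmental system with three coupled
parts.

**Geometric dose placement.** Needles are pyramids of height `H` inserted
to depth `L_ins = f_p·H`. Because a pyramid scales linearly in both lateral
directions away from its apex, the fraction of needle volume within
distance `d` of the tip is `(d/H)³`; with drug assumed uniformly
distributed through the needle matrix, the dose deposited in a sublayer
spanning depths `[a, b)` is the difference of that cube law evaluated at
the two bounding planes. Two normalisation conventions are provided:
`inserted` (default) treats the full patch load as delivered and expresses
fractions of the inserted-tip volume; `total` expresses fractions of the
whole-needle volume and books the non-inserted `1 − f_p³` as an inert
undeposited remainder. The default follows the view that a dissolvable
patch's load is its delivered dose, which is also how delivered-dose
kinetics are validated; the alternative is kept because the geometric
argument alone cannot decide it. Baseplate/backing drug and back-migration
are not modelled.

**Release-limited availability.** Each sublayer's deposit is split into an
immobile depot and a mobile pool. The measured in-vitro cumulative release
fraction is used as a piecewise-linear table `F(t)`; the depot→mobile
transfer rate of a sublayer holding dose `m` is `m·F′(t)`, spread evenly
over the sublayer's ten sections (intra-sublayer mixing is fast compared
with trans-layer diffusion). Beyond the last tabulated time the fraction is
held constant, so a table ending below 1 never releases the remainder.
Piecewise-linear interpolation was chosen over splines to preserve
monotonicity exactly. Applying one common release table to per-sublayer
depots is mathematically identical to applying it to the total dose.

**Transport.** Within a layer, sections exchange drug by Fickian diffusion
(`dA/dt = D·ΔC·Ar/dh`). The three layers share one `D` and one `K` each;
the 4-sublayer structure is retained purely as the dose-application grid.
Layer interfaces use a two-film series conductance with the partition
ratio `R = K_deep/K_shallow`, so flux vanishes at `C_deep = R·C_shallow`
and the homogeneous limit (`R = 1`, equal `D`, equal half-widths) reduces
to plain series-resistance diffusion. The effective film thickness `h*` is
the **half-width of the section adjoining the interface** (`dh/2`), which
is the only choice consistent with the intra-layer discretisation — a
switch (`interface_half_width=False`) restores the literal full-layer
reading for comparison. In-vitro runs drain the deepest dermal section
into a perfect sink at `D_DE·C/dh·Ar`; in-vivo runs remove drug from every
dermal section at `k_DE·dh·Ar·C_free` (switchable to deepest-sublayer-only
via `clearance_deepest_only`). Hair-follicle and surface-evaporation
pathways carry exactly zero flux. A third mode, `closed`, disables both
exits; it exists for diagnostics (partition-equilibrium and mass-balance
checks) and is not a physiological scenario.

**Dermal binding.** The binding factor `BF ≥ 1` is implemented as a
mobile-fraction divisor: the concentration driving intra-dermal diffusion,
the sink flux and clearance is `C_free = C/BF`. Interface driving terms use
total concentration (partitioning between layers is what `K` describes).
This is a modelling assumption — the commercial implementation this model
mirrors does not publish its binding equations — and it produces the
expected phenomenology: binding chiefly delays systemic appearance without
changing the mass balance.

**Systemic link.** Cleared drug enters a single well-stirred compartment,
`dC_p/dt = (input − CL_sys·C_p)/V_d`. A one-compartment linear model
deliberately replaces organ-level whole-body modelling, which is
software-specific and not reproducible from published inputs; with amounts
in µg and `V_d` in litres, `C_p` is directly in ng/ml.

## Numerics

The assembled system is linear with a piecewise-constant source (the
release-table derivative), so the right-hand side is a constant matrix
`M` plus a per-segment vector. Integration uses the stiff-capable LSODA
solver with the exact constant Jacobian, relative tolerance 1e-8 and
absolute tolerance 1e-12 × dose, restarting at every release-table knot so
source discontinuities never cross a solver step. Output times are solver
evaluation points, not interpolations. Identical inputs give bitwise
identical trajectories on one platform. Internally the model works in
cm/s/µg; all I/O uses µm, hours, mg/µg and ng/ml.

Section counts trade accuracy for speed: with the default 4 × 10 grid the
24-h cumulative sink amount of the fast-releasing scenario changes by
about 0.2 % when sections are doubled and under 0.1 % on the next
doubling (recomputed by `scripts/acceptance.py`). Negative amounts beyond
1e-9 × dose abort the run with a diagnostic carrying the failure time.

The standalone `constant_source_slab` helper simulates the classic
single-membrane Franz-cell configuration (clamped donor concentration,
perfect sink) with half-width boundary conductances, making its discrete
steady-state flux equal the Fickian `D·K·C·Ar/h` exactly; it is the
package's analytic-limit check for the discretisation.

## Parameters

| parameter | units | meaning |
|---|---|---|
| `D_SC, D_ED, D_DE` | cm²/s | layer diffusion coefficients |
| `K_SC, K_ED, K_DE` | – | layer/vehicle partition coefficients |
| `k_DE` | 1/s | dermal clearance rate into the circulation |
| `BF` | – | dermal binding factor (total/free concentration) |
| `h_SC, h_ED, h_DE` | µm | layer thicknesses |
| `V_d`, `CL_sys` | l, l/h | lumped systemic disposition |

The three bundled scenarios (`LOR`, `CPM`, `ITZ`) use the study geometry
(500 µm pyramidal needles, 333 µm base, ~70 % insertion; 25 needles/cm²
for LOR and CPM at 0.5/0.1 mg, a 14 × 14 array at 4.1 mg for ITZ) and
porcine-ear layer thicknesses (21/72/1500 µm nominal). Parameters that
were reported after optimisation are the bundle defaults (LOR:
`D_DE = 5.34e-8` cm²/s, `K_DE = 38.55`, `K_ED = 46.00`, `h_DE = 1439.42`,
`h_ED = 85`; CPM: `D_DE = 2.79e-7`, `h_DE = 1237.02`, `h_ED = 80`; ITZ:
`BF = 1262.99`), with the corresponding pre-optimisation values shipped in
`TABLE_STARTING` for fitting studies.

**Stand-ins.** No published values exist for the remaining coefficients,
so the bundles carry order-of-magnitude choices made once for
physiological plausibility and documented here as such: `D_SC = 1e-9`
cm²/s everywhere (tight SC barrier, though largely bypassed by the
needles); `D_ED = 1e-8` for the lipophilic drugs and `1e-7` for
hydrophilic chlorpheniramine; `K_SC = 44.67` for loratadine (matching its
pre-optimisation partition family), unit partition for chlorpheniramine,
`K = 50` for itraconazole (high skin affinity); dermal clearance
`k_DE = 5e-3` 1/s, which combined with the ITZ binding factor gives an
effective systemic transfer of ~0.014 1/h and a plasma peak near 100 h;
minipig disposition `V_d = 40` l, `CL_sys = 0.8` l/h, giving exposure of
the right order for a ~4 mg dermal dose. None of these is asserted as a
measured value.

## Release tables

The fast (`CPM`) table uses the two measured anchors — 39.3 % at 5 min,
complete at 30 min — with linear infill. The prolonged profiles are
first-order curves normalised to reach 1 exactly at 24 h (`LOR`,
`k = 0.25`/h) and 120 h (`ITZ`, `k = 0.05`/h), tabulated at 13 points.
These shapes are plausible stand-ins consistent with the reported release
durations, not digitised experimental curves.

## Synthetic observations

`make_noisy_observations` samples a simulated trajectory (ED, DE and sink
amounts in vitro; plasma in vivo) at given times and multiplies each point
by independent lognormal noise with unit mean and the requested CV
(`σ² = ln(1+cv²)`), seeded for reproducibility. This emulates assay-level
multiplicative error only: it has no inter-animal or inter-cell
variability, no correlated errors from shared skin preparations, no
quantification limits, and no model misspecification. Tests passing on
these data therefore demonstrate the correctness and statistical behaviour
of the machinery under the model's own assumptions, not predictive
accuracy on real skin.

## Inference

Sensitivity coefficients are normalised local elasticities
`S = (ΔY/Y)/(Δp/p)` from central differences at ±10 % by default. Fitting
minimises weighted least squares with the Levenberg–Marquardt algorithm
(via lmfit) inside box bounds; residuals are linear by default with a
log₁₀ option for data spanning decades. Default bounds: thicknesses ±50 %
of nominal, other parameters a factor of 2 either way.

**Identifiability.** The bundled recovery study (refit of the five
loratadine parameters from ED/DE/sink amounts at 1, 3, 6, 8 and 24 h with
10 % noise) is deliberately kept as an honest characterisation of the
experimental design rather than a demonstration of success: the log-log
sensitivity Jacobian at the optimum is ill-conditioned (singular values
spanning three orders of magnitude), because over a 24-hour window the
dermis is only partially penetrated and the data constrain combinations
close to `K·√D` rather than partition and diffusion separately — the
classic sloppiness of dermal absorption parameters. Noise-free data refit
from a different start reach machine-zero residuals on a parameter ridge,
and under noise the per-parameter recovery rates reported by
`scripts/acceptance.py` are correspondingly far from certain for
`K_DE`, `K_ED` and `D_DE`, while `h_ED` is recovered reliably. Log-scale
residuals are used for this study (the sink spans ~four decades over the
window) and each fit is capped at 500 model evaluations, since on the flat
ridge the optimiser otherwise stalls making sub-ppm parameter changes.
Breaking the degeneracy would require later sampling times (so the finite
dermal thickness is felt) or independent measurements of one of the
confounded parameters.

## Validation metrics

AAFE is `10^(mean |log₁₀(pred/obs)|)`; for a single pair this is
`max(pred/obs, obs/pred)`, which the worked PK-table example confirms.
Pairs with a zero observation are excluded and counted (fold metrics are
undefined at zero — the same reason in-vivo profile comparison windows
start after the last observed zero). The two-fold gate is
`0.5 ≤ pred/obs ≤ 2`. Non-compartmental parameters use first-occurrence
`t_max` and linear-trapezoid AUC with interpolated, span-clipped window
edges, making the summary invariant to inserting interpolated points.

## Known limitations

* One `D`/`K` per layer: the four "phases" per layer are a bookkeeping
  grid, not parameterised sub-phases.
* No needle-density ("bed of nails") effects, insertion variability,
  polymer-matrix influence on in-skin diffusion, hair-follicle transport,
  evaporation, or skin metabolism.
* The systemic stand-in is one linear compartment; organ-level PBPK,
  enterohepatic recycling and oral-arm simulation are out of scope (an
  exogenous tabulated plasma input can be coupled manually for exploratory
  use).
* The interface half-width convention and the binding-factor placement are
  reasoned reconstructions of an unpublished discretisation, exposed as
  switches rather than asserted.
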