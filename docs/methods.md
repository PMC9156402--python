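# Methods

## The system

A ring of soft, 3D-printed protein-hydrogel pillars is coated with a minimal
actomyosin cortex: a crosslinked F-actin meshwork spanning the ring, with
pre-assembled myosin-II myofilaments that generate contractile stress upon
ATP addition. The network pulls the pillar tips toward the ring centre; the
pillars act as calibrated cantilever force sensors. `cortexforge` implements
the quantitative chain of that assay — contraction dynamics, force
inference from pillar bending, centreline extraction from image stacks, and
myofilament counting — together with seeded synthetic-data generators that
close the loop against known ground truth.

## Contractility model

The 1D model (`cortexforge.model`) treats one pillar and its share of the
network. The pillar is a spring `k_p` (pN/µm); the network contributes a
parallel spring `k_am` and a dashpot `gamma_am` (pN·s/µm). Myofilaments from
a pool of `N_m` bind and unbind the actin network; each bound filament
exerts `f_s` (pN). With tip displacement `x` (µm, positive inward) and
bound number `n_b`, the overdamped dynamics are

    gamma_am dx/dt = F_A − (k_p + k_am) x
    dn_b/dt        = k_on (N_m − n_b) − k_off n_b

**Load-dependent mode** (the full model): `F_A = n_b f_s`, `k_on = k_on0`,
and the unbinding rate falls with the per-filament load,

    k_off(f) = k_off0 exp(−f / f_d),    f = (k_p + k_am) x / max(n_b, 1e-6),

a catch-bond-like law. As stress builds, motors stay engaged longer, more
motors share the load, and the force grows — positive feedback that
produces the observed accelerating-then-decelerating contraction. At any
fixed point with `n_b > 0` the force balance pins the per-filament load at
exactly `f_s`, so the steady bound number — and hence the steady active
force — is independent of `k_p`; the pillar-borne share `k_p/(k_p+k_am)`
varies by under 5% across `k_p` ∈ [20, 500] pN/µm when `k_am` = 1 pN/µm.
This is the mechanism behind the stiffness-insensitive steady-state force.

**Density-only mode** (the control): all feedback enters through actin
densification instead. As the network contracts toward the ring centre
(radius `R`), the areal density grows as `rho(x)/rho0 = R/(R−x)`; both the
force per bound filament and the binding rate scale with this factor, while
unbinding is load-independent (`k_off = k_off0`). Putting the density
factor on binding as well as force follows from the premise of the control
— myosin engagement depends on how much actin there is to bind — and is
what gives this variant its distinctly larger (and oppositely mechanistic)
stiffness dependence of the steady force: simulated spread 1.12 vs 1.05 for
the load-dependent model over `k_p` ∈ [20, 500] pN/µm. For sufficiently
strong motor activity the density-only model has no balance point short of
`x = R` (runaway densification); the integrator detects this and raises an
explicit error rather than grinding at the singularity.

### Reference parameters

Defaults (`REFERENCE_PARAMETERS`), overridable everywhere; a documented
operating point, not a measurement:

| parameter | value | unit | why |
|---|---|---|---|
| `k_p` | 35 | pN/µm | stiffness of the softest well-characterised pillars |
| `k_am` | 1 | pN/µm | network much softer than the pillars |
| `gamma_am` | 2000 | pN·s/µm | sets the ~1 min stress build-up timescale |
| `N_m` | 10 | – | effective force-generating pool per pillar |
| `f_s` | 40 | pN | mid-range single-myofilament force (20–60 pN) |
| `k_on0` | 0.05 | 1/s | slow baseline recruitment |
| `k_off0` | 1.0 | 1/s | fast zero-load unbinding |
| `f_d` | 10 | pN | load scale of unbinding suppression |
| `R` | 13 | µm | ring radius at tip height (D = 26 µm) |

At this point the simulated steady pillar force is ≈ 285 pN, time to peak
velocity ≈ 1.9 min, and ring-level peak power (ten pillars) ≈ 3.6 × 10⁻¹⁷ W
— the order of magnitude of the assay. Note the load-dependent model has no
geometric coupling to `R`; at the softest stiffness in the sweep the steady
displacement (13.2 µm) slightly exceeds `R`, which is tolerated in this
mode (`x < R` is enforced only where the densification law needs it).

### Numerics

LSODA (stiffness-switching) with `rtol = 1e-8`, `atol = 1e-10`: binding is
fast (1/s) against slow stress build-up (~100 s), so the system is
moderately stiff. Parameter schedules (ATP switch, washout, photoactivation
emulations) restart the integrator exactly at each switch time, carrying the
state across the discontinuity. The "unloaded" initial condition is
`x = 0`, `n_b = k_on0 N_m/(k_on0 + k_off0)` (motors equilibrate with the
network before activation); "preloaded" starts from the steady-state bound
number and responds measurably faster. Velocity is reported from the model
right-hand side, so the force balance holds exactly at every sample. The
steady state is found by bracketing root finding (1D in `n_b` for the
load-dependent mode, 1D in `x` on `[0, R)` for the density mode, taking the
first, stable crossing); cases with no positive fixed point return a
zero state flagged degenerate. Reaching 1e-6 relative agreement between the
integrator and the fixed point takes roughly 50 mechanical timescales — the
slow coupled binding/stress eigenmode relaxes much more slowly than
`gamma_am/(k_p + k_am)` alone.

Mechanical power is reported as `P = n_pillars · F_pillar · v` (converted
at 1 pN·µm/s = 10⁻¹⁸ W), i.e. the rate of work done *through* the pillars;
the work done *by* the motors, `∫ n F_A v dt` (`active_work`), additionally
pays the dashpot dissipation and strictly exceeds the stored elastic energy
whenever `gamma_am > 0`.

## Beam mechanics

`cortexforge.beam` uses linear Euler–Bernoulli theory for a clamped
circular cantilever: `I = π d⁴/64`, tip stiffness `k_p = 3EI/L³`
(1 kPa = 1000 pN/µm²), and the standard cubic profile for a point load at
height `a` (default: the tip; `attach_height` is exposed because the exact
engagement height of the network is not known — moving it is a sensitivity
analysis, not a fit parameter). Strains up to ~0.3 are treated within
linear theory, matching how the assay itself is analysed.

The inverse problem is linear in the force, so `fit_force` is closed-form
least squares on the unit-load shape, optionally `1/σ²`-weighted. Samples
below `foot_cutoff` (default 2 µm) are excluded: printed pillars have a
stiffer foot that the ideal cantilever model does not describe. Imperfectly
straight pillars are handled by fitting a force to the pre-contraction
profile and subtracting its *predicted* shape (raw subtraction available);
subtracting the fitted shape filters measurement noise in the reference
profile instead of injecting it into the corrected one.

## Image pipeline

`cortexforge.imaging` mirrors a slice-wise confocal protocol: per-slice
binarization (Otsu by default; fixed-value and percentile thresholds
available since the appropriate choice is instrument-dependent), watershed
splitting of touching footprints seeded from Euclidean-distance-transform
maxima (minimum seed separation ≈ one pillar radius), area filtering,
intensity-weighted centre of mass per footprint, and cross-slice linking by
globally optimal nearest-centroid assignment within 2 µm. Before/after
centrelines are matched by base position and differenced; the displacement
is projected on the unit vector from the pillar base toward the ring
centre, giving a signed deflection profile per pillar that feeds
`fit_force`. Processing is 2D-per-slice with linking, not 3D segmentation,
because pillars are near-vertical and the slice-wise protocol is what the
assay uses.

## Myofilament quantification

`cortexforge.quantify` fits an ordinary-least-squares standard curve to a
labelled-myosin dilution series, inverts a measured mean intensity to the
labelled concentration, scales by the labelling ratio (default 10%),
converts to molecules in the interrogated volume (defaults 1,055 µm³ inner
+ 1,225 µm³ ring, summed because the assay reports one count over both
regions; per-region counts are also emitted), and divides by the monomers
per average myofilament (560 µm⁻¹ × 0.56 µm = 313.6). Intensity and curve
uncertainty propagate to the count by a first-order delta method including
the slope–intercept covariance.

## Model calibration

`cortexforge.fitting` implements "fit once, predict everywhere": bounded
nonlinear least squares in log10 parameter space from seeded
Latin-hypercube multistarts, against a single displacement trajectory at
one known stiffness (`k_p` comes from geometry and is never fitted).
`N_m·f_s` is fittable only as a lumped amplitude: pool size and unit force
are not separately identifiable from one displacement curve.

A single curve does not constrain four free parameters either: the
four-dimensional default set `{gamma_am, f_d, n_m_f_s, k_off0}` has sloppy
directions (loss-Hessian condition numbers above 1e8 are detected and
reported as a warning instead of meaningless standard errors, and optima
with different `gamma_am` can beat the generating parameters on noisy
data). The recommended recovery protocol therefore fixes the parameters
known from the literature block and frees only `{gamma_am, f_d}`; under
that protocol both are recovered to ~1% median error at 2% trajectory
noise. Optima landing within 0.1% of a bound are flagged as boundary
solutions. `predict_across_stiffness` then sweeps `k_p`, reporting the
steady force and peak velocity per grid point; failed grid points are NaN
rows, never silently dropped.

## Synthetic data

Generators return ground truth alongside every output and require explicit
seeds. Contraction curves get i.i.d. Gaussian position noise (default
σ = 0.05 µm) with velocity recomputed by central differences, as it would
be from tracked positions. The renderer draws pillars as circular
cylinders along straight (before) or Euler-beam-bent (after) centrelines on
a ring of diameter 26 µm, blurs with an anisotropic Gaussian PSF (default
σ = 0.3 µm axial, 0.15 µm lateral — nominal confocal values), and adds
mixed Poisson + Gaussian read noise. The default lateral voxel, 0.099 µm,
matches the assay's pixel scaling; the axial step (0.5 µm) is a typical
confocal z-step, chosen since no value is dictated by the data format.
SNR is defined as signal amplitude over the total noise standard deviation
at a bright voxel; the default settings give SNR ≈ 12.8.

What the renderer does **not** emulate: the actin meshwork texture, network
holes, uneven labelling, stack drift/registration error, depth-dependent
attenuation, or a measured PSF. Passing closed-loop tests therefore shows
the pipeline is unbiased and precise for cylinder-like objects under
realistic blur and shot noise — not that it is robust to every artefact of
real confocal data.

## Problem sizes in the test suite

End-to-end force-recovery checks run 20 seeded replicates of full 10-pillar
rings at a 0.15 µm lateral voxel (the rendering and segmentation cost
scales quadratically with lateral sampling, and recovery error at 0.15 µm
is far below the 5% criterion); parameter recovery runs 20 seeded noisy
fits with the two-parameter protocol; the quantification round trip runs
200 replicates. Simulated horizons are 600 s (dynamics) or ~50 mechanical
timescales (steady-state comparisons).

## Known limitations

- The 1D model lumps the ring into identical non-interacting pillars; no
  spatial continuum, no network rupture or plasticity, no photodamage.
- The beam model assumes linear elasticity, a uniform circular section and
  a perfectly clamped base; the stiff printed foot is handled by exclusion,
  not by modelling.
- The density-only control is one reasonable formalisation of
  density-mediated contractility; other densification laws would change
  the magnitude (not the existence) of its stiffness dependence.
- Delta-method count uncertainties are first-order and assume the
  calibration residual variance is well estimated from few dilution levels.
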