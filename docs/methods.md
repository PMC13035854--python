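# Model and methods

`carsim` simulates the light-controlled assembly and contraction of
networks of Tcb2, a Ca²⁺-binding contractile protein from *Tetrahymena
thermophila*, in a thin in-vitro sample. Ca²⁺ is stored on a photolabile
chelator (DMNP-EDTA); patterned 365 nm light cleaves the chelator,
releases Ca²⁺ locally, and the Ca²⁺-loaded protein polymerizes into a
contractile gel. The package couples a reaction–diffusion description of
the chemistry to overdamped linear elasticity with a chemically set rest
strain, plus analysis metrics, a reduced fixed-chemistry contraction
model, and a reinforcement-learning control layer.

## Chemical model

Eight species live on the domain (concentrations in µM): free Ca²⁺
(`C_C`), viable unbound chelator (`C_D`), Ca-loaded chelator (`C_E`),
degraded chelator (`C_X`, bookkeeping), diffusing Tcb2 without/with Ca²⁺
(`C_F0`, `C_FC`), and network-bound Tcb2 without/with Ca²⁺ (`C_B0`,
`C_BC`). The reactions are

* photolysis `E → C + (1−f_deg)·D + f_deg·X` at rate `k_ph·L(r,t)·C_E`,
  where `L` is the light intensity (arbitrary units; only `k_ph·L` is
  physical) and `f_deg` is the fraction of chelator destroyed per
  photolysis event;
* chelation `D + C ⇌ E` (`k_onD`, `k_offD`), effectively irreversible at
  the defaults (nM-scale affinity);
* Ca²⁺ exchange `F0 + C ⇌ FC` and `B0 + C ⇌ BC` with the same
  (`k_onT`, `k_offT`) in the free and bound states;
* network joining `FC → BC` at `k_bind·S(C_Btot)` and `F0 → B0` at the
  much smaller `k_bind0·S(C_Btot)` — the polymerization interface is
  exposed by the Ca²⁺-induced conformational change, and zero-light
  controls show no network, so Ca-free joining is limited to a weak
  nucleation channel;
* network leaving `B0 → F0` at `k_u0` and `BC → FC` at `k_uCa ≪ k_u0`
  (Ca²⁺ stabilizes the network).

`S(C) = (σ₀ + C)·max(0, 1 − C/C_sat)` is the density of available
binding sites: bound Tcb2 creates new sites (with a nucleation floor σ₀)
while dense network blocks them sterically. The functional form is a
modeling choice; only its non-monotonicity matters for the phenomena
reproduced here, and both parameters are config-exposed.

Mobile species diffuse; bound Tcb2 does not; advection of the diffusing
species by network motion is neglected (the system is at low Péclet
number). Degraded chelator is tracked explicitly so that the chelator
pool is a testable conserved quantity.

## Mechanical model

The gel is an overdamped, azimuthally symmetric, linearly elastic solid
on the fixed grid (small-strain, plane-stress interpretation of the thin
sample). The Lamé fields grow with the bound density,
`μ = μ_floor + μ₀·C_Btot^p` and `λ = λ_ratio·μ`, and the isotropic rest
strain is `g = g_max·φ` with `φ = C_BC/C_Btot` the Ca-loaded fraction —
Ca²⁺ binding shortens the monomer rest length, so loaded regions want to
contract (`g_max < 0`). Motion obeys the instantaneous force balance
`Γ·V_r = f_r`, with `f_r = ∂_r σ_rr + (σ_rr − σ_θθ)/r` and the spatially
varying coefficients kept inside the derivative: it is exactly these
density-gradient terms that push material *up* the stiffness gradient and
reverse the contraction direction near a boundary density peak.

The discretization is variational: strains are evaluated on the cells
between nodes, the elastic energy is a cell quadrature, and the nodal
force is its exact analytic gradient. Consequences: the
force/energy-gradient consistency check holds to round-off, the
homogeneous operator is symmetric negative semi-definite, and overdamped
relaxation can never increase the energy. Boundary conditions are
`U_r(0) = U_r(R_max) = 0`.

## Numerics

Explicit Heun (predictor–corrector) stepping with a fixed step per run,
`dt = safety · min(dr²/4D_max, 1/R_rate, Γ·dr²/4(λ+2μ)_max)`, where
`R_rate` bounds the fastest linearized per-capita consumption rate of any
species. Because every species' sinks are proportional to the species
itself, this step bound also guarantees non-negative concentrations:
the integrator never clips, and a negative value beyond round-off aborts
the run with the offending field and node named. Chemical species use
no-flux (Neumann) boundaries in flux form, so the discrete cell totals of
Ca²⁺, Tcb2 and chelator are conserved exactly; `conserved_totals` audits
them with the finite-volume cell weights that make the invariance exact
(the general-purpose `radial_integral` uses Simpson's rule instead, which
is higher order but not the scheme's discrete invariant). The radial
Laplacian is regularized at the origin by symmetry (`2·∂²_r f`).

The same arithmetic is implemented twice: a vectorized numpy path and a
numba-compiled loop kernel used for long runs; a regression test holds
them to round-off agreement. A chemistry-only Cartesian 2D mode supports
arbitrary illumination masks (star shapes, moving spots) and matches the
radial solver on disks to <2 % RMS.

Problem sizes used by the shipped analyses: continuous-protocol runs use
a 1 µm grid out to R_max = 192 µm; pulsed 30-cycle runs 3 µm out to
384 µm; the 160-cycle endurance run 6 µm out to 864 µm; RL training
3 µm out to 192 µm. The outer radius matters physically, not just
numerically: it sets the chelator reservoir that refills the illuminated
zone between pulses (the experimental chamber is millimetres across, so
its reservoir is effectively infinite; the endurance run therefore gets
the largest affordable domain).

## Default parameters and calibration

`scripts/calibrate.py` writes `carsim/data/default_params.toml` and
re-measures the calibration observables. Anchored values: the pool
concentrations (0.54 mM Tcb2, 6.8 mM DMNP-EDTA, 3.4 mM Ca²⁺; 2:1
chelator:Ca premix, all Ca initially chelated), the Tcb2 monomer
diffusivity `D_T = 10 µm²/s`, millisecond photolysis (`k_ph = 100` per
intensity per s at full power `A = 1`), effectively irreversible
chelation, and `Γ = 1` fixing the stress unit. The remaining rates and
moduli were calibrated, in the same spirit as fitting a model to
observables, against: √t growth of the detected network radius,
growth stalling when `f_deg = 0`, second-scale pattern formation,
continuous-protocol CAR width/speed (~13 µm, ~0.21 µm/s at 30 s),
pulsed-protocol CAR (~62 µm, ~0.52 µm/s at the 30th cycle), ~0.4 µm/s
across 50–100 µm illumination diameters, ≥150-cycle endurance, and a
fast-mechanics/slow-chemistry timescale separation.

Two calibration outcomes deserve emphasis:

* **Supply-limited binding (`C_sat > C_T_tot`).** With the saturation
  density above the total Tcb2 pool, the local bound density is limited
  by monomer supply; inward-diffusing monomers bind first at the
  periphery, producing the boundary-peaked density profiles that drive
  both the broad pulsed-protocol active region and the contraction
  reversal. With `C_sat` below the pool the density saturates flat,
  stress becomes uniform, and the active region collapses to a thin edge
  layer — qualitatively wrong.
* **A 2:1 mass-balance halo.** On first exposure the released Ca²⁺ bolus
  is fully absorbed by the free chelator at radius `ρ·√2` (set by the 2:1
  loading, independent of rates), stamping a low-density network out to
  ~53 µm for a 75 µm disk within seconds. The sustained front then
  advances diffusively through this halo.

## Analysis metrics

The Ca²⁺-driven active region (CAR) is the outermost contiguous radial
region where `|V_r|` exceeds 0.2 µm/s (the conventional cutoff; the
region edges are taken at the first/last super-cutoff nodes, and the
total width over all disjoint regions is also reported). Pulsed-protocol
CAR metrics are read at the end of each 1 s on-window; the
diameter-consistency speed averages pulses 11–30. The network radius is
the outermost threshold crossing of `C_Btot`, linearly interpolated,
with a default threshold of 5 % of `C_sat`; the growth exponent is the
log–log slope of radius against time over the second half of a run.
Tracer advection integrates `dR/dt = V_r(R, t)` through saved frames
(midpoint velocity between frames).

## Reduced contraction model

Chemistry is frozen: a plateau-plus-boundary-peak density
`C(r) = C_max·[a + (1−a)·exp(−(r−r*)²/2s²)]` inside `r*` (Gaussian decay
outside) and a sigmoidal activation `φ(r) = 1/(1+exp((r−ρ)/w))` are
imposed, and the instantaneous velocity at `U_r ≡ 0` is solved once.
The flatness `a` controls the relative boundary accumulation; sweeps of
`a`, `r*`, `w` and `μ₀` reproduce the reversal phenomenology (outward
lobe shrinking with `a`, vanishing as `r*` outgrows the light, weakening
with `w`, both extrema linear in `μ₀`). The profile family is a
documented choice with the stated limiting behaviors; the defaults are
`a = 0.3`, `r* = 40 µm`, `s = 10 µm`, `ρ = 37.5 µm`, `w = 5 µm`. The
`w`-monotonicity holds on sweeps up to `w ≈ 12 µm` in this geometry; at
much larger widths the activation tail couples to the outer density
flank and the trend flattens.

## Control layer

The environment advances the full coupled model by one control interval
(1 s) per action; the agent observes `U_r(r0 = 50 µm)` (optionally
augmented with the reference value and normalized episode time — the
default), and actions are the radius and amplitude of a sigmoidal light
profile. The reward `−(U_r(r0) − U_ref)²` tracks an overdamped-spring
reference toward `U_goal` with rate `k_spring`, giving set-point and
rate-shaping task families. Episodes are 30 steps; evaluation episodes
jitter the chemical pools by ±2 % (pipetting variability) and can delay
the displacement observation by an integer number of control steps.

DDPG is implemented directly in numpy (MLPs with manual backprop and
Adam, target networks, replay buffer). Three choices matter and are
deliberate:

* The amplitude action is bounded at `A_max = 0.05` and mapped
  quadratically. At `k_ph = 100` any amplitude above ~0.05 uncages the
  local chelator completely within one control interval, so the entire
  useful dynamic range lies at small amplitudes; without the bound and
  the quadratic map the usable actions collapse into the saturated tail
  of the tanh actor and learning degenerates to bang-at-maximum.
* Exploration noise is temporally correlated (Ornstein–Uhlenbeck).
  Discovering the "back off the light" half of the policy requires
  sustained low-amplitude excursions, which uncorrelated Gaussian noise
  essentially never produces.
* Training randomizes the observation latency per episode over 0–3
  control steps, evaluates greedy checkpoints on a settling score (late
  half of the episode, at zero and maximal latency), keeps the best
  checkpoint, and returns the best of several independent restarts (two
  by default; the reproduction script uses six). This
  makes per-seed outcomes reliable despite DDPG's notorious run-to-run
  variance.

## What the synthetic data does and does not capture

All inputs are generated by the model itself from uniform initial
conditions; there is no external data. The generator reproduces the
qualitative mechanisms (diffusion-limited growth, chelator-degradation
dependence, pulsed recharging, density-gradient reversal, particle-scale
transport by the velocity field) and the calibrated magnitudes of the
headline observables. It does not emulate experimental imperfections:
angular asymmetries, optical sectioning and segmentation noise,
viscoelastic (fluid-like) relaxation seen as residual particle drift,
sample boundaries, or photobleaching. Passing tests therefore validate
the model and its implementation, not agreement with any particular
experimental image.

## Known limitations

* Mechanics is azimuthally symmetric; the 2D mode is chemistry-only.
* Linear elastic solid with drag — no viscoelastic flow, no inertia,
  no finite-strain remeshing.
* One effective Ca²⁺ site per Tcb2 (the four EF-hands are
  coarse-grained); cooperative binding is not modeled.
* The mechanical re-expansion/dissolution 1/e-time ratio is ≈6 at the
  defaults when both are measured from their post-pulse peaks; the
  contraction transient itself overlaps the first seconds of the
  light-off phase.
* The timescale hierarchy (ms photolysis vs multi-second mechanics)
  makes the explicit integrator reaction-limited during illumination;
  very long protocols rely on the compiled kernel.
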