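# carsim

Simulation and analysis of light-controlled, Ca²⁺-driven contractile
protein networks.

Tcb2, an EF-hand Ca²⁺-binding protein from the ciliate *Tetrahymena
thermophila*, self-assembles into a contractile gel when Ca²⁺ is
released — for example by photolysis of the caged chelator DMNP-EDTA
under patterned 365 nm light. `carsim` is for modelers and
experimentalists studying such chemomechanical materials: it integrates
a coupled reaction–diffusion / overdamped-elasticity continuum model of
the system, measures the observables used to characterize it
(network radius and growth exponent, the Ca²⁺-driven active region,
kymographs, tracer transport), solves a reduced fixed-chemistry
contraction model that isolates the density-gradient reversal of
contraction direction, and trains closed-loop light-control policies by
reinforcement learning.

## Model in brief

Chemistry: eight species (free Ca²⁺, viable/loaded/degraded chelator,
free and network-bound Tcb2 with and without Ca²⁺) react and diffuse
with no-flux boundaries; light drives photolysis `E → C` at rate
`k_ph·L·C_E`, destroying a fraction `f_deg` of the chelator per event.
Network joining is fast for Ca²⁺-loaded Tcb2 and gated by a non-monotone
binding-site availability `S(C_B) = (σ₀+C_B)(1−C_B/C_sat)`.

Mechanics: an overdamped, azimuthally symmetric linear elastic solid
whose Lamé fields grow with the bound density, `μ = μ_floor + μ₀·C_B`,
and whose isotropic rest strain `g = g_max·φ` shifts negative with the
Ca²⁺-loaded bound fraction φ. Velocity obeys the instantaneous force
balance

    Γ V_r = ∂_r σ_rr + (σ_rr − σ_θθ)/r ,
    σ = λ(r) tr(ε − gI) I + 2μ(r)(ε − gI) ,

with the inhomogeneous coefficients kept inside the derivative — these
density-gradient forces are what push interior material outward, up the
stiffness gradient, when bound Tcb2 accumulates at the network boundary.

See `docs/methods.md` for the full model, discretization, calibration
provenance, and limitations.

## Worked example

Continuous versus pulsed illumination through a 75 µm disk, with the
calibrated defaults:

```python
import numpy as np
import carsim as cs

p = cs.default_params()

# 30 s of continuous illumination
grid = cs.build_grid(192, 1.0)
proto = cs.LightProtocol(kind="disk_step", A=1.0, rho=37.5, w_s=3.0)
cont = cs.run_simulation(cs.RunConfig(grid=grid, params=p, protocol=proto,
                                      duration=30.0, save_every=1.0))
car = cs.car_metrics(cont.field_frames("V_r")[-1], grid, cutoff=0.2)
print(f"continuous 30 s: CAR width {car.width:.1f} um, "
      f"mean speed {car.mean_speed:.2f} um/s")

# 30 cycles of 1 s light / 29 s dark
g3 = cs.build_grid(128, 3.0)
pulsed = cs.LightProtocol(kind="pulse_train", A=1.0, rho=37.5, w_s=3.0,
                          t_on=1.0, t_off=29.0, n_cyc=30)
traj = cs.run_simulation(cs.RunConfig(grid=g3, params=p, protocol=pulsed,
                                      duration=900.0, save_every=0.5))
i30 = int(np.argmin(np.abs(traj.times - 871.0)))   # end of 30th pulse
car30 = cs.car_metrics(traj.field_frames("V_r")[i30], g3, cutoff=0.2)
print(f"pulsed 30th cycle: CAR width {car30.width:.1f} um, "
      f"mean speed {car30.mean_speed:.2f} um/s")

R = [cs.network_radius(c, g3, 0.05 * p.C_sat)
     for c in traj.field_frames("C_Btot")]
print(f"network radius after 30 cycles: {R[-1]:.0f} um")
```

prints

```
continuous 30 s: CAR width 7.0 um, mean speed 0.24 um/s
pulsed 30th cycle: CAR width 57.0 um, mean speed 0.59 um/s
network radius after 30 cycles: 75 um
```

Both protocols deliver the same 30 s of total light, but the pulsed one
"recharges" between flashes: Ca²⁺ unbinds in the dark, the rest length
resets while the network only partially dissolves, and the next flash
re-contracts nearly the whole network — so its active region is about
eight times wider and more than twice as fast as the thin peripheral
annulus of the continuous protocol.

The same runs are available from the shell:

```
carsim simulate --config run.toml --out traj.h5
carsim analyze traj.h5 --metrics car,radius,growth --out metrics.csv
carsim reduced-sweep --param a --values 0.05:1:20 --out sweep.csv
carsim train-control --task task.toml --out policy.bin
carsim eval-control --policy policy.bin --latency 3 --episodes 5 --out eval.csv
```

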