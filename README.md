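# npbilayer

Region-resolved analysis of gold-nanoparticle / lipid-bilayer molecular
dynamics trajectories.

A bare (uncapped) gold nanoparticle adsorbed on a phosphatidylcholine
bilayer perturbs the membrane in two distinct zones: lipids in direct
contact deform and slow down, while lipids far from the adhesion site
become *more* ordered, thicker-packed and less fluid. Quantifying that
requires splitting the interacting leaflet into **short-range (SR)**,
**buffer** and **long-range (LR)** lipid populations around the particle
and computing every observable per population. This package implements
that full analysis chain for united-atom AOPC
(1-arachidoyl-2-oleoyl-*sn*-glycero-3-phosphocholine, 56 sites: a
saturated 20-carbon *sn1* chain and a mono-unsaturated 18-carbon *sn2*
chain) bilayers with an embedded fcc gold sphere and water:

* **Nanoparticle construction** — a sphere of radius *r* cut from the
  conventional fcc gold lattice (*a* = 0.4078 nm), centered on a lattice
  atom with an inclusive boundary (*d* ≤ *r*); surface-atom detection by
  coordination number (< 12 neighbours within 0.35 nm).
* **Region partition** — lipids of the interacting leaflet classified by
  the 3D minimum-image distance of their head-group nitrogen from the
  particle center of mass: SR for *d* ≤ *r* + 1.5 nm, buffer for the next
  0.5 nm shell (excluded from most analyses), LR beyond; re-tagged every
  10 ns epoch.
* **Structural observables** — partial density profiles ρ(z), 2D water
  density maps ρ(x,z), head-group–gold distance distributions, Au–O RDF
  g(r), head-group angle/dihedral distributions, chain order parameters
  −S<sub>CD</sub> per carbon (molecular-frame reconstruction for
  united-atom chains: S<sub>CD</sub> = ⅔S<sub>xx</sub> + ⅓S<sub>yy</sub>),
  grid-based (50×50) bilayer thickness from leaflet nitrogen planes, and
  the LR area per lipid A<sub>LR</sub> = (l<sub>x</sub>l<sub>y</sub> −
  π(r + 2 nm)²)/N<sub>LR</sub>.
* **Dynamics** — interval-averaged lateral and normal MSD per region and
  diffusion coefficients from the Einstein relation
  (MSD = 4Dτ lateral, 2Dτ normal), reported in units of 10⁻⁷ cm²/s.
* **Synthetic trajectory generator** — a kinematic bilayer +
  nanoparticle + water generator with *known* ground truth (imposed tilt
  order, leaflet separation, area per lipid, per-region diffusion
  constants), so every analysis stage is validated by parameter recovery.

## Worked example

Build the 2-nm particle and run the full pipeline on a synthetic system:

```bash
$ npbilayer build-np --radius 1.0 --out np2nm.gro
249 atoms
```

The 249 atoms are exactly the fcc lattice points within 1.0 nm of the
central atom. With a run config

```yaml
# run.yaml
generator:
  n_lipids_per_leaflet: 64
  n_frames: 201
  dt: 0.1            # ns between frames -> 20 ns trajectory
  np_radius: 1.0     # nm
  np_z_start: 0.5    # particle center 0.5 nm above the midplane (penetrated)
  water_number_density: 3.0
out_dir: results_demo
seed: 2
```

```bash
$ npbilayer run --config run.yaml --quiet
```

the pipeline tags regions per epoch (epoch 0: 21 SR, 11 buffer, 32 LR
lipids of the 64 in the interacting leaflet), writes every observable as
CSV, and summarizes diffusion in `results_demo/diffusion.json`:

```json
"SR_lateral": { "D_e7_cm2_s": 0.998, "uncertainty_e7_cm2_s": 0.002 },
"LR_lateral": { "D_e7_cm2_s": 1.415, "uncertainty_e7_cm2_s": 0.074 }
```

The generator imposed D_SR = 0.98 and D_LR = 1.50 ×10⁻⁷ cm²/s, so the
SR < LR fluidity ordering and the magnitudes are recovered from the
trajectory alone. The mean sn1 −S<sub>CD</sub> per region from
`order_parameters.csv` (SR 0.107 < LR 0.211 here) reproduces the imposed
order contrast between contact and distant lipids in the same way.

## Layout

```
src/npbilayer/
  model.py         data model: Box/Topology/Frame/Trajectory, PBC, leaflets
  gro.py           GRO multi-frame I/O, XYZ/PDB export
  nanoparticle.py  fcc sphere builder, composition, surface atoms
  synth.py         synthetic generator + ground truth, Brownian tracers
  regions.py       SR/buffer/LR classification, epoch re-tagging
  structure.py     densities, distributions, -S_CD, thickness, APL
  dynamics.py      unwrapping, MSD, diffusion coefficients
  pipeline.py      config-driven end-to-end run
  cli.py           `npbilayer` command-line interface
```

See `docs/methods.md` for the models, conventions and known limitations.
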