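# Methods

## Scope and units

The package analyzes trajectories of a united-atom AOPC bilayer with an
embedded rigid gold nanoparticle and water. Units are fixed throughout:
nm, ns, atomic mass units; mass densities are reported in kg/m³ via
1 u/nm³ = 1.66054 kg/m³. Boxes are orthorhombic; triclinic input is
rejected explicitly. The bilayer normal is the box z axis — no director
fitting is attempted. Positions are stored as read; every analysis that
needs whole molecules re-wraps each molecule about its first site under
the minimum-image convention.

## Nanoparticle construction

The particle is the set of fcc lattice atoms within radius *r* of a
lattice atom placed at the origin (conventional cubic cell, 4-atom
basis, lattice constant *a* = 0.4078 nm — the standard value for bulk
gold, exposed as a parameter). The boundary is inclusive (*d* ≤ *r*,
tolerance 10⁻⁹ nm): with this convention the r = 1.0 / 1.75 / 2.5 nm
spheres contain 249 / 1289 / 3925 atoms, each verified in the tests
against an independent integer-lattice enumeration (triples (i,j,k) with
i+j+k even and (i²+j²+k²)(a/2)² ≤ r²). The construction is
inversion-symmetric and its nearest-neighbour distance is a/√2. No
energy minimization or relaxation is applied; structural diagnostics
(pair-distance distribution, coordination-based surface detection) stand
in for it. Surface atoms are those with coordination < 12 within a
0.35 nm cutoff, which sits between the first (a/√2 ≈ 0.288 nm) and
second (a ≈ 0.408 nm) neighbour shells. Note that by this rule the
central atom of the 13-atom cluster is bulk (it has exactly 12
neighbours); the surface set of that cluster is the 12-atom shell.

## AOPC site model

Each lipid has 56 united-atom sites. Head group: choline N with three
N-methyl carbons (C26–C28), the N–C25–C24–O6–P backbone, non-ester
phosphate oxygens O4/O5 and bridging O3/O6, glycerol C23–C22–C1, the
*sn1* ester (O1, carbonyl O7) carrying the saturated 20-carbon chain
C21…C2, and the *sn2* ester (O2, carbonyl O8) carrying the 18-carbon
chain C31…C48 with a cis double bond at C37–C38. The numbering is
self-consistent within this package: the names that carry analysis
semantics (N, P, C24, C25, O3–O6, the chain order) follow the
conventional head-group connectivity, but no claim is made that the full
numbering matches any particular published structure figure.

## Region partition

Lipids of the nanoparticle-interacting leaflet are classified by the 3D
minimum-image distance d of their head-group nitrogen from the particle
center of mass: SR for d ≤ r + 1.5 nm, buffer for
r + 1.5 nm < d < r + 2.0 nm, LR for d ≥ r + 2.0 nm. The 3D Euclidean
distance realizes the "sphere of radius r + 1.5 nm" reading of the
cutoff; boundary ties go to the non-buffer regions (SR closed at its
cutoff, LR closed at its cutoff, buffer open on both sides). Leaflets
are split by the sign of z_P − median(z_P); the interacting leaflet is
the one whose mean phosphorus z is nearer the particle CoM along z, with
exact ties going to the upper leaflet. Tags are re-evaluated every epoch
(default 10 ns) on the first frame at/after the epoch start, with the
particle CoM recomputed there; a running-average CoM would be an equally
defensible choice, and the single-frame convention is declared rather
than inferred. Without a nanoparticle every lipid is LR (reference-system
convention). Buffer lipids enter only the region-count table and the
order-parameter profiles.

## Structural observables

* **Density profiles.** Mass-weighted z histograms divided by bin
  volume, frame-averaged; number-density mode available. The integral
  over z times the box cross-section returns the total selected mass
  exactly (conservation is a test invariant).
* **2D water map.** Counts on an (x,z) grid divided by (dx · l_y · dz),
  averaged over the window (default: last 10 ns).
* **Gold–head-group distances.** Surface gold atoms are restricted per
  frame to those within 0.6 nm of any head-group site; each named site
  within 1.0 nm of that set contributes its *minimum* distance (the
  contact-layer measure; an all-pairs mode exists behind a flag).
  Heights are normalized by contributing sites × bin width, i.e. unit
  area over contributors.
* **RDF.** Standard pair correlation normalized by ideal-gas shell
  counts at the target's mean density; r_max is clipped to half the
  smallest box edge with a warning.
* **Angles/dihedrals.** Interior angle at the middle site;
  signed dihedral in (−180°, 180°] with cis = 0, matching the sign
  convention of MDAnalysis (cross-checked in the tests). Degenerate
  (collinear) quadruplets are skipped and counted.
* **Order parameters.** For chain carbon i, the molecular frame is
  z along C(i−1)→C(i+1), x normal to the C(i−1),C(i),C(i+1) plane, y
  completing the right-handed set; S_aa = ⟨(3cos²θ_a − 1)/2⟩ against the
  lab normal and S_CD = ⅔S_xx + ⅓S_yy, reported as −S_CD per carbon,
  per region. Closed-form anchors: 0.5 for an all-trans chain along the
  normal, 0 for isotropic orientations, (3⟨cos²θ⟩ − 1)/4 for a rigid
  chain tilted by θ with uniform azimuth.
* **Thickness.** N sites binned per leaflet into an (50×50 by default)
  xy grid; cell thickness = mean(upper N z) − mean(lower N z); empty
  cells are filled from the nearest occupied cell using minimum-image
  distances between cell centers. The LR mask keeps cells whose center
  is ≥ r + 2.0 nm (xy distance) from the particle CoM. The distribution
  collects masked cell values over frames, unit-area normalized
  (0.05 nm bins).
* **Area per lipid (LR).** Per frame,
  A_LR = (l_x·l_y − π(r + 2.0 nm)²)/N_LR: the SR + buffer footprint is
  modeled as the projected disc of the classification boundary. The
  disc is the default strategy; it is exact for the synthetic geometry
  and a declared approximation for rough real interfaces. Without a
  nanoparticle, A = l_x·l_y / N_leaflet.

Window defaults follow the analysis tradition of the target system:
distributions and the 2D map over the last 10 ns, MSD/area over the last
20 ns; the order-parameter window (not dictated by anything) defaults to
the last 20 ns and is configurable.

## Dynamics

Coordinates are unwrapped by undoing inter-frame jumps larger than half
the box (a jump of exactly half a box edge is ambiguous and raises).
Molecule position is the mass-weighted CoM of all sites (an N-site mode
exists). The MSD window is cut into consecutive, non-overlapping
intervals (default 2 ns); within each interval displacements are taken
from the interval's first frame and averaged over intervals and over
molecules whose region tag is constant across the interval — since the
epoch length (10 ns) is a multiple of the interval, intervals never
straddle epochs. Lateral MSD uses (x,y), normal uses z, and the two add
exactly to the 3D MSD. D comes from the least-squares slope over the
central 10–90% of the lag range, D = slope/(2d), converted by
1 nm²/ns = 10⁻⁵ cm²/s. No leaflet-CoM motion removal is applied by
default (the generator adds no drift); it is available as a flag.

**Uncertainty convention and its limitation.** The quoted uncertainty is
|D(first half of fit range) − D(second half)|/2. This is a declared
convention, not an error model: the two half-curves share the same walk
realizations, so the half-difference systematically *underestimates* the
ensemble sampling error — in repeated synthetic experiments the quoted
band covers the true D in only about half the replicates, while the
estimate itself stays within 10% of truth in ≥ 90% of them at moderate
ensemble sizes (500 tracers) and within 5% at 2000 tracers × 2000
frames. Treat the band as a smoothness diagnostic, not a confidence
interval.

## Synthetic generator

The generator is kinematic, not a physics engine: observables are
imposed, which is exactly what makes parameter recovery a valid oracle.
Lipids sit on a jittered rectangular grid at the configured area per
lipid, leaflet N planes at ± h/2 about the box mid-height
(default h = 4.0 nm, a typical fluid-phase PC N–N distance). Each lipid
keeps one internal conformation (chains grown with bond 0.153 nm, angle
111°, trans dihedrals with probability 1 − p_gauche, cis kink at
C37–C38) and moves rigidly: a 2D Gaussian walk with per-axis step
variance 2·D(region)·dt, and an Ornstein–Uhlenbeck z offset
(σ = 0.05 nm, τ = 1 ns by default). The whole molecule is tilted by a
*fixed* polar angle with cos²θ equal to the region's configured value
(uniform azimuth and pre-twist), so the expected −S_CD is the closed
form (3⟨cos²θ⟩ − 1)/4 without distributional assumptions. Default
conditions mirror a fluid PC bilayer perturbed by a 2-nm particle:
64 lipids/leaflet, area per lipid 0.62 nm², D = 0.0098/0.012/0.015
nm²/ns for SR/buffer/LR (i.e. 0.98–1.5 ×10⁻⁷ cm²/s), tilt order
⟨cos²θ⟩ = 0.45/0.55/0.65.

Water is single-site (OW, mass 18.015): every analysis that touches
water uses oxygen positions only. Bulk water is resampled uniformly
outside the bilayer slab each frame — valid for density observables,
meaningless for water dynamics (none are computed). A configurable
cluster of waters rides rigidly within 0.5 nm of the particle surface on
the bilayer side, emulating the trapped-water pocket next to a
penetrated particle. The default bulk water number density (8 nm⁻³) is
deliberately thinned relative to real water (~33 nm⁻³) to keep synthetic
systems small; density observables scale linearly so nothing downstream
depends on the absolute value.

What the generator does *not* emulate: inter-lipid forces and packing
correlations, chain isomerization dynamics (conformations are frozen per
lipid), lipid exchange between leaflets, membrane undulations beyond
independent z noise, electrostatics and water structure. Passing
recovery tests therefore validates the *analysis machinery* — geometry,
bookkeeping, estimators, normalizations — not force-field physics.

## Problem sizes and numerical choices

Test and demo systems use 16–256 lipids per leaflet and 2–201 frames;
these sizes were chosen so the whole validation suite represents the
analysis faithfully at desk scale. Tolerances: order-parameter recovery
to 0.02 (≥ 500 lipids), diffusion recovery to 5% (2000 tracers × 2000
frames), thickness mean to 0.02 nm; exact invariants (histogram
normalization, mass conservation, MSD decomposition, partition
completeness) to 10⁻⁹. Determinism: one seeded NumPy generator drives
all randomness; a fixed config is bit-reproducible, and the pipeline
writes identical CSV bodies for identical seeds. Degenerate inputs raise
explicit errors (monolayers, empty selections, empty regions, zero-size
bins, half-box jumps).

## Known limitations

* The fcc builder reports 3925 atoms for the r = 2.5 nm sphere — the
  count the enumeration oracle confirms; no atom-centered
  inclusive-boundary convention yields 3926 (the next lattice shell
  would add 72 atoms at once).
* The disc model of the SR + buffer excluded area ignores interface
  roughness; a convex-hull strategy is a natural extension and the API
  reserves the switch.
* The two-segment uncertainty underestimates ensemble error (see above).
* XTC/TRR reading is not implemented; multi-frame GRO is the native
  trajectory format (zero binary dependencies), and MDAnalysis can be
  used upstream to convert.
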