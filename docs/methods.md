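# Methods

`cnvsim` simulates choroidal neovascularization (CNV) — the invasion of the
outer retina by capillaries sprouting from the choriocapillaris (CC) — as a
3D Glazier–Graner–Hogeweg (cellular Potts) model of the CC / Bruch's
membrane (BrM) / retinal pigment epithelium (RPE) / photoreceptor complex.
This note documents the model, its numerical choices, the calibration of
parameters that are not fixed by published values, and the limitations of
the scaled test configuration.

## Lattice model

Space is a 3D voxel lattice (2 µm voxels by default), periodic laterally,
with fixed walls at the choroidal base and at the outer limiting membrane
(OLM).  Each voxel belongs to one *generalized cell*; cell types are
Vascular (quiescent CC endothelium), Tip and Stalk (activated endothelium),
RPE, POS/PIS (photoreceptor outer/inner segment compartments), BrM blocks
(frozen, immotile) and Medium.  Configurations evolve by Metropolis
index-copy dynamics: per Monte Carlo step (MCS) one copy attempt is made per
non-frozen voxel; a random voxel takes the cell ID of a random 6-neighbor
with probability `min(1, exp(−ΔH/T))`.  The effective energy is

    H = Σ_boundary pairs  J(τ_a, τ_b)            (26-neighborhood, unit weights)
      + Σ_cells           λ_vol (V − V_t)²
      + Σ_active links    (λ_link / 2)(ℓ − ℓ_rest)²

plus two optional engine terms (below) and a non-conservative chemotaxis
contribution `−λ_chem Δc` applied when the advancing cell is chemotactic
and the displaced cell is not endothelial (contact-inhibited chemotaxis).
The concentration difference Δc = c(target) − c(source) is clipped to a
per-type saturation value (a saturable receptor response): stalk and
vascular cells saturate at Δc = 0.005 concentration units per step, while
the tip cell — the specialized invasive phenotype — responds linearly.
Saturation caps the maximal chemotactic force a stalk can exert on a
junction, which is what lets graded adhesion rather than local gradient
hot-spots decide whether invasion proceeds.

### Adhesion

Adhesion has two modes.  *Labile adhesion* is the contact-energy table `J`
(more negative = stickier); the graded entries are

| pair      | normal | moderate | severe |
|-----------|-------:|---------:|-------:|
| RPE–RPE   | −40    | –        | −18    |
| RPE–BrM   | −38    | −28      | −18    |
| RPE–POS   | −16    | –        | −1     |

with fixed entries for the remaining pairs (endothelial–endothelial −20,
endothelial–anything-else −10, photoreceptor pairs −16, cell–Medium +3,
BrM–BrM −12, BrM–Medium −1).  *Plastic coupling* is a breakable linear
spring between cell centers of mass, created when a junctional type pair
first reaches 4 voxel faces of contact, with rest length equal to the
separation at formation.  Graded stiffnesses: RPE–RPE and RPE–BrM
300/60/30; fixed stiffnesses: Vascular–Vascular and Vascular–BrM 200,
Stalk–Vascular 150, Stalk/Tip pairs 50, Stalk/Tip–BrM 25, photoreceptor
junctions 30 (energy/µm²).

**Spring rupture.**  A link breaks when stretched more than 1.5 µm beyond
its rest length, and re-forms at the current separation while the pair
remains in contact.  This makes junctions *plastic*: they yield under
sustained load at a rate proportional to how often the load exceeds the
rupture extension, which scales with 1/√λ_link, while resisting transient
fluctuations.  A fixed multiplicative break length (e.g. 2× rest) would put
rupture energies in the thousands at λ ≈ 150–300 — junctions would never
break, all relative cell motion would freeze, and the graded spring levels
of the adhesion factorial would be behaviorally inert.

**Baseline interfacial tension.**  The engine exposes
`contact_tension` (γ): the energy of a cell–cell boundary pair is
`J + 2γ` and of a cell–Medium pair `J + γ`; γ = 0 reduces exactly to the
raw table.  The adhesion table alone is uniformly negative, which in a bare
CPM *rewards* creation of fresh interface: distinct same-type cells finger
into one another and invaders tunnel through cell bodies.  Interpreting the
table as adhesion offsets relative to a positive baseline tension restores
compact cells and junction-selective invasion while preserving every
relative adhesion relationship.  The retina model uses γ = 25, the smallest
round value for which the stickiest pair (RPE–RPE at −40) still has
positive effective tension.  The engine also supports a per-cell quadratic
surface-area constraint `λ_surf (S − S_t)²`; with the tension in place the
retina model leaves it off (λ_surf = 0).

### Tissue construction

Bottom to top: an 8 µm choroidal margin filled by a sheet of Vascular cells
(8 µm tiles, one third removed in a staggered pattern as lumen gaps,
leaving a connected network covering ≈ 2/3 of the choroidal BrM face); a
6 µm BrM slab of frozen 8×8 µm blocks; a confluent monolayer of 12 µm
cuboidal RPE cells; photoreceptors as 6×6 µm columns of paired POS (30 µm)
and PIS (24 µm) compartments, four columns per RPE cell.  The OLM is the
upper wall at ≈ 67 µm from the RPE side of BrM.  Junctional links are
created from the initial contacts; all cells start at their target volumes.
The reference domain is 120×120 µm laterally (100 RPE cells); the `mini`
preset used by the test suite is 48×48 µm (16 RPE cells).

### Fields

Four scalar fields live on the lattice and are solved quasi-statically (a
sparse steady-state solve per biology tick, warm-started conjugate
gradients): field relaxation times (minutes) are far below cell
rearrangement times (hours).  An explicit Euler stepper with the standard
stability bound dt ≤ h²/6D is provided and used for the conservation and
decay tests.

* **Oxygen** (mmHg): endothelial voxels are clamped toward the CC tension
  (80 mmHg) by a fast exchange term, the OLM holds 20 mmHg, and the inner
  segments consume at a uniform rate; RPE oxygen uptake is zero.  A
  closed-form 1D profile (linear in BrM/RPE/POS, quadratic across the
  consuming inner-segment band, Dirichlet ends) supports calibration: the
  inner-segment consumption is set so the profile passes ≈ 65 mmHg at the
  RPE–POS interface when the CC face is at 80 mmHg; the same consumption
  then yields ≈ 49.9 mmHg when the CC drops to 60 mmHg.
* **RPE-derived VEGF-A**: secreted by the RPE, taken up by all endothelial
  cells (first-order, 3 h⁻¹), decay 0.5 h⁻¹, diffusion length 50 µm.  It is
  the endothelial survival factor and the chemoattractant that draws
  activated cells toward the RPE.
* **Short-diffusing VEGF-A**: secreted by all endothelial cells, diffusion
  length 10 µm at the same decay rate (the stated 5× length ratio = 25× in
  D); it provides autocrine endothelial cohesion cues.
* **MMP**: secreted only by the tip cell, near-immobile (diffusion length
  < 1 voxel).  Each BrM voxel converts to Medium with probability
  `rate · c_MMP · dt` per tick; the rate (1.0 per concentration·hour) is
  set so 24 h of tip secretion opens a hole of roughly one to one-and-a-half
  cell diameters.

Concentration units are arbitrary (secretion normalized to 1 per voxel per
hour); all concentration-coupled rates are expressed against the resulting
intact-tissue levels (the steady RPE-apical VEGF level is ≈ 0.3).

### Cell behavior

* **Tip cell** (protocol): at most one per run, converted from the CC
  vascular cell nearest the lateral domain center.  It secretes MMP,
  chemotaxes strongly up the RPE-derived VEGF gradient, and after exactly
  24 h differentiates into a stalk cell, ending MMP secretion.
* **Stalk cells** chemotax up both VEGF pools (contact-inhibited) and grow
  in proportion to local RPE-derived VEGF unless the endothelial fraction
  of their surface exceeds the inhibition threshold (0.75).  Growth is
  implemented as *bounded pressure*: the target volume may lead the
  realized volume by at most 4 voxels, so expansion stalls where the
  surrounding adhesion resists and proceeds where the tissue yields — this
  is the mechanism by which the BrM–RPE–POS complex blocks or admits
  invasion.  At twice the initial volume (128 voxels) a stalk divides by a
  random COM plane; both daughters are stalk cells with half the target
  volume.  The growth rate (18 voxels/h per unit VEGF) reproduces roughly
  one division per 12 h at the sub-RPE VEGF level.
* **Survival**: endothelial cells whose mean RPE-derived VEGF stays below
  10% of the intact RPE-apical level for 6 h, and RPE cells that have had
  *neither* lateral RPE contact *nor* BrM contact for 12 h, ramp their
  target volume to zero over 6 h and are removed when their last voxel
  disappears; every removal is logged with exactly one cause.  The RPE rule
  uses the both-contacts-lost reading because the epithelium demonstrably
  survives transient BrM detachment during translocation dynamics.
  RPE cells never grow or divide.

### Time calibration and scaled runs

One MCS is 7.5 simulated minutes (8 MCS/h); biology (link maintenance,
fields, degradation, survival, growth/mitosis) runs on a 2 h tick and
morphometric records are written every 6 simulated hours.  The `mini`
preset (48×48 µm, one simulated month, ≈ 25k voxels) is the desk-scale
configuration used by the tests and the acceptance script; a replica takes
tens of seconds.  When the early-window locus of a fast-initiating
scenario is evaluated at mini scale, replicas run on a two-month horizon
(early window = first 15 days, covering onset plus a development week, the
scaled analog of the reference three-month early window) and stop once the
window closes and initiation is decided.  The `full` preset (120×120 µm, 12 months) reproduces the
reference geometry and is intended for batch sweeps outside the test suite.

Hidden kinetic constants (temperature, chemotaxis strengths, secretion/
uptake/degradation rates, growth pressure) were fixed once by a calibration
protocol with three constraints, in this order: (1) the intact all-normal
retina with a seeded tip cell stays quiescent — the tip opens a ~one-cell
hole in BrM, differentiates, and the stalk count never exceeds three;
(2) severe impairment of RPE–RPE labile adhesion alone (levels 1,3,3,3,3)
produces reliable initiation within one simulated month with a sub-retinal
(low morphometric weight) locus; (3) free stalk cells divide roughly every
12 h at sub-RPE VEGF levels.  Resulting values: T = 10, λ_vol = 5, γ = 25,
λ_chem = 45000 (stalk, saturated at Δc = 0.005) / 50000 (tip, unsaturated)
on RPE-derived VEGF and 100 on the short pool, growth rate 18 voxels/h per
unit VEGF with pressure margin 4, endothelial contact-inhibition threshold
0.75.  The tip's unsaturated drive makes its
BrM crossing protocol-reliable in every scenario (crossing is
non-discriminating, as observed); the stalk's saturated drive plus the
bounded growth pressure sit *between* the junction-opening costs of
severely impaired and normal RPE–RPE labile adhesion, so invasion is
decided by the adhesion scenario.
The temperature is the sharpest selectivity lever: the labile-adhesion
difference between an impaired and a normal RPE–RPE junction is a fixed
≈22 energy units per boundary face, so the rate ratio between crossing a
weak junction and a normal one scales as exp(22·k/T) for a k-face front —
at T = 10 weak junctions yield in days while normal junctions hold for the
whole horizon.

## Quantification

The morphometric weight of a record is
`MW = area(stalk, BrM) / (area(stalk, BrM) + area(stalk, POS))`
(6-neighbor voxel faces), undefined when stalk cells touch neither
structure.  MW ≥ 0.75 → Type 1 (sub-RPE), MW ≤ 0.25 → Type 2
(sub-retinal), otherwise Type 3; stalk cells whose dominant contact is
lateral RPE are flagged separately but still count toward Type 3.  CNV
*initiates* when the stalk count first exceeds three.  Early and late CNV
types are the stalk-count-weighted mean MW over the first and last quarters
of the run (the first/last three months of a year-long run), and the
ordered (early, late) pair maps to one of nine dynamics classes
(S11, T12, P13, T21, S22, P23, T31, T32, S33).

## Sweep statistics

`run_replicas` executes independent seeded replicas per adhesion scenario
(one counter-based RNG stream per replica derived from the base seed,
scenario ID and replica index) and aggregates initiation probability, mean
MW and dynamics-class frequencies.  `fit_regression` is ordinary least
squares of a per-scenario response on the five levels (coded numerically
1–3) plus all ten pairwise products, reporting R² and adjusted R²;
`project_symmetric` tabulates the fitted surface under the symmetric
reduction RRp = RRl, RBp = RBl for isosurface-style reporting.

## What the scaled tests do and do not show

The mini preset preserves the layer anatomy, adhesion physics and
classification pipeline but has 16 RPE cells, a single BrM hole and
one-month horizons.  Because the outer limiting membrane is a hard wall,
every voxel of invading stalk volume must be absorbed by photoreceptor
compression, and at 48 µm the lateral room for redistributing that load is
small: an occasional replica (roughly one in eight) jams with a stalk pair
wedged in a single junction channel and initiates only after the one-month
mark, an artifact of the scaled domain rather than of the adhesion
mechanism (the reference 120 µm domain offers ~6× the relief paths).  Quantities tied to the reference domain (≈ 45 stalk
cells at sub-RPE confluence ≈ 3000/mm², late-window translocations on
multi-month timescales, sweep-wide regression variance fractions) require
the full preset and replica counts beyond the test budget; the library
supports them through the `sweep` interface.  The synthetic tissue also
omits drusen/basal deposits, BrM re-synthesis, explicit immune cells,
blood-flow-coupled oxygen delivery and ECM-bound VEGF release, so passing
tests speak to the adhesion-gated invasion mechanism, not to clinical
quantitative prediction.

## Numerical notes

* ΔH bookkeeping (volume, COM with periodic unwrap, surface, springs) is
  incremental and audited against brute-force recounts in the tests.
* The steady-state field solver assembles the constant operator once per
  field (Kronecker 7-point Laplacian with per-face boundary conditions) and
  adds voxel-wise uptake to the diagonal at solve time.
* Randomness: lattice dynamics use an embedded xorshift128+ stream seeded
  per replica (bit-reproducible trajectories); construction, mitosis planes
  and degradation draws use a numpy generator with the same replica seed.
* Degenerate inputs: an empty copy neighborhood never occurs (6-neighbor
  proposals are clipped at walls and count as rejections); a cell shrinking
  to zero volume is removed and its links deactivate at the next
  maintenance pass; Medium carries no constraints.
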