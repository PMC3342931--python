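# cnvsim

A 3D multi-cell simulator of **choroidal neovascularization (CNV)** — the
invasion of the outer retina by capillaries sprouting from the
choriocapillaris — built on the Glazier–Graner–Hogeweg (cellular Potts)
model.  It is aimed at computational biologists studying how **adhesion
failures** in the Bruch's membrane (BrM) / retinal pigment epithelium (RPE)
/ photoreceptor complex select among the clinically observed CNV patterns:
sub-RPE (Type 1), sub-retinal (Type 2) or combined (Type 3).

## The model in brief

A voxel lattice holds generalized cells — choriocapillaris endothelium,
activated tip/stalk endothelial cells, RPE, photoreceptor inner/outer
segment compartments, frozen BrM blocks and Medium — evolving by Metropolis
index-copy dynamics under the effective energy

```
H = Σ J(τa, τb)  +  Σ λ_vol (V − V_t)²  +  Σ (λ_link/2)(ℓ − ℓ_rest)²
```

(contact adhesion, volume constraint, breakable-spring junctions) plus
contact-inhibited chemotaxis on two VEGF-A pools.  Four reaction–diffusion
fields (oxygen, RPE-derived VEGF-A, short-diffusing VEGF-A, MMP) couple the
tissue to cell fate: a seeded endothelial **tip cell** digests a ~one-cell
hole in BrM for 24 h, then differentiates into a **stalk cell** whose
VEGF-driven, contact-inhibited growth and divisions either stall against
intact adhesion or invade the sub-RPE / sub-retinal spaces when specific
adhesions are impaired.

Five graded adhesion strengths — RPE–RPE labile (`RRl`) and plastic
(`RRp`), RPE–BrM labile (`RBl`) and plastic (`RBp`), RPE–POS labile
(`ROl`), each normal (3), moderately (2) or severely (1) impaired — form a
**108-scenario factorial**.  Runs are quantified by the *morphometric
weight* `MW = A(stalk,BrM) / (A(stalk,BrM) + A(stalk,POS))`, classified per
three-month window (Type 1 iff MW ≥ 0.75, Type 2 iff MW ≤ 0.25, else
Type 3), and the (early, late) pair gives one of nine dynamics classes
(S11, T12, P13, …).  *Initiation* is the moment the stalk-cell count
exceeds three.  See `docs/methods.md` for the full model account.

## Worked example

Steady transretinal oxygen: calibrate the photoreceptor inner-segment
consumption so the profile passes 65 mmHg at the RPE when the
choriocapillaris is at 80 mmHg, then ask what systemic hypoxia (CC at
60 mmHg) does:

```
$ cnvsim oxygen1d --pcc 60 --polm 20 --calibrate-at 80:65
calibrated Q_pis = 0.00267094 mmHg/um^2 (P_rpe=65.0 at P_cc=80.0)
PO2 at the RPE for P_cc=60.0: 49.93 mmHg
```

The RPE oxygen tension falls from 65 to ≈ 50 mmHg — the drop expected for
light-adapted systemic hypoxia in an anatomically normal retina.

Run one desk-scale replica of the scenario in which only RPE–RPE labile
adhesion is severely impaired (the sub-retinal-injection/inflammation-like
condition), with a seeded tip cell:

```
$ cnvsim run --scenario 1,3,3,3,3 --scale mini --months 1 --seed 11 --out-dir out/
run: scenario=1,3,3,3,3 scale=mini seed=11 hash=5b3c3a727c6285cc
onset: 234 h; dynamics: S22
```

`out/records.csv` holds one morphometric record per 6 simulated hours.
Onset at 234 h means the stalk-cell count exceeded three within ten
simulated days, and the S22 class (stable Type 2) reflects a sub-retinal
capillary network between the RPE and the photoreceptor outer segments in
both the early and late windows.  The same run for scenario 1
(`--scenario 1`, all adhesions normal) ends with `onset: none` — a tip cell
and a hole in BrM are not sufficient to initiate CNV against an intact
adhesion complex.

Python API equivalent:

```python
from cnvsim import RunConfig, run_simulation
res = run_simulation(RunConfig(scenario=(1, 3, 3, 3, 3), scale="mini",
                               months=1, seed=11))
print(res.classification)   # onset, early/late MW and types, dynamics class
```

Factorial sweeps and the regression analysis of initiation probability
against the five adhesion levels (plus pairwise products) run through
`cnvsim sweep` / `cnvsim report`, or `cnvsim.sweep.run_sweep` and
`cnvsim.sweep.fit_regression`.

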