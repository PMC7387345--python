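# Methods

## The model

`p53combo` simulates single-cell fate decisions in the p53 signalling
network under fractionated γ-irradiation combined with an Mdm2 inhibitor
(a nutlin-like molecule blocking the p53–Mdm2 interaction), and uses those
simulations to rank and optimize combination treatment protocols for two
radio-resistant cancer phenotypes: cells with fivefold Wip1 overexpression
("Wip1-cancer") and cells with fivefold reduced PTEN expression
("PTEN-cancer").

The network (33 species, 66 reaction channels; `p53combo.network`) contains:

* **Damage sensing.** Each irradiation of dose *D* Gy creates
  `dsb_per_gy`·*D* DNA double-strand breaks (a Poisson draw in the
  stochastic engine, the mean in the ODE engine). Breaks are repaired by a
  saturating (Michaelis–Menten) channel, so the duration of the damage
  signal grows with dose and very large insults persist for days. Active
  ATM is a damage-gated, auto-activating kinase switch, reset basally and —
  cooperatively — by Wip1.
* **p53 phosphoforms.** ATM phosphorylates p53 to the *arrester* form
  (transactivating Mdm2, Wip1 and p21). A damage-duration integrator
  (HIPK2: synthesized while breaks persist, rapidly degraded once repair
  completes) converts arrester to the *killer* form (transactivating PTEN
  and driving the caspase switch). Wip1 dephosphorylates both forms with
  saturable (Michaelis–Menten in Wip1) kinetics.
* **Negative feedback.** p53_arrester → Mdm2 → p53 degradation, and
  p53_arrester → Wip1 ⊣ ATM. The Wip1–ATM loop is a relaxation oscillator:
  under persistent damage ATM toggles with a period of ~5–7 h, producing
  the pulsatile p53 dynamics on which inhibitor timing acts.
* **Positive feedback.** p53_killer → PTEN ⊣ PIP3 → AKT → nuclear import of
  Mdm2 ⊣ p53. PTEN is long-lived (t½ ≈ 24 h) and integrates killer activity
  across treatment cycles; once it crosses the AKT shut-off point, Mdm2 is
  retained in the cytoplasm, p53 rises several-fold and the killer form
  ignites the caspase switch.
* **Commitment.** Caspase activation is bistable (cooperative
  self-amplification) and commitment is the first crossing of half-maximal
  caspase; the flag is absorbing. In the stochastic engine a committed run
  terminates.
* **Pharmacokinetics.** Oral doses fill a gut depot that liberates drug to
  blood at `d_r1` = 1/h with elimination `d_r2` = 0.25/h (Bateman kinetics,
  peak ≈ 1.85 h post-dose); drip delivery is a zero-order infusion with the
  same elimination (plateau relaxation time 4 h). Doses are in IC50 units:
  association and dissociation constants of the inhibitor–Mdm2 complex are
  numerically equal in those units, so the equilibrium bound fraction is
  F = INH_B/(1+INH_B). Inhibitor specificity for cancer over normal cells
  (1, 3 or 10×) divides the association constant k_a of normal cells,
  which is algebraically identical to dividing their effective dose.

Promoters are explicit two-state species (two copies per gene) whose
switching — together with the Poisson lesion counts — is the model's
intrinsic noise; this is what makes sub-critical doses kill a finite
fraction of cells.

## Parameterization

The two transcription coefficients with published values are s₁ = 0.1
mRNA/s (Wip1) and s₂ = 0.03 mRNA/s (PTEN), interpreted as rates at full
two-copy promoter occupancy. The remaining constants were set by timescale
and steady-state analysis and then calibrated once, against the published
deterministic reference behaviours, **before** any acceptance measurement:
resting stability with low p53; damage-driven pulses of ≈7-h period;
0.8 Gy/day subcritical and 1.3 Gy/day lethal-in-cycle-3 for normal cells on
24-h cycles; complete radio-resistance of both cancer phenotypes at
10 Gy/day; inhibitor-induced sensitization with critical-dose ordering
normal < PTEN-cancer < Wip1-cancer. They are model constants, not run-time
dials. Where the calibrated model misses a printed number, the gap is
reported, not re-tuned (see Limitations).

Two deliberate structural choices matter for interpretation:

* The killer-form drive saturates in the damage integrator (Hill in HIPK2),
  so persistent damage cannot reward resistant cells with unbounded killer
  flux; dose discrimination then lives in damage *duration* per cycle.
* Wip1's phosphatase activity saturates (Michaelis–Menten), so Wip1-cancer
  protection comes from ATM duty-cycle suppression and killer clipping, not
  from an unphysical unbounded dephosphorylation rate.

## Engines

One declarative reaction table compiles to flat arrays consumed by both
engines (they cannot drift apart).

**Deterministic.** Fixed-step RK4 (30 s; the stiffest rates are ~10⁻²/s) in
seconds, restarted at every protocol event; irradiation and dosing are
impulsive state updates applied before the coincident sample. Halving the
step changes trajectories by <0.1% sup-norm (asserted in the suite).
Promoter states become occupancy fractions in the ODE limit.

**Stochastic.** Exact Gillespie over the discrete channels with two
accelerations: (i) steps are capped at 60 s so propensities follow the
continuously evolving state; (ii) in the default *scaled* mode, species
flagged `scalable` (mRNA/protein pools; everything except promoter states
and lesion counts) advance deterministically by 5-s Euler substeps between
discrete events. The exact path (everything discrete except the macroscopic
blood drug pools) is retained as the reference; a fixture test requires the
two modes to agree in commitment-time distribution (two-sample KS,
α = 0.01). Per-cell streams are spawned from the root seed by a
counter-based splitmix64 hash, so enlarging a cohort never reshuffles
earlier cells, and every result is a pure function of (configuration, seed).

**Critical doses.** IR_crit is found by bisection of the
apoptotic/non-apoptotic predicate over [0, 10] Gy/day (default tolerance
0.01 Gy/day) after an 8-point coarse scan that reports non-monotone dose
responses as a warning instead of silently bisecting. Resistant cells are
reported as unbounded (∞), and the ratio-curve machinery maps that to a
zero normal-to-cancer ratio.

## Protocol selection

Treatment cycles are 12/18/24/36 h; irradiation opens each cycle; doses are
stored in Gy/day and converted to per-event doses by cycle length. The
catalog holds the ten oral templates plus drip at 20 IC50/day; the three
timing variants named in print (24 h/(6,18), 36 h/(6,30), 36 h/(0,24)) are
fixed, the other seven are evenly spaced reconstructions and remain
configurable because only a figure records them.

Selection is two-step. Step 1 (deterministic) computes R(d) =
IR_crit(normal)/IR_crit(cancer) over an inhibitor-dose grid (default 0–20
IC50, step 0.5) and takes the argmax (ties to the lower dose; multimodality
warns). Step 2 (stochastic) scans irradiation over [0.8, 1.5] ×
IR_crit(cancer) for seven cycles; cancer cells receive (IR, dose), normal
cells (IR/3, dose/specificity). A setting is *plausible* when ≥95% of
cancer cells and ≤10% of normal cells commit; IR_opt is the lowest
plausible dose in the scan (the scan itself is always reported). Dose
minimization then descends the dose grid while plausibility holds.
12/18-h protocols are verified over a matched ~168-h horizon — an
extension, flagged as such, since only 24/36-h cycles were verified in
print. Default cohort size is 1000 cells; the `--fast` mode (100 cells) is
used by the smoke-scale acceptance checks, always with exact binomial CIs
so reduced-n results stay honest.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the deterministic landmarks
at full scale (they are seconds each) and the stochastic/pipeline steps at
smoke scale: 100 cells per condition, 3-point irradiation scans, coarse
(4-point) inhibitor-dose grids with 3-day preselection horizons, and
sequential early stopping of verification arms whose verdict is already
decided. These sizes are the package's default smoke profile; `--full`
restores paper-scale settings.

## Known limitations

* The authoritative species list and constants of the source model live in
  supplementary materials that are not part of this package's inputs; the
  network here is a faithful-by-construction reconstruction calibrated to
  the printed reference behaviours. Consequences measured after freezing
  (and deliberately not re-tuned): the 18-h-cycle monotherapy IR_crit is
  ≈1.0 Gy/day rather than ≈0.8 and the 18-h cycle is not strictly the
  minimal one; the combination IR_crit values are 0.64/0.74/1.84 Gy/day for
  normal/PTEN-/Wip1-cancer versus 0.61/1.6/3.98 in print (orderings and the
  inhibitor's sensitizing direction are reproduced, phenotype separations
  are compressed); the PTEN-cancer oscillation period is 5.2 h versus
  "about 7 h" (Wip1-cancer: 6.9 h); sub-critical stochastic killing at
  0.5 Gy/day reaches ~40–50% in 6 days versus >60%.
* Normal cells show a non-monotone window of the 3/6-day dose response
  (roughly 1.4–1.8 Gy/day on 24-h cycles) where strong Wip1 entrainment
  transiently protects them; the bisection prescan detects and warns about
  it. The printed behaviour implies monotone lethality there.
* Intrinsic noise only: no extrinsic (cell-to-cell parameter) variability,
  so the synthetic cohorts underestimate real population heterogeneity;
  passing fraction tests demonstrates the intrinsic-noise mechanism, not
  clinical dose–response shapes.
* One-compartment PK without inter-individual variability or toxicity; the
  inhibitor alone cannot kill cells in this model by construction.
* No population dynamics (division, repopulation, resistance evolution) and
  no spatial dose geometry beyond the scalar 3:1 beam-intersection ratio.
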