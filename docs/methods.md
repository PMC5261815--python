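# Methods

## Model

`ferroflux` describes whole-animal iron metabolism in a 25 g mouse as 20
coupled ODEs (time in hours). Seven state variables are organ iron masses
(µg/animal): serum, liver, spleen, duodenum, bone marrow, red blood cells
(RBC) and a lumped "other organs" compartment covering the remaining carcass.
Eight describe ferroportin expression (mRNA and protein in liver, spleen,
duodenum and "other"), and five the regulatory layer: hepcidin, liver *BMP6*
mRNA, serum IL6, LPS and phosphorylated STAT3. SMAD activity is treated as an
algebraic saturating function of BMP6, `S = BMP6/(K_SMAD + BMP6)` — the SMAD
phosphorylation cycle is fast relative to the slowest processes the model
resolves, so making it dynamic would add a state without adding an observable
time scale.

Serum is the hub. Import into organs is mass action (`v_o · Fe_ser`); export
back to serum is gated by the organ's ferroportin level (`u_o · Fe_o ·
Fpn_o`). Bone marrow passes iron to RBCs (erythropoiesis) and, via
ineffective erythropoiesis, directly to the spleen; senescent RBCs are
recycled by splenic macrophages. Iron enters through a saturable duodenal
uptake `V_duo · Fe_food/(K_duo + Fe_food)` and leaves only by enterocyte
shedding (`l_duo`) and skin desquamation (`l_other`); there is no regulated
excretion, which is why the uptake side carries the homeostatic burden.

Three liver-specific mechanisms are included. Liver import has a supralinear
non-transferrin-bound-iron (NTBI) component `v_NTBI · Fe_ser²/(K_NTBI +
Fe_ser)`: negligible at normal serum iron, it grows ~quadratically as
transferrin saturates, and approaches `(v_liver + v_NTBI) · Fe_ser` far above
`K_NTBI`. The smooth form keeps the objective differentiable for
gradient-based fitting; a hard transferrin-capacity threshold
`v_NTBI · max(0, Fe_ser − Tf_cap)` is available through
`ParameterSet.ntbi_mode = "threshold"` for model selection. Liver export is
proportional to liver iron only up to a ferritin storage cap,
`u_liver · Fpn_liver · min(Fe_liver, Fe_max)`; iron beyond the cap is treated
as ferritin-bound and unavailable for transfer to plasma.

Ferroportin is regulated three ways: LPS represses transcription
(`a_o · K_LPS/(K_LPS + LPS)`, with `K_LPS` shared across organs),
intracellular iron enhances translation through the IRE/IRP system
(`Fe_o/(K_IRE + Fe_o)`, one shared `K_IRE`), and hepcidin accelerates protein
degradation (`k1 + k2_o · Hep`, so the protein half-life is
`ln 2/(k1 + k2_o · Hep)`). Hepcidin transcription uses a thermodynamic
state-ensemble promoter over the four occupancy states of SMAD and STAT3:

    P(S, T) = (1 + w_S q_S S + w_T q_T T + w_ST ω q_S q_T S T)
              / (1 + q_S S + q_T T + ω q_S q_T S T)

with basal activity exactly 1 and saturation at the state weights. The
promoter constants are fixed (previously calibrated on hepatoma-cell data in
the original modelling line) and are loaded from configuration, never
re-fitted. The packaged weights satisfy `w_ST ≥ w_S, w_T ≥ 1`, which makes
the activity monotone in each activator — the doubly bound state is the most
active one (synergistic activation), and this condition is asserted by a
property test.

48 kinetic parameters are flagged estimable, including the whole-body tracer
loss rate `r_loss` (1/day), which is treated as a fitted constant of the
tracer normalization rather than a literature prior. Structural constants
(normal dietary influx `Fe_food = 1`, chronic LPS source, `K_SMAD`, promoter
weights) are never optimized.

## Perturbations

Experiments are encoded exactly the way they are performed: a diet change
multiplies `Fe_food`; an intraperitoneal LPS bolus of D µg/g sets
`LPS(0⁺) = D`; chronic inflammation sets `s_LPS = d_LPS · D` so the LPS
plateau equals the dose; hepcidin knockout zeroes hepcidin synthesis (the
peptide then decays — a gene deletion, not an instantaneous clamp; the
clamped-at-zero variant is available through `hamp_ko_mode`); C326S
hepcidin-resistant ferroportin zeroes the selected `k2_*`; liver SMAD4
knockout forces SMAD activity to zero. Mechanism-dissection runs freeze
selected state variables by zeroing their derivatives, with the clamp taking
its value at the moment of challenge. Scenarios may carry a pre-phase
(`pre_h`): parameter perturbations act from `t = −pre_h` (four weeks of
dietary loading before an LPS bolus; adult knockout animals), while boluses
and clamps start at `t = 0`.

## Simulation and steady states

Trajectories use LSODA at `rtol = 1e-8` (`1e-6` inside fitting loops, where a
tolerance-refinement test bounds the induced error). Steady states exploit
the model structure: conditional on the seven iron pools, every regulatory
species has a closed-form steady value, so the root problem is reduced to
seven dimensions and solved in log-pool space with multi-started damped
Newton iteration and a long-integration fallback. Residuals are scaled by
fixed per-pool magnitudes — not by the current pool values — so runaway
pseudo-roots (pools drifting to infinity with vanishing *relative*
derivatives) are rejected rather than accepted.

A structural property of the hard ferritin cap deserves note: once liver iron
exceeds `Fe_max`, export no longer grows with liver iron, while rising
hepcidin keeps suppressing Fpn, so any balance point in that regime is
generically unstable or absent. Consequently the reference model keeps every
*steady state* that the analyses interrogate below the cap, and the cap
shapes only finite-horizon accumulation. Relatedly, the reduced model
variants of the homeostasis scan (no hepcidin action, linear uptake, both
removed) genuinely lose bounded steady states at high dietary folds — liver
loading runs away. `diet_scan` reports NaN there; this is a statement about
the variant (no homeostatic set point exists), not a solver failure, and the
variant-ordering tests therefore compare log–log slopes on fold windows where
all variants still possess steady states (low regime 0.3–1×, high regime
1–3×; "both removed ≈ proportional" on 0.3–3×).

The dietary scan reports, besides absolute values, serum iron relative to
each variant's own normal-diet steady state: removing a mechanism shifts the
absolute baseline, and homeostasis is a statement about relative buffering.
The scan classifies slopes with the conventions `< 0.3` homeostatic and
`> 0.8` lost.

Tracer kinetics use the smallness of the injected dose: regulation is
unperturbed, so the label obeys the linear system `dx/dt = A x` with
fractional transfer rates `F_ij/Q_i` frozen at the background steady state,
injected as 100 % of dose into serum (intravenous protocol) and propagated by
matrix exponentials. Raw tracer data are normalized per time point by a
single factor so the whole-body sum equals `100 · exp(−r t)`.

## Calibration

The objective is `χ² = Σ ((s_g · x_i(θ) − y_i)/σ_i)²`. Records carry the
replicate mean, the noise SD and the replicate count; the weight is the
standard error of the mean, `σ_i = SD_i/√n_i`. Molecular observables in
arbitrary units belong to one of 20 scaling groups — one per
(study, observable) pair across the three arbitrary-unit studies of the
design (8 acute-LPS, 7 LPS+diet, 5 diet-modulation) — and the group scalings
are profiled analytically inside the objective
(`s*_g = Σ x y/σ² / Σ x²/σ²`), which removes 20 search dimensions without
moving the optimum. Kinetic parameters are searched in log10 space by a
trust-region least-squares optimizer, multi-started log-uniformly inside
positive finite bounds (default ±3 decades around nominal). An optional
sample-then-refine stage scores a larger candidate pool first and refines the
best candidates subject to a minimum log-distance between starts, so distinct
basins get refined instead of the single best-looking one. The best fits
(default cut: best 30) form the prediction ensemble; bands are pointwise
min/max across members.

Log-sensitivities `m_ij = d log x_j / d log p_i` of steady-state pools (and
of dietary fold changes) use central differences in log-parameter space with
a 1 % step.

## Synthetic data

The generator emulates the calibration design: acute LPS at 1 µg/g followed
for 72 h (10 time points, serum iron plus eight molecular readouts), LPS at
normal diet with organ iron pools and molecular readouts at 0/6/18/48 h, the
state after four weeks of a 2 % carbonyl-iron diet (≈100× the 200 ppm normal
diet), nine weeks of reduced (0.5×) or loaded (100×) diet, 28-day radiotracer
kinetics under three diets (0.03×/1×/100×), and hepcidin-knockout serum and
liver iron — 344 records in total (90 + 60 + 80 + 105 + 9; the allocation is
configurable). Replicates default to 4 with multiplicative Gaussian noise of
CV 0.2. The recorded SD is the generative noise SD rather than the sample SD
of the four replicates: combined with the SEM weighting this makes the data
exactly noise-matched (`E[χ²/N] = 1` at the true parameters, minus the ~6 %
absorbed by scaling profiling), whereas weighting by a 4-replicate sample SD
would inflate `E[χ²/N]` to `E[t²₃] = 3` and no parameter set could ever look
noise-consistent.

What the generator does *not* emulate: assay-specific artifacts (western-blot
saturation, hemolysis), animal-to-animal heterogeneity beyond i.i.d.
multiplicative noise, inter-study systematic offsets beyond one scaling per
group, and model misspecification — the data are generated by the same
equations that are fitted. Passing recovery and coverage tests therefore
demonstrates that the pipeline is statistically sound and the parameters
identifiable *given the model*, not that the model is correct for real mice.

## Packaged studies and problem sizes

The packaged reference parameter set is a synthetic calibration: transport
rates are derived exactly from target steady-state pools of a healthy mouse
(serum 2, liver 65, spleen 12, duodenum 3, marrow 4, RBC 850, other 150
µg; ~40 µg/day net absorption with a ~27 % mucosal transfer fraction), and
the regulation constants were hand-tuned so the model reproduces the
characteristic systemic behaviours: transcription-dominant inflammatory
hypoferremia with sub-additive mechanism combination, recovery by 72 h,
anemia of chronic inflammation (deep serum nadir within two days, slow RBC
decline, liver loading), ~10-fold liver iron after four weeks of the 100×
diet driven by NTBI uptake, strong serum buffering across a 1000-fold dietary
range, and the knockout phenotypes (hepcidin loss raises serum/liver iron and
drains the spleen; only duodenal hepcidin resistance acts systemically). The
hepcidin turnover rate is 0.068 h⁻¹ and the tracer loss rate 0.5 %/day.

The two calibration studies shipped with the package are deliberately scaled
down so a complete run stays in the minutes range: the recovery study refits
the two turnover-rate exemplars (`d_hep`, tightly identified; `d_BMP6`,
weakly identified) on the full 344-record design from ±2-decade log-uniform
starts (60 candidates, 8 refinements, final polish); the ensemble study
refits four parameters on the most informative datasets with 12 starts and
keeps the best 5 — the same ~30 % acceptance ratio as keeping the best 30 of
a 100-start campaign. Ensemble members back the prediction bands and the
requirement that the knockout directional claims hold for *every* member,
not just the best fit.

## Numerical choices and degenerate inputs

* Negative states are floored at zero inside flux evaluations; NaNs raise
  immediately so integration fails loudly.
* `steady_state` refuses models with clamped states (a clamped system has no
  well-defined free steady state) and reports its best residual on failure.
* Scaling groups whose model values are identically zero get scaling 1 and
  are reported; records with SD ≤ 0 are rejected for fitting (the CSV reader
  drops them with a warning).
* All-zero tracer rows cannot be normalized and raise.
* Optimizer failures inside a multi-start are collected per start; the fit
  only errors if every start fails.

## Verification bands

Where the quantitative targets involve modelling choices whose exact
functional forms are themselves decisions (IRE translation form, NTBI form,
promoter weights), the acceptance tests use bands chosen once, up front:
±10 percentage points for fraction-type summaries (the dissection fractions,
the chronic serum drop and RBC plateau) and ±25 % for fold-type summaries
(the 2.5-fold absorption increase at 100× diet, the uptake half-saturation at
5× the normal diet, the ~10-fold dietary liver loading).

## Known limitations

* Sub-organ compartments (Kupffer cells vs hepatocytes), activin B,
  erythroferrone and the ferroxidases are outside the model's scope.
* Erythropoiesis is mass action in serum iron, so the RBC compartment scales
  with chronically altered serum iron; knockout steady states can therefore
  overstate total-body iron changes (directions, not magnitudes, are the
  validated claims).
* RBC aging is first-order rather than fixed-lifespan, which blurs the
  timing of slow anemia development.
* The ferritin cap cannot produce a *stable steady state* above `Fe_max`
  (see above); it acts on transient accumulation only.
* The reference parameter set is a synthetic calibration for simulation
  studies, not a fit to animal data; absolute magnitudes outside the tuned
  behaviours should not be over-interpreted.
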