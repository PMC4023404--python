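# Methods

## Model

The cell is two well-mixed compartments, nucleus (volume fraction `φ_n`,
default 0.2) and cytosol (`φ_c = 1 − φ_n`).  All state variables are
concentrations normalized so that total MEK = 1 and total ERK = 1; substrate
totals `Sc_tot`, `Sn_tot` are in the same units.  The 15 states are

| group | states |
|---|---|
| MEK (cytosolic) | `M0`, `M1`, `M2` (un/mono/bi-phosphorylated), `D` (desensitized upstream signal) |
| ERK, cytosol | `E0c`, `E1c`, `E2c` (phospho-forms), `EBc` (substrate-bound active) |
| ERK, nucleus | `E0n`, `E1n`, `E2n`, `EBn`, `EIn` (import-carrier-bound, importin variants only) |
| product | `Pc`, `Pn` (phosphorylated substrate per compartment) |

Processes:

- **MEK activation.** Input `u(t)` (the stimulus program) drives
  `M0 → M1 → M2` at rate `a_M·u·(1−D)`; constitutive deactivation `d_M`.
  Negative feedback: active cytosolic ERK desensitizes the upstream signal,
  `dD/dt = k_fb·E2c·(1−D) − k_rec·D`.  This produces the peak-and-adapt
  shape of the MEK and ppERK timecourses.
- **ERK phosphorylation (cytosol only).** Distributive two-site:
  `E0c → E1c → E2c` at rates `a_E1·M2/φ_c`, `a_E2·M2/φ_c`; phosphatase
  steps `d_c2`, `d_c1` back down.  Nuclear dephosphorylation `d_n2`, `d_n1`
  acts on `E2n`, `E1n`.
- **Shuttling.** All free ERK forms exchange passively (`k_pass` in,
  `k_out` out).  Bi-phosphorylated ERK is additionally imported at `k_in`
  (facilitated).  Bound ERK (`EBc`, `EBn`, `EIn`) does not cross the
  envelope.  In the `importin`/`combined` variants the facilitated flux
  arrives as a carrier complex `EIn` that releases free `E2n` at `k_rel`.
- **Substrate binding and catalysis.** In each compartment active ERK binds
  free substrate (`k_on·E2·(S_tot − P − EB)/φ`), unbinds (`k_off`), or
  converts it (`k_cat`) releasing product `P` and free active ERK; product
  is dephosphorylated at `k_sdp` (set to zero while okadaic acid is
  applied).  Bound ERK is protected from dephosphorylation and anchored.

Bimolecular terms divide by the compartment volume fraction because the
states are whole-cell-normalized amounts; local concentration is
amount/fraction.

**Variants.** `full` is the model above; `control` removes substrates
(`S_tot → 0`); `importin` is control plus the carrier step; `combined` is
full plus carrier; `constant_mek` clamps `M2` at `M2_const` after stimulus
onset (and at its basal value before), removing feedback adaptation.

**Perturbations.** A protocol is a piecewise-constant stimulus plus optional
event times: `u0126_time` sets MEK kinase activity to zero from that time
on; `okadaic_time` sets substrate-product dephosphorylation to zero.

## Observation model

Simulated states map to nine readouts.  Blot/MS readouts
(`ppMEK_blot`, `ppERK_blot`, `ms_pERK`, `ms_ppERK`) are arbitrary-unit
linear readouts of the summed phospho-pools; bound ERK counts as
phosphorylated (`ppERK = E2c + EBc + E2n + EBn + EIn`).  Imaging readouts
are self-normalized to their pre-stimulus value: `nucloc` (nuclear/basal
nuclear ERK concentration) and FRET-style activity reporters `ekar_cyt`,
`ekar_nuc`, which read `ρ + E2/φ` normalized to t = 0 — i.e. they sense
*free* active ERK over a basal offset `ρ`, which sets their dynamic range.

## Reference parameters

`data/theta_ref.yaml` was produced once by `scripts/derive_theta_ref.py`: a
Nelder–Mead fit of 18 log-parameters to a battery of waypoint features
(peak times, adaptation ratios, rise and decay half-times, dose-step-up
behavior, constant-MEK contrast) with hinge penalties keeping qualitative
orderings.  Buffering strengths are fixed by construction at `B_n = 20`,
`B_c = 0.3` (association rates are derived from the other binding
parameters to hit these).  The file is frozen; everything downstream —
synthetic data, fits, targets — derives from it.

## Synthetic data generator

Seven fitted experiments (blot, MS, three imaging campaigns, two inhibition
campaigns) plus three held-out prediction designs.  Realism choices:

- **Population assays** (blot, MS): lognormal multiplicative noise,
  CV = 20%, 3 replicates — few, noisy, whole-population.
- **Single-cell imaging**: per-cell amplitude jitter (CV = 15%, a fixed
  lognormal factor per cell, mimicking expression variability) times
  per-frame measurement noise (CV = 5%); each normalized trace is then
  re-normalized to its own t = 0 frame, exactly as image analysis would.
- Reported `sigma` is the model CV with a small absolute floor (1e-3).
- Reproducibility: each design seeds an independent `default_rng((master,
  design))` stream, so datasets are byte-identical across runs and
  adding/removing one design does not perturb the others.

## Fitting

Cost: `J = Σ_d w_d Σ_i (s_d·m(t_i) − y_i)² / σ_i²`.  For arbitrary-unit
readouts the gain `s_d` is profiled analytically (weighted least squares);
normalized readouts use `s = 1`.  Search runs in transformed coordinates
(log10 for rates and totals, logit for `φ_n`).  Stage 1 is a Metropolis
anneal with geometric cooling; stage 2 a threshold random walk that accepts
any move with `J ≤ 1.25·J_min` — a flat-acceptance sampler of the
near-optimal set, which is what the ensemble analysis needs (parameter
*ranges* consistent with the data, not a posterior).  Both are driven by
seeded `default_rng` streams and are exactly reproducible.

## Ensemble analysis

For each accepted member we compute `B_c`, `B_n` and classify the buffering
mode (`nuclear` / `cytosolic` / `mixed` / `unbuffered`, boundary B = 1), and
push the ensemble through held-out protocols to get prediction bands and
half-decay statistics.  The headline check is that the data pull the
ensemble back to nuclear-dominant buffering with `B_n` within a factor of
two of the generator.

## Numerical choices

- **Integrator: `scipy.integrate.solve_ivp(method="BDF")`** at
  `rtol = 1e-8`, `atol = 1e-10` (cost evaluations use 1e-7/1e-9).  The
  system is stiff (binding rates ×100 faster than shuttling).  BDF was
  chosen over the Fortran-backed LSODA deliberately: in testing, LSODA
  showed rare (~1%/call) last-bits run-to-run nondeterminism that depended
  on prior in-process integrations, which breaks byte-reproducible dataset
  generation and can diverge seeded MCMC chains near the acceptance
  threshold.  The pure-Python BDF is bit-reproducible at ~4× the cost
  (~60–75 ms per simulation).
- **Initial state.** Basal steady state is found by integrating the basal
  system for 1e4 min, then polishing with a damped Newton solve in which
  the two redundant equations (the right-hand side is neutral along the
  total-MEK and total-ERK directions) are replaced by the conservation
  constraints `ΣMEK = 1`, `ΣERK = 1`.  This pins conservation to machine
  precision; without it, pre-equilibration drift (~1e-7) is permanent.
  The polished state must satisfy `max|f(y)| ≤ 1e-10` or a
  `SimulationError` is raised.
- **Events.** Integration restarts at every protocol event (segment
  boundaries, inhibitor additions) so discontinuities never sit inside a
  solver step.
- **Verification oracles** in the test suite: a fixed-step RK4 integration
  agrees to 1e-6; variant reductions (`full → control` at zero substrate,
  `importin → control` at large `k_rel`) hold; half-life extraction matches
  `ln 2 / k` on analytic decays; the analytic gain beats a 2001-point grid
  search; noise-free data at the generating parameters gives zero cost.

## Limitations

- Two well-mixed compartments: no spatial gradients, no cytoplasmic
  scaffolds, no transcriptional feedback (relevant beyond ~2 h).
- One aggregate substrate species per compartment; real anchoring involves
  many substrates with heterogeneous kinetics, so `K_m` and `B` are
  effective parameters.
- The noise model is stationary and lognormal; real imaging has
  photobleaching, segmentation error drift, and cell-cycle heterogeneity.
- The ensemble is a threshold set, not a posterior: member density carries
  no probabilistic meaning, only membership does.
- Parameters are identifiable only as the data constrain them; several
  (e.g. absolute binding rates) are pinned largely by the calibration
  choices, not the synthetic data.
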