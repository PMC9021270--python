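# Methods

## The model

`gabadmf` simulates whole-brain resting-state activity with a two-population
dynamic mean-field (DMF) model. Each cortical region *n* contains one
excitatory (NMDA-like) and one inhibitory (GABA-like) neural mass with
input currents

    I_E(n) = W_E*I0 + w+*J_NMDA*S_E(n) + G*J_NMDA * sum_p C_np S_E(p) - J_FIC(n)*S_I(n)
    I_I(n) = W_I*I0 + J_NMDA*S_E(n) - S_I(n)

firing rates given by the sigmoidal F–I curve

    F(x) = x / (1 - exp(-d*x)),    x = m * g * (I - I_thr)

(with modulator m = 1 for the excitatory population and m = g_NM(n) for the
inhibitory one), and synaptic gating dynamics integrated by Euler–Maruyama:

    dS_E/dt = -S_E/tau_NMDA + (1 - S_E)*gamma*r_E + sigma*nu(t)
    dS_I/dt = -S_I/tau_GABA + r_I + sigma*nu(t)

Gating is clipped to [0, 1] after every step. The decaying (-S/tau) and
saturating ((1 - S)) forms are the standard mean-field reduction; no other
sign convention is exposed.

Regional neuromodulation enters only through the inhibitory gain,

    g_NM(n) = 1 + s_I * d_n,

where d_n in [0, 1] is the normalised regional GABA-A receptor density
(benzodiazepine-site binding from flumazenil PET in the intended
application) and s_I >= 0 a global inhibitory gain scaling. s_I = 0
recovers the unmodulated model, whose only free parameter is the global
coupling G.

### Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| I0 | external current | 0.382 | nA |
| W_E, W_I | scaling of I0 | 1, 0.7 | – |
| w+ | local excitatory recurrence | 1.4 | – |
| J_NMDA | excitatory coupling | 0.15 | nA |
| g_E, g_I | F–I gain factors | 310, 615 | nC⁻¹ |
| I_thr_E, I_thr_I | F–I thresholds | 0.403, 0.288 | nA |
| d_E, d_I | F–I shape | 0.16, 0.087 | s |
| gamma | excitatory kinetic factor | 0.641 | – |
| sigma | noise amplitude | 0.01 | nA |
| tau_NMDA, tau_GABA | gating time constants | 100, 10 | ms |
| G | global coupling | free | – |
| s_I | inhibitory gain scaling | free, [0, 1] | – |
| J_FIC | feedback inhibitory weight | tuned | nA |

Connectome weights are rescaled so the maximum entry equals 0.2 before
simulation (configurable); tractography leaves the units of C arbitrary
and G absorbs the overall scale, so a fixed normalisation keeps G sweeps
comparable across connectomes.

## Feedback inhibition control (FIC)

J_FIC(n) is tuned so each region's excitatory population fires near 3 Hz.
The tuner first solves the noise-free fixed point analytically — inverting
F_E for the current at 3 Hz, solving the per-region inhibitory
self-consistency S_I = tau_I * F_I(W_I*I0 + J_NMDA*S_E* - S_I), and
reading J_FIC off the excitatory current balance — then runs noise-driven
verification rounds (10 s each, 2 s within-round burn-in, state carried
over). A round whose time-averaged rates all fall within ±0.5 Hz of target
terminates tuning; otherwise each weight is nudged by
eta*(rate - target)/target (eta = 0.01 nA, floor at 0, at most 200
rounds). On desk-scale fixtures the analytic start lands inside tolerance
within one or two rounds; the greedy rounds matter near the model's
stability edge, where they accumulate extra inhibition until the target
holds.

### Direction of the gain effect

With the constants above, the inhibitory population's balanced input
current (~0.25 nA) lies *below* its threshold (0.288 nA). For subthreshold
currents F(m·g·(I - I_thr)) *decreases* as the modulator m grows, so
raising s_I lowers inhibitory firing at fixed current: applied without
re-balancing, the gain map *disinhibits* the network (mean excitatory rate
rises), and re-tuning under a stronger gain map converges to *larger*
J_FIC. This is an emergent property of the printed F–I curve and
constants, not a modelling choice; what matters for the fitting machinery
is that s_I shifts the collective dynamics monotonically through the
model's working point, which it does.

## Haemodynamics and filtering

Regional excitatory rate drives an independent Balloon–Windkessel cascade
per region, in the canonical parameterisation (kappa = 0.65 s⁻¹,
gamma_h = 0.41 s⁻¹, tau_h = 0.98 s, alpha = 0.32, rho = 0.34, V0 = 0.02,
k1 = 7 rho, k2 = 2, k3 = 2 rho - 0.2). Choices the source material leaves
open, fixed here:

- **Neural drive**: z = r_E/⟨r_E⟩ - 1, the rate normalised by the region's
  own time-mean, so a steady model sits exactly at the resting fixed point
  (s, f, v, q) = (0, 1, 1, 1) and emits zero BOLD. Rate rather than
  synaptic current is used as the coupling variable.
- **Integration**: Euler at the neural-trace sampling interval (1 ms
  default), with inflow, volume and deoxyhaemoglobin integrated in log
  space — the standard positivity-preserving change of variables — plus a
  ±3 log-unit saturation guard (an e³ ≈ 20-fold physiological range).
  Without it, sustained negative drive (which arises when the model
  switches into a high-rate state and the normalised drive of
  low-rate epochs pins near -1) collapses inflow through zero.
- **Sampling and filtering**: BOLD is sampled every TR (2 s default) and
  band-pass filtered to 0.008–0.09 Hz with a zero-phase order-2
  Butterworth (filtfilt), then demeaned exactly.

## FCD and model fit

Functional connectivity is the Pearson correlation of regional BOLD inside
a sliding window of 30 TRs advancing by 3 TRs (last partial window
dropped). The FCD matrix correlates the vectorised upper triangles of the
per-window FC matrices for every window pair; raw Pearson values are used
(no Fisher transform), and by default every upper-triangle entry —
including overlapping-window pairs — enters the FCD sample (a flag
excludes pairs closer than window/step). Group-wise empirical FCD pools
upper-triangle values across scans.

Fit is the two-sample Kolmogorov–Smirnov distance between simulated and
empirical FCD value distributions (sup-norm ECDF distance on raw samples,
no binning). A Peacock-style two-sample 2-D KS over (value, lag) pairs —
maximum over both samples' data points and all four quadrant orientations
of the empirical quadrant-CDF difference — is available as a variant
sensitive to the temporal placement of correlations.

Grid searches (G: 0.1–2.5 step 0.1; s_I: 0–1 step 0.02 by default) pick
the grid value minimising the mean KS across seeded simulations, ties
breaking to the smaller value. Numerical failures are excluded and
counted; a grid point must keep ≥80% of its simulations to be eligible as
the argmin, and a point losing all simulations is an error. FIC is
re-tuned at every G (stronger coupling needs stronger feedback inhibition)
but held fixed across an s_I sweep and across connectome replacement, which
swaps the coupling matrix of a calibrated model while keeping G and J_FIC.

Group comparisons of fit use a permutation-based pooled-variance t-test
(10,000 label permutations, add-one p estimator, two-sided) plus Cohen's d
and Hedges' g.

## Synthetic data

No patient or volunteer imaging ships with the package; the `fixtures`
module generates every input:

- **Connectomes**: regions on a sphere (default) or a circle ("ring"
  layout), edge weights exp(-decay·distance) with the closest
  `edge_density` fraction of pairs connected. Geometry-dominated topology
  makes lattice and random rewirings genuinely different. The ring layout
  assigns labels in angular order so the ring order used by the lattice
  null (label order) coincides with the generating geometry; the
  replacement experiment uses it, because with spatially arbitrary label
  order a ring-lattice rewiring is as disruptive as a random one and the
  lattice/random asymmetry cannot appear.
- **Cohorts**: per-subject multiplicative log-normal weight noise plus
  independent edge dropout, exercising the strict-majority consensus rule.
- **Receptor maps**: Gaussian-kernel-smoothed noise over the region
  coordinates, shifted positive, then z-scored and min–max normalised.
- **Pseudo-empirical BOLD**: the full simulate → Balloon–Windkessel →
  band-pass chain at known parameters, one seeded scan per subject. This
  is circular by design: recovery experiments validate the inference
  machinery, not biology. The generator emulates none of scanner noise,
  motion, physiological confounds or lesion geometry, so passing tests say
  nothing about robustness to those.

The autocorrelation-preserving map shuffle is a variogram-matching
surrogate: candidates are spatially smoothed Gaussian noise fields (8
kernel widths spanning the observed distance range, 100 candidates by
default), each rank-remapped onto the original value multiset and scored
by the mean absolute deviation between its 25-bin distance-binned
semivariance and the input's; the best candidate is returned. The shuffled
control keeps the already-normalised values (no re-normalisation after
permutation).

## Desk-scale experiment configurations

The test suite runs the full pipeline at sizes chosen for a single CPU;
all use 20-region fixtures and dt = 0.5 ms (the package default is
0.1 ms; the noise-free integrator's dt-halving error at these sizes is
below 1e-3, and the recovery experiments are self-consistent — generator
and sweep share one configuration — so the working point is the same on
both sides):

- **Firing-rate target**: FIC tuning at G = 1.2 on the sphere fixture,
  then ≥60 s of noise-driven simulation at package defaults (dt = 0.1 ms);
  grand-mean excitatory rate within 3 ± 0.5 Hz.
- **G recovery**: pseudo-empirical data at G* = 1.2 (3 scans × 120 TRs,
  TR 2 s), swept over G ∈ {0.4, …, 1.8} step 0.2 with 5 simulations per
  point.
- **s_I recovery**: the KS(FCD) objective resolves s_I only near the
  model's dynamical working point — away from it the landscape is flat
  relative to run-to-run FCD variability. The experiment therefore places
  the generating model at the fixture's working point (G = 1.9) and
  balances (FIC-tunes) it at the generating condition, i.e. under the
  gain map at the true s_I; the sweep holds that calibrated J_FIC fixed
  across the grid (0–0.6, step 0.05, 5 simulations per point, 3 scans ×
  200 TRs). Calibrating at s_I = 0 only, as one would on real data where
  the truth is unknown, leaves s_I* = 0.4 unidentifiable at this scale.
- **Connectome replacement**: ring-layout fixture at G = 1.9, J_FIC from
  the intact connectome H and held fixed; pseudo-empirical conditions from
  H and from a weight-preserving randomisation P (3 scans × 100 TRs each);
  50 simulations per model. The H-calibrated model fits H-data better
  (positive ΔKS), replacing H by P or by a fresh random null flips the
  sign, and the lattice null does not flip — its rewiring respects the
  generating ring geometry, so its dynamics stay on the H side.

## Numerical and reproducibility notes

- One master seed per entry point; all internal streams are spawned via
  `numpy.random.SeedSequence`, and the compiled integrator is seeded per
  call — identical seeds give bit-identical trajectories.
- The Euler–Maruyama kernel and the Balloon–Windkessel kernel are
  numba-compiled; the pure-NumPy `dmf.step` is the reference
  implementation and the two are cross-checked in the tests.
- Degenerate simulations (zero-variance FC windows from a saturated or
  silent run) are treated like numerical failures by the sweep machinery.
- The F–I curve's removable singularity at I = I_thr uses the analytic
  limit 1/d via a first-order expansion for |d·x| < 1e-8.
- Validation never repairs data: asymmetric matrices, negative weights,
  non-finite entries and constant receptor maps are errors, not warnings.

## Known limitations

- No conduction delays, no spiking detail, no excitatory-gain
  neuromodulation variant.
- The haemodynamic stage is single-compartment and noise-free; empirical
  BOLD confounds are not modelled.
- The KS(FCD) objective is shallow away from dynamical transitions; on
  small fixtures parameter recovery is only meaningful at the working
  point (see above), and the same caution applies to interpreting fits on
  real data at this scale.
- Lattice rewiring quality depends on the label order defining the ring;
  for connectomes whose labels carry no spatial meaning the lattice null
  is a generic regular network, not a geometry-preserving one.
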