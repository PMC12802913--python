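# Methods

`taildyn` implements the computational chain that connects all-atom MD
trajectories of a nucleosome to solution-NMR observables of its histone
tails, together with the surrounding analyses: tail–DNA contact kinetics
and ensemble thermodynamics, chemical-shift-perturbation and relaxation
table processing, intra-tail ensemble descriptors, and thermal-shift melt
analysis. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic-data generators do and do not
emulate.

## Spin relaxation from bond-vector trajectories

**Model.** Backbone amide ¹⁵N relaxation is driven by the reorientation
of the N–H bond vector through the ¹H–¹⁵N dipolar interaction and the ¹⁵N
chemical shift anisotropy. From a trajectory superposed on the rigid core
(so only internal motion remains), the orientational autocorrelation
function of each residue's unit N–H vector is

C(t) = ⟨P₂(u(τ)·u(τ+t))⟩,  P₂(x) = (3x² − 1)/2.

The trajectory is split into `n_chunks` equal segments (default 20); C(t)
is computed per segment over all time origins (exactly, via an FFT
expansion of the squared dot product into component products), averaged
across segments, and the across-segment scatter provides per-lag standard
errors. Lags are limited to `max_lag_fraction` (default 0.5) of the
segment length.

**Exponential representation.** C(t) is fitted with up to three
exponentials, A_i ≥ 0, ΣA_i ≤ 1, τ_i > 0, by bounded nonlinear least
squares with multiple log-spaced starts (best residual wins; ties broken
by the smallest Σ|log τ_i| for reproducibility). A deficit 1 − ΣA_i is
reported as an unresolved fast component. Two safeguards keep the
representation identifiable:

* components whose time constants differ by less than 1.5× are merged
  (amplitude-weighted geometric-mean τ) — near-degenerate exponentials
  are not separable;
* components slower than half the observation window are retained only
  when their amplitude exceeds twice the median standard error of the
  C(t) tail. The tail values are strongly correlated across lags (they
  share the same segments), so an unweighted fit will otherwise absorb
  pure noise into a plateau term that enters J(0) — and hence R₂ —
  multiplied by an arbitrarily long effective time.

**Tumbling and spectral density.** Overall tumbling of the nucleosome is
reintroduced by multiplying C(t) with exp(−t/τ_rot), i.e. per component
1/τ_eff = 1/τ_i + 1/τ_rot, with τ_rot = 163.4 ns by default (the
nucleosome core particle value used throughout; overridable). The
spectral density is the analytic transform of the fitted exponentials,

J(ω) = (2/5) Σ A_i τ_eff,i / (1 + (ω τ_eff,i)²),

normalized so that the rigid rotor gives J(ω) = (2/5) τ/(1+(ωτ)²). The
analytic transform is the primary path because it is noise-free and
closed-form; a trapezoid cosine transform of the raw C(t) is available as
a diagnostic only (it is truncation-limited).

**Rates.** With d = (μ₀/4π) ħ γ_H γ_N / r_NH³ and c = ω_N Δσ/√3:

* R₁ = (d²/4)[J(ω_H−ω_N) + 3J(ω_N) + 6J(ω_H+ω_N)] + c² J(ω_N)
* R₂ = (d²/8)[4J(0) + J(ω_H−ω_N) + 3J(ω_N) + 6J(ω_H) + 6J(ω_H+ω_N)]
      + (c²/6)[4J(0) + 3J(ω_N)]
* NOE = 1 + (d²/4)(γ_H/γ_N)[6J(ω_H+ω_N) − J(ω_H−ω_N)]/R₁

Defaults (all overridable, reported in output headers): r_NH = 1.02 Å,
Δσ = −172 ppm, γ_H = 2.6752×10⁸ and γ_N = −2.7126×10⁷ rad s⁻¹ T⁻¹, ¹H
frequency 600.13 MHz with ν_N derived through |γ_N/γ_H|. These are the
field-standard amide values; the rate formulas and the J-normalization
use one consistent convention, which the tests lock (mixing conventions
is the classic failure mode).

**Effective correlation time.** The residue-wise τ_c inverts the ratio:

τ_c = (1/(4π ν_N)) √(6 R₂/R₁ − 7),

with σ propagated first to the ratio and then through the derivative
3σ_ratio/((4π ν_N)√(6r−7)). When the high-frequency terms J(ω_H±ω_N) and
J(ω_H) are zeroed, this inversion is an algebraic identity for any τ and
any CSA, because R₁ and R₂ then share the factor (3d²/4 + c²) —
(d²/8 + c²/6) = (3d²/4 + c²)/6 — and the tests verify the identity to
machine precision. With the full expressions at τ = 163.4 ns and 600 MHz
the inversion recovers the input τ to better than 1%. Ratios ≤ 7/6 are
flagged undefined rather than raised.

**Burn-in.** The relaxometry chain applies no burn-in by default; the
contact analyses discard the first 200 ns. Callers who want the same
exclusion for relaxometry can slice the vector series.

## Experimental NMR tables

Chemical shift perturbations combine ¹H and ¹⁵N differences as
Δδ = √((Δδ_H)² + (0.154·Δδ_N)²); the 0.154 nitrogen weight is a named
constant (other conventions use 0.14–0.2). Tables are matched by residue
id, never row order; prolines and unobserved peaks carry a missing flag
and propagate as flagged rows, not silent drops.

Relaxation rates come from fitting I(t) = I₀·exp(−Rt) (two parameters, no
offset) with unit weights; σ_R is the covariance scaled by the residual
variance, so duplicate delay points contribute their scatter to the
reported uncertainty. This choice treats peak-intensity noise as additive
(constant spectral noise), which Monte-Carlo tests confirm calibrates
σ_R against replicate scatter to well within 30%.

## Tail–DNA contacts, kinetics and thermodynamics

A tail residue contacts DNA in a frame when any of its heavy atoms lies
strictly within 4 Å (strict `<`) of a DNA heavy atom; contact search is
an exact all-pairs query (k-d-tree accelerated with a strict-inequality
post-filter, identical to the brute-force double loop). Frames before the
200 ns burn-in are discarded and a 1 ns stride is applied to the rest
(both configurable).

The full tail is **unbound** in a frame when at most ⌊0.10·n_residues⌋
residues are in contact (for a 36-residue tail: ≤ 3), otherwise bound.
The floor rule is a documented choice; the rounding convention of "no
more than 10%" is otherwise ambiguous.

Episodes come from run-length encoding the state series. An unbinding
event is a bound→unbound transition. Bound episodes shorter than the
50 ns minimum residence (the time scale needed to establish stable
interactions) are merged into the flanking unbound time before events are
counted, so a single consistent state sequence underlies both event
counts and residence statistics; `count_short_events=True` retains them.
The final episode is right-censored by the trajectory end: it is flagged
and excluded from residence statistics (the first episode's start is
taken as observed). Ensemble thermodynamics uses all analyzed frames:
K_d = n_unbound/n_bound and ΔG⁰ = RT ln K_d (R = 1.98720425×10⁻³
kcal mol⁻¹ K⁻¹, T = 310 K by default, matching the simulation
thermostat); ΔG⁰ is negative when binding dominates. A state with zero
frames yields an undefined result with a count report, never ±∞.

Per-base-pair contact maps aggregate atom-pair contacts onto the bp index
of the DNA atom, with both strands of a duplex sharing one index
(i ↔ 2N+1−i by default) and means taken per analyzed frame; the sum over
bp equals the mean total atomic contact count (conservation, tested).

## Ensemble descriptors

DCCM: C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) over one representative
atom per residue (Cα by convention; the pseudo-bead in toy systems), on a
superposed trajectory. Zero-variance residues give flagged NaN entries.
Radius of gyration is mass-weighted by default. Residue–residue contact
probability maps support a heavy-atom distance criterion (< 4 Å) and a
geometric hydrogen-bond proxy (donor-heavy–acceptor < 3.5 Å, D–H···A
angle > 120°, hydrogens assigned to donors by a 1.3 Å same-residue rule);
pairs of adjacent residues are masked. The H-bond proxy is explicitly a
proxy: faithful interaction typing comes from imported edge tables
(TSV: residue_a, residue_b, probability, class), on which node degree is
the sum of incident edge probabilities, with duplicate (pair, class) rows
rejected rather than silently double-counted.

## Thermal shift analysis

Raw fluorescence is min–max normalized per replicate, differentiated by
the forward difference assigned to the upper temperature of each
interval, and melting temperatures are read from derivative peaks ranked
by topographic prominence (up to `max_peaks`, default 2, reported in
ascending temperature). The forward-difference/T_{i+1} assignment biases
a symmetric transition by about half a grid step towards higher
temperature; this is implemented exactly as defined and documented
rather than corrected. The prominence threshold (default 0.05 of the
derivative range) drops attenuated transitions too small to assign a Tm —
a decision, since "too small to measure" is qualitative. No smoothing by
default; an optional 3-point moving average handles noisy data.
Replicate Tm values are matched across replicates by single-linkage
clustering within 3 °C (chosen to separate transitions near 72 and 81 °C
comfortably) and reported as mean ± sample sd per transition. The whole
pipeline is invariant to affine transformations of the raw fluorescence.

## Synthetic data: what it emulates and what it does not

* **Rotational diffusion** (`gen_rotdiff_vectors`): a unit vector takes
  per-frame rotations about a uniformly random perpendicular axis by an
  angle ~ N(0, √(4D·dt)), D = 1/(6τ_c) — the correct small-step limit,
  with C(t) = exp(−t/τ_c). Grids with per-step angular variance above
  0.1 rad² are refused. This is the analytic oracle for the relaxometry
  chain, not a model of a real amide vector.
* **Cone motion** (`gen_cone_vectors`): a uniform-in-cap jump process
  (resampling probability 1 − exp(−dt/τ_int) per frame), chosen over
  reflected Brownian motion because its correlation function is exactly
  C(t) = S² + (1−S²)exp(−t/τ_int) with S = cosθ₀(1+cosθ₀)/2, making the
  model-free (Lipari–Szabo) limit testable against a closed form.
* **Binding timelines** (`gen_two_state_timeline`): a two-state Markov
  chain with switching probabilities 1 − exp(−k·dt); dwell times are
  geometric with mean ≈ 1/k, the stationary bound fraction is
  k_on/(k_on+k_off).
* **Toy nucleosome** (`gen_toy_nucleosome_traj`): a static lattice of DNA
  beads plus a tail chain that sits ~3 Å from DNA (≈30% of beads) when
  bound and beyond 6 Å when unbound, with ±0.3 Å jitter — margins
  guarantee the contact pipeline recovers the scripted state exactly.
  At least 10 tail beads are required so the 10% threshold is meaningful.
* **Melt curves** (`gen_melt_curve`): sums of logistic transitions plus
  additive Gaussian noise on the normalized scale; replicates use
  spawned child seeds. Heteroscedastic noise is out of scope.
* **Peak tables** (`gen_peak_tables`): the second table is the first plus
  prescribed (Δδ_H, Δδ_N) shifts.

All generators are deterministic given their seed and store their ground
truth in output metadata. None of them reproduce force-field physics,
solvent, sequence specificity, chemical exchange or anisotropic tumbling;
passing tests therefore demonstrate the correctness of the analysis
chain, not the realism of any MD model.

## Problem sizes used in validation

The validation suite uses single-vector series of 2×10⁵ frames at 10 ps
spacing (2 µs of pseudo-dynamics, matching the per-run trajectory length
the pipeline targets, at a coarser frame spacing), 10⁶-frame Markov
timelines at 1 ns, toy nucleosomes of 12–15 beads over a few hundred
frames, and melt curves on the 25–95 °C, 1 °C grid. Stochastic
recoveries average three independent seeds, as one would average
replicate MD runs. With these sizes the relaxometry chain reproduces
closed-form rates to a few percent (the irreducible sampling noise of a
single 400·τ_c series is ~10% on J(0), which is why replicates are
averaged), the cone plateau matches S² within 0.05, Markov K_d is within
10% and mean residence within 15% of ground truth, and scripted contact
fixtures are recovered exactly.

## Known limitations

* Isotropic overall tumbling only; no rotational diffusion tensor, no
  chemical-exchange (R_ex) contribution, no reduced spectral density
  mapping.
* The tri-exponential representation cannot resolve motions faster than
  the frame spacing (reported as the amplitude deficit) or slower than
  the observation window (suppressed unless statistically significant).
* Contact analysis ignores periodic boundary conditions; trajectories
  must be pre-imaged.
* The hydrogen-bond criterion is geometric, not energetic, and the
  BMRB reader is a stub: experimental tables enter as CSV.
* ΔG⁰ from frame counting inherits all sampling limitations of the
  underlying trajectory; censored episodes are excluded from residence
  statistics but counted in the frame totals.
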