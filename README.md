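# taildyn

Histone tails are intrinsically disordered arms of the nucleosome that
spend most of their time draped over the nucleosomal DNA as a "fuzzy"
ensemble of rapidly exchanging conformations. Probing how mutations or
modifications shift that ensemble requires connecting two very different
measurements: solution-NMR observables (chemical shift perturbations,
¹⁵N R₁/R₂ relaxation rates, residue-wise rotational correlation times
τ_c, thermal-shift melting temperatures) and all-atom MD trajectories
(tail–DNA contacts, binding/unbinding kinetics, intra-tail interaction
networks). `taildyn` implements that bridge as a tested Python library
with a thin CLI, for structural biologists and simulators who want the
same analysis to run on real trajectories, experimental tables and
synthetic fixtures with known ground truth.

## What it computes

**MD → NMR relaxometry.** From per-residue N–H unit-vector series (after
superposition on the histone core Cα atoms), the chunk-averaged
orientational autocorrelation C(t) = ⟨P₂(u(τ)·u(τ+t))⟩ is fitted with up
to three exponentials; overall tumbling is reintroduced as exp(−t/τ_rot)
(τ_rot = 163.4 ns for the nucleosome core particle), giving the analytic
spectral density

J(ω) = (2/5) Σᵢ Aᵢ τ_eff,ᵢ / (1 + (ω τ_eff,ᵢ)²),  1/τ_eff,ᵢ = 1/τᵢ + 1/τ_rot,

from which R₁, R₂ and the heteronuclear NOE follow via the standard
dipolar + CSA expressions, and the residue-wise correlation time via

τ_c = (1/(4π ν_N)) √(6 R₂/R₁ − 7).

**Experimental tables.** CSPs Δδ = √((Δδ_H)² + (0.154 Δδ_N)²) between
peak tables; single-exponential fits I(t) = I₀e^(−Rt) of intensity-vs-
delay series with error propagation through R₂/R₁ to τ_c.

**Contact kinetics.** Tail–DNA contacts (heavy-atom pairs strictly within
4 Å, 1 ns stride, 200 ns burn-in), bound/unbound classification of the
full tail (unbound when ≤ ⌊10%⌋ of residues touch DNA), binding events
and residence times (≥ 50 ns filter), and ensemble thermodynamics
K_d = n_unbound/n_bound, ΔG⁰ = RT ln K_d, plus per-base-pair contact maps.

**Ensemble descriptors.** Dynamic cross-correlation matrices, radius of
gyration, residue–residue contact-probability maps (distance or geometric
H-bond criterion), and node degrees over interaction edge tables.

**Thermal shift.** Min–max normalization of melt curves, forward-difference
derivative assigned to T_{i+1}, peak-prominence Tm extraction for mono-
and biphasic transitions, replicate aggregation.

**Synthetic data.** Seeded generators for every input above — rotational-
diffusion and cone-restricted bond vectors, two-state Markov binding
timelines, toy tail+DNA pseudo-atom trajectories with scripted binding,
logistic melt curves, perturbed peak-table pairs — each with ground truth
stored in metadata. See `docs/methods.md` for models and assumptions.

## Worked example

Simulate 1 µs of a bond vector tumbling with an internal correlation time
of 5 ns, then push it through the full relaxometry chain with nucleosome
tumbling reintroduced:

```sh
$ taildyn simulate vectors --kind rotdiff --tau-c-ns 5 --dt-ps 10 \
      --n-frames 100000 --seed 11 --out vec.txt
$ taildyn relax vec.txt --tau-rot-ns 163.4 --chunks 20
{
  "R1_per_s": 2.4118557850371696,
  "R2_per_s": 7.979425226841743,
  "NOE": 0.883236400401422,
  "tau_c_ns": 4.687867916992257,
  "fit_amplitudes": [1.0],
  "fit_taus_ns": [4.880319188458888],
  ...
}
```

The fitted internal time (4.88 ns) recovers the generator's 5 ns within
the sampling error of a single trajectory; R₂ > R₁ because the slow
overall tumbling dominates J(0); and inverting R₂/R₁ gives an effective
τ_c of 4.7 ns — the internal motion, since the tail decorrelates much
faster than the nucleosome tumbles.

Melt-curve analysis on three noisy synthetic replicates of a biphasic
nucleosome disassembly profile:

```sh
$ taildyn simulate melt --tm 72 --tm 81 --noise-sd 0.01 --replicates 3 \
      --seed 5 --out melt.csv
$ taildyn meltfit melt.csv --smooth
replicate 0: Tm = [73.0, 81.0]
replicate 1: Tm = [72.0, 82.0]
replicate 2: Tm = [73.0, 81.0]
 transition   tm_mean   tm_sd  n_replicates  in_all_replicates
          1 72.666667 0.57735             3               True
          2 81.333333 0.57735             3               True
```

Both transitions are recovered within one 1 °C grid step of the ground
truth (72 and 81 °C); the forward-difference convention biases estimates
about half a grid step high.

The same operations are available as library calls
(`taildyn.p2_autocorrelation`, `taildyn.relaxation_rates`,
`taildyn.classify_bound_state`, `taildyn.find_tm`, ...) returning numpy
arrays and pandas DataFrames.

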