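# Methods

This note documents the model, its numerical treatment, the provenance of
every default parameter, what the synthetic generators emulate, and the
design decisions taken where the problem was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Steady-state model

The dendrite is a one-dimensional segment [0, L] with the soma at x = 0
and a sealed tip at x = L. Three coupled fields describe one molecular
species: dendritic mRNA density m(x) (per µm), shaft protein density
p(x), and spine protein density p_spine(x). At dynamical equilibrium,

* mRNA: `0 = D̃_m m″ − λ_m m` (optionally `− v_bias m′` with a net
  anterograde drift), `m′(L) = 0`. The solution is
  `A·cosh((L−x)/ℓ_m)/cosh(L/ℓ_m)` with `ℓ_m = √(D̃_m/λ_m)`.
* shaft protein: `0 = τ m + D_p p″ − λ_p p − u_p p (1 − p_spine/(ρη_p)) +
  ν_p p_spine`, `p′(L) = 0`, and a somatic influx at x = 0 (below).
* spines: the quasi-steady balance gives exactly
  `p_spine(p) = u_p p ρη_p / (u_p p + (ν_p+λ_p) ρη_p)`,
  which saturates below the capacity density ρη_p. Substituting it into
  the shaft equation is exact at equilibrium and avoids a stiff coupled
  system.

**Localisation scenarios.** `somatic` keeps all mRNA in the soma
(m ≡ 0); `dendritic(r_soma)` keeps the share r_soma in the soma. The
somatic coupling condition equates the protein flux entering the dendrite
with the somatic synthesis, `−D_p p′(0) = τ m_soma`. A consequence is
that the somatic protein pool itself is empty at steady state (all
somatic synthesis is exported); total counts therefore comprise soma mRNA
plus the dendritic integrals. How to model the somatic protein pool is
the one place where this model family is genuinely underdetermined; the
exported-flux convention is the simplest member and is used consistently.

**Filling constraint.** The free amplitude (the species' total mRNA) is
scaled until the least-filled spine reaches ϕ of its capacity
(ϕ = 0.95). For the monotonically decreasing profiles produced by a
somatic source this pins the distal boundary value
`p(L) = (1/π_p)·ϕ/(1−ϕ)·ρη_p` with the spine permeability
`π_p = u_p/(ν_p+λ_p)`; the solver enforces the constraint at the spatial
minimum of p_spine, so it also holds for non-monotone profiles.

## 2. Transport mapping

Motor transport follows a three-state model: anterograde and retrograde
runs at instantaneous velocity v that terminate with rate β, and a
resting state that diffuses with D_m0, decays with λ_m and re-enters each
run direction with rate α. The steady state on [0, L] (somatic injection
into the anterograde state, reflecting tip, no diffusive flux through the
ends) is a linear constant-coefficient ODE system solved exactly by
eigenmode decomposition, with growing modes anchored at the tip for
numerical stability. The transported fraction is θ_m = 2α/(2α+β).

The one-state solver uses an ensemble diffusion constant D̃_m obtained by
fitting: the unit-normalised one-state cosh profile is matched to the
unit-normalised total three-state density by least squares over the decay
length ℓ (`D̃_m = λ_m ℓ²`). A `decay_length` strategy (matching the
soma-to-tip density ratio instead) is available; the profile fit is the
default because the spatial decay length is the quantity that feeds the
steady-state equations. The fit residual is reported and bounded. A
Monte-Carlo particle simulation of the same run-and-pause rules serves as
an independent oracle in the test suite.

## 3. Energy accounting

Maintaining a steady state costs, in ATP per second,

* transcription `2.17 · N_nt · λ_m · (m_soma + ∫m)` — every decayed
  transcript is re-synthesised at 2.17 ATP per nucleotide;
* translation `5 · N_aa · τ · (m_soma + ∫m)` — 5 ATP per amino acid
  covers synthesis and the eventual degradation of the chain (at steady
  state synthesised and degraded counts match, so one term covers both;
  no separate degradation term);
* transport `125 · (v/1 µm s⁻¹) · θ_m · ∫m / g` — each cargo in transit
  burns 125 ATP/s at the 1 µm/s reference speed, scaled linearly with
  the run velocity; g mRNAs per granule divide the cargo count.

Infrastructure costs (ribosome or mitochondria biogenesis, tRNA
synthesis, regulatory signalling) are excluded throughout. The somatic
scenario needs no transport machinery, so its transport term is
identically zero. The decision for a species compares the somatic budget
with the minimum dendritic budget over the r_soma sweep
{0.1, …, 0.9}; ties go to the somatic strategy. Because every cost
term is linear in the molecule counts and the filling constraint is
linear in η_p, scaling a species' spine capacity rescales all budgets by
the same factor — spine copy number can never change the preferred
strategy (this homogeneity is asserted exactly in the tests).

## 4. Numerics

The protein equation is discretised with a conservative finite-volume
stencil (half cells at both ends, dx = 1 µm by default, matching the
1/µm spine density), so the discrete flux balance
`J_0 + τ Σw m = λ_p Σw (p + p_spine)` holds to solver precision with
trapezoidal weights. The nonlinear spine sink is handled by Newton
linearisation with tridiagonal Jacobian solves; a damped fixed-point
iteration on the sink was rejected because its contraction factor is of
order π_p (≈ 100 at the defaults) and diverges. Newton stops at 1e−12
relative steps or at the machine-precision floor (detected as a
non-contracting step below 1e−7 relative). The amplitude satisfying the
filling constraint is bracketed in decades and bisected in log space to
1e−10 relative; monotonicity of the spatial minimum of p in the
amplitude makes the bisection exact. The inner kernels are numba-compiled;
a full population run (2187 species × (1 somatic + 9 dendritic) solves)
takes ~15–40 s per dendrite length on one CPU.

Degenerate inputs raise configuration errors rather than producing NaNs:
ϕ ∉ (0,1), u_p = 0 (spines can never fill), non-positive rates or
lengths, transcripts shorter than their coding sequence.

## 5. Synthetic species grid

Population statements are made over a full factorial grid: three values
(low/medium/high) for each of seven dimensions — mRNA half-life,
non-coding/coding length ratio (setting N_nt = 3·N_aa·(1+ratio)),
protein half-life, protein length, spine capacity η_p, protein diffusion
constant, and mRNA transport intensity (the re-entry rate α, which sets
θ_m and D̃_m) — giving 3⁷ = 2187 species. Sampling is uncorrelated by
design; each species carries its per-dimension group label.

The bundled levels (`src/dendrocost/data/defaults.yaml`) are provisional:
they were chosen once to span the experimentally reported ranges —
mRNA half-lives 2/8/24 h, non-coding ratios 0.25/1/2.5, protein
half-lives 2/8/32 d, protein lengths 150/450/1350 aa, spine capacities
10²/2·10³/3.2·10⁴, protein diffusion 0.002/0.02/0.2 µm²/s, α
0.0125/0.05/0.25 s⁻¹ (θ_m ≈ 0.05/0.17/0.5 at β = 0.5 s⁻¹) — and to
bracket the CaMKIIα preset, whose diffusion constant (see §7) anchors
the scale of the D_p dimension. Fixed baseline: τ = 0.01 proteins per
mRNA per s, ρ = 1 spine/µm, ϕ = 0.95, D_m0 = 0.001 µm²/s, v = 1 µm/s,
β = 0.5 s⁻¹, u_p = 0.03 s⁻¹, ν_p = 3·10⁻⁴ s⁻¹, one mRNA per granule.

Quantities that depend on the absolute level values (preference
fractions, the median transcription+translation saving, the population
energy demand) inherit their uncertainty; the direction properties
(which parameters push a species toward dendritic mRNA) do not, and are
tested at all four dendrite lengths (250–1000 µm).

## 6. Synthetic screens

`synthetic_screen` emulates a compartment-resolved enrichment screen:
two latent groups (soma-destined, neurite-destined) with lognormal
property distributions whose medians differ by configurable
multiplicative effects, and lognormal enrichment scores centred at 0.25×
(soma group) and 4× (neurite group) so that 2-fold classification
recovers the latent groups with a realistic unclassified middle band.
Default noise is σ_log = 0.6; default effect directions follow the
model's predictions (neurite group: 1.5× mRNA half-life, 1.3× transcript
length, 1/1.4× protein half-life, 1.3× protein length, equal spine
copies, 2× abundances). What passing tests show: the statistical
pipeline is calibrated (type-I error ≈ α on null screens) and powered
for the configured effects. What they do not show: that real screens
carry these effect sizes, or anything about real-data artefacts
(detection limits, batch effects, annotation mismatches) — real tables
are ingested through the same readers but are not bundled.

Count rescaling for incomplete mRNA detection divides by the detection
probability (25% → ×4, 20% → ×5). Rank-sum tests use the exact null
distribution for pooled samples ≤ 12 without ties, otherwise the
tie-corrected normal approximation; no multiple-testing correction is
applied (panel comparisons are pairwise). Bootstrap resampling is
within-group, with-replacement, 10,000-fold by default, fully seeded.

## 7. Presets

**CaMKIIα** carries the printed values N_aa = 478, N_nt = 4900,
η_p = 32,336, protein half-life 8 d, mRNA half-life 20 h, τ = 0.01/s.
Its diffusion constant and transport kinetics are not printed; the
bundled defaults D_p = 0.02 µm²/s and α = 0.05 s⁻¹ are provisional,
chosen within the literature range for the large holoenzyme so that the
preset reproduces the example's qualitative behaviour (motor-associated
mRNA, dendritic localisation energetically optimal). With these values
the dendritic strategy is ~1.6× cheaper at L = 500 µm.

**Shank3** (photoactivation paradigm) is provisional throughout:
N_aa = 1731, N_nt = 7500, η_p = 300, protein half-life 4 d, mRNA
half-life 10 h, D_p = 0.1 µm²/s. Its spine-exchange rates override the
baseline (u_p = 0.03 s⁻¹, ν_p = 10⁻³ s⁻¹, ~17 min residence) because
photoactivation experiments report sub-hour fast-pool exchange for this
scaffold.

## 8. Photoactivation dynamics

The labelled subpopulation rides on the frozen steady state, so its
dynamics are linear and time-invariant: shaft diffusion, degradation,
spine entry at `k_in(x) = u_p(1 − p_spine/ρη_p)` and spine exit at ν_p.
The soma is modelled as a well-mixed, fully labelled reservoir from
t = 0: the labelled shaft density at x = 0 is clamped to its steady
value (Dirichlet), which encodes both the instantaneous labelling of the
somatic pool and labelled somatic synthesis; the unlabelled remainder
has boundary value zero. Because the same finite-volume operator is used
as in the steady solver, the steady profile is an exact fixed point and
labelled+unlabelled mass is conserved to solver precision (asserted at
0.1% in the tests). Stepping is backward-Euler for the shaft with the
spine exchange coupled semi-implicitly, dt = 10 s over 8 h.

Two time scales are reported. `saturation_time` follows the strict
definition: first crossing of 95% of the analytic asymptote (the full
steady occupancy, since labelled/total → 1 as t → ∞). Under
slow protein turnover (half-lives of days) the unlabelled pool can only
disappear at λ_p, so no spine strictly saturates within 8 h — a model
property, not a numerical artefact. The experimentally reported
"starts to saturate" refers to the visible flattening of the trace
within the 8-h recording; the acceptance script therefore quantifies it
as the time to reach 95% of the trace's own 8-h plateau at the proximal
(25 µm) spine. Both definitions are exposed; the level and window are
configurable.

## 9. Known limitations

* No dendritic branching, no time-varying synaptic demand, no
  stochastic reaction noise; single-compartment spines with one
  exchangeable pool (no stable core fraction).
* The somatic protein pool is not modelled (exported-flux convention);
  rank-abundance totals count soma mRNA but no somatic protein.
* The r_soma sweep is a 9-point grid; optima at the 0.1 edge indicate
  the continuum optimum may lie below it.
* The anterograde-bias variant applies drift in the one-state equation
  rather than asymmetric switching rates — an approximation.
* Grid-level absolute numbers depend on provisional level choices (§5);
  direction and homogeneity properties are the robust outputs.
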