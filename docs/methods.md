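# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `modefit`, in the spirit of a model-description appendix.

## Models

### Constitutive circuit

Two species (mRNA, Protein), four mass-action reactions: zeroth-order
transcription `k_tx` (molecules/min), first-order mRNA decay `d_mrna`,
translation `k_tl * mRNA`, protein decay `d_prot` (all 1/min). The ODE
limit is linear with the unique stable fixed point

    mRNA* = k_tx / d_mrna,     Protein* = k_tx k_tl / (d_mrna d_prot),

and Jacobian eigenvalues −d_mrna, −d_prot; these closed forms serve as
oracles in the test suite. The reference ("true") parameter set is
(5, 0.03, 0.1, 0.03) with observable = Protein, φ = 1, and initial state
(0, 0) for all in-silico experiments.

### IRF7 circuit

Seven species: IFN (the interferon-β stimulus, measured in "units"
mapped 1:1 to molecules/cell, so a 150 U treatment is 150 initial
molecules), ISGF3 (lumped JAK-STAT output), Pa (active-promoter
occupancy), mRNA, IRF7, IRF7phosp, IRF7dimer. Thirteen reactions: IFN
self-amplification with a Hill-saturable rate V_IFN·IFN²/(k_IFN²+IFN²);
ISGF3 production proportional to IFN; promoter activation at rate
k_on · ISGF3·D / (k_aI3 k_aI7 + k_aI3 ISGF3 + k_aI7 D + ISGF3·D) · (1−Pa)
(D = IRF7dimer) — the two-ligand saturable form of independent ISGF3 and
dimer binding; active (k_Active·Pa) and basal (k_Basal·(1−Pa))
transcription; translation; phosphorylation; dimerization
(k_IRF7dimer·IRF7phosp²); and first-order decay of Pa, IFN, mRNA, dimer
and ISGF3. Time unit is minutes throughout; 48 h = 2880 min. The
observable is total IRF7 protein (free + phosphorylated + dimer), φ = 1.

Pa is a 0/1 copy number in the stochastic regime — the (1−Pa) factor in
the activation rate guarantees at most one active promoter copy — and a
continuous occupancy in [0, 1] in the ODE regime.

**Dimerization convention.** The propensity is implemented exactly as the
model's printed rate law, k·X² with X the phosphorylated-IRF7 count, not
the combinatorial k·X(X−1)/2 form that is standard for bimolecular SSA
channels. At X = 1 the printed law is positive although no reaction
partner exists; firing would create a negative count whose propensity
then *grows* (X²), a divergence. The simulator therefore enforces
copy-number feasibility generically: any channel whose firing would make
some species negative has zero propensity. For X ≥ 2 the printed law is
used unchanged; the deterministic regime always uses the printed law.

## Stochastic simulation

Direct-method sampling of the jump process: exponential waiting times at
the total propensity, channel selection proportional to propensity,
piecewise-constant recording (state at the last event ≤ tᵢ). The inner
loop is JIT-compiled per network (the rate laws are code-generated from
their symbolic form), which puts a 48-hour IRF7 trajectory at nominal
rates (≈6×10⁶ events) at about half a second on one core. Exactness is
validated against a Poisson oracle (pure-birth network, chi-square
goodness of fit) and the analytic transient/stationary moments of the
constitutive circuit.

Reproducibility: member j of an ensemble uses the seed derived from
`SeedSequence([base_seed, j])`, so ensembles are order-independent and
growing an ensemble preserves its prefix bit-exactly. All optimizer
randomness likewise derives from one base seed.

## Deterministic analysis

The ODE right-hand side is S·a(x, θ) (stoichiometry times propensities);
the Jacobian is symbolic (sympy differentiation, with power terms merged
so Hill derivatives stay finite on the boundary). Steady states are
located by Powell-hybrid root iterations from a fixed multi-start
lattice: the origin neighborhood, the model's default initial state, and
20 log-uniform states per species in [10⁻³, 10⁴] drawn from a dedicated
seeded generator (the lattice is identical across calls). Converged
roots are deduplicated componentwise (atol 10⁻⁹, rtol 10⁻⁶), clamped to
zero within a negativity tolerance, and classified stable iff the
maximum eigenvalue real part is below −10⁻⁹ (marginal points are
rejected). Residual tolerance for accepting a root: ‖RHS‖∞ <
10⁻⁹·(1 + ‖x‖∞).

**Boundary branches.** An absorbing branch (e.g. the unstimulated IRF7
branch with IFN = 0) can lie arbitrarily close to an interior repeller
(at nominal rates, an unstable root at IFN ≈ 2.4×10⁻⁷), and root
iterations converge to the repeller. Each root with components below
10⁻³ is therefore also tested with those components clamped to exactly
zero; the clamped point is kept as a distinct fixed point when it
satisfies the residual tolerance itself. This recovers both stable
branches of the IRF7 circuit, matching its documented steady-state
table on the entries that are reproducible from the printed rate
constants (the active-branch protein-chain entries of that table are not
mutually consistent with the printed constants and are not used as
references).

**Precondition.** Stable steady states are mapped to observation units,
sorted ascending and paired index-wise with the ascending modes (the
pairing rule when several modes exist). Pass requires the stable count
to equal the mode count and every pair to satisfy the β band. The "∞"
penalty of the conditional objective is a finite 10¹² so optimizers can
rank rejected candidates; it exceeds any attainable F (F ≤ 2n).

## Distributions and modes

Histograms use L = round(√nm) bins (nm = experimental events per time
point, minimum 2 bins), equal-width on the experimental range per time
point; the same L and edges are reused for the simulated ensemble
regardless of ns, with simulated outliers clipped into the terminal bins
(the objective needs a common grid; the handling of simulated outliers
is a recorded choice). A zero-range time point degenerates to a flagged
single-support distribution. Mode detection operates on the final-time
distribution only (equilibrium assumption): peaks of the binned mass
sequence, zero-padded so boundary bins can be modes, with prominence ≥
0.05 × the maximum mass and separation ≥ 3 bins. Because √nm-rule
histograms carry visible sampling noise, detection runs on a 5-bin
moving average and each detected peak is then refined to the raw-mass
argmax within the half-window; this recovers the single constitutive
in-silico mode and both surrogate modes across seeds (the calibration is
part of the test suite). Modes are reported on the raw (linear)
fluorescence scale.

## Optimizers

Random search: uniform draws on the linear scale of the box bounds
(ranges here span only ~4×, so log sampling buys little), fixed
parameters held, best conditional objective wins.

Genetic algorithm: generation 0 is a large uniform population (default
3000) sized to survive the ~99% precondition rejection; later
generations default to 20 individuals. Parents are the top ⌈ε·N⌉ ranked
individuals (N = the subsequent population size; ε = 0.4 → 8 parents),
ties broken by evaluation order; offspring are uniform per-gene
crossovers of random parent pairs, each gene mutated with probability μ
(default 0.2) by uniform resampling within its bounds; the best
individual is carried over unchanged, so the population best is
non-increasing by construction. Penalized individuals can only become
parents when fewer passing individuals exist than parent slots. The
operator set (truncation selection, uniform crossover, uniform-resample
mutation) is the simplest choice consistent with a ranked, elitist,
mutation-rate-parameterized GA; it is isolated behind `GAConfig` so
variants can be swapped in.

## Synthetic data

`generate_insilico_data` is the ground-truth path: exact ensembles of a
bundled model at known rates, observation-mapped into an event table
(defaults: constitutive circuit, 10000 runs, times 50/100/150/200 min).

`generate_flow_surrogate` emulates a bimodal cytometry time course for
the IRF7 study, where the real measurements are not publicly available
and only their final-time modes (77 and 1000 a.u. at 48 h) are
documented. Each time point is a two-component log-normal mixture
(right-skewed, positive — the shape of fluorescence data); components
are parameterized by their density peak (μ_log = ln(location) + σ²,
σ_log = 0.35), so the stated locations are what a mode finder recovers
from the binned data. The high-expression weight follows a logistic
switch in time (midpoint 1000 min, scale 250 min, final weight 0.55) —
a qualitative stand-in for the switch-like population transition; the
transient kinetics, intermediate time points (0, 4, 8, 16, 24, 48 h) and
dispersion are recorded choices, not measured quantities. Consequences
for interpretation: fits to the surrogate exercise the full pipeline
(mode detection, precondition, ensemble scoring) but say nothing about
the real circuit's transient kinetics — only the final-time mode
structure is calibrated.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the studies at the
following sizes (chosen to keep a full run in the minutes range on one
core): in-silico datasets of 3000 events for unit-level checks and
10000 for the recovery study; recovery by random search with 1000
candidates × 1000 simulations per accepted candidate, medians over 5
seeds in the tests and 11 in the acceptance script (the per-seed best
scatters ±20-30% along the product ridge, so the median needs several
repeats); precondition selectivity over 2000 (tests) / 10000 (script)
uniform draws; GA behavior at the default 3000 + 5×20 populations with
10 simulations per accepted evaluation; IRF7 ensemble bimodality with
400 members at 48 h.

## Known limitations

- The method targets monostable/bistable systems; limit cycles and
  >2-stable-state systems are rejected by the precondition rather than
  handled.
- Mode–steady-state pairing is index-wise after sorting; systems where
  the k-th mode does not correspond to the k-th steady state in
  magnitude would be mis-paired.
- The binned lower mode of the stochastic IRF7 population at 48 h does
  not coincide with the basal deterministic total (≈80 molecules/cell):
  transcript-extinction episodes (P(mRNA = 0) ≈ 0.3 in the basal state)
  drain the fast-turnover protein chain (dimer half-life ≈ 1.6 min) and
  create a second density concentration near zero, and √ns bin widths at
  ensemble-feasible sizes are far coarser than that distinction. The
  bimodality itself (two well-separated population modes) is robust.
- Bimodal distributions can arise without bistability (e.g. slow
  promoter switching); the precondition would reject such parameter
  regimes even when they fit the data.
- FCS reading is optional and minimal (one file per time point, one
  channel); no compensation/gating is applied.
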