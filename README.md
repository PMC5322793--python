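# modefit

Fit stochastic reaction-network models to single-cell *distribution* data
— flow-cytometry-style event tables — with a deterministic precondition
that makes distribution matching affordable.

## The problem

Gene-expression circuits with low molecule counts need stochastic
(Gillespie-type) models, but fitting such a model to measured
distributions is expensive: every candidate parameter set θ costs an
ensemble of exact simulations before it can be scored. `modefit`
implements a filter-then-simulate strategy:

1. **Observation.** Measured per-cell values m(tᵢ) and simulated states
   are made comparable through h(S) = φ · Σ (observable species), with φ
   the a.u.-per-molecule scale factor.
2. **Objective.** Experimental and simulated values are binned into
   normalized histograms (PDFs) on a shared grid with L = √nm bins, and
   scored with the squared difference

   F(θ, m) = Σᵢ Σₗ ( Pₑ(m(tᵢ), bₗ) − Pₛ(s(tᵢ), θ, bₗ) )².

3. **Deterministic precondition.** Assuming the data are in equilibrium at
   the final time tₙ, the modes α₁ ≤ … ≤ α_q of the measured final-time
   distribution are compared with the stable steady states X*₁, …, X*_ss
   of the model's ODE limit (located by multi-start root finding and
   classified by Jacobian eigenvalues). Only if ss = q and

   βₖˡᵒʷ · h(X*ₖ) ≤ αₖ ≤ βₖᵘᵖ · h(X*ₖ)   for every k

   (defaults β = 0.95 / 1.05) is the stochastic ensemble simulated and F
   evaluated; otherwise the candidate is rejected at a large penalty with
   **zero** stochastic runs. The conditional objective F_cond is minimized
   by uniform random search or an elitist genetic algorithm with adaptive
   population size.

Two case-study models are bundled: a constitutive mRNA/protein
birth-death circuit, and an interferon-driven IRF7 gene-expression
circuit (7 species, 13 reactions) whose promoter is activated jointly by
ISGF3 and the IRF7 dimer — a positive feedback loop that makes the
circuit bistable and the measured population bimodal.

## Worked example

Steady states and stability of the IRF7 circuit at its nominal rates:

```sh
$ modefit steady-states --model irf7
model=irf7  fixed points: 3  stable: 2
variable  state 1 (stable, lam_max=-0.0013)  state 2 (unstable, lam_max=0.0492)  state 3 (stable, lam_max=-0.0017)
IFN                   0.00          0.00        124.70
ISGF3                 0.00          0.00         22.01
Pa                    0.00          0.00          0.88
mRNA                  1.20          1.20         14.29
IRF7                 13.63         13.63        161.67
IRF7phosp             6.62          6.62         22.82
IRF7dimer            60.16         60.16        713.88
observable           80.41         80.41        898.36
```

The circuit is bistable: a basal branch (no stimulus; total IRF7 protein
≈ 80 molecules/cell) and a stimulated branch (IFN ≈ 125, active promoter
occupancy 0.88, total ≈ 900). The unstable fixed point between them is
the tiny-IFN repeller. With measured modes at (77, 1000) a.u. and φ = 1,
the basal branch brackets the lower mode (0.95·80.4 = 76.4 ≤ 77) — this
is exactly the test the precondition applies to every fit candidate.

A complete in-silico fitting round trip:

```sh
$ modefit generate --kind insilico --out events.csv --nm 10000 --seed 11
wrote 40000 events to events.csv
$ modefit fit --model constitutive --method rs --data events.csv --seed 2 --out fit.json
best value 0.00434062 after 1000 evaluations (precondition pass rate 3.10%); wrote fit.json
```

The data are 10000 exact simulations of the constitutive circuit at the
true rates θ = (5, 0.03, 0.1, 0.03); the search treats the transcription
and translation rates as unknown. Only ~3% of candidates pass the
precondition (the steady-state ridge θ₁θ₃ ≈ 0.5 mapped against the
measured ~543 a.u. mode). `fit.json` records the full evaluation trace;
its best candidate here is k_tx = 5.20, k_tl = 0.0954 — within a few
percent of the true rates. Per-seed bests scatter along the ridge, so
quantitative recovery studies report the median over several seeds.

The same pipeline is available as a library — see
`modefit.objective_Fcond`, `modefit.random_search`,
`modefit.genetic_algorithm`, and `modefit.generate_flow_surrogate` for a
synthetic bimodal cytometry time course with final-time modes at 77 and
1000 a.u.

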