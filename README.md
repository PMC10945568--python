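# eccwater

Parameterization toolkit for four-site rigid water models that are
compatible with charge scaling (the electronic continuum correction, ECC).

## Why

Charge scaling treats electronic polarization in a mean-field way by
immersing the system in a dielectric continuum of permittivity ε_e ≈ n² =
1.78 and multiplying ionic charges by 1/√ε_e ≈ 0.75. For this to be
consistent, the water model itself must exhibit only the *nuclear* part of
the dielectric constant, ε_N = ε_r/ε_e ≈ 79.2/1.78 ≈ 45 — far below the
55–80 of standard four-site models, which consequently "overscale" ion–ion
interactions. Finding good parameters under that constraint is a search
problem over the six scalars that fully define a TIP4P-family model:

σ, ε (Lennard-Jones on oxygen) · q_H (hydrogen charge; the massless M site
on the H–O–H bisector carries q_M = −2 q_H) · d_OH · d_OM · θ.

`eccwater` provides, for people building or auditing such models:

- **watermodel** — geometry construction in a canonical frame, dipole
  μ = |Σ q_i r_i| and tetrahedral quadrupole Q_T = (Q_xx − Q_yy)/2 of the
  traceless quadrupole tensor, ECC charge scaling, bounds/normalization,
  and a GROMACS `.itp`/`.mdp` writer (settle + bisector virtual site).
- **reference_data** — experimental targets with the derivations behind
  them: ε_N = ε_r/ε_e, the Yeh–Hummer finite-size diffusion correction
  D − ξ k_B T/(6πηL), and first-RDF-peak extraction with sub-grid
  refinement.
- **cost** — the weighted-MAPE objective C = Σ w_i · MAPE_i(%)/10 with
  weights renormalized to sum to 1; variants C_ECC (dielectric included)
  and C_G (excluded, for cross-model comparison).
- **mapper** — a small MLP surrogate (4×40 ReLU, dropout 0.10, max-norm
  5.0, early stopping) predicting a candidate's cost so that predicted-bad
  candidates skip the expensive evaluation.
- **optimizer** — the three-phase search: bounded random-walk seeding,
  differential evolution with the surrogate gate, surrogate-guided
  refinement; append-only CSV ledger; reproducible under one seed.
- **toy_evaluator** — an instantaneous parameters→properties map with a
  planted optimum, standing in for the MD engine so the whole loop can be
  exercised and tested at desk scale. No MD is ever run by this package;
  real evaluations go through a file-exchange work directory.

## Worked example

Moments of the bundled presets (`eccw2024`, `tip4p2005`, `tip4pfb`,
`opc4`), straight from their six parameters:

```
$ eccwater moments --params eccw2024
mu  = 2.167735 D
Q_T = 2.444550 D.A
```

The ECC-compatible model carries a *smaller* dipole (2.17 D vs 2.31–2.48 D
for TIP4P/2005, TIP4P-FB, OPC4) — the signature of its ≈45 dielectric
constant — while its quadrupole stays in the usual 2.2–2.4 D·Å band.

Scoring a set of per-property errors (%) with the general cost:

```
$ eccwater cost --results results.yaml --variant general
C_G = 0.2615
  D_OW: loss 0.7000
  rdf_1h: loss 2.5600
  rdf_1p: loss 0.1429
  rho_1bar: loss 0.0072
```

Here `results.yaml` held the ECC model's published MAPEs (density 0.072%,
diffusion 7.0%, RDF peak position 1.429%, height 25.6%); the weighted sum
0.26 means "comparable to the best existing four-site models", which score
0.21–0.26 on the same metric.

Running the search loop against the built-in synthetic evaluator:

```python
from eccwater import OptimizerConfig, ToyEvaluator, ToyLandscapeConfig, run_optimization

config = OptimizerConfig(seed=1, rw_count=400, gate_threshold=0.7)
state = run_optimization(ToyEvaluator(ToyLandscapeConfig(seed=1)),
                         budget=2000, config=config)
best = state.population.best()
print(best.cost.total, state.n_evaluated, state.n_skipped)
```

With the gate enabled the loop typically reaches the same final cost as an
ungated run while truly evaluating ~35% fewer candidates; the full ledger
of every proposed/evaluated/skipped candidate is in `state.ledger_frame()`.

For a real parameterization campaign, use
`eccwater optimize --evaluator external --workdir run/`: each candidate is
written as `candidate_NNNNNN/params.yaml` plus a GROMACS topology, and the
loop resumes when your simulation pipeline deposits a `results.yaml`
alongside them.

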