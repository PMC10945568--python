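# Methods

## The problem

Nonpolarizable water models used with charge-scaled (electronic continuum
correction, ECC) force fields should exhibit a *nuclear* dielectric constant
ε_N = ε_r/ε_e ≈ 79.2/1.78 ≈ 45; popular four-site models (TIP4P/2005,
TIP4P-FB, OPC) sit at 55–80 and thus overscale ion–ion interactions.
`eccwater` implements the machinery for parameterizing four-site rigid
water models under that constraint: model construction and diagnostics, a
weighted-MAPE cost against experimental targets, and a simulation-budget-
aware search loop (random walk → differential evolution with a neural
surrogate gate → surrogate-guided refinement). Property evaluation by MD
is out of scope; the package either talks to an external evaluator through
a file-exchange directory or uses a built-in synthetic evaluator.

## Model definition and moments

A model is six scalars: σ, ε (Lennard-Jones on oxygen), q_H (hydrogen
charge; the M-site carries −2 q_H structurally, so neutrality cannot be
violated), d_OH, d_OM, and the H–O–H angle θ. Geometries are built in a
canonical frame (O at origin, bisector along +z, hydrogens in the
xz-plane), which makes the moments bit-reproducible:

- dipole μ = |Σ q_i r_i|, equal to 2 q_H (d_OH cos(θ/2) − d_OM) in e·nm;
- tetrahedral quadrupole Q_T = (Q_xx − Q_yy)/2 of the traceless tensor
  Q_ab = ½ Σ q_i (3 r_a r_b − r²δ_ab), equal to (3/2) q_H (d_OH sin(θ/2))².

The implementation evaluates the full tensor; the closed forms serve as an
independent oracle in the tests (equivalence to 1e-10 relative on random
models). Q_T under this convention reproduces the published values of all
four bundled presets to better than ±0.001 D·Å, which is what fixes the
convention choice; likewise μ to ±0.001 D. Unit conversions use a single
constant, 1 e·nm = 48.032047 D, derived from the CODATA elementary charge
and the debye definition. The residual ~1.2e-4 D offset against the
published table is consistent with that table having used a slightly
smaller (unstated) conversion constant; it is far inside every tolerance
used here.

Validation is strict on the optimizer path (out-of-bounds → error) but
relaxed to a warning for standalone moment/topology calculations, because
two of the bundled published models (TIP4P-FB's d_OM, OPC4's d_OH) fall
outside the search box.

## Targets and cost

The default reference set holds: the density isobar at 1 bar on a 260–360 K
grid (six points, 20 K spacing; handbook values shipped as clearly labeled
literature defaults, overridable), ε_r = 44.5 (the ECC-reduced nuclear
value), D_OW = 2.16×10⁻⁵ cm²/s (experimental self-diffusion at 300 K minus
the Yeh–Hummer finite-size correction ξ k_B T/(6πηL), ξ = 2.837297, for an
832-molecule cubic box), and the first O–O RDF peak position (0.280 nm) and
height (2.58). The RDF descriptor extractor takes the *first* local maximum
above g = 1 and refines its position with a three-point parabola, giving
sub-grid accuracy on smooth peaks.

Each property contributes a loss f_i = MAPE_i(%)/10 — so a uniform 10%
error costs exactly 1 — and the cost is Σ w_i f_i with weights
(0.667, 0.111, 0.111, 0.0555, 0.0555) renormalized to sum to 1 over the
included set. `C_ECC` includes ε_r; `C_G` excludes it (for comparing
models with very different dielectric constants). The /10 scaling is fixed
by requiring the published C_G values of all four reference models to be
reproduced (they are, within ±0.002, the rounding of the printed inputs).
The density isobar is a single MAPE over its six grid points, matching its
single weight. Comparisons are strict: ties keep the incumbent.

## Surrogate (mapper)

A fully connected MLP maps the six normalized parameters to the scalar
cost: four ReLU hidden layers of 40 nodes, dropout 0.10 after each hidden
layer (training only), per-unit max-norm 5.0 on hidden weight matrices,
linear output, early stopping on a 20% validation split with patience 50
and best-weights restoration. Hyperparameters not fixed by the
architecture — Adam at 1e-3, batch 64, epoch cap 150 — are exposed in
`MapperConfig`. The network is implemented directly on numpy: it is a few
thousand weights, is retrained dozens of times per run, and must be
bit-reproducible under a seed; no installed framework provides dropout and
max-norm together.

Two numerical choices matter:

- **Log-cost targets.** The net fits log(cost + 1e-3), exponentiated at
  prediction time. Costs span three orders of magnitude across the box and
  the gate needs *relative* accuracy near the minimum; a raw-MSE fit has
  absolute errors of a few tenths there, which (measured on planted
  landscapes) falsely rejects over half of the genuinely good candidates,
  while the log fit rejects none.
- **Minimum data rule.** Below 20 observations training refuses and
  returns a pass-through surrogate whose gate never skips, so a cold-start
  loop degenerates to plain optimization.

`should_skip` is the pure gate: skip iff predicted cost > threshold;
pass-through never skips.

## Search loop

Phase 1 — *random walk*: reflected uniform steps of ±2% of each parameter
range per coordinate, started from the seeding point; every visited point
is evaluated and feeds the population (capacity 96, admission only on
strict improvement over the worst member once full). The previous
evaluation is handed to the evaluator as a warm start (a real MD evaluator
can use it as the starting configuration; the toy evaluator ignores it).

Phase 2 — *differential evolution*: mutation x_a + F(x_b − x_c) with
a, b, c distinct members of the elite (best 25%), F = 0.7 dithered
uniformly by ±0.25; binomial crossover at CR = 0.7 against a member of the
better half of the population; clipping to the unit cube. These constants
were tuned on the package's own recovery experiment (planted-optimum
landscape, 2000-proposal budget, seed grids of 20–40): higher CR or a
smaller population collapse the difference vectors prematurely in 15–25%
of runs, while the shipped settings recovered the optimum in 40/40 seeds.
Drawing the crossover partner from the better half (not the whole
population) matters specifically under gating, where the unrefreshed tail
otherwise keeps proposals wide indefinitely.

The gate, when enabled, predicts each DE candidate's cost and skips its
evaluation if the prediction exceeds the working bar
max(threshold, 1.75 × current best cost). The absolute threshold (default
0.7, the "acceptable quality" band) is the floor; the adaptive term exists
because a *correct* surrogate otherwise walls off the approach path — at
the start of the DE phase nothing is below 0.7 yet, so skipping everything
predicted above it starves the search (measured: ~90% skips and no
convergence). Ten percent of gate-rejected candidates are evaluated
anyway; this is the mechanism by which wrongly rejected regions get
re-sampled and the surrogate corrected. The surrogate is retrained after
every 25 new evaluations, and additionally after 150 proposals if at least
one new evaluation arrived, so skip-heavy stretches cannot freeze a bad
fit in place. Evaluator exceptions mark the candidate failed and the loop
continues.

Phase 3 — *refinement*: multi-start coordinate-wise line search on the
surrogate (starts at elite members; 33-point grids over [0,1], then two
zoomed passes shrinking the window ×0.12 per level), each proposal truly
evaluated. The run stops at the proposal budget or when the best cost has
improved by less than 1% over 500 consecutive *evaluations* (skipped
proposals carry no convergence information, so they do not advance the
clock).

Everything derives from one master seed: proposals, gate exploration, and
per-retraining surrogate seeds, giving bit-identical ledgers on re-runs.

## Synthetic evaluator

The toy evaluator replaces the MD stage with a smooth map whose global
minimum is planted at the bundled ECC-compatible model's parameters
(verified in-bounds): each property equals its reference value times
1 + s_p Σ_j c_j (x_j − x*_j)² in normalized coordinates, optionally with
multiplicative Gaussian noise, so the planted optimum scores exactly zero.
Defaults: c_j = 1 (isotropic; the cost is then 10·Σ∆², placing the
seeding point at cost ≈ 3.7), s_p = 1, noise 0. A `coupled` variant
applies a fixed rotation to the displacement before the quadratic form,
which is only distinguishable from the separable case when the curvature
is anisotropic — tests that stress coupling set an uneven c_j. What the
toy landscape deliberately does not emulate: evaluation noise of finite
trajectories (unless enabled), property-specific nonlinearity, correlated
property responses, and simulation failures — so passing recovery tests
demonstrate the search machinery, not MD realism.

## Scaled-down study sizes

The recovery experiment in the acceptance tests uses 400 random-walk steps
inside a 2000-proposal budget (the same ~20% seeding share as the
full-scale campaign the defaults describe: 1000 RW of ~4500), over ten
seeds, gated and ungated arms. Gate parity is asserted in aggregate over
the seed grid — mean final-cost gap within 0.05 and mean true-evaluation
savings of at least 25% — because near-converged costs are ~1e-6, where
per-seed relative comparisons are meaningless. Measured at the time of
writing: 10/10 ungated recoveries at the 2% per-coordinate tolerance,
mean gap ≈ 0.02, mean savings ≈ 35%.

## Known limitations

- The refinement step cannot polish below the surrogate's accuracy floor;
  its value is insurance, not extra precision, when DE has converged.
- The published C_ECC of the reference ECC model (0.231) requires the
  per-property dielectric MAPE, which is not printed anywhere accessible;
  it is therefore not a reproduction target.
- The density-isobar defaults are literature values, not the exact
  tabulation the original optimization used; users fitting against a
  specific equation of state should supply their own reference YAML.
- The GROMACS writer emits one dialect (settle + type-1 three-body virtual
  site, self-contained atomtypes); exotic topology layouts are not parsed.
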