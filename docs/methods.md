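# Methods

## Model and assumptions

Each brain region is a 2D reduction of the Epileptor neural mass model: a
fast variable `x` (bistable between a quiescent branch and ictal
oscillation) and a slow permittivity variable `z` that drives the
alternation between interictal and ictal states. Regions are coupled
diffusively on the slow timescale through the structural connectome `K`:

    dx_i/dt = -x_i^3 - 2 x_i^2 + 1 - z_i + I
    dz_i/dt = (1/tau) [ 4 (x_i - x0_i) - z_i - sum_j K_ij (x_j - x_i) ]

The system is autonomous and deterministic; there is no stochastic input
(an additive-noise hook exists on request but defaults off). The coupling
sits inside the `1/tau` bracket, consistent with the Jacobian's
`-K_ij/tau` off-diagonal entries.

Key parameters (all dimensionless):

| parameter | default | meaning |
|---|---|---|
| `tau` | 2857 | timescale separation between x and z |
| `I_ext` | 3.1 | passive current setting the operating point |
| `x_c` | −2.1 | critical excitability labelling EZ vs healthy |
| `x0_ez` | −1.6 | excitability assigned to EZ nodes |
| `x0_healthy` | −2.2 | excitability assigned to all other nodes |

A node is epileptogenic iff `x0 > x_c`: the single-node fixed point loses
stability at `x0* = -4/3 + ((-4/3)^3 + 2(-4/3)^2 - (1+I))/4 ≈ -2.0620`
(for `I = 3.1`; the finite-`tau` correction is `O(1/tau)`), so `x0 = -1.6`
yields autonomous relaxation-oscillation seizures while `x0 = -2.2` is a
stable equilibrium. `x_c = -2.1` is retained as the conventional
labelling constant even though the analytic threshold is ≈ −2.062; the
two-level default assignment keeps every node clearly on one side of
both values. Note the healthy equilibrium at `x0 = -2.2` sits only
~0.045 above the fold of its z-nullcline — this small margin is what
makes recruitment possible at all, and calibrates everything below.

## Fixed points and stability analysis

Eliminating `z` via the x-nullcline `z = -x^3 - 2x^2 + 1 + I` reduces the
steady state to `g(x) = 0` with Jacobian `diag(3x^2 + 4x + 4 + s_i) - K`
(`s_i` = row sums of `K`), which is positive definite for every `x`
because `3x^2 + 4x + 4 ≥ 8/3` and `diag(s) - K` is a graph Laplacian.
The solution is therefore unique, and damped Newton started from the
per-node closed roots converges in a handful of iterations (tolerance
1e−12 on the max-norm residual; non-convergence is reported explicitly,
never silently).

The 2N×2N Jacobian at the fixed point is assembled analytically
(x-block `diag(-3x^2-4x)`, cross blocks `-I` and `(diag(4+s)-K)/tau`,
z-block `-I/tau`). Eigenvalues are sorted by descending real part;
`n_positive` counts real parts above `eps_pos = 1e-8` (distinguishing
genuine instability from round-off). Node scores are the moduli of the
leading eigenvector's x-components: the z-components are `O(1/tau)`
suppressed and carry no extra localization information, and the modulus
makes the scores invariant under the eigenvector's arbitrary complex
phase. The predicted PZ is the set of non-EZ nodes with score at least
`eps_loc = 1e-5` on the unit-norm eigenvector (the delocalization scale
of interest); a relative mode (fraction of the maximum non-EZ score) is
provided for matrices whose overall scale differs.

A tangent-space maximum-Lyapunov computation (Benettin-style periodic
renormalization, default interval 50 time units, first 20% of the horizon
discarded as transient) provides an independent localization profile; at
a stable fixed point its exponent reduces to the leading eigenvalue's
real part, which the tests exploit as a cross-check.

## Simulation and event detection

The default integrator is LSODA (adaptive, stiff-capable, tolerances
1e−8/1e−8) — the `tau = 2857` timescale separation makes fixed-step
explicit schemes fragile; a fixed-step RK4 at `dt = 0.05` is provided as
a cross-check mode. The canonical initial condition is the healthy-branch
fixed point of the all-healthy system (EZ entries of `x0` replaced by the
healthy level): from there the EZ drifts into seizure through its own
z-dynamics, which is the scenario of interest.

Seizure events are threshold crossings with hysteresis: onset at an
upward crossing of `theta_on = 0`, offset at a downward crossing of
`theta_off = -1`, events shorter than 5 time units discarded. The healthy
branch satisfies `x < -4/3` while ictal oscillation visits `x > 0`, so
these thresholds separate the states unambiguously regardless of fine
tuning. Default simulation horizon is `10 tau` (several seizure cycles,
whose period is ~0.65 tau).

Containment — the criterion for a successful disconnection — is decided
by simulation, not by the eigenvalue count: after a successful plan the
spectrum still has positive eigenvalues because the EZ itself remains
unstable (it keeps seizing "asymptomatically"); what matters is that no
other node ever crosses threshold. Containment tests integrate over
`3 tau` (more than four EZ seizure cycles) with a terminal event at the
first seizure outside the EZ. The shorter horizon is deliberate:
recruitment, when dynamically possible, occurs within the first one or
two cycles, because a sub-threshold perturbation of a neighbor's
permittivity relaxes back between cycles (linear decay rate ≈ 8/tau
against an inter-seizure interval ≈ 0.65 tau gives a per-cycle decay
factor of ~e^−5, so there is no slow ratchet toward seizure). The
terminal event makes "not contained" verdicts cheap, which is what the
sequential lesioning strategies mostly encounter.

The clinical signal-energy PZ criterion (for multichannel recordings)
band-passes 1–50 Hz with a 4th-order Butterworth filter applied
forward-backward (zero phase, the common SEEG-practice choice), sums
squared samples per channel, and selects non-EZ channels with at least
30% of the maximum energy (inclusive at the boundary).

## Lesion planning

All strategies operate on the candidate set of positive-weight edges
incident to the EZ (the macro-area strategy instead uses edges with
exactly one endpoint in EZ ∪ predicted PZ). Ties are always broken
toward the smaller node index. Sequential strategies test containment
after every removal, including once before the first removal, so a focus
that cannot recruit anything reports zero lesions. The random strategy
runs 5 replicates with child seeds spawned from the master seed and
reports the mean count alongside every per-replicate plan. Plans that
exhaust the `max_lesions` cap (or their candidate set) are returned with
`contained=False` and a cap flag rather than raising.

The LSA strategy recomputes fixed point, Jacobian and leading eigenvector
after every cut, targets the highest-scoring non-EZ node that still has
an EZ link, and severs the heaviest (EZ, target) edge; for multi-node EZs
the heaviest-link rule decides which EZ member's edge is cut. Because the
macro-area candidate set excludes edges internal to EZ ∪ PZ — and the
links that actually transmit recruitment are exactly those internal
EZ–PZ edges — that strategy cannot achieve containment while a true PZ
exists; it then runs to its cap and reports `contained=False`, which is
the informative outcome.

## Graph measures

Degree and clustering (triangle fraction) are computed on the binarized
nonzero adjacency; strength on the weights; efficiency, betweenness and
closeness on shortest paths with the inverse-weight distance `d = 1/w`,
so strong connections are short and short paths mean strong integration
(summing raw weights as "lengths" would invert that reading). Disconnected
pairs contribute zero to efficiency and are excluded from the closeness
average; betweenness uses standard fractional credit for equal-length
paths; a weighted clustering variant is available behind a flag.

## Synthetic connectomes

Patient connectomes are not shipped; two seeded generators stand in.

**Planted scenarios** manufacture an unambiguous ground truth: one EZ
node with `n_strong` strong links (weights 0.7–1.0 before normalization)
to designated PZ nodes, atop a weak background (density 0.3, weights
0.002–0.015). The weak ceiling is a calibrated constant chosen so that
(i) even several simultaneously seizing nodes cannot push a background
node over its ~0.045 permittivity margin, and (ii) background eigenvector
scores (~4e−6) stay an order below the 1e−5 localization threshold while
planted scores (~4e−4) sit well above. The strong/weak separation (≥ 47×)
comfortably exceeds the ≥ 5× construction invariant. Under these
conditions the planted edges are the unique minimal lesion set, verified
by simulation across seeded ensembles.

**Modular connectomes** emulate the statistical structure of
max-normalized track-count matrices: 3 contiguous modules whose
within-module densities are graded over 0.55–1.45× the base
`p_within = 0.65` (cortical subsystems are not equally dense; uniform
densities would make nodal clustering near-constant across nodes),
between-module density `p_between = 0.15` scaled by the geometric mean of
the two modules' density factors (denser subsystems interconnect
preferentially — a rich-club signature that gives hub nodes both high
centrality and many strong links), lognormal weights (`sd = 0.25`)
multiplied by `1 + 0.5 ×` common-neighbor count (the weight–topology
coupling of spatially embedded connectomes: edges inside triangle-rich
neighborhoods tend to be the strong ones). The weight spread matters
dynamically: the single-link recruitment threshold is ~0.3 of the maximum
weight, so a much heavier-tailed distribution leaves (after
max-normalization) essentially no link able to transmit recruitment and
every seizure trivially confined, while a much flatter one recruits
through every link. The defaults place a graded fraction of links on
each side, so lesions-needed varies meaningfully (typically 1–8 at
N = 30) across EZ positions.

What the generators do **not** emulate: spatial embedding and distance-
dependent connection lengths, hemispheric symmetry, subject-level
variability structure, measurement noise of tractography, or any
quantitative fit to real track-count distributions. Passing tests on
these fixtures therefore demonstrate the method's internal correctness
and its behavior on networks with known ground truth — not clinical
validity on patient data.

## Problem sizes and numerical choices

Ensemble checks use 30-node networks: 20 planted scenarios for exact
recovery and PZ prediction, 50 for the strategy ordering, and a full
30-node sweep for the topology correlations — sizes at which the
complete pipeline (hundreds of containment simulations) runs in minutes
while every phenomenon of interest (autonomous seizures, selective
recruitment, strategy separation) is fully expressed. Recruited sets are
measured over a `2 tau` window (≥ 2 EZ seizure cycles). The EZ-sweep cap
is 20 lesions; capped nodes are excluded from correlations and flagged.
Newton tolerance is 1e−12, integration tolerances 1e−8, `eps_pos = 1e−8`,
`eps_loc = 1e−5`. Degenerate inputs are handled explicitly: all-zero
matrices cannot be normalized (error), isolated EZs contain in zero
lesions, empty rasters are valid, zero-variance metrics yield NaN
correlations rather than raising.

## Known limitations

- The 2D reduction omits the fast oscillatory discharges of the full
  Epileptor; rasters carry onset/offset envelopes only.
- Lesion plans are purely topological; no anatomical feasibility or
  surgical constraint is modelled.
- The macro-area strategy follows its strict "outgoing edges only"
  definition and therefore cannot contain when the propagation runs
  through EZ–PZ internal links (reported via the cap flag).
- Directed connectomes are out of scope; asymmetric inputs are
  symmetrized with a warning.
- Multi-node-EZ sweeps are not provided (combinatorial); single-node
  sweeps only.
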