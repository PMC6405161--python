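"""Virtual-resection planning: minimal edge lesions that stop propagation.

Five strategies are compared:

* ``full_disconnection`` -- remove every positive-weight edge incident to
  the EZ, all at once (the network analogue of resecting the EZ).
* ``random`` -- remove EZ-incident edges in seeded random order, one at a
  time, until the seizure no longer propagates; averaged over replicates.
* ``strongest_ez`` -- remove EZ-incident edges in order of descending
  weight until containment.
* ``strongest_macroarea`` -- remove the strongest edges leaving the
  macro-area EZ + predicted PZ until containment.
* ``lsa`` -- linear stability analysis: at each step cut the EZ link to
  the highest-scoring node of the leading Jacobian eigenvector, recompute,
  and stop as soon as simulation shows the seizure stays confined.

Containment is decided by simulation, not by the eigenvalue count: the
EZ's own instability keeps the spectrum positive even after a successful
disconnection (the EZ still seizes, "asymptomatically"), so the criterion
is an empty recruited set over the containment horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .connectome import Connectome, remove_edge
from .epileptor import (
    ExcitabilityMap,
    ModelParams,
    SeizureRaster,
    detect_seizure_events,
    network_fixed_point,
    recruited_set,
    simulate,
)
from .errors import ValidationError
from .stability import (
    EPS_LOC_DEFAULT,
    build_jacobian,
    eigen_analysis,
    predict_pz,
)

STRATEGIES = (
    "full_disconnection",
    "random",
    "strongest_macroarea",
    "strongest_ez",
    "lsa",
)

#: containment-test horizon, in units of tau. Recruitment, when dynamically
#: possible, occurs within the first one or two EZ seizure cycles, because
#: sub-threshold permittivity perturbations relax back between cycles
#: (decay factor ~ e^-5 per cycle); three tau cover more than four cycles.
CONTAINMENT_HORIZON_FACTOR = 3.0


@dataclass(frozen=True)
class LesionPlan:
    """Ordered record of removed edges under one strategy.

    ``per_step`` holds (number of positive eigenvalues, predicted-PZ size)
    after each removal. For the random strategy the returned plan is the
    first replicate; ``replicate_plans`` carries all replicates and
    ``mean_n_lesions`` their average count.
    """

    strategy: str
    removed_edges: tuple[tuple[int, int, float], ...]
    n_lesions: int
    contained: bool
    per_step: tuple[tuple[int, int], ...] = ()
    capped: bool = False
    seed: int | None = None
    replicate_plans: tuple["LesionPlan", ...] | None = None
    mean_n_lesions: float | None = None

    @property
    def effective_n_lesions(self) -> float:
        """Replicate-mean count for random plans, plain count otherwise."""
        return self.mean_n_lesions if self.mean_n_lesions is not None else float(self.n_lesions)


def containment_test(
    c: Connectome,
    ex: ExcitabilityMap,
    params: ModelParams = ModelParams(),
    horizon: float | None = None,
    theta_on: float = 0.0,
    theta_off: float = -1.0,
    min_duration: float = 5.0,
) -> tuple[bool, SeizureRaster]:
    """Simulate from the healthy reference state and check for recruitment.

    Contained means no node outside the EZ emits a seizure event over the
    horizon (default ``CONTAINMENT_HORIZON_FACTOR * tau``). Integration
    stops at the first seizure outside the EZ, so an uncontained verdict
    is cheap.
    """
    if horizon is None:
        horizon = CONTAINMENT_HORIZON_FACTOR * params.tau
    ez = ex.ez
    traj = simulate(
        c,
        ex,
        params,
        horizon=horizon,
        stop_on_seizure_outside=ez,
        theta_on=theta_on,
        grace=4.0 * min_duration,
    )
    raster = detect_seizure_events(traj, theta_on, theta_off, min_duration)
    contained = len(recruited_set(raster, ez).nodes) == 0
    return contained, raster


def ez_incident_edges(c: Connectome, ez: Iterable[int]) -> list[tuple[int, int, float]]:
    """Positive-weight edges incident to the EZ, as (i, j, weight), i < j."""
    ez = set(int(v) for v in ez)
    edges = []
    for i in range(c.n):
        for j in range(i + 1, c.n):
            if c.weights[i, j] > 0 and (i in ez or j in ez):
                edges.append((i, j, float(c.weights[i, j])))
    return edges


def macroarea_outgoing_edges(
    c: Connectome, macroarea: Iterable[int]
) -> list[tuple[int, int, float]]:
    """Positive-weight edges with exactly one endpoint in the macro-area."""
    area = set(int(v) for v in macroarea)
    edges = []
    for i in range(c.n):
        for j in range(i + 1, c.n):
            if c.weights[i, j] > 0 and ((i in area) != (j in area)):
                edges.append((i, j, float(c.weights[i, j])))
    return edges


def _analyze(c, ex, params, eps_loc):
    fp = network_fixed_point(c, ex, params)
    report = eigen_analysis(build_jacobian(c, fp, params))
    pz = predict_pz(report, ex.ez, eps_loc)
    return report, pz


def _sequential_removal(
    c: Connectome,
    ex: ExcitabilityMap,
    params: ModelParams,
    ordered_edges: Sequence[tuple[int, int, float]],
    strategy: str,
    max_lesions: int,
    horizon: float | None,
    eps_loc: float,
    seed: int | None = None,
) -> LesionPlan:
    """Remove edges in the given order, testing containment after each."""
    work = c
    removed: list[tuple[int, int, float]] = []
    per_step: list[tuple[int, int]] = []
    contained, _ = containment_test(work, ex, params, horizon)
    if contained or not ordered_edges:
        return LesionPlan(strategy, (), 0, contained, (), capped=not contained, seed=seed)
    for i, j, w in ordered_edges:
        if len(removed) >= max_lesions:
            return LesionPlan(
                strategy, tuple(removed), len(removed), False, tuple(per_step),
                capped=True, seed=seed,
            )
        work = remove_edge(work, i, j)
        removed.append((i, j, w))
        report, pz = _analyze(work, ex, params, eps_loc)
        per_step.append((report.n_positive, len(pz)))
        contained, _ = containment_test(work, ex, params, horizon)
        if contained:
            return LesionPlan(
                strategy, tuple(removed), len(removed), True, tuple(per_step), seed=seed
            )
    return LesionPlan(
        strategy, tuple(removed), len(removed), False, tuple(per_step),
        capped=True, seed=seed,
    )


def plan_lesions(
    c: Connectome,
    ex: ExcitabilityMap,
    params: ModelParams = ModelParams(),
    strategy: str = "lsa",
    max_lesions: int = 100,
    seed: int | None = None,
    replicates: int = 5,
    horizon: float | None = None,
    eps_loc: float = EPS_LOC_DEFAULT,
    check_every: int = 1,
) -> LesionPlan:
    """Compute a lesion plan under the named strategy.

    Ties are always broken toward the smaller node index, so plans are
    reproducible. ``max_lesions`` caps every sequential strategy; a capped
    plan is returned with ``contained=False`` rather than raising.
    """
    if strategy not in STRATEGIES:
        raise ValidationError(
            f"unknown strategy {strategy!r}; choose from {STRATEGIES}"
        )
    ez = ex.ez
    if not ez:
        raise ValidationError("EZ is empty: no excitability above critical")

    if strategy == "full_disconnection":
        edges = ez_incident_edges(c, ez)
        work = c
        for i, j, _ in edges:
            work = remove_edge(work, i, j)
        report, pz = _analyze(work, ex, params, eps_loc)
        contained, _ = containment_test(work, ex, params, horizon)
        return LesionPlan(
            strategy,
            tuple(edges),
            len(edges),
            contained,
            ((report.n_positive, len(pz)),),
        )

    if strategy == "random":
        if seed is None:
            raise ValidationError("random strategy requires a seed")
        edges = ez_incident_edges(c, ez)
        child_seeds = np.random.SeedSequence(seed).generate_state(replicates)
        plans = []
        for rep, child in enumerate(child_seeds):
            rng = np.random.default_rng(child)
            order = [edges[k] for k in rng.permutation(len(edges))]
            plans.append(
                _sequential_removal(
                    c, ex, params, order, strategy, max_lesions, horizon,
                    eps_loc, seed=int(child),
                )
            )
        mean_count = float(np.mean([p.n_lesions for p in plans]))
        return replace(
            plans[0],
            seed=seed,
            replicate_plans=tuple(plans),
            mean_n_lesions=mean_count,
        )

    if strategy == "strongest_ez":
        edges = sorted(ez_incident_edges(c, ez), key=lambda e: (-e[2], e[0], e[1]))
        return _sequential_removal(
            c, ex, params, edges, strategy, max_lesions, horizon, eps_loc
        )

    if strategy == "strongest_macroarea":
        _, pz0 = _analyze(c, ex, params, eps_loc)
        area = set(ez) | set(pz0)
        edges = sorted(
            macroarea_outgoing_edges(c, area), key=lambda e: (-e[2], e[0], e[1])
        )
        return _sequential_removal(
            c, ex, params, edges, strategy, max_lesions, horizon, eps_loc
        )

    # strategy == "lsa"
    return _plan_lsa(c, ex, params, max_lesions, horizon, eps_loc, check_every)


def _plan_lsa(
    c: Connectome,
    ex: ExcitabilityMap,
    params: ModelParams,
    max_lesions: int,
    horizon: float | None,
    eps_loc: float,
    check_every: int,
) -> LesionPlan:
    """Iterative eigenvector-guided disconnection.

    Each step: recompute the fixed point, Jacobian and leading eigenvector;
    target the highest-scoring non-EZ node that still has a positive-weight
    link to the EZ; among the EZ nodes, cut the heaviest link to the
    target. Containment is simulated whenever the predicted PZ is empty or
    every ``check_every`` steps.
    """
    ez = sorted(ex.ez)
    work = c
    removed: list[tuple[int, int, float]] = []
    per_step: list[tuple[int, int]] = []
    report, pz = _analyze(work, ex, params, eps_loc)
    if not pz:
        # nothing predicted to be recruited; the seizure may already be confined
        contained, _ = containment_test(work, ex, params, horizon)
        if contained:
            return LesionPlan("lsa", (), 0, True, ())
    while len(removed) < max_lesions:
        candidates = [
            t
            for t in range(work.n)
            if t not in ex.ez and work.weights[np.array(ez), t].max() > 0
        ]
        if not candidates:
            contained, _ = containment_test(work, ex, params, horizon)
            return LesionPlan(
                "lsa", tuple(removed), len(removed), contained, tuple(per_step),
                capped=not contained,
            )
        target = max(candidates, key=lambda t: (report.node_scores[t], -t))
        e = max(ez, key=lambda v: (work.weights[v, target], -v))
        w = float(work.weights[e, target])
        work = remove_edge(work, e, target)
        removed.append((min(e, target), max(e, target), w))
        report, pz = _analyze(work, ex, params, eps_loc)
        per_step.append((report.n_positive, len(pz)))
        if not pz or (len(removed) % check_every == 0):
            contained, _ = containment_test(work, ex, params, horizon)
            if contained:
                return LesionPlan(
                    "lsa", tuple(removed), len(removed), True, tuple(per_step)
                )
    contained, _ = containment_test(work, ex, params, horizon)
    return LesionPlan(
        "lsa", tuple(removed), len(removed), contained, tuple(per_step),
        capped=not contained,
    )


def apply_plan(c: Connectome, plan: LesionPlan) -> Connectome:
    """Replay a plan's removals on a fresh copy of the connectome."""
    work = c
    for i, j, _ in plan.removed_edges:
        work = remove_edge(work, i, j)
    return work


def compare_strategies(
    c: Connectome,
    ex: ExcitabilityMap,
    params: ModelParams = ModelParams(),
    strategies: Sequence[str] = STRATEGIES,
    seed: int = 0,
    max_lesions: int = 100,
    replicates: int = 5,
    horizon: float | None = None,
    eps_loc: float = EPS_LOC_DEFAULT,
) -> pd.DataFrame:
    """One row per strategy: lesion count (mean over replicates for random)
    and whether the plan achieved containment. Deterministic given seed."""
    if not strategies:
        raise ValidationError("need at least one strategy")
    rows = []
    for k, strategy in enumerate(strategies):
        plan = plan_lesions(
            c, ex, params, strategy,
            max_lesions=max_lesions,
            seed=seed + k if strategy == "random" else None,
            replicates=replicates,
            horizon=horizon,
            eps_loc=eps_loc,
        )
        rows.append(
            {
                "strategy": strategy,
                "n_lesions": plan.effective_n_lesions,
                "contained": plan.contained,
            }
        )
    return pd.DataFrame(rows)
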