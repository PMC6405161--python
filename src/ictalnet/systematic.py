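"""Systematic epileptogenic-zone sweep and graph-metric correlations.

Placing the EZ at every node in turn, computing a lesion plan for each
position, and correlating the number of lesions needed with the EZ node's
graph measures reveals how network topology shapes the difficulty of
containing propagation: nodes embedded in dense, high-clustering,
high-efficiency neighborhoods need more disconnections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import Connectome
from .epileptor import ExcitabilityMap, ModelParams, X0_EZ_DEFAULT, X0_HEALTHY_DEFAULT
from .errors import IctalnetError, ValidationError
from .lesioning import LesionPlan, plan_lesions
from .metrics import METRIC_NAMES
from .stability import EPS_LOC_DEFAULT


@dataclass(frozen=True)
class SweepResult:
    """Per-candidate-EZ lesion counts and per-step predicted-PZ sizes.

    ``pz_size_map[i, k]`` is the predicted-PZ size after lesion step k+1
    with the EZ at node i; rows shorter than ``max_lesions`` are padded
    with their final value. ``capped[i]`` flags nodes whose plan hit the
    cap without containment; ``failures`` maps node -> error message for
    nodes where planning raised.
    """

    lesions_needed: np.ndarray  # (N,) int
    pz_size_map: np.ndarray  # (N, max_lesions) int
    capped: np.ndarray  # (N,) bool
    max_lesions: int
    strategy: str
    failures: dict[int, str]
    plans: tuple[LesionPlan | None, ...] = ()


def ez_sweep(
    c: Connectome,
    params: ModelParams = ModelParams(),
    x0_ez: float = X0_EZ_DEFAULT,
    x0_healthy: float = X0_HEALTHY_DEFAULT,
    strategy: str = "lsa",
    max_lesions: int = 20,
    seed: int = 0,
    horizon: float | None = None,
    eps_loc: float = EPS_LOC_DEFAULT,
) -> SweepResult:
    """Plan lesions with the EZ placed at each node in turn.

    Per-node failures are recorded and the sweep continues; results do not
    depend on the order in which nodes are visited.
    """
    if max_lesions < 1:
        raise ValidationError("max_lesions cap must be at least 1")
    n = c.n
    lesions = np.zeros(n, dtype=int)
    pz_map = np.zeros((n, max_lesions), dtype=int)
    capped = np.zeros(n, dtype=bool)
    failures: dict[int, str] = {}
    plans: list[LesionPlan | None] = []
    for node in range(n):
        ex = ExcitabilityMap.from_ez(n, [node], x0_ez, x0_healthy, params.x_c)
        try:
            plan = plan_lesions(
                c, ex, params, strategy,
                max_lesions=max_lesions,
                seed=seed + node if strategy == "random" else None,
                horizon=horizon,
                eps_loc=eps_loc,
            )
        except IctalnetError as exc:
            failures[node] = str(exc)
            capped[node] = True
            plans.append(None)
            continue
        plans.append(plan)
        lesions[node] = plan.n_lesions
        capped[node] = not plan.contained
        sizes = [pz for _, pz in plan.per_step]
        if sizes:
            padded = sizes + [sizes[-1]] * (max_lesions - len(sizes))
        else:
            padded = [0] * max_lesions
        pz_map[node] = padded[:max_lesions]
    return SweepResult(
        lesions, pz_map, capped, max_lesions, strategy, failures, tuple(plans)
    )


def metric_lesion_correlation(
    sweep: SweepResult, metrics: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of lesions-needed against each nodal metric.

    Capped and failed nodes are excluded. A zero-variance metric yields an
    undefined correlation, reported as NaN rather than raising.
    """
    if len(metrics) != len(sweep.lesions_needed):
        raise ValidationError("metrics table size does not match sweep size")
    ok = ~sweep.capped
    if ok.sum() < 3:
        raise ValidationError(
            f"need at least 3 uncapped EZ nodes for correlations, got {int(ok.sum())}"
        )
    y = sweep.lesions_needed[ok].astype(float)
    rows = []
    for name in METRIC_NAMES:
        x = metrics[name].to_numpy()[ok]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"metric": name, "r": np.nan, "p": np.nan})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"metric": name, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
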