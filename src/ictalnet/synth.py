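"""Synthetic connectome generators.

Real DTI track-count matrices are symmetric, non-negative, zero-diagonal,
heavy-tailed in their nonzero weights, and organized into communities with
strong weight-topology coupling (edges embedded in many triangles tend to
be the strong ones, a signature of the brain's spatial embedding). The
modular generator emulates these features. The planted generator instead
manufactures an unambiguous ground truth -- one epileptogenic node with a
few strong links to designated propagation-zone nodes, everything else so
weakly coupled that recruitment can only travel the planted links -- for
end-to-end validation of propagation-zone prediction and lesion planning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome, normalize
from .errors import ValidationError

# --- planted-scenario calibration constants -------------------------------
# Strong (planted) weights are drawn from [STRONG_LOW, STRONG_HIGH]; the
# background from [WEAK_LOW, WEAK_HIGH]. The weak ceiling is calibrated so
# that (i) weak links sit below the dynamic recruitment threshold of the
# default Epileptor parameters even when several seizing nodes push the
# same target at once, and (ii) their leading-eigenvector components stay
# below the 1e-5 localization threshold. A healthy node (x0 = -2.2) rests
# only ~0.045 above the fold of its z-nullcline, so the ceiling must be
# small; 0.015 (pre-normalization) leaves a safety factor of ~2 in both
# respects while keeping the required >= 5x strong/weak separation at ~47x.
STRONG_LOW = 0.7
STRONG_HIGH = 1.0
WEAK_LOW = 0.002
WEAK_HIGH = 0.015
BACKGROUND_DENSITY = 0.3


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the modular generator.

    p_within / p_between are edge probabilities inside / between modules;
    nonzero weights are lognormal (heavy-tailed, mimicking track counts).
    overlap_coupling multiplies each weight by (1 + coupling * common
    neighbors), reproducing the weight-topology coupling of tractography
    connectomes; set it to 0 for plain independent lognormal weights.
    """

    n_nodes: int = 30
    n_modules: int = 3
    p_within: float = 0.65
    p_between: float = 0.15
    weight_log_mean: float = 0.0
    weight_log_sd: float = 0.25
    seed: int = 0
    overlap_coupling: float = 0.5

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValidationError("n_nodes must be at least 2")
        if self.n_modules < 1:
            raise ValidationError("n_modules must be at least 1")
        if not (0.0 <= self.p_between <= self.p_within <= 1.0):
            raise ValidationError(
                "edge probabilities must satisfy 0 <= p_between <= p_within <= 1"
            )
        if self.weight_log_sd < 0:
            raise ValidationError("weight_log_sd must be non-negative")
        if self.overlap_coupling < 0:
            raise ValidationError("overlap_coupling must be non-negative")


def module_assignment(n_nodes: int, n_modules: int) -> np.ndarray:
    """Contiguous near-equal module membership for each node."""
    return np.repeat(
        np.arange(n_modules),
        np.diff(np.linspace(0, n_nodes, n_modules + 1).astype(int)),
    )


#: spread of per-module densities around p_within (dimensionless factors).
#: Cortical subsystems are not equally dense; grading the modules creates
#: genuine node-to-node variance in clustering and degree, as in real
#: parcellated connectomes, instead of every node seeing the same density.
DENSITY_GRADIENT_RANGE = (0.55, 1.45)


def generate_modular(params: SynthParams) -> Connectome:
    """Seeded modular connectome with heavy-tailed, max-normalized weights."""
    rng = np.random.default_rng(params.seed)
    n = params.n_nodes
    modules = module_assignment(n, params.n_modules)
    same = modules[:, None] == modules[None, :]
    if params.n_modules > 1:
        gradient = np.linspace(*DENSITY_GRADIENT_RANGE, params.n_modules)
    else:
        gradient = np.ones(1)
    p_module = np.clip(params.p_within * gradient, 0.0, 1.0)
    # within-module pairs use their module's graded density; between-module
    # pairs scale with the geometric mean of the two density factors
    # (denser subsystems interconnect preferentially, a rich-club signature)
    f = gradient[modules]
    p_bridge = np.clip(params.p_between * np.sqrt(f[:, None] * f[None, :]), 0.0, 1.0)
    p = np.where(same, p_module[modules][:, None], p_bridge)
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    adj = np.zeros((n, n), dtype=bool)
    adj[upper] = rng.random(upper.sum()) < p[upper]
    weights = np.zeros((n, n))
    weights[upper] = np.where(
        adj[upper],
        rng.lognormal(params.weight_log_mean, params.weight_log_sd, upper.sum()),
        0.0,
    )
    adj = adj | adj.T
    weights = weights + weights.T
    if params.overlap_coupling > 0:
        a = adj.astype(float)
        common = a @ a  # common-neighbor counts
        weights = weights * (1.0 + params.overlap_coupling * common)
    np.fill_diagonal(weights, 0.0)
    return normalize(Connectome(weights))


@dataclass(frozen=True)
class PlantedScenario:
    """Ground-truth propagation scenario.

    One EZ node with ``n_strong`` strong links to the planted propagation
    zone; every other edge is too weak to transmit recruitment. The planted
    edges are the unique minimal lesion set.
    """

    connectome: Connectome
    ez: frozenset[int]
    planted_pz: frozenset[int]
    planted_edges: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.ez & self.planted_pz:
            raise ValidationError("EZ and planted PZ must be disjoint")
        w = self.connectome.weights
        ez_node = next(iter(self.ez))
        planted_w = min(w[i, j] for i, j in self.planted_edges)
        others = [
            w[ez_node, j]
            for j in range(self.connectome.n)
            if j not in self.planted_pz and j != ez_node and w[ez_node, j] > 0
        ]
        if others and planted_w < 5.0 * max(others):
            raise ValidationError(
                "planted edges are not separated >= 5x from other EZ-incident weights"
            )

    @property
    def ez_node(self) -> int:
        return next(iter(self.ez))


def generate_planted(
    n_nodes: int,
    n_strong: int,
    seed: int,
    background_density: float = BACKGROUND_DENSITY,
) -> PlantedScenario:
    """Seeded planted-propagation scenario with known ground truth."""
    if n_nodes < 3:
        raise ValidationError("planted scenarios need at least 3 nodes")
    if not (1 <= n_strong <= n_nodes - 2):
        raise ValidationError(
            f"n_strong={n_strong} must lie in [1, n_nodes - 2] = [1, {n_nodes - 2}]"
        )
    rng = np.random.default_rng(seed)
    nodes = rng.permutation(n_nodes)
    ez = int(nodes[0])
    pz = [int(v) for v in nodes[1 : 1 + n_strong]]
    w = np.zeros((n_nodes, n_nodes))
    # weak background everywhere (including EZ's non-planted links)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < background_density:
                w[i, j] = w[j, i] = rng.uniform(WEAK_LOW, WEAK_HIGH)
    # planted strong links overwrite whatever the background drew
    strong = rng.uniform(STRONG_LOW, STRONG_HIGH, n_strong)
    for weight, j in zip(strong, pz):
        w[ez, j] = w[j, ez] = weight
    c = normalize(Connectome(w))
    order = np.argsort(-c.weights[ez, pz], kind="stable")
    edges = tuple((ez, pz[k]) for k in order)
    return PlantedScenario(
        connectome=c,
        ez=frozenset({ez}),
        planted_pz=frozenset(pz),
        planted_edges=edges,
    )
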