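"""Linear-Gaussian DAG simulator with source/intermediate/sink node roles.

The generator draws a ground-truth DAG on a randomly chosen connected subset
of the p variables and fills the remaining p0 variables with independent
noise.  Connected nodes are ordered with sources first and sinks last; each
non-source connected node draws 1..max_parents parents uniformly from the
nodes above it in that ordering, which guarantees acyclicity.  Data are then
generated in topological order by linear regression on the parents plus
homoscedastic Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CONTINUOUS, DataMatrix, from_array

ROLE_INDEPENDENT = "independent"
ROLE_SOURCE = "source"
ROLE_INTERMEDIATE = "intermediate"
ROLE_SINK = "sink"


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated study.

    N: samples; p: variables; p0/p1/p2/p3: counts of independent, source,
    intermediate and sink nodes (p0+p1+p2+p3 == p); beta_range: absolute
    effect-size range for edge coefficients (sign is random); noise_sd:
    residual standard deviation of every child node; max_parents: upper
    bound on parents drawn per non-source connected node.
    """

    N: int
    p: int
    p0: int
    p1: int
    p2: int
    p3: int
    beta_range: tuple[float, float] = (0.5, 1.5)
    noise_sd: float = 1.0
    max_parents: int = 2
    seed: int | None = None

    def __post_init__(self):
        if self.p0 + self.p1 + self.p2 + self.p3 != self.p:
            raise ValueError("p0 + p1 + p2 + p3 must equal p")
        if min(self.p0, self.p1, self.p2, self.p3) < 0:
            raise ValueError("role counts must be nonnegative")
        if self.p1 == 0 and self.p2 + self.p3 > 0:
            raise ValueError(
                "p1 = 0 with dependent nodes present: no possible ancestors"
            )
        lo, hi = self.beta_range
        if not (0 < lo <= hi):
            raise ValueError("beta_range must satisfy 0 < min <= max")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.max_parents < 1 and self.p2 + self.p3 > 0:
            raise ValueError("max_parents must be >= 1")


@dataclass
class TrueNetwork:
    """Ground-truth DAG: parent sets, edge coefficients and node roles."""

    nodes: list[str]
    parent_map: dict[str, set[str]]
    coeffs: dict[tuple[str, str], float]
    roles: dict[str, str]
    order: tuple[str, ...] = ()  # generating ordering of connected nodes

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Directed edges as (parent, child) pairs."""
        return {(u, v) for v, ps in self.parent_map.items() for u in ps}


def default_roles(p: int) -> tuple[int, int, int, int]:
    """Role counts (p0, p1, p2, p3) used by the simulation-grid harness.

    A three-generation pathway (equal numbers of sources, intermediates and
    sinks, each max(2, p // 10)) embedded among otherwise independent
    variables — the sparse-signal regime the partial-orderings search
    targets.
    """
    k = max(2, p // 10)
    if 3 * k > p:
        k = p // 3
    return p - 3 * k, k, k, k


def simulate_dag(spec: SimulationSpec, rng: np.random.Generator | None = None) -> TrueNetwork:
    """Draw a random ground-truth DAG according to ``spec``."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    names = [f"v{i + 1}" for i in range(spec.p)]
    n_conn = spec.p1 + spec.p2 + spec.p3
    connected = list(rng.choice(spec.p, size=n_conn, replace=False)) if n_conn else []

    # sources first, sinks last; roles interleave only within their block
    sources = connected[: spec.p1]
    intermediates = connected[spec.p1 : spec.p1 + spec.p2]
    sinks = connected[spec.p1 + spec.p2 :]
    ordering = (
        list(rng.permutation(sources).astype(int))
        + list(rng.permutation(intermediates).astype(int))
        + list(rng.permutation(sinks).astype(int))
    )

    roles = {n: ROLE_INDEPENDENT for n in names}
    for i in sources:
        roles[names[i]] = ROLE_SOURCE
    for i in intermediates:
        roles[names[i]] = ROLE_INTERMEDIATE
    for i in sinks:
        roles[names[i]] = ROLE_SINK

    parent_map: dict[str, set[str]] = {n: set() for n in names}
    coeffs: dict[tuple[str, str], float] = {}
    lo, hi = spec.beta_range
    for pos in range(spec.p1, len(ordering)):
        child = names[ordering[pos]]
        # parents come from above in the ordering, excluding the sink block
        # (sinks must remain childless)
        above = [names[j] for j in ordering[: min(pos, spec.p1 + spec.p2)]]
        k = int(rng.integers(1, spec.max_parents + 1))
        k = min(k, len(above))
        parents = rng.choice(len(above), size=k, replace=False)
        for j in parents:
            parent = above[int(j)]
            parent_map[child].add(parent)
            beta = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
            coeffs[(parent, child)] = beta

    # sinks must have no children: guaranteed because sinks occupy the last
    # block of the ordering and parents are drawn strictly from above
    return TrueNetwork(
        nodes=names,
        parent_map=parent_map,
        coeffs=coeffs,
        roles=roles,
        order=tuple(names[i] for i in ordering),
    )


def simulate_data(
    net: TrueNetwork, spec: SimulationSpec, rng: np.random.Generator | None = None
) -> DataMatrix:
    """Generate an N x p continuous data matrix from the true DAG.

    Roots (sources and independent nodes) are standard normal; each child is
    the coefficient-weighted sum of its parents plus N(0, noise_sd) noise.
    """
    if spec.N < 2:
        raise ValueError("N must be >= 2")
    if rng is None:
        rng = np.random.default_rng(
            spec.seed + 1 if spec.seed is not None else None
        )
    idx = {n: i for i, n in enumerate(net.nodes)}
    X = np.empty((spec.N, spec.p))
    topo = [n for n in net.nodes if not net.parent_map[n]]
    topo += [n for n in net.order if net.parent_map[n]]
    for n in topo:
        parents = net.parent_map[n]
        if not parents:
            X[:, idx[n]] = rng.standard_normal(spec.N)
        else:
            mean = np.zeros(spec.N)
            for u in sorted(parents):
                mean += net.coeffs[(u, n)] * X[:, idx[u]]
            X[:, idx[n]] = mean + spec.noise_sd * rng.standard_normal(spec.N)
    return from_array(X, names=net.nodes)


def simulate(spec: SimulationSpec) -> tuple[TrueNetwork, DataMatrix]:
    """Draw (truth DAG, data matrix) from a single seeded RNG stream."""
    rng = np.random.default_rng(spec.seed)
    net = simulate_dag(spec, rng=rng)
    dat = simulate_data(net, spec, rng=rng)
    return net, dat
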