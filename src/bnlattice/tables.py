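"""Local-score enumeration and best-parents / best-score tables.

Parent subsets are encoded as bitmasks over feasible-set positions
(0-based, original column order).  The local table holds localscore(v, S)
for every S subseteq pp_v with |S| <= indegree; each entry is computed by
the scoring module exactly once.  bestScore(v, U) / bestParents(v, U) — the
best local score attainable with parents drawn from a pool U — are exposed
two equivalent ways: an eager table filled by the downward recurrence
bestScore(v, U) = max(local(v, U), max_u bestScore(v, U \\ {u})) over all
pools U subseteq pp_v, and a lazy memoized bounded enumeration used by the
search (feasible even when pp_v is large).  Argmax ties prefer the smaller
cardinality, then the lexicographically smallest subset in feasible-set
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

from .candidates import CandidateSets
from .data import DataMatrix
from .scoring import NEG_INF, make_scorer


def mask_of(positions) -> int:
    m = 0
    for p in positions:
        m |= 1 << p
    return m


def positions_of(mask: int) -> tuple[int, ...]:
    out = []
    i = 0
    while mask:
        if mask & 1:
            out.append(i)
        mask >>= 1
        i += 1
    return tuple(out)


@dataclass
class ScoreTables:
    """Score tables over the feasible set.

    ``local`` maps (node position, parent-subset mask) to the local score;
    ``indegree`` is the per-node parent cap (None = uncapped, used only by
    the search-space instrumentation).
    """

    nodes: list[str]
    pp_masks: list[int]
    indegree: int | None
    local: dict[tuple[int, int], float] = field(default_factory=dict)
    best_table: dict[tuple[int, int], tuple[float, int]] = field(default_factory=dict)
    _memo: dict[tuple[int, int], tuple[float, int]] = field(default_factory=dict)

    def __post_init__(self):
        self.index = {v: i for i, v in enumerate(self.nodes)}

    @property
    def p_bar(self) -> int:
        return len(self.nodes)

    def _subset_masks(self, pool: tuple[int, ...]):
        """Subsets of ``pool`` up to the indegree cap, in canonical order:
        cardinality ascending, then lexicographic by sorted positions."""
        cap = len(pool) if self.indegree is None else min(self.indegree, len(pool))
        for k in range(cap + 1):
            for combo in combinations(pool, k):
                yield mask_of(combo)

    def n_parent_subsets(self, pool_size: int) -> int:
        """How many parent subsets are enumerated for a pool of this size."""
        if self.indegree is None:
            return 1 << pool_size
        return sum(comb(pool_size, k) for k in range(min(self.indegree, pool_size) + 1))

    def best(self, v: int, pool_mask: int) -> tuple[float, int]:
        """(bestScore, bestParents mask) for node v with parents from pool.

        Lazy route: direct enumeration of admissible subsets of the pool,
        memoized per (node, pool).  Ties keep the first subset in canonical
        order (smaller cardinality, then lexicographic).
        """
        pool_mask &= self.pp_masks[v]
        key = (v, pool_mask)
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        pool = positions_of(pool_mask)
        best_score, best_mask = NEG_INF, 0
        for m in self._subset_masks(pool):
            s = self.local[(v, m)]
            if s > best_score:
                best_score, best_mask = s, m
        self._memo[key] = (best_score, best_mask)
        return best_score, best_mask


def enumerate_local_scores(
    data: DataMatrix | None,
    cands: CandidateSets,
    indegree: int | None = 2,
    method: str = "bic",
    score_fn=None,
) -> ScoreTables:
    """Fill the local table for every node and every subset of its possible
    parents up to cardinality ``indegree`` (the empty set included).

    ``score_fn(node_name, parent_names) -> float`` may be supplied directly
    (tests and instrumentation); otherwise it is built from the data.
    """
    if indegree is not None and indegree < 0:
        raise ValueError("indegree must be >= 0")
    nodes = list(cands.feas_set)
    index = {v: i for i, v in enumerate(nodes)}
    pp_masks = [mask_of(index[u] for u in cands.pp.get(v, set())) for v in nodes]
    if score_fn is None:
        if data is None:
            raise ValueError("either data or score_fn is required")
        score_fn = make_scorer(data, method)
    tables = ScoreTables(nodes=nodes, pp_masks=pp_masks, indegree=indegree)
    for vi, v in enumerate(nodes):
        pool = positions_of(pp_masks[vi])
        for m in tables._subset_masks(pool):
            if (vi, m) not in tables.local:
                parents = frozenset(nodes[j] for j in positions_of(m))
                tables.local[(vi, m)] = float(score_fn(v, parents))
    return tables


def best_parents_tables(tables: ScoreTables) -> ScoreTables:
    """Eagerly fill bestScore/bestParents for every pool U subseteq pp_v by
    the downward recurrence (feasible for small pp sets; the lazy
    :meth:`ScoreTables.best` is the equivalent large-scale route).
    """
    cap = tables.indegree

    def card(m: int) -> int:
        return bin(m).count("1")

    def lex_key(m: int) -> tuple:
        return positions_of(m)

    for vi in range(tables.p_bar):
        pp = positions_of(tables.pp_masks[vi])
        pools = sorted(
            (mask_of(c) for k in range(len(pp) + 1) for c in combinations(pp, k)),
            key=card,
        )
        for U in pools:
            candidates: list[tuple[float, int]] = []
            if cap is None or card(U) <= cap:
                candidates.append((tables.local[(vi, U)], U))
            for u in positions_of(U):
                candidates.append(tables.best_table[(vi, U & ~(1 << u))])
            # tie policy: among equal scores prefer smaller cardinality,
            # then lexicographically smallest subset
            top = max(t[0] for t in candidates)
            tied = [m for s, m in candidates if s == top]
            best_mask = min(tied, key=lambda m: (card(m), lex_key(m)))
            tables.best_table[(vi, U)] = (top, best_mask)
    return tables
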