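"""Dynamic programming over (partial) generational orderings.

Every DAG has a sink, so the best network over a node set V satisfies

    bestscore(V) = bestscore(V \\ {s}) + bestScore(s, V \\ {s})

maximized over candidate sinks s.  The DP expands a subset lattice
breadth-first: a node v may be appended to a nonempty subset S only if it
has a possible parent inside S (generational admissibility), so only
subsets lying on complete generational orderings are ever materialized.
Full mode starts from the empty set (singletons score local(v, null));
partial mode starts from every subset of cardinality p_bar − pOrd with
accumulated score 0, so totals compare the contribution of the last pOrd
appended nodes only.  Reconstruction peels stored best sinks back down to
the base, yielding the reverse ordering(s) and per-node best parents; ties
within relative 1e-9 yield multiple equal-score networks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

from .candidates import CandidateSets
from .scoring import NEG_INF
from .tables import ScoreTables, mask_of, positions_of

TIE_RTOL = 1e-9
MAX_SINKS_PER_SUBSET = 5


def _tol(a: float, b: float) -> float:
    return TIE_RTOL * max(1.0, abs(a), abs(b))


@dataclass
class LatticeEntry:
    score: float
    sinks: tuple[int, ...]


@dataclass
class SinkLattice:
    """Reachable subsets (bitmask-keyed) with best accumulated score/sinks."""

    entries: dict[int, LatticeEntry]
    base_cardinality: int
    pord: int
    p_bar: int
    top_cardinality: int
    warnings: list[str] = field(default_factory=list)
    n_expanded: int = 0

    def best_top(self) -> tuple[float, list[int]]:
        """Best score at the top cardinality and the tied subset masks."""
        tops = {
            m: e
            for m, e in self.entries.items()
            if bin(m).count("1") == self.top_cardinality
        }
        best = max(e.score for e in tops.values())
        tied = [m for m, e in tops.items() if abs(e.score - best) <= _tol(e.score, best)]
        return best, sorted(tied)


@dataclass
class Network:
    """A reconstructed DAG with its ordering and DP score."""

    nodes: list[str]
    parent_map: dict[str, set[str]]
    ordering: tuple[str, ...]
    score: float
    root_only_nodes: set[str] = field(default_factory=set)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(u, v) for v, ps in self.parent_map.items() for u in ps}


def _expand(
    tables: ScoreTables,
    bases: dict[int, LatticeEntry],
    levels: int,
    count_weight=None,
) -> tuple[dict[int, LatticeEntry], dict[int, int], int, int]:
    """Breadth-first lattice expansion for ``levels`` cardinality steps.

    Returns (entries, covered-counts, top cardinality, #expansions).  The
    covered counts propagate how many (ordering, parent-choice) combinations
    each recorded subset summarizes, weighting every appended sink by
    ``count_weight(pool_size)`` (1 counts orderings/paths only).
    """
    n = tables.p_bar
    entries = dict(bases)
    covered = {m: 1 for m in bases}
    frontier = dict(bases)
    base_card = bin(next(iter(bases))).count("1") if bases else 0
    top = base_card
    n_expanded = 0
    for _ in range(levels):
        nxt: dict[int, LatticeEntry] = {}
        for S, ent in frontier.items():
            for v in range(n):
                bit = 1 << v
                if S & bit:
                    continue
                pool = tables.pp_masks[v] & S
                if S != 0 and pool == 0:
                    continue  # generational admissibility
                sc, _ = tables.best(v, pool)
                total = ent.score + sc
                n_expanded += 1
                key = S | bit
                cur = nxt.get(key)
                if cur is None or total > cur.score + _tol(total, cur.score):
                    nxt[key] = LatticeEntry(total, (v,))
                elif abs(total - cur.score) <= _tol(total, cur.score):
                    if len(cur.sinks) < MAX_SINKS_PER_SUBSET and v not in cur.sinks:
                        nxt[key] = LatticeEntry(cur.score, cur.sinks + (v,))
                if count_weight is not None:
                    w = covered[S] * count_weight(bin(pool).count("1"))
                    covered[key] = covered.get(key, 0) + w
        if not nxt:
            break
        entries.update(nxt)
        frontier = nxt
        top += 1
    return entries, covered, top, n_expanded


def best_sinks_full(cands: CandidateSets, tables: ScoreTables) -> SinkLattice:
    """Full-mode DP: expand from the empty set up to cardinality p_bar."""
    return best_sinks_partial(cands, tables, pord=tables.p_bar)


def best_sinks_partial(
    cands: CandidateSets, tables: ScoreTables, pord: int
) -> SinkLattice:
    """Partial-mode DP: bases are all subsets of cardinality p_bar − pOrd
    (score 0); expansion runs for pOrd levels.  pOrd = p_bar reduces exactly
    to full mode (single base: the empty set)."""
    p_bar = tables.p_bar
    if not (1 <= pord <= p_bar):
        raise ValueError(f"pord must be in [1, {p_bar}], got {pord}")
    base_card = p_bar - pord
    bases = {
        mask_of(c): LatticeEntry(0.0, ())
        for c in combinations(range(p_bar), base_card)
    }
    entries, _, top, n_exp = _expand(tables, bases, levels=pord)
    warns: list[str] = []
    if top < p_bar:
        if top == base_card:
            msg = "no expandable base subsets; result is empty"
        else:
            msg = (
                f"full cardinality {p_bar} unreachable; results reported at "
                f"cardinality {top}"
            )
        warnings.warn(msg, stacklevel=2)
        warns.append(msg)
    return SinkLattice(
        entries=entries,
        base_cardinality=base_card,
        pord=pord,
        p_bar=p_bar,
        top_cardinality=top,
        warnings=warns,
        n_expanded=n_exp,
    )


def reconstruct(
    lattice: SinkLattice, tables: ScoreTables, max_networks: int = 10
) -> list[Network]:
    """Peel stored best sinks from the best top subset(s) down to the base,
    yielding up to ``max_networks`` equal-score networks.

    Each peeled node v receives parents bestParents(v, remaining subset);
    in partial mode, base nodes referenced as parents are included as
    parentless roots (``root_only_nodes``)."""
    if not lattice.entries:
        raise ValueError("empty lattice")
    if lattice.top_cardinality == lattice.base_cardinality:
        return []
    best, tops = lattice.best_top()
    orderings: list[tuple[int, tuple[int, ...]]] = []  # (base source, reversed peel)

    def peel(mask: int, acc: tuple[int, ...]):
        if len(orderings) >= max_networks:
            return
        if bin(mask).count("1") == lattice.base_cardinality:
            orderings.append((mask, acc))
            return
        entry = lattice.entries.get(mask)
        if entry is None:
            raise RuntimeError(f"inconsistent lattice: subset {mask:b} missing")
        for s in entry.sinks:
            prev = mask & ~(1 << s)
            if bin(prev).count("1") > lattice.base_cardinality and prev not in lattice.entries:
                raise RuntimeError(f"inconsistent lattice: predecessor {prev:b} missing")
            peel(prev, acc + (s,))

    for m in tops:
        peel(m, ())

    nets: list[Network] = []
    nodes = tables.nodes
    for base_mask, reversed_peel in orderings[:max_networks]:
        forward = tuple(reversed(reversed_peel))
        parent_map: dict[str, set[str]] = {}
        roots: set[str] = set()
        cur = base_mask
        score = 0.0
        for v in forward:
            pool = tables.pp_masks[v] & cur
            sc, pmask = tables.best(v, pool)
            parents = {nodes[j] for j in positions_of(pmask)}
            parent_map[nodes[v]] = parents
            score += sc
            for u in positions_of(pmask):
                if base_mask & (1 << u):
                    roots.add(nodes[u])
            cur |= 1 << v
        for r in roots:
            parent_map.setdefault(r, set())
        net = Network(
            nodes=[nodes[v] for v in forward] + sorted(roots),
            parent_map=parent_map,
            ordering=tuple(nodes[v] for v in forward),
            score=score,
            root_only_nodes=roots,
        )
        nets.append(net)
    return nets


def network_score(net: Network, tables: ScoreTables) -> float:
    """Recompute the network score as the sum of local scores of the ordered
    nodes (decomposability); root-only nodes contribute nothing."""
    total = 0.0
    for v in net.ordering:
        vi = tables.index[v]
        pmask = mask_of(tables.index[u] for u in net.parent_map[v])
        try:
            total += tables.local[(vi, pmask)]
        except KeyError as exc:
            raise RuntimeError(
                f"parent set {sorted(net.parent_map[v])} of {v} absent from "
                "the local table"
            ) from exc
    return total


# ---------------------------------------------------------------------------
# Instrumented counting (search-space size checks)
# ---------------------------------------------------------------------------


def _counting_tables(n: int, indegree: int | None) -> tuple[CandidateSets, ScoreTables]:
    from .tables import enumerate_local_scores

    names = [f"v{i + 1}" for i in range(n)]
    pp = {v: set(names) - {v} for v in names}
    cands = CandidateSets(
        pp=pp,
        po={v: set(names) - {v} for v in names},
        feas_set=names,
        alpha=1.0,
    )
    tables = enumerate_local_scores(
        None, cands, indegree=indegree, score_fn=lambda v, ps: 0.0
    )
    return cands, tables


def count_generational_orderings(tables: ScoreTables, pord: int | None = None) -> int:
    """Number of complete base-to-top paths (orderings) the DP covers."""
    p_bar = tables.p_bar
    if pord is None:
        pord = p_bar
    base_card = p_bar - pord
    bases = {
        mask_of(c): LatticeEntry(0.0, ())
        for c in combinations(range(p_bar), base_card)
    }
    _, covered, top, _ = _expand(tables, bases, levels=pord, count_weight=lambda k: 1)
    return sum(c for m, c in covered.items() if bin(m).count("1") == top)


def searched_network_count(p: int, pord: int, indegree: int | None = None) -> int:
    """Instrumented count of (ordering, parent-set choice) combinations the
    partial DP covers on p all-pairs-connected nodes.

    Every appended sink with a pool of size k contributes a factor equal to
    the number of parent subsets the tables enumerate for that pool (2^k
    when the indegree is uncapped)."""
    cands, tables = _counting_tables(p, indegree)
    base_card = p - pord
    bases = {
        mask_of(c): LatticeEntry(0.0, ()) for c in combinations(range(p), base_card)
    }
    _, covered, top, _ = _expand(
        tables, bases, levels=pord, count_weight=tables.n_parent_subsets
    )
    return sum(c for m, c in covered.items() if bin(m).count("1") == p)


# ---------------------------------------------------------------------------
# High-level pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunResult:
    networks: list[Network]
    lattice: SinkLattice
    cands: CandidateSets
    tables: ScoreTables
    params: dict
    warnings: list[str]


def discover(
    data,
    score: str = "bic",
    alpha: float = 0.3,
    indegree: int = 2,
    pord: int | None = None,
    phenotype_driven: bool = False,
    pp: dict | None = None,
    corr_floor: float = 0.0,
    max_networks: int = 10,
    clamp_pord: bool = False,
    standardize: bool = True,
) -> RunResult:
    """End-to-end structure discovery on one data matrix.

    Candidate screening → feasible-set reduction → local-score tables →
    sink-lattice DP (full when pord is None, else partial) → network
    reconstruction.  ``clamp_pord`` lowers pord to the feasible-set size
    when screening retains fewer nodes than the requested ordering length.
    Continuous columns are z-scored before scoring by default so the
    discovered structure does not depend on measurement units (residual
    variance based scores are not scale invariant).
    """
    from .candidates import (
        feasible_set,
        find_possible_parents,
        phenotype_driven_parents,
        user_supplied_parents,
    )
    from .tables import enumerate_local_scores

    warns: list[str] = []
    if pp is not None:
        cands = user_supplied_parents(pp, data, alpha=alpha)
    elif phenotype_driven:
        cands = phenotype_driven_parents(data, alpha=alpha, corr_floor=corr_floor)
    else:
        cands = find_possible_parents(data, alpha=alpha, corr_floor=corr_floor)
    cands, reduced = feasible_set(cands, data)
    warns.extend(cands.warnings)
    if standardize:
        reduced = reduced.standardized()
    tables = enumerate_local_scores(reduced, cands, indegree=indegree, method=score)
    p_bar = tables.p_bar
    effective_pord = p_bar if pord is None else pord
    if effective_pord > p_bar:
        if clamp_pord:
            warns.append(
                f"pord {effective_pord} exceeds feasible-set size {p_bar}; clamped"
            )
            effective_pord = p_bar
        else:
            raise ValueError(f"pord {effective_pord} exceeds feasible-set size {p_bar}")
    lattice = best_sinks_partial(cands, tables, pord=effective_pord)
    warns.extend(lattice.warnings)
    nets = reconstruct(lattice, tables, max_networks=max_networks)
    params = {
        "score": score,
        "alpha": alpha,
        "indegree": indegree,
        "pord": None if pord is None else effective_pord,
        "mode": "full" if pord is None else "partial",
        "phenotype_driven": phenotype_driven,
        "corr_floor": corr_floor,
        "max_networks": max_networks,
        "p_bar": p_bar,
    }
    return RunResult(
        networks=nets,
        lattice=lattice,
        cands=cands,
        tables=tables,
        params=params,
        warnings=warns,
    )
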