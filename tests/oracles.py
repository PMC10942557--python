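"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the package's DP/lattice code paths: orderings are
enumerated explicitly, regressions are solved by normal equations, and
counting formulas are computed directly.
"""

from __future__ import annotations

import math
from itertools import combinations, permutations

import numpy as np

from bnlattice.candidates import CandidateSets
from bnlattice.tables import ScoreTables, mask_of


def ols_gaussian_bic(y: np.ndarray, X: np.ndarray | None) -> float:
    """Gaussian BIC by explicit normal equations (independent of lstsq path)."""
    n = len(y)
    Z = np.ones((n, 1)) if X is None else np.column_stack([np.ones(n), X])
    beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
    resid = y - Z @ beta
    s2 = float(resid @ resid) / n
    ll = -0.5 * n * (math.log(2 * math.pi * s2) + 1.0)
    k = Z.shape[1] + 1
    return ll - 0.5 * k * math.log(n)


def contingency_loglik(child: np.ndarray, parents: list[np.ndarray]) -> float:
    """Multinomial log-likelihood by direct contingency enumeration."""
    n = len(child)
    if not parents:
        ll = 0.0
        for lv in np.unique(child):
            c = int((child == lv).sum())
            ll += c * math.log(c / n)
        return ll
    configs = np.array([tuple(p[i] for p in parents) for i in range(n)], dtype=object)
    keys = [tuple(row) for row in configs]
    ll = 0.0
    for cfg in set(keys):
        idx = [i for i, k in enumerate(keys) if k == cfg]
        nj = len(idx)
        sub = child[idx]
        for lv in np.unique(sub):
            njk = int((sub == lv).sum())
            ll += njk * math.log(njk / nj)
    return ll


def random_instance(rng: np.random.Generator, p_bar: int, indegree: int = 2,
                    pair_prob: float = 0.6) -> tuple[CandidateSets, ScoreTables]:
    """Random symmetric pp sets with random local scores (no data)."""
    from bnlattice.tables import enumerate_local_scores

    names = [f"v{i + 1}" for i in range(p_bar)]
    pp: dict[str, set] = {v: set() for v in names}
    for a, b in combinations(names, 2):
        if rng.random() < pair_prob:
            pp[a].add(b)
            pp[b].add(a)
    po = {v: {u for u in names if v in pp[u]} for v in names}
    cands = CandidateSets(pp=pp, po=po, feas_set=names, alpha=0.3)
    scores: dict[tuple[str, frozenset], float] = {}

    def score_fn(v, parents):
        key = (v, frozenset(parents))
        if key not in scores:
            scores[key] = float(rng.normal(scale=5.0))
        return scores[key]

    tables = enumerate_local_scores(None, cands, indegree=indegree, score_fn=score_fn)
    return cands, tables


def _admissible_extensions(tables: ScoreTables, prefix: list[int]) -> list[int]:
    used = set(prefix)
    mask = mask_of(prefix)
    out = []
    for v in range(tables.p_bar):
        if v in used:
            continue
        if not prefix or (tables.pp_masks[v] & mask):
            out.append(v)
    return out


def brute_force_full(tables: ScoreTables) -> tuple[float, int]:
    """Max score over all generational orderings of maximal length.

    Returns (best score, maximal ordering length).  Each non-first node must
    have a possible parent among its predecessors; node v appended after
    prefix P scores bestScore(v, pp_v intersect P) (empty prefix: local(v, null)).
    """
    best: dict[int, float] = {}

    def rec(prefix: list[int], score: float):
        L = len(prefix)
        if L:
            best[L] = max(best.get(L, -math.inf), score)
        for v in _admissible_extensions(tables, prefix):
            sc, _ = tables.best(v, mask_of(prefix))
            rec(prefix + [v], score + sc)

    rec([], 0.0)
    max_len = max(best)
    return best[max_len], max_len


def brute_force_partial(tables: ScoreTables, pord: int) -> tuple[float, int]:
    """Max tail score over all bases and ordered admissible sink tuples.

    Returns (best tail score, maximal tail length reached)."""
    p_bar = tables.p_bar
    base_card = p_bar - pord
    best: dict[int, float] = {}
    for base in combinations(range(p_bar), base_card):
        base_mask = mask_of(base)
        rest = [v for v in range(p_bar) if v not in base]
        for k in range(1, pord + 1):
            for tail in permutations(rest, k):
                mask = base_mask
                total = 0.0
                ok = True
                for v in tail:
                    if mask != 0 and not (tables.pp_masks[v] & mask):
                        ok = False
                        break
                    sc, _ = tables.best(v, tables.pp_masks[v] & mask)
                    total += sc
                    mask |= 1 << v
                if ok:
                    best[k] = max(best.get(k, -math.inf), total)
    if not best:
        return -math.inf, 0
    max_len = max(best)
    return best[max_len], max_len


def counting_product(p: int, r: int) -> int:
    """Independently computed product prod_{k=p-r+1..p} k * 2^(k-1)."""
    out = 1
    for k in range(p - r + 1, p + 1):
        out *= k * 2 ** (k - 1)
    return out
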