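import math

import networkx as nx
import numpy as np
import pytest

from bnlattice.candidates import CandidateSets
from bnlattice.search import (
    LatticeEntry,
    SinkLattice,
    best_sinks_full,
    best_sinks_partial,
    count_generational_orderings,
    discover,
    network_score,
    reconstruct,
    searched_network_count,
)
from bnlattice.simulate import SimulationSpec, simulate
from bnlattice.tables import enumerate_local_scores, mask_of, positions_of
from oracles import (
    brute_force_full,
    brute_force_partial,
    random_instance,
    counting_product,
)


def tables_for(cands, score_fn=lambda v, ps: 0.0, indegree=2):
    return enumerate_local_scores(None, cands, indegree=indegree, score_fn=score_fn)


def masks_by_card(lattice):
    out = {}
    for m in lattice.entries:
        out.setdefault(bin(m).count("1"), set()).add(m)
    return out


def test_single_node_lattice():
    cands = CandidateSets(pp={"v": set()}, po={"v": set()}, feas_set=["v"], alpha=0.3)
    tables = tables_for(cands, score_fn=lambda v, ps: -3.0)
    lat = best_sinks_full(cands, tables)
    assert set(lat.entries) == {0, 1}
    nets = reconstruct(lat, tables)
    assert len(nets) == 1 and nets[0].ordering == ("v",)
    assert nets[0].score == pytest.approx(-3.0)


def test_worked_example_recorded_subsets(fig_candidates):
    """With pp1={2,4}, pp2={1,3}, pp3={2}, pp4={1}, the full DP records only
    subsets on complete generational orderings."""
    tables = tables_for(fig_candidates)
    lat = best_sinks_full(fig_candidates, tables)
    name_mask = lambda *vs: mask_of(int(v) - 1 for v in vs)
    expected = {
        0,
        name_mask(1), name_mask(2), name_mask(3), name_mask(4),
        name_mask(1, 2), name_mask(1, 4), name_mask(2, 3),
        name_mask(1, 2, 3), name_mask(1, 2, 4),
        name_mask(1, 2, 3, 4),
    }
    assert set(lat.entries) == expected
    assert lat.top_cardinality == 4


def test_reverse_ordering_reconstruction_from_stored_sinks():
    """A sink table encoding bestSink({1,2,3,4})=3, bestSink({1,2,4})=2,
    bestSink({1,4})=1, bestSink({4})=4 reconstructs the ordering (4,1,2,3)."""
    names = ["v1", "v2", "v3", "v4"]
    pp = {v: set(names) - {v} for v in names}
    cands = CandidateSets(pp=pp, po=dict(pp), feas_set=names, alpha=0.3)
    tables = tables_for(cands, score_fn=lambda v, ps: 0.0)
    m = lambda *vs: mask_of(v - 1 for v in vs)
    entries = {
        m(1, 2, 3, 4): LatticeEntry(0.0, (2,)),
        m(1, 2, 4): LatticeEntry(0.0, (1,)),
        m(1, 4): LatticeEntry(0.0, (0,)),
        m(4): LatticeEntry(0.0, (3,)),
        0: LatticeEntry(0.0, ()),
    }
    lat = SinkLattice(
        entries=entries, base_cardinality=0, pord=4, p_bar=4, top_cardinality=4
    )
    nets = reconstruct(lat, tables, max_networks=1)
    assert nets[0].ordering == ("v4", "v1", "v2", "v3")


@pytest.mark.parametrize("seed", range(30))
def test_full_dp_matches_generational_brute_force(seed):
    """DP best score equals exhaustive enumeration over all generational
    orderings (of the maximal reachable length)."""
    rng = np.random.default_rng(seed)
    p_bar = int(rng.integers(3, 6))
    cands, tables = random_instance(rng, p_bar=p_bar, indegree=2)
    lat = best_sinks_full(cands, tables)
    want, want_len = brute_force_full(tables)
    assert lat.top_cardinality == want_len
    got, _ = lat.best_top()
    assert got == pytest.approx(want, abs=1e-9)
    for net in reconstruct(lat, tables):
        assert network_score(net, tables) == pytest.approx(net.score, abs=1e-9)


@pytest.mark.parametrize("seed", range(30))
def test_partial_reduction_identity(seed):
    """best_sinks_partial with pOrd = p_bar is identical to full mode."""
    rng = np.random.default_rng(1000 + seed)
    p_bar = int(rng.integers(3, 6))
    cands, tables = random_instance(rng, p_bar=p_bar, indegree=2)
    full = best_sinks_full(cands, tables)
    part = best_sinks_partial(cands, tables, pord=tables.p_bar)
    assert full.entries.keys() == part.entries.keys()
    for m in full.entries:
        assert full.entries[m].score == pytest.approx(part.entries[m].score, abs=1e-12)
        assert full.entries[m].sinks == part.entries[m].sinks
    nets_f = reconstruct(full, tables)
    nets_p = reconstruct(part, tables)
    assert [n.ordering for n in nets_f] == [n.ordering for n in nets_p]
    assert [n.score for n in nets_f] == pytest.approx([n.score for n in nets_p])


@pytest.mark.parametrize("seed", range(15))
@pytest.mark.parametrize("pord", [1, 2])
def test_partial_tail_matches_brute_force(seed, pord):
    """Partial DP best tail score equals exhaustive enumeration over ordered
    sink tuples for p_bar <= 6."""
    rng = np.random.default_rng(2000 + seed)
    p_bar = int(rng.integers(max(3, pord + 1), 7))
    cands, tables = random_instance(rng, p_bar=p_bar, indegree=2)
    lat = best_sinks_partial(cands, tables, pord=pord)
    want, want_len = brute_force_partial(tables, pord)
    got, _ = lat.best_top()
    assert lat.top_cardinality - lat.base_cardinality == want_len
    assert got == pytest.approx(want, abs=1e-9)


def test_partial_pord_one_is_single_best_node():
    rng = np.random.default_rng(77)
    cands, tables = random_instance(rng, p_bar=5, indegree=2)
    lat = best_sinks_partial(cands, tables, pord=1)
    nets = reconstruct(lat, tables, max_networks=1)
    best = -math.inf
    for v in range(5):
        pool = tables.pp_masks[v] & (mask_of(range(5)) & ~(1 << v))
        sc, _ = tables.best(v, pool)
        best = max(best, sc)
    assert nets[0].score == pytest.approx(best, abs=1e-9)
    assert len(nets[0].ordering) == 1
    # parents of the single ordered node appear as parentless roots
    ordered = nets[0].ordering[0]
    assert nets[0].root_only_nodes == nets[0].parent_map[ordered]


def test_pord_validation(fig_candidates):
    tables = tables_for(fig_candidates)
    with pytest.raises(ValueError):
        best_sinks_partial(fig_candidates, tables, pord=0)
    with pytest.raises(ValueError):
        best_sinks_partial(fig_candidates, tables, pord=5)


def test_all_ties_returns_multiple_equal_score_networks(fig_candidates):
    tables = tables_for(fig_candidates, score_fn=lambda v, ps: -1.0)
    lat = best_sinks_full(fig_candidates, tables)
    nets = reconstruct(lat, tables, max_networks=10)
    assert len(nets) > 1
    assert all(n.score == pytest.approx(nets[0].score, abs=1e-12) for n in nets)


@pytest.mark.parametrize("seed", range(10))
def test_returned_networks_respect_constraints(seed):
    """Every output respects pp membership, the indegree cap and acyclicity."""
    spec = SimulationSpec(N=400, p=12, p0=3, p1=3, p2=3, p3=3, seed=seed)
    truth, data = simulate(spec)
    res = discover(data, pord=3, clamp_pord=True)
    for net in res.networks:
        g = nx.DiGraph()
        g.add_nodes_from(net.nodes)
        g.add_edges_from(net.edges)
        assert nx.is_directed_acyclic_graph(g)
        for v in net.ordering:
            assert len(net.parent_map[v]) <= 2
            assert net.parent_map[v] <= res.cands.pp[v]
        for r in net.root_only_nodes:
            assert not net.parent_map[r]
        # decomposability: recomputed sum of local scores matches DP score
        assert network_score(net, res.tables) == pytest.approx(net.score, abs=1e-9)


def test_unconstrained_four_node_lattice_has_factorial_paths():
    names = [f"v{i+1}" for i in range(4)]
    pp = {v: set(names) - {v} for v in names}
    cands = CandidateSets(pp=pp, po=dict(pp), feas_set=names, alpha=1.0)
    tables = tables_for(cands, indegree=None)
    assert count_generational_orderings(tables) == math.factorial(4)


@pytest.mark.parametrize("p,r", [(3, 1), (3, 2), (4, 2)])
def test_searched_network_count_matches_product(p, r):
    """Instrumented (ordering, parent-choice) coverage of the partial DP on
    all-pairs candidates, no indegree cap, equals prod k*2^(k-1)."""
    assert searched_network_count(p, r) == counting_product(p, r)


def test_disconnected_feasset_warns_and_reports_partial():
    names = ["a", "b", "c", "d"]
    pp = {"a": {"b"}, "b": {"a"}, "c": {"d"}, "d": {"c"}}
    po = {v: {u for u in names if v in pp[u]} for v in names}
    cands = CandidateSets(pp=pp, po=po, feas_set=names, alpha=0.3)
    tables = tables_for(cands)
    with pytest.warns(UserWarning, match="unreachable"):
        lat = best_sinks_full(cands, tables)
    assert lat.top_cardinality == 2
    nets = reconstruct(lat, tables)
    assert nets and len(nets[0].ordering) == 2


def test_network_score_missing_entry_is_internal_error(fig_candidates):
    tables = tables_for(fig_candidates)
    lat = best_sinks_full(fig_candidates, tables)
    net = reconstruct(lat, tables, max_networks=1)[0]
    net.parent_map[net.ordering[0]] = {"v1", "v2", "v3"}  # beyond indegree
    with pytest.raises(RuntimeError):
        network_score(net, tables)
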