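"""Structure-recovery metrics and the simulation-grid benchmark harness.

FDR = FP / (FP + TP) over predicted edges (0/0 defined as 0: an empty
prediction makes no false discoveries) and structural Hamming distance =
FP + FN, both in directed mode (ordered edge pairs) and undirected mode
(deduplicated skeletons).  The grid harness simulates replicate (DAG, data)
pairs per (N, p) cell, runs the configured search, and reports per-cell and
grand means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .search import Network, discover
from .simulate import SimulationSpec, TrueNetwork, default_roles, simulate


@dataclass(frozen=True)
class EvalResult:
    """Edge confusion counts and derived metrics for one comparison mode."""

    tp: int
    fp: int
    fn: int
    fdr_directed: float
    fdr_undirected: float
    hamming: int
    directed: bool

    @property
    def fdr(self) -> float:
        return self.fdr_directed if self.directed else self.fdr_undirected


def _edge_set(g) -> set[tuple[str, str]]:
    if isinstance(g, (Network, TrueNetwork)):
        return set(g.edges)
    return {(str(a), str(b)) for a, b in g}


def _confusion(pred: set, truth: set) -> tuple[int, int, int]:
    tp = len(pred & truth)
    fp = len(pred - truth)
    fn = len(truth - pred)
    return tp, fp, fn


def _fdr(fp: int, tp: int) -> float:
    return fp / (fp + tp) if fp + tp else 0.0


def edge_confusion(pred, truth, directed: bool = True) -> EvalResult:
    """Compare predicted vs true edges; FN is counted over the full truth
    graph.  Undirected mode compares skeletons (unordered pairs)."""
    pe, te = _edge_set(pred), _edge_set(truth)
    known = {n for e in te for n in e} | (
        set(truth.nodes) if isinstance(truth, (Network, TrueNetwork)) else set()
    )
    if known:
        unknown = {n for e in pe for n in e} - known
        if unknown:
            raise ValueError(f"prediction references unknown labels: {sorted(unknown)}")
    pu = {frozenset(e) for e in pe}
    tu = {frozenset(e) for e in te}
    tp_d, fp_d, fn_d = _confusion(pe, te)
    tp_u, fp_u, fn_u = _confusion(pu, tu)
    if directed:
        tp, fp, fn = tp_d, fp_d, fn_d
    else:
        tp, fp, fn = tp_u, fp_u, fn_u
    return EvalResult(
        tp=tp,
        fp=fp,
        fn=fn,
        fdr_directed=_fdr(fp_d, tp_d),
        fdr_undirected=_fdr(fp_u, tp_u),
        hamming=fp + fn,
        directed=directed,
    )


@dataclass(frozen=True)
class MethodConfig:
    """Search configuration used by the grid harness."""

    score: str = "bic"
    alpha: float = 0.3
    indegree: int = 2
    pord: int | None = 3  # None = full search
    corr_floor: float = 0.0
    average_ties: bool = False


@dataclass
class GridResult:
    table: pd.DataFrame
    grand: dict[str, float]
    failures: int = 0


def _replicate_metrics(
    net: TrueNetwork, pred: Network | None
) -> tuple[float, float, int, int]:
    pred_edges = pred.edges if pred is not None else set()
    r_d = edge_confusion(pred_edges, net, directed=True)
    r_u = edge_confusion(pred_edges, net, directed=False)
    return r_d.fdr_directed, r_u.fdr_undirected, r_d.hamming, r_u.hamming


def simulation_grid(
    grid: list[tuple[int, int]],
    reps: int = 5,
    config: MethodConfig | None = None,
    seed: int = 0,
    spec_for=None,
) -> GridResult:
    """Run the benchmark over (N, p) cells.

    For each cell, ``reps`` replicate (network, data) pairs are simulated
    (roles from :func:`simulate.default_roles` unless ``spec_for(N, p,
    seed)`` is supplied), the configured method is run, and mean directed /
    undirected FDR and Hamming distance are reported per cell together with
    the grand mean across cells.  A replicate where the method fails is
    recorded as missing and excluded from the means.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if config is None:
        config = MethodConfig()
    ss = np.random.SeedSequence(seed)
    cells = ss.spawn(len(grid))
    rows = []
    failures = 0
    for (N, p), cell_ss in zip(grid, cells):
        cell_seeds = [int(s) % (2**31) for s in cell_ss.generate_state(reps)]
        vals = {"fdr_directed": [], "fdr_undirected": [], "hamming_directed": [], "hamming_undirected": []}
        for rep_seed in cell_seeds:
            if spec_for is not None:
                spec = spec_for(N, p, rep_seed)
            else:
                p0, p1, p2, p3 = default_roles(p)
                spec = SimulationSpec(N=N, p=p, p0=p0, p1=p1, p2=p2, p3=p3, seed=rep_seed)
            truth, data = simulate(spec)
            try:
                res = discover(
                    data,
                    score=config.score,
                    alpha=config.alpha,
                    indegree=config.indegree,
                    pord=config.pord,
                    corr_floor=config.corr_floor,
                    clamp_pord=True,
                )
                nets = res.networks
            except ValueError:
                # e.g. no connected variables at this alpha → empty prediction
                nets = []
            except Exception as exc:  # method failure: record as missing
                warnings.warn(f"method failed on replicate (N={N}, p={p}): {exc}")
                failures += 1
                continue
            if config.average_ties and nets:
                mets = np.mean(
                    [_replicate_metrics(truth, nw) for nw in nets], axis=0
                )
            else:
                mets = _replicate_metrics(truth, nets[0] if nets else None)
            for k, v in zip(vals, mets):
                vals[k].append(float(v))
        row = {"N": N, "p": p, "n_ok": len(vals["fdr_directed"])}
        for k, v in vals.items():
            row[f"mean_{k}"] = float(np.mean(v)) if v else float("nan")
        rows.append(row)
    table = pd.DataFrame(rows)
    grand = {
        c.replace("mean_", "grand_"): float(np.nanmean(table[c]))
        for c in table.columns
        if c.startswith("mean_")
    }
    return GridResult(table=table, grand=grand, failures=failures)
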