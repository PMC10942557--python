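"""Possible-parent discovery by FDR-screened pairwise association.

Every unordered variable pair is tested for marginal association (Pearson
t-test for continuous–continuous, chi-square for categorical–categorical,
one-way ANOVA F-test for mixed pairs, univariate Cox for pairs involving a
survival outcome).  P-values are Benjamini–Hochberg adjusted in one family;
pairs passing q <= alpha (and an optional association floor) become mutual
possible parents, except that the designated outcome is never a parent.
Possible offspring are the exact inverse relation, and the feasible set
drops nodes with no candidate relations at all.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import CATEGORICAL, CONTINUOUS, DataMatrix


@dataclass
class CandidateSets:
    """Per-node possible parents/offspring and the retained feasible set."""

    pp: dict[str, set[str]]
    po: dict[str, set[str]]
    feas_set: list[str]
    alpha: float
    corr_floor: float = 0.0
    outcome: str | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def p_bar(self) -> int:
        return len(self.feas_set)

    def check_duality(self) -> bool:
        """pp/po inversion: j in pp_i iff i in po_j."""
        inv: dict[str, set[str]] = {v: set() for v in self.pp}
        for i, ps in self.pp.items():
            for j in ps:
                inv.setdefault(j, set()).add(i)
        return all(self.po.get(v, set()) == inv.get(v, set()) for v in self.pp)


def _invert(pp: dict[str, set[str]]) -> dict[str, set[str]]:
    po: dict[str, set[str]] = {v: set() for v in pp}
    for child, parents in pp.items():
        for pa in parents:
            po.setdefault(pa, set()).add(child)
    return po


def _pair_test(data: DataMatrix, a: str, b: str) -> tuple[float, float]:
    """(p-value, association strength in [0, inf)) for one variable pair."""
    ka, kb = data.kind_of(a), data.kind_of(b)
    if "survival" in (ka, kb):
        surv, other = (a, b) if ka == "survival" else (b, a)
        return _cox_pair_test(data, other)
    if ka == CONTINUOUS and kb == CONTINUOUS:
        r, p = stats.pearsonr(data.column(a).astype(float), data.column(b).astype(float))
        return float(p), abs(float(r))
    if ka == CATEGORICAL and kb == CATEGORICAL:
        tab = np.asarray(pd.crosstab(data.frame[a], data.frame[b]))
        chi2, p, _, _ = stats.chi2_contingency(tab)
        n = tab.sum()
        k = min(tab.shape) - 1
        v = math.sqrt(chi2 / (n * k)) if k > 0 else 0.0
        return float(p), float(v)
    # mixed: one-way ANOVA of the continuous variable across category levels
    cont, cat = (a, b) if ka == CONTINUOUS else (b, a)
    y = data.column(cont).astype(float)
    groups = [y[data.frame[cat].to_numpy() == lv] for lv in data.frame[cat].unique()]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        return 1.0, 0.0
    f, p = stats.f_oneway(*groups)
    gm = y.mean()
    ss_between = sum(len(g) * (g.mean() - gm) ** 2 for g in groups)
    ss_total = float(((y - gm) ** 2).sum())
    eta = math.sqrt(ss_between / ss_total) if ss_total > 0 else 0.0
    return float(p), float(eta)


def _cox_pair_test(data: DataMatrix, covariate: str) -> tuple[float, float]:
    """Univariate Cox association of a covariate with the survival outcome."""
    import pandas as pd
    from lifelines import CoxPHFitter

    time, event = data.survival_arrays()
    if data.kind_of(covariate) == CATEGORICAL:
        X = pd.get_dummies(data.frame[covariate], drop_first=True).to_numpy(dtype=float)
    else:
        X = data.column(covariate).astype(float)[:, None]
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
    df["time"], df["event"] = time, event
    cph = CoxPHFitter(penalizer=1e-6)
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception:
        return 1.0, 0.0
    p = float(cph.summary["p"].min())
    strength = float(
        (cph.summary["coef"].abs() * df.iloc[:, : X.shape[1]].std(ddof=0)).max()
    )
    return p, strength


def _test_pairs(
    data: DataMatrix, pairs: list[tuple[str, str]], warn: list[str]
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """P-values and strengths for the given pairs, skipping constant columns.

    Continuous–continuous pairs are evaluated in one vectorized correlation
    pass; other pair types fall back to per-pair tests.
    """
    const = set()
    for v in data.variables:
        if data.kind_of(v) == "survival":
            continue
        if np.unique(data.column(v)).size < 2:
            const.add(v)
            msg = f"constant column {v!r}: association tests skipped"
            if msg not in warn:
                warnings.warn(msg, stacklevel=3)
                warn.append(msg)
    tested = [(a, b) for a, b in pairs if a not in const and b not in const]

    cc = [
        (a, b)
        for a, b in tested
        if data.kind_of(a) == CONTINUOUS and data.kind_of(b) == CONTINUOUS
    ]
    pvals: dict[tuple[str, str], float] = {}
    strengths: dict[tuple[str, str], float] = {}
    if cc:
        cols = sorted({v for ab in cc for v in ab})
        pos = {v: i for i, v in enumerate(cols)}
        X = np.column_stack([data.column(v).astype(float) for v in cols])
        n = X.shape[0]
        C = np.corrcoef(X, rowvar=False)
        C = np.atleast_2d(C)
        for a, b in cc:
            r = float(np.clip(C[pos[a], pos[b]], -1.0, 1.0))
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * math.sqrt((n - 2) / (1.0 - r * r))
                p = 2.0 * stats.t.sf(abs(t), df=n - 2)
            pvals[(a, b)] = p
            strengths[(a, b)] = abs(r)
    for a, b in tested:
        if (a, b) not in pvals:
            p, s = _pair_test(data, a, b)
            pvals[(a, b)] = p
            strengths[(a, b)] = s
    pv = np.array([pvals[ab] for ab in tested])
    st = np.array([strengths[ab] for ab in tested])
    return pv, st, tested


def _bh_select(
    pvals: np.ndarray, strengths: np.ndarray, pairs, alpha: float, corr_floor: float
) -> set[tuple[str, str]]:
    if len(pairs) == 0:
        return set()
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    keep = set()
    for (a, b), q, s in zip(pairs, qvals, strengths):
        if q <= alpha and s >= corr_floor:
            keep.add((a, b))
    return keep


def find_possible_parents(
    data: DataMatrix, alpha: float = 0.3, corr_floor: float = 0.0
) -> CandidateSets:
    """Screen all unordered variable pairs; passing pairs become mutual
    possible parents (the outcome is never anyone's parent)."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    variables = data.variables
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    warn: list[str] = []
    pairs = list(combinations(variables, 2))
    pv, st, tested = _test_pairs(data, pairs, warn)
    keep = _bh_select(pv, st, tested, alpha, corr_floor)
    out = data.outcome_name
    pp: dict[str, set[str]] = {v: set() for v in variables}
    for a, b in keep:
        if b != out:
            pp[a].add(b)
        if a != out:
            pp[b].add(a)
    return CandidateSets(
        pp=pp,
        po=_invert(pp),
        feas_set=list(variables),
        alpha=alpha,
        corr_floor=corr_floor,
        outcome=out,
        warnings=warn,
    )


def phenotype_driven_parents(
    data: DataMatrix,
    outcome: str | None = None,
    alpha: float = 0.3,
    corr_floor: float = 0.0,
) -> CandidateSets:
    """Two-generation, outcome-anchored screening.

    Stage 1 finds candidate parents of the outcome; stage 2 finds candidate
    parents of those candidates.  The feasible set is the outcome, its
    candidate parents, and theirs; everything else is dropped.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if outcome is None:
        outcome = data.outcome_name
    if outcome is None:
        raise ValueError("phenotype-driven screening requires an outcome")
    variables = data.variables
    warn: list[str] = []

    stage1 = [(outcome, v) for v in variables if v != outcome]
    pv, st, tested = _test_pairs(data, stage1, warn)
    keep1 = _bh_select(pv, st, tested, alpha, corr_floor)
    pp_out = {b if a == outcome else a for a, b in keep1}
    if not pp_out:
        msg = f"outcome {outcome!r} has no associations at alpha={alpha}"
        warnings.warn(msg, stacklevel=2)
        warn.append(msg)

    gen1 = sorted(pp_out)
    stage2 = []
    seen = set()
    for u in gen1:
        for v in variables:
            if v == u or v == outcome:
                continue
            key = tuple(sorted((u, v)))
            if key not in seen:
                seen.add(key)
                stage2.append(key)
    keep2 = set()
    if stage2:
        pv2, st2, tested2 = _test_pairs(data, stage2, warn)
        keep2 = _bh_select(pv2, st2, tested2, alpha, corr_floor)

    pp: dict[str, set[str]] = {v: set() for v in variables}
    pp[outcome] = set(pp_out)
    gen1_set = set(gen1)
    for a, b in keep2:
        # symmetric possible-parent relation among screened pairs
        if a in gen1_set:
            pp[a].add(b)
        if b in gen1_set:
            pp[b].add(a)
    feas = {outcome} | gen1_set
    for u in gen1:
        feas |= pp[u]
    pp = {v: (ps & feas) for v, ps in pp.items()}
    feas_ordered = [v for v in variables if v in feas]
    return CandidateSets(
        pp=pp,
        po=_invert(pp),
        feas_set=feas_ordered,
        alpha=alpha,
        corr_floor=corr_floor,
        outcome=outcome,
        warnings=warn,
    )


def user_supplied_parents(
    pp: dict[str, set[str]], data: DataMatrix, alpha: float = 0.3
) -> CandidateSets:
    """Honor a user-supplied possible-parent map verbatim (screening bypass)."""
    variables = data.variables
    full = {v: set(pp.get(v, set())) for v in variables}
    out = data.outcome_name
    if out is not None:
        for v in full:
            full[v].discard(out)
    for v, ps in full.items():
        unknown = ps - set(variables)
        if unknown:
            raise ValueError(f"unknown possible parents for {v!r}: {sorted(unknown)}")
        ps.discard(v)
    return CandidateSets(
        pp=full,
        po=_invert(full),
        feas_set=list(variables),
        alpha=alpha,
        outcome=out,
    )


def feasible_set(
    cands: CandidateSets, data: DataMatrix
) -> tuple[CandidateSets, DataMatrix]:
    """Drop nodes with no candidate relations and reduce the data to match.

    Nodes with empty pp and empty po are removed (the outcome is always
    kept); retained pp/po entries referencing dropped nodes are pruned.
    Column order is preserved.
    """
    keep = {
        v
        for v in cands.feas_set
        if cands.pp.get(v) or cands.po.get(v) or v == cands.outcome
    }
    if not keep:
        raise ValueError("no connected variables at this alpha")
    feas = [v for v in cands.feas_set if v in keep]
    pp = {v: cands.pp[v] & keep for v in feas}
    reduced = CandidateSets(
        pp=pp,
        po=_invert(pp),
        feas_set=feas,
        alpha=cands.alpha,
        corr_floor=cands.corr_floor,
        outcome=cands.outcome,
        warnings=list(cands.warnings),
    )
    return reduced, data.restrict(feas)
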