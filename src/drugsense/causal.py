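"""Causal biomarker discovery for imputed drug response.

Three stages, mirroring the constraint-based discovery workflow used on
tumor transcriptomes:

1. ``scc_filter`` -- univariate Spearman pre-filter of genes against the
   drug's imputed AUC (FDR and |r| thresholds), reducing tens of thousands
   of genes to a tractable candidate set and making the later stages
   insensitive to variable ordering.
2. ``mmpc`` -- min-max parents-children discovery: candidates are added by
   the max-min-association heuristic and pruned whenever some conditioning
   subset (up to ``max_k`` variables drawn from the current PC set) renders
   them independent of the response. Independence is judged by the Fisher-z
   test on the partial correlation; the *sign* of the weakest surviving
   statistic is kept per PC gene, since it encodes whether high expression
   tracks resistance (positive, higher AUC) or sensitivity (negative).
3. ``orient_parents`` -- a restricted PC-style pass over the response, its
   PC genes and their own PC sets: CI-based skeleton (order-independent,
   PC-stable neighbor snapshots), collider (v-structure) orientation, and
   Meek propagation. PC genes with an edge oriented *into* the response are
   the parental candidates -- genes whose expression causally influences
   response rather than merely reacting to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .imputation import spearman_table

__all__ = [
    "GeneFilterResult",
    "CITestResult",
    "PCResult",
    "OrientationResult",
    "scc_filter",
    "partial_correlation",
    "fisher_z_test",
    "mmpc",
    "orient_parents",
    "biomarker_report",
]

RESPONSE = "__response__"


def scc_filter(expr: pd.DataFrame, response: pd.Series,
               r_min: float = 0.60, q_max: float = 0.05) -> pd.DataFrame:
    """Univariate Spearman pre-filter of genes against a response vector.

    A gene is retained when its BH-adjusted p is below ``q_max`` *and*
    |Spearman r| is at least ``r_min``. Returns a DataFrame
    (gene, r, p, q, retained).
    """
    response = response.reindex(expr.columns)
    if expr.shape[1] < 4:
        raise ValueError("need >= 4 samples")
    if response.nunique() <= 1:
        raise ValueError("response is constant; correlation filter undefined")
    tab = spearman_table(expr, response)
    tab["retained"] = (tab["q"] < q_max) & (tab["r"].abs() >= r_min)
    tab.loc[tab["q"].isna(), "retained"] = False
    return tab


def partial_correlation(x, y, Z=None) -> float:
    """Partial correlation of x and y given Z, by the residual method.

    Both x and y are regressed (OLS with intercept) on the conditioning
    variables; the partial correlation is the Pearson correlation of the
    two residual vectors. With empty Z this is the plain Pearson r.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if Z is None or (hasattr(Z, "size") and np.asarray(Z).size == 0) or \
            (isinstance(Z, (list, tuple)) and len(Z) == 0):
        Zm = np.empty((n, 0))
    else:
        Zm = np.asarray(Z, dtype=float)
        if Zm.ndim == 1:
            Zm = Zm[:, None]
    k = Zm.shape[1]
    if n <= k + 3:
        raise ValueError(f"need n > |Z| + 3 (n={n}, |Z|={k})")
    design = np.column_stack([np.ones(n), Zm])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("conditioning variables are linearly dependent")
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ coef_x
    ry = y - design @ coef_y
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))


def fisher_z_test(rho: float, n: int, k: int) -> tuple[float, float]:
    """Fisher-z independence test on a partial correlation.

    ``T = sqrt(n - k - 3) * atanh(rho)`` (signed) with two-sided normal
    p-value; k is the conditioning-set size. |rho| = 1 is reported as an
    infinite statistic with p = 0.
    """
    if n <= k + 3:
        raise ValueError(f"need n > k + 3 (n={n}, k={k})")
    if abs(rho) >= 1.0:
        return math.copysign(math.inf, rho), 0.0
    t = math.sqrt(n - k - 3) * math.atanh(rho)
    p = 2.0 * stats.norm.sf(abs(t))
    return t, p


@dataclass(frozen=True)
class CITestResult:
    """One conditional-independence query gene vs response (or gene pair)."""

    gene: str
    z: tuple[str, ...]
    rho: float
    stat: float        # signed Fisher-z statistic
    p: float
    n: int


@dataclass
class PCResult:
    """Parents-children set of the response with per-gene evidence."""

    pc_genes: list[str]
    stats: dict[str, CITestResult]
    alpha: float
    max_k: int


@dataclass
class OrientationResult:
    """Outcome of the restricted PC orientation pass."""

    parental_genes: list[str]
    edges: pd.DataFrame            # source, target, orientation ('->' / '--')
    skeleton_nodes: list[str] = field(default_factory=list)


class _CIEngine:
    """Fisher-z CI tests over a fixed sample matrix.

    Partial correlations are computed from the precomputed full correlation
    matrix by inverting the {x, y} + Z submatrix -- algebraically identical
    to correlating the OLS residuals, but O(|Z|^3) per query instead of a
    fresh regression.
    """

    def __init__(self, data: np.ndarray, names: list[str]):
        # data: samples x variables
        self.names = names
        self.index = {v: i for i, v in enumerate(names)}
        self.n = data.shape[0]
        sd = data.std(axis=0)
        if np.any(sd == 0):
            const = [names[i] for i in np.where(sd == 0)[0]]
            raise ValueError(f"constant variables: {const[:5]}")
        self.corr = np.corrcoef(data, rowvar=False)
        if self.corr.ndim == 0:     # single variable
            self.corr = np.array([[1.0]])
        self.cache: dict[tuple, tuple[float, float, float]] = {}

    def pcorr(self, x: str, y: str, z: tuple[str, ...]) -> float:
        idx = [self.index[x], self.index[y]] + [self.index[v] for v in z]
        sub = self.corr[np.ix_(idx, idx)]
        try:
            prec = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            prec = np.linalg.pinv(sub)
        denom = math.sqrt(abs(prec[0, 0] * prec[1, 1]))
        if denom == 0:
            return 0.0
        return float(np.clip(-prec[0, 1] / denom, -1.0, 1.0))

    def test(self, x: str, y: str, z: tuple[str, ...]) -> tuple[float, float, float]:
        key = (x, y, tuple(sorted(z)))
        if key not in self.cache:
            rho = self.pcorr(x, y, key[2])
            stat, p = fisher_z_test(rho, self.n, len(z))
            self.cache[key] = (rho, stat, p)
        return self.cache[key]


def _candidate_order(response: pd.Series, candidates: pd.DataFrame) -> list[str]:
    """Deterministic processing order: descending |SCC|, ties by gene ID."""
    tab = spearman_table(candidates, response)
    tab["absr"] = tab["r"].abs().fillna(0.0)
    tab = tab.sort_values(["absr", "gene"], ascending=[False, True])
    return list(tab["gene"])


def _build_engine(response: pd.Series, candidates: pd.DataFrame,
                  order: list[str]) -> _CIEngine:
    data = np.column_stack(
        [response.to_numpy(dtype=float)]
        + [candidates.loc[g].to_numpy(dtype=float) for g in order])
    return _CIEngine(data, [RESPONSE] + order)


def mmpc(response: pd.Series, candidates: pd.DataFrame,
         alpha: float = 0.05, max_k: int = 3) -> PCResult:
    """Min-max parents-children discovery for the response variable.

    Forward phase: the candidate whose *minimum* association with the
    response -- the smallest |T| over all conditioning subsets of the
    current PC set up to size ``max_k`` -- is largest gets added, as long
    as that minimum is still significant at ``alpha``; candidates whose
    minimum association becomes non-significant are permanently discarded.
    Backward phase: a PC member is removed if any subset of the remaining
    members (<= ``max_k``) renders it independent of the response. Each
    surviving gene carries the signed statistic of its weakest surviving
    test. Candidates are processed in descending-|SCC| order for
    reproducibility.

    Parameters are the samples-indexed response, a genes x samples
    candidate matrix, the CI-test level and the conditioning-set cap.
    """
    if candidates.shape[0] == 0:
        return PCResult(pc_genes=[], stats={}, alpha=alpha, max_k=max_k)
    order = _candidate_order(response, candidates)
    engine = _build_engine(response, candidates, order)
    return _mmpc_on_engine(engine, RESPONSE, order, alpha, max_k)


def _mmpc_on_engine(engine: _CIEngine, target: str, order: list[str],
                    alpha: float, max_k: int) -> PCResult:
    """MMPC over a prebuilt CI engine; ``order`` fixes candidate processing."""
    n = engine.n
    if n <= max_k + 3:
        raise ValueError(f"need n > max_k + 3 (n={n}, max_k={max_k})")
    if not order:
        return PCResult(pc_genes=[], stats={}, alpha=alpha, max_k=max_k)

    rank = {g: i for i, g in enumerate(order)}
    # per-candidate weakest evidence so far: (|stat|, CITestResult)
    weakest: dict[str, CITestResult] = {}
    alive: list[str] = []
    for g in order:
        rho, stat, p = engine.test(target, g, ())
        weakest[g] = CITestResult(gene=g, z=(), rho=rho, stat=stat, p=p, n=n)
        if p <= alpha:
            alive.append(g)

    pc: list[str] = []
    while alive:
        # max-min-association choice; ties broken by SCC order
        best = max(alive, key=lambda g: (abs(weakest[g].stat), -rank[g]))
        pc.append(best)
        alive.remove(best)
        prev = [g for g in pc if g != best]
        survivors = []
        for g in alive:
            rec = weakest[g]
            for size in range(0, min(max_k, len(prev) + 1)):
                for sub in combinations(prev, size):
                    z = tuple(sub) + (best,)
                    if len(z) > max_k:
                        continue
                    rho, stat, p = engine.test(target, g, z)
                    if abs(stat) < abs(rec.stat):
                        rec = CITestResult(gene=g, z=z, rho=rho, stat=stat,
                                           p=p, n=n)
            weakest[g] = rec
            if rec.p <= alpha:
                survivors.append(g)
        alive = survivors

    # backward pruning against the final set
    for g in list(pc):
        others = [h for h in pc if h != g]
        removed = False
        for size in range(0, min(max_k, len(others)) + 1):
            for z in combinations(others, size):
                _, _, p = engine.test(target, g, z)
                if p > alpha:
                    pc.remove(g)
                    removed = True
                    break
            if removed:
                break

    stats_out: dict[str, CITestResult] = {}
    for g in pc:
        others = [h for h in pc if h != g]
        rec = None
        for size in range(0, min(max_k, len(others)) + 1):
            for z in combinations(others, size):
                rho, stat, p = engine.test(target, g, z)
                if rec is None or abs(stat) < abs(rec.stat):
                    rec = CITestResult(gene=g, z=z, rho=rho, stat=stat, p=p, n=n)
        stats_out[g] = rec
    return PCResult(pc_genes=pc, stats=stats_out, alpha=alpha, max_k=max_k)


def _skeleton(engine: _CIEngine, nodes: list[str], alpha: float,
              max_k: int) -> tuple[dict[str, set[str]], dict]:
    """PC-stable skeleton over ``nodes``: edges minus separable pairs."""
    adj = {v: set(nodes) - {v} for v in nodes}
    sepset: dict[tuple[str, str], tuple[str, ...]] = {}
    for depth in range(0, max_k + 1):
        snapshot = {v: set(adj[v]) for v in nodes}
        for x in nodes:
            for y in sorted(snapshot[x]):
                if y not in adj[x]:
                    continue
                pool = sorted(snapshot[x] - {y})
                if len(pool) < depth:
                    continue
                for z in combinations(pool, depth):
                    _, _, p = engine.test(x, y, z)
                    if p > alpha:
                        adj[x].discard(y)
                        adj[y].discard(x)
                        sepset[(x, y)] = z
                        sepset[(y, x)] = z
                        break
        if all(len(adj[v]) - 1 < depth + 1 for v in nodes):
            break
    return adj, sepset


def _orient(adj: dict[str, set[str]], sepset: dict,
            nodes: list[str]) -> set[tuple[str, str]]:
    """Collider orientation followed by Meek propagation rules R1-R3."""
    arrows: set[tuple[str, str]] = set()

    def directed(u, v):
        return (u, v) in arrows and (v, u) not in arrows

    def undirected(u, v):
        return v in adj[u] and (u, v) not in arrows and (v, u) not in arrows

    # v-structures: x - z - y with x, y non-adjacent and z outside sepset(x, y)
    for z in nodes:
        for x, y in combinations(sorted(adj[z]), 2):
            if y in adj[x]:
                continue
            if z not in sepset.get((x, y), ()):
                arrows.add((x, z))
                arrows.add((y, z))

    changed = True
    while changed:
        changed = False
        for a in nodes:
            for b in sorted(adj[a]):
                if not undirected(a, b):
                    continue
                # R1: c -> a, a - b, c and b non-adjacent  =>  a -> b
                if any(directed(c, a) and b not in adj[c] and c != b
                       for c in adj[a]):
                    arrows.add((a, b))
                    changed = True
                    continue
                # R2: a -> c -> b and a - b  =>  a -> b
                if any(directed(a, c) and directed(c, b)
                       for c in adj[a] & adj[b]):
                    arrows.add((a, b))
                    changed = True
                    continue
                # R3: a - c -> b, a - d -> b, c and d non-adjacent  =>  a -> b
                mids = [c for c in adj[a] & adj[b]
                        if undirected(a, c) and directed(c, b)]
                if any(d not in adj[c] for c, d in combinations(mids, 2)):
                    arrows.add((a, b))
                    changed = True
    return arrows


def orient_parents(response: pd.Series, pc_result: PCResult,
                   candidates: pd.DataFrame, alpha: float = 0.05,
                   max_k: int = 3) -> OrientationResult:
    """Distinguish parents from children among the response's PC genes.

    The local context is the response, its PC genes, and each PC gene's own
    PC set (discovered by MMPC with the response included as a candidate).
    A CI-test skeleton is learned over this context, v-structures are
    oriented, and orientations are propagated; PC genes with an edge
    oriented into the response are returned as parental. Edges whose
    orientation cannot be determined stay undirected -- a lone PC gene with
    no collider evidence is reported as such, never forced.
    """
    if not pc_result.pc_genes:
        return OrientationResult(parental_genes=[], edges=pd.DataFrame(
            columns=["source", "target", "orientation", "stat"]))

    order = _candidate_order(response, candidates)
    engine = _build_engine(response, candidates, order)

    context: set[str] = set(pc_result.pc_genes)
    for g in pc_result.pc_genes:
        # candidates for g's own PC set: the response plus all other genes,
        # ordered by |marginal correlation| with g for determinism
        others = [RESPONSE] + [h for h in order if h != g]
        gi = engine.index[g]
        others.sort(key=lambda h: (-abs(engine.corr[gi, engine.index[h]]), h))
        sub = _mmpc_on_engine(engine, g, others, alpha, max_k)
        context |= set(sub.pc_genes) - {RESPONSE}
    nodes = [RESPONSE] + sorted(context)

    adj, sepset = _skeleton(engine, nodes, alpha, max_k)
    arrows = _orient(adj, sepset, nodes)

    def is_directed(u, v):
        return (u, v) in arrows and (v, u) not in arrows

    rows = []
    seen = set()
    for u in nodes:
        for v in sorted(adj[u]):
            if (v, u) in seen:
                continue
            seen.add((u, v))
            if is_directed(u, v):
                s, t, o = u, v, "->"
            elif is_directed(v, u):
                s, t, o = v, u, "->"
            else:
                s, t, o = u, v, "--"
            stat = np.nan
            if RESPONSE in (s, t):
                g = t if s == RESPONSE else s
                if g in pc_result.stats:
                    stat = pc_result.stats[g].stat
            rows.append((s, t, o, stat))
    edges = pd.DataFrame(rows, columns=["source", "target", "orientation", "stat"])
    parental = [g for g in pc_result.pc_genes if is_directed(g, RESPONSE)]
    return OrientationResult(parental_genes=parental, edges=edges,
                             skeleton_nodes=nodes)


#: directionality labels against AUC (higher AUC = less sensitive)
LABEL_RESISTANCE = "high expression -> resistance"
LABEL_SENSITIVITY = "high expression -> sensitivity"


def biomarker_report(filter_result: pd.DataFrame, pc_result: PCResult,
                     oriented: OrientationResult | None = None,
                     drug: str = "") -> pd.DataFrame:
    """Tidy per-gene biomarker table for one drug.

    One row per gene retained by the Spearman filter: correlation,
    FDR q, PC membership, the signed statistic of its weakest surviving CI
    test, the parental call, and a direction label -- a positive statistic
    against AUC means high expression tracks *resistance* (higher AUC,
    less sensitive), a negative one sensitivity.
    """
    retained = filter_result[filter_result["retained"]].copy()
    pc_set = set(pc_result.pc_genes)
    parents = set(oriented.parental_genes) if oriented is not None else set()

    def stat_of(g):
        rec = pc_result.stats.get(g)
        return rec.stat if rec is not None else np.nan

    retained["drug"] = drug
    retained["is_pc"] = retained["gene"].isin(pc_set)
    retained["stat"] = retained["gene"].map(stat_of)
    retained["is_parent"] = retained["gene"].isin(parents)
    retained["direction"] = [
        (LABEL_RESISTANCE if s > 0 else LABEL_SENSITIVITY) if pc and np.isfinite(s)
        else ""
        for pc, s in zip(retained["is_pc"], retained["stat"])
    ]
    cols = ["drug", "gene", "r", "p", "q", "is_pc", "stat", "is_parent", "direction"]
    return retained[cols].reset_index(drop=True)
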