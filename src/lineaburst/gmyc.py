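"""General mixed Yule-coalescent (GMYC) species delimitation.

The model assumes an ultrametric gene tree in which branching older than a
threshold age T reflects speciation (a generalized Yule process) and
branching younger than T reflects within-species coalescence. Successive
branching events delimit waiting intervals; during interval i the total
branching rate is

    b_i = lambda1 * k_i**p1 + lambda2 * sum_j [n_ij * (n_ij - 1)]**p2

where k_i counts the species-level lineages in interval i — every
observed lineage above the threshold, plus one persisting (unobserved)
species lineage for each coalescent group below it — and n_ij counts
lineages within coalescent group j (a subtree crossing T). Waiting
intervals are delimited by the branching events plus the threshold
itself, so each interval lies wholly on one side of every local
threshold, and k_i >= 1 always. The log-likelihood is

    sum_events ln b_(i-1)  -  sum_i b_i * x_i

with each event priced by the combined rate of the interval it ends
(the crown is conditioned on and carries no event term). The combined-
rate event term is what lets a model with many small coalescent groups
compete fairly against one pooled group. The null model is the
degenerate case with T younger than every node (diversification only);
at that threshold the mixed likelihood reduces to the null likelihood
exactly.

Tips of a subtree crossing T form one delimited entity (putative
species); entities with a single tip are singletons, those with two or
more are clusters.

Fitting profiles the threshold over midpoints between consecutive
distinct node ages plus the two degenerate extremes (older than the
root: one entity; younger than every node: all singletons). Per
candidate the four continuous parameters are optimized by seeded
multi-start L-BFGS-B (rates in log space, exponents box-bounded); the
single-process degenerate cases profile out their rate in closed form
and reduce to a concave 1-D problem solved exactly.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .treekit import Chronogram

logger = logging.getLogger(__name__)

__all__ = [
    "GmycFit",
    "gmyc_loglik",
    "fit_gmyc_single",
    "fit_gmyc_multiple",
    "lr_test",
]

DEFAULT_EXPONENT_BOUNDS = (1e-3, 3.0)
_LOG_RATE_BOUNDS = (-30.0, 12.0)


class _TreeIndex:
    """Flat arrays over the nodes of a chronogram (preorder)."""

    def __init__(self, ch: Chronogram):
        nodes = list(ch.tree.preorder_node_iter())
        self.nodes = nodes
        self.n = len(nodes)
        pos = {id(nd): i for i, nd in enumerate(nodes)}
        self.age = np.array([nd.age for nd in nodes])
        self.is_tip = np.array([nd.is_leaf() for nd in nodes])
        self.parent = np.array([
            pos[id(nd.parent_node)] if nd.parent_node is not None else -1
            for nd in nodes])
        self.parent_age = np.where(
            self.parent >= 0, self.age[self.parent], -np.inf)
        self.labels = [Chronogram._label(nd) if nd.is_leaf() else None
                       for nd in nodes]
        self.exit = np.empty(self.n, dtype=int)

        def fill(idx_node, nd):
            last = idx_node
            for c in nd.child_nodes():
                last = fill(pos[id(c)], c)
            self.exit[idx_node] = last
            return last

        fill(0, nodes[0])
        internal_idx = np.flatnonzero(~self.is_tip)
        order = np.argsort(self.age[internal_idx])[::-1]
        self.events = internal_idx[order]  # crown first

    def subtree(self, v: int) -> np.ndarray:
        return np.arange(v, self.exit[v] + 1)

    def tips_under(self, v: int) -> list[str]:
        sub = self.subtree(v)
        return [self.labels[i] for i in sub if self.is_tip[i]]


def _classify(idx: _TreeIndex, t_loc: np.ndarray):
    """Per-branch process assignment given per-node local thresholds.

    Returns (yule_branch, group) where ``group[v]`` is the index of the
    subtree-root branch of v's coalescent group (-1 for diversification
    branches). When both root children are coalescent the two sides merge
    into a single root-spanning group (threshold older than the root).
    """
    yule_branch = (~idx.is_tip) & (idx.age > t_loc)
    yule_branch[0] = False  # root has no branch
    group = np.full(idx.n, -1, dtype=int)
    root_children = np.flatnonzero(idx.parent == 0)
    merge_root = all(not yule_branch[c] for c in root_children)
    for v in range(1, idx.n):
        if yule_branch[v]:
            continue
        p = idx.parent[v]
        if p == 0:
            group[v] = 0 if merge_root else v
        elif group[p] != -1:
            group[v] = group[p]
        else:
            group[v] = v
    return yule_branch, group


@dataclass
class _IntervalTable:
    """Sufficient statistics of the interval decomposition at one
    threshold configuration."""

    x: np.ndarray             # interval durations, oldest interval first
    logk: np.ndarray          # ln k_i (-inf where k_i = 0)
    coal_idx: np.ndarray      # interval index of each active group (>= 2)
    coal_logprod: np.ndarray  # ln[c (c-1)] for that group in that interval
    ev_rate_idx: np.ndarray   # interval whose total rate prices each event
    n_yule_events: int
    n_coal_events: int

    @property
    def n_events(self) -> int:
        return len(self.ev_rate_idx)

    def rate_vector(self, lambda1, p1, lambda2, p2) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            b = lambda1 * np.exp(p1 * self.logk)
        b = np.nan_to_num(b, nan=0.0, posinf=np.inf)
        if len(self.coal_idx):
            b = b + lambda2 * np.bincount(
                self.coal_idx,
                weights=np.exp(p2 * self.coal_logprod),
                minlength=len(self.x))
        return b

    def loglik(self, lambda1, p1, lambda2, p2) -> float:
        b = self.rate_vector(lambda1, p1, lambda2, p2)
        ev_b = b[self.ev_rate_idx]
        if np.any(ev_b <= 0) or not np.all(np.isfinite(b)):
            return -np.inf
        return float(np.sum(np.log(ev_b)) - np.dot(b, self.x))


def _interval_table(idx: _TreeIndex, t_loc: np.ndarray) -> _IntervalTable:
    _, group = _classify(idx, t_loc)
    ev = idx.events
    ev_ages = idx.age[ev]
    crown = ev_ages[0]
    thr = np.unique(t_loc)
    thr = thr[(thr > 0) & (thr < crown)]
    bounds = np.unique(np.concatenate((ev_ages, thr)))[::-1]  # desc
    lowers = np.append(bounds[1:], 0.0)
    mids = (bounds + lowers) / 2.0
    x = bounds - lowers
    n_int = len(bounds)
    span = (idx.age[None, :] < mids[:, None]) & \
           (idx.parent_age[None, :] > mids[:, None])
    # a lineage belongs to the diversification process during interval i iff
    # that interval lies above its local threshold (intervals never straddle
    # a threshold); below, each group persists as one species lineage
    above = mids[:, None] > t_loc[None, :]
    k_above = (span & above).sum(axis=1)
    coal_mask = span & ~above & (group[None, :] != -1)
    counts = np.zeros((n_int, idx.n), dtype=int)
    for i in range(n_int):
        rows = group[coal_mask[i]]
        if len(rows):
            counts[i] = np.bincount(rows, minlength=idx.n)
    k = k_above + (counts >= 1).sum(axis=1)
    coal_idx, coal_logprod = [], []
    for i in range(n_int):
        c = counts[i][counts[i] >= 2]
        if len(c):
            coal_idx.extend([i] * len(c))
            coal_logprod.extend(np.log(c * (c - 1.0)))
    pos_of = {float(b): i for i, b in enumerate(bounds)}
    ev_rate_idx = []
    n_yule_ev = n_coal_ev = 0
    for w, a in zip(ev[1:], ev_ages[1:]):  # crown is conditioned on, no term
        j = pos_of[float(a)]
        if k[j - 1] < 1:
            raise AssertionError("branching event in empty interval")
        ev_rate_idx.append(j - 1)       # price by the interval the event ends
        if a > t_loc[w]:
            n_yule_ev += 1
        else:
            n_coal_ev += 1
    with np.errstate(divide="ignore"):
        logk = np.log(k.astype(float))
    return _IntervalTable(
        x=x, logk=logk,
        coal_idx=np.asarray(coal_idx, dtype=int),
        coal_logprod=np.asarray(coal_logprod),
        ev_rate_idx=np.asarray(ev_rate_idx, dtype=int),
        n_yule_events=n_yule_ev, n_coal_events=n_coal_ev)


def _profile_single_process(n_ev: int, sum_log_ev: float,
                            surv_logv: np.ndarray, surv_x: np.ndarray,
                            bounds) -> tuple[float, float, float]:
    """Exact fit of a one-component model: maximize over (rate, exponent)
    after profiling the rate in closed form; the 1-D objective
    n ln(n/A(p)) + p*S - n is concave (A is a positive sum of
    exponentials in p). Returns (rate_hat, p_hat, logL)."""
    if n_ev == 0:
        return 0.0, 1.0, 0.0

    def negh(p):
        A = float(np.dot(surv_x, np.exp(p * surv_logv)))
        return -(n_ev * np.log(n_ev / A) + p * sum_log_ev - n_ev)

    res = minimize_scalar(negh, bounds=bounds, method="bounded",
                          options={"xatol": 1e-10})
    p_hat = min((float(res.x), bounds[0], bounds[1]), key=negh)
    A = float(np.dot(surv_x, np.exp(p_hat * surv_logv)))
    return n_ev / A, p_hat, -negh(p_hat)


def _fit_table(table: _IntervalTable, bounds, n_restarts: int = 5,
               seed: int = 0):
    """ML fit of (lambda1, p1, lambda2, p2) for one interval table."""
    if len(table.coal_idx) == 0:  # single-process (diversification only)
        ev_logk = table.logk[table.ev_rate_idx]
        l1, p1, ll = _profile_single_process(
            table.n_events, float(ev_logk.sum()),
            table.logk, table.x, bounds)
        return (l1, p1, 0.0, 1.0), ll

    # mixed model: seeded multi-start L-BFGS-B over (ln l1, p1, ln l2, p2)
    A1 = float(np.dot(table.x, np.exp(table.logk)))
    A2 = float(np.dot(
        np.bincount(table.coal_idx, weights=np.exp(table.coal_logprod),
                    minlength=len(table.x)), table.x))
    l1_0 = max(table.n_yule_events, 1) / max(A1, 1e-12)
    l2_0 = max(table.n_coal_events, 1) / max(A2, 1e-12)
    z0 = np.array([np.log(l1_0), 1.0, np.log(l2_0), 1.0])
    rng = np.random.default_rng(seed)
    box = [_LOG_RATE_BOUNDS, bounds, _LOG_RATE_BOUNDS, bounds]

    def neg(z):
        return -table.loglik(np.exp(z[0]), z[1], np.exp(z[2]), z[3])

    def clip(z):
        return np.array([np.clip(v, lo, hi) for v, (lo, hi) in zip(z, box)])

    starts = [z0]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(clip(z0 + rng.normal(0, [1.0, 0.5, 1.0, 0.5])))
    best = None
    for z_start in starts:
        res = minimize(neg, z_start, method="L-BFGS-B", bounds=box)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("GMYC optimizer failed on all restarts "
                           f"({n_restarts} starts)")
    z = best.x
    params = (float(np.exp(z[0])), float(z[1]),
              float(np.exp(z[2])), float(z[3]))
    return params, -float(best.fun)


def gmyc_loglik(chronogram: Chronogram, threshold: float,
                lambda1: float, p1: float,
                lambda2: float, p2: float) -> float:
    """GMYC log-likelihood at fixed threshold and process parameters."""
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("rates must be nonnegative")
    if threshold < 0:
        raise ValueError("threshold age must be >= 0")
    idx = _TreeIndex(chronogram)
    t_loc = np.full(idx.n, float(threshold))
    table = _interval_table(idx, t_loc)
    return table.loglik(lambda1, p1, lambda2, p2)


def _threshold_candidates(idx: _TreeIndex) -> np.ndarray:
    ages = np.unique(idx.age[~idx.is_tip])[::-1]  # desc
    mids = (ages[:-1] + ages[1:]) / 2.0
    low = ages[-1] / 2.0
    high = ages[0] * 1.01 + 1.0
    return np.concatenate(([high], mids, [low]))


def _entities(idx: _TreeIndex, t_loc: np.ndarray) -> list[list[str]]:
    _, group = _classify(idx, t_loc)
    roots: list[int] = []
    seen = set()
    for v in range(idx.n):
        g = group[v]
        if g != -1 and g not in seen:
            seen.add(g)
            roots.append(g)
    return [idx.tips_under(g) if g != 0 else
            [lab for lab in idx.labels if lab is not None] for g in roots]


@dataclass
class GmycFit:
    """Result of a GMYC fit: threshold(s), process parameters, entities."""

    method: str
    thresholds: list[float]
    lambda1: float
    p1: float
    lambda2: float
    p2: float
    logL_alt: float
    logL_null: float
    lambda0: float
    p0: float
    entities: list[list[str]] = field(repr=False)
    n_entities: int = 0
    n_clusters: int = 0
    lr_stat: float = 0.0
    lr_p: float = 1.0
    df: int = 3

    @property
    def n_singletons(self) -> int:
        return self.n_entities - self.n_clusters

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "thresholds": [float(t) for t in self.thresholds],
            "lambda1": self.lambda1, "p1": self.p1,
            "lambda2": self.lambda2, "p2": self.p2,
            "logL_alt": self.logL_alt, "logL_null": self.logL_null,
            "lambda0": self.lambda0, "p0": self.p0,
            "n_entities": self.n_entities, "n_clusters": self.n_clusters,
            "lr_stat": self.lr_stat, "lr_p": self.lr_p, "df": self.df,
            "entities": self.entities,
        }


def _make_fit(method, idx, t_loc, thresholds, params, ll_alt, null,
              df) -> GmycFit:
    lambda0, p0, ll_null = null
    ents = _entities(idx, t_loc)
    stat, p = lr_test(ll_null, ll_alt, df)
    n_clusters = sum(1 for e in ents if len(e) >= 2)
    return GmycFit(
        method=method, thresholds=list(thresholds),
        lambda1=params[0], p1=params[1], lambda2=params[2], p2=params[3],
        logL_alt=ll_alt, logL_null=ll_null, lambda0=lambda0, p0=p0,
        entities=ents, n_entities=len(ents), n_clusters=n_clusters,
        lr_stat=stat, lr_p=p, df=df)


def fit_gmyc_single(chronogram: Chronogram,
                    exponent_bounds=DEFAULT_EXPONENT_BOUNDS,
                    n_restarts: int = 5,
                    seed: int | None = None) -> GmycFit:
    """Maximum-likelihood single-threshold GMYC fit.

    Thresholds are profiled over midpoints between consecutive distinct
    node ages plus the degenerate extremes; per candidate the four
    continuous parameters are fitted by seeded multi-start L-BFGS-B. The
    null (single-process) model is the degenerate threshold younger than
    every node, fitted exactly by its concave profile likelihood; the
    likelihood-ratio test against it uses df = 3 by convention.
    """
    if chronogram.n_tips < 3:
        raise ValueError("GMYC fit needs at least 3 tips")
    idx = _TreeIndex(chronogram)
    candidates = _threshold_candidates(idx)
    fit_seed = 0 if seed is None else int(seed)
    best = None
    null = None
    for ci, T in enumerate(candidates):
        t_loc = np.full(idx.n, float(T))
        table = _interval_table(idx, t_loc)
        params, ll = _fit_table(table, exponent_bounds,
                                n_restarts=n_restarts, seed=fit_seed)
        if ci == len(candidates) - 1:  # degenerate low extreme == null
            null = (params[0], params[1], ll)
        if best is None or ll > best[0]:
            best = (ll, T, params, t_loc)
    ll_alt, T_best, params, t_loc = best
    return _make_fit("single", idx, t_loc, [T_best], params, ll_alt, null, 3)


def fit_gmyc_multiple(chronogram: Chronogram, max_thresholds: int = 10,
                      exponent_bounds=DEFAULT_EXPONENT_BOUNDS,
                      n_restarts: int = 5,
                      seed: int | None = None) -> GmycFit:
    """Greedy stepwise multiple-threshold GMYC fit.

    Starts from the single-threshold optimum; each coalescent group gets a
    ladder of local threshold candidates (midpoints between its internal
    node ages, from "keep whole" down to "all singletons"). One move
    shifts one group's local threshold to an adjacent rung; the move with
    the best AIC improvement is accepted until none improves or the number
    of distinct thresholds would exceed ``max_thresholds``. The search is
    greedy, not exhaustive, and is documented as an approximation.
    """
    single = fit_gmyc_single(chronogram, exponent_bounds=exponent_bounds,
                             n_restarts=n_restarts, seed=seed)
    idx = _TreeIndex(chronogram)
    fit_seed = 0 if seed is None else int(seed)
    T_star = single.thresholds[0]
    base_t_loc = np.full(idx.n, float(T_star))
    _, group = _classify(idx, base_t_loc)
    group_roots = sorted({int(g) for g in group if g != -1})

    ladders: dict[int, np.ndarray] = {}
    for g in group_roots:
        sub = idx.subtree(g) if g != 0 else np.arange(idx.n)
        ages = np.unique(idx.age[sub][~idx.is_tip[sub]])[::-1]
        if len(ages) == 0:
            continue
        top_ref = idx.parent_age[g] if g != 0 else idx.age[0] * 1.01 + 1.0
        top = (ages[0] + top_ref) / 2.0
        mids = (ages[:-1] + ages[1:]) / 2.0
        ladders[g] = np.concatenate(([top], mids, [ages[-1] / 2.0]))

    state = {g: 0 for g in ladders}

    def build_t_loc(st) -> np.ndarray:
        t_loc = np.full(idx.n, float(T_star))
        for g, pos in st.items():
            sub = idx.subtree(g) if g != 0 else np.arange(idx.n)
            t_loc[sub] = ladders[g][pos]
        return t_loc

    def evaluate(st):
        t_loc = build_t_loc(st)
        table = _interval_table(idx, t_loc)
        params, ll = _fit_table(table, exponent_bounds,
                                n_restarts=n_restarts, seed=fit_seed)
        moved = {round(float(ladders[g][pos]), 12)
                 for g, pos in st.items() if pos > 0}
        n_params = 5 + len(moved)
        return ll, params, t_loc, n_params, -2.0 * ll + 2.0 * n_params

    ll, params, t_loc, n_params, aic = evaluate(state)
    for _ in range(100):
        proposals = []
        for g in state:
            for step in (-1, 1):
                pos = state[g] + step
                if not 0 <= pos < len(ladders[g]):
                    continue
                cand = dict(state)
                cand[g] = pos
                res = evaluate(cand)
                if res[3] - 4 > max_thresholds:
                    continue
                proposals.append((res[4], g, pos, res))
        if not proposals:
            break
        proposals.sort(key=lambda p: p[0])
        best_aic, g, pos, res = proposals[0]
        if best_aic >= aic - 1e-9:
            break
        state[g] = pos
        ll, params, t_loc, n_params, aic = res

    if ll < single.logL_alt - 1e-6:  # defensive: never worse than the start
        logger.warning("multiple-threshold search fell below the single-"
                       "threshold optimum; returning the single solution")
        return GmycFit(**{**single.__dict__, "method": "multiple"})
    thresholds = sorted({round(float(v), 12) for v in
                         [ladders[g][pos] for g, pos in state.items()
                          if pos > 0] + ([T_star] if any(
                              pos == 0 for pos in state.values()) else [])},
                        reverse=True)
    null = (single.lambda0, single.p0, single.logL_null)
    return _make_fit("multiple", idx, t_loc, thresholds, params, ll, null,
                     n_params - 2)


def lr_test(logL_null: float, logL_alt: float, df: int,
            statistic: float | None = None) -> tuple[float, float]:
    """Likelihood-ratio test with an upper-tail chi-square p-value.

    ``statistic`` overrides 2*(logL_alt - logL_null) when a precomputed
    value is supplied. Negative statistics are clamped to 0 with a warning.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (logL_alt - logL_null) if statistic is None else statistic
    if stat < 0:
        warnings.warn(f"negative LR statistic {stat:.3g} clamped to 0")
        stat = 0.0
    return float(stat), float(chi2.sf(stat, df))
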