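"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as plainly as possible (site-by-site loops,
explicit interval enumeration over dendropy nodes) and shares no code
with the package internals it checks.
"""
from __future__ import annotations

import math

from scipy.optimize import brentq, minimize_scalar

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def k2p_brute(seq_a: str, seq_b: str):
    """(d, P, Q, m) by explicit per-site classification; d None if saturated."""
    m = s = v = 0
    for ca, cb in zip(seq_a.upper(), seq_b.upper()):
        if ca not in "ACGT" or cb not in "ACGT":
            continue
        m += 1
        if ca == cb:
            continue
        same_class = (ca in PURINES) == (cb in PURINES)
        if same_class:
            s += 1
        else:
            v += 1
    if m == 0:
        raise ZeroDivisionError("no overlap")
    P, Q = s / m, v / m
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return None, P, Q, m
    return -0.5 * math.log(w1) - 0.25 * math.log(w2), P, Q, m


def gmyc_loglik_brute(chronogram, T, lam1, p1, lam2, p2):
    """GMYC log-likelihood by naive interval enumeration.

    Walks dendropy nodes directly: for every inter-boundary interval
    (successive node ages plus the threshold) it recomputes, from
    scratch, which branches are present, which are species-level, and the
    per-group lineage counts; each non-crown node is priced by the total
    rate of the interval it terminates.
    """
    tree = chronogram.tree
    nodes = list(tree.preorder_node_iter())
    root = tree.seed_node

    # coalescent groups: maximal branches with child age <= T
    group_of_branch = {}
    merge_root = all(c.age <= T for c in root.child_nodes())
    for nd in nodes:
        if nd is root:
            continue
        anc_chain = []
        cur = nd
        while cur is not root:
            anc_chain.append(cur)
            cur = cur.parent_node
        # highest ancestor (incl. self) with age <= T defines the group
        group_root = None
        for cand in reversed(anc_chain):
            if cand.age <= T:
                group_root = cand
                break
        if group_root is not None and merge_root:
            group_root = root
        group_of_branch[id(nd)] = group_root

    internal_ages = sorted({nd.age for nd in nodes if not nd.is_leaf()},
                           reverse=True)
    crown = internal_ages[0]
    boundaries = sorted({a for a in internal_ages} |
                        ({T} if 0 < T < crown else set()), reverse=True)
    boundaries.append(0.0)

    def interval_state(hi, lo):
        mid = (hi + lo) / 2
        present = [nd for nd in nodes
                   if nd is not root and nd.age < mid < nd.parent_node.age]
        k = sum(1 for nd in present if mid > T)
        groups = {}
        for nd in present:
            if mid <= T:
                g = group_of_branch[id(nd)]
                groups.setdefault(id(g), 0)
                groups[id(g)] += 1
        k += sum(1 for c in groups.values() if c >= 1)
        coal = sum((c * (c - 1)) ** p2 for c in groups.values() if c >= 2)
        return lam1 * k ** p1 + lam2 * coal

    logL = 0.0
    for hi, lo in zip(boundaries[:-1], boundaries[1:]):
        b = interval_state(hi, lo)
        logL -= b * (hi - lo)
        ending_nodes = [nd for nd in nodes
                        if (not nd.is_leaf()) and nd is not root
                        and nd.age == lo]
        for _ in ending_nodes:
            if b <= 0:
                return -math.inf
            logL += math.log(b)
    return logL


def pure_birth_mle_numeric(branching_times):
    """Numeric maximizer of the pure-birth log-likelihood."""
    n = branching_times.n
    S = branching_times.lineage_time()

    def neg(lam):
        return -((n - 2) * math.log(lam) - lam * S)

    res = minimize_scalar(neg, bounds=(1e-8, 1e4), method="bounded",
                          options={"xatol": 1e-12})
    lam = float(res.x)
    # a pure function-value search cannot resolve the optimum beyond
    # ~sqrt(eps) relative; polish by locating the zero of the numerical
    # central-difference gradient, which is much sharper
    h = 1e-5 * lam

    def grad(x):
        return (neg(x + h) - neg(x - h)) / (2 * h)

    lo, hi = 0.9 * lam, 1.1 * lam
    lam = brentq(grad, lo, hi, xtol=1e-13 * lam)
    return float(lam), -neg(lam)
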