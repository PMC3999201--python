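"""Seeded generators for every synthetic input the analysis consumes.

The simulators mirror the statistical structure the downstream methods
assume, with known ground truth:

* :func:`sim_yule` — constant-rate pure-birth chronograms conditioned on a
  tip count (the rate-constant null used to calibrate shift detection).
* :func:`sim_yule_shift` — pure-birth with piecewise-constant speciation
  rates on fixed ages before present (truth for rate-shift recovery).
* :func:`sim_bd` — constant birth-death, reconstructed (extinct lineages
  pruned), conditioned on the number of survivors by rejection.
* :func:`sim_species_coalescent` — gene trees from within-species Kingman
  coalescents along a Yule species tree (the mixed Yule/coalescent regime
  the GMYC delimitation model targets).
* :func:`sim_sequences` — GTR+Gamma sequence evolution along a chronogram,
  optionally masking terminal runs with N to emulate partial-length
  fragments.

Determinism: identical (configuration, seed) yields bit-identical output.

Time convention: "present" for a tree conditioned on n tips is the instant
the (n+1)-th lineage would appear, so the final interval with n lineages
has its natural exponential length.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .seqdist import Alignment
from .treekit import Chronogram

__all__ = [
    "SimConfig",
    "sim_yule",
    "sim_yule_shift",
    "sim_bd",
    "sim_species_coalescent",
    "sim_sequences",
]


@dataclass
class SimConfig:
    """Simulation knobs with study-scale defaults.

    Rates are in events per lineage per Myr, ages in Myr before present.
    The defaults describe a Hyalospheniidae-like regime: a slow background
    speciation rate with a recent acceleration at 7 Myr, ten species
    sampled four times each with within-species coalescence two orders of
    magnitude faster than the species splits, and COI-length fragments
    under GTR+Gamma with a mild transition bias.
    """

    seed: int = 0
    n_tips: int = 100
    rates: list[float] = field(default_factory=lambda: [0.05, 0.5])
    shift_ages: list[float] = field(default_factory=lambda: [7.0])
    extinction_rate: float = 0.0
    n_species: int = 10
    species_tree_rate: float = 0.05
    samples_per_species: int = 4
    coalescent_scale: float = 0.05
    seq_length: int = 600
    gtr_exchangeabilities: list[float] = field(
        default_factory=lambda: [1.0, 4.0, 1.0, 1.0, 4.0, 1.0])
    base_freqs: list[float] = field(
        default_factory=lambda: [0.30, 0.17, 0.15, 0.38])
    gamma_shape: float = 0.5
    n_gamma_cats: int = 4
    n_mask_fraction: float = 0.0

    def validate(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if any(r <= 0 for r in self.rates):
            raise ValueError("all rates must be > 0")
        sa = list(self.shift_ages)
        if sa and (any(a <= 0 for a in sa)
                   or any(a >= b for a, b in zip(sa[1:], sa[:-1]))):
            raise ValueError("shift_ages must be strictly decreasing and > 0")
        if len(self.rates) != len(sa) + 1:
            raise ValueError("need len(rates) == len(shift_ages) + 1")
        if self.extinction_rate < 0:
            raise ValueError("extinction_rate must be >= 0")
        if abs(sum(self.base_freqs) - 1.0) > 1e-12:
            raise ValueError("base_freqs must sum to 1")
        if len(self.base_freqs) != 4 or any(f < 0 for f in self.base_freqs):
            raise ValueError("base_freqs must be 4 nonnegative probabilities")
        if len(self.gtr_exchangeabilities) != 6 or \
                any(x < 0 for x in self.gtr_exchangeabilities):
            raise ValueError("need 6 nonnegative GTR exchangeabilities")
        if self.gamma_shape <= 0 or self.n_gamma_cats < 1:
            raise ValueError("gamma_shape must be > 0 and n_gamma_cats >= 1")
        if self.seq_length <= 0:
            raise ValueError("seq_length must be > 0")
        if not 0 <= self.n_mask_fraction < 1:
            raise ValueError("n_mask_fraction must be in [0, 1)")


class _Pending:
    """A lineage still alive during forward growth of a pure-birth tree."""

    __slots__ = ("children", "age", "_tip_label")

    def __init__(self):
        self.children: list["_Pending"] | None = None
        self.age: float | None = None
        self._tip_label: str | None = None


def _grow_conditioned(event_ages: np.ndarray,
                      rng: np.random.Generator) -> Chronogram:
    """Build a chronogram from event ages (crown first) with uniform splits."""
    root = _Pending()
    root.age = float(event_ages[0])
    a, b = _Pending(), _Pending()
    root.children = [a, b]
    active = [a, b]
    for age in event_ages[1:]:
        idx = int(rng.integers(len(active)))
        nd = active[idx]
        nd.age = float(age)
        nd.children = [_Pending(), _Pending()]
        active[idx] = nd.children[0]
        active.append(nd.children[1])
    labels = iter(f"T{i + 1}" for i in range(len(active)))
    for tip in active:
        tip.age = 0.0
    return _pending_to_chronogram(root, labels)


def _pending_to_chronogram(root: _Pending, labels) -> Chronogram:
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(p: _Pending, parent_age: float | None) -> dendropy.Node:
        nd = dendropy.Node()
        if parent_age is not None:
            nd.edge.length = parent_age - p.age
        if p.children is None:
            nd.taxon = taxa.new_taxon(label=next(labels))
        else:
            for c in p.children:
                nd.add_child(build(c, p.age))
        return nd

    tree.seed_node = build(root, None)
    return Chronogram(tree)


def _yule_event_ages(n_tips: int, rate: float,
                     rng: np.random.Generator) -> np.ndarray:
    # waits w_k ~ Exp(k * rate) for k = 2..n; t_k = sum_{j>=k} w_j
    k = np.arange(2, n_tips + 1)
    waits = rng.exponential(1.0 / (k * rate))
    return np.cumsum(waits[::-1])[::-1]


def sim_yule(n_tips: int, rate: float, seed: int | None = None,
             rng: np.random.Generator | None = None) -> Chronogram:
    """Constant-rate pure-birth chronogram conditioned on ``n_tips``.

    Inter-event waits with k lineages are Exp(k * rate); the present is
    the instant the (n+1)-th lineage would appear. Topology grows by
    uniform random splits.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    ages = _yule_event_ages(n_tips, rate, rng)
    ch = _grow_conditioned(ages, rng)
    ch.info.update({"model": "yule", "rate": rate})
    return ch


def _piecewise_cumrate(rates, shift_ages):
    """Knots of the cumulative rate Lambda(a) = int_0^a lambda(s) ds."""
    # shift_ages strictly decreasing; epochs young -> old for integration
    bounds = [0.0] + list(reversed(shift_ages))
    r_young_to_old = list(reversed(rates))
    cum = [0.0]
    for i in range(1, len(bounds)):
        cum.append(cum[-1] + r_young_to_old[i - 1] * (bounds[i] - bounds[i - 1]))
    return np.array(bounds), np.array(cum), r_young_to_old[-1]


def sim_yule_shift(n_tips: int, rates: list[float], shift_ages: list[float],
                   seed: int | None = None,
                   rng: np.random.Generator | None = None) -> Chronogram:
    """Piecewise-constant pure-birth chronogram conditioned on ``n_tips``.

    ``rates[0]`` applies to ages older than ``shift_ages[0]`` and
    ``rates[-1]`` to the youngest epoch; boundaries are fixed ages before
    present. Simulated by time rescaling: a rate-1 conditioned Yule is
    drawn in transformed time u = Lambda(age) and event ages are mapped
    back through the piecewise-linear inverse, so equal rates reduce
    exactly to :func:`sim_yule`.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if any(r <= 0 for r in rates):
        raise ValueError("all rates must be > 0")
    sa = list(shift_ages)
    if any(a <= 0 for a in sa) or any(x >= y for x, y in zip(sa[1:], sa[:-1])):
        raise ValueError("shift_ages must be strictly decreasing and positive")
    if len(rates) != len(sa) + 1:
        raise ValueError("need len(rates) == len(shift_ages) + 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    u_ages = _yule_event_ages(n_tips, 1.0, rng)
    age_knots, cum_knots, oldest_rate = _piecewise_cumrate(rates, sa)
    ages = np.where(
        u_ages <= cum_knots[-1],
        np.interp(u_ages, cum_knots, age_knots),
        age_knots[-1] + (u_ages - cum_knots[-1]) / oldest_rate)
    ch = _grow_conditioned(ages, rng)
    ch.info.update({"model": "yule_shift", "rates": list(rates),
                    "shift_ages": sa})
    return ch


class _BDLineage:
    __slots__ = ("parent", "birth", "death", "children")

    def __init__(self, parent, birth):
        self.parent = parent
        self.birth = birth
        self.death = None  # None = alive
        self.children: list["_BDLineage"] = []


def _sim_bd_once(n_tips, birth_rate, death_rate, rng):
    """One forward Gillespie attempt; None if extinct before reaching n+1."""
    root = _BDLineage(None, 0.0)
    c1, c2 = _BDLineage(root, 0.0), _BDLineage(root, 0.0)
    root.children = [c1, c2]
    root.death = 0.0
    alive = [c1, c2]
    t = 0.0
    total = birth_rate + death_rate
    while True:
        t += rng.exponential(1.0 / (len(alive) * total))
        idx = int(rng.integers(len(alive)))
        if rng.random() < birth_rate / total:
            if len(alive) == n_tips:
                return root, alive, t  # present: just before this birth
            parent = alive[idx]
            parent.death = t
            kids = [_BDLineage(parent, t), _BDLineage(parent, t)]
            parent.children = kids
            alive[idx] = kids[0]
            alive.append(kids[1])
        else:
            lin = alive.pop(idx)
            lin.death = t
            if not alive:
                return None


def sim_bd(n_tips: int, birth_rate: float, death_rate: float,
           seed: int | None = None, rng: np.random.Generator | None = None,
           max_attempts: int = 100_000) -> Chronogram:
    """Reconstructed constant birth-death chronogram with ``n_tips`` survivors.

    Forward Gillespie simulation from the crown; a replicate is accepted
    at the first instant a birth would raise the survivor count to
    n_tips + 1 (that instant is the present), and rejected if the clade
    dies first. Extinct lineages are pruned; the returned tree is the
    reconstructed process.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not birth_rate > death_rate >= 0:
        raise ValueError("need birth_rate > death_rate >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        out = _sim_bd_once(n_tips, birth_rate, death_rate, rng)
        if out is None:
            continue
        root, alive, present = out
        ch = _bd_reconstruct(root, alive, present)
        ch.info.update({"model": "bd", "birth_rate": birth_rate,
                        "death_rate": death_rate})
        return ch
    raise RuntimeError(
        f"no surviving birth-death replicate in {max_attempts} attempts")


def _bd_reconstruct(root, alive, present) -> Chronogram:
    alive_set = set(map(id, alive))

    def survives(lin) -> bool:
        if id(lin) in alive_set:
            return True
        return any(survives(c) for c in lin.children)

    def build(lin) -> _Pending | None:
        """Collapse to the reconstructed tree of surviving lineages."""
        if id(lin) in alive_set:
            tip = _Pending()
            tip.age = 0.0
            return tip
        kids = [c for c in lin.children if survives(c)]
        if not kids:
            return None
        if len(kids) == 1:
            return build(kids[0])
        node = _Pending()
        node.age = present - lin.death  # split time -> age before present
        node.children = [build(k) for k in kids]
        return node

    rec_root = build(root)
    labels = iter(f"T{i + 1}" for i in range(len(alive)))
    return _pending_to_chronogram(rec_root, labels)


class _GeneLineage:
    __slots__ = ("children", "age", "label")

    def __init__(self, age, label=None):
        self.children = None
        self.age = age
        self.label = label


def sim_species_coalescent(species_tree: Chronogram,
                           samples_per_species: int,
                           coalescent_scale: float,
                           seed: int | None = None,
                           rng: np.random.Generator | None = None,
                           ) -> tuple[Chronogram, dict[str, str]]:
    """Gene tree from Kingman coalescents within a species chronogram.

    Within every species-tree branch, the k gene lineages present coalesce
    at rate k(k-1)/2 / ``coalescent_scale``, so ``coalescent_scale`` is the
    expected pairwise coalescent time (Myr) of two lineages in an
    unbounded population. Lineages that fail to coalesce before the top of
    a branch are handed to the ancestral branch; the root population is
    unbounded.

    Returns the gene tree plus a tip -> species truth map; gene tips are
    labelled ``<species>_<i>``.
    """
    if samples_per_species < 1:
        raise ValueError("samples_per_species must be >= 1")
    if coalescent_scale <= 0:
        raise ValueError("coalescent_scale must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    truth: dict[str, str] = {}

    def coalesce(lineages, start_age, end_age):
        lineages = list(lineages)
        t = start_age
        while len(lineages) >= 2:
            k = len(lineages)
            t = t + rng.exponential(coalescent_scale / (k * (k - 1) / 2.0))
            if t >= end_age:
                break
            i, j = sorted(rng.choice(k, size=2, replace=False))
            node = _GeneLineage(t)
            node.children = [lineages[i], lineages[j]]
            lineages[i] = node
            lineages.pop(j)
        return lineages

    def walk(sp_node) -> list[_GeneLineage]:
        if sp_node.is_leaf():
            sp = Chronogram._label(sp_node)
            lineages = []
            for i in range(samples_per_species):
                lab = f"{sp}_{i + 1}"
                truth[lab] = sp
                lineages.append(_GeneLineage(0.0, lab))
        else:
            lineages = []
            for child in sp_node.child_nodes():
                lineages.extend(walk(child))
        parent = sp_node.parent_node
        top = parent.age if parent is not None else np.inf
        return coalesce(lineages, sp_node.age, top)

    survivors = walk(species_tree.tree.seed_node)
    (gene_root,) = coalesce(survivors, species_tree.crown_age, np.inf) \
        if len(survivors) > 1 else (survivors[0],)

    def to_pending(g: _GeneLineage) -> _Pending:
        p = _Pending()
        p.age = g.age
        if g.children is not None:
            p.children = [to_pending(c) for c in g.children]
        else:
            p._tip_label = g.label
        return p

    root_p = to_pending(gene_root)
    # labels assigned in the deterministic traversal order of the build
    label_stack: list[str] = []

    def collect(p: _Pending):
        if p.children is None:
            label_stack.append(p._tip_label)
        else:
            for c in p.children:
                collect(c)

    collect(root_p)
    ch = _pending_to_chronogram(root_p, iter(label_stack))
    ch.info.update({"model": "species_coalescent",
                    "coalescent_scale": coalescent_scale})
    return ch, truth


def _gtr_rate_matrix(exchangeabilities, base_freqs) -> np.ndarray:
    s = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(base_freqs, dtype=float)
    if s.shape != (6,) or np.any(s < 0) or not np.any(s > 0):
        raise ValueError("invalid GTR exchangeabilities")
    if pi.shape != (4,) or np.any(pi < 0) or abs(pi.sum() - 1) > 1e-12:
        raise ValueError("invalid base frequencies")
    Q = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]  # AC AG AT CG CT GT
    for rate, (i, j) in zip(s, pairs):
        Q[i, j] = rate * pi[j]
        Q[j, i] = rate * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(Q)))  # expected substitutions per unit time
    if mu <= 0:
        raise ValueError("degenerate GTR rate matrix")
    return Q / mu


def _gamma_category_rates(shape: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability categories of a mean-1 Gamma."""
    if k == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=shape, scale=1.0 / shape)
    upper = gammainc(shape + 1, edges[1:] * shape)
    lower = gammainc(shape + 1, edges[:-1] * shape)
    return (upper - lower) * k


def sim_sequences(tree: Chronogram, config: SimConfig,
                  rng: np.random.Generator | None = None) -> Alignment:
    """Evolve GTR+Gamma sequences along a chronogram, one per tip.

    Branch lengths are ages in Myr times the (mean-1-normalized) GTR rate,
    i.e. the chronogram is read in expected substitutions per site per
    Myr = 1; rescale branch lengths beforehand for other clock rates.
    With ``config.n_mask_fraction`` > 0, each sequence gets a terminal run
    (random side) of up to that fraction of sites replaced by N,
    emulating partial-length fragments.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.seq_length
    Q = _gtr_rate_matrix(config.gtr_exchangeabilities, config.base_freqs)
    cat_rates = _gamma_category_rates(config.gamma_shape, config.n_gamma_cats)
    pi = np.asarray(config.base_freqs)
    site_cat = rng.integers(0, len(cat_rates), size=L)
    root_states = rng.choice(4, size=L, p=pi)

    seqs: dict[str, np.ndarray] = {}

    def evolve(node, states):
        if node.is_leaf():
            seqs[Chronogram._label(node)] = states
            return
        for child in node.child_nodes():
            blen = node.age - child.age
            child_states = states.copy()
            if blen > 0:
                u = rng.random(L)
                for c, r in enumerate(cat_rates):
                    P = expm(Q * blen * r)
                    cum = np.cumsum(P, axis=1)
                    cum[:, -1] = 1.0
                    in_cat = site_cat == c
                    for s in range(4):
                        sel = in_cat & (states == s)
                        if sel.any():
                            child_states[sel] = np.searchsorted(cum[s], u[sel])
            evolve(child, child_states)

    evolve(tree.tree.seed_node, root_states)

    bases = np.array(list("ACGT"))
    records = []
    for lab in tree.tip_labels:
        chars = bases[seqs[lab]]
        if config.n_mask_fraction > 0:
            run = int(rng.integers(0, int(config.n_mask_fraction * L) + 1))
            if run:
                if rng.random() < 0.5:
                    chars[:run] = "N"
                else:
                    chars[L - run:] = "N"
        records.append((lab, "".join(chars)))
    return Alignment(records)
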