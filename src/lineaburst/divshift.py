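"""Diversification-rate model selection and net-diversification estimators.

Fits constant-rate models (pure birth, constant birth-death) and
piecewise-constant pure-birth models with 2 or 3 rates to the branching
times of a chronogram, compares them through

    delta_AIC_rc = AIC(best rate-constant) - AIC(best rate-variable),

calibrates the statistic by simulating rate-constant trees under the
fitted null (the "critical" value is the 95th null percentile), applies
the machinery tree-by-tree to a posterior sample of chronograms, and
computes Magallon-Sanderson style net diversification rates from a
species count, an age and a relative-extinction fraction.

Likelihood conventions (shared so AICs are comparable): all models
condition on the crown and drop the same combinatorial constants. With
branching times t_2 >= ... >= t_n (t_2 the crown age), durations x_k and
total lineage-time S = sum_k k*x_k = 2*t_2 + sum_{i>=3} t_i:

* pure birth:    logL(lam) = (n-2) ln lam - lam * S
* birth-death:   logL(r, a) = (n-2) ln r - r S + n ln(1-a)
                              - 2 sum_{i=2}^{n} log(1 - a e^{-r t_i}),
  with r = lam - mu the net rate and a = mu/lam the extinction fraction
  (algebraically identical to the conditioned reconstructed-process
  likelihood; reduces exactly to pure birth at a = 0)
* yule-k-rate:   each epoch e contributes d_e ln(lam_e) - lam_e * LT_e with
  d_e its events and LT_e its lineage-time; shift ages are searched
  exhaustively over the observed branching times.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize, minimize_scalar
from scipy.stats import chi2 as chi2_dist

from . import simdata
from .treekit import BranchingTimes, Chronogram, branching_times, sample_trees

logger = logging.getLogger(__name__)

__all__ = [
    "RateFit",
    "RateEstimate",
    "ShiftReport",
    "fit_pure_birth",
    "fit_bd_constant",
    "fit_yule_k_rate",
    "delta_aic_rc",
    "critical_delta_aic",
    "ensemble_shift_analysis",
    "magallon_sanderson",
    "pure_birth_profile_ci",
    "bd_profile_ci_r",
]


@dataclass
class RateFit:
    """A fitted diversification model: parameters, logL and AIC."""

    model: str
    params: dict
    logL: float
    n_params: int
    aic: float = field(init=False)

    def __post_init__(self):
        self.aic = -2.0 * self.logL + 2.0 * self.n_params


def fit_pure_birth(bt: BranchingTimes) -> RateFit:
    """Closed-form pure-birth (Yule) MLE conditioned on the crown."""
    n = bt.n
    if n < 3:
        raise ValueError("need at least 3 tips")
    S = bt.lineage_time()
    if S <= 0:
        raise ValueError("degenerate branching times: zero lineage-time")
    lam = (n - 2) / S
    logL = (n - 2) * np.log(lam) - lam * S
    return RateFit("pureBirth", {"lambda": lam}, logL, 1)


def _bd_loglik(r: float, a: float, t: np.ndarray, S: float) -> float:
    """Constant birth-death log-likelihood; t = branching times (desc)."""
    n = len(t) + 1
    if r <= 0 or not 0 <= a < 1:
        return -np.inf
    return ((n - 2) * np.log(r) - r * S + n * np.log1p(-a)
            - 2.0 * float(np.sum(np.log1p(-a * np.exp(-r * t)))))


def fit_bd_constant(bt: BranchingTimes, n_starts: int = 4) -> RateFit:
    """ML constant birth-death fit over (r, a) with multi-start L-BFGS-B."""
    n = bt.n
    if n < 3:
        raise ValueError("need at least 3 tips")
    t, S = bt.ages, bt.lineage_time()
    r0 = (n - 2) / S

    def neg(x):
        return -_bd_loglik(np.exp(x[0]), x[1], t, S)

    best = None
    for a_start in np.linspace(0.0, 0.9, n_starts):
        res = minimize(neg, x0=np.array([np.log(r0), a_start]),
                       method="L-BFGS-B",
                       bounds=[(np.log(r0) - 12, np.log(r0) + 6),
                               (0.0, 1.0 - 1e-9)])
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("birth-death optimizer failed to converge")
    r, a = float(np.exp(best.x[0])), float(best.x[1])
    lam = r / (1.0 - a)
    return RateFit("bd", {"r": r, "a": a, "lambda": lam, "mu": a * lam},
                   -float(best.fun), 2)


def _epoch_loglik(d: np.ndarray, lt: np.ndarray) -> np.ndarray:
    """Profile pure-birth contribution d*ln(d/LT) - d per epoch (0 if d=0)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(d > 0, d * (np.log(d) - np.log(lt)) - d, 0.0)
    return out


def fit_yule_k_rate(bt: BranchingTimes, k: int) -> RateFit:
    """Pure birth with k = 2 or 3 epochs; shifts at observed branching times.

    The shift-age search is exhaustive over branching times (ordered pairs
    for k = 3); an event exactly at a shift age belongs to the older
    epoch. Per-epoch MLE is events / lineage-time. AIC charges 2k - 1
    parameters (k rates + k - 1 shift ages).
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    n = bt.n
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} tips for {k} rates")
    t = bt.ages                      # t[0] = t_2 ... t[n-2] = t_n
    S = bt.lineage_time()
    m = len(t)                       # n - 1 internal nodes
    # cumulative lineage-time from the crown down to each branching time:
    # C[j] = lineage-time spent in (t[j], t_2], j = 0..m-1; C[0] = 0
    kcount = np.arange(2, n + 1)     # lineages in interval below t[j]
    seg = kcount[:-1] * (t[:-1] - t[1:])
    C = np.concatenate(([0.0], np.cumsum(seg)))[:m]
    # events are t[1..m-1]; boundary at t[j] puts events t[1..j] in the
    # older epoch (d_old = j) and leaves d_young = (n - 2) - j
    j = np.arange(1, m)              # candidate boundary indices
    if k == 2:
        d1, d2 = j.astype(float), (n - 2.0) - j
        lt1, lt2 = C[j], S - C[j]
        ll = _epoch_loglik(d1, lt1) + _epoch_loglik(d2, lt2)
        ll[np.minimum(lt1, lt2) <= 0] = -np.inf
        best = int(np.argmax(ll))
        jb = j[best]
        rates = [d1[best] / lt1[best] if lt1[best] > 0 else 0.0,
                 d2[best] / lt2[best] if lt2[best] > 0 else 0.0]
        return RateFit("yule2rate",
                       {"rates": rates, "shift_ages": [float(t[jb])]},
                       float(ll[best]), 3)
    first, second = np.triu_indices(len(j), k=1)
    a_idx, b_idx = j[first], j[second]          # a_idx < b_idx (older, younger)
    d1 = a_idx.astype(float)
    d2 = (b_idx - a_idx).astype(float)
    d3 = (n - 2.0) - b_idx
    lt1 = C[a_idx]
    lt2 = C[b_idx] - C[a_idx]
    lt3 = S - C[b_idx]
    ll = (_epoch_loglik(d1, lt1) + _epoch_loglik(d2, lt2)
          + _epoch_loglik(d3, lt3))
    ll[np.minimum(np.minimum(lt1, lt2), lt3) <= 0] = -np.inf
    best = int(np.argmax(ll))
    ja, jb = a_idx[best], b_idx[best]
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = [float(d1[best] / lt1[best]) if lt1[best] > 0 else 0.0,
                 float(d2[best] / lt2[best]) if lt2[best] > 0 else 0.0,
                 float(d3[best] / lt3[best]) if lt3[best] > 0 else 0.0]
    return RateFit("yule3rate",
                   {"rates": rates,
                    "shift_ages": [float(t[ja]), float(t[jb])]},
                   float(ll[best]), 5)


def delta_aic_rc(bt: BranchingTimes) -> tuple[float, RateFit, RateFit]:
    """AIC(best rate-constant) - AIC(best rate-variable); positive favors
    rate variation."""
    if bt.n < 5:
        raise ValueError("need at least 5 tips")
    best_const = min((fit_pure_birth(bt), fit_bd_constant(bt)),
                     key=lambda f: f.aic)
    best_var = min((fit_yule_k_rate(bt, 2), fit_yule_k_rate(bt, 3)),
                   key=lambda f: f.aic)
    return best_const.aic - best_var.aic, best_const, best_var


def _simulate_constant(fit: RateFit, n_tips: int,
                       rng: np.random.Generator) -> Chronogram:
    if fit.model == "pureBirth":
        return simdata.sim_yule(n_tips, fit.params["lambda"], rng=rng)
    return simdata.sim_bd(n_tips, fit.params["lambda"], fit.params["mu"],
                          rng=rng)


def critical_delta_aic(bt: BranchingTimes, n_sim: int = 1000,
                       alpha: float = 0.95,
                       seed: int | None = None) -> float:
    """Critical delta-AIC_rc: the alpha-quantile of the statistic under the
    best-fitting rate-constant model, from ``n_sim`` simulated trees of the
    same tip count."""
    _, best_const, _ = delta_aic_rc(bt)
    rng = np.random.default_rng(seed)
    deltas, skipped = [], 0
    for _ in range(n_sim):
        try:
            sim_bt = branching_times(_simulate_constant(best_const, bt.n, rng))
            deltas.append(delta_aic_rc(sim_bt)[0])
        except (RuntimeError, ValueError) as exc:  # pragma: no cover
            skipped += 1
            logger.warning("null replicate skipped: %s", exc)
    if skipped > 0.05 * n_sim:
        raise RuntimeError(f"{skipped}/{n_sim} null replicates failed")
    return float(np.quantile(deltas, alpha))


@dataclass
class ShiftReport:
    """Ensemble summary of rate-shift fits over a posterior tree sample."""

    n_trees: int
    variable_model: str
    increase_shift_mean: float | None
    increase_shift_ci: tuple[float, float] | None
    decrease_shift_mean: float | None
    decrease_shift_ci: tuple[float, float] | None
    delta_aic_rc: list[float]
    critical_delta_aic: float
    critical_mode: str
    exceedance_fraction: float
    per_tree: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        def _ci(ci):
            return [float(ci[0]), float(ci[1])] if ci is not None else None

        return {
            "n_trees": self.n_trees,
            "variable_model": self.variable_model,
            "increase_shift_mean": self.increase_shift_mean,
            "increase_shift_ci": _ci(self.increase_shift_ci),
            "decrease_shift_mean": self.decrease_shift_mean,
            "decrease_shift_ci": _ci(self.decrease_shift_ci),
            "delta_aic_rc": [float(d) for d in self.delta_aic_rc],
            "critical_delta_aic": self.critical_delta_aic,
            "critical_mode": self.critical_mode,
            "exceedance_fraction": self.exceedance_fraction,
        }


def _classify_shifts(fit: RateFit) -> list[tuple[float, str]]:
    """(age, 'increase'|'decrease') per shift, comparing the epoch after
    (younger than) the shift with the one before."""
    rates = fit.params["rates"]
    ages = fit.params["shift_ages"]
    out = []
    for i, age in enumerate(ages):
        older, younger = rates[i], rates[i + 1]
        if younger == older:
            continue
        out.append((age, "increase" if younger > older else "decrease"))
    return out


def ensemble_shift_analysis(trees: list[Chronogram], n_sample: int = 100,
                            seed: int | None = None, n_sim: int = 1000,
                            variable_model: str = "yule3",
                            critical_mode: str = "pooled",
                            alpha: float = 0.95,
                            replace: bool = False) -> ShiftReport:
    """Rate-shift analysis over a random sample of posterior chronograms.

    Per sampled tree the best rate-constant model and the requested
    rate-variable model (yule3 by default, yule2 optional) are fitted;
    shift ages are classified as increases or decreases by comparing
    adjacent epoch rates, then pooled across trees into means and
    2.5/97.5% quantile intervals. The per-tree delta-AIC_rc (constant
    minus variable) is compared against either one pooled critical value
    (simulated once at the median constant-rate MLEs, default) or a
    per-tree critical value.
    """
    if variable_model not in ("yule2", "yule3"):
        raise ValueError("variable_model must be 'yule2' or 'yule3'")
    if critical_mode not in ("pooled", "per_tree"):
        raise ValueError("critical_mode must be 'pooled' or 'per_tree'")
    sample = sample_trees(trees, n=n_sample, seed=seed, replace=replace)
    k = 3 if variable_model == "yule3" else 2
    rows, deltas = [], []
    shifts: dict[str, list[float]] = {"increase": [], "decrease": []}
    const_fits = []
    rng = np.random.default_rng(None if seed is None else seed + 1)
    for i, ch in enumerate(sample):
        bt = branching_times(ch)
        const = min((fit_pure_birth(bt), fit_bd_constant(bt)),
                    key=lambda f: f.aic)
        var = fit_yule_k_rate(bt, k)
        delta = const.aic - var.aic
        deltas.append(delta)
        const_fits.append(const)
        tree_shifts = _classify_shifts(var)
        for age, direction in tree_shifts:
            shifts[direction].append(age)
        rows.append({
            "tree": i, "n_tips": bt.n, "crown_age": bt.crown_age,
            "const_model": const.model, "const_aic": const.aic,
            "var_model": var.model, "var_aic": var.aic,
            "delta_aic_rc": delta,
            "shift_ages": var.params["shift_ages"],
            "rates": var.params["rates"],
        })

    if critical_mode == "pooled":
        lams = np.array([f.params["lambda"] for f in const_fits])
        med = const_fits[int(np.argsort(lams)[len(lams) // 2])]
        bt0 = branching_times(sample[0])
        crit = _critical_from_fit(med, bt0.n, n_sim, alpha, rng)
    else:
        crits = [critical_delta_aic(branching_times(ch), n_sim=n_sim,
                                    alpha=alpha,
                                    seed=int(rng.integers(2 ** 31)))
                 for ch in sample]
        crit = float(np.mean(crits))
    exceed = float(np.mean([d > crit for d in deltas]))

    def _summ(vals):
        if not vals:
            return None, None
        arr = np.asarray(vals)
        return float(arr.mean()), (float(np.quantile(arr, 0.025)),
                                   float(np.quantile(arr, 0.975)))

    inc_mean, inc_ci = _summ(shifts["increase"])
    dec_mean, dec_ci = _summ(shifts["decrease"])
    return ShiftReport(
        n_trees=len(sample), variable_model=variable_model,
        increase_shift_mean=inc_mean, increase_shift_ci=inc_ci,
        decrease_shift_mean=dec_mean, decrease_shift_ci=dec_ci,
        delta_aic_rc=deltas, critical_delta_aic=crit,
        critical_mode=critical_mode, exceedance_fraction=exceed,
        per_tree=pd.DataFrame(rows))


def _critical_from_fit(fit: RateFit, n_tips: int, n_sim: int, alpha: float,
                       rng: np.random.Generator) -> float:
    deltas = []
    for _ in range(n_sim):
        sim_bt = branching_times(_simulate_constant(fit, n_tips, rng))
        deltas.append(delta_aic_rc(sim_bt)[0])
    return float(np.quantile(deltas, alpha))


@dataclass
class RateEstimate:
    """Net diversification rate r-hat with the inputs that produced it."""

    r: float
    n: int
    t: float
    epsilon: float
    mode: str


def magallon_sanderson(n: int, t: float, epsilon: float,
                       mode: str = "crown") -> RateEstimate:
    """Net diversification rate from a standing diversity and an age.

    Method-of-moments estimators under constant birth-death with relative
    extinction ``epsilon`` = mu/lambda:

    * stem:  r = ln(n (1 - eps) + eps) / t
    * crown: r = [ln( n (1 - eps^2)/2 + 2 eps
                     + (1 - eps) sqrt(n (n eps^2 - 8 eps + 2 n eps + n)) / 2 )
                  - ln 2] / t

    At eps = 0 the crown form reduces exactly to ln(n/2) / t.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if t <= 0:
        raise ValueError("t must be > 0")
    if not 0 <= epsilon < 1:
        raise ValueError("epsilon must be in [0, 1)")
    if mode == "stem":
        r = np.log(n * (1.0 - epsilon) + epsilon) / t
    elif mode == "crown":
        inner = (n * (1.0 - epsilon ** 2) / 2.0 + 2.0 * epsilon
                 + (1.0 - epsilon)
                 * np.sqrt(n * (n * epsilon ** 2 - 8.0 * epsilon
                                + 2.0 * n * epsilon + n)) / 2.0)
        r = (np.log(inner) - np.log(2.0)) / t
    else:
        raise ValueError("mode must be 'stem' or 'crown'")
    return RateEstimate(r=float(r), n=n, t=t, epsilon=epsilon, mode=mode)


def pure_birth_profile_ci(bt: BranchingTimes,
                          level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood interval for the pure-birth speciation rate."""
    fit = fit_pure_birth(bt)
    lam, S, n = fit.params["lambda"], bt.lineage_time(), bt.n
    cut = chi2_dist.ppf(level, 1) / 2.0

    def g(l):
        return ((n - 2) * np.log(l) - l * S) - (fit.logL - cut)

    lo = brentq(g, lam * 1e-6, lam)
    hi = brentq(g, lam, lam * 1e6)
    return float(lo), float(hi)


def bd_profile_ci_r(bt: BranchingTimes,
                    level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood interval for the net rate r of the constant
    birth-death model (profiling out the extinction fraction)."""
    fit = fit_bd_constant(bt)
    t, S = bt.ages, bt.lineage_time()
    cut = chi2_dist.ppf(level, 1) / 2.0

    def prof(r):
        res = minimize_scalar(lambda a: -_bd_loglik(r, a, t, S),
                              bounds=(0.0, 1.0 - 1e-9), method="bounded")
        return -res.fun

    r_hat = fit.params["r"]

    def g(r):
        return prof(r) - (fit.logL - cut)

    lo = brentq(g, r_hat * 1e-6, r_hat, xtol=1e-10)
    hi = brentq(g, r_hat, r_hat * 1e3)
    return float(lo), float(hi)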