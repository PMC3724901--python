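"""Time-stratified dispersal-extinction-cladogenesis (DEC) likelihood.

Geographic ranges are subsets of a fixed area list, evolving along a
time-scaled phylogeny by anagenetic dispersal (area gain at global rate
``d``, modulated by a per-stratum 0/1-or-scaled dispersal matrix ``D``) and
extinction (area loss at global rate ``e``; singleton ranges drop into an
absorbing null range), with cladogenetic range inheritance at nodes drawn
equiprobably from the classic DEC scenario set: sympatric inheritance of a
singleton, single-area vicariance, and peripheral-isolate (subset)
sympatry — widespread sympatry (R, R) for |R| >= 2 is excluded.

Time stratification models glacial cycles: the strata tile the interval
from the model span down to the present, and each stratum carries its own
dispersal matrix (all-zero during glacials).  Likelihoods are computed by
postorder pruning with per-branch transition matrices assembled as products
of per-segment matrix exponentials; the total likelihood sums the root
conditional likelihoods over all allowed nonempty ranges (an unweighted
sum, so a root constrained to any single range can never beat the global
fit).

Maximum-likelihood fitting is a bounded two-parameter optimisation of
``(d, e)`` with multistart; the upper bound defaults to 100 per time unit.
Rates are in events per lineage per tree time unit.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from refugia import trees as _trees

logger = logging.getLogger(__name__)

__all__ = [
    "Stratum",
    "DECModel",
    "DECParams",
    "DECFit",
    "enumerate_ranges",
    "build_q",
    "branch_transition",
    "cladogenesis_distribution",
    "dec_loglik",
    "fit_dec",
    "compare_models",
    "simulate_dec",
    "preset_dec_model",
    "load_ranges",
    "write_ranges",
]

DEFAULT_AREAS: tuple[str, ...] = ("NAI", "NAC", "BER", "CAS", "JAP")


# ---------------------------------------------------------------------------
# model containers


@dataclass
class Stratum:
    """A time slice [older, younger) with its dispersal constraint matrix."""

    older: float
    younger: float
    dispersal: np.ndarray  # D[i, j] multiplies base rate d for i -> j

    def __post_init__(self) -> None:
        self.dispersal = np.asarray(self.dispersal, dtype=float)
        if self.older <= self.younger:
            raise ValueError("stratum must have older > younger")
        if (self.dispersal < 0).any():
            raise ValueError("dispersal multipliers must be >= 0")


@dataclass
class DECModel:
    areas: tuple[str, ...] = DEFAULT_AREAS
    strata: list[Stratum] = field(default_factory=list)
    max_range_size: int = 2
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.areas)
        if not (1 <= self.max_range_size <= n):
            raise ValueError("max_range_size must be in [1, n_areas]")
        if not self.strata:
            self.strata = [Stratum(math.inf, 0.0, np.ones((n, n)))]
        bounds = sorted(self.strata, key=lambda s: -s.older)
        self.strata = bounds
        for s in self.strata:
            if s.dispersal.shape != (n, n):
                raise ValueError("dispersal matrix shape must match area count")
        for a, b in itertools.pairwise(self.strata):
            if not math.isclose(a.younger, b.older, rel_tol=0, abs_tol=1e-9):
                raise ValueError("strata must tile time without gaps or overlaps")
        if self.strata[-1].younger != 0.0:
            raise ValueError("youngest stratum must end at the present (0)")

    @property
    def span(self) -> float:
        return self.strata[0].older

    def stratum_at(self, age: float) -> int:
        """Index of the stratum containing ``age`` (age in (younger, older])."""
        if self.span < age <= self.span * (1 + 1e-9) + 1e-12:
            age = self.span
        for i, s in enumerate(self.strata):
            if s.younger < age <= s.older or (age == 0.0 and s.younger == 0.0):
                return i
        raise ValueError(f"age {age} outside model span [0, {self.span}]")

    @property
    def states(self) -> list[int]:
        return enumerate_ranges(len(self.areas), self.max_range_size)

    def state_label(self, mask: int) -> str:
        if mask == 0:
            return "0"
        return "+".join(a for i, a in enumerate(self.areas) if mask >> i & 1)


@dataclass
class DECParams:
    d: float  # dispersal rate, events / lineage / time unit
    e: float  # extinction (area loss) rate

    def __post_init__(self) -> None:
        if self.d < 0 or self.e < 0:
            raise ValueError("rates must be nonnegative")


@dataclass
class DECFit:
    model: DECModel
    params: DECParams
    neg_log_likelihood: float
    root_table: list[tuple[str, float]]  # (range label, -lnL with root constrained)
    converged: bool = True


# ---------------------------------------------------------------------------
# state space


def enumerate_ranges(n_areas: int, max_size: int) -> list[int]:
    """Canonical state list: the null range then all masks of size <= max_size,
    ordered by size and, within a size, by area indices."""
    if not (1 <= max_size <= n_areas):
        raise ValueError("max_size must satisfy 1 <= max_size <= n_areas")
    states = [0]
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(range(n_areas), size):
            mask = 0
            for a in combo:
                mask |= 1 << a
            states.append(mask)
    return states


def _bits(mask: int) -> list[int]:
    return [i for i in range(mask.bit_length()) if mask >> i & 1]


# ---------------------------------------------------------------------------
# generator and transition matrices


def build_q(model: DECModel, params: DECParams, stratum: int) -> np.ndarray:
    """Anagenetic rate generator over the range state space for one stratum.

    Gains: rate(R -> R+a) = sum_{b in R} d * D[b, a] for a not in R while
    |R+a| <= max_range_size.  Losses: rate(R -> R-a) = e per occupied area
    (singletons drop to the absorbing null range).  Diagonal = -row sum.
    """
    D = model.strata[stratum].dispersal
    states = model.states
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    Q = np.zeros((n, n))
    for i, R in enumerate(states):
        if R == 0:
            continue  # null range is absorbing
        occ = _bits(R)
        for a in range(len(model.areas)):
            if R >> a & 1:
                Q[i, index[R & ~(1 << a)]] += params.e
            else:
                new = R | 1 << a
                if new in index:
                    rate = params.d * sum(D[b, a] for b in occ)
                    Q[i, index[new]] += rate
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def branch_transition(
    model: DECModel,
    params: DECParams,
    older_end: float,
    younger_end: float,
    q_cache: dict | None = None,
) -> np.ndarray:
    """Transition probability matrix along a branch from age ``older_end``
    down to ``younger_end``, segmented at stratum boundaries; per-segment
    matrix exponentials are multiplied rootward -> tipward."""
    if younger_end < 0 or older_end > model.span + 1e-9:
        raise ValueError(
            f"branch [{older_end}, {younger_end}] outside model span [0, {model.span}]"
        )
    if older_end < younger_end:
        raise ValueError("older_end must be >= younger_end")
    n = len(model.states)
    P = np.eye(n)
    if older_end == younger_end:
        return P
    t = older_end
    cache = q_cache if q_cache is not None else {}
    while t > younger_end + 1e-12:
        k = model.stratum_at(t)
        seg_bottom = max(model.strata[k].younger, younger_end)
        dt = t - seg_bottom
        # interior segments spanning a whole stratum recur across branches,
        # so the per-segment exponentials are worth caching
        pkey = ("P", k, dt)
        seg = cache.get(pkey)
        if seg is None:
            Q = cache.get(("Q", k))
            if Q is None:
                Q = build_q(model, params, k)
                cache[("Q", k)] = Q
            seg = expm(Q * dt)
            cache[pkey] = seg
        P = P @ seg
        t = seg_bottom
    return P


# ---------------------------------------------------------------------------
# cladogenesis


def cladogenesis_distribution(
    parent_range: int, max_range_size: int | None = None
) -> list[tuple[int, int, float]]:
    """Equiprobable DEC scenario set as (left_mask, right_mask, prob).

    Singleton parents pass the range to both daughters.  For |R| >= 2 the
    outcomes are single-area vicariance (a | R-a, both orders) and subset
    sympatry (a | R, both orders); widespread sympatry (R, R) is excluded.
    """
    del max_range_size  # daughters never exceed the parent's size
    if parent_range == 0:
        raise ValueError("cladogenesis undefined for the null range")
    occ = _bits(parent_range)
    if len(occ) == 1:
        return [(parent_range, parent_range, 1.0)]
    outcomes: set[tuple[int, int]] = set()
    for a in occ:
        single = 1 << a
        rest = parent_range & ~single
        outcomes.add((single, rest))
        outcomes.add((rest, single))
        outcomes.add((single, parent_range))
        outcomes.add((parent_range, single))
    p = 1.0 / len(outcomes)
    return [(l, r, p) for (l, r) in sorted(outcomes)]


# ---------------------------------------------------------------------------
# range observations


def load_ranges(path, areas: tuple[str, ...] = DEFAULT_AREAS) -> dict[str, int]:
    """Read a 0/1 range matrix TSV (rows = tips, columns = areas) to tip->mask."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [a for a in areas if a not in df.columns]
    if missing:
        raise ValueError(f"range matrix missing area column(s) {missing}")
    out: dict[str, int] = {}
    for tip, row in df.iterrows():
        mask = 0
        for i, a in enumerate(areas):
            v = int(row[a])
            if v not in (0, 1):
                raise ValueError(f"range entry for {tip}/{a} must be 0 or 1")
            mask |= v << i
        if mask == 0:
            raise ValueError(f"tip {tip!r} has an empty range")
        out[str(tip)] = mask
    return out


def write_ranges(ranges: dict[str, int], path, areas: tuple[str, ...] = DEFAULT_AREAS):
    rows = {
        tip: {a: mask >> i & 1 for i, a in enumerate(areas)}
        for tip, mask in sorted(ranges.items())
    }
    pd.DataFrame.from_dict(rows, orient="index")[list(areas)].to_csv(
        path, sep="\t", index_label="tip", lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# likelihood


def _node_ages(tree: dendropy.Tree) -> dict[int, float]:
    depths = _trees.tip_depths(tree)
    total = max(depths.values())
    ages: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        d = 0.0
        n = node
        while n.parent_node is not None:
            d += n.edge.length or 0.0
            n = n.parent_node
        ages[id(node)] = max(total - d, 0.0)
    return ages


def _check_binary(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        k = len(node.child_nodes())
        if k not in (0, 2):
            raise ValueError(
                "DEC likelihood requires a strictly bifurcating tree; "
                "resolve polytomies first"
            )


def _conditional_root(
    tree: dendropy.Tree,
    ranges: dict[str, int],
    model: DECModel,
    params: DECParams,
    condition_on_survival: bool = False,
) -> tuple[np.ndarray, float]:
    """Postorder pruning; returns the root conditional-likelihood vector and
    the accumulated log scaling factor (vectors are rescaled per node to
    avoid underflow on large trees)."""
    _check_binary(tree)
    states = model.states
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    ages = _node_ages(tree)
    if max(ages.values()) > model.span + 1e-6:
        raise ValueError(
            f"tree depth {max(ages.values()):.6g} exceeds model span {model.span:.6g}"
        )
    clado = {s: cladogenesis_distribution(s) for s in states if s != 0}
    q_cache: dict = {}
    partial: dict[int, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in ranges:
                raise ValueError(f"tip {label!r} has no observed range")
            vec = np.zeros(n)
            vec[index[ranges[label]]] = 1.0
            partial[id(node)] = vec
        else:
            evolved = []
            for c in node.child_nodes():
                P = branch_transition(
                    model, params, ages[id(node)], ages[id(c)], q_cache
                )
                vec = P @ partial[id(c)]
                if condition_on_survival:
                    # renormalise each branch kernel on non-extinction, the
                    # same conditioning the forward simulator applies
                    surv = 1.0 - P[:, 0]
                    vec = np.where(surv > 0, vec / np.where(surv > 0, surv, 1.0), 0.0)
                evolved.append(vec)
            L = np.zeros(n)
            for s in states:
                if s == 0:
                    continue
                acc = 0.0
                for left, right, p in clado[s]:
                    acc += p * evolved[0][index[left]] * evolved[1][index[right]]
                L[index[s]] = acc
            m = L.max()
            if m > 0:
                L = L / m
                log_scale += math.log(m)
            partial[id(node)] = L
    return partial[id(tree.seed_node)], log_scale


def dec_loglik(
    tree: dendropy.Tree,
    ranges: dict[str, int],
    model: DECModel,
    params: DECParams,
    root_state: int | None = None,
    condition_on_survival: bool = False,
) -> float:
    """Negative log-likelihood of the observed tip ranges.

    The root likelihood sums over all allowed nonempty ranges unless
    ``root_state`` constrains the root to a single range.  Data impossible
    under the parameters give ``inf``.  ``condition_on_survival``
    renormalises every branch transition on non-extinction — the likelihood
    matching data in which extinct lineages cannot be observed (as
    :func:`simulate_dec` generates them).
    """
    vec, log_scale = _conditional_root(
        tree, ranges, model, params, condition_on_survival
    )
    index = {s: i for i, s in enumerate(model.states)}
    if root_state is not None:
        if root_state == 0 or root_state not in index:
            raise ValueError("root_state must be an allowed nonempty range")
        lik = vec[index[root_state]]
    else:
        lik = sum(vec[index[s]] for s in model.states if s != 0)
    if lik <= 0 or not np.isfinite(lik):
        return math.inf
    return -(math.log(lik) + log_scale)


# ---------------------------------------------------------------------------
# fitting


def fit_dec(
    tree: dendropy.Tree,
    ranges: dict[str, int],
    model: DECModel,
    n_starts: int = 4,
    bounds: tuple[float, float] = (1e-9, 100.0),
    seed: int = 0,
    condition_on_survival: bool = False,
) -> DECFit:
    """Bounded two-parameter ML fit of (d, e) with multistart, plus the
    per-root-range constrained likelihood table (ascending -lnL)."""
    lo, hi = bounds
    rng = np.random.default_rng(seed)

    def objective(x: np.ndarray) -> float:
        params = DECParams(d=float(np.exp(x[0])), e=float(np.exp(x[1])))
        val = dec_loglik(tree, ranges, model, params,
                         condition_on_survival=condition_on_survival)
        return val if np.isfinite(val) else 1e10

    # seeded multistart: rate scales spread around ~1 expected event per
    # lineage over the tree span, jittered; avoids the flat impossible-data
    # plateau near the lower bound
    scale = 1.0 / max(model.span, 1e-12)
    anchors = np.geomspace(0.1, 10.0, max(n_starts, 1)) * scale
    starts = []
    for a in anchors:
        jitter = np.exp(rng.normal(0.0, 0.3, size=2))
        d0 = min(max(a * jitter[0], lo * 10), hi / 10)
        e0 = min(max(a * 0.3 * jitter[1], lo * 10), hi / 10)
        starts.append(np.log([d0, e0]))
    best = None
    converged = False
    log_bounds = [(math.log(lo), math.log(hi))] * 2
    for x0 in starts:
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=log_bounds,
            options={"maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    if best is None or best.fun >= 1e10:
        raise RuntimeError("DEC optimisation found no finite likelihood")
    if not converged:
        logger.warning("DEC optimiser did not report convergence; best -lnL %.4f",
                       best.fun)
    params = DECParams(d=float(np.exp(best.x[0])), e=float(np.exp(best.x[1])))
    global_nll = dec_loglik(tree, ranges, model, params,
                            condition_on_survival=condition_on_survival)
    table = []
    for s in model.states:
        if s == 0:
            continue
        nll = dec_loglik(tree, ranges, model, params, root_state=s,
                         condition_on_survival=condition_on_survival)
        if np.isfinite(nll):
            table.append((model.state_label(s), nll))
    table.sort(key=lambda kv: kv[1])
    return DECFit(
        model=model,
        params=params,
        neg_log_likelihood=global_nll,
        root_table=table,
        converged=converged,
    )


def compare_models(fits: list[DECFit], window: float = 2.0) -> pd.DataFrame:
    """Rank fits by -lnL and flag those within ``window`` lnL units of the best."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    rows = []
    best = min(f.neg_log_likelihood for f in fits)
    for f in sorted(fits, key=lambda f: f.neg_log_likelihood):
        rows.append(
            {
                "model": f.model.name or "model",
                "neg_lnL": round(f.neg_log_likelihood, 4),
                "dispersal": round(f.params.d, 6),
                "extinction": round(f.params.e, 6),
                "delta_lnL": round(f.neg_log_likelihood - best, 4),
                "within_2lnL": f.neg_log_likelihood - best <= window,
                "best_root_ranges": "; ".join(
                    f"{lab}:{nll:.2f}" for lab, nll in f.root_table[:3]
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# forward simulation


def simulate_dec(
    tree: dendropy.Tree,
    model: DECModel,
    params: DECParams,
    seed: int,
    root_state: int | None = None,
    max_retries: int = 1000,
) -> dict[str, int]:
    """Forward-simulate tip ranges under the stratified DEC process.

    The root range is drawn uniformly from allowed nonempty states (or fixed
    by ``root_state``); cladogenetic scenarios are sampled at nodes and
    anagenesis runs by a Gillespie walk honouring stratum boundaries.  A
    lineage absorbed into the null range is extinct; its branch walk is
    re-simulated (up to ``max_retries`` per branch, count logged), so each
    branch is conditioned on survival.
    """
    _check_binary(tree)
    rng = random.Random(seed)
    states = [s for s in model.states if s != 0]
    ages = _node_ages(tree)
    if max(ages.values()) > model.span + 1e-6:
        raise ValueError("tree depth exceeds model span")
    n_areas = len(model.areas)

    def walk(state: int, older: float, younger: float) -> int:
        t = older
        while state != 0 and t > younger + 1e-12:
            k = model.stratum_at(t)
            D = model.strata[k].dispersal
            seg_bottom = max(model.strata[k].younger, younger)
            occ = _bits(state)
            events: list[tuple[int, float]] = []
            for a in occ:
                events.append((state & ~(1 << a), params.e))
            for a in range(n_areas):
                if not state >> a & 1:
                    new = state | 1 << a
                    if bin(new).count("1") <= model.max_range_size:
                        rate = params.d * sum(D[b, a] for b in occ)
                        if rate > 0:
                            events.append((new, rate))
            total = sum(r for _, r in events)
            if total <= 0:
                t = seg_bottom
                continue
            wait = rng.expovariate(total)
            if t - wait <= seg_bottom:
                t = seg_bottom
                continue
            t -= wait
            u = rng.random() * total
            for new, r in events:
                u -= r
                if u <= 0:
                    state = new
                    break
        return state

    n_extinct = 0

    def surviving_walk(state: int, older: float, younger: float) -> int:
        nonlocal n_extinct
        for _ in range(max_retries):
            end = walk(state, older, younger)
            if end != 0:
                return end
            n_extinct += 1
        raise RuntimeError(
            f"simulate_dec: per-branch retry cap {max_retries} exceeded"
        )

    root_range = root_state if root_state is not None else rng.choice(states)
    result: dict[str, int] = {}
    root = tree.seed_node
    left, right, _ = _sample_scenario(cladogenesis_distribution(root_range), rng)
    kids = root.child_nodes()
    stack: list[tuple[dendropy.Node, int]] = [(kids[0], left), (kids[1], right)]
    while stack:
        node, state = stack.pop()
        state = surviving_walk(state, ages[id(node.parent_node)], ages[id(node)])
        if node.is_leaf():
            result[node.taxon.label] = state
        else:
            l, r, _ = _sample_scenario(cladogenesis_distribution(state), rng)
            kids = node.child_nodes()
            stack.append((kids[0], l))
            stack.append((kids[1], r))
    if n_extinct:
        logger.info("simulate_dec: %d extinct branch walk(s) resimulated", n_extinct)
    return result


def _sample_scenario(scenarios, rng: random.Random):
    u = rng.random()
    acc = 0.0
    for left, right, p in scenarios:
        acc += p
        if u <= acc:
            return left, right, p
    return scenarios[-1]


# ---------------------------------------------------------------------------
# preset glacial-cycle models


def _adjacency_pairs() -> list[tuple[str, str]]:
    """Adjacency chain NAI - NAC - BER - CAS - JAP."""
    chain = ["NAI", "NAC", "BER", "CAS", "JAP"]
    return list(itertools.pairwise(chain))


def _matrix_from_arrows(arrows: list[tuple[str, str]], areas) -> np.ndarray:
    idx = {a: i for i, a in enumerate(areas)}
    D = np.zeros((len(areas), len(areas)))
    for src, dst in arrows:
        D[idx[src], idx[dst]] = 1.0
    return D


#: Directional interglacial dispersal arrows for the five preset scenarios
#: (adjacency chain NAI-NAC-BER-CAS-JAP; user-overridable defaults).
PRESET_ARROWS: dict[str, list[tuple[str, str]]] = {
    # origin in the southern Rocky Mountains; westward stepping stones
    "SRM": [("NAI", "NAC"), ("NAC", "BER"), ("BER", "CAS"), ("CAS", "JAP")],
    # out of Beringia onto both continents
    "BER": [("BER", "NAC"), ("NAC", "NAI"), ("BER", "CAS"), ("CAS", "JAP")],
    # origin in Japan; east/northward
    "JAP": [("JAP", "CAS"), ("CAS", "BER"), ("BER", "NAC"), ("NAC", "NAI")],
    # central-Asian origin; east through Beringia, south to Japan
    "CAS": [("CAS", "BER"), ("CAS", "JAP"), ("BER", "NAC"), ("NAC", "NAI")],
}

#: Glacial-cycle time slices (ky before present): interglacial, glacial, ...
GLACIAL_STRATA: list[tuple[float, float, bool]] = [
    (240.0, 190.0, True),   # interglacial
    (190.0, 130.0, False),  # glacial
    (130.0, 90.0, True),    # interglacial
    (90.0, 10.0, False),    # glacial
    (10.0, 0.0, True),      # Holocene interglacial
]


def preset_dec_model(
    name: str,
    areas: tuple[str, ...] = DEFAULT_AREAS,
    max_range_size: int = 2,
) -> DECModel:
    """Build one of the five stratified glacial-cycle models.

    ``SRM``, ``BER``, ``JAP``, ``CAS`` permit their directional adjacent-area
    dispersal only during interglacials (240-190, 130-90, 10-0 ky) and no
    dispersal during glacials (190-130, 90-10 ky).  ``REF`` forbids all
    dispersal before 10 ky but allows unrestricted adjacent dispersal (both
    directions) in the Holocene.
    """
    name = name.upper()
    n = len(areas)
    zero = np.zeros((n, n))
    if name == "REF":
        both = _matrix_from_arrows(
            [(a, b) for a, b in _adjacency_pairs()]
            + [(b, a) for a, b in _adjacency_pairs()],
            areas,
        )
        strata = [
            Stratum(older, younger, both if (older, younger) == (10.0, 0.0) else zero)
            for older, younger, _ in GLACIAL_STRATA
        ]
    elif name in PRESET_ARROWS:
        D = _matrix_from_arrows(PRESET_ARROWS[name], areas)
        strata = [
            Stratum(older, younger, D if inter else zero)
            for older, younger, inter in GLACIAL_STRATA
        ]
    else:
        raise ValueError(f"unknown DEC preset {name!r}")
    return DECModel(areas=areas, strata=strata, max_range_size=max_range_size, name=name)


# ---------------------------------------------------------------------------
# config I/O


def model_to_config(model: DECModel) -> dict:
    return {
        "name": model.name,
        "areas": list(model.areas),
        "max_range_size": model.max_range_size,
        "strata": [
            {
                "older": s.older,
                "younger": s.younger,
                "dispersal": s.dispersal.tolist(),
            }
            for s in model.strata
        ],
    }


def model_from_config(cfg: dict) -> DECModel:
    return DECModel(
        areas=tuple(cfg["areas"]),
        strata=[
            Stratum(s["older"], s["younger"], np.asarray(s["dispersal"]))
            for s in cfg["strata"]
        ],
        max_range_size=int(cfg.get("max_range_size", 2)),
        name=cfg.get("name", ""),
    )


def save_model(model: DECModel, path) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(model_to_config(model), fh, indent=2)
        fh.write("\n")


def load_model(path) -> DECModel:
    with open(path) as fh:
        return model_from_config(json.load(fh))
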