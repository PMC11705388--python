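"""Constrained three-objective optimization of county × CFT planting areas.

The decision variable is the allocation matrix s_ij (county i, CFT j) subject
to Σ_j s_ij = S_i per county. Objectives:

    max F_CP  = (Σ_ij s_ij · y_ij · c_j) · p_sf − p_cp          [kcal]
    min F_LN  = Σ_ij s_ij · n_ij · ϖ_i^LN                        [kg N]
    min F_IWU = Σ_ij s_ij · w_ij · ϖ_i^IWU                       [mm·ha]

p_sf is the minimum national self-sufficiency rate across the five crop-demand
categories, capped at 1 (oversupply earns no bonus); p_cp is the total
production shortfall versus the baseline allocation multiplied by the number
of crops suffering a shortfall. County weights ϖ concentrate the environmental
objectives on nitrogen-loaded (ϖ^LN) and water-scarce (ϖ^IWU) counties.

The search is an NSGA-III-style evolutionary algorithm: per-county fraction
genotypes kept feasible by repair, binary tournament selection on front rank,
simulated-binary crossover, polynomial mutation, and environmental selection
by nondominated sorting with Das–Dennis reference-point niching. The result is
the deduplicated nondominated set of the final population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from cropswitch.cfts import CROP_GROUPS, DEMAND_CATEGORIES, GROUP_TO_CATEGORY
from cropswitch.demand import DemandSet
from cropswitch.synthetic import Allocation, Region, SuitabilitySurface

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# weights and penalties
# ---------------------------------------------------------------------------


@dataclass
class CountyWeights:
    """Per-county environmental weights in [0, 1]."""

    ln: np.ndarray  # ϖ^LN, from normalized nitrogen surplus
    iwu: np.ndarray  # ϖ^IWU, 1 − normalized terrestrial water storage


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        logger.warning("all-identical scores; using uniform weight 0.5")
        return np.full_like(x, 0.5, dtype=float)
    return (x - lo) / (hi - lo)


def compute_weights(region: Region) -> CountyWeights:
    """Min–max normalize nitrogen surplus (ϖ^LN) and invert normalized TWS (ϖ^IWU)."""
    ns = region.counties["n_surplus"].to_numpy(dtype=float)
    tws = region.counties["tws"].to_numpy(dtype=float)
    tws_norm = _minmax(tws)
    # uniform-score fallback must stay at 0.5, not 1 − 0.5 applied twice
    iwu = 1.0 - tws_norm if tws.min() != tws.max() else tws_norm
    return CountyWeights(ln=_minmax(ns), iwu=iwu)


def self_sufficiency_factor(
    production_by_category: np.ndarray | dict[str, float], demand: DemandSet
) -> float:
    """p_sf = min over the five categories of min(1, production / demand)."""
    if isinstance(production_by_category, dict):
        prod = np.array([production_by_category[c] for c in DEMAND_CATEGORIES])
    else:
        prod = np.asarray(production_by_category, dtype=float)
    dem = demand.as_array()
    if (dem <= 0).any():
        raise ValueError("demand must be positive in every category")
    return float(np.minimum(1.0, prod / dem).min())


def supply_chain_penalty(
    cp_by_crop: np.ndarray, baseline_cp_by_crop: np.ndarray
) -> float:
    """p_cp = (total production shortfall) × (number of crops with a shortfall)."""
    cur = np.asarray(cp_by_crop, dtype=float)
    base = np.asarray(baseline_cp_by_crop, dtype=float)
    if cur.shape != base.shape:
        raise ValueError("crop production vectors must have equal length")
    loss = np.maximum(base - cur, 0.0)
    n_loss = int((loss > 0).sum())
    return float(loss.sum() * n_loss)


@dataclass
class PenaltyConfig:
    """Penalty toggles/weights for the sensitivity mode.

    ``sf_weight`` exponentiates p_sf (1 → as defined, 0 → off); ``cp_weight``
    scales p_cp. ``order`` places p_sf multiplicatively ("multiplicative") or,
    for the alternative reading of the objective, as a subtractive term scaled
    by raw CP ("subtractive": F_CP = rawCP − (1 − p_sf)·rawCP − p_cp, which is
    algebraically the same here but kept as an explicit switch for clarity).
    """

    use_sf: bool = True
    use_cp: bool = True
    sf_weight: float = 1.0
    cp_weight: float = 1.0

    def apply(self, raw_cp: float, p_sf: float, p_cp: float) -> float:
        f = raw_cp
        if self.use_sf:
            f = f * p_sf**self.sf_weight
        if self.use_cp:
            f = f - self.cp_weight * p_cp
        return f


@dataclass
class ObjectiveVector:
    """The three objective values plus the penalties that produced them."""

    f_cp: float  # kcal, maximize
    f_ln: float  # kg N, minimize
    f_iwu: float  # mm·ha, minimize
    p_sf: float
    p_cp: float
    raw_cp: float = 0.0

    def min_space(self) -> np.ndarray:
        """(−F_CP, F_LN, F_IWU): uniform minimization for dominance checks."""
        return np.array([-self.f_cp, self.f_ln, self.f_iwu])


# ---------------------------------------------------------------------------
# objective evaluation
# ---------------------------------------------------------------------------


def _membership(cfts: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(J×7 crop-group, J×5 demand-category) one-hot membership matrices."""
    J = len(cfts)
    G = np.zeros((J, len(CROP_GROUPS)))
    M = np.zeros((J, len(DEMAND_CATEGORIES)))
    for k, row in enumerate(cfts.itertuples()):
        G[k, CROP_GROUPS.index(row.crop_group)] = 1.0
        M[k, DEMAND_CATEGORIES.index(GROUP_TO_CATEGORY[row.crop_group])] = 1.0
    return G, M


def crop_production(
    alloc: Allocation, suit: SuitabilitySurface, cfts: pd.DataFrame
) -> np.ndarray:
    """National CP per crop group (kcal, length 7), CFTs aggregated by group."""
    G, _ = _membership(cfts)
    yc = suit.yield_t_ha * cfts["calories_kcal_t"].to_numpy()[None, :]
    return np.einsum("nj,nj,jg->g", alloc.areas_ha, yc, G)


def evaluate_objectives(
    alloc: Allocation,
    suit: SuitabilitySurface,
    weights: CountyWeights,
    cfts: pd.DataFrame,
    demand: DemandSet,
    baseline_cp_by_crop: np.ndarray,
    penalties: PenaltyConfig | None = None,
) -> ObjectiveVector:
    """Evaluate (F_CP, F_LN, F_IWU) with penalties for one allocation."""
    if alloc.areas_ha.shape != suit.yield_t_ha.shape:
        raise ValueError("allocation and suitability index sets disagree")
    pen = penalties or PenaltyConfig()
    _, M = _membership(cfts)
    yc = suit.yield_t_ha * cfts["calories_kcal_t"].to_numpy()[None, :]

    cp_crop = crop_production(alloc, suit, cfts)
    raw_cp = float(cp_crop.sum())
    prod_cat = np.einsum("nj,nj,jm->m", alloc.areas_ha, yc, M)
    p_sf = self_sufficiency_factor(prod_cat, demand)
    p_cp = supply_chain_penalty(cp_crop, baseline_cp_by_crop)
    f_cp = pen.apply(raw_cp, p_sf, p_cp)
    f_ln = float(np.einsum("nj,nj,n->", alloc.areas_ha, suit.leach_kg_ha, weights.ln))
    f_iwu = float(
        np.einsum("nj,nj,n->", alloc.areas_ha, suit.irrigation_mm, weights.iwu)
    )
    return ObjectiveVector(
        f_cp=f_cp, f_ln=f_ln, f_iwu=f_iwu, p_sf=p_sf, p_cp=p_cp, raw_cp=raw_cp
    )


# ---------------------------------------------------------------------------
# NSGA-III machinery
# ---------------------------------------------------------------------------


def nondominated_sort(points) -> list[np.ndarray]:
    """Partition points into Pareto fronts (minimization; fast dominance matrix).

    Accepts an (n, m) array in minimization space or a list of
    :class:`ObjectiveVector` (F_CP negated internally). Duplicated points are
    mutually non-dominating and land in the same front. Returns a list of
    index arrays, best front first; empty input gives an empty list.
    """
    if isinstance(points, (list, tuple)):
        if len(points) == 0:
            return []
        if isinstance(points[0], ObjectiveVector):
            F = np.array([p.min_space() for p in points])
        else:
            F = np.asarray(points, dtype=float)
    else:
        F = np.asarray(points, dtype=float)
    if F.size == 0:
        return []
    n = F.shape[0]
    le = (F[:, None, :] <= F[None, :, :]).all(axis=2)
    lt = (F[:, None, :] < F[None, :, :]).any(axis=2)
    dom = le & lt  # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0)
    fronts: list[np.ndarray] = []
    remaining = np.ones(n, dtype=bool)
    counts = n_dominators.copy()
    while remaining.any():
        front = np.flatnonzero(remaining & (counts == 0))
        if front.size == 0:  # pragma: no cover - cannot happen with finite F
            raise RuntimeError("cyclic dominance; non-finite objectives?")
        fronts.append(front)
        remaining[front] = False
        counts = counts - dom[front].sum(axis=0)
    return fronts


def reference_points(n_objectives: int, divisions: int) -> np.ndarray:
    """Das–Dennis lattice on the unit simplex, C(d+m−1, m−1) points summing to 1."""
    if n_objectives < 2 or divisions < 1:
        raise ValueError("need n_objectives >= 2 and divisions >= 1")
    pts = []
    for bars in combinations(range(divisions + n_objectives - 1), n_objectives - 1):
        prev = -1
        counts = []
        for b in bars:
            counts.append(b - prev - 1)
            prev = b
        counts.append(divisions + n_objectives - 2 - prev)
        pts.append(counts)
    return np.array(pts, dtype=float) / divisions


def repair_allocation(raw_fractions: np.ndarray, region: Region) -> Allocation:
    """Project raw county × CFT reals onto the per-county area simplices.

    Negatives clip to 0, rows renormalize to sum 1 and scale by S_i; an
    all-zero row falls back to the uniform allocation.
    """
    x = np.clip(np.asarray(raw_fractions, dtype=float), 0.0, None)
    sums = x.sum(axis=1, keepdims=True)
    zero = sums[:, 0] == 0
    if zero.any():
        x[zero] = 1.0
        sums = x.sum(axis=1, keepdims=True)
    fracs = x / sums
    return Allocation(areas_ha=fracs * region.areas[:, None])


def _repair_batch(x: np.ndarray, areas: np.ndarray) -> np.ndarray:
    """Vectorized repair for a (P, n, J) population of raw fractions."""
    x = np.clip(x, 0.0, None)
    sums = x.sum(axis=2, keepdims=True)
    zero = sums == 0
    if zero.any():
        x = np.where(np.broadcast_to(zero, x.shape), 1.0, x)
        sums = x.sum(axis=2, keepdims=True)
    return x / sums * areas[None, :, None]


@dataclass
class OptimizerConfig:
    """Evolutionary search settings.

    Defaults are a desk-scale configuration (population 52 × 100 generations,
    4 reference-point divisions); the full study-scale setting of 1,000
    solutions × 3,000 generations is expressible through the same fields.
    """

    pop_size: int = 52
    generations: int = 100
    divisions: int = 4
    eta_crossover: float = 15.0
    eta_mutation: float = 20.0
    mutation_rate: float | None = None  # default 1 / n_genes
    crossover_prob: float = 0.9
    seed: int = 0
    penalties: PenaltyConfig = field(default_factory=PenaltyConfig)

    def validate(self) -> None:
        if self.pop_size < 4 or self.pop_size % 2:
            raise ValueError("population size must be even and >= 4")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.divisions < 1:
            raise ValueError("divisions must be >= 1")


@dataclass
class OptimizationProblem:
    """Everything a fitness evaluation needs."""

    region: Region
    cfts: pd.DataFrame
    suit: SuitabilitySurface
    weights: CountyWeights
    demand: DemandSet
    baseline_cp_by_crop: np.ndarray

    def __post_init__(self) -> None:
        n, J = self.suit.yield_t_ha.shape
        if n != self.region.n_counties or J != len(self.cfts):
            raise ValueError("problem index sets inconsistent")


@dataclass
class EvolutionLog:
    """Per-generation progress diagnostics."""

    best_f_cp: list[float] = field(default_factory=list)
    hypervolume: list[float] = field(default_factory=list)
    max_area_violation: float = 0.0


class _BatchEvaluator:
    """Vectorized objective evaluation over a population of fraction genomes."""

    def __init__(self, problem: OptimizationProblem, penalties: PenaltyConfig):
        p = problem
        self.pen = penalties
        self.areas = p.region.areas
        self.G, self.M = _membership(p.cfts)
        self.yc = p.suit.yield_t_ha * p.cfts["calories_kcal_t"].to_numpy()[None, :]
        self.lnw = p.suit.leach_kg_ha * p.weights.ln[:, None]
        self.iwuw = p.suit.irrigation_mm * p.weights.iwu[:, None]
        self.demand = p.demand.as_array()
        self.baseline = np.asarray(p.baseline_cp_by_crop, dtype=float)
        self.max_violation = 0.0

    def __call__(self, fracs: np.ndarray):
        """fracs (P, n, J) -> (F min-space (P,3), extras dict)."""
        s = _repair_batch(fracs, self.areas)
        dev = np.abs(s.sum(axis=2) - self.areas[None, :]) / self.areas[None, :]
        self.max_violation = max(self.max_violation, float(dev.max()))
        cp_crop = np.einsum("pnj,nj,jg->pg", s, self.yc, self.G)
        raw_cp = cp_crop.sum(axis=1)
        prod_cat = np.einsum("pnj,nj,jm->pm", s, self.yc, self.M)
        p_sf = np.minimum(1.0, prod_cat / self.demand[None, :]).min(axis=1)
        loss = np.maximum(self.baseline[None, :] - cp_crop, 0.0)
        p_cp = loss.sum(axis=1) * (loss > 0).sum(axis=1)
        f_cp = raw_cp.copy()
        if self.pen.use_sf:
            f_cp = f_cp * p_sf**self.pen.sf_weight
        if self.pen.use_cp:
            f_cp = f_cp - self.pen.cp_weight * p_cp
        f_ln = np.einsum("pnj,nj->p", s, self.lnw)
        f_iwu = np.einsum("pnj,nj->p", s, self.iwuw)
        F = np.column_stack([-f_cp, f_ln, f_iwu])
        extras = {
            "p_sf": p_sf,
            "p_cp": p_cp,
            "raw_cp": raw_cp,
            "areas": s,
            "f_cp": f_cp,
        }
        return F, extras


def _sbx(
    rng: np.random.Generator, a: np.ndarray, b: np.ndarray, eta: float, prob: float
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover on [0, 1]-bounded genomes."""
    u = rng.random(a.shape)
    beta = np.where(
        u <= 0.5,
        (2.0 * u) ** (1.0 / (eta + 1.0)),
        (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0)),
    )
    do = rng.random(a.shape) < 0.5
    beta = np.where(do, beta, 1.0)
    if rng.random() > prob:  # whole-pair crossover probability
        beta = np.ones_like(beta)
    c1 = 0.5 * ((1 + beta) * a + (1 - beta) * b)
    c2 = 0.5 * ((1 - beta) * a + (1 + beta) * b)
    return np.clip(c1, 0.0, 1.0), np.clip(c2, 0.0, 1.0)


def _poly_mutation(
    rng: np.random.Generator, x: np.ndarray, eta: float, rate: float
) -> np.ndarray:
    """Polynomial mutation on [0, 1]-bounded genomes."""
    y = x.copy()
    mask = rng.random(x.shape) < rate
    if not mask.any():
        return y
    u = rng.random(x.shape)
    xm = x[mask]
    d1, d2 = xm, 1.0 - xm
    mpow = 1.0 / (eta + 1.0)
    um = u[mask]
    lo = um < 0.5
    val = np.where(
        lo,
        (2 * um + (1 - 2 * um) * (1 - d1) ** (eta + 1)) ** mpow - 1.0,
        1.0 - (2 * (1 - um) + 2 * (um - 0.5) * (1 - d2) ** (eta + 1)) ** mpow,
    )
    y[mask] = np.clip(xm + val, 0.0, 1.0)
    return y


def _normalize(F: np.ndarray, front0: np.ndarray) -> np.ndarray:
    """Scale objectives by the per-generation ideal point and first-front nadir."""
    ideal = F.min(axis=0)
    nadir = F[front0].max(axis=0)
    span = np.where(nadir - ideal > 1e-12, nadir - ideal, 1.0)
    return (F - ideal) / span


def _associate(Fn: np.ndarray, refs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest reference direction (by perpendicular distance) per point."""
    norms = np.linalg.norm(refs, axis=1)
    dirs = refs / norms[:, None]
    proj = Fn @ dirs.T  # (n, R) scalar projections
    # squared perpendicular distance ||z||² − (z·ŵ)²
    d2 = (Fn * Fn).sum(axis=1)[:, None] - proj**2
    idx = np.argmin(d2, axis=1)
    dist = np.sqrt(np.maximum(d2[np.arange(len(Fn)), idx], 0.0))
    return idx, dist


def _niching_select(
    F: np.ndarray,
    fronts: list[np.ndarray],
    refs: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """NSGA-III environmental selection of k survivors from the merged population."""
    chosen: list[int] = []
    for fi, front in enumerate(fronts):
        if len(chosen) + len(front) <= k:
            chosen.extend(front.tolist())
            if len(chosen) == k:
                return np.array(chosen)
        else:
            last = front
            break
    else:
        return np.array(chosen)

    Fn = _normalize(F, fronts[0])
    pool = np.array(chosen + last.tolist())
    assoc, dist = _associate(Fn[pool], refs)
    n_chosen = len(chosen)
    niche_count = np.bincount(assoc[:n_chosen], minlength=len(refs))
    last_assoc = assoc[n_chosen:]
    last_dist = dist[n_chosen:]
    available = np.ones(len(last), dtype=bool)

    selected = list(chosen)
    while len(selected) < k:
        open_refs = np.unique(last_assoc[available])
        counts = niche_count[open_refs]
        cands = open_refs[counts == counts.min()]
        ref = cands[rng.integers(len(cands))] if len(cands) > 1 else cands[0]
        members = np.flatnonzero(available & (last_assoc == ref))
        if niche_count[ref] == 0:
            pick = members[np.argmin(last_dist[members])]
        else:
            pick = members[rng.integers(len(members))]
        selected.append(int(last[pick]))
        available[pick] = False
        niche_count[ref] += 1
    return np.array(selected)


def _ranks_of(fronts: list[np.ndarray], n: int) -> np.ndarray:
    ranks = np.empty(n, dtype=int)
    for r, fr in enumerate(fronts):
        ranks[fr] = r
    return ranks


def hypervolume_3d(points: np.ndarray, ref: np.ndarray) -> float:
    """Exact hypervolume of a 3-objective minimization front w.r.t. ``ref``.

    Sweeps the third objective and accumulates 2D staircase areas; quadratic
    in the front size, which is small here.
    """
    P = np.asarray(points, dtype=float)
    P = P[(P < ref[None, :]).all(axis=1)]
    if len(P) == 0:
        return 0.0
    fronts = nondominated_sort(P)
    P = P[fronts[0]]
    order = np.argsort(P[:, 2])
    P = P[order]
    hv = 0.0
    zs = np.append(P[:, 2], ref[2])
    active: list[np.ndarray] = []
    for k in range(len(P)):
        active.append(P[k, :2])
        dz = zs[k + 1] - zs[k]
        if dz <= 0:
            continue
        pts2 = np.array(active)
        keep = nondominated_sort(pts2)[0]
        pts2 = pts2[keep]
        pts2 = pts2[np.argsort(pts2[:, 0])]
        area = 0.0
        y_prev = ref[1]
        for x, y in pts2:
            area += (ref[0] - x) * (y_prev - y)
            y_prev = y
        hv += area * dz
    return float(hv)


def evolve(
    problem: OptimizationProblem,
    config: OptimizerConfig,
    *,
    return_log: bool = False,
    log_hypervolume: bool = False,
):
    """Run the evolutionary search; return the final nondominated solutions.

    Returns a list of (Allocation, ObjectiveVector) pairs — the deduplicated
    rank-1 set of the last generation — or ``(solutions, EvolutionLog)`` when
    ``return_log`` is set. Fully deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, J = problem.suit.yield_t_ha.shape
    P = config.pop_size
    n_genes = n * J
    pm = config.mutation_rate if config.mutation_rate is not None else 1.0 / n_genes
    refs = reference_points(3, config.divisions)
    ev = _BatchEvaluator(problem, config.penalties)
    log = EvolutionLog()

    # feasible initialization: Dirichlet fractions per county
    pop = rng.dirichlet(np.ones(J), size=(P, n))
    F, extras = ev(pop)
    fronts = nondominated_sort(F)
    ranks = _ranks_of(fronts, P)

    for _gen in range(config.generations):
        log.best_f_cp.append(float(extras["f_cp"].max()))
        if log_hypervolume:
            ref_pt = F.max(axis=0) * 1.1 + 1e-9
            log.hypervolume.append(hypervolume_3d(F[fronts[0]], ref_pt))

        # binary tournament on front rank
        flat = pop.reshape(P, n_genes)
        cand = rng.integers(0, P, size=(P, 2))
        better = np.where(
            ranks[cand[:, 0]] < ranks[cand[:, 1]],
            cand[:, 0],
            np.where(
                ranks[cand[:, 1]] < ranks[cand[:, 0]],
                cand[:, 1],
                cand[np.arange(P), rng.integers(0, 2, size=P)],
            ),
        )
        parents = flat[better]
        children = np.empty_like(parents)
        for k in range(0, P, 2):
            c1, c2 = _sbx(
                rng, parents[k], parents[k + 1], config.eta_crossover,
                config.crossover_prob,
            )
            children[k], children[k + 1] = c1, c2
        children = _poly_mutation(rng, children, config.eta_mutation, pm)
        off = children.reshape(P, n, J)

        F_off, extras_off = ev(off)
        F_all = np.vstack([F, F_off])
        pop_all = np.vstack([pop, off])
        extras_all = {
            key: np.concatenate([extras[key], extras_off[key]])
            for key in ("p_sf", "p_cp", "raw_cp", "f_cp")
        }
        areas_all = np.concatenate([extras["areas"], extras_off["areas"]])
        fronts_all = nondominated_sort(F_all)
        keep = _niching_select(F_all, fronts_all, refs, P, rng)
        pop = pop_all[keep]
        F = F_all[keep]
        extras = {key: extras_all[key][keep] for key in extras_all}
        extras["areas"] = areas_all[keep]
        fronts = nondominated_sort(F)
        ranks = _ranks_of(fronts, P)

    log.best_f_cp.append(float(extras["f_cp"].max()))
    log.max_area_violation = ev.max_violation

    # final answer: deduplicated rank-1 set of the last generation
    first = fronts[0]
    seen: set[bytes] = set()
    solutions: list[tuple[Allocation, ObjectiveVector]] = []
    for i in first:
        key = np.round(extras["areas"][i], 6).tobytes()
        if key in seen:
            continue
        seen.add(key)
        solutions.append(
            (
                Allocation(areas_ha=extras["areas"][i].copy()),
                ObjectiveVector(
                    f_cp=float(extras["f_cp"][i]),
                    f_ln=float(F[i, 1]),
                    f_iwu=float(F[i, 2]),
                    p_sf=float(extras["p_sf"][i]),
                    p_cp=float(extras["p_cp"][i]),
                    raw_cp=float(extras["raw_cp"][i]),
                ),
            )
        )
    if return_log:
        return solutions, log
    return solutions
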