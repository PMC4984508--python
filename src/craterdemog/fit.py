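"""Composite-likelihood demographic inference on the joint SFS.

The observed folded joint SFS is treated as multinomial counts over its
cells; the cell probabilities come from Monte-Carlo expected branch
lengths under a candidate model (mu x expected branch length per cell is
the per-site probability of a segregating site in that cell).  By default
the monomorphic class is included — with the substitution rate fixed, it
is what ties the spectrum to absolute sizes and times; a conditional
polymorphic-only mode is available.

Optimization is an ECM-style cycle: each free parameter is maximized
conditionally on the others by a shrinking-step pattern search, with
joint diagonal steps for strongly coupled parameter pairs, under common
random numbers (one simulation seed per round) so accepted steps never
decrease the composite likelihood within a round.  The simulation count
per evaluation follows an increasing per-round schedule.  Multiple random
starts guard against local optima, optionally followed by a small-step
polish of the winner; parametric bootstrap gives percentile confidence
intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .coalescent import StrandedLineagesError, expected_branch_sfs, simulate_sfs
from .demography import DemographicModel, crater_colonization_model
from .types import FitResult, InferenceConfig, JointSFS

__all__ = [
    "FreeParam",
    "ModelSpec",
    "crater_model_spec",
    "expected_sfs",
    "composite_lnl",
    "ecm_fit",
    "rank_models",
    "parametric_bootstrap",
    "scale_params",
    "unscale_params",
]

ZERO_CELL_FLOOR = 1e-10  # fraction of total mass assigned to empty expected cells


@dataclass
class FreeParam:
    """A free model parameter with box bounds and search scale."""

    name: str
    lo: float
    hi: float
    scale: str = "linear"  # or "log"

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"{self.name}: lower bound must be < upper bound")
        if self.scale == "log" and self.lo <= 0:
            raise ValueError(f"{self.name}: log scale needs positive bounds")

    def to_search(self, x: float) -> float:
        return math.log(x) if self.scale == "log" else x

    def from_search(self, u: float) -> float:
        return math.exp(u) if self.scale == "log" else u


@dataclass
class ModelSpec:
    """A parameterized demographic-model template.

    ``builder`` maps a complete parameter dict (free + fixed) to a
    :class:`DemographicModel`.  ``constraints`` lists ``(a, b)`` pairs
    meaning parameter ``a`` must stay strictly below parameter ``b``
    (used for time ordering); they tighten the line-search bounds
    dynamically.
    """

    model_id: str
    params: List[FreeParam]
    builder: Callable[[Dict[str, float]], DemographicModel]
    fixed: Dict[str, float] = field(default_factory=dict)
    constraints: List[Tuple[str, str]] = field(default_factory=list)
    # pairs of strongly coupled parameters that get joint (diagonal)
    # conditional-maximization steps in addition to the per-coordinate ones
    blocks: List[Tuple[str, str]] = field(default_factory=list)
    # deterministic stratified starting points covering directions along
    # which the likelihood is known to be multi-modal; used to seed the
    # screening pool ahead of the uniform random draws
    start_grid: List[Dict[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.params]
        if len(names) != len(set(names)):
            raise ValueError("duplicate free parameter names")
        overlap = set(names) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {overlap}")

    @property
    def n_free(self) -> int:
        return len(self.params)

    def build(self, values: Dict[str, float]) -> DemographicModel:
        full = dict(self.fixed)
        full.update(values)
        return self.builder(full)

    def draw_start(self, rng: np.random.Generator) -> Dict[str, float]:
        """Uniform (log-uniform for log-scale) start within bounds, respecting
        ordering constraints (rejection with a deterministic fallback)."""
        for _ in range(200):
            vals = {}
            for p in self.params:
                u = rng.uniform(p.to_search(p.lo), p.to_search(p.hi))
                vals[p.name] = p.from_search(u)
            if self._feasible(vals):
                return vals
        # fallback: mid-bounds, then nudge constrained params into order
        vals = {
            p.name: p.from_search(0.5 * (p.to_search(p.lo) + p.to_search(p.hi)))
            for p in self.params
        }
        full = dict(self.fixed)
        full.update(vals)
        for a, b in self.constraints:
            if full[a] >= full[b]:
                if a in vals:
                    vals[a] = 0.5 * full[b]
                elif b in vals:
                    vals[b] = min(2.0 * full[a], full[a] + 1.0)
        return vals

    def _feasible(self, vals: Dict[str, float]) -> bool:
        full = dict(self.fixed)
        full.update(vals)
        return all(full[a] < full[b] for a, b in self.constraints)

    def search_bounds(
        self, name: str, current: Dict[str, float]
    ) -> Tuple[float, float]:
        """Box bounds for ``name`` tightened by the ordering constraints
        given the other parameters' current values."""
        p = next(q for q in self.params if q.name == name)
        lo, hi = p.lo, p.hi
        full = dict(self.fixed)
        full.update(current)
        for a, b in self.constraints:
            if a == name and b in full:
                hi = min(hi, full[b] * (1.0 - 1e-3))
            if b == name and a in full:
                lo = max(lo, full[a] * (1.0 + 1e-3))
        if not lo < hi:
            lo = hi * (1.0 - 1e-6)
        return lo, hi


def crater_model_spec(
    samples: Tuple[int, int] = (50, 50),
    admixture: bool = True,
    migration: bool = True,
    source_bottlegrowth: bool = True,
    crater_growth: bool = True,
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    fixed: Optional[Dict[str, float]] = None,
    model_id: Optional[str] = None,
) -> ModelSpec:
    """The crater-lake colonization model family as an optimizable spec.

    Structure toggles remove the admixture pulse, continuous migration,
    the source bottleneck-plus-growth, or crater growth (then the crater
    stays at its founder size), generating the nested family used for
    model choice.  Default bounds are broad, biologically motivated boxes;
    colonization cannot predate the source bottleneck, the admixture pulse
    cannot predate colonization.
    """
    default_bounds: Dict[str, Tuple[float, float, str]] = {
        "n_anc": (1e3, 1e5, "log"),
        "n_bneck": (1e2, 2e4, "log"),
        "t_bneck": (900.0, 5000.0, "linear"),
        "n_source_now": (1e4, 1e6, "log"),
        "n_founder": (2.0, 500.0, "log"),
        "t_col": (100.0, 1240.0, "linear"),
        "n_crater_now": (1e3, 1e5, "log"),
        "t_admix": (50.0, 1200.0, "linear"),
        "admix_prop": (0.01, 0.9, "linear"),
        "mig": (1e-6, 1e-3, "log"),
    }
    names = ["n_anc", "n_founder", "t_col", "n_crater_now"]
    constraints: List[Tuple[str, str]] = []
    fixed_all: Dict[str, float] = dict(fixed or {})
    if source_bottlegrowth:
        names += ["n_bneck", "t_bneck", "n_source_now"]
        constraints.append(("t_col", "t_bneck"))
    else:
        fixed_all.setdefault("n_bneck", 1.0)
        fixed_all.setdefault("t_bneck", 1e9)
        fixed_all.setdefault("n_source_now", 1.0)
    if admixture:
        names += ["t_admix", "admix_prop"]
        constraints.append(("t_admix", "t_col"))
    else:
        fixed_all.setdefault("t_admix", 0.0)
        fixed_all.setdefault("admix_prop", 0.0)
    if migration:
        names += ["mig"]
    else:
        fixed_all.setdefault("mig", 0.0)

    params = []
    for n in names:
        if n in fixed_all:
            continue
        lo, hi, scale = default_bounds[n]
        if bounds and n in bounds:
            lo, hi = bounds[n]
        params.append(FreeParam(n, lo, hi, scale))
    constraints = [
        (a, b)
        for (a, b) in constraints
        if not (a in fixed_all and b in fixed_all)
    ]

    def builder(v: Dict[str, float]) -> DemographicModel:
        return crater_colonization_model(
            n_anc=v["n_anc"],
            n_bneck=v["n_bneck"],
            t_bneck=v["t_bneck"],
            n_source_now=v["n_source_now"],
            n_founder=v["n_founder"],
            t_col=v["t_col"],
            n_crater_now=v["n_crater_now"],
            t_admix=v.get("t_admix", 0.0),
            admix_prop=v.get("admix_prop", 0.0),
            mig=v.get("mig", 0.0),
            samples=samples,
            source_bottlegrowth=source_bottlegrowth,
            crater_growth=crater_growth,
        )

    blocks = [
        ("t_col", "n_founder"),  # founder-bottleneck intensity trade-off
        ("t_col", "admix_prop"),  # colonization-age vs admixture ridge
        ("t_admix", "admix_prop"),
        ("n_anc", "t_bneck"),  # ancestral scale vs bottleneck age
    ]
    free_names = {p.name for p in params}
    blocks = [(a, b) for (a, b) in blocks if a in free_names and b in free_names]

    # the surface is multi-modal along (t_col, admix_prop): a late, weak
    # founder event plus a weak pulse mimics an early, strong founder event
    # plus a strong pulse.  Stratified starts over that plane (other
    # parameters at their box midpoints on the search scale) make sure the
    # screening pool covers both basins regardless of the run seed.
    grid: List[Dict[str, float]] = []
    if admixture and "t_col" in free_names and "admix_prop" in free_names:
        mids = {
            p.name: p.from_search(0.5 * (p.to_search(p.lo) + p.to_search(p.hi)))
            for p in params
        }
        t_lo, t_hi = next(
            (p.lo, p.hi) for p in params if p.name == "t_col"
        )
        for tc in np.linspace(t_lo + 0.2 * (t_hi - t_lo), t_hi * 0.95, 4):
            for ap in (0.15, 0.35, 0.55):
                point = dict(mids)
                point["t_col"] = float(tc)
                point["admix_prop"] = ap
                if "t_admix" in free_names:
                    point["t_admix"] = 0.6 * float(tc)
                if "t_bneck" in free_names:
                    point["t_bneck"] = max(point["t_bneck"], 1.5 * float(tc))
                grid.append(point)

    if model_id is None:
        model_id = "crater" + "".join(
            tag
            for flag, tag in [
                (source_bottlegrowth, "+bottlegrowth"),
                (crater_growth, "+growth"),
                (admixture, "+admix"),
                (migration, "+mig"),
            ]
            if flag
        )
    return ModelSpec(
        model_id, params, builder, fixed_all, constraints, blocks, grid
    )


def expected_sfs(
    model: DemographicModel,
    n_sims: int,
    seed: int = 0,
    mu: Optional[float] = None,
    monomorphic: bool = True,
    fold: bool = True,
) -> JointSFS:
    """Normalized Monte-Carlo expected SFS under ``model``.

    With ``monomorphic=True`` (requires ``mu``), the (0, 0) cell carries
    the per-site probability of no mutation, 1 - mu x E[tree length], and
    polymorphic cells carry mu x E[branch length]; otherwise cells are
    normalized over polymorphic entries only.
    """
    if n_sims < 1000:
        raise ValueError("n_sims must be >= 1000 for a usable expected SFS")
    B, total = expected_branch_sfs(model, n_sims, seed=seed)
    n1, n2 = B.shape[0] - 1, B.shape[1] - 1
    sfs = JointSFS(B, n1, n2, folded=False)
    if fold:
        sfs = sfs.fold()
    grid = sfs.counts
    poly = grid.sum() - grid[0, 0] - grid[n1, n2]
    if poly <= 0:
        raise ValueError("model produced no polymorphic branch mass")
    if monomorphic:
        if mu is None:
            raise ValueError("monomorphic mode requires mu")
        p = grid * mu
        p[0, 0] = max(1.0 - mu * total, ZERO_CELL_FLOOR)
        p[n1, n2] = 0.0
    else:
        p = grid / poly
        p[0, 0] = 0.0
        p[n1, n2] = 0.0
    return JointSFS(p, n1, n2, folded=sfs.folded)


def composite_lnl(obs: JointSFS, expected: JointSFS) -> float:
    """Multinomial composite log-likelihood sum(obs * ln p) over cells.

    Polymorphic cells always contribute; the (0, 0) cell contributes when
    the expected spectrum carries monomorphic probability there.  Expected
    zeros under positive observations are floored at ``ZERO_CELL_FLOOR`` of
    total expected mass (with a floor of 0 the result would be -inf).
    """
    if (obs.n1, obs.n2) != (expected.n1, expected.n2):
        raise ValueError("observed and expected SFS dimensions differ")
    o = obs.counts
    p = expected.counts.copy()
    total = p.sum()
    include_mono = p[0, 0] > 0
    floor = ZERO_CELL_FLOOR * (total if total > 0 else 1.0)
    mask = np.ones_like(o, dtype=bool)
    mask[obs.n1, obs.n2] = False
    if not include_mono:
        mask[0, 0] = False
    o = np.where(mask, o, 0.0)
    p = np.where(p > floor, p, floor)
    with np.errstate(divide="ignore"):
        return float(np.sum(o * np.log(p)))


def _evaluate(
    spec: ModelSpec,
    values: Dict[str, float],
    obs: JointSFS,
    n_sims: int,
    seed: int,
    mu: float,
    monomorphic: bool,
) -> float:
    try:
        model = spec.build(values)
        exp = expected_sfs(
            model, n_sims, seed=seed, mu=mu, monomorphic=monomorphic, fold=obs.folded
        )
        return composite_lnl(obs, exp)
    except (ValueError, ArithmeticError, StrandedLineagesError):
        return -np.inf


def _coordinate_step(
    f: Callable[[float], float],
    p: FreeParam,
    lo: float,
    hi: float,
    current: float,
    step_frac: float,
    max_evals: int,
    f_current: Optional[float] = None,
    accept_tol: float = 0.0,
) -> Tuple[float, float]:
    """Pattern-search step for one coordinate on its search scale.

    Starting from the current value, probe +/- ``step_frac`` of the box
    width and keep walking in an improving direction (up to ``max_evals``
    evaluations).  The current value is always a candidate, so the result
    never falls below f(current) at the shared simulation seed.
    """
    a, b = p.to_search(lo), p.to_search(hi)
    x0 = min(max(p.to_search(current), a), b)
    step = (b - a) * step_frac
    cache: Dict[float, float] = {}
    if f_current is not None:
        cache[x0] = f_current

    def eval_at(u: float):
        u = min(max(u, a), b)
        if u not in cache:
            cache[u] = f(p.from_search(u))
        return u, cache[u]

    _, f0 = eval_at(x0)
    best_x, best_f = x0, f0
    evals = 1
    for direction in (+1.0, -1.0):
        x = x0 + direction * step
        while evals < max_evals:
            xe, fx = eval_at(x)
            evals += 1
            if fx > best_f + accept_tol:
                best_x, best_f = xe, fx
                if xe in (a, b):
                    break
                x = xe + direction * step
            else:
                break
        if best_x != x0:
            break  # improving direction found; stop
    if best_x == x0:
        # no move at the coarse step: probe at quarter resolution
        for direction in (+1.0, -1.0):
            xe, fx = eval_at(x0 + direction * 0.25 * step)
            if fx > best_f + accept_tol:
                best_x, best_f = xe, fx
    return p.from_search(best_x), best_f


def _block_step(
    f2: Callable[[float, float], float],
    pa: FreeParam,
    pb: FreeParam,
    bounds_a: Tuple[float, float],
    bounds_b: Tuple[float, float],
    current: Tuple[float, float],
    step_frac: float,
    max_evals: int,
    f_current: Optional[float] = None,
    accept_tol: float = 0.0,
) -> Tuple[float, float, float]:
    """Joint diagonal pattern step for a coupled parameter pair.

    Probes the four diagonal combinations at the current step size and
    walks along the best improving diagonal; returns the (possibly
    unchanged) pair and its objective value.
    """
    aa, ab = pa.to_search(bounds_a[0]), pa.to_search(bounds_a[1])
    ba, bb = pb.to_search(bounds_b[0]), pb.to_search(bounds_b[1])
    sa = (ab - aa) * step_frac
    sb = (bb - ba) * step_frac
    x0 = min(max(pa.to_search(current[0]), aa), ab)
    y0 = min(max(pb.to_search(current[1]), ba), bb)
    cache: Dict[Tuple[float, float], float] = {}
    if f_current is not None:
        cache[(x0, y0)] = f_current

    def eval_at(x: float, y: float):
        x = min(max(x, aa), ab)
        y = min(max(y, ba), bb)
        if (x, y) not in cache:
            cache[(x, y)] = f2(pa.from_search(x), pb.from_search(y))
        return x, y, cache[(x, y)]

    _, _, f0 = eval_at(x0, y0)
    best = (x0, y0, f0)
    evals = 1
    best_dir = None
    for da, db in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        if evals >= max_evals:
            break
        x, y, fx = eval_at(x0 + da * sa, y0 + db * sb)
        evals += 1
        if fx > best[2] + accept_tol:
            best = (x, y, fx)
            best_dir = (da, db)
    while best_dir is not None and evals < max_evals:
        x, y, fx = eval_at(best[0] + best_dir[0] * sa, best[1] + best_dir[1] * sb)
        evals += 1
        if fx > best[2] + accept_tol:
            best = (x, y, fx)
        else:
            break
    return pa.from_search(best[0]), pb.from_search(best[1]), best[2]


def ecm_fit(
    spec: ModelSpec,
    obs: JointSFS,
    config: InferenceConfig,
    start: Optional[Dict[str, float]] = None,
    verbose: bool = False,
) -> FitResult:
    """Fit ``spec`` to ``obs`` by ECM coordinate maximization.

    Runs ``config.n_starts`` independent starts (or the single provided
    ``start``); within each round all evaluations share one simulation
    seed (common random numbers), so each accepted coordinate step does
    not decrease the round's likelihood.  Starts are compared by
    re-evaluating their final parameters at a common seed with
    ``config.sims_end`` simulations.
    """
    if obs.n_polymorphic <= 0:
        raise ValueError("observed SFS has no polymorphic sites")
    mu = config.mu
    monomorphic = config.monomorphic
    if monomorphic and obs.counts[0, 0] <= 0:
        raise ValueError(
            "monomorphic-inclusive likelihood needs the monomorphic count in "
            "the observed (0, 0) cell; build the SFS with effective_length "
            "or set config.monomorphic=False"
        )
    rng = np.random.default_rng(config.seed)
    n_screen = max(config.n_screen, config.n_starts) if start is None else 1
    round_seeds = rng.integers(0, 2**31 - 1, size=(n_screen, config.ecm_rounds))
    assess_seed = int(rng.integers(0, 2**31 - 1))

    starts: List[Dict[str, float]] = []
    if start is not None:
        starts = [dict(start)]
    elif n_screen > config.n_starts:
        # screening pool: stratified grid first, uniform draws for the rest
        grid = [dict(g) for g in spec.start_grid if spec._feasible(g)]
        starts = grid[:n_screen]
        starts += [spec.draw_start(rng) for _ in range(n_screen - len(starts))]
    else:
        starts = [spec.draw_start(rng) for _ in range(n_screen)]

    if spec.n_free == 0:
        lnl = _evaluate(
            spec, {}, obs, config.sims_end, assess_seed, mu, monomorphic
        )
        return FitResult(spec.model_id, dict(spec.fixed), lnl, 0,
                         seed=config.seed, n_sims=config.sims_end)

    def cm_round(values: Dict[str, float], n_sims: int, seed_r: int,
                 step_frac: float) -> Dict[str, float]:
        """One conditional-maximization cycle (singles then blocks) at a
        fixed simulation seed; mutates and returns ``values``."""
        lnl_cur: Optional[float] = None  # current point at this round's seed
        for p in spec.params:
            lo, hi = spec.search_bounds(p.name, values)

            def f(x: float, _name=p.name) -> float:
                trial = dict(values)
                trial[_name] = x
                return _evaluate(
                    spec, trial, obs, n_sims, seed_r, mu, monomorphic
                )

            x_best, lnl_cur = _coordinate_step(
                f, p, lo, hi, values[p.name], step_frac, config.coord_evals,
                f_current=lnl_cur, accept_tol=config.accept_tol,
            )
            values[p.name] = x_best
        by_name = {p.name: p for p in spec.params}
        for na, nb in spec.blocks:
            if na not in by_name or nb not in by_name:
                continue
            pa, pb = by_name[na], by_name[nb]

            def f2(xa: float, xb: float, _na=na, _nb=nb) -> float:
                trial = dict(values)
                trial[_na] = xa
                trial[_nb] = xb
                if not spec._feasible(trial):
                    return -np.inf
                return _evaluate(
                    spec, trial, obs, n_sims, seed_r, mu, monomorphic
                )

            xa, xb, lnl_cur = _block_step(
                f2, pa, pb,
                spec.search_bounds(na, values),
                spec.search_bounds(nb, values),
                (values[na], values[nb]),
                step_frac,
                config.coord_evals,
                f_current=lnl_cur, accept_tol=config.accept_tol,
            )
            values[na], values[nb] = xa, xb
        return values

    # optional racing phase: run every start through the first rounds at a
    # reduced simulation count, keep only the best n_starts
    states = [dict(v) for v in starts]
    first_round = 0
    if len(states) > config.n_starts:
        screen_sims = config.screen_sims or max(config.sims_start // 2, 1000)
        screen_rounds = min(config.screen_rounds, config.ecm_rounds)
        for r in range(screen_rounds):
            step_frac = max(0.30 * 0.75**r, 0.004)
            for s_idx in range(len(states)):
                seed_r = int(round_seeds[s_idx, r])
                states[s_idx] = cm_round(states[s_idx], screen_sims, seed_r,
                                         step_frac)
        scores = [
            _evaluate(spec, v, obs, 4 * screen_sims, assess_seed, mu, monomorphic)
            for v in states
        ]
        keep = np.argsort(scores)[::-1][: config.n_starts]
        if verbose:
            print(f"screen kept starts {list(keep)} of {len(states)}")
        states = [states[i] for i in keep]
        round_seeds = round_seeds[keep]
        first_round = screen_rounds

    best: Optional[Tuple[float, Dict[str, float]]] = None
    for s_idx, values in enumerate(states):
        for r in range(first_round, config.ecm_rounds):
            n_sims = config.sims_for_round(r)
            seed_r = int(round_seeds[s_idx % round_seeds.shape[0], r])
            step_frac = max(0.30 * 0.75**r, 0.004)
            values = cm_round(values, n_sims, seed_r, step_frac)
            if verbose:
                print(f"start {s_idx} round {r}: {values}")
        final_lnl = _evaluate(
            spec, values, obs, 2 * config.sims_end, assess_seed, mu, monomorphic
        )
        if best is None or final_lnl > best[0]:
            best = (final_lnl, values)
        if verbose:
            print(f"start {s_idx} final lnL {final_lnl:.2f}")

    lnl, values = best
    if config.polish_rounds > 0 and np.isfinite(lnl):
        # refine the winning start with fresh seeds at the top simulation
        # count, walking the step size back down from a moderate width so
        # the coupled-parameter ridges get a second, finer traversal
        values = dict(values)
        polish_seeds = rng.integers(0, 2**31 - 1, size=config.polish_rounds)
        for r in range(config.polish_rounds):
            step_frac = max(0.08 * 0.6**r, 0.003)
            values = cm_round(values, config.sims_end, int(polish_seeds[r]),
                              step_frac)
            if verbose:
                print(f"polish round {r}: {values}")
        lnl = _evaluate(
            spec, values, obs, 2 * config.sims_end, assess_seed, mu, monomorphic
        )
    if not np.isfinite(lnl):
        raise RuntimeError("all starts produced non-finite composite likelihoods")
    params = dict(spec.fixed)
    params.update(values)
    return FitResult(
        spec.model_id,
        params,
        float(lnl),
        spec.n_free,
        seed=config.seed,
        n_sims=config.sims_end,
    )


def rank_models(fits: Sequence[FitResult]) -> List[dict]:
    """Order fits of competing models on the same data by AIC.

    Ties break by fewer free parameters, then model id.  Returns a table
    (list of dicts) with AIC, delta-AIC and max lnL.
    """
    if len(fits) < 1:
        raise ValueError("need at least one fit")
    obs_ids = {f.obs_id for f in fits}
    if len(obs_ids) > 1:
        raise ValueError(f"fits are not on the same observed SFS: {obs_ids}")
    ordered = sorted(fits, key=lambda f: (f.aic, f.n_free, f.model_id))
    best_aic = ordered[0].aic
    return [
        dict(
            rank=i + 1,
            model_id=f.model_id,
            lnl=f.lnl,
            n_free=f.n_free,
            aic=f.aic,
            delta_aic=f.aic - best_aic,
        )
        for i, f in enumerate(ordered)
    ]


def parametric_bootstrap(
    spec: ModelSpec,
    mle: FitResult,
    effective_length: float,
    config: InferenceConfig,
    n_boot: Optional[int] = None,
    max_failure_rate: float = 0.2,
) -> Dict[str, Tuple[float, float]]:
    """Percentile (2.5/97.5) bootstrap CIs by simulate-at-MLE-and-refit.

    Each replicate simulates a fresh SFS of the same effective length at
    the MLE and refits from the MLE start.  Failed refits are dropped; more
    than ``max_failure_rate`` failures is an error.
    """
    n_boot = config.n_bootstrap if n_boot is None else n_boot
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    model = spec.build({k: v for k, v in mle.params.items()})
    rng = np.random.default_rng(config.seed + 1)
    estimates: Dict[str, List[float]] = {p.name: [] for p in spec.params}
    failures = 0
    for b in range(n_boot):
        sim_seed = int(rng.integers(0, 2**31 - 1))
        pseudo = simulate_sfs(
            model, mu=config.mu, effective_length=effective_length, seed=sim_seed
        )
        boot_cfg = InferenceConfig(
            mu=config.mu,
            ecm_rounds=config.ecm_rounds,
            sims_start=config.sims_start,
            sims_end=config.sims_end,
            sims_step=config.sims_step,
            n_starts=1,
            seed=int(rng.integers(0, 2**31 - 1)),
            monomorphic=config.monomorphic,
            coord_evals=config.coord_evals,
        )
        try:
            refit = ecm_fit(
                spec,
                pseudo,
                boot_cfg,
                start={p.name: mle.params[p.name] for p in spec.params},
            )
        except (RuntimeError, ValueError):
            failures += 1
            continue
        for p in spec.params:
            estimates[p.name].append(refit.params[p.name])
    if failures > max_failure_rate * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed")
    return {
        name: (
            float(np.percentile(vals, 2.5)),
            float(np.percentile(vals, 97.5)),
        )
        for name, vals in estimates.items()
    }


# ------------------------------------------------------------- unit scaling


def scale_params(
    params: Dict[str, float],
    mu: float,
    effective_length: float,
    ref: str = "n_anc",
) -> Dict[str, float]:
    """Demographic units -> mutation-scaled units.

    The reference size ``ref`` becomes ``theta = 4 N_ref mu L``; other
    sizes (``n_*``) become ratios nu = N / N_ref; times (``t_*``) become
    tau = T / (2 N_ref); migration probabilities become M = 2 N_ref m.
    Proportions are untouched.  Inverse of :func:`unscale_params`.
    """
    if not mu > 0:
        raise ValueError("mu must be > 0")
    n_ref = params[ref]
    out: Dict[str, float] = {"theta": 4.0 * n_ref * mu * effective_length}
    for k, v in params.items():
        if k == ref:
            continue
        if k.startswith("n_"):
            out["nu_" + k[2:]] = v / n_ref
        elif k.startswith("t_"):
            out["tau_" + k[2:]] = v / (2.0 * n_ref)
        elif k.startswith("mig"):
            out["M" + k[3:]] = 2.0 * n_ref * v
        else:
            out[k] = v
    return out


def unscale_params(
    scaled: Dict[str, float],
    mu: float,
    effective_length: float,
    ref: str = "n_anc",
) -> Dict[str, float]:
    """Mutation-scaled units -> demographic units (see :func:`scale_params`)."""
    if not mu > 0:
        raise ValueError("mu must be > 0")
    n_ref = scaled["theta"] / (4.0 * mu * effective_length)
    out: Dict[str, float] = {ref: n_ref}
    for k, v in scaled.items():
        if k == "theta":
            continue
        if k.startswith("nu_"):
            out["n_" + k[3:]] = v * n_ref
        elif k.startswith("tau_"):
            out["t_" + k[4:]] = v * 2.0 * n_ref
        elif k.startswith("M"):
            out["mig" + k[1:]] = v / (2.0 * n_ref)
        else:
            out[k] = v
    return out
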