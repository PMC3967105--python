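"""Candidate-restricted OptKnock refinement of screening results.

OptKnock is the bilevel program

    max_{y}  v_target          (outer: strain designer)
    s.t.     v  solves  max v_growth  s.t.  S v = 0, bounds(y),
                                            v_growth >= min_growth
             sum(y) <= K,  y binary,

where y_u = 1 deletes all member reactions of candidate unit u.  The
inner LP is folded into a single MILP by strong duality: primal and
dual feasibility of the inner problem are imposed together with the
requirement that the dual objective not exceed the primal one (weak
duality supplies the opposite direction), with big-M terms switching
bound duals off for knocked-out reactions.  Restricting the binary
variables to units harvested from the shadow-price screening keeps the
MILP small.

A pure enumeration backend (lexicographic FBA over every subset of
size <= K) doubles as an exact oracle and is used automatically when
the subset count is small.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import cobra
import numpy as np
from cobra.util.array import create_stoichiometric_matrix
from optlang.glpk_interface import Constraint, Model as MilpModel, Objective, Variable

from .environment import EnvironmentConfig
from .exceptions import SolverError
from .fba import lexicographic_target_max, theoretical_max_yield
from .io import biomass_reaction_id, resolve_target
from .reduction import KnockoutUnit
from .screening import ScreeningResult

logger = logging.getLogger(__name__)

#: subsets at or below which the enumeration backend is preferred
ENUM_LIMIT = 10_000

#: big-M for dual variables of knockable reaction bounds
M_DUAL = 1000.0

#: allowed inner-LP duality gap in the MILP
DUALITY_GAP = 1e-6


@dataclass
class OptKnockResult:
    """Best knockout set of size <= K and its production metrics."""

    status: str  # optimal | infeasible | no_candidates
    k: int
    knockout_units: frozenset[str]
    knockout_reactions: frozenset[str]
    growth: float
    target_flux_at_biomass_max: float
    tmy_flux: float
    yield_fraction_tmy: float
    backend: str


def _subset_count(n: int, k: int) -> int:
    return sum(math.comb(n, i) for i in range(0, min(k, n) + 1))


def optknock(
    model: cobra.Model,
    env: EnvironmentConfig,
    target: str,
    candidate_units: Sequence[KnockoutUnit],
    k: int,
    backend: str = "auto",
) -> OptKnockResult:
    """Find the knockout set (<= ``k`` candidate units) maximizing target export.

    The outer objective is evaluated inner-optimistically: among the
    biomass-optimal flux distributions of the knockout strain, the one
    with the largest target flux counts (the lexicographic convention).
    ``backend`` is "milp", "enumeration", or "auto" (enumeration when
    the subset count is at most 10,000).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    candidates = sorted((u for u in candidate_units if u.knockable), key=lambda u: u.unit_id)
    if backend == "auto":
        backend = "enumeration" if _subset_count(len(candidates), k) <= ENUM_LIMIT else "milp"
    if backend == "enumeration":
        best = _enumerate(model, env, target, candidates, k)
    elif backend == "milp":
        best = _milp(model, env, target, candidates, k)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    unit_ids, status = best
    if status != "optimal":
        return OptKnockResult(
            status=status, k=k, knockout_units=frozenset(), knockout_reactions=frozenset(),
            growth=float("nan"), target_flux_at_biomass_max=0.0, tmy_flux=float("nan"),
            yield_fraction_tmy=0.0, backend=backend,
        )
    by_id = {u.unit_id: u for u in candidates}
    reactions = frozenset(r for uid in unit_ids for r in by_id[uid].member_reactions)
    # audit: plain lexicographic FBA on the chosen set gives the reported fluxes
    growth, target_flux = lexicographic_target_max(
        model, env, target, reactions, enforce_min_growth=True
    )
    tmy = theoretical_max_yield(model, env, target)
    return OptKnockResult(
        status="optimal",
        k=k,
        knockout_units=frozenset(unit_ids),
        knockout_reactions=reactions,
        growth=growth,
        target_flux_at_biomass_max=target_flux,
        tmy_flux=tmy.target_flux,
        yield_fraction_tmy=(target_flux / tmy.target_flux) if tmy.target_flux > 1e-12 else 0.0,
        backend=backend,
    )


def _enumerate(
    model: cobra.Model,
    env: EnvironmentConfig,
    target: str,
    candidates: Sequence[KnockoutUnit],
    k: int,
) -> tuple[frozenset[str], str]:
    ids = [u.unit_id for u in candidates]
    by_id = {u.unit_id: u for u in candidates}
    best: tuple[float, int, tuple[str, ...]] | None = None
    feasible = False
    for size in range(0, min(k, len(ids)) + 1):
        for combo in combinations(ids, size):
            reactions = frozenset(r for uid in combo for r in by_id[uid].member_reactions)
            growth, flux = lexicographic_target_max(
                model, env, target, reactions, enforce_min_growth=True
            )
            if math.isnan(growth):
                continue
            feasible = True
            key = (-flux, size, combo)
            if best is None or key < best:
                best = key
    if not feasible or best is None:
        return frozenset(), "infeasible"
    return frozenset(best[2]), "optimal"


def _milp(
    model: cobra.Model,
    env: EnvironmentConfig,
    target: str,
    candidates: Sequence[KnockoutUnit],
    k: int,
) -> tuple[frozenset[str], str]:
    target_rxn = resolve_target(model, target)
    growth_id = biomass_reaction_id(model)
    reactions = sorted(model.reactions, key=lambda r: r.id)
    rids = [r.id for r in reactions]
    S = create_stoichiometric_matrix(model)  # metabolites x reactions (model order)
    order = {r.id: i for i, r in enumerate(model.reactions)}
    unit_of: dict[str, str] = {}
    for u in candidates:
        for rid in u.member_reactions:
            if rid not in order:
                raise ValueError(f"candidate unit member {rid} not in model")
            unit_of[rid] = u.unit_id

    milp = MilpModel(name="optknock")
    v: dict[str, Variable] = {}
    mu: dict[str, Variable] = {}
    nu: dict[str, Variable] = {}
    lbs: dict[str, float] = {}
    ubs: dict[str, float] = {}
    for r in reactions:
        lb, ub = r.lower_bound, r.upper_bound
        if r.id == growth_id:
            lb = max(lb, env.min_growth)
        lbs[r.id], ubs[r.id] = lb, ub
        if r.id in unit_of:
            vlb, vub = min(lb, 0.0), max(ub, 0.0)
        else:
            vlb, vub = lb, ub
        v[r.id] = Variable(f"v_{r.id}", lb=vlb, ub=vub)
        dual_ub = M_DUAL if r.id in unit_of else None
        mu[r.id] = Variable(f"mu_{r.id}", lb=0, ub=dual_ub)
        nu[r.id] = Variable(f"nu_{r.id}", lb=0, ub=dual_ub)
    lam = {m.id: Variable(f"lam_{m.id}", lb=None, ub=None) for m in model.metabolites}
    y = {u.unit_id: Variable(f"y_{u.unit_id}", type="binary") for u in candidates}

    cons: list[Constraint] = []
    # primal: S v = 0
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    for m in model.metabolites:
        i = met_index[m.id]
        expr = sum(S[i, order[rid]] * v[rid] for rid in rids if S[i, order[rid]] != 0.0)
        cons.append(Constraint(expr, lb=0, ub=0, name=f"mass_{m.id}"))
    # primal: bounds switched off by y for knockable members
    for rid, uid in unit_of.items():
        cons.append(Constraint(v[rid] - ubs[rid] * (1 - y[uid]), ub=0, name=f"pub_{rid}"))
        cons.append(Constraint(v[rid] - lbs[rid] * (1 - y[uid]), lb=0, name=f"plb_{rid}"))
    # dual feasibility: S^T lam + mu - nu = c
    for rid in rids:
        j = order[rid]
        expr = sum(S[met_index[m.id], j] * lam[m.id] for m in model.metabolites
                   if S[met_index[m.id], j] != 0.0)
        c_j = 1.0 if rid == growth_id else 0.0
        cons.append(Constraint(expr + mu[rid] - nu[rid], lb=c_j, ub=c_j, name=f"dual_{rid}"))
    # linearized products z = y*mu, w = y*nu for knockable members
    z: dict[str, Variable] = {}
    w: dict[str, Variable] = {}
    for rid, uid in unit_of.items():
        z[rid] = Variable(f"z_{rid}", lb=0, ub=M_DUAL)
        w[rid] = Variable(f"w_{rid}", lb=0, ub=M_DUAL)
        cons.append(Constraint(z[rid] - M_DUAL * y[uid], ub=0, name=f"z1_{rid}"))
        cons.append(Constraint(z[rid] - mu[rid], ub=0, name=f"z2_{rid}"))
        cons.append(Constraint(z[rid] - mu[rid] + M_DUAL * (1 - y[uid]), lb=0, name=f"z3_{rid}"))
        cons.append(Constraint(w[rid] - M_DUAL * y[uid], ub=0, name=f"w1_{rid}"))
        cons.append(Constraint(w[rid] - nu[rid], ub=0, name=f"w2_{rid}"))
        cons.append(Constraint(w[rid] - nu[rid] + M_DUAL * (1 - y[uid]), lb=0, name=f"w3_{rid}"))
    # strong duality: dual objective <= primal growth (+ gap); weak duality
    # guarantees the reverse inequality for any feasible primal/dual pair
    dual_obj = 0
    for rid in rids:
        term_mu = ubs[rid] * mu[rid]
        term_nu = lbs[rid] * nu[rid]
        if rid in unit_of:
            term_mu = term_mu - ubs[rid] * z[rid]
            term_nu = term_nu - lbs[rid] * w[rid]
        dual_obj = dual_obj + term_mu - term_nu
    cons.append(Constraint(dual_obj - v[growth_id], ub=DUALITY_GAP, name="strong_duality"))
    cons.append(Constraint(sum(y.values()), ub=k, name="knockout_budget"))

    milp.add(list(v.values()) + list(mu.values()) + list(nu.values())
             + list(lam.values()) + list(y.values()) + list(z.values()) + list(w.values()))
    milp.add(cons)
    milp.objective = Objective(v[target_rxn], direction="max")
    status = milp.optimize()
    if status in ("infeasible", "undefined"):
        return frozenset(), "infeasible"
    if status != "optimal":
        raise SolverError(f"MILP solver returned status {status!r}", status=status)
    chosen = frozenset(uid for uid, var in y.items() if var.primal > 0.5)
    return chosen, "optimal"


def select_candidate_reactions(
    screening: ScreeningResult,
    model: cobra.Model,
    env: EnvironmentConfig,
    target: str,
    units: Sequence[KnockoutUnit],
    top_n: int = 30,
) -> list[KnockoutUnit]:
    """Pick the units behind the best-yielding screened candidate sets.

    Each unit occurring in any stored candidate set is scored by the
    highest lexicographic target flux among the candidate sets that
    contain it; the ``top_n`` units by that score are returned (ties
    broken by unit id).  Default 30.
    """
    by_id = {u.unit_id: u for u in units}
    if not screening.candidate_units:
        logger.warning("screening for %s stored no candidates", target)
        return []
    best_flux: dict[str, float] = {}
    for unit_set in screening.candidate_units:
        reactions = frozenset(
            rid for uid in unit_set for rid in by_id[uid].member_reactions
        )
        _, flux = lexicographic_target_max(
            model, env, target, reactions, enforce_min_growth=True
        )
        if math.isnan(flux):
            continue
        for uid in unit_set:
            if flux > best_flux.get(uid, -math.inf):
                best_flux[uid] = flux
    ranked = sorted(best_flux, key=lambda uid: (-best_flux[uid], uid))
    return [by_id[uid] for uid in ranked[:top_n]]


def fastpros_then_optknock(
    model: cobra.Model,
    env: EnvironmentConfig,
    target: str,
    units: Sequence[KnockoutUnit],
    cfg=None,
    k_list: Iterable[int] = (3, 5, 10),
    top_n: int = 30,
) -> dict[int, OptKnockResult]:
    """Screen, pick the top candidate units, then OptKnock for each K."""
    from .screening import screen  # local import to avoid cycle at module load

    screening = screen(model, env, target, units, cfg)
    selected = select_candidate_reactions(screening, model, env, target, units, top_n)
    results: dict[int, OptKnockResult] = {}
    for k in k_list:
        if not selected:
            results[k] = OptKnockResult(
                status="no_candidates", k=k, knockout_units=frozenset(),
                knockout_reactions=frozenset(), growth=float("nan"),
                target_flux_at_biomass_max=0.0, tmy_flux=float("nan"),
                yield_fraction_tmy=0.0, backend="none",
            )
        else:
            results[k] = optknock(model, env, target, selected, k)
    return results
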