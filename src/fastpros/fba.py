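"""Flux-balance LPs: biomass maximization, lexicographic target
maximization, theoretical maximum yield, and the shadow-price score.

The screening score of a knockout set is the dual value (shadow price)
of the equality constraint ``v_target = b_target`` in the LP

    max  v_growth
    s.t. S v = 0,  bounds,  v_growth >= min_growth,
         v_j = 0 for knocked-out reactions,
         v_target = b_target,

i.e. the marginal change in maximal biomass production per unit of
forced target production.  A negative score means production costs
growth; zero or positive means the target is (or has become) a
by-product of growth-optimal metabolism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import cobra
import pandas as pd

from .environment import EnvironmentConfig
from .exceptions import SolverError
from .io import biomass_reaction_id, resolve_target

#: |dual| at or below this is classified "zero" (absorbs solver noise)
ZERO_TOL = 1e-9

OPTIMAL = "optimal"


def knockout_reaction_ids(knockouts: Iterable) -> frozenset[str]:
    """Flatten knockouts given as reaction ids or KnockoutUnit objects."""
    rids: set[str] = set()
    for ko in knockouts:
        if isinstance(ko, str):
            rids.add(ko)
        elif hasattr(ko, "member_reactions"):
            rids.update(ko.member_reactions)
        else:
            raise TypeError(f"cannot interpret knockout {ko!r}")
    return frozenset(rids)


@dataclass
class FluxSolution:
    """Result of a single LP solve."""

    status: str
    objective_value: float
    fluxes: pd.Series | None = None
    duals: pd.Series | None = None

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL


@dataclass(frozen=True)
class ScoreRecord:
    """A knockout set with its shadow-price score and classification."""

    knockouts: frozenset[str]
    f_target: float
    classification: str  # negative | zero | positive | infeasible
    growth: float = float("nan")

    @property
    def is_candidate(self) -> bool:
        """Candidate knockout sets have score >= 0 (zero or positive)."""
        return self.classification in ("zero", "positive")


def classify(f_target: float) -> str:
    if math.isnan(f_target):
        return "infeasible"
    if abs(f_target) <= ZERO_TOL:
        return "zero"
    return "positive" if f_target > 0 else "negative"


def _apply_knockouts(model: cobra.Model, knockouts: Iterable) -> None:
    for rid in knockout_reaction_ids(knockouts):
        model.reactions.get_by_id(rid).knock_out()


def configure_solver(model: cobra.Model) -> None:
    """Disable the GLPK presolver retry on this model's solver.

    With presolve left on "auto", optlang re-runs a non-optimal solve
    through the GLPK presolver, whose failure path can mis-report an
    infeasible LP as optimal with an all-zero solution.  Infeasible
    scoring LPs are meaningful here (they classify a knockout set as
    unable to sustain the minimum growth), so they must be detected
    reliably.
    """
    model.solver.configuration.presolve = False


def _slim(model: cobra.Model) -> tuple[str, float]:
    configure_solver(model)
    value = model.slim_optimize(error_value=float("nan"))
    status = model.solver.status
    if status not in (OPTIMAL, "infeasible", "undefined", "unbounded"):
        raise SolverError(f"unexpected solver status {status!r}", status=status)
    if status != OPTIMAL:
        value = float("nan")
    return ("infeasible" if status != OPTIMAL else OPTIMAL), value


def maximize_biomass(
    model: cobra.Model,
    env: EnvironmentConfig,
    knockouts: Iterable = (),
    enforce_min_growth: bool = False,
) -> FluxSolution:
    """Maximize biomass production under the given knockouts.

    Returns the full flux distribution and metabolite shadow prices.
    ``min_growth`` is not imposed unless requested (it only matters for
    feasibility classification).
    """
    configure_solver(model)
    with model:
        _apply_knockouts(model, knockouts)
        if enforce_min_growth:
            growth = model.reactions.get_by_id(biomass_reaction_id(model))
            growth.lower_bound = max(growth.lower_bound, env.min_growth)
        solution = model.optimize()
        if solution.status != OPTIMAL:
            return FluxSolution(status="infeasible", objective_value=float("nan"))
        return FluxSolution(
            status=OPTIMAL,
            objective_value=solution.objective_value,
            fluxes=solution.fluxes,
            duals=solution.shadow_prices,
        )


def lexicographic_target_max(
    model: cobra.Model,
    env: EnvironmentConfig,
    target: str,
    knockouts: Iterable = (),
    enforce_min_growth: bool = False,
) -> tuple[float, float]:
    """Maximize biomass, then maximize target export at fixed optimal biomass.

    Returns ``(growth, target_flux)``; ``(nan, nan)`` when infeasible.
    The secondary LP fixes growth at its optimum with a 1e-9 relative
    slack to avoid spurious infeasibility at the vertex.
    """
    target_rxn_id = resolve_target(model, target)
    growth_id = biomass_reaction_id(model)
    with model:
        _apply_knockouts(model, knockouts)
        growth_rxn = model.reactions.get_by_id(growth_id)
        if enforce_min_growth:
            growth_rxn.lower_bound = max(growth_rxn.lower_bound, env.min_growth)
        status, growth = _slim(model)
        if status != OPTIMAL:
            return float("nan"), float("nan")
        # refix growth at its optimum with a tiny relative slack; GLPK
        # restarts from the optimal basis, so exact refixing is safe and
        # the slack leaks < 1e-10 into the secondary objective
        growth_rxn.lower_bound = growth - abs(growth) * 1e-12
        model.objective = model.reactions.get_by_id(target_rxn_id)
        status, target_flux = _slim(model)
        if status != OPTIMAL:  # numerically impossible unless degenerate
            return growth, float("nan")
        return growth, target_flux


@dataclass
class TMYResult:
    """Theoretical maximum yield of a target metabolite."""

    target_flux: float  # mmol/gDW/h at max production
    substrate_uptake: float  # mmol/gDW/h
    mol_per_mol: float
    g_per_g: float | None = None


def theoretical_max_yield(
    model: cobra.Model,
    env: EnvironmentConfig,
    target: str,
    enforce_min_growth: bool = False,
) -> TMYResult:
    """Maximum target production per unit substrate, ignoring growth optimality.

    Growth is required only to meet ``min_growth`` when
    ``enforce_min_growth`` is set; by default the cell may divert all
    substrate to the product.
    """
    target_rxn_id = resolve_target(model, target)
    configure_solver(model)
    with model:
        if enforce_min_growth:
            growth = model.reactions.get_by_id(biomass_reaction_id(model))
            growth.lower_bound = max(growth.lower_bound, env.min_growth)
        model.objective = model.reactions.get_by_id(target_rxn_id)
        solution = model.optimize()
        if solution.status != OPTIMAL:
            raise SolverError("TMY LP not optimal", status=solution.status)
        target_flux = solution.objective_value
        uptake = -solution.fluxes[env.glucose_exchange]
    if uptake <= 1e-12:
        raise ZeroDivisionError(
            "substrate uptake is zero at maximum production; yield undefined"
        )
    g_per_g = None
    try:
        target_rxn = model.reactions.get_by_id(target_rxn_id)
        tmet = next(iter(target_rxn.metabolites))
        smet = next(iter(model.reactions.get_by_id(env.glucose_exchange).metabolites))
        if tmet.formula_weight and smet.formula_weight:
            g_per_g = (target_flux * tmet.formula_weight) / (uptake * smet.formula_weight)
    except Exception:  # missing formulas on toy models
        pass
    return TMYResult(
        target_flux=target_flux,
        substrate_uptake=uptake,
        mol_per_mol=target_flux / uptake,
        g_per_g=g_per_g,
    )


def shadow_price_score(
    model: cobra.Model,
    env: EnvironmentConfig,
    target: str,
    knockouts: Iterable = (),
) -> ScoreRecord:
    """Score a knockout set by the shadow price of forced target production.

    Solves the biomass-maximizing LP with the equality
    ``v_target = env.b_target`` and ``v_growth >= env.min_growth`` and
    returns the dual value of the production constraint.  An infeasible
    LP (the strain cannot sustain the minimum growth while producing)
    yields classification ``"infeasible"``.
    """
    target_rxn_id = resolve_target(model, target)
    growth_id = biomass_reaction_id(model)
    ko = knockout_reaction_ids(knockouts)
    with model:
        _apply_knockouts(model, ko)
        growth_rxn = model.reactions.get_by_id(growth_id)
        growth_rxn.lower_bound = max(growth_rxn.lower_bound, env.min_growth)
        target_rxn = model.reactions.get_by_id(target_rxn_id)
        constraint = model.problem.Constraint(
            target_rxn.flux_expression,
            lb=env.b_target,
            ub=env.b_target,
            name="fastpros_force_target",
        )
        model.add_cons_vars([constraint])
        status, growth = _slim(model)
        if status != OPTIMAL:
            return ScoreRecord(
                knockouts=ko, f_target=float("nan"), classification="infeasible"
            )
        dual = float(constraint.dual)
        return ScoreRecord(
            knockouts=ko, f_target=dual, classification=classify(dual), growth=growth
        )
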