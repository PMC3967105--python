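"""Model reduction and knockout-unit construction.

Three structural steps shrink the search space before screening while
leaving every flux optimum unchanged:

1. reactions that can carry no flux under the environment (flux
   variability range identically zero) are removed;
2. adjacent reactions joined by an unbranched intermediate are lumped
   into one reaction (knocking out either member has the same effect);
3. reactions encoded by identical gene sets are grouped into a single
   knockout unit, since they cannot be disrupted independently.

Units whose genes appear in a protected list (by default *gapA*, *pgk*,
*eno*, *gpmA*, which are essential in vivo) are kept but flagged
non-knockable, as are exchanges, the biomass reaction, ATP maintenance,
target exporters and spontaneous (gene-less) reactions.
"""

from __future__ import annotations

import ast
import logging
from dataclasses import dataclass, field
from typing import Iterable

import cobra
import pandas as pd
from cobra import Reaction
from cobra.flux_analysis import flux_variability_analysis

from .environment import EnvironmentConfig
from .exceptions import InfeasibleModelError
from .fba import OPTIMAL, configure_solver
from .io import ROLE_KEY, EXPORTER_ROLE, biomass_reaction_id

logger = logging.getLogger(__name__)

#: default genes whose reactions are never offered as knockouts
DEFAULT_PROTECTED_GENES = frozenset({"gapA", "pgk", "eno", "gpmA"})

#: metabolite base ids (compartment suffix stripped) excluded from
#: pathway lumping — they occur in many reactions as cofactors, and an
#: apparent two-reaction adjacency through them is not a linear pathway
DEFAULT_COFACTORS = frozenset(
    {"atp", "adp", "amp", "nad", "nadh", "nadp", "nadph", "h", "h2o", "pi",
     "ppi", "co2", "o2", "coa", "nh4", "q8", "q8h2", "fad", "fadh2"}
)

#: FVA tolerance for calling a reaction blocked, on the ±1000-bounded LP
BLOCKED_TOL = 1e-9


@dataclass(frozen=True)
class KnockoutUnit:
    """A group of reactions that can only be deleted together."""

    unit_id: str
    member_reactions: frozenset[str]
    gene_sets: frozenset[frozenset[str]]
    knockable: bool

    def __post_init__(self):
        if not self.member_reactions:
            raise ValueError("knockout unit must have at least one member reaction")


@dataclass
class ReductionMap:
    """Bookkeeping from a reduced model back to the original.

    ``lumped_to_original`` maps each lumped reaction id to the original
    member reactions with the scale factor converting the lumped flux to
    each member flux.  Reactions absent from both mappings were kept
    unchanged.
    """

    lumped_to_original: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    removed_blocked: list[str] = field(default_factory=list)
    protected_removed: list[str] = field(default_factory=list)

    def original_reactions(self, reaction_id: str) -> list[str]:
        """Original reaction ids behind a (possibly lumped) reduced id."""
        if reaction_id in self.lumped_to_original:
            return [rid for rid, _ in self.lumped_to_original[reaction_id]]
        return [reaction_id]

    def to_dict(self) -> dict:
        return {
            "lumped_to_original": {
                k: [[rid, s] for rid, s in v] for k, v in self.lumped_to_original.items()
            },
            "removed_blocked": list(self.removed_blocked),
            "protected_removed": list(self.protected_removed),
        }


def flux_variability(model: cobra.Model, env: EnvironmentConfig) -> pd.DataFrame:
    """Per-reaction (minimum, maximum) flux under the environment.

    No growth-optimality constraint is imposed — reactions that only
    carry flux away from the growth optimum must survive reduction, or
    knockout phenotypes would change.  ``min_growth`` is likewise not
    imposed.
    """
    configure_solver(model)
    value = model.slim_optimize(error_value=float("nan"))
    if model.solver.status != OPTIMAL or value != value:
        raise InfeasibleModelError("model is infeasible under the environment")
    return flux_variability_analysis(model, fraction_of_optimum=0.0, processes=1)


def remove_blocked(
    model: cobra.Model,
    fva: pd.DataFrame,
    tol: float = BLOCKED_TOL,
) -> tuple[cobra.Model, ReductionMap]:
    """Remove reactions whose FVA range is identically zero.

    Returns a copy; the input model is untouched.  Raises KeyError if
    the FVA table does not cover the model's reactions (a guard against
    applying variability computed under a different environment/model).
    """
    missing = {r.id for r in model.reactions} - set(fva.index)
    if missing:
        raise KeyError(
            f"FVA table does not cover reactions {sorted(missing)[:5]}...; "
            "recompute flux_variability on this model"
        )
    blocked = [
        rid
        for rid in (r.id for r in model.reactions)
        if abs(fva.at[rid, "minimum"]) <= tol and abs(fva.at[rid, "maximum"]) <= tol
    ]
    reduced = model.copy()
    rmap = ReductionMap(removed_blocked=blocked)
    if blocked:
        reduced.remove_reactions(
            [reduced.reactions.get_by_id(r) for r in blocked], remove_orphans=True
        )
        logger.info("removed %d blocked reactions", len(blocked))
    return reduced, rmap


def _gpr_dnf(reaction: Reaction) -> frozenset[frozenset[str]]:
    """Gene rule in disjunctive normal form: a set of alternative gene sets."""
    rule = reaction.gene_reaction_rule
    if not rule or not rule.strip():
        return frozenset()

    def rec(node) -> set[frozenset[str]]:
        if isinstance(node, ast.Name):
            return {frozenset({node.id})}
        if isinstance(node, ast.BoolOp):
            parts = [rec(v) for v in node.values]
            if isinstance(node.op, ast.Or):
                out: set[frozenset[str]] = set()
                for p in parts:
                    out |= p
                return out
            out = {frozenset()}
            for p in parts:
                out = {a | b for a in out for b in p}
            return out
        if isinstance(node, ast.Expression):
            return rec(node.body)
        raise ValueError(f"unsupported GPR node {ast.dump(node)}")

    body = reaction.gpr.body
    if isinstance(body, list):  # ast.Module-style body
        body = body[0]
    return frozenset(rec(body))


def _never_lump(model: cobra.Model, protected_ids: set[str]):
    def check(rxn: Reaction) -> bool:
        return rxn.boundary or rxn.id in protected_ids or rxn.annotation.get(ROLE_KEY) == EXPORTER_ROLE
    return check


def lump_linear_pathways(
    model: cobra.Model,
    env: EnvironmentConfig | None = None,
    cofactors: frozenset[str] = DEFAULT_COFACTORS,
) -> tuple[cobra.Model, ReductionMap]:
    """Merge reaction pairs joined by an unbranched internal metabolite.

    A metabolite occurring in exactly two non-boundary reactions forces
    a fixed flux ratio between them; the pair is replaced by one lumped
    reaction with rescaled stoichiometry and intersected bounds, and the
    mapping from lumped flux back to member fluxes is recorded.  Applied
    to a fixpoint, so chains of any length collapse.  Merges across a
    knockable/non-knockable divide (one reaction gene-encoded, the other
    spontaneous or protected plumbing) are skipped to keep knockout
    semantics clean, as are adjacencies through common cofactors.
    """
    reduced = model.copy()
    rmap = ReductionMap()
    protected_ids = {biomass_reaction_id(reduced)}
    if env is not None and env.atp_maintenance is not None:
        protected_ids.add(env.atp_maintenance)
    skip_rxn = _never_lump(reduced, protected_ids)
    members: dict[str, list[tuple[str, float]]] = {}

    def member_list(rxn: Reaction, scale: float) -> list[tuple[str, float]]:
        if rxn.id in members:
            return [(rid, s * scale) for rid, s in members[rxn.id]]
        return [(rxn.id, scale)]

    changed = True
    counter = 0
    while changed:
        changed = False
        for met in list(reduced.metabolites):
            if met.id not in reduced.metabolites:
                continue
            base = met.id.rsplit("_", 1)[0].lower()
            if base in cofactors:
                continue
            rxns = sorted(met.reactions, key=lambda r: r.id)
            if len(rxns) != 2:
                continue
            p, q = rxns
            if skip_rxn(p) or skip_rxn(q):
                continue
            if bool(p.genes) != bool(q.genes):
                continue  # knockable/non-knockable boundary
            alpha = p.metabolites[met]
            beta = q.metabolites[met]
            scale = -alpha / beta  # v_q = scale * v_p balances met
            if scale > 0:
                lb_q, ub_q = q.lower_bound / scale, q.upper_bound / scale
            else:
                lb_q, ub_q = q.upper_bound / scale, q.lower_bound / scale
            lb = max(p.lower_bound, lb_q)
            ub = min(p.upper_bound, ub_q)
            if lb > ub + 1e-12 or (abs(lb) < 1e-12 and abs(ub) < 1e-12):
                continue  # incompatible orientations; leave as is
            stoich: dict = {}
            for m, c in p.metabolites.items():
                stoich[m] = stoich.get(m, 0.0) + c
            for m, c in q.metabolites.items():
                stoich[m] = stoich.get(m, 0.0) + scale * c
            assert abs(stoich.get(met, 0.0)) < 1e-9
            stoich = {m: c for m, c in stoich.items() if m is not met and abs(c) > 1e-12}

            counter += 1
            lump = Reaction(f"LUMP_{counter}__{p.id}__{q.id}", lower_bound=lb, upper_bound=ub)
            reduced.add_reactions([lump])
            lump.add_metabolites(stoich)
            rules = [r.gene_reaction_rule for r in (p, q) if r.gene_reaction_rule.strip()]
            if rules:
                lump.gene_reaction_rule = " and ".join(f"({r})" for r in rules)
            members[lump.id] = member_list(p, 1.0) + member_list(q, scale)
            members.pop(p.id, None)
            members.pop(q.id, None)
            reduced.remove_reactions([p, q], remove_orphans=True)
            changed = True
    rmap.lumped_to_original = dict(members)
    if members:
        logger.info("lumped %d linear pathway segments", len(members))
    return reduced, rmap


def build_knockout_units(
    model: cobra.Model,
    env: EnvironmentConfig | None = None,
    protected_genes: frozenset[str] = DEFAULT_PROTECTED_GENES,
) -> list[KnockoutUnit]:
    """Partition reactions into knockout units by gene-set signature.

    Reactions whose gene rules reduce to exactly the same set of
    alternative gene sets form one unit (they cannot be disrupted
    separately).  Boundary reactions, the biomass reaction, ATP
    maintenance, target exporters and spontaneous reactions each form
    their own non-knockable unit; units touching a protected gene are
    kept but marked non-knockable.
    """
    growth_id = biomass_reaction_id(model)
    atpm = env.atp_maintenance if env is not None else None
    groups: dict[frozenset[frozenset[str]], list[str]] = {}
    singles: list[KnockoutUnit] = []
    for rxn in sorted(model.reactions, key=lambda r: r.id):
        structural = (
            rxn.boundary
            or rxn.id == growth_id
            or rxn.id == atpm
            or rxn.annotation.get(ROLE_KEY) == EXPORTER_ROLE
        )
        signature = _gpr_dnf(rxn)
        if structural or not signature:
            singles.append(
                KnockoutUnit(
                    unit_id=rxn.id,
                    member_reactions=frozenset({rxn.id}),
                    gene_sets=signature,
                    knockable=False,
                )
            )
            continue
        groups.setdefault(signature, []).append(rxn.id)

    units = singles
    for signature, rids in groups.items():
        genes = frozenset(g for gs in signature for g in gs)
        units.append(
            KnockoutUnit(
                unit_id="+".join(sorted(rids)),
                member_reactions=frozenset(rids),
                gene_sets=signature,
                knockable=not (genes & protected_genes),
            )
        )
    units.sort(key=lambda u: u.unit_id)
    return units


@dataclass
class ReducedModel:
    """Result of the full reduction pipeline."""

    model: cobra.Model
    map: ReductionMap
    units: list[KnockoutUnit]

    @property
    def knockable_units(self) -> list[KnockoutUnit]:
        return [u for u in self.units if u.knockable]


def reduce_model(
    model: cobra.Model,
    env: EnvironmentConfig,
    protected_genes: frozenset[str] = DEFAULT_PROTECTED_GENES,
    cofactors: frozenset[str] = DEFAULT_COFACTORS,
    lump: bool = True,
) -> ReducedModel:
    """Run blocked-reaction removal, pathway lumping and unit construction."""
    fva = flux_variability(model, env)
    pruned, rmap = remove_blocked(model, fva)
    if lump:
        lumped, lmap = lump_linear_pathways(pruned, env, cofactors)
        rmap.lumped_to_original = lmap.lumped_to_original
    else:
        lumped = pruned
    units = build_knockout_units(lumped, env, protected_genes)
    rmap.protected_removed = [
        u.unit_id
        for u in units
        if not u.knockable
        and any(g in protected_genes for gs in u.gene_sets for g in gs)
    ]
    return ReducedModel(model=lumped, map=rmap, units=units)


def map_knockouts_to_original(
    rmap: ReductionMap, units: Iterable[KnockoutUnit]
) -> frozenset[str]:
    """Original-model reaction ids corresponding to a set of reduced units."""
    rids: set[str] = set()
    for unit in units:
        for rid in unit.member_reactions:
            rids.update(rmap.original_reactions(rid))
    return frozenset(rids)
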