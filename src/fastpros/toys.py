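"""Hand-checkable toy metabolic models and brute-force oracles.

``make_toy1`` builds the canonical six-metabolite network whose optima
are exact rationals: a substrate A feeding biomass through B, an NADH
by-product that must be vented (fermentation R2) or respired (R3,
oxygen-limited), and a target T drawing on both A and NADH.  Knocking
out the vent R2 forces NADH through the target route, which makes T a
growth-coupled by-product — the smallest instance of the redox-coupling
mechanism the screening method exploits.

``make_random_toy`` draws seeded variants of the same architecture with
randomized pathway multiplicity and stoichiometry, plus optional linear
chains (lumping fodder) and dead ends (blocked-reaction fodder), each
certified at generation time to be feasible and, when redox coupling is
requested, to admit a growth-coupling knockout set of at most three
units.  The brute-force subset screen and the finite-difference score
serve as independent oracles for the beam search, the MILP and the LP
dual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import cobra
import numpy as np
from cobra import Metabolite, Model, Reaction

from .environment import BIG, EnvironmentConfig
from .exceptions import InfeasibleModelError
from .fba import OPTIMAL, configure_solver, knockout_reaction_ids, lexicographic_target_max
from .io import ROLE_KEY, EXPORTER_ROLE, biomass_reaction_id
from .reduction import KnockoutUnit

PRODUCING_TOL = 1e-9


def toy_environment(our: float = 5.0) -> EnvironmentConfig:
    """Environment matching the toy models (no ATP maintenance, min growth 0)."""
    return EnvironmentConfig(
        gur=10.0,
        our=our,
        ngam=0.0,
        min_growth=0.0,
        b_target=1e-5,
        glucose_exchange="EX_A",
        oxygen_exchange="EX_O2",
        atp_maintenance=None,
        free_exchanges=(),
    )


def _add_reaction(model, rid, stoich, lb, ub, gene=""):
    rxn = Reaction(rid, lower_bound=lb, upper_bound=ub)
    model.add_reactions([rxn])
    rxn.add_metabolites(stoich)
    if gene:
        rxn.gene_reaction_rule = gene
    return rxn


def make_toy1() -> Model:
    """The canonical toy network; all optima are exact rationals.

    Wild-type max growth is 10; the target T becomes growth-coupled
    only after deleting the NADH vent R2, after which the lexicographic
    optimum is (20/3, 10/3) and the shadow-price score flips from −1 to
    +1/2.  The theoretical maximum of T export is 20/3.
    """
    model = Model("TOY1")
    A = Metabolite("A_c", compartment="c")
    B = Metabolite("B_c", compartment="c")
    NADH = Metabolite("NADH_c", compartment="c")
    O2 = Metabolite("O2_c", compartment="c")
    T = Metabolite("T_c", compartment="c")
    F = Metabolite("F_c", compartment="c")
    _add_reaction(model, "EX_A", {A: -1}, -10, 0)
    _add_reaction(model, "EX_O2", {O2: -1}, -5, 0)
    _add_reaction(model, "R1", {A: -1, B: 1, NADH: 2}, 0, BIG, "g1")
    _add_reaction(model, "R2", {NADH: -1, F: 1}, 0, BIG, "g2")
    _add_reaction(model, "R3", {NADH: -1, O2: -0.5}, 0, BIG, "g3")
    _add_reaction(model, "GROWTH", {B: -1}, 0, BIG)
    _add_reaction(model, "R5", {A: -1, NADH: -1, T: 1}, 0, BIG, "g5")
    ex_t = _add_reaction(model, "EX_T", {T: -1}, 0, BIG)
    ex_t.annotation[ROLE_KEY] = EXPORTER_ROLE
    _add_reaction(model, "EX_F", {F: -1}, 0, BIG)
    model.objective = "GROWTH"
    return model


@dataclass
class ToyModelSpec:
    """Parameters of a randomized toy network draw."""

    n_branches: int = 2
    redox_coupling: bool = True
    seed: int = 0
    substrate_bound: float = 10.0
    oxygen_bound: float = 5.0
    with_chain: bool = True
    with_dead_end: bool = True
    max_retries: int = 50

    def __post_init__(self) -> None:
        if self.n_branches < 1:
            raise ValueError("n_branches must be >= 1")
        if self.substrate_bound <= 0 or self.oxygen_bound < 0:
            raise ValueError("bounds must be positive (substrate) / non-negative (oxygen)")


def _build_random_toy(spec: ToyModelSpec, rng: np.random.Generator) -> Model:
    model = Model(f"RTOY_seed{spec.seed}")
    A = Metabolite("A_c", compartment="c")
    B = Metabolite("B_c", compartment="c")
    NADH = Metabolite("NADH_c", compartment="c")
    O2 = Metabolite("O2_c", compartment="c")
    T = Metabolite("T_c", compartment="c")
    F = Metabolite("F_c", compartment="c")
    _add_reaction(model, "EX_A", {A: -1}, -spec.substrate_bound, 0)
    _add_reaction(model, "EX_O2", {O2: -1}, -spec.oxygen_bound, 0)
    _add_reaction(model, "GROWTH", {B: -1}, 0, BIG)
    nadh_coef = 0
    for i in range(spec.n_branches):
        a_i = int(rng.integers(1, 3))  # NADH per substrate, 1 or 2
        if spec.redox_coupling:
            nadh_coef = a_i
        chain = spec.with_chain and i == spec.n_branches - 1 and rng.random() < 0.7
        if chain:
            C = Metabolite(f"C{i}_c", compartment="c")
            c_i = int(rng.integers(1, 3))
            _add_reaction(model, f"P{i}a", {A: -1, C: c_i}, 0, BIG, f"gp{i}a")
            stoich = {C: -c_i, B: 1}
            if spec.redox_coupling:
                stoich[NADH] = a_i
            _add_reaction(model, f"P{i}b", stoich, 0, BIG, f"gp{i}b")
        else:
            stoich = {A: -1, B: 1}
            if spec.redox_coupling:
                stoich[NADH] = a_i
            _add_reaction(model, f"P{i}", stoich, 0, BIG, f"gp{i}")
    if spec.redox_coupling:
        _add_reaction(model, "V1", {NADH: -1, F: 1}, 0, BIG, "gv1")
        if rng.random() < 0.5:
            _add_reaction(model, "V2", {NADH: -2, F: 1}, 0, BIG, "gv2")
        _add_reaction(model, "RESP", {NADH: -1, O2: -0.5}, 0, BIG, "gr")
        t_coef = int(rng.integers(1, 3))
        _add_reaction(model, "TGT", {A: -1, NADH: -t_coef, T: 1}, 0, BIG, "gt")
    else:
        _add_reaction(model, "TGT", {A: -1, T: 1}, 0, BIG, "gt")
    if spec.with_dead_end and rng.random() < 0.5:
        X = Metabolite("X_c", compartment="c")
        _add_reaction(model, "DEAD", {B: -1, X: 1}, 0, BIG, "gd")
    ex_t = _add_reaction(model, "EX_T", {T: -1}, 0, BIG)
    ex_t.annotation[ROLE_KEY] = EXPORTER_ROLE
    _add_reaction(model, "EX_F", {F: -1}, 0, BIG)
    model.objective = "GROWTH"
    return model


def default_toy_units(model: Model) -> list[KnockoutUnit]:
    """One knockable unit per gene-bearing internal reaction of a toy model."""
    units = []
    growth = biomass_reaction_id(model)
    for rxn in sorted(model.reactions, key=lambda r: r.id):
        knockable = (
            bool(rxn.genes)
            and not rxn.boundary
            and rxn.id != growth
            and rxn.annotation.get(ROLE_KEY) != EXPORTER_ROLE
        )
        units.append(
            KnockoutUnit(
                unit_id=rxn.id,
                member_reactions=frozenset({rxn.id}),
                gene_sets=frozenset({frozenset(g.id for g in rxn.genes)})
                if rxn.genes
                else frozenset(),
                knockable=knockable,
            )
        )
    return units


def has_increasing_lineage(
    model: Model,
    env: EnvironmentConfig,
    target: str,
    units_by_id: dict[str, KnockoutUnit],
    unit_set: frozenset[str],
    eps: float = 1e-9,
) -> bool:
    """True if some knockout ordering of ``unit_set`` strictly raises the score.

    Checked with the finite-difference slope oracle.  An iterative
    screen that grows sets one knockout at a time and discards children
    whose score did not strictly improve can only discover sets with
    such an ordering; sets shielded by score plateaus (e.g. redundant
    by-product vents that must all fall before the score moves) are
    invisible to it by construction.
    """

    def reactions_of(uids: frozenset[str]) -> frozenset[str]:
        return frozenset(r for uid in uids for r in units_by_id[uid].member_reactions)

    def grow(prefix: frozenset[str], score: float) -> bool:
        if prefix == unit_set:
            return True
        for uid in sorted(unit_set - prefix):
            child = prefix | {uid}
            child_score = finite_difference_score(
                model, env, target, reactions_of(child)
            )
            if math.isnan(child_score) or not child_score > score + eps:
                continue
            if grow(child, child_score):
                return True
        return False

    for uid in sorted(unit_set):
        first = frozenset({uid})
        score = finite_difference_score(model, env, target, reactions_of(first))
        if math.isnan(score):
            continue
        if grow(first, score):
            return True
    return len(unit_set) == 0


def make_random_toy(spec: ToyModelSpec) -> Model:
    """Draw a feasible randomized toy network (same seed, same model).

    When ``spec.redox_coupling`` is set, the draw is certified by the
    enumeration oracle to admit a producing knockout set of at most
    three units, and every minimal producing set of size <= 3 is
    certified to have a strictly score-increasing knockout ordering
    (the reachability assumption of iterative screening; see
    :func:`has_increasing_lineage`).  Infeasible, uncoupled or
    plateau-shielded draws are resampled up to ``spec.max_retries``
    times with sub-seeds derived from ``spec.seed``.
    """
    env = toy_environment(our=spec.oxygen_bound)
    for attempt in range(spec.max_retries):
        rng = np.random.default_rng([spec.seed, attempt])
        model = _build_random_toy(spec, rng)
        configure_solver(model)
        growth = model.slim_optimize(error_value=float("nan"))
        if model.solver.status != OPTIMAL or not growth > PRODUCING_TOL:
            continue
        if spec.redox_coupling:
            units = [u for u in default_toy_units(model) if u.knockable]
            by_id = {u.unit_id: u for u in units}
            result = brute_force_screen(model, env, "T_c", units, max_k=3)
            if not result.producing:
                continue
            if not all(
                has_increasing_lineage(model, env, "T_c", by_id, s)
                for s in result.minimal
            ):
                continue
        return model
    raise InfeasibleModelError(
        f"could not draw a valid toy model for seed {spec.seed} "
        f"after {spec.max_retries} attempts"
    )


@dataclass
class BruteForceResult:
    """All producing knockout subsets up to a size cap, plus the minimal ones."""

    producing: list[frozenset[str]]
    minimal: list[frozenset[str]]
    target_flux: dict[frozenset[str], float]


def brute_force_screen(
    model: Model,
    env: EnvironmentConfig,
    target: str,
    units: Sequence[KnockoutUnit],
    max_k: int,
    guard: int = 10**6,
) -> BruteForceResult:
    """Exhaustive oracle: lexicographic FBA over every unit subset of size <= max_k.

    A subset is producing when the target flux at maximal biomass
    exceeds 1e-9.  Minimal sets are producing sets with no producing
    proper subset.
    """
    knockable = sorted((u for u in units if u.knockable), key=lambda u: u.unit_id)
    ids = [u.unit_id for u in knockable]
    total = sum(math.comb(len(ids), i) for i in range(0, min(max_k, len(ids)) + 1))
    if total > guard:
        raise ValueError(f"{total} subsets exceed the enumeration guard ({guard})")
    by_id = {u.unit_id: u for u in knockable}
    producing: list[frozenset[str]] = []
    flux_of: dict[frozenset[str], float] = {}
    for size in range(0, min(max_k, len(ids)) + 1):
        for combo in combinations(ids, size):
            subset = frozenset(combo)
            reactions = frozenset(r for uid in combo for r in by_id[uid].member_reactions)
            _, flux = lexicographic_target_max(
                model, env, target, reactions, enforce_min_growth=True
            )
            if math.isnan(flux):
                continue
            flux_of[subset] = flux
            if flux > PRODUCING_TOL:
                producing.append(subset)
    producing_set = set(producing)
    minimal = [
        s
        for s in producing
        if not any(p in producing_set for p in _proper_subsets(s))
    ]
    return BruteForceResult(producing=producing, minimal=minimal, target_flux=flux_of)


def _proper_subsets(s: frozenset[str]):
    for size in range(0, len(s)):
        yield from (frozenset(c) for c in combinations(sorted(s), size))


def _biomass_at_forced_target(
    model: Model, env: EnvironmentConfig, target: str, knockouts: Iterable, b: float
) -> float:
    from .io import resolve_target

    target_rxn_id = resolve_target(model, target)
    growth_id = biomass_reaction_id(model)
    configure_solver(model)
    with model:
        for rid in knockout_reaction_ids(knockouts):
            model.reactions.get_by_id(rid).knock_out()
        growth_rxn = model.reactions.get_by_id(growth_id)
        growth_rxn.lower_bound = max(growth_rxn.lower_bound, env.min_growth)
        target_rxn = model.reactions.get_by_id(target_rxn_id)
        constraint = model.problem.Constraint(
            target_rxn.flux_expression, lb=b, ub=b, name="fd_force_target"
        )
        model.add_cons_vars([constraint])
        value = model.slim_optimize(error_value=float("nan"))
        if model.solver.status != OPTIMAL:
            return float("nan")
        return value


def finite_difference_score(
    model: Model,
    env: EnvironmentConfig,
    target: str,
    knockouts: Iterable = (),
    delta: float | None = None,
) -> float:
    """Independent slope oracle (Φ(δ) − Φ(0)) / δ for the shadow price.

    Φ(b) is the maximal biomass production with target export fixed at
    ``b``.  Returns NaN when either LP is infeasible (matching the
    "infeasible" classification of the dual-based score).
    """
    if delta is None:
        delta = env.b_target
    phi0 = _biomass_at_forced_target(model, env, target, knockouts, 0.0)
    phid = _biomass_at_forced_target(model, env, target, knockouts, delta)
    if math.isnan(phi0) or math.isnan(phid):
        return float("nan")
    return (phid - phi0) / delta


def certify_locally_linear(
    model: Model,
    env: EnvironmentConfig,
    target: str,
    knockouts: Iterable = (),
    delta: float | None = None,
    tol: float = 1e-9,
) -> bool:
    """True when Φ is linear on [0, 2δ], certifying a unique dual at δ.

    Φ is concave (LP value function of a right-hand side), so equality
    of the chord slopes over [0, δ] and [0, 2δ] implies linearity on
    [0, 2δ]; the dual of the production constraint at b = δ is then
    unique and equals the slope.  Cases failing this check are LP-
    degenerate and excluded from dual-equality comparisons.
    """
    if delta is None:
        delta = env.b_target
    s1 = finite_difference_score(model, env, target, knockouts, delta)
    s2 = finite_difference_score(model, env, target, knockouts, 2 * delta)
    if math.isnan(s1) or math.isnan(s2):
        return False
    return abs(s1 - s2) <= tol * max(1.0, abs(s1))
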