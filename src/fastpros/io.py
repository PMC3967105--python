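"""Reading, writing and preparing constraint-based metabolic models.

Models are held in memory as :class:`cobra.Model` objects; this module
wraps the SBML (Level 3 + FBC) and BiGG-style JSON dialects, inserts a
diffusion exporter for a chosen target metabolite, and applies an
:class:`~fastpros.environment.EnvironmentConfig` to the exchange bounds.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import cobra
from cobra import Metabolite, Reaction
from cobra.util.solver import linear_reaction_coefficients

from .environment import BIG, EnvironmentConfig
from .exceptions import ConfigurationError, LookupError_, ModelFormatError

logger = logging.getLogger(__name__)

#: annotation key used to flag reactions fastpros inserted or relies on
ROLE_KEY = "fastpros_role"
EXPORTER_ROLE = "target_exporter"


def read_model(path: str | Path, format: str | None = None) -> cobra.Model:
    """Read a model from SBML-FBC or BiGG-style JSON.

    The dialect is inferred from the file suffix (``.xml``/``.sbml`` vs
    ``.json``) unless ``format`` ("sbml-fbc" or "bigg-json") is given.
    Bounds of infinite magnitude are clamped to ±1000 mmol/gDW/h so that
    downstream big-M formulations stay well posed.
    """
    path = Path(path)
    if not path.exists():
        raise ModelFormatError(f"model file not found: {path}")
    if format is None:
        format = "bigg-json" if path.suffix == ".json" else "sbml-fbc"
    try:
        if format == "bigg-json":
            model = cobra.io.load_json_model(str(path))
        elif format == "sbml-fbc":
            model = cobra.io.read_sbml_model(str(path))
        else:
            raise ModelFormatError(f"unknown model format: {format!r}")
    except ModelFormatError:
        raise
    except Exception as exc:  # libsbml / json decoding errors
        raise ModelFormatError(f"could not parse {path} as {format}: {exc}") from exc

    if not linear_reaction_coefficients(model):
        raise ModelFormatError(
            f"{path}: no biomass reaction (model declares no linear objective)"
        )
    _clamp_bounds(model)
    return model


def write_model(model: cobra.Model, path: str | Path, format: str | None = None) -> None:
    """Write a model as SBML-FBC (``.xml``) or BiGG-style JSON (``.json``)."""
    path = Path(path)
    if format is None:
        format = "bigg-json" if path.suffix == ".json" else "sbml-fbc"
    if format == "bigg-json":
        cobra.io.save_json_model(model, str(path))
    elif format == "sbml-fbc":
        cobra.io.write_sbml_model(model, str(path))
    else:
        raise ModelFormatError(f"unknown model format: {format!r}")


def _clamp_bounds(model: cobra.Model) -> None:
    for rxn in model.reactions:
        lb, ub = rxn.bounds
        changed = False
        if not math.isfinite(lb) or lb < -BIG:
            lb, changed = -BIG, True
        if not math.isfinite(ub) or ub > BIG:
            ub, changed = BIG, True
        if changed:
            logger.debug("clamping bounds of %s to [%g, %g]", rxn.id, lb, ub)
            rxn.bounds = (lb, ub)


def biomass_reaction_id(model: cobra.Model) -> str:
    """Id of the biomass reaction, taken from the model's linear objective."""
    coeffs = linear_reaction_coefficients(model)
    if not coeffs:
        raise ModelFormatError("model declares no linear objective")
    # with several objective terms, take the one with the largest weight
    return max(coeffs, key=lambda r: abs(coeffs[r])).id


def find_target_exporter(
    model: cobra.Model, metabolite_id: str, compartment_suffix: str = "_c"
) -> str | None:
    """Return the id of the boundary reaction exporting ``metabolite_id``.

    Two layouts are recognised: a boundary reaction draining the
    metabolite directly, or a transport reaction to an extracellular
    counterpart (same base id, ``_e`` suffix) that itself has an open
    boundary exchange.  Returns ``None`` when neither exists.
    """
    try:
        met = model.metabolites.get_by_id(metabolite_id)
    except KeyError as exc:
        raise LookupError_(f"unknown metabolite id: {metabolite_id}") from exc

    for rxn in model.boundary:
        if rxn.objective_coefficient != 0:
            continue  # a biomass drain is not an export route
        if set(rxn.metabolites) == {met} and rxn.metabolites[met] < 0 and rxn.upper_bound > 0:
            return rxn.id

    base = met.id[: -len(compartment_suffix)] if met.id.endswith(compartment_suffix) else met.id
    ext_id = base + "_e"
    if ext_id not in model.metabolites:
        return None
    ext = model.metabolites.get_by_id(ext_id)
    has_transport = any(
        met in rxn.metabolites
        and ext in rxn.metabolites
        and (
            (rxn.metabolites[met] < 0 < rxn.metabolites[ext] and rxn.upper_bound > 0)
            or (rxn.metabolites[ext] < 0 < rxn.metabolites[met] and rxn.lower_bound < 0)
        )
        for rxn in model.reactions
        if not rxn.boundary
    )
    if not has_transport:
        return None
    for rxn in model.boundary:
        if set(rxn.metabolites) == {ext} and rxn.metabolites[ext] < 0 and rxn.upper_bound > 0:
            return rxn.id
    return None


def add_target_exporter(
    model: cobra.Model, metabolite_id: str, compartment_suffix: str = "_c"
) -> cobra.Model:
    """Ensure the model can secrete ``metabolite_id``; modify in place.

    If an export route already exists the model is returned unchanged.
    Otherwise an irreversible diffusion transport to the extracellular
    compartment plus (if needed) a boundary exchange are inserted, both
    flagged as target exporters so they are never offered as knockouts.
    """
    existing = find_target_exporter(model, metabolite_id, compartment_suffix)
    if existing is not None:
        model.reactions.get_by_id(existing).annotation.setdefault(ROLE_KEY, EXPORTER_ROLE)
        return model

    met = model.metabolites.get_by_id(metabolite_id)
    base = met.id[: -len(compartment_suffix)] if met.id.endswith(compartment_suffix) else met.id
    ext_id = base + "_e"
    if ext_id in model.metabolites:
        ext = model.metabolites.get_by_id(ext_id)
    else:
        ext = Metabolite(
            ext_id,
            name=(met.name or base) + " (extracellular)",
            compartment="e",
            formula=met.formula,
            charge=met.charge,
        )

    transport = Reaction(f"TP_{base}", lower_bound=0.0, upper_bound=BIG)
    transport.annotation[ROLE_KEY] = EXPORTER_ROLE
    model.add_reactions([transport])
    transport.add_metabolites({met: -1.0, ext: 1.0})

    has_exchange = any(
        set(r.metabolites) == {ext} and r.metabolites[ext] < 0 and r.upper_bound > 0
        for r in model.boundary
    )
    if not has_exchange:
        exchange = Reaction(f"EX_{ext_id}", lower_bound=0.0, upper_bound=BIG)
        exchange.annotation[ROLE_KEY] = EXPORTER_ROLE
        model.add_reactions([exchange])
        exchange.add_metabolites({ext: -1.0})
    logger.info("added diffusion exporter for %s", metabolite_id)
    return model


def resolve_target(model: cobra.Model, target: str) -> str:
    """Resolve a target (metabolite id or reaction id) to its export reaction id."""
    if target in model.reactions:
        return target
    if target in model.metabolites:
        exporter = find_target_exporter(model, target)
        if exporter is None:
            raise LookupError_(
                f"metabolite {target} has no export route; call add_target_exporter first"
            )
        return exporter
    raise LookupError_(f"unknown target id: {target}")


def apply_environment(model: cobra.Model, env: EnvironmentConfig) -> cobra.Model:
    """Apply environmental bounds in place and return the model.

    Glucose uptake is capped at ``env.gur`` and oxygen at ``env.our``;
    ATP maintenance is fixed to ``env.ngam`` as an equality; exchanges
    listed in ``env.free_exchanges`` are opened in both directions; all
    other boundary uptakes are closed (secretion stays open).  The
    operation is idempotent.
    """
    boundary_ids = {r.id for r in model.boundary}
    for name, rid in (("glucose_exchange", env.glucose_exchange),
                      ("oxygen_exchange", env.oxygen_exchange)):
        if rid not in boundary_ids:
            raise ConfigurationError(
                f"{name} {rid!r} is not a boundary reaction of the model; "
                f"available exchanges: {sorted(boundary_ids)}"
            )
    free = set(env.free_exchanges)
    for rxn in model.boundary:
        if rxn.id == env.glucose_exchange:
            rxn.lower_bound = -env.gur
        elif rxn.id == env.oxygen_exchange:
            rxn.lower_bound = -env.our
        elif rxn.id in free:
            rxn.bounds = (-BIG, BIG)
        else:
            # close uptake, keep secretion open
            if rxn.lower_bound < 0:
                rxn.lower_bound = 0.0
    if env.atp_maintenance is not None:
        if env.atp_maintenance not in model.reactions:
            raise ConfigurationError(
                f"ATP maintenance reaction {env.atp_maintenance!r} not in model"
            )
        model.reactions.get_by_id(env.atp_maintenance).bounds = (env.ngam, env.ngam)
    return model


def write_provenance(path: str | Path, record: dict) -> None:
    """Write a sidecar JSON describing how a model file was prepared."""
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
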