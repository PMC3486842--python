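"""Minimal flux-balance-analysis engine.

Flux balance analysis treats a metabolic network as a stoichiometric matrix
``S`` (one row per reaction, one column per metabolite; ``S[r, j]`` is the
coefficient of metabolite ``j`` in reaction ``r``) and finds the flux vector
``v`` that maximizes the biomass reaction subject to steady state
(``v @ S = 0``) and per-reaction bounds. Uptake of nutrients is encoded as
exchange reactions whose upper bound is set by the medium.

This engine exists to generate *in silico* ground truth — growth/no-growth
(G/NG) labels and molar biomass yields — on small networks; it is not meant
to replace a full constraint-based modeling stack for genome-scale work.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .catalog import Nutrient

#: Default uptake flux bound for a carbon source (mmol·gDW⁻¹·h⁻¹ convention).
DEFAULT_UPTAKE_BOUND = 10.0
#: Biomass-flux threshold below which growth is not considered significant.
DEFAULT_EPSILON = 1e-6
#: Feasibility tolerance for the steady-state constraint.
FEASIBILITY_TOL = 1e-9


class FBAError(ValueError):
    pass


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]  # metabolite -> coefficient (products > 0)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0


@dataclass(frozen=True)
class MetabolicModel:
    """Stoichiometric network with a designated biomass reaction.

    ``exchange_reactions`` maps a nutrient id to the reaction that imports
    it; by convention an exchange reaction produces its extracellular
    metabolite from nothing, so positive flux is uptake.
    """

    metabolites: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    biomass_reaction_id: str
    exchange_reactions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise FBAError("duplicate reaction ids")
        if self.biomass_reaction_id not in set(ids):
            raise FBAError(f"biomass reaction {self.biomass_reaction_id!r} absent")
        met_set = set(self.metabolites)
        for rxn in self.reactions:
            unknown = set(rxn.stoichiometry) - met_set
            if unknown:
                raise FBAError(f"reaction {rxn.id}: unknown metabolites {unknown}")
        for nid, rid in self.exchange_reactions.items():
            if rid not in set(ids):
                raise FBAError(f"exchange for {nid} references missing reaction {rid}")

    @property
    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def stoichiometric_matrix(self) -> np.ndarray:
        """``S`` with one row per reaction and one column per metabolite."""
        met_index = {m: j for j, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.reactions), len(self.metabolites)))
        for i, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                S[i, met_index[met]] = coef
        return S

    def reaction(self, reaction_id: str) -> Reaction:
        return self.reactions[self.reaction_index[reaction_id]]


@dataclass(frozen=True)
class Medium:
    """Non-negative uptake bounds per nutrient; absent nutrients have bound 0."""

    uptake_bounds: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for nid, b in self.uptake_bounds.items():
            if b < 0:
                raise FBAError(f"negative uptake bound for {nid}")

    def bound(self, nutrient_id: str) -> float:
        return self.uptake_bounds.get(nutrient_id, 0.0)

    def with_nutrient(self, nutrient_id: str, bound: float) -> "Medium":
        merged = dict(self.uptake_bounds)
        merged[nutrient_id] = bound
        return Medium(merged)


@dataclass(frozen=True)
class FluxSolution:
    fluxes: Mapping[str, float]
    biomass_flux: float
    status: str  # optimal | infeasible | unbounded


def _apply_medium(model: MetabolicModel, medium: Medium) -> list[tuple[float, float]]:
    """Per-reaction bounds with exchange uptake capped by the medium."""
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    ridx = model.reaction_index
    for nid, rid in model.exchange_reactions.items():
        i = ridx[rid]
        bounds[i] = (0.0, medium.bound(nid))
    return bounds


def maximize_biomass(model: MetabolicModel, medium: Medium) -> FluxSolution:
    """LP optimum of biomass flux subject to steady state and bounds.

    The objective value is deterministic; the flux vector itself may sit on
    a degenerate vertex. An unbounded LP signals a mass-balance defect in
    the model and is reported as ``status="unbounded"``.
    """
    S = model.stoichiometric_matrix()
    n = len(model.reactions)
    c = np.zeros(n)
    c[model.reaction_index[model.biomass_reaction_id]] = -1.0  # linprog minimizes
    bounds = _apply_medium(model, medium)
    res = linprog(c, A_eq=S.T, b_eq=np.zeros(S.shape[1]), bounds=bounds, method="highs")
    if res.status == 3:
        return FluxSolution(fluxes={}, biomass_flux=np.inf, status="unbounded")
    if res.status != 0:
        return FluxSolution(fluxes={}, biomass_flux=0.0, status="infeasible")
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    return FluxSolution(
        fluxes=fluxes,
        biomass_flux=float(-res.fun),
        status="optimal",
    )


def label_growth(
    model: MetabolicModel,
    minimal_medium: Medium,
    nutrient: Nutrient | str,
    uptake_bound: float = DEFAULT_UPTAKE_BOUND,
    epsilon: float = DEFAULT_EPSILON,
) -> str:
    """Label a nutrient ``"G"`` or ``"NG"`` as a sole carbon source.

    A nutrient is G when adding it to the minimal medium raises biomass flux
    above ``epsilon``. The minimal medium itself must not support growth
    above ``epsilon``; if it does the model/medium pair is inconsistent and
    an error is raised. Nutrients with no exchange reaction cannot be
    uptaken and are NG.
    """
    nid = nutrient.id if isinstance(nutrient, Nutrient) else nutrient
    base = maximize_biomass(model, minimal_medium)
    if base.status == "optimal" and base.biomass_flux > epsilon:
        raise FBAError(
            f"minimal medium alone yields biomass flux {base.biomass_flux:.3g} "
            f"> epsilon={epsilon:g}; not a minimal medium"
        )
    if nid not in model.exchange_reactions:
        return "NG"
    sol = maximize_biomass(model, minimal_medium.with_nutrient(nid, uptake_bound))
    return "G" if sol.status == "optimal" and sol.biomass_flux > epsilon else "NG"


def measure_yield(
    model: MetabolicModel,
    minimal_medium: Medium,
    nutrient: Nutrient | str,
    uptake_bound: float = DEFAULT_UPTAKE_BOUND,
) -> float:
    """Molar biomass yield: optimal biomass flux per unit uptake flux used.

    On a linear (homogeneous) network this is invariant to the uptake bound.
    """
    nid = nutrient.id if isinstance(nutrient, Nutrient) else nutrient
    if nid not in model.exchange_reactions:
        raise FBAError(f"nutrient {nid} has no exchange reaction")
    sol = maximize_biomass(model, minimal_medium.with_nutrient(nid, uptake_bound))
    if sol.status != "optimal":
        raise FBAError(f"LP not optimal for {nid}: {sol.status}")
    uptake = sol.fluxes[model.exchange_reactions[nid]]
    if uptake <= FEASIBILITY_TOL * max(1.0, uptake_bound):
        raise FBAError(f"zero uptake of {nid} at optimum; yield undefined")
    return sol.biomass_flux / uptake


_DEFAULT_MAINTENANCE_PATTERN = r"(?i)^(R_)?ATPM$|maintenance"


def remove_atp_maintenance(
    model: MetabolicModel, pattern: str = _DEFAULT_MAINTENANCE_PATTERN
) -> MetabolicModel:
    """Disable the non-growth ATP maintenance drain (bounds set to [0, 0]).

    Reconstructions fit a forced ATP hydrolysis flux to empirical growth
    rates; maximal-conversion analysis removes it. The reaction is located
    by an id regex; more than one match is an error, no match leaves the
    model unchanged with a warning. Biomass stoichiometry is untouched.
    """
    rx = re.compile(pattern)
    matches = [r.id for r in model.reactions if rx.search(r.id)]
    if len(matches) > 1:
        raise FBAError(f"maintenance pattern matches several reactions: {matches}")
    if not matches:
        warnings.warn("no ATP-maintenance reaction found; model unchanged")
        return model
    new_reactions = tuple(
        replace(r, lower_bound=0.0, upper_bound=0.0) if r.id == matches[0] else r
        for r in model.reactions
    )
    return replace(model, reactions=new_reactions)


# ---------------------------------------------------------------------------
# TSV reaction dialect
#
# One reaction per line:
#   id <TAB> equation <TAB> lower <TAB> upper [<TAB> role]
# equation grammar: "A + 2 B -> C"; either side may be empty (exchanges and
# drains). role is empty, "biomass", or "exchange:<nutrient_id>". Reversible
# reactions are encoded by a negative lower bound, not by arrow style.


def _parse_side(text: str, sign: float, stoich: dict[str, float]) -> None:
    text = text.strip()
    if not text:
        return
    for term in text.split("+"):
        term = term.strip()
        if not term:
            continue
        parts = term.split()
        if len(parts) == 2:
            coef, met = float(parts[0]), parts[1]
        elif len(parts) == 1:
            coef, met = 1.0, parts[0]
        else:
            raise FBAError(f"cannot parse term {term!r}")
        stoich[met] = stoich.get(met, 0.0) + sign * coef


def parse_equation(equation: str) -> dict[str, float]:
    if "->" not in equation:
        raise FBAError(f"equation {equation!r} lacks '->'")
    left, right = equation.split("->", 1)
    stoich: dict[str, float] = {}
    _parse_side(left, -1.0, stoich)
    _parse_side(right, +1.0, stoich)
    return {m: c for m, c in stoich.items() if c != 0.0}


def format_equation(stoichiometry: Mapping[str, float]) -> str:
    def side(items: list[tuple[str, float]]) -> str:
        terms = []
        for met, coef in items:
            coef = abs(coef)
            terms.append(met if coef == 1 else f"{coef:g} {met}")
        return " + ".join(terms)

    subs = sorted((m, c) for m, c in stoichiometry.items() if c < 0)
    prods = sorted((m, c) for m, c in stoichiometry.items() if c > 0)
    return f"{side(subs)} -> {side(prods)}".strip()


def load_model_tsv(path: str | Path) -> MetabolicModel:
    """Read the TSV reaction dialect into a :class:`MetabolicModel`."""
    reactions: list[Reaction] = []
    biomass_id: str | None = None
    exchanges: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise FBAError(f"bad reaction line: {line!r}")
        rid, equation, lb, ub = fields[:4]
        role = fields[4].strip() if len(fields) > 4 else ""
        reactions.append(
            Reaction(rid, parse_equation(equation), float(lb), float(ub))
        )
        if role == "biomass":
            biomass_id = rid
        elif role.startswith("exchange:"):
            exchanges[role.split(":", 1)[1]] = rid
    if biomass_id is None:
        raise FBAError("no reaction marked with role 'biomass'")
    metabolites: list[str] = []
    seen: set[str] = set()
    for rxn in reactions:
        for met in rxn.stoichiometry:
            if met not in seen:
                seen.add(met)
                metabolites.append(met)
    return MetabolicModel(
        metabolites=tuple(metabolites),
        reactions=tuple(reactions),
        biomass_reaction_id=biomass_id,
        exchange_reactions=exchanges,
    )


def write_model_tsv(model: MetabolicModel, path: str | Path) -> None:
    rid_to_nutrient = {rid: nid for nid, rid in model.exchange_reactions.items()}
    lines = []
    for rxn in model.reactions:
        if rxn.id == model.biomass_reaction_id:
            role = "biomass"
        elif rxn.id in rid_to_nutrient:
            role = f"exchange:{rid_to_nutrient[rxn.id]}"
        else:
            role = ""
        lines.append(
            "\t".join(
                [
                    rxn.id,
                    format_equation(rxn.stoichiometry),
                    f"{rxn.lower_bound:g}",
                    f"{rxn.upper_bound:g}",
                    role,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_sbml(path: str | Path, biomass_pattern: str = r"(?i)biomass") -> MetabolicModel:
    """Read an SBML reconstruction (requires the optional ``cobra`` extra).

    Exchange reactions are taken from the boundary reactions; the biomass
    reaction is located by id/name regex (first match on the objective if
    one is set).
    """
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover
        raise FBAError("SBML support requires the 'cobra' package") from exc
    cmodel = cobra.io.read_sbml_model(str(path))
    reactions = []
    exchanges: dict[str, str] = {}
    biomass_id = None
    rx = re.compile(biomass_pattern)
    for rxn in cmodel.reactions:
        stoich = {m.id: coef for m, coef in rxn.metabolites.items()}
        reactions.append(Reaction(rxn.id, stoich, rxn.lower_bound, rxn.upper_bound))
        if rxn.objective_coefficient or rx.search(rxn.id):
            if biomass_id is None:
                biomass_id = rxn.id
    for rxn in cmodel.exchanges:
        mets = list(rxn.metabolites)
        if len(mets) == 1:
            # cobra convention is "met_e <->"; flip so positive flux = uptake
            stoich = {mets[0].id: 1.0}
            idx = [i for i, r in enumerate(reactions) if r.id == rxn.id][0]
            reactions[idx] = Reaction(
                rxn.id, stoich, max(0.0, -rxn.upper_bound), -rxn.lower_bound
            )
            exchanges[mets[0].id] = rxn.id
    if biomass_id is None:
        raise FBAError("no biomass reaction found in SBML model")
    metabolites = tuple(m.id for m in cmodel.metabolites)
    return MetabolicModel(
        metabolites=metabolites,
        reactions=tuple(reactions),
        biomass_reaction_id=biomass_id,
        exchange_reactions=exchanges,
    )
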