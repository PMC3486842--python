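"""Synthetic fixtures: toy catalogs, organisms, stoichiometric networks and
labeled datasets with planted structure.

Real inputs to this kind of analysis are genome-scale reconstructions and
curated pathway annotations. The generator stands in for them at desk
scale: it emits catalogs spanning all twelve nutrient classes (including
complex nutrients with known effective carbon counts), organism profiles
with controlled enzyme flags, linear stoichiometric networks whose biomass
yield is *exactly* proportional to catabolizable carbons (B_i = y0 · C_eff,
with an optional planted synergy reaction that makes multi-nutrient media
super-additive), and logistic training tables drawn from known
coefficients. Everything is driven by a single seeded RNG stream; the seed
is mandatory and the same seed reproduces every fixture bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    Catalog,
    G_CLASSES,
    NG_CLASSES,
    Nutrient,
    NutrientClass,
    OrganismProfile,
    PathwayCatalog,
    decompose,
)
from .classifier import classify
from .fba import (
    DEFAULT_UPTAKE_BOUND,
    Medium,
    MetabolicModel,
    Reaction,
    maximize_biomass,
)
from .logistic import LabeledDataset, LogisticPathwayModel
from .yields import PURINE_CARBON_LEAK


@dataclass
class FixtureSpec:
    """Knobs for the fixture generator; the seed is mandatory."""

    seed: int
    n_organic: int = 10
    uptake_prob: float = 0.85
    membership_prob: float = 0.5
    # planted logistic design: the four membership cells sit at logits
    # -1, 1, -2, 1.5, all informative enough (binomial Fisher information)
    # for coefficient recovery at moderate sample sizes
    planted_beta0: float = -1.0
    planted_beta: dict[str, float] = field(
        default_factory=lambda: {"pw_A": 2.0, "pw_B": -1.0}
    )
    planted_pair_beta: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("pw_A", "pw_B"): 1.5}
    )
    n_decoy_pathways: int = 3
    y0: float = 0.1
    synergy: bool = False
    n_rows: int = 1000


def planted_model(spec: FixtureSpec) -> LogisticPathwayModel:
    """The generating logistic model, packaged as a fitted model object."""
    pairs = [tuple(sorted(pr)) for pr in spec.planted_pair_beta]
    return LogisticPathwayModel(
        pathways=list(spec.planted_beta),
        pairs=pairs,  # type: ignore[arg-type]
        beta0=spec.planted_beta0,
        beta=dict(spec.planted_beta),
        beta_pairs={
            tuple(sorted(pr)): v for pr, v in spec.planted_pair_beta.items()
        },  # type: ignore[misc]
        fitted=True,
    )


# ---------------------------------------------------------------------------
# catalog + organisms


def make_catalog(
    spec: FixtureSpec,
) -> tuple[Catalog, PathwayCatalog, list[OrganismProfile]]:
    """Toy catalog spanning all 12 classes, pathway table, organism panel.

    Deterministic fixed-structure nutrients (glucose, a phospho-ribose-like
    sugar derivative, nucleobases, a thymidine-like nucleotide, a
    tryptophan-like complex amino acid, a lipid-A-like cell-boundary
    complex with multi-copy fatty-acid chains, a nested complex) are
    combined with seeded random organic compounds carrying pathway
    memberships. The organism panel varies the three gating enzymes, and
    includes one anaerobe.
    """
    rng = np.random.default_rng(spec.seed)
    pathway_ids = sorted(spec.planted_beta) + [
        f"pw_dec{i}" for i in range(spec.n_decoy_pathways)
    ]

    nutrients: list[Nutrient] = [
        # sugars
        Nutrient("glc", "glucose-like sugar", 6, NutrientClass.SUGARS),
        Nutrient("sug1", "pentose-like sugar", 5, NutrientClass.SUGARS),
        Nutrient("sug2", "disaccharide-like sugar", 12, NutrientClass.SUGARS),
        # sugar derivatives
        Nutrient("ribp", "phospho-ribose-like", 5, NutrientClass.SUGAR_DERIVATIVES),
        Nutrient("sgd1", "hexitol-like", 6, NutrientClass.SUGAR_DERIVATIVES),
        Nutrient("sgd2", "uronate-like", 6, NutrientClass.SUGAR_DERIVATIVES),
        # amino acids route through the logistic rule; membership in the
        # planted G pathway pw_A makes the simple ones catabolizable
        Nutrient("aa_ala", "small amino acid", 3, NutrientClass.AMINO_ACIDS, frozenset({"pw_A"})),
        Nutrient("aa_glu", "acidic amino acid", 5, NutrientClass.AMINO_ACIDS, frozenset({"pw_A"})),
        Nutrient("aa_lys", "basic amino acid", 6, NutrientClass.AMINO_ACIDS, frozenset({"pw_A"})),
        Nutrient("aa_phe", "aromatic amino acid", 9, NutrientClass.AMINO_ACIDS, frozenset({"pw_A"})),
        Nutrient("aa_ser", "hydroxy amino acid", 3, NutrientClass.AMINO_ACIDS, frozenset({"pw_A"})),
        Nutrient(
            "aa_trp",
            "tryptophan-like complex amino acid",
            11,
            NutrientClass.AMINO_ACIDS,
            components=(("org_pyr", 1), ("org_ind", 1)),
        ),
        # amino acid derivatives
        Nutrient("aad1", "amine derivative", 4, NutrientClass.AMINO_ACID_DERIVATIVES),
        Nutrient(
            "aad2",
            "dipeptide-like derivative",
            8,
            NutrientClass.AMINO_ACID_DERIVATIVES,
            components=(("aa_ala", 1), ("aa_glu", 1)),
        ),
        # fatty acids
        Nutrient("fa_but", "short-chain fatty acid", 4, NutrientClass.FATTY_ACIDS),
        Nutrient("fa_hex", "medium-chain fatty acid", 6, NutrientClass.FATTY_ACIDS),
        Nutrient("fa_pal", "long-chain fatty acid", 16, NutrientClass.FATTY_ACIDS),
        # fatty acid derivative
        Nutrient("fad1", "acyl derivative", 7, NutrientClass.FATTY_ACID_DERIVATIVES),
        # purines (nucleobases; the 3-carbon leak applies)
        Nutrient("pur_ade", "adenine-like purine", 5, NutrientClass.PURINES),
        Nutrient("pur_gua", "guanine-like purine", 5, NutrientClass.PURINES),
        # pyrimidines (nucleobases)
        Nutrient("pyr_thy", "thymine-like pyrimidine", 5, NutrientClass.PYRIMIDINES),
        Nutrient("pyr_cyt", "cytosine-like pyrimidine", 4, NutrientClass.PYRIMIDINES),
        Nutrient("pyr_ura", "uracil-like pyrimidine", 4, NutrientClass.PYRIMIDINES),
        # inorganic (carbon-free; minimal-medium components)
        Nutrient("inorg_n", "nitrogen source", 0, NutrientClass.INORGANIC),
        Nutrient("inorg_p", "phosphate source", 0, NutrientClass.INORGANIC),
        Nutrient("inorg_s", "sulfate source", 0, NutrientClass.INORGANIC),
        # cofactors
        Nutrient("cof1", "vitamin-like cofactor", 12, NutrientClass.COFACTORS),
        Nutrient("cof2", "chelator-like cofactor", 6, NutrientClass.COFACTORS),
        # cell boundary (lipid-A-like carries two fatty-acid chains)
        Nutrient(
            "cb_lipidA",
            "lipid-A-like boundary lipid",
            30,
            NutrientClass.CELL_BOUNDARY,
            components=(("fa_hex", 2), ("ribp", 1)),
        ),
        Nutrient("cb_pep", "peptidoglycan-like", 20, NutrientClass.CELL_BOUNDARY),
        # complex organics: thymidine-like nucleotide and a nested complex
        Nutrient(
            "org_thd",
            "thymidine-like nucleotide",
            10,
            NutrientClass.ORGANIC,
            components=(("ribp", 1), ("pyr_thy", 1)),
        ),
        Nutrient(
            "org_nested",
            "nested complex organic",
            13,
            NutrientClass.ORGANIC,
            components=(("org_thd", 1), ("aa_ala", 1)),
        ),
        # the trp-like parts: the pyruvate-like moiety is catabolizable,
        # the indole-like one is not (no pathway membership)
        Nutrient("org_pyr", "pyruvate-like organic", 3, NutrientClass.ORGANIC, frozenset({"pw_A"})),
        Nutrient("org_ind", "indole-like organic", 8, NutrientClass.ORGANIC),
    ]

    members: dict[str, set[str]] = {pid: set() for pid in pathway_ids}
    for nut in nutrients:
        for pid in nut.pathways:
            members.setdefault(pid, set()).add(nut.id)
    for i in range(spec.n_organic):
        nid = f"org{i:02d}"
        carbons = int(rng.integers(2, 13))
        paths = frozenset(
            pid for pid in pathway_ids if rng.random() < spec.membership_prob
        )
        nutrients.append(
            Nutrient(nid, f"organic compound {i}", carbons, NutrientClass.ORGANIC, paths)
        )
        for pid in paths:
            members[pid].add(nid)
    members = {pid: m for pid, m in members.items() if m}

    catalog = Catalog(nutrients)
    pathway_catalog = PathwayCatalog(members)
    pathway_catalog.cross_check(catalog)

    minimal = frozenset({"inorg_n", "inorg_p", "inorg_s"})
    panel = [
        ("org_all", True, True, True, False),
        ("org_beta", True, True, False, False),
        ("org_purine", False, False, True, False),
        ("org_none", False, False, False, False),
        ("org_anaerobe", False, False, False, True),
    ]
    organisms = []
    for oid, ec1, ec2, ec3, anaerobic in panel:
        uptaken = {
            n.id for n in catalog if rng.random() < spec.uptake_prob
        } | {"glc"} | set(minimal)
        organisms.append(
            OrganismProfile(
                id=oid,
                uptaken=frozenset(uptaken),
                has_ec_1_1_1_35=ec1,
                has_ec_2_3_1_16=ec2,
                has_ec_3_5_2_17=ec3,
                minimal_medium=minimal,
                training_member=oid in {"org_all", "org_beta", "org_purine"},
                anaerobic=anaerobic,
                glucose_id="glc",
            )
        )
    return catalog, pathway_catalog, organisms


# ---------------------------------------------------------------------------
# linear FBA networks


def _simple_effective(nut: Nutrient) -> int:
    if nut.nutrient_class is NutrientClass.PURINES:
        return max(nut.n_carbons - PURINE_CARBON_LEAK, 0)
    return nut.n_carbons


def make_linear_fba_model(
    catalog: Catalog,
    g_labels: Mapping[str, str],
    y0: float,
    *,
    exchange_ids: Sequence[str] | None = None,
    synergy: bool = False,
    synergy_pair: tuple[str, str] | None = None,
    maintenance_flux: float = 0.0,
) -> MetabolicModel:
    """Linear toy network in which every catabolizable carbon yields ``y0`` biomass.

    ``g_labels`` gives G/NG for *simple* nutrients (catabolic capability;
    uptake is encoded separately by which nutrients get exchange
    reactions). Each G simple nutrient gets a chain
    exchange → cytosol → (effective carbons × y0) biomass precursor; purine
    chains lose the three leaked carbons. NG simple nutrients get a
    secretion drain, so complex hydrolysis is never blocked. Complex
    nutrients of decomposition-eligible classes get a hydrolysis reaction
    into their simple parts; complex nutrients of hard-ruled classes (cell
    boundary, cofactors, …) get none — no hydrolase exists for them. With
    ``synergy``, the first two G chains co-produce a planted cofactor pair
    whose combination yields a biomass bonus, making multi-nutrient media
    strictly super-additive.
    """
    if y0 <= 0:
        raise ValueError("y0 must be positive")
    if exchange_ids is None:
        exchange_ids = [n.id for n in catalog]
    exchange_ids = list(exchange_ids)

    reactions: list[Reaction] = []
    exchanges: dict[str, str] = {}
    metabolites: list[str] = ["P"]

    for nid in exchange_ids:
        nut = catalog[nid]
        metabolites += [f"{nid}_e"]
        rid = f"EX_{nid}"
        reactions.append(Reaction(rid, {f"{nid}_e": 1.0}, 0.0, 0.0))
        exchanges[nid] = rid
        reactions.append(
            Reaction(f"T_{nid}", {f"{nid}_e": -1.0, f"{nid}_c": 1.0}, 0.0, 1000.0)
        )

    for nut in catalog:
        metabolites.append(f"{nut.id}_c")

    g_simple: list[Nutrient] = []
    for nut in catalog:
        if nut.is_complex:
            decides_by_class = (
                nut.nutrient_class in NG_CLASSES
                or nut.nutrient_class in G_CLASSES
                or nut.nutrient_class is NutrientClass.PURINES
            )
            if decides_by_class:
                continue  # no hydrolase: carbon locked in the parent
            stoich: dict[str, float] = {f"{nut.id}_c": -1.0}
            for part, mult in decompose(nut, catalog):
                stoich[f"{part.id}_c"] = stoich.get(f"{part.id}_c", 0.0) + mult
            reactions.append(Reaction(f"HYD_{nut.id}", stoich, 0.0, 1000.0))
            continue
        eff = _simple_effective(nut)
        if g_labels.get(nut.id) == "G" and eff > 0:
            g_simple.append(nut)
        else:
            reactions.append(
                Reaction(f"SEC_{nut.id}", {f"{nut.id}_c": -1.0}, 0.0, 1000.0)
            )

    pair: tuple[str, str] | None = None
    if synergy:
        if synergy_pair is not None:
            pair = synergy_pair
        else:
            # prefer media-eligible non-sugar chains so the bonus is
            # observable in random complex media (which carry one sugar)
            from .catalog import MEDIA_CLASSES

            preferred = [
                n.id
                for n in g_simple
                if n.n_carbons > 0
                and n.nutrient_class in MEDIA_CLASSES
                and n.nutrient_class is not NutrientClass.SUGARS
            ]
            carbon_g = preferred or [n.id for n in g_simple if n.n_carbons > 0]
            if len(carbon_g) < 2:
                raise ValueError("synergy needs at least two G nutrients")
            pair = (carbon_g[0], carbon_g[1])
        metabolites += [f"E_{pair[0]}", f"E_{pair[1]}"]

    for nut in g_simple:
        eff = _simple_effective(nut)
        stoich = {f"{nut.id}_c": -1.0, "P": eff * y0}
        if pair is not None and nut.id in pair:
            stoich[f"E_{nut.id}"] = 1.0
        reactions.append(Reaction(f"CAT_{nut.id}", stoich, 0.0, 1000.0))

    if pair is not None:
        reactions.append(
            Reaction(
                "SYN",
                {f"E_{pair[0]}": -1.0, f"E_{pair[1]}": -1.0, "P": y0},
                0.0,
                1000.0,
            )
        )
        reactions.append(Reaction(f"DR_E_{pair[0]}", {f"E_{pair[0]}": -1.0}, 0.0, 1000.0))
        reactions.append(Reaction(f"DR_E_{pair[1]}", {f"E_{pair[1]}": -1.0}, 0.0, 1000.0))

    reactions.append(Reaction("BIOMASS", {"P": -1.0}, 0.0, 1000.0))
    if maintenance_flux > 0:
        reactions.append(Reaction("ATPM", {"P": -1.0}, maintenance_flux, 1000.0))

    return MetabolicModel(
        metabolites=tuple(dict.fromkeys(metabolites)),
        reactions=tuple(reactions),
        biomass_reaction_id="BIOMASS",
        exchange_reactions=exchanges,
    )


def cascade_labels(
    catalog: Catalog,
    organism: OrganismProfile,
    model: LogisticPathwayModel | None,
) -> dict[str, str]:
    """Catabolic-capability labels (uptake gate skipped) for simple nutrients."""
    labels = {}
    for nut in catalog:
        if nut.is_complex:
            continue
        labels[nut.id] = classify(
            nut, organism, model, catalog, _skip_uptake_gate=True
        ).label
    return labels


def organism_fba_model(
    catalog: Catalog,
    organism: OrganismProfile,
    logistic: LogisticPathwayModel | None,
    y0: float,
    *,
    synergy: bool = False,
    maintenance_flux: float = 0.0,
) -> tuple[MetabolicModel, Medium]:
    """Network + minimal medium encoding one organism's catabolic capabilities.

    Exchange reactions exist for the uptaken nutrients and all fatty acids
    (membrane diffusion); catabolic chains follow the organism's enzyme
    flags and the logistic model for pathway-ruled organics.
    """
    labels = cascade_labels(catalog, organism, logistic)
    fatty = {n.id for n in catalog.of_class(NutrientClass.FATTY_ACIDS)}
    exchange_ids = [
        n.id for n in catalog if n.id in organism.uptaken or n.id in fatty
    ]
    model = make_linear_fba_model(
        catalog,
        labels,
        y0,
        exchange_ids=exchange_ids,
        synergy=synergy,
        maintenance_flux=maintenance_flux,
    )
    minimal = Medium(
        {nid: DEFAULT_UPTAKE_BOUND for nid in organism.minimal_medium}
    )
    return model, minimal


def measure_production(
    model: MetabolicModel,
    minimal_medium: Medium,
    nutrient_id: str,
    uptake_bound: float = DEFAULT_UPTAKE_BOUND,
) -> float:
    """Biomass flux on minimal medium + one nutrient at the standard bound."""
    sol = maximize_biomass(model, minimal_medium.with_nutrient(nutrient_id, uptake_bound))
    return sol.biomass_flux if sol.status == "optimal" else 0.0


# ---------------------------------------------------------------------------
# labeled datasets


def make_labeled_dataset(spec: FixtureSpec, n_rows: int | None = None) -> LabeledDataset:
    """Training table drawn from the planted logistic model.

    Membership indicators are i.i.d. Bernoulli(membership_prob) over the
    planted and decoy pathways; labels are Bernoulli draws from the planted
    probabilities, so refitting should recover the planted coefficients as
    the sample grows.
    """
    rng = np.random.default_rng(spec.seed)
    n = n_rows if n_rows is not None else spec.n_rows
    pathway_ids = sorted(
        set(spec.planted_beta)
        | {p for pr in spec.planted_pair_beta for p in pr}
        | {f"pw_dec{i}" for i in range(spec.n_decoy_pathways)}
    )
    X = rng.random((n, len(pathway_ids))) < spec.membership_prob
    frame = pd.DataFrame(X, columns=pathway_ids)
    z = np.full(n, spec.planted_beta0)
    for pid, beta in spec.planted_beta.items():
        z += beta * frame[pid].to_numpy(dtype=float)
    for (p, q), beta in spec.planted_pair_beta.items():
        z += beta * frame[p].to_numpy(dtype=float) * frame[q].to_numpy(dtype=float)
    labels = rng.random(n) < 1.0 / (1.0 + np.exp(-z))
    frame.index = pd.MultiIndex.from_arrays(
        [[f"n{i:05d}" for i in range(n)], ["sim"] * n], names=["nutrient", "organism"]
    )
    return LabeledDataset(memberships=frame, labels=labels)


def planted_selection_dataset(
    seed: int, n: int = 400
) -> tuple[LabeledDataset, list[str], list[tuple[str, str]]]:
    """Deterministic-label dataset whose optimal model is two pathways + one pair.

    Pathways pwA..pwE; pwC membership occurs only inside pwA. A nutrient is
    G when it belongs to pwA or pwB *unless* it is in both pwA and pwC —
    the pattern the (pwA, pwC) interaction term exists to correct. The
    planted model {pwA, pwB} + (pwA, pwC) separates the labels perfectly.
    """
    rng = np.random.default_rng(seed)
    xa = rng.random(n) < 0.4
    xb = rng.random(n) < 0.4
    xc = xa & (rng.random(n) < 0.4)
    xd = rng.random(n) < 0.4
    xe = rng.random(n) < 0.4
    frame = pd.DataFrame(
        {"pwA": xa, "pwB": xb, "pwC": xc, "pwD": xd, "pwE": xe}
    )
    labels = (xa | xb) & ~xc
    frame.index = pd.MultiIndex.from_arrays(
        [[f"n{i:05d}" for i in range(n)], ["sim"] * n], names=["nutrient", "organism"]
    )
    return (
        LabeledDataset(memberships=frame, labels=labels),
        ["pwA", "pwB"],
        [("pwA", "pwC")],
    )
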