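"""Single-nutrient biomass yield model.

Biomass produced from a sole carbon source scales with the number of
carbons the organism can actually catabolize:

    B_i = y_s * C_i^eff

where ``y_s`` is the species' sugar-reference yield — the mean per-carbon
biomass yield over the G sugars it takes up, sugars being the nutrients
that sit at the efficiency envelope — and ``C_i^eff`` the *effective*
carbon count. For a simple non-purine nutrient C_eff equals the carbon
count C_i. Purines are degraded to glyoxylate and leak three carbons as
CO2 and urea, so C_eff = C_i − 3. A complex nutrient contributes the sum
of the effective carbons of its catabolizable (G) simple components only:
thymidine (C=10) with a G phospho-ribose (C=5) and an NG thymine (C=5)
has C_eff = 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .catalog import Catalog, Nutrient, NutrientClass, OrganismProfile, decompose

#: Carbons lost as CO2/urea when a purine skeleton is reduced to glyoxylate.
PURINE_CARBON_LEAK = 3


class YieldError(ValueError):
    pass


def _simple_effective_carbons(nutrient: Nutrient, label: str) -> int:
    if label != "G":
        return 0
    if nutrient.nutrient_class is NutrientClass.PURINES:
        return max(nutrient.n_carbons - PURINE_CARBON_LEAK, 0)
    return nutrient.n_carbons


def effective_carbons(
    nutrient: Nutrient,
    labels: Mapping[str, str],
    catalog: Catalog,
) -> int:
    """Effective (catabolizable) carbon count of a G nutrient.

    ``labels`` maps nutrient id to "G"/"NG" — the cascade or FBA labels for
    the organism at hand; components missing from the mapping raise.
    """
    if not nutrient.is_complex:
        label = labels.get(nutrient.id)
        if label is None:
            raise YieldError(f"no G/NG label for nutrient {nutrient.id}")
        return _simple_effective_carbons(nutrient, label)
    total = 0
    for component, mult in decompose(nutrient, catalog):
        label = labels.get(component.id)
        if label is None:
            raise YieldError(
                f"no G/NG label for component {component.id} of {nutrient.id}"
            )
        total += mult * _simple_effective_carbons(component, label)
    return total


def sugar_reference_yield(
    species_yields: Mapping[str, float],
    labels: Mapping[str, str],
    catalog: Catalog,
    fallback: float | None = None,
) -> float:
    """Mean per-carbon biomass yield over the species' G sugars.

    ``species_yields`` maps nutrient id to measured molar biomass yield
    B_i^m. With no G sugar among the measurements the reference is
    undefined; pass ``fallback`` (e.g. the training-set class-table sugar
    yield) to substitute it, otherwise an error explains the options.
    """
    per_carbon = []
    for nid, b in species_yields.items():
        nut = catalog[nid]
        if nut.nutrient_class is NutrientClass.SUGARS and labels.get(nid) == "G":
            if nut.n_carbons == 0:
                raise YieldError(f"sugar {nid} has zero carbons")
            per_carbon.append(b / nut.n_carbons)
    if not per_carbon:
        if fallback is not None:
            return fallback
        raise YieldError(
            "no G sugars with measured yields; supply fallback= from the "
            "training-set class yield table"
        )
    return sum(per_carbon) / len(per_carbon)


def predict_single_nutrient(
    nutrient: Nutrient,
    y_s: float,
    labels: Mapping[str, str],
    catalog: Catalog,
) -> float:
    """Predicted biomass B_i = y_s * C_eff for a G nutrient, 0 for NG."""
    if labels.get(nutrient.id) != "G":
        return 0.0
    return y_s * effective_carbons(nutrient, labels, catalog)


@dataclass
class YieldTable:
    """Per-species yield accounting: y_s plus per-nutrient records."""

    species_id: str
    y_s: float
    records: pd.DataFrame  # nutrient, B_measured, C, C_eff, normalized_yield

    def to_csv(self, path) -> None:
        out = self.records.copy()
        out.insert(0, "species", self.species_id)
        out.insert(1, "y_s", self.y_s)
        out.to_csv(path, index=False)


def build_yield_table(
    organism: OrganismProfile,
    species_yields: Mapping[str, float],
    labels: Mapping[str, str],
    catalog: Catalog,
    fallback_y_s: float | None = None,
) -> YieldTable:
    """Assemble the per-species yield table from measured (FBA) yields.

    ``normalized_yield`` is B_i^m / (y_s * C_i); ``normalized_yield_eff``
    divides by effective carbons instead and is the quantity whose
    within-class variance the effective-carbon correction shrinks.
    Anaerobes are refused: anaerobic energetics shift the polymerization
    cost of biomass and break the aerobic yield envelope the model assumes.
    """
    if organism.anaerobic:
        raise YieldError(
            f"organism {organism.id} is anaerobic; the yield model only "
            f"covers aerobic growth"
        )
    y_s = sugar_reference_yield(species_yields, labels, catalog, fallback=fallback_y_s)
    rows = []
    for nid, b in species_yields.items():
        nut = catalog[nid]
        if labels.get(nid) != "G":
            continue
        c_eff = effective_carbons(nut, labels, catalog)
        rows.append(
            {
                "nutrient": nid,
                "nutrient_class": nut.nutrient_class.value,
                "B_measured": b,
                "C": nut.n_carbons,
                "C_eff": c_eff,
                "normalized_yield": b / (y_s * nut.n_carbons)
                if nut.n_carbons
                else float("nan"),
                "normalized_yield_eff": b / (y_s * c_eff) if c_eff else float("nan"),
            }
        )
    records = pd.DataFrame(
        rows,
        columns=[
            "nutrient",
            "nutrient_class",
            "B_measured",
            "C",
            "C_eff",
            "normalized_yield",
            "normalized_yield_eff",
        ],
    )
    return YieldTable(species_id=organism.id, y_s=y_s, records=records)
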