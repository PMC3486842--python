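"""G/NG decision cascade for a nutrient–organism pair.

The cascade predicts whether a nutrient can serve as a sole carbon source
(G) from cheap annotations only, in a fixed order:

1.  uptake gate — a nutrient the organism cannot transport is NG, except
    fatty acids, which diffuse through the membrane and bypass the gate;
2.  class rules — cell-boundary compounds, cofactors, inorganic compounds
    and pyrimidines are NG; sugars and sugar derivatives are G;
3.  purines are G exactly when the organism encodes 5-hydroxyisourate
    hydrolase (EC 3.5.2.17), the committed purine-degradation step;
4.  fatty acids are G exactly when the organism encodes both terminal
    β-oxidation enzymes (EC 1.1.1.35 and EC 2.3.1.16);
5.  complex nutrients of the remaining classes are decomposed; the parent
    is G when at least one simple component classifies G;
6.  everything else falls through to the logistic pathway model, G when
    P(i ∈ G) > 0.5 (ties count as NG).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .catalog import (
    Catalog,
    G_CLASSES,
    NG_CLASSES,
    Nutrient,
    NutrientClass,
    OrganismProfile,
    decompose,
)
from .logistic import LogisticPathwayModel, ModelSelectionError


@dataclass(frozen=True)
class ClassificationResult:
    label: str  # "G" | "NG"
    rule_fired: str  # not-uptaken | class-rule | purine-enzyme |
    #                  fatty-acid-enzyme | complex-decomposition | logistic
    probability: float | None = None  # set only when rule_fired == "logistic"


def classify(
    nutrient: Nutrient,
    organism: OrganismProfile,
    model: LogisticPathwayModel | None,
    catalog: Catalog,
    threshold: float = 0.5,
    _skip_uptake_gate: bool = False,
) -> ClassificationResult:
    """Apply the decision cascade to one nutrient–organism pair.

    ``model`` may be None as long as no nutrient reaches the logistic step.
    Components of a complex nutrient are classified with the uptake gate
    skipped: decomposition happens inside the cell, so transporter presence
    is irrelevant for the parts.
    """
    cls = nutrient.nutrient_class

    # 1. uptake gate (fatty acids diffuse through the membrane)
    if cls is not NutrientClass.FATTY_ACIDS and not _skip_uptake_gate:
        if nutrient.id not in organism.uptaken:
            return ClassificationResult("NG", "not-uptaken")

    # 2. hard class rules
    if cls in NG_CLASSES:
        return ClassificationResult("NG", "class-rule")
    if cls in G_CLASSES:
        return ClassificationResult("G", "class-rule")

    # 3. purines gated by EC 3.5.2.17
    if cls is NutrientClass.PURINES:
        label = "G" if organism.has_ec_3_5_2_17 else "NG"
        return ClassificationResult(label, "purine-enzyme")

    # 4. fatty acids gated by the two terminal β-oxidation enzymes
    if cls is NutrientClass.FATTY_ACIDS:
        label = "G" if organism.can_beta_oxidize else "NG"
        return ClassificationResult(label, "fatty-acid-enzyme")

    # 5. complex nutrients: G iff any simple component is G
    if nutrient.is_complex:
        for component, _mult in decompose(nutrient, catalog):
            sub = classify(
                component, organism, model, catalog, threshold, _skip_uptake_gate=True
            )
            if sub.label == "G":
                return ClassificationResult("G", "complex-decomposition")
        return ClassificationResult("NG", "complex-decomposition")

    # 6. logistic pathway model
    if model is None or not model.fitted:
        raise ModelSelectionError(
            f"nutrient {nutrient.id} requires the logistic rule but no fitted "
            f"model was provided"
        )
    prob = model.predict_proba_one(nutrient.pathways)
    return ClassificationResult("G" if prob > threshold else "NG", "logistic", prob)


def classify_all(
    organism: OrganismProfile,
    catalog: Catalog,
    model: LogisticPathwayModel | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Classify every catalog nutrient for one organism.

    Returns a DataFrame indexed by nutrient id with columns ``label``,
    ``rule`` and ``probability``; deterministic in catalog order.
    """
    rows = {}
    for nutrient in catalog:
        result = classify(nutrient, organism, model, catalog, threshold)
        rows[nutrient.id] = {
            "label": result.label,
            "rule": result.rule_fired,
            "probability": result.probability,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "nutrient"
    return frame


def rule_counts(results: pd.DataFrame) -> pd.Series:
    """Per-rule row counts for a :func:`classify_all` table."""
    return results["rule"].value_counts()
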