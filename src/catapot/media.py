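"""Additive biomass prediction on complex media and its validation.

On a medium with several carbon sources the simplest plausible model lets
each nutrient contribute independently:

    B_m = sum over present G nutrients of y_c(i) * C_i^eff

where ``y_c`` is the per-carbon yield of the nutrient's class, estimated on
the training species as a two-level average (first the mean per-carbon
yield over class members within each species, then the mean of those means
across species). Media are restricted to five classes — sugars, fatty
acids, amino acids, purines, pyrimidines — with at most one sugar
(glucose), mirroring diauxic repression of secondary sugars; purine and
pyrimidine slots use nucleobases only, since nucleosides are just a base
plus a sugar already covered by the sugar slot.

Validation against FBA-measured biomass over a random-media ensemble uses
the through-origin regression slope K (prediction = K × measurement, so
K < 1 means the additive model under-predicts — the signature of synergy
between catabolic pathways) and the Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import (
    Catalog,
    MEDIA_CLASSES,
    NutrientClass,
)
from .yields import YieldTable, effective_carbons

#: Ensemble defaults: 1000 media at each inclusion probability.
DEFAULT_ENSEMBLE_P = (0.1, 0.5, 0.9)
DEFAULT_MEDIA_PER_P = 1000


class MediaError(ValueError):
    pass


@dataclass
class ClassYieldTable:
    """Per-class per-carbon yields averaged over the training species."""

    y_c: dict[NutrientClass, float]

    def __getitem__(self, nutrient_class: NutrientClass) -> float:
        try:
            return self.y_c[nutrient_class]
        except KeyError:
            raise MediaError(
                f"class {nutrient_class.value!r} absent from the yield table"
            ) from None

    def __contains__(self, nutrient_class: NutrientClass) -> bool:
        return nutrient_class in self.y_c


@dataclass(frozen=True)
class ComplexMedium:
    """A randomly drawn medium: nutrient ids, at most one sugar."""

    id: str
    nutrients: frozenset[str]
    p: float | None = None
    seed: int | None = None


def class_yield_table(
    training_tables: Sequence[YieldTable],
    catalog: Catalog,
    classes: Iterable[NutrientClass] = MEDIA_CLASSES,
) -> ClassYieldTable:
    """Two-level average of per-carbon yields: within species, then across.

    Per-carbon yields divide measured biomass by *effective* carbons, which
    matters for purines and for complex amino acids like tryptophan whose
    indole moiety is not catabolized; for simple non-purines it is just
    B_i / C_i.
    """
    classes = set(classes)
    per_species: dict[NutrientClass, list[float]] = {c: [] for c in classes}
    for table in training_tables:
        rec = table.records
        for cls in classes:
            members = rec[rec["nutrient_class"] == cls.value]
            members = members[members["C_eff"] > 0]
            if len(members):
                per_species[cls].append(
                    float((members["B_measured"] / members["C_eff"]).mean())
                )
    return ClassYieldTable(
        y_c={c: float(np.mean(v)) for c, v in per_species.items() if v}
    )


def eligible_media_nutrients(catalog: Catalog, glucose_id: str) -> list[str]:
    """Non-sugar nutrients eligible for random media, in catalog order.

    Eligible: simple nutrients of the fatty acid, amino acid, purine and
    pyrimidine classes (nucleobases only — no nucleosides). The sugar slot
    is handled separately and is glucose-only.
    """
    if glucose_id not in catalog:
        raise MediaError(f"glucose id {glucose_id!r} not in catalog")
    out = []
    for nut in catalog:
        if nut.nutrient_class is NutrientClass.SUGARS:
            continue
        if nut.nutrient_class not in MEDIA_CLASSES:
            continue
        if nut.is_complex:
            continue
        out.append(nut.id)
    return out


def generate_media_ensemble(
    catalog: Catalog,
    p: float,
    n_media: int,
    seed: int,
    glucose_id: str,
) -> list[ComplexMedium]:
    """Draw ``n_media`` random media, each nutrient included i.i.d. with probability ``p``.

    Every eligible non-sugar nutrient enters a medium independently with
    probability ``p``; glucose fills the single sugar slot, also with
    probability ``p``. Reproducible under ``seed``.
    """
    if not 0 < p < 1:
        raise MediaError(f"inclusion probability must be in (0, 1); got {p}")
    eligible = eligible_media_nutrients(catalog, glucose_id)
    slots = [glucose_id] + eligible
    if not slots:
        raise MediaError("catalog has no media-eligible nutrients")
    rng = np.random.default_rng(seed)
    media = []
    for m in range(n_media):
        draws = rng.random(len(slots)) < p
        present = frozenset(nid for nid, take in zip(slots, draws) if take)
        media.append(
            ComplexMedium(id=f"medium_p{p:g}_{m:04d}", nutrients=present, p=p, seed=seed)
        )
    return media


def predict_medium(
    medium: ComplexMedium,
    table: ClassYieldTable,
    catalog: Catalog,
    labels: Mapping[str, str],
) -> float:
    """Additive biomass prediction: sum of y_class × C_eff over present G nutrients."""
    total = 0.0
    for nid in sorted(medium.nutrients):
        nut = catalog[nid]
        if labels.get(nid) != "G":
            continue
        total += table[nut.nutrient_class] * effective_carbons(nut, labels, catalog)
    return total


def _snap(values: np.ndarray, rel_tol: float) -> np.ndarray:
    """Collapse values that differ by less than ``rel_tol``·scale onto a grid.

    FBA measurements are LP objectives: media with identical true biomass
    come back equal only up to solver tolerance, and spurious sub-tolerance
    differences would turn rank ties into noise.
    """
    scale = float(np.max(np.abs(values)))
    if scale == 0 or rel_tol <= 0:
        return values
    return np.round(values / (scale * rel_tol))


def validate_ensemble(
    predictions: Sequence[float],
    measurements: Sequence[float],
    rel_tol: float = 1e-8,
) -> tuple[float, float | None]:
    """Through-origin slope K and Spearman rho of predicted vs measured biomass.

    K minimizes sum (pred − K·meas)^2, i.e. K = Σ pred·meas / Σ meas².
    Spearman uses average ranks for ties, after snapping values equal to
    within ``rel_tol`` of the series scale; an all-constant series leaves
    rho undefined (returned as None).
    """
    pred = np.asarray(predictions, dtype=float)
    meas = np.asarray(measurements, dtype=float)
    if pred.shape != meas.shape or len(pred) < 3:
        raise MediaError("need >= 3 paired prediction/measurement values")
    denom = float(np.sum(meas**2))
    if denom == 0:
        raise MediaError("all measurements are zero; slope undefined")
    k = float(np.sum(pred * meas) / denom)
    if np.ptp(pred) == 0 or np.ptp(meas) == 0:
        return k, None
    rho = float(stats.spearmanr(_snap(pred, rel_tol), _snap(meas, rel_tol)).statistic)
    return k, rho


def ensemble_frame(
    media: Sequence[ComplexMedium],
    predictions: Sequence[float],
    measurements: Sequence[float] | None = None,
) -> pd.DataFrame:
    rows = {
        m.id: {
            "n_nutrients": len(m.nutrients),
            "p": m.p,
            "B_pred": pred,
        }
        for m, pred in zip(media, predictions)
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "medium"
    if measurements is not None:
        frame["B_fba"] = list(measurements)
    return frame
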