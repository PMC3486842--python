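"""End-to-end workflow: fixtures → FBA labels → model selection →
classification → yields → complex-media validation.

Every stage writes its inputs and outputs to the run directory as CSV/JSON
so a run can be inspected and replayed; reruns with the same configuration
are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import fixtures
from .catalog import Catalog, NutrientClass, OrganismProfile, write_catalog, write_profile
from .classifier import classify_all
from .fba import DEFAULT_EPSILON, DEFAULT_UPTAKE_BOUND, label_growth, write_model_tsv
from .logistic import greedy_select
from .media import (
    ClassYieldTable,
    class_yield_table,
    ensemble_frame,
    generate_media_ensemble,
    predict_medium,
    validate_ensemble,
)
from .fba import Medium, maximize_biomass
from .yields import build_yield_table


@dataclass
class RunConfig:
    """Numeric knobs and paths for a pipeline run; all defaults documented.

    ``epsilon`` is the growth-significance threshold on biomass flux,
    ``uptake_bound`` the standard carbon-source uptake flux,
    ``ensemble_p``/``n_media`` the inclusion probabilities and per-p size
    of the random-media ensembles.
    """

    seed: int = 0
    y0: float = 0.1
    epsilon: float = DEFAULT_EPSILON
    uptake_bound: float = DEFAULT_UPTAKE_BOUND
    logistic_threshold: float = 0.5
    ensemble_p: tuple[float, ...] = (0.1, 0.5, 0.9)
    n_media: int = 200
    synergy: bool = False
    out_dir: str = "catapot_run"


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow on generated fixtures; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(asdict(config), indent=2, default=list) + "\n"
    )

    spec = fixtures.FixtureSpec(seed=config.seed, y0=config.y0, synergy=config.synergy)
    catalog, pathway_catalog, organisms = fixtures.make_catalog(spec)
    write_catalog(catalog, pathway_catalog, out / "nutrients.tsv", out / "pathways.tsv")
    for org in organisms:
        write_profile(org, out / f"profile_{org.id}.json")

    # --- model selection on the planted training table
    dataset = fixtures.make_labeled_dataset(spec)
    trajectory = greedy_select(dataset, pathway_catalog=None)
    final = trajectory[-1]
    final.model.to_json(out / "model.json", score=final.score)
    pd.DataFrame(
        [
            {
                "step": i,
                "term": step.term or "",
                "strategy": step.strategy,
                **step.score.as_dict(),
            }
            for i, step in enumerate(trajectory)
        ]
    ).to_csv(out / "selection_trajectory.csv", index=False)
    logistic = final.model

    # --- FBA ground truth + classification per organism
    training_tables = []
    label_frames = {}
    for org in organisms:
        fba_model, minimal = fixtures.organism_fba_model(
            catalog, org, logistic, config.y0, synergy=config.synergy
        )
        write_model_tsv(fba_model, out / f"fba_model_{org.id}.tsv")
        fba_labels = {
            n.id: label_growth(
                fba_model, minimal, n, config.uptake_bound, config.epsilon
            )
            for n in catalog
        }
        predicted = classify_all(catalog=catalog, organism=org, model=logistic,
                                 threshold=config.logistic_threshold)
        predicted["fba_label"] = pd.Series(fba_labels)
        predicted.to_csv(out / f"labels_{org.id}.csv")
        label_frames[org.id] = predicted

        if org.training_member and not org.anaerobic:
            production = {
                nid: fixtures.measure_production(
                    fba_model, minimal, nid, config.uptake_bound
                )
                for nid, lab in fba_labels.items()
                if lab == "G"
            }
            capability = fixtures.cascade_labels(catalog, org, logistic)
            table = build_yield_table(org, production, capability, catalog)
            table.to_csv(out / f"yields_{org.id}.csv")
            training_tables.append((org, table))

    # --- class yields and media validation on the first training organism
    yields_only = [t for _, t in training_tables]
    cyt = class_yield_table(yields_only, catalog)
    (out / "class_yields.json").write_text(
        json.dumps({c.value: y for c, y in cyt.y_c.items()}, indent=2, sort_keys=True)
        + "\n"
    )

    org, _ = training_tables[0]
    fba_model, minimal = fixtures.organism_fba_model(
        catalog, org, logistic, config.y0, synergy=config.synergy
    )
    capability = fixtures.cascade_labels(catalog, org, logistic)
    validation = {}
    frames = []
    for i, p in enumerate(config.ensemble_p):
        media = generate_media_ensemble(
            catalog, p, config.n_media, seed=config.seed + i, glucose_id=org.glucose_id
        )
        preds, meas = [], []
        for medium in media:
            preds.append(predict_medium(medium, cyt, catalog, capability))
            bounds = Medium(
                {nid: config.uptake_bound for nid in medium.nutrients}
                | {nid: config.uptake_bound for nid in org.minimal_medium}
            )
            sol = maximize_biomass(fba_model, bounds)
            meas.append(sol.biomass_flux if sol.status == "optimal" else 0.0)
        frames.append(ensemble_frame(media, preds, meas))
        k, rho = validate_ensemble(preds, meas)
        validation[f"p={p:g}"] = {"K": k, "spearman_rho": rho, "n_media": len(media)}
    pd.concat(frames).to_csv(out / "media.csv")
    (out / "validation.json").write_text(json.dumps(validation, indent=2) + "\n")
    return out
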