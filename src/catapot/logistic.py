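"""Logistic pathway model: fitting, scoring, and greedy forward selection.

Nutrients that escape the hard class and enzyme rules are classified by a
logistic regression on pathway membership. The linear predictor is

    z_i = b0 + sum_p b_p x_ip + sum_(p,q) b_pq x_ip x_iq

with x_ip the 0/1 indicator that nutrient i belongs to pathway p, and
P(i in G) = 1 / (1 + exp(-z_i)). Forward selection grows the model from the
null (intercept-only) model, adding the pathway — and later the pathway
pair — that most improves accuracy on the not-yet-covered nutrients, and
stops when neither the AIC nor the BIC improves.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .catalog import PathwayCatalog

#: Coefficient magnitude cap; keeps separated fits finite and flagged.
COEF_CAP = 20.0


class ModelSelectionError(ValueError):
    pass


@dataclass
class LabeledDataset:
    """Rows of (nutrient, organism, pathway-membership vector, G/NG label).

    ``memberships`` is a boolean DataFrame whose index identifies the rows
    (``(nutrient_id, organism_id)``) and whose columns are pathway ids;
    ``labels`` is the parallel boolean array (True = G).
    """

    memberships: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if len(self.labels) != len(self.memberships):
            raise ModelSelectionError("labels and membership rows disagree in length")
        if len(self.labels) == 0:
            raise ModelSelectionError("empty dataset")
        if self.memberships.index.duplicated().any():
            raise ModelSelectionError("duplicate (nutrient, organism) rows")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.memberships.columns)

    def column(self, pathway_id: str) -> np.ndarray:
        return self.memberships[pathway_id].to_numpy(dtype=float)


PathwayPair = tuple[str, str]


def _canonical_pair(pair: Iterable[str]) -> PathwayPair:
    a, b = sorted(pair)
    return (a, b)


@dataclass
class LogisticPathwayModel:
    """Fitted logistic model over selected pathways and pathway pairs."""

    pathways: list[str] = field(default_factory=list)
    pairs: list[PathwayPair] = field(default_factory=list)
    beta0: float = 0.0
    beta: dict[str, float] = field(default_factory=dict)
    beta_pairs: dict[PathwayPair, float] = field(default_factory=dict)
    separated: bool = False
    fitted: bool = False

    @property
    def k(self) -> int:
        """Parameter count: intercept + P pathways + z pairs."""
        return 1 + len(self.pathways) + len(self.pairs)

    def linear_predictor(self, membership: Iterable[str] | frozenset[str]) -> float:
        member = set(membership)
        z = self.beta0
        for p in self.pathways:
            if p in member:
                z += self.beta[p]
        for p, q in self.pairs:
            if p in member and q in member:
                z += self.beta_pairs[(p, q)]
        return z

    def predict_proba_one(self, membership: Iterable[str]) -> float:
        if not self.fitted:
            raise ModelSelectionError("model has not been fitted")
        return float(1.0 / (1.0 + np.exp(-self.linear_predictor(membership))))

    def design_matrix(self, dataset: LabeledDataset) -> np.ndarray:
        cols = [np.ones(dataset.n)]
        for p in self.pathways:
            cols.append(dataset.column(p))
        for p, q in self.pairs:
            cols.append(dataset.column(p) * dataset.column(q))
        return np.column_stack(cols)

    def predict_proba(self, dataset: LabeledDataset) -> np.ndarray:
        if not self.fitted:
            raise ModelSelectionError("model has not been fitted")
        X = self.design_matrix(dataset)
        coefs = self.coefficient_vector()
        z = X @ coefs
        return 1.0 / (1.0 + np.exp(-z))

    def coefficient_vector(self) -> np.ndarray:
        return np.array(
            [self.beta0]
            + [self.beta[p] for p in self.pathways]
            + [self.beta_pairs[pr] for pr in self.pairs]
        )

    def to_json(self, path: str | Path, score: "ModelScore | None" = None) -> None:
        payload = {
            "pathways": self.pathways,
            "pairs": [list(pr) for pr in self.pairs],
            "beta0": self.beta0,
            "beta": self.beta,
            "beta_pairs": {f"{p}|{q}": v for (p, q), v in self.beta_pairs.items()},
            "separated": self.separated,
        }
        if score is not None:
            payload["score"] = score.as_dict()
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LogisticPathwayModel":
        raw = json.loads(Path(path).read_text())
        return cls(
            pathways=list(raw["pathways"]),
            pairs=[_canonical_pair(pr) for pr in raw["pairs"]],
            beta0=float(raw["beta0"]),
            beta={k: float(v) for k, v in raw["beta"].items()},
            beta_pairs={
                _canonical_pair(k.split("|")): float(v)
                for k, v in raw.get("beta_pairs", {}).items()
            },
            separated=bool(raw.get("separated", False)),
            fitted=True,
        )


@dataclass
class ModelScore:
    """Accuracy and economy of a fitted model on a dataset."""

    tp_rate: float
    tn_rate: float
    auc: float | None
    log_likelihood: float
    aic: float
    bic: float
    k: int
    n: int

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.tp_rate + self.tn_rate)

    def as_dict(self) -> dict:
        return {
            "tp_rate": self.tp_rate,
            "tn_rate": self.tn_rate,
            "auc": self.auc,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "bic": self.bic,
            "k": self.k,
            "n": self.n,
        }


def fit_logistic(
    dataset: LabeledDataset,
    pathways: Sequence[str] = (),
    pairs: Sequence[PathwayPair] = (),
    cap: float = COEF_CAP,
) -> LogisticPathwayModel:
    """Maximum-likelihood fit of the logistic pathway model.

    Pathway indicators separate easily at small sample sizes (a pathway
    whose members are all G drives its coefficient to infinity), so all
    coefficients are box-constrained to ``|beta| <= cap``; a fit with any
    coefficient at the cap is flagged ``separated``.
    """
    model = LogisticPathwayModel(
        pathways=list(pathways),
        pairs=[_canonical_pair(pr) for pr in pairs],
        beta0=0.0,
        beta={p: 0.0 for p in pathways},
        beta_pairs={_canonical_pair(pr): 0.0 for pr in pairs},
    )
    X = model.design_matrix(dataset)
    y = dataset.labels.astype(float)

    def nll(beta: np.ndarray) -> float:
        z = X @ beta
        return float(np.sum(np.logaddexp(0.0, z) - y * z))

    def grad(beta: np.ndarray) -> np.ndarray:
        z = X @ beta
        p = 1.0 / (1.0 + np.exp(-z))
        return X.T @ (p - y)

    x0 = np.zeros(X.shape[1])
    res = minimize(
        nll,
        x0,
        jac=grad,
        method="L-BFGS-B",
        bounds=[(-cap, cap)] * X.shape[1],
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
    )
    beta = res.x
    model.beta0 = float(beta[0])
    for i, p in enumerate(model.pathways):
        model.beta[p] = float(beta[1 + i])
    for j, pr in enumerate(model.pairs):
        model.beta_pairs[pr] = float(beta[1 + len(model.pathways) + j])
    model.separated = bool(np.any(np.abs(beta) >= cap - 1e-6))
    model.fitted = True
    return model


def log_likelihood(model: LogisticPathwayModel, dataset: LabeledDataset) -> float:
    X = model.design_matrix(dataset)
    y = dataset.labels.astype(float)
    z = X @ model.coefficient_vector()
    return float(-(np.sum(np.logaddexp(0.0, z) - y * z)))


def ranked_sweep_auc(probabilities: np.ndarray, labels: np.ndarray) -> float | None:
    """Area under the ROC curve by the ranked-sweep construction.

    Nutrients are ranked by predicted probability (highest first); walking
    down the list accumulates the fraction of G and of NG nutrients seen so
    far, and the area under the resulting (fraction-NG, fraction-G) curve is
    taken by the trapezoid rule. Tied probabilities advance as one block,
    which makes the result identical to the Mann–Whitney U formulation with
    average ranks. Returns ``None`` when only one class is present.
    """
    labels = np.asarray(labels, dtype=bool)
    n_g = int(labels.sum())
    n_ng = int((~labels).sum())
    if n_g == 0 or n_ng == 0:
        return None
    order = np.argsort(-np.asarray(probabilities, dtype=float), kind="stable")
    p_sorted = np.asarray(probabilities, dtype=float)[order]
    y_sorted = labels[order]
    xs = [0.0]
    ys = [0.0]
    tp = fp = 0
    i = 0
    while i < len(p_sorted):
        j = i
        while j < len(p_sorted) and p_sorted[j] == p_sorted[i]:
            j += 1
        tp += int(y_sorted[i:j].sum())
        fp += int((~y_sorted[i:j]).sum())
        xs.append(fp / n_ng)
        ys.append(tp / n_g)
        i = j
    return float(np.trapezoid(ys, xs))


def score_model(
    model: LogisticPathwayModel,
    dataset: LabeledDataset,
    threshold: float = 0.5,
) -> ModelScore:
    """TP/TN rates at the decision threshold, ranked-sweep AUC, AIC and BIC.

    AIC = 2k − 2 ln L and BIC = k ln n − 2 ln L with k = 1 + P + z
    parameters and n dataset rows. Predictions exactly at the threshold
    count as NG (the conservative side).
    """
    probs = model.predict_proba(dataset)
    y = dataset.labels
    pred_g = probs > threshold
    n_g = int(y.sum())
    n_ng = int((~y).sum())
    tp = int((pred_g & y).sum())
    tn = int((~pred_g & ~y).sum())
    tp_rate = tp / n_g if n_g else float("nan")
    tn_rate = tn / n_ng if n_ng else float("nan")
    ll = log_likelihood(model, dataset)
    k = model.k
    n = dataset.n
    return ModelScore(
        tp_rate=tp_rate,
        tn_rate=tn_rate,
        auc=ranked_sweep_auc(probs, y),
        log_likelihood=ll,
        aic=2 * k - 2 * ll,
        bic=k * np.log(n) - 2 * ll,
        k=k,
        n=n,
    )


@dataclass
class SelectionStep:
    term: str | None  # pathway id, "pair:p|q", or None for the null model
    strategy: str  # "null", "pathway-G", "pathway-NG", "pair"
    model: LogisticPathwayModel
    score: ModelScore


def _uncovered_mask(dataset: LabeledDataset, covered_pathways: list[str]) -> np.ndarray:
    mask = np.ones(dataset.n, dtype=bool)
    for p in covered_pathways:
        mask &= ~dataset.memberships[p].to_numpy(dtype=bool)
    return mask


def _accuracy_on(
    model: LogisticPathwayModel,
    dataset: LabeledDataset,
    mask: np.ndarray,
    criterion: str,
    threshold: float,
) -> float:
    probs = model.predict_proba(dataset)[mask]
    y = dataset.labels[mask]
    if len(y) == 0:
        return 0.0
    pred_g = probs > threshold
    if criterion == "raw":
        return float((pred_g == y).mean())
    n_g = int(y.sum())
    n_ng = int((~y).sum())
    tpr = float((pred_g & y).sum() / n_g) if n_g else 1.0
    tnr = float((~pred_g & ~y).sum() / n_ng) if n_ng else 1.0
    return 0.5 * (tpr + tnr)


def greedy_select(
    dataset: LabeledDataset,
    pathway_catalog: PathwayCatalog | Sequence[str] | None = None,
    max_terms: int = 20,
    criterion: str = "balanced",
    threshold: float = 0.5,
) -> list[SelectionStep]:
    """Greedy forward selection of pathways, then pathway pairs.

    Starting from the intercept-only null model, each step fits every
    remaining candidate term on the full dataset and ranks candidates by
    accuracy gain. Pathway candidates are ranked on the nutrients *not yet
    covered* by a selected G-type pathway — pathways overlap heavily, so a
    candidate gets no credit for nutrients an earlier pathway already
    explains — and pathways left with no uncovered members are dropped.
    Pair candidates (interactions between catalog pathways) are ranked on
    all rows, since their role is to flip false positives *inside* already
    selected pathways. The best candidate is accepted only if it improves
    both the AIC and the BIC of the full fit (a term that improves only
    one is weak evidence and tends to be a redundant reparametrization);
    otherwise selection moves from pathways to pairs, and then stops. Ties
    break lexicographically. Returns the full trajectory, null model first.
    """
    if pathway_catalog is None:
        candidate_pathways = sorted(dataset.pathway_ids)
    elif isinstance(pathway_catalog, PathwayCatalog):
        candidate_pathways = sorted(set(pathway_catalog.ids) & set(dataset.pathway_ids))
    else:
        candidate_pathways = sorted(set(pathway_catalog) & set(dataset.pathway_ids))

    null = fit_logistic(dataset)
    trajectory = [SelectionStep(None, "null", null, score_model(null, dataset, threshold))]
    selected: list[str] = []
    selected_pairs: list[PathwayPair] = []
    covered_g_pathways: list[str] = []
    phase = "pathways"

    while len(selected) + len(selected_pairs) < max_terms:
        current = trajectory[-1].score
        mask = _uncovered_mask(dataset, covered_g_pathways)

        best: tuple[float, str, object, LogisticPathwayModel, ModelScore] | None = None
        if phase == "pathways":
            for p in candidate_pathways:
                if p in selected:
                    continue
                col = dataset.memberships[p].to_numpy(dtype=bool)
                if not (col & mask).any():
                    continue  # pruned: no uncovered members left
                cand = fit_logistic(dataset, selected + [p], selected_pairs)
                acc = _accuracy_on(cand, dataset, mask, criterion, threshold)
                sc = score_model(cand, dataset, threshold)
                key = (-acc, p)
                if best is None or key < best[0:2]:
                    best = (key[0], key[1], p, cand, sc)
            if best is not None:
                _, _, term, cand, sc = best
                if sc.aic < current.aic and sc.bic < current.bic:
                    selected.append(term)  # type: ignore[arg-type]
                    col = dataset.memberships[term].to_numpy(dtype=bool)
                    frac_g = dataset.labels[col].mean() if col.any() else 0.0
                    strategy = "pathway-G" if frac_g > 0.5 else "pathway-NG"
                    if strategy == "pathway-G":
                        covered_g_pathways.append(term)  # type: ignore[arg-type]
                    trajectory.append(SelectionStep(term, strategy, cand, sc))
                    continue
            phase = "pairs"
            continue

        # pair phase
        all_ones = np.ones(dataset.n, dtype=bool)
        for p, q in itertools.combinations(candidate_pathways, 2):
            pr = _canonical_pair((p, q))
            if pr in selected_pairs:
                continue
            inter = dataset.column(p) * dataset.column(q)
            if not inter.any():
                continue
            cand = fit_logistic(dataset, selected, selected_pairs + [pr])
            acc = _accuracy_on(cand, dataset, all_ones, criterion, threshold)
            sc = score_model(cand, dataset, threshold)
            key = (-acc, f"{pr[0]}|{pr[1]}")
            if best is None or key < best[0:2]:
                best = (key[0], key[1], pr, cand, sc)
        if best is None:
            break
        _, _, term, cand, sc = best
        if sc.aic < current.aic and sc.bic < current.bic:
            selected_pairs.append(term)  # type: ignore[arg-type]
            trajectory.append(
                SelectionStep(f"pair:{term[0]}|{term[1]}", "pair", cand, sc)
            )
        else:
            break

    return trajectory
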