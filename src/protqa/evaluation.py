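"""ROC-based evaluation of per-residue quality predictions.

Residues with lDDT strictly above the classification cut (default 0.6)
count as correctly modelled.  Two AUC views are reported: the overall AUC
on all pooled residues (absolute-scale calibration) and the mean per-model
AUC (within-model discrimination).  Models whose residues all fall in one
class yield no ROC curve and are excluded from the per-model mean.

A naive baseline assigns each model's global score to all of its residues;
it can score well on the pooled view while being undefined per model —
a useful control for apparent pooled performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .lddt import classify_correct


def roc_auc(predictions, labels) -> float | None:
    """Rank-based (Mann–Whitney) AUC with tie averaging.

    Returns None (the exclusion signal) when only one class is present or
    when all predictions are identical — both cases define no ranking.
    """
    labels = np.asarray(labels)
    predictions = np.asarray(predictions, dtype=float)
    if len(np.unique(labels)) < 2 or len(np.unique(predictions)) < 2:
        return None
    return float(roc_auc_score(labels, predictions))


@dataclass
class EvaluationReport:
    overall_auc: float
    per_model_aucs: dict               # model id -> AUC or None (excluded)
    mean_per_model_auc: float | None
    n_excluded_models: int
    cut: float

    def to_dict(self) -> dict:
        return {
            "overall_auc": self.overall_auc,
            "mean_per_model_auc": self.mean_per_model_auc,
            "n_excluded_models": self.n_excluded_models,
            "cut": self.cut,
            "per_model_aucs": {k: v for k, v in self.per_model_aucs.items()},
        }


def evaluate(predictions_by_model: dict, lddt_by_model: dict,
             cut: float = 0.6) -> EvaluationReport:
    """Evaluate per-residue predictions against per-residue lDDT.

    Both arguments map model id -> array; invalid (NaN) lDDT entries are
    dropped pairwise.
    """
    pooled_pred, pooled_label = [], []
    per_model = {}
    for model_id, preds in predictions_by_model.items():
        preds = np.asarray(preds, dtype=float)
        scores = np.asarray(lddt_by_model[model_id], dtype=float)
        if len(preds) != len(scores):
            raise ValueError(f"{model_id}: prediction/label length mismatch")
        labels, valid = classify_correct(scores, cut=cut)
        preds = preds[valid]
        keep = np.isfinite(preds)
        preds, labels = preds[keep], labels[keep]
        if len(preds) == 0:
            per_model[model_id] = None
            continue
        pooled_pred.append(preds)
        pooled_label.append(labels)
        per_model[model_id] = roc_auc(preds, labels)
    if not pooled_pred:
        raise ValueError("no valid models to evaluate")
    overall = roc_auc(np.concatenate(pooled_pred),
                      np.concatenate(pooled_label))
    if overall is None:
        raise ValueError("pooled data contains a single class")
    valid_aucs = [a for a in per_model.values() if a is not None]
    return EvaluationReport(
        overall_auc=overall,
        per_model_aucs=per_model,
        mean_per_model_auc=(float(np.mean(valid_aucs)) if valid_aucs
                            else None),
        n_excluded_models=sum(a is None for a in per_model.values()),
        cut=cut,
    )


def naive_predictor(global_scores: dict, n_residues: dict) -> dict:
    """model id -> constant per-residue prediction (the model's global
    score broadcast to every residue)."""
    return {
        model_id: np.full(n_residues[model_id], float(score))
        for model_id, score in global_scores.items()
    }
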