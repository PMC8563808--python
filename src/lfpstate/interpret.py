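"""Feature importance from the regularization path of the nested CV.

The importance of a feature is its selection frequency: the fraction of
inner-fold models (at each outer fold's selected penalty) in which the
feature's coefficient survived regularization. Per-outer-fold fractions are
kept as replicates so a one-way ANOVA with Tukey-corrected pairwise
comparisons can isolate the subset of features whose importance dominates
the rest. A success-weighted variant rescales importance by how far the
contrast's mean AUC sits above chance.

The default selection rule is ``|w| > tol``: a feature whose effect is
negative (such as a post-stimulation beta-power *decrease*) is still
"selected" when its negative coefficient survives the penalty. The literal
sign rule ``w > tol`` is available as ``rule="positive"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .classify import CvResult

__all__ = ["ImportanceScores", "importance_from_cv", "importance_anova", "weighted_importance"]

SELECTION_RULES = ("nonzero", "positive")


@dataclass
class ImportanceScores:
    """Selection-frequency importance with per-outer-fold replicates."""

    feature_names: list[str]
    overall: np.ndarray  # (n_features,), in [0, 1]
    replicates: np.ndarray  # (n_outer_folds, n_features)
    rule: str
    tol: float

    def as_dict(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(self.feature_names, self.overall)}

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "overall": [float(v) for v in self.overall],
            "replicates": self.replicates.tolist(),
            "rule": self.rule,
            "tol": self.tol,
        }


def importance_from_cv(
    cv: CvResult, rule: str = "nonzero", tol: float = 1e-8
) -> ImportanceScores:
    """Fraction of inner-fold models in which each feature was selected.

    One replicate per outer fold (the fraction over that fold's inner
    models); the overall importance is the mean of the replicates.
    """
    if rule not in SELECTION_RULES:
        raise ValueError(f"rule must be one of {SELECTION_RULES}")
    if not cv.outer or any(not f.inner_models for f in cv.outer):
        raise ValueError("CvResult carries no stored inner-fold models")
    replicates = []
    for fold in cv.outer:
        coefs = np.array([m.coefficients for m in fold.inner_models])
        selected = (np.abs(coefs) > tol) if rule == "nonzero" else (coefs > tol)
        replicates.append(selected.mean(axis=0))
    replicates = np.array(replicates)
    return ImportanceScores(
        feature_names=list(cv.feature_names),
        overall=replicates.mean(axis=0),
        replicates=replicates,
        rule=rule,
        tol=tol,
    )


@dataclass
class ImportanceAnova:
    F: float
    p: float
    significant_subset: tuple[str, ...]
    defined: bool  # False when every replicate is identical (zero variance)


def importance_anova(scores: ImportanceScores, alpha: float = 0.05) -> ImportanceAnova:
    """One-way ANOVA across features on replicate-level importances.

    The significant subset is the smallest prefix of the importance ranking
    whose every member is significantly greater (Tukey HSD at ``alpha``) than
    every feature outside it; empty when no such prefix exists.
    """
    groups = [scores.replicates[:, j] for j in range(scores.replicates.shape[1])]
    if min(len(g) for g in groups) < 2:
        raise ValueError("need >= 2 replicates per feature")
    if np.ptp(scores.replicates) == 0:
        return ImportanceAnova(F=float("nan"), p=float("nan"), significant_subset=(), defined=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = sps.f_oneway(*groups)
    if not np.isfinite(F):
        return ImportanceAnova(F=float("nan"), p=float("nan"), significant_subset=(), defined=False)
    tukey = sps.tukey_hsd(*groups)
    means = scores.overall
    order = np.argsort(means)[::-1]
    subset: tuple[str, ...] = ()
    for k in range(1, len(order)):
        top, rest = order[:k], order[k:]
        all_sig = all(
            tukey.pvalue[i, j] < alpha and means[i] > means[j] for i in top for j in rest
        )
        if all_sig:
            subset = tuple(scores.feature_names[i] for i in top)
            break
    return ImportanceAnova(F=float(F), p=float(p), significant_subset=subset, defined=True)


def weighted_importance(scores: ImportanceScores, cv: CvResult) -> dict[str, float]:
    """Importance rescaled by classifier success.

    The weight is ``max(0, 2 * (auc_mean - 0.5))``: zero at chance-level
    classification, one at perfect separation.
    """
    weight = max(0.0, 2.0 * (cv.auc_mean - 0.5))
    return {
        name: float(weight * v) for name, v in zip(scores.feature_names, scores.overall)
    }
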