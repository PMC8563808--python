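"""Elastic-net logistic classification of spectral features between epochs.

The group-level analysis is a nested leave-one-subject-out (LOSO)
cross-validation: the outer loop holds out one subject to estimate
out-of-sample separability (AUC); the inner loop is LOSO over the remaining
subjects and selects the regularization strength lambda minimizing the mean
validation cross-entropy. Feature standardization uses training-fold
statistics only, so no information leaks from held-out subjects. 1-s
segments are treated as exchangeable samples within a subject; grouping is
preserved by the subject-wise folds.

The penalized objective is::

    mean logistic loss + lambda * (mixing * ||w||_1 + (1 - mixing) / 2 * ||w||_2^2)

with an unpenalized intercept. The chronologically later epoch of a contrast
is the positive class, fixing the sign interpretation of coefficients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .sigio import EPOCH_LABELS, FEATURE_COLUMNS
from .stats import RmAnovaResult, two_condition_rmanova

__all__ = [
    "EnetModel",
    "OuterFold",
    "CvResult",
    "DEFAULT_LAMBDA_GRID",
    "fit_enet_logistic",
    "enet_path",
    "nested_cv",
    "subject_level_cv",
    "compare_subject_aucs",
]

FEATURE_NAMES = FEATURE_COLUMNS[3:]

#: 50 log-spaced regularization strengths, 1e-4 ... 1e2.
DEFAULT_LAMBDA_GRID = np.logspace(-4, 2, 50)

_SAGA_TOL = 1e-6
_SAGA_MAX_ITER = 5000


@dataclass
class EnetModel:
    """A fitted elastic-net logistic model on standardized features."""

    coefficients: np.ndarray
    intercept: float
    lam: float
    mixing: float
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coefficients + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision(X)))

    def to_dict(self) -> dict:
        return {
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "lambda": float(self.lam),
            "mixing": float(self.mixing),
            "feature_names": list(self.feature_names),
        }


@dataclass
class OuterFold:
    held_out: str
    chosen_lambda: float
    auc: float
    model: EnetModel
    inner_models: list[EnetModel]

    def to_dict(self) -> dict:
        return {
            "held_out": self.held_out,
            "chosen_lambda": float(self.chosen_lambda),
            "auc": float(self.auc),
            "model": self.model.to_dict(),
            "inner_models": [m.to_dict() for m in self.inner_models],
        }


@dataclass
class CvResult:
    """Outer-fold AUCs plus the per-fold inner models that feed importance."""

    contrast: tuple[str, str]
    feature_names: list[str]
    outer: list[OuterFold]
    mixing: float
    seed: int

    @property
    def outer_aucs(self) -> np.ndarray:
        return np.array([f.auc for f in self.outer])

    @property
    def auc_mean(self) -> float:
        return float(self.outer_aucs.mean())

    @property
    def auc_sd(self) -> float:
        aucs = self.outer_aucs
        return float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "contrast": list(self.contrast),
            "feature_names": list(self.feature_names),
            "mixing": float(self.mixing),
            "seed": int(self.seed),
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "outer_folds": [f.to_dict() for f in self.outer],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "CvResult":
        outer = [
            OuterFold(
                held_out=f["held_out"],
                chosen_lambda=f["chosen_lambda"],
                auc=f["auc"],
                model=_model_from_dict(f["model"]),
                inner_models=[_model_from_dict(m) for m in f["inner_models"]],
            )
            for f in d["outer_folds"]
        ]
        return cls(
            contrast=tuple(d["contrast"]),
            feature_names=list(d["feature_names"]),
            outer=outer,
            mixing=d["mixing"],
            seed=d["seed"],
        )

    @classmethod
    def load(cls, path: str | Path) -> "CvResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _model_from_dict(d: dict) -> EnetModel:
    return EnetModel(
        coefficients=np.asarray(d["coefficients"], dtype=float),
        intercept=d["intercept"],
        lam=d["lambda"],
        mixing=d["mixing"],
        feature_names=list(d["feature_names"]),
    )


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"y must contain exactly 2 classes, got {classes.tolist()}")
    return X, (y == classes.max()).astype(int)


def _polish_intercept(X: np.ndarray, y: np.ndarray, w: np.ndarray, b0: float) -> float:
    """Exact 1-D Newton solve of the unpenalized intercept with ``w`` fixed.

    The intercept carries no penalty, so at the optimum the mean residual
    ``mean(sigmoid(Xw + b) - y)`` is zero. saga can declare convergence
    before the intercept settles when the penalty is extreme (all-zero
    coefficients); this polish is a no-op whenever the solver truly
    converged and otherwise restores the optimality condition.
    """
    z = X @ w
    b = float(b0)
    for _ in range(50):
        p = 1.0 / (1.0 + np.exp(-(z + b)))
        grad = p.mean() - y.mean()
        hess = (p * (1.0 - p)).mean()
        if hess <= 0 or abs(grad) < 1e-12:
            break
        b -= grad / hess
    return b


def fit_enet_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    mixing: float = 0.5,
    random_state: int = 0,
    feature_names: list[str] | None = None,
) -> EnetModel:
    """Fit one elastic-net logistic model at a fixed penalty strength.

    ``X`` is assumed already standardized. ``lam = 0`` gives the
    unregularized maximum-likelihood fit.
    """
    X, y01 = _check_xy(X, y)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not 0.0 <= mixing <= 1.0:
        raise ValueError("mixing must be in [0, 1]")
    n = X.shape[0]
    if lam == 0.0:
        est = LogisticRegression(penalty=None, solver="lbfgs", tol=1e-10, max_iter=20000)
    else:
        est = LogisticRegression(
            penalty="elasticnet",
            solver="saga",
            C=1.0 / (lam * n),
            l1_ratio=mixing,
            tol=_SAGA_TOL,
            max_iter=_SAGA_MAX_ITER,
            random_state=random_state,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y01)
    names = feature_names if feature_names is not None else [f"x{i}" for i in range(X.shape[1])]
    coefs = est.coef_.ravel().copy()
    return EnetModel(
        coefficients=coefs,
        intercept=_polish_intercept(X, y01, coefs, float(est.intercept_[0])),
        lam=float(lam),
        mixing=float(mixing),
        feature_names=list(names),
    )


def enet_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    mixing: float = 0.5,
    random_state: int = 0,
    feature_names: list[str] | None = None,
) -> list[EnetModel]:
    """Fit the whole regularization path with warm starts.

    ``lambdas`` may be in any order; fitting proceeds from strongest to
    weakest penalty internally and results are returned in input order.
    """
    X, y01 = _check_xy(X, y)
    n = X.shape[0]
    order = np.argsort(lambdas)[::-1]
    est = LogisticRegression(
        penalty="elasticnet",
        solver="saga",
        l1_ratio=mixing,
        tol=_SAGA_TOL,
        max_iter=_SAGA_MAX_ITER,
        random_state=random_state,
        warm_start=True,
        C=1.0,
    )
    names = feature_names if feature_names is not None else [f"x{i}" for i in range(X.shape[1])]
    out: list[EnetModel | None] = [None] * len(lambdas)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for idx in order:
            lam = float(lambdas[idx])
            if lam == 0.0:
                out[idx] = fit_enet_logistic(X, y01, 0.0, mixing, feature_names=names)
                continue
            est.C = 1.0 / (lam * n)
            est.fit(X, y01)
            coefs = est.coef_.ravel().copy()
            out[idx] = EnetModel(
                coefficients=coefs,
                intercept=_polish_intercept(X, y01, coefs, float(est.intercept_[0])),
                lam=lam,
                mixing=float(mixing),
                feature_names=list(names),
            )
    return out  # type: ignore[return-value]


class _Standardizer:
    """Zero-mean / unit-variance transform with training-set statistics."""

    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.sd = np.where(sd > 0, sd, 1.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def _cross_entropy(model: EnetModel, X: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(model.predict_proba(X), 1e-12, 1 - 1e-12)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def _contrast_frame(
    features: pd.DataFrame, contrast: tuple[str, str]
) -> tuple[pd.DataFrame, str]:
    a, b = contrast
    for label in (a, b):
        if label not in EPOCH_LABELS:
            raise ValueError(f"unknown epoch label {label!r}")
    if a == b:
        raise ValueError("contrast epochs must differ")
    positive = a if EPOCH_LABELS.index(a) > EPOCH_LABELS.index(b) else b
    sub = features[features["epoch"].isin(contrast)].copy()
    return sub, positive


def _select_lambda(mean_ce: np.ndarray, lambdas: np.ndarray) -> int:
    """Index of the CE-minimizing lambda; ties go to the larger lambda."""
    best = mean_ce.min()
    tied = np.flatnonzero(mean_ce <= best + 1e-12)
    return int(tied[np.argmax(lambdas[tied])])


def nested_cv(
    features: pd.DataFrame,
    contrast: tuple[str, str] = ("PRE", "POST"),
    lambda_grid: np.ndarray | None = None,
    mixing: float = 0.5,
    seed: int = 0,
) -> CvResult:
    """Group-level nested LOSO cross-validation for one epoch contrast.

    Only complete-case subjects (all six features present, segments for both
    contrast epochs) participate; others are dropped with a warning. Returns
    one outer fold per usable subject, each carrying the held-out AUC, the
    selected lambda, and the inner-fold models fitted at that lambda (the raw
    material of the selection-frequency importance statistic).
    """
    lambdas = np.asarray(DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid, dtype=float)
    sub, positive = _contrast_frame(features, contrast)

    usable = []
    for sid, grp in sub.groupby("subject_id", sort=True):
        if set(grp["epoch"]) != set(contrast):
            warnings.warn(f"subject {sid} lacks an epoch for {contrast}; excluded", stacklevel=2)
            continue
        if grp[FEATURE_NAMES].isna().any().any():
            warnings.warn(f"subject {sid} has missing features; excluded", stacklevel=2)
            continue
        usable.append(sid)
    if len(usable) < 3:
        raise ValueError(f"need >= 3 complete-case subjects, have {len(usable)}")

    data = {
        sid: (
            sub.loc[sub["subject_id"] == sid, FEATURE_NAMES].to_numpy(float),
            (sub.loc[sub["subject_id"] == sid, "epoch"] == positive).to_numpy(int),
        )
        for sid in usable
    }
    rs = int(seed) % (2**31 - 1)

    outer_folds = []
    for held in usable:
        train_subjects = [s for s in usable if s != held]
        # Inner LOSO: path fit per left-out training subject.
        ce = np.zeros((len(train_subjects), len(lambdas)))
        inner_paths = []
        for i, val in enumerate(train_subjects):
            fit_subjects = [s for s in train_subjects if s != val]
            X_fit = np.vstack([data[s][0] for s in fit_subjects])
            y_fit = np.concatenate([data[s][1] for s in fit_subjects])
            std = _Standardizer(X_fit)
            path = enet_path(
                std.transform(X_fit),
                y_fit,
                lambdas,
                mixing=mixing,
                random_state=rs,
                feature_names=FEATURE_NAMES,
            )
            X_val = std.transform(data[val][0])
            y_val = data[val][1]
            ce[i] = [_cross_entropy(m, X_val, y_val) for m in path]
            inner_paths.append(path)
        best = _select_lambda(ce.mean(axis=0), lambdas)
        chosen = float(lambdas[best])
        inner_models = [path[best] for path in inner_paths]

        X_train = np.vstack([data[s][0] for s in train_subjects])
        y_train = np.concatenate([data[s][1] for s in train_subjects])
        std = _Standardizer(X_train)
        model = fit_enet_logistic(
            std.transform(X_train),
            y_train,
            chosen,
            mixing=mixing,
            random_state=rs,
            feature_names=FEATURE_NAMES,
        )
        X_test = std.transform(data[held][0])
        scores = model.decision(X_test)
        auc = float(roc_auc_score(data[held][1], scores))
        outer_folds.append(
            OuterFold(
                held_out=held,
                chosen_lambda=chosen,
                auc=auc,
                model=model,
                inner_models=inner_models,
            )
        )
    return CvResult(
        contrast=tuple(contrast),
        feature_names=list(FEATURE_NAMES),
        outer=outer_folds,
        mixing=mixing,
        seed=int(seed),
    )


def _subject_feature_columns(grp: pd.DataFrame) -> list[str]:
    return [c for c in FEATURE_NAMES if grp[c].notna().all()]


def subject_level_cv(
    features: pd.DataFrame,
    contrasts: tuple[tuple[str, str], ...] = (("PRE", "MID"), ("PRE", "POST")),
    lambda_grid: np.ndarray | None = None,
    mixing: float = 0.5,
    seed: int = 0,
    outer_folds: int = 5,
    inner_folds: int = 5,
    min_segments: int = 10,
) -> pd.DataFrame:
    """Per-subject classifiers: nested stratified segment-fold CV per contrast.

    Within a single subject the outer unit is the 1-s segment, so the outer
    loop is a stratified K-fold over segments and the inner loop a stratified
    K-fold over the outer-training segments. Subjects with fewer than
    ``min_segments`` segments per class, or no fully observed feature
    columns, are skipped with a warning. Returns one row per eligible subject
    with one mean-AUC column per contrast (e.g. ``auc_pre_post``).
    """
    lambdas = np.asarray(DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid, dtype=float)
    rows = []
    for si, (sid, grp) in enumerate(features.groupby("subject_id", sort=True)):
        cols = _subject_feature_columns(grp)
        if not cols:
            warnings.warn(f"subject {sid}: no fully observed features; skipped", stacklevel=2)
            continue
        row: dict = {"subject_id": sid}
        ok = True
        for contrast in contrasts:
            sub, positive = _contrast_frame(grp, contrast)
            y = (sub["epoch"] == positive).to_numpy(int)
            X = sub[cols].to_numpy(float)
            if len(np.unique(y)) < 2 or min(np.bincount(y)) < min_segments:
                warnings.warn(
                    f"subject {sid}: too few segments for {contrast}; skipped", stacklevel=2
                )
                ok = False
                break
            rs = (int(seed) * 1000 + si) % (2**31 - 1)
            outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=rs)
            aucs = []
            for tr_idx, te_idx in outer.split(X, y):
                X_tr, y_tr = X[tr_idx], y[tr_idx]
                inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=rs + 1)
                ce = np.zeros((inner_folds, len(lambdas)))
                for j, (fit_idx, val_idx) in enumerate(inner.split(X_tr, y_tr)):
                    std = _Standardizer(X_tr[fit_idx])
                    path = enet_path(
                        std.transform(X_tr[fit_idx]),
                        y_tr[fit_idx],
                        lambdas,
                        mixing=mixing,
                        random_state=rs,
                        feature_names=cols,
                    )
                    X_val = std.transform(X_tr[val_idx])
                    ce[j] = [_cross_entropy(m, X_val, y_tr[val_idx]) for m in path]
                best = _select_lambda(ce.mean(axis=0), lambdas)
                std = _Standardizer(X_tr)
                model = fit_enet_logistic(
                    std.transform(X_tr),
                    y_tr,
                    float(lambdas[best]),
                    mixing=mixing,
                    random_state=rs,
                    feature_names=cols,
                )
                aucs.append(roc_auc_score(y[te_idx], model.decision(std.transform(X[te_idx]))))
            row[f"auc_{contrast[0].lower()}_{contrast[1].lower()}"] = float(np.mean(aucs))
        if ok:
            rows.append(row)
    return pd.DataFrame(rows)


def compare_subject_aucs(table: pd.DataFrame, columns: tuple[str, str] | None = None) -> RmAnovaResult:
    """Repeated-measures ANOVA over the two per-subject AUC conditions."""
    if columns is None:
        columns = tuple(c for c in table.columns if c.startswith("auc_"))[:2]  # type: ignore[assignment]
    if len(columns) != 2:
        raise ValueError("need exactly two AUC columns")
    return two_condition_rmanova(table[columns[0]], table[columns[1]], warn_label="AUC pairs")
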