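"""Clinical-outcome arm: depression-score summaries, pre/post repeated-
measures ANOVA, and correlation of spectral change with early symptom change
under a permutation-based family-wise significance correction.

Percent change is defined identically for scores and band powers,
``100 * (post - pre) / pre`` (signed; negative = decrease), so a positive
Pearson correlation means the two decreases co-occur. A "responder" is a
subject whose HDRS-17 score declined by strictly more than 50% from
baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sigio import ClinicalTable, HDRS_MAX, ValidationError
from .stats import RmAnovaResult, round_half_up, two_condition_rmanova

__all__ = [
    "HdrsSummary",
    "CorrelationResult",
    "load_reference_cohort",
    "summarize_hdrs",
    "pre_post_rmanova",
    "percent_change",
    "pearson_slope_test",
    "permutation_fdr",
    "beta_outcome_correlation",
]

#: Clinical scores of the eight-patient intraoperative SCC-DBS cohort this
#: pipeline models: 4-week pre-surgical HDRS-17 averages, scores one week
#: after the operating-room stimulation session, and ages at surgery.
_REFERENCE_ROWS = [
    ("S01", "F", 43, 23.50, 19.0),
    ("S02", "F", 43, 20.50, 13.0),
    ("S03", "F", 66, 23.25, 8.0),
    ("S04", "F", 58, 23.50, 15.0),
    ("S05", "M", 53, 20.50, 9.0),
    ("S06", "F", 56, 23.25, 9.0),
    ("S07", "M", 37, 22.75, 13.0),
    ("S08", "F", 44, 24.75, 13.0),
]


def load_reference_cohort() -> ClinicalTable:
    """The reference eight-subject clinical table (with age and gender)."""
    df = pd.DataFrame(
        _REFERENCE_ROWS, columns=["subject_id", "gender", "age", "hdrs_baseline", "hdrs_post"]
    )
    return ClinicalTable(df[["subject_id", "hdrs_baseline", "hdrs_post", "age", "gender"]])


@dataclass
class HdrsSummary:
    """Cohort-level HDRS-17 summary in the conventional reporting layout."""

    mean_baseline: float
    sd_baseline: float
    mean_post: float
    sd_post: float
    percent_decline: float  # positive = improvement
    n_responders: int
    n: int
    mean_age: float | None = None

    def rounded(self) -> dict:
        """Values at reporting precision (2 decimals; percents 1 decimal)."""
        out = {
            "mean_baseline": round_half_up(self.mean_baseline, 2),
            "sd_baseline": round_half_up(self.sd_baseline, 2),
            "mean_post": round_half_up(self.mean_post, 2),
            "sd_post": round_half_up(self.sd_post, 2),
            "percent_decline": round_half_up(self.percent_decline, 1),
            "n_responders": self.n_responders,
            "n": self.n,
        }
        if self.mean_age is not None:
            out["mean_age"] = round_half_up(self.mean_age, 2)
        return out


def summarize_hdrs(table: ClinicalTable) -> HdrsSummary:
    """Means, sample SDs, cohort percent decline and strict >50% responder count."""
    df = table.df
    if len(df) < 1:
        raise ValidationError("empty clinical table")
    base = df["hdrs_baseline"].to_numpy(float)
    post = df["hdrs_post"].to_numpy(float)
    mean_baseline = base.mean()
    mean_post = post.mean()
    decline = 100.0 * (base - post) / base
    summary = HdrsSummary(
        mean_baseline=float(mean_baseline),
        sd_baseline=float(base.std(ddof=1)) if len(base) > 1 else 0.0,
        mean_post=float(mean_post),
        sd_post=float(post.std(ddof=1)) if len(post) > 1 else 0.0,
        percent_decline=float(100.0 * (mean_baseline - mean_post) / mean_baseline),
        n_responders=int((decline > 50.0).sum()),
        n=len(df),
        mean_age=float(df["age"].mean()) if "age" in df.columns else None,
    )
    return summary


def pre_post_rmanova(table: ClinicalTable) -> RmAnovaResult:
    """Two-condition repeated-measures ANOVA of baseline vs post scores."""
    return two_condition_rmanova(
        table.df["hdrs_baseline"], table.df["hdrs_post"], warn_label="score pairs"
    )


def percent_change(pre: float, post: float) -> float:
    """Signed percent change ``100 * (post - pre) / pre``."""
    if pre == 0:
        raise ZeroDivisionError("percent change undefined for pre == 0")
    return 100.0 * (post - pre) / pre


@dataclass
class CorrelationResult:
    """Pearson correlation with slope t-test and permutation-corrected p."""

    name: str
    r: float
    n: int
    p_uncorrected: float  # two-tailed parametric slope test
    p_permutation: float | None = None  # marginal permutation p, same statistic
    p_corrected: float | None = None  # family-wise min-p corrected


def pearson_slope_test(x: Sequence[float], y: Sequence[float], name: str = "") -> CorrelationResult:
    """Pearson r with a two-tailed t-test of zero regression slope.

    ``t = r * sqrt((n - 2) / (1 - r^2))`` with ``n - 2`` degrees of freedom.
    Pairs with a missing member are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, have {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(name=name, r=float(r), n=n, p_uncorrected=float(p))


def _pearson_r_matrix(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r of ``x`` against every row of ``Y`` (vectorized)."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = Yc @ xc
    den = np.sqrt((xc**2).sum() * (Yc**2).sum(axis=1))
    return num / den


def _slope_test_p(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    return 2.0 * sps.t.sf(np.abs(t), df=n - 2)


def permutation_fdr(
    tests: list[tuple[np.ndarray, np.ndarray]],
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> list[CorrelationResult]:
    """Family-wise permutation correction of correlation slope tests (min-p).

    For every permutation the outcome vector of each test is shuffled
    independently, the slope-test p of each test is recomputed, and the
    family minimum is recorded. The corrected p of an observed test is the
    fraction of permutation minima at or below its observed p (with the
    identity permutation included in the null set, so corrected p is never
    0). The marginal permutation p — the same fraction computed against the
    test's own permuted p values — is reported alongside and is a lower
    bound on the corrected p by construction.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; p values will be coarse", stacklevel=2)
    names = list(names) if names is not None else [f"test{i}" for i in range(len(tests))]
    observed: list[CorrelationResult] = []
    clean: list[tuple[np.ndarray, np.ndarray, str]] = []
    for (x, y), name in zip(tests, names):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"degenerate test {name!r}: too few pairs or zero variance")
        observed.append(pearson_slope_test(x, y, name=name))
        clean.append((x, y, name))

    rng = np.random.default_rng(int(seed))
    perm_p = np.empty((len(clean), n_perm))
    for i, (x, y, _) in enumerate(clean):
        n = len(x)
        perms = np.array([rng.permutation(y) for _ in range(n_perm)])
        r = _pearson_r_matrix(x, perms)
        perm_p[i] = _slope_test_p(r, n)
    min_p = perm_p.min(axis=0)

    for i, res in enumerate(observed):
        res.p_permutation = float(
            (1 + (perm_p[i] <= res.p_uncorrected).sum()) / (n_perm + 1)
        )
        res.p_corrected = float((1 + (min_p <= res.p_uncorrected).sum()) / (n_perm + 1))
    return observed


def _epoch_mean_power(features: pd.DataFrame, feature: str, epoch: str) -> pd.Series:
    sub = features[features["epoch"] == epoch]
    return sub.groupby("subject_id")[feature].mean()


def beta_outcome_correlation(
    features: pd.DataFrame,
    clinical: ClinicalTable,
    feature_names: tuple[str, ...] = ("beta_L", "alpha_R"),
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[CorrelationResult]:
    """Correlate per-subject spectral percent change with HDRS percent change.

    For each named feature: mean PRE and POST power per subject, percent
    change, Pearson correlation against the HDRS percent change, and a
    permutation-FDR correction across the feature family. Subjects missing a
    hemisphere drop out of that hemisphere's features only, so the per-test n
    can differ across features.
    """
    cdf = clinical.df.set_index("subject_id")
    hdrs_change = pd.Series(
        {
            sid: percent_change(row["hdrs_baseline"], row["hdrs_post"])
            for sid, row in cdf.iterrows()
        }
    )
    tests = []
    kept_names = []
    for feat in feature_names:
        pre = _epoch_mean_power(features, feat, "PRE")
        post = _epoch_mean_power(features, feat, "POST")
        joined = pd.concat(
            {"pre": pre, "post": post, "hdrs": hdrs_change}, axis=1, join="inner"
        ).dropna()
        if len(joined) < 3:
            warnings.warn(f"feature {feat}: <3 usable subjects; skipped", stacklevel=2)
            continue
        power_change = np.array(
            [percent_change(p, q) for p, q in zip(joined["pre"], joined["post"])]
        )
        tests.append((power_change, joined["hdrs"].to_numpy(float)))
        kept_names.append(feat)
    if not tests:
        raise ValueError("no feature had enough usable subjects")
    return permutation_fdr(tests, n_perm=n_perm, alpha=alpha, seed=seed, names=kept_names)
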