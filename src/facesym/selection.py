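"""Effect-size-driven landmark-pair selection against ordinal clinical grades.

Clinical severity is the Stennert index: two ordinal scales, at rest
(0 = no asymmetry .. 4 = severe) and during voluntary movement
(0 = normal .. 6 = complete/near-complete impairment). Per landmark pair,
absolute angles are averaged to one deviation value per analysis unit
(session by default), and one-way-ANOVA eta-squared

    eta2 = SS_between / SS_total

measures the fraction of that deviation's variance explained by grade.
A threshold sweep (0.001..0.400 in 0.001 steps) retains pairs whose
eta-squared exceeds the threshold in *both* conditions; each candidate
subset is scored (mean absolute angle) and rated by the Kruskal-Wallis H
statistic across grades, and the subset maximizing the combined H is
selected. Spearman rank correlations between subset scores and grades
provide the final validity report. No multiple-testing correction is
applied to the selection path (a Benjamini-Hochberg column is emitted for
reference only).

The sweep is implemented as a scikit-learn selector
(:class:`EtaThresholdPairSelector`); module functions wrap it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import (
    AggregationError,
    IntegrityError,
    SelectionError,
    UndefinedStatisticError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GradeRecord",
    "TestResult",
    "SweepResult",
    "read_grades",
    "eta_squared",
    "kruskal_wallis",
    "spearman",
    "unit_deviations",
    "EtaThresholdPairSelector",
    "threshold_sweep",
    "correlation_report",
]

GRADE_COLUMNS = ["dataset_id", "patient_id", "stennert_rest", "stennert_move"]

DEFAULT_THRESHOLDS = np.round(np.arange(1, 401) * 0.001, 3)


@dataclass(frozen=True)
class GradeRecord:
    """Clinical grading of one dataset (session)."""

    dataset_id: str
    patient_id: str
    stennert_rest: int
    stennert_move: int

    def __post_init__(self) -> None:
        if not (0 <= self.stennert_rest <= 4):
            raise IntegrityError(f"stennert_rest out of range: {self.stennert_rest}")
        if not (0 <= self.stennert_move <= 6):
            raise IntegrityError(f"stennert_move out of range: {self.stennert_move}")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    df: int


def read_grades(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in GRADE_COLUMNS if c not in df.columns]
    if missing:
        raise IntegrityError(f"{path}: grade file missing columns {missing}")
    if df["dataset_id"].duplicated().any():
        raise IntegrityError(f"{path}: more than one grade record per dataset")
    for _, row in df.iterrows():  # range validation via the dataclass
        GradeRecord(str(row.dataset_id), str(row.patient_id),
                    int(row.stennert_rest), int(row.stennert_move))
    return df[GRADE_COLUMNS].astype(
        {"dataset_id": str, "patient_id": str,
         "stennert_rest": int, "stennert_move": int}
    )


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def _as_groups(values, groups) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape[0] != g.shape[0]:
        raise ValueError("values and groups must have equal length")
    return v, g


def eta_squared(values: Sequence[float], groups: Sequence) -> float:
    """One-way-ANOVA effect size SS_between / SS_total.

    Returns 0.0 when SS_total = 0 (all values identical); raises when only
    one group is present.
    """
    v, g = _as_groups(values, groups)
    labels = np.unique(g)
    if labels.size < 2:
        raise UndefinedStatisticError("eta-squared needs at least 2 groups")
    grand = v.mean()
    ss_total = float(np.sum((v - grand) ** 2))
    if ss_total == 0.0:
        return 0.0
    ss_between = float(
        sum(np.sum(g == lab) * (v[g == lab].mean() - grand) ** 2 for lab in labels)
    )
    return ss_between / ss_total


def eta_squared_matrix(X: np.ndarray, groups: Sequence) -> np.ndarray:
    """Column-wise eta-squared of an (n_units, n_pairs) deviation matrix."""
    X = np.asarray(X, dtype=float)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size < 2:
        raise UndefinedStatisticError("eta-squared needs at least 2 groups")
    grand = X.mean(axis=0)
    ss_total = np.sum((X - grand) ** 2, axis=0)
    ss_between = np.zeros(X.shape[1])
    for lab in labels:
        sel = g == lab
        ss_between += sel.sum() * (X[sel].mean(axis=0) - grand) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        eta2 = np.where(ss_total == 0.0, 0.0, ss_between / ss_total)
    return eta2


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df)."""
    v, g = _as_groups(values, groups)
    labels = np.unique(g)
    if labels.size < 2:
        raise UndefinedStatisticError("Kruskal-Wallis needs at least 2 groups")
    if np.ptp(v) == 0.0:
        # all values identical: no separation at all
        return TestResult(statistic=0.0, p_value=1.0,
                          n=int(v.size), df=int(labels.size - 1))
    samples = [v[g == lab] for lab in labels]
    h, p = stats.kruskal(*samples)
    return TestResult(statistic=float(h), p_value=float(p),
                      n=int(v.size), df=int(labels.size - 1))


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rho on average ranks with two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman needs equal-length vectors of length >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return TestResult(statistic=float(rho), p_value=float(p),
                      n=int(x.size), df=int(x.size - 2))


# ---------------------------------------------------------------------------
# Aggregation to analysis units
# ---------------------------------------------------------------------------


def unit_deviations(
    angle_df: pd.DataFrame,
    grades: pd.DataFrame,
    unit: str = "session",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean absolute pair angle per analysis unit, with aligned grades.

    unit="session": one row per dataset, |theta| averaged over its nine
    expressions. unit="patient": |theta| averaged over all images of all
    the patient's graded sessions; the patient's grades must be constant
    across sessions (strict reducer), otherwise an :class:`AggregationError`
    directs the caller to unit="session". Datasets without a grade record
    are excluded with a logged count.

    Returns ``(U, unit_grades)`` where ``U`` holds theta_* columns of mean
    absolute deviations, indexed like ``unit_grades``.
    """
    if unit not in ("session", "patient"):
        raise ValueError("unit must be 'session' or 'patient'")
    theta_cols = [c for c in angle_df.columns if c.startswith("theta_")]
    graded_ids = set(grades["dataset_id"])
    have_ids = angle_df["dataset_id"].unique()
    keep = angle_df["dataset_id"].isin(graded_ids)
    n_excluded = len(set(have_ids) - graded_ids)
    if n_excluded:
        logger.info(
            "excluding %d of %d dataset(s) without grade records",
            n_excluded, len(have_ids),
        )
    df = angle_df.loc[keep].copy()
    df[theta_cols] = df[theta_cols].abs()
    if unit == "session":
        U = df.groupby("dataset_id", sort=True)[theta_cols].mean()
        unit_grades = (
            grades.set_index("dataset_id")
            .loc[U.index, ["patient_id", "stennert_rest", "stennert_move"]]
        )
        return U.reset_index(drop=True), unit_grades.reset_index()
    # unit == "patient"
    merged = df.merge(grades, on=["dataset_id", "patient_id"], how="left")
    per_patient = merged.groupby("patient_id", sort=True)
    for pid, block in per_patient:
        if block["stennert_rest"].nunique() > 1 or block["stennert_move"].nunique() > 1:
            raise AggregationError(
                f"patient {pid} has differing grades across sessions; "
                "use unit='session'"
            )
    U = per_patient[theta_cols].mean()
    unit_grades = per_patient[["stennert_rest", "stennert_move"]].first().reset_index()
    unit_grades.insert(0, "dataset_id", unit_grades["patient_id"])
    return U.reset_index(drop=True), unit_grades


# ---------------------------------------------------------------------------
# Threshold sweep (scikit-learn selector)
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    thresholds: np.ndarray
    table: pd.DataFrame  # threshold, n_pairs, H_rest, p_rest, H_move, p_move, objective
    chosen_subset: list[int]
    chosen_size: int
    chosen_threshold: float
    min_eta2: float
    objective: str
    discriminative: bool
    eta2_rest: np.ndarray
    eta2_move: np.ndarray


class EtaThresholdPairSelector(SelectorMixin, BaseEstimator):
    """Select landmark pairs by a two-condition eta-squared threshold sweep.

    Parameters
    ----------
    thresholds : array-like of float, default 0.001..0.400 step 0.001
        Candidate eta-squared thresholds.
    objective : {"sum", "min"}, default "sum"
        How the rest- and movement-condition Kruskal-Wallis H statistics
        are combined when ranking candidate subsets.
    strict : bool, default True
        Retain pairs with eta2 strictly greater than the threshold
        (False: greater-or-equal).

    ``fit(X, y)`` expects ``X`` as the (n_units, n_pairs) matrix of mean
    absolute pair angles and ``y`` as an (n_units, 2) integer array with
    columns (stennert_rest, stennert_move).

    Attributes
    ----------
    support_ : bool array of shape (n_pairs,)
        Mask of the selected pairs.
    eta2_rest_, eta2_move_ : float arrays
        Per-pair effect sizes in each condition.
    sweep_ : SweepResult
        Full per-threshold trace and selection metadata.
    """

    def __init__(self, thresholds=None, objective: str = "sum", strict: bool = True):
        self.thresholds = thresholds
        self.objective = objective
        self.strict = strict

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be an (n_units, n_pairs) matrix")
        if y.ndim != 2 or y.shape[1] != 2 or y.shape[0] != X.shape[0]:
            raise ValueError("y must be an (n_units, 2) array of (rest, move) grades")
        if self.objective not in ("sum", "min"):
            raise ValueError("objective must be 'sum' or 'min'")
        thresholds = (
            DEFAULT_THRESHOLDS
            if self.thresholds is None
            else np.asarray(self.thresholds, dtype=float)
        )
        rest, move = y[:, 0], y[:, 1]
        eta2_rest = eta_squared_matrix(X, rest)
        eta2_move = eta_squared_matrix(X, move)

        combine = (lambda a, b: a + b) if self.objective == "sum" else min
        rows = []
        cache: dict[bytes, tuple[float, float, float, float, float]] = {}
        best = None  # (objective, -n_pairs, threshold, mask)
        for t in thresholds:
            if self.strict:
                mask = (eta2_rest > t) & (eta2_move > t)
            else:
                mask = (eta2_rest >= t) & (eta2_move >= t)
            n_sel = int(mask.sum())
            if n_sel == 0:
                rows.append((t, 0, np.nan, np.nan, np.nan, np.nan, np.nan))
                continue
            key = mask.tobytes()
            if key not in cache:
                unit_scores = X[:, mask].mean(axis=1)
                kw_rest = kruskal_wallis(unit_scores, rest)
                kw_move = kruskal_wallis(unit_scores, move)
                obj = float(combine(kw_rest.statistic, kw_move.statistic))
                cache[key] = (kw_rest.statistic, kw_rest.p_value,
                              kw_move.statistic, kw_move.p_value, obj)
            h_rest, p_rest, h_move, p_move, obj = cache[key]
            rows.append((t, n_sel, h_rest, p_rest, h_move, p_move, obj))
            cand = (obj, -n_sel, t)
            if best is None or cand > best[0]:
                best = (cand, mask, float(t))
        if best is None:
            raise SelectionError("no threshold yields a non-empty pair subset")
        _, mask, threshold = best
        chosen = np.flatnonzero(mask)
        chosen_scores = X[:, mask].mean(axis=1)
        kw_rest = kruskal_wallis(chosen_scores, rest)
        kw_move = kruskal_wallis(chosen_scores, move)
        discriminative = kw_rest.p_value < 0.05 or kw_move.p_value < 0.05
        if not discriminative:
            logger.warning(
                "chosen subset is non-discriminative (p_rest=%.3f, p_move=%.3f)",
                kw_rest.p_value, kw_move.p_value,
            )
        table = pd.DataFrame(
            rows,
            columns=["threshold", "n_pairs", "H_rest", "p_rest",
                     "H_move", "p_move", "objective"],
        )
        self.n_features_in_ = X.shape[1]
        self.eta2_rest_ = eta2_rest
        self.eta2_move_ = eta2_move
        self.support_ = mask
        self.threshold_ = threshold
        self.min_eta2_ = float(
            min(eta2_rest[mask].min(), eta2_move[mask].min())
        )
        self.sweep_ = SweepResult(
            thresholds=thresholds,
            table=table,
            chosen_subset=[int(i) for i in chosen],
            chosen_size=int(chosen.size),
            chosen_threshold=threshold,
            min_eta2=self.min_eta2_,
            objective=self.objective,
            discriminative=bool(discriminative),
            eta2_rest=eta2_rest,
            eta2_move=eta2_move,
        )
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def threshold_sweep(
    U: pd.DataFrame | np.ndarray,
    unit_grades: pd.DataFrame,
    thresholds=None,
    objective: str = "sum",
) -> SweepResult:
    """Functional wrapper around :class:`EtaThresholdPairSelector`."""
    X = U.to_numpy(dtype=float) if isinstance(U, pd.DataFrame) else np.asarray(U, float)
    y = unit_grades[["stennert_rest", "stennert_move"]].to_numpy(int)
    sel = EtaThresholdPairSelector(thresholds=thresholds, objective=objective)
    sel.fit(X, y)
    return sel.sweep_


# ---------------------------------------------------------------------------
# Correlation report (validity table)
# ---------------------------------------------------------------------------


def correlation_report(
    score_df: pd.DataFrame,
    grades: pd.DataFrame,
    subsets: Sequence[str] = ("91", "eye", "nose", "mouth"),
) -> pd.DataFrame:
    """Spearman rho and p between subset scores and Stennert grades.

    One row per (subset, condition, expression in 1..9 + "all"); cells
    with undefined correlations (constant input) are reported as NaN with
    a note, never raised.
    """
    df = score_df.copy()
    df["expression_id"] = df["expression_id"].astype(str)
    graded = df.merge(grades, on=["patient_id", "dataset_id"], how="inner")
    rows = []
    expressions = [str(e) for e in range(1, 10)] + ["all"]
    for subset in subsets:
        block = graded[graded["subset_name"] == subset]
        for condition, col in (("rest", "stennert_rest"), ("move", "stennert_move")):
            for expr in expressions:
                cell = block[block["expression_id"] == expr]
                note = ""
                rho = p = np.nan
                n = len(cell)
                if n >= 3:
                    try:
                        res = spearman(cell["score_deg"], cell[col])
                        rho, p = res.statistic, res.p_value
                    except UndefinedStatisticError:
                        note = "undefined (constant input)"
                else:
                    note = "insufficient n"
                rows.append((subset, condition, expr, rho, p, n, note))
    report = pd.DataFrame(
        rows, columns=["subset", "condition", "expression", "rho", "p", "n", "note"]
    )
    # reference-only BH-adjusted p per (subset, condition); never used upstream
    def _bh(p):
        p = p.to_numpy(float)
        q = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        if ok.sum():
            m = ok.sum()
            order = np.argsort(p[ok])
            ranked = p[ok][order] * m / (np.arange(m) + 1)
            q_ok = np.minimum.accumulate(ranked[::-1])[::-1]
            tmp = np.empty(m)
            tmp[order] = np.minimum(q_ok, 1.0)
            q[ok] = tmp
        return pd.Series(q, index=np.flatnonzero(np.ones(len(p))))

    report["p_bh"] = (
        report.groupby(["subset", "condition"], sort=False)["p"]
        .transform(lambda s: _bh(s).to_numpy())
    )
    return report
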