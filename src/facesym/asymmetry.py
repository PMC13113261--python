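"""Pair-angle features and the asymmetry score.

For a mirror-corresponding landmark pair with image-left point
``L = (xL, yL)`` and image-right point ``R = (xR, yR)`` on the aligned
face, the signed angle of the connecting segment relative to horizontal is

    theta = (180/pi) * atan2(yR - yL, xR - xL)   [degrees]

With y pointing down, theta > 0 means the right-side point hangs lower in
the image. The per-image feature vector a = (theta_1, ..., theta_N) holds
one angle per registry pair; the global (or regional) asymmetry score over
a pair subset is the mean of absolute angles

    Score_AI = (1/N) * sum_i |theta_i|   [degrees]

A perfectly symmetric aligned face scores 0; larger scores mean stronger
asymmetry. Angles are stored signed (direction + magnitude); only the
score takes absolute values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import alignment
from .errors import FacesymError
from .landmarks import DatasetRecord, LandmarkSet, PairRegistry, N_EXPRESSIONS

logger = logging.getLogger(__name__)

__all__ = [
    "AngleVector",
    "ScoreResult",
    "pair_angles",
    "score",
    "region_scores",
    "angle_table",
    "score_table",
    "expression_summary",
]


@dataclass(frozen=True)
class AngleVector:
    """Signed per-pair angles (degrees) for one aligned image."""

    dataset_id: str
    expression_id: int
    registry_name: str
    theta: np.ndarray

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "theta", theta)
        if not np.all(np.isfinite(theta)):
            raise FacesymError("non-finite pair angles")


@dataclass(frozen=True)
class ScoreResult:
    dataset_id: str
    expression_id: int | str
    subset_name: str
    n_pairs: int
    score_deg: float


def pair_angles(aligned: LandmarkSet, registry: PairRegistry) -> AngleVector:
    """Signed angle per registry pair on an aligned landmark set.

    Coincident pair points yield theta = 0 (the atan2(0, 0) convention)
    with a logged warning, never an exception.
    """
    pairs = np.asarray(registry.pairs, dtype=int)
    left = aligned.xy[pairs[:, 0]]
    right = aligned.xy[pairs[:, 1]]
    dx = right[:, 0] - left[:, 0]
    dy = right[:, 1] - left[:, 1]
    coincident = (dx == 0.0) & (dy == 0.0)
    if coincident.any():
        logger.warning(
            "%s/expr%d: %d coincident landmark pair(s) -> angle 0",
            aligned.dataset_id,
            aligned.expression_id,
            int(coincident.sum()),
        )
    theta = np.degrees(np.arctan2(dy, dx))
    return AngleVector(
        dataset_id=aligned.dataset_id,
        expression_id=aligned.expression_id,
        registry_name=registry.name,
        theta=theta,
    )


def _resolve_theta(angles: AngleVector | np.ndarray) -> np.ndarray:
    return angles.theta if isinstance(angles, AngleVector) else np.asarray(angles, float)


def score(
    angles: AngleVector | np.ndarray,
    subset: Sequence[int] | None = None,
    subset_name: str = "custom",
) -> ScoreResult:
    """Mean absolute pair angle over a subset of pair ordinals (degrees)."""
    theta = _resolve_theta(angles)
    ordinals = np.arange(theta.size) if subset is None else np.asarray(list(subset), int)
    if ordinals.size == 0:
        raise ValueError("score requires a non-empty pair subset")
    if ordinals.min() < 0 or ordinals.max() >= theta.size:
        raise ValueError("subset ordinals out of range")
    value = float(np.mean(np.abs(theta[ordinals])))
    return ScoreResult(
        dataset_id=getattr(angles, "dataset_id", ""),
        expression_id=getattr(angles, "expression_id", 0),
        subset_name=subset_name if subset is not None else "full",
        n_pairs=int(ordinals.size),
        score_deg=value,
    )


def region_scores(
    angles: AngleVector | np.ndarray,
    registry: PairRegistry,
    base_subset: Sequence[int] | str | None = None,
) -> dict[str, ScoreResult]:
    """One regional score per region present in the base subset.

    The full-subset score decomposes exactly as the pair-count-weighted
    mean of the regional scores.
    """
    base = registry.subset_ordinals(base_subset)
    regions = registry.region_of(base)
    out: dict[str, ScoreResult] = {}
    for region in ("eye", "nose", "mouth", "other"):
        ordinals = base[regions == region]
        if ordinals.size == 0:
            if region != "other":
                logger.warning("region %s absent from subset; omitted", region)
            continue
        out[region] = score(angles, ordinals, subset_name=region)
    return out


# ---------------------------------------------------------------------------
# Cohort-level tables
# ---------------------------------------------------------------------------


def angle_table(
    records: Iterable[DatasetRecord], registry: PairRegistry
) -> pd.DataFrame:
    """Run align -> pair_angles over a cohort.

    Returns one row per (dataset, expression) with metadata columns
    (patient_id, dataset_id, session_order, expression_id, rotation_deg,
    midline_slope) followed by theta_0 .. theta_{N-1}.
    """
    rows = []
    theta_cols = [f"theta_{i}" for i in range(registry.n_pairs)]
    for rec in records:
        for ls in rec:
            res = alignment.align(ls, registry.midline_indices)
            av = pair_angles(res.aligned, registry)
            rows.append(
                [
                    rec.patient_id,
                    rec.dataset_id,
                    rec.session_order,
                    ls.expression_id,
                    res.rotation_deg,
                    res.fit.slope_b,
                    *av.theta,
                ]
            )
    meta = ["patient_id", "dataset_id", "session_order", "expression_id",
            "rotation_deg", "midline_slope"]
    return pd.DataFrame(rows, columns=meta + theta_cols)


def theta_matrix(angle_df: pd.DataFrame) -> np.ndarray:
    """The (n_images, n_pairs) signed-angle matrix of an angle table."""
    cols = [c for c in angle_df.columns if c.startswith("theta_")]
    return angle_df[cols].to_numpy(dtype=float)


def score_table(
    angle_df: pd.DataFrame,
    registry: PairRegistry,
    subsets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-image scores for several subsets, plus a per-dataset "all" row.

    ``subsets`` defaults to full + every stored subset + the three named
    regions restricted to the 91-style subset when stored (otherwise over
    all pairs). The "all" expression aggregate is the unweighted mean of
    the nine per-expression scores of a dataset.
    """
    if subsets is None:
        subsets = ["full", *sorted(registry.subsets, key=lambda s: -int(s))]
        base = "91" if "91" in registry.subsets else "full"
        subsets += [f"{base}:{r}" for r in ("eye", "nose", "mouth")]
    theta = theta_matrix(angle_df)
    out = []
    for name in subsets:
        if ":" in name:
            base_name, region = name.split(":", 1)
            base = registry.subset_ordinals(None if base_name == "full" else base_name)
            ordinals = base[registry.region_of(base) == region]
            label = region
        else:
            ordinals = registry.subset_ordinals(None if name == "full" else name)
            label = name
        if ordinals.size == 0:
            logger.warning("subset %s empty; skipped", name)
            continue
        scores = np.mean(np.abs(theta[:, ordinals]), axis=1)
        block = angle_df[
            ["patient_id", "dataset_id", "session_order", "expression_id",
             "rotation_deg", "midline_slope"]
        ].copy()
        block.insert(4, "subset_name", label)
        block.insert(5, "n_pairs", int(ordinals.size))
        block["score_deg"] = scores
        out.append(block)
        # per-dataset "all" aggregate: unweighted mean over the expressions
        agg = (
            block.groupby(["patient_id", "dataset_id", "session_order"], sort=True)
            .agg(score_deg=("score_deg", "mean"),
                 rotation_deg=("rotation_deg", "mean"),
                 midline_slope=("midline_slope", "mean"))
            .reset_index()
        )
        agg["expression_id"] = "all"
        agg["subset_name"] = label
        agg["n_pairs"] = int(ordinals.size)
        out.append(agg[block.columns])
    return pd.concat(out, ignore_index=True)


def expression_summary(score_df: pd.DataFrame, subset_name: str | None = None) -> pd.DataFrame:
    """Summary statistics of scores per expression (and "all") across datasets.

    Rows: mean, SD (sample, n-1), variance, median, max, min. Columns:
    expressions 1..9 and "all".
    """
    df = score_df
    if subset_name is not None:
        df = df[df["subset_name"] == subset_name]
    stats = ["mean", "SD", "variance", "median", "max", "min"]
    cols = [*range(1, N_EXPRESSIONS + 1), "all"]
    table = pd.DataFrame(index=stats, columns=cols, dtype=float)
    for col in cols:
        vals = df.loc[df["expression_id"] == col, "score_deg"].to_numpy(float)
        if vals.size == 0:
            continue
        table.loc["mean", col] = np.mean(vals)
        table.loc["SD", col] = np.std(vals, ddof=1) if vals.size > 1 else 0.0
        table.loc["variance", col] = np.var(vals, ddof=1) if vals.size > 1 else 0.0
        table.loc["median", col] = np.median(vals)
        table.loc["max", col] = np.max(vals)
        table.loc["min", col] = np.min(vals)
    return table
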