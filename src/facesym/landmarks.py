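"""Landmark domain types, file I/O and pair registries.

Coordinates follow the raster convention: pixel units, ``x`` increases to
the right, ``y`` increases downward, origin at the top-left pixel centre.
A *pair registry* names which landmark indices form mirror-corresponding
left/right pairs, which indices sit on the facial midline, and which
stored subsets (e.g. the 91 most informative pairs) are available.

The shipped dense registry is a synthetic reconstruction of a symmetric
478-point layout (the original study's exact index assignment is not
published); the sparse registries use the canonical 68-point left/right
correspondence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .errors import (
    CapabilityError,
    DetectionError,
    FormatError,
    IntegrityError,
    RegistryError,
)

logger = logging.getLogger(__name__)

REGIONS = ("eye", "nose", "mouth", "other")

LANDMARK_COLUMNS = [
    "patient_id",
    "dataset_id",
    "session_order",
    "expression_id",
    "landmark_index",
    "x",
    "y",
    "image_width",
    "image_height",
]

N_EXPRESSIONS = 9


@dataclass(frozen=True)
class Landmark:
    """One indexed 2-D landmark in pixel coordinates."""

    index: int
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.index < 0:
            raise IntegrityError(f"landmark index must be >= 0, got {self.index}")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise IntegrityError(f"non-finite coordinates for landmark {self.index}")


class LandmarkSet:
    """All landmarks of one photograph (one dataset x expression cell).

    Internally stores an ``(n, 2)`` float array ordered by landmark index;
    :attr:`landmarks` exposes :class:`Landmark` views for the record API.
    """

    __slots__ = ("dataset_id", "expression_id", "image_width", "image_height", "xy")

    def __init__(
        self,
        dataset_id: str,
        expression_id: int,
        image_width: int,
        image_height: int,
        xy: np.ndarray | Sequence[Landmark],
    ) -> None:
        if not (1 <= int(expression_id) <= N_EXPRESSIONS):
            raise IntegrityError(
                f"expression_id must be 1..{N_EXPRESSIONS}, got {expression_id}"
            )
        if image_width <= 0 or image_height <= 0:
            raise IntegrityError("image dimensions must be positive")
        if not isinstance(xy, np.ndarray):
            marks = list(xy)
            seen = sorted(m.index for m in marks)
            if seen != list(range(len(marks))):
                raise IntegrityError(
                    f"landmark indices of {dataset_id}/expr{expression_id} must be "
                    f"0..{len(marks) - 1} exactly once"
                )
            arr = np.empty((len(marks), 2), dtype=float)
            for m in marks:
                arr[m.index] = (m.x, m.y)
            xy = arr
        else:
            xy = np.asarray(xy, dtype=float)
            if xy.ndim != 2 or xy.shape[1] != 2:
                raise IntegrityError("xy must have shape (n_landmarks, 2)")
        if not np.all(np.isfinite(xy)):
            raise IntegrityError(
                f"non-finite coordinates in {dataset_id}/expr{expression_id}"
            )
        self.dataset_id = str(dataset_id)
        self.expression_id = int(expression_id)
        self.image_width = int(image_width)
        self.image_height = int(image_height)
        self.xy = xy

    @property
    def n_landmarks(self) -> int:
        return self.xy.shape[0]

    @property
    def landmarks(self) -> list[Landmark]:
        return [Landmark(i, float(x), float(y)) for i, (x, y) in enumerate(self.xy)]

    def replace(self, xy: np.ndarray) -> "LandmarkSet":
        """Same metadata, new coordinates."""
        return LandmarkSet(
            self.dataset_id,
            self.expression_id,
            self.image_width,
            self.image_height,
            xy,
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, LandmarkSet)
            and self.dataset_id == other.dataset_id
            and self.expression_id == other.expression_id
            and self.image_width == other.image_width
            and self.image_height == other.image_height
            and np.array_equal(self.xy, other.xy)
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"LandmarkSet({self.dataset_id!r}, expr={self.expression_id}, "
            f"n={self.n_landmarks}, {self.image_width}x{self.image_height})"
        )


@dataclass(frozen=True)
class PairRegistry:
    """Left/right landmark pairing with region labels and midline indices.

    ``subsets`` maps a subset name (``"140"``, ``"91"``, ...) to a tuple of
    pair *ordinals* (positions in :attr:`pairs`, not landmark indices).
    """

    name: str
    n_landmarks: int
    pairs: tuple[tuple[int, int], ...]
    regions: tuple[str, ...]
    midline_indices: tuple[int, ...]
    subsets: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def validate(self) -> None:
        if len(self.regions) != len(self.pairs):
            raise RegistryError("one region label required per pair")
        bad = [r for r in self.regions if r not in REGIONS]
        if bad:
            raise RegistryError(f"unknown region labels: {sorted(set(bad))}")
        seen: dict[int, int] = {}
        offending: list[int] = []
        for ordinal, (left, right) in enumerate(self.pairs):
            for idx in (left, right):
                if idx < 0 or idx >= self.n_landmarks:
                    raise RegistryError(
                        f"pair {ordinal}: landmark index {idx} out of range"
                    )
                if idx in seen:
                    offending.append(idx)
                seen[idx] = ordinal
        if offending:
            raise RegistryError(
                f"landmark indices used more than once across pairs: {sorted(set(offending))}"
            )
        overlap = set(self.midline_indices) & set(seen)
        if overlap:
            raise RegistryError(
                f"midline indices also used in pairs: {sorted(overlap)}"
            )
        if any(i < 0 or i >= self.n_landmarks for i in self.midline_indices):
            raise RegistryError("midline index out of range")
        for sub_name, ordinals in self.subsets.items():
            bad_ords = [o for o in ordinals if o < 0 or o >= len(self.pairs)]
            if bad_ords:
                raise RegistryError(
                    f"subset {sub_name!r}: pair ordinals out of range: {bad_ords}"
                )
            if len(set(ordinals)) != len(ordinals):
                raise RegistryError(f"subset {sub_name!r}: duplicate ordinals")

    def subset_ordinals(self, subset: str | Sequence[int] | None) -> np.ndarray:
        """Resolve a subset selector to pair ordinals.

        Accepts ``None``/``"full"`` (all pairs), a stored subset name, a
        region name (restricted over all pairs), or an explicit sequence.
        """
        if subset is None or subset == "full":
            return np.arange(self.n_pairs)
        if isinstance(subset, str):
            if subset in self.subsets:
                return np.asarray(self.subsets[subset], dtype=int)
            if subset in REGIONS:
                return np.flatnonzero(np.asarray(self.regions) == subset)
            raise RegistryError(
                f"unknown subset {subset!r}; known: {sorted(self.subsets)} + regions"
            )
        ordinals = np.asarray(list(subset), dtype=int)
        if ordinals.size and (ordinals.min() < 0 or ordinals.max() >= self.n_pairs):
            raise RegistryError("subset ordinals out of range")
        return ordinals

    def region_of(self, ordinals: Sequence[int]) -> np.ndarray:
        return np.asarray(self.regions)[np.asarray(ordinals, dtype=int)]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_landmarks": self.n_landmarks,
            "midline_indices": list(self.midline_indices),
            "pairs": [
                {"left": l, "right": r, "region": g}
                for (l, r), g in zip(self.pairs, self.regions)
            ],
            "subsets": {k: list(v) for k, v in self.subsets.items()},
        }

    @classmethod
    def from_dict(cls, obj: Mapping) -> "PairRegistry":
        try:
            pairs = tuple((int(p["left"]), int(p["right"])) for p in obj["pairs"])
            regions = tuple(str(p["region"]) for p in obj["pairs"])
            return cls(
                name=str(obj["name"]),
                n_landmarks=int(obj["n_landmarks"]),
                pairs=pairs,
                regions=regions,
                midline_indices=tuple(int(i) for i in obj["midline_indices"]),
                subsets={
                    str(k): tuple(int(o) for o in v)
                    for k, v in obj.get("subsets", {}).items()
                },
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise RegistryError(f"malformed registry definition: {exc}") from exc


@dataclass
class DatasetRecord:
    """One acquisition session: nine expression photographs of one patient."""

    patient_id: str
    dataset_id: str
    session_order: int
    expressions: dict[int, LandmarkSet]

    def __post_init__(self) -> None:
        missing = sorted(set(range(1, N_EXPRESSIONS + 1)) - set(self.expressions))
        if missing:
            raise IntegrityError(
                f"dataset {self.dataset_id}: missing expressions {missing}"
            )
        if self.session_order < 1:
            raise IntegrityError("session_order must be >= 1")

    def __iter__(self) -> Iterator[LandmarkSet]:
        for expr in sorted(self.expressions):
            yield self.expressions[expr]


# ---------------------------------------------------------------------------
# File I/O (long-format CSV/JSON, one row per landmark)
# ---------------------------------------------------------------------------


def _records_from_frame(df: pd.DataFrame, source: str) -> list[DatasetRecord]:
    missing_cols = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{source}: missing columns {missing_cols}")
    dup = df.duplicated(subset=["dataset_id", "expression_id", "landmark_index"])
    if dup.any():
        row = df[dup].iloc[0]
        raise IntegrityError(
            f"{source}: duplicate landmark index {int(row.landmark_index)} in "
            f"dataset {row.dataset_id} expression {int(row.expression_id)}"
        )
    records: list[DatasetRecord] = []
    n_excluded = 0
    for dataset_id, ds in df.groupby("dataset_id", sort=True):
        expressions: dict[int, LandmarkSet] = {}
        for expr_id, cell in ds.groupby("expression_id", sort=True):
            cell = cell.sort_values("landmark_index")
            idx = cell["landmark_index"].to_numpy()
            if not np.array_equal(idx, np.arange(len(idx))):
                raise IntegrityError(
                    f"{source}: landmark indices not contiguous in dataset "
                    f"{dataset_id} expression {int(expr_id)}"
                )
            expressions[int(expr_id)] = LandmarkSet(
                dataset_id=str(dataset_id),
                expression_id=int(expr_id),
                image_width=int(cell["image_width"].iloc[0]),
                image_height=int(cell["image_height"].iloc[0]),
                xy=cell[["x", "y"]].to_numpy(dtype=float),
            )
        have = set(expressions)
        if have != set(range(1, N_EXPRESSIONS + 1)):
            n_excluded += 1
            logger.warning(
                "excluding dataset %s: expressions %s missing",
                dataset_id,
                sorted(set(range(1, N_EXPRESSIONS + 1)) - have),
            )
            continue
        records.append(
            DatasetRecord(
                patient_id=str(ds["patient_id"].iloc[0]),
                dataset_id=str(dataset_id),
                session_order=int(ds["session_order"].iloc[0]),
                expressions=expressions,
            )
        )
    if n_excluded:
        logger.info("excluded %d incomplete dataset(s)", n_excluded)
    return records


def read_landmark_file(path: str | Path, format: str | None = None) -> list[DatasetRecord]:
    """Read a long-format landmark file (CSV or JSON) into dataset records.

    Datasets missing any of the nine expressions are excluded (logged), not
    fatal; structural violations (missing columns, duplicate indices) raise.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
    elif format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        df = pd.DataFrame(payload["landmarks"] if isinstance(payload, dict) else payload)
    else:
        raise FormatError(f"unknown landmark file format {format!r}")
    return _records_from_frame(df, str(path))


def records_to_frame(records: Iterable[DatasetRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for ls in rec:
            n = ls.n_landmarks
            rows.append(
                pd.DataFrame(
                    {
                        "patient_id": rec.patient_id,
                        "dataset_id": rec.dataset_id,
                        "session_order": rec.session_order,
                        "expression_id": ls.expression_id,
                        "landmark_index": np.arange(n),
                        "x": ls.xy[:, 0],
                        "y": ls.xy[:, 1],
                        "image_width": ls.image_width,
                        "image_height": ls.image_height,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=LANDMARK_COLUMNS)
    return pd.concat(rows, ignore_index=True)[LANDMARK_COLUMNS]


def write_landmark_file(
    records: Iterable[DatasetRecord], path: str | Path, format: str | None = None
) -> None:
    """Write records as long-format CSV/JSON with round-tripping float text."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    df = records_to_frame(records)
    if format == "csv":
        df.to_csv(path, index=False)  # pandas writes shortest round-trip reprs
    elif format == "json":
        with open(path, "w") as fh:
            json.dump({"landmarks": df.to_dict(orient="records")}, fh)
    else:
        raise FormatError(f"unknown landmark file format {format!r}")


# ---------------------------------------------------------------------------
# Registries
# ---------------------------------------------------------------------------

BUILTIN_REGISTRIES = ("dense-225", "sparse-29", "sparse-21")


def load_registry(name_or_path: str | Path | PairRegistry) -> PairRegistry:
    """Load a pair registry by builtin name or JSON path."""
    if isinstance(name_or_path, PairRegistry):
        return name_or_path
    name = str(name_or_path)
    if name in BUILTIN_REGISTRIES:
        text = (
            resources.files("facesym").joinpath(f"registries/{name}.json").read_text()
        )
        return PairRegistry.from_dict(json.loads(text))
    path = Path(name_or_path)
    if not path.exists():
        raise RegistryError(
            f"no builtin registry {name!r} (known: {BUILTIN_REGISTRIES}) and no such file"
        )
    with open(path) as fh:
        return PairRegistry.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Detector adapter contract (optional; no detection library is bundled)
# ---------------------------------------------------------------------------


@runtime_checkable
class DetectorAdapter(Protocol):
    """Two-method contract every landmark detector plug-in must satisfy."""

    def detect(self, image: np.ndarray) -> np.ndarray:
        """Return an (n_landmarks, 2) pixel-coordinate array; raise on no face."""
        ...

    def version(self) -> str:
        ...


def detect_landmarks(
    image: np.ndarray,
    backend: DetectorAdapter | None,
    dataset_id: str = "image",
    expression_id: int = 1,
) -> LandmarkSet:
    """Run a detector adapter on a decoded image.

    The core package bundles no detector; pass an adapter implementing
    :class:`DetectorAdapter`, or use file-based landmark input instead.
    """
    if backend is None:
        raise CapabilityError(
            "no detector adapter configured; provide landmarks as CSV/JSON files "
            "or install and pass a detector adapter"
        )
    image = np.asarray(image)
    if image.ndim < 2:
        raise DetectionError(f"{dataset_id}: not a decodable raster image")
    xy = np.asarray(backend.detect(image), dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] == 0:
        raise DetectionError(f"{dataset_id}: adapter returned no usable landmarks")
    height, width = image.shape[:2]
    return LandmarkSet(dataset_id, expression_id, width, height, xy)
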