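"""MS-IT questionnaire scoring and exposure classification.

The Management Standards Indicator Tool (MS-IT) is a 35-item questionnaire
measuring seven psychosocial hazard dimensions: demands, control, management
support, colleague support, role, relationships and change.  Items are
answered on a 1-5 Likert scale; after reverse-coding the negatively worded
items, higher scores reflect better working conditions.

This module scores responses into dimension means and a single overall
score, derives percentile thresholds from a normative sample of overall
scores, and labels each respondent as exposed or unexposed to work-related
stress risk: workers scoring at or below the normative first-quartile
cutoff are exposed, workers scoring strictly above it are unexposed.
A finer four-level risk band (high / medium-high / medium-low / low) is
assigned from the 20th, 50th and 80th normative percentiles.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

N_ITEMS = 35

DIMENSIONS = (
    "demands",
    "control",
    "management_support",
    "colleague_support",
    "role",
    "relationships",
    "change",
)

#: Standard 35-item Management Standards layout: 1-based item index ->
#: dimension.  Demands and relationships items are negatively worded and
#: therefore reverse-coded so that higher always means better conditions.
_DEFAULT_LAYOUT: dict[str, tuple[int, ...]] = {
    "demands": (3, 6, 9, 12, 16, 18, 20, 22),
    "control": (2, 10, 15, 19, 25, 30),
    "management_support": (8, 23, 29, 33, 35),
    "colleague_support": (7, 24, 27, 31),
    "role": (1, 4, 11, 13, 17),
    "relationships": (5, 14, 21, 34),
    "change": (26, 28, 32),
}
_DEFAULT_REVERSED_DIMS = ("demands", "relationships")


class MsitValidationError(ValueError):
    """Raised when a response, item map or threshold input is malformed."""


@dataclass(frozen=True)
class MsitResponse:
    """One worker's raw questionnaire response.

    Parameters
    ----------
    worker_id:
        Identifier linking the response to the roster.
    items:
        Exactly 35 slots; each is an integer in [1, 5] or ``None`` for a
        missing answer.
    """

    worker_id: str
    items: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise MsitValidationError(
                f"worker {self.worker_id}: expected {N_ITEMS} item slots, got {len(self.items)}"
            )
        for idx, value in enumerate(self.items, start=1):
            if value is None:
                continue
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise MsitValidationError(
                    f"worker {self.worker_id}: item {idx} is not an integer ({value!r})"
                )
            if not 1 <= value <= 5:
                raise MsitValidationError(
                    f"worker {self.worker_id}: item {idx} value {value} outside [1, 5]"
                )


@dataclass(frozen=True)
class ItemMap:
    """Assignment of the 35 items to the seven dimensions plus polarity.

    ``dimensions[i]`` names the dimension of item ``i + 1``;
    ``reverse[i]`` is True when the raw value must be mapped v -> 6 - v so
    that higher means better conditions.
    """

    dimensions: tuple[str, ...]
    reverse: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.dimensions) != N_ITEMS or len(self.reverse) != N_ITEMS:
            raise MsitValidationError(
                f"item map must cover exactly {N_ITEMS} items "
                f"(got {len(self.dimensions)} dimensions, {len(self.reverse)} flags)"
            )
        unknown = set(self.dimensions) - set(DIMENSIONS)
        if unknown:
            raise MsitValidationError(f"unknown dimension names: {sorted(unknown)}")
        missing = set(DIMENSIONS) - set(self.dimensions)
        if missing:
            raise MsitValidationError(f"dimensions with no items: {sorted(missing)}")

    def items_of(self, dimension: str) -> tuple[int, ...]:
        """1-based item indices assigned to ``dimension``."""
        return tuple(i + 1 for i, d in enumerate(self.dimensions) if d == dimension)


def default_item_map() -> ItemMap:
    """The standard Management Standards 35-item layout.

    Demands (8 items) and relationships (4 items) are reverse-coded;
    control (6), management support (5), colleague support (4), role (5)
    and change (3) are scored as answered.
    """
    dims: list[str] = [""] * N_ITEMS
    for dim, indices in _DEFAULT_LAYOUT.items():
        for idx in indices:
            dims[idx - 1] = dim
    reverse = tuple(d in _DEFAULT_REVERSED_DIMS for d in dims)
    return ItemMap(dimensions=tuple(dims), reverse=reverse)


def load_item_map(path: str | Path) -> ItemMap:
    """Read an item map from a YAML file.

    Expected shape::

        items:
          1: {dimension: role, reverse: false}
          2: {dimension: control, reverse: false}
          ...

    Every index 1..35 must appear exactly once.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        entries = raw["items"]
    except (TypeError, KeyError) as exc:
        raise MsitValidationError(f"{path}: missing top-level 'items' mapping") from exc
    dims: list[Optional[str]] = [None] * N_ITEMS
    reverse: list[bool] = [False] * N_ITEMS
    for key, entry in entries.items():
        idx = int(key)
        if not 1 <= idx <= N_ITEMS:
            raise MsitValidationError(f"{path}: item index {idx} outside 1..{N_ITEMS}")
        if dims[idx - 1] is not None:
            raise MsitValidationError(f"{path}: item {idx} defined twice")
        dims[idx - 1] = str(entry["dimension"])
        reverse[idx - 1] = bool(entry.get("reverse", False))
    if any(d is None for d in dims):
        absent = [i + 1 for i, d in enumerate(dims) if d is None]
        raise MsitValidationError(f"{path}: items without a dimension: {absent}")
    return ItemMap(dimensions=tuple(dims), reverse=tuple(reverse))  # type: ignore[arg-type]


@dataclass(frozen=True)
class DimensionScores:
    """Per-dimension mean scores for one worker, on the 1-5 scale."""

    worker_id: str
    scores: Mapping[str, Optional[float]]
    valid: bool

    def as_vector(self) -> tuple[float, ...]:
        """The seven dimension scores in canonical order; requires validity."""
        if not self.valid:
            raise MsitValidationError(f"worker {self.worker_id}: scores incomplete")
        return tuple(float(self.scores[d]) for d in DIMENSIONS)  # type: ignore[arg-type]


@dataclass(frozen=True)
class ExposureThresholds:
    """Normative percentile cutoffs for exposure classification.

    ``binary_cutoff`` is the overall-score value at the configured
    percentile (default 25th, the first quartile) of the normative
    distribution; scores at or below it mark a worker as exposed.
    ``band_cutoffs`` are the 20th/50th/80th percentiles defining the four
    risk bands.
    """

    binary_cutoff: float
    band_cutoffs: tuple[float, float, float]
    normative_n: int
    binary_percentile: float = 25.0

    def __post_init__(self) -> None:
        c20, c50, c80 = self.band_cutoffs
        if not (c20 <= c50 <= c80):
            raise MsitValidationError(f"band cutoffs must be non-decreasing: {self.band_cutoffs}")


RISK_BANDS = ("high", "medium-high", "medium-low", "low")


@dataclass(frozen=True)
class ExposureLabel:
    """Exposure status and risk band for one worker."""

    worker_id: str
    status: str  # exposed | unexposed | unknown
    risk_band: str  # high | medium-high | medium-low | low | unknown


def reverse_code(value: int) -> int:
    """Map a raw Likert value v to 6 - v (an involution on {1..5})."""
    return 6 - value


def score_dimensions(
    response: MsitResponse,
    item_map: Optional[ItemMap] = None,
    *,
    min_fraction_present: float = 0.5,
) -> DimensionScores:
    """Score a response into seven dimension means.

    Reverse-coded items are mapped v -> 6 - v before averaging, so every
    dimension score is on a higher-is-better 1-5 scale.  A dimension score
    is missing when fewer than ``min_fraction_present`` of its items were
    answered; the response is ``valid`` only when all seven dimension
    scores are present.
    """
    item_map = item_map or default_item_map()
    per_dim: dict[str, list[float]] = {d: [] for d in DIMENSIONS}
    counts: dict[str, int] = {d: 0 for d in DIMENSIONS}
    for i, value in enumerate(response.items):
        dim = item_map.dimensions[i]
        counts[dim] += 1
        if value is None:
            continue
        coded = reverse_code(value) if item_map.reverse[i] else value
        per_dim[dim].append(float(coded))

    scores: dict[str, Optional[float]] = {}
    for dim in DIMENSIONS:
        present = per_dim[dim]
        if counts[dim] and len(present) / counts[dim] >= min_fraction_present:
            scores[dim] = sum(present) / len(present)
        else:
            scores[dim] = None
    valid = all(scores[d] is not None for d in DIMENSIONS)
    return DimensionScores(worker_id=response.worker_id, scores=scores, valid=valid)


def overall_score(
    scores: DimensionScores,
    *,
    method: str = "dimension_mean",
    response: Optional[MsitResponse] = None,
    item_map: Optional[ItemMap] = None,
) -> Optional[float]:
    """Combine dimension scores into a single work-related-stress score.

    The default combines the seven dimension means with equal weight.  The
    alternative ``method="item_mean"`` averages all answered items directly
    (weighting dimensions by item count); it requires the raw ``response``.
    Returns ``None`` for an invalid (incomplete) response — never a
    fabricated number.
    """
    if not scores.valid:
        return None
    if method == "dimension_mean":
        vec = scores.as_vector()
        return sum(vec) / len(vec)
    if method == "item_mean":
        if response is None:
            raise MsitValidationError("item_mean method requires the raw response")
        item_map = item_map or default_item_map()
        values = [
            float(reverse_code(v) if item_map.reverse[i] else v)
            for i, v in enumerate(response.items)
            if v is not None
        ]
        return sum(values) / len(values)
    raise MsitValidationError(f"unknown overall-score method: {method!r}")


def derive_thresholds(
    normative_scores: Sequence[float] | np.ndarray,
    *,
    binary_percentile: float = 25.0,
) -> ExposureThresholds:
    """Derive exposure thresholds from a normative overall-score sample.

    Percentiles are computed with linear interpolation between order
    statistics of the sorted sample.  The binary cutoff sits at
    ``binary_percentile`` (default the first quartile); the band cutoffs at
    the 20th, 50th and 80th percentiles delimit the four risk bands.
    """
    arr = np.asarray(normative_scores, dtype=float)
    if arr.size < 20:
        raise MsitValidationError(
            f"need at least 20 normative scores to derive thresholds, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise MsitValidationError("normative scores must all be finite")
    if not 0.0 < binary_percentile < 100.0:
        raise MsitValidationError(f"binary percentile {binary_percentile} outside (0, 100)")
    binary = float(np.percentile(arr, binary_percentile, method="linear"))
    c20, c50, c80 = (float(np.percentile(arr, q, method="linear")) for q in (20, 50, 80))
    return ExposureThresholds(
        binary_cutoff=binary,
        band_cutoffs=(c20, c50, c80),
        normative_n=int(arr.size),
        binary_percentile=float(binary_percentile),
    )


def risk_band(score: float, thresholds: ExposureThresholds) -> str:
    """Assign the four-level risk band from the 20/50/80 cutoffs."""
    c20, c50, c80 = thresholds.band_cutoffs
    if score < c20:
        return "high"
    if score < c50:
        return "medium-high"
    if score < c80:
        return "medium-low"
    return "low"


def classify_exposure(
    score: Optional[float],
    thresholds: ExposureThresholds,
    *,
    worker_id: str = "",
) -> ExposureLabel:
    """Label a worker exposed/unexposed from the overall score.

    Scores strictly above the binary cutoff are unexposed; scores at or
    below it are exposed (a tie counts toward risk).  A missing score
    yields status ``unknown``.
    """
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return ExposureLabel(worker_id=worker_id, status="unknown", risk_band="unknown")
    status = "unexposed" if score > thresholds.binary_cutoff else "exposed"
    return ExposureLabel(worker_id=worker_id, status=status, risk_band=risk_band(score, thresholds))


def score_questionnaire_frame(
    frame,
    item_map: Optional[ItemMap] = None,
    *,
    method: str = "dimension_mean",
    min_fraction_present: float = 0.5,
) -> dict[str, Optional[float]]:
    """Score a questionnaire table into {worker_id: overall score or None}.

    ``frame`` is a pandas DataFrame with columns ``worker_id`` and
    ``item_01`` .. ``item_35`` (NaN/blank = missing answer).
    """
    item_map = item_map or default_item_map()
    item_cols = [f"item_{i:02d}" for i in range(1, N_ITEMS + 1)]
    missing_cols = [c for c in item_cols if c not in frame.columns]
    if missing_cols:
        raise MsitValidationError(f"questionnaire table lacks columns: {missing_cols}")
    out: dict[str, Optional[float]] = {}
    for row in frame.itertuples(index=False):
        rec = row._asdict()
        items = []
        for col in item_cols:
            v = rec[col]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                items.append(None)
            else:
                items.append(int(v))
        resp = MsitResponse(worker_id=str(rec["worker_id"]), items=tuple(items))
        dscores = score_dimensions(resp, item_map, min_fraction_present=min_fraction_present)
        out[resp.worker_id] = overall_score(
            dscores, method=method, response=resp, item_map=item_map
        )
    return out


def read_normative_scores(path: str | Path) -> np.ndarray:
    """Read a one-column CSV of normative overall scores.

    The column may be named anything (``score`` conventionally); a header
    row is required.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = [r for r in reader if r]
    if len(rows) < 2:
        raise MsitValidationError(f"{path}: no normative scores found")
    return np.array([float(r[0]) for r in rows[1:]], dtype=float)


def read_thresholds(path: str | Path) -> ExposureThresholds:
    """Read precomputed thresholds from a YAML file.

    Expected keys: ``binary_cutoff``, ``band_cutoffs`` (list of three),
    ``normative_n``, optional ``binary_percentile``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ExposureThresholds(
        binary_cutoff=float(raw["binary_cutoff"]),
        band_cutoffs=tuple(float(v) for v in raw["band_cutoffs"]),
        normative_n=int(raw.get("normative_n", 0)),
        binary_percentile=float(raw.get("binary_percentile", 25.0)),
    )


def write_thresholds(thresholds: ExposureThresholds, path: str | Path) -> None:
    """Write thresholds to YAML, readable by :func:`read_thresholds`."""
    payload = {
        "binary_cutoff": thresholds.binary_cutoff,
        "band_cutoffs": list(thresholds.band_cutoffs),
        "normative_n": thresholds.normative_n,
        "binary_percentile": thresholds.binary_percentile,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
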