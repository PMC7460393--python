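"""Filtering, gap-filling, smoothing and Z-normalization of daily records.

A lactation enters the analysis only if its recording is complete enough
over the DIM 10-280 window (calving day = DIM 0). Three exclusion rules
are applied in fixed order, each record receiving at most one reason:

* ``TYPE_I``   — recording does not reach back to DIM <= 10 (late start);
* ``TYPE_II``  — any missing day in DIM 10..70 (the non-interpolation
  window around the expected peak);
* ``TYPE_III`` — a run of more than 10 consecutive missing days in
  DIM 70..280 (a lactation whose last record precedes DIM 270
  necessarily fails this rule).

Kept records are trimmed to DIM 10..280, interior gaps are filled by
linear interpolation, trailing gaps (at most 10 days by the TYPE_III
guarantee) by carrying the last value forward, the series is smoothed
with a centered 10-day moving average, and finally Z-normalized per
lactation so that clustering compares curve *shape* rather than
production level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DIM_GRID",
    "LactationRecord",
    "FilterReport",
    "CurveMatrix",
    "DegenerateCurveError",
    "filter_lactations",
    "interpolate_gaps",
    "moving_average",
    "znormalize",
    "build_curve_matrix",
]

#: Analysis grid: DIM 10..280 inclusive, 271 daily points.
DIM_GRID = np.arange(10, 281)

TYPE_I = "TYPE_I"
TYPE_II = "TYPE_II"
TYPE_III = "TYPE_III"


class DegenerateCurveError(ValueError):
    """A constant curve cannot be Z-normalized (zero standard deviation)."""


@dataclass
class LactationRecord:
    """One animal-lactation: a sparse map DIM -> daily milk yield (L)."""

    animal_id: str
    parity: int
    yields: dict[int, float]

    def __post_init__(self) -> None:
        if self.parity < 1:
            raise ValueError(f"parity must be >= 1, got {self.parity}")
        for dim, y in self.yields.items():
            if dim < 0:
                raise ValueError(f"{self.animal_id}: negative DIM {dim}")
            if not np.isfinite(y) or y < 0:
                raise ValueError(f"{self.animal_id}: invalid yield {y!r} at DIM {dim}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.animal_id, self.parity)


@dataclass
class FilterReport:
    """Outcome of the three-rule exclusion pass; kept + rejected partition input."""

    kept: list[LactationRecord]
    rejected: list[tuple[LactationRecord, str]]

    @property
    def counts(self) -> dict[str, int]:
        out = {"kept": len(self.kept), TYPE_I: 0, TYPE_II: 0, TYPE_III: 0}
        for _, reason in self.rejected:
            out[reason] += 1
        return out


@dataclass
class CurveMatrix:
    """Aligned gap-free curves on the fixed grid, in three parallel forms.

    ``raw`` holds interpolated curves in litres (model fitting operates on
    these), ``smoothed`` the 10-day moving average, ``znorm`` the
    per-lactation Z-scores of the smoothed curves (clustering operates on
    these).
    """

    grid: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    znorm: np.ndarray
    ids: list[str]
    parities: list[int]

    @property
    def n(self) -> int:
        return self.raw.shape[0]


def _consecutive_missing(missing: np.ndarray) -> int:
    """Longest run of True in a boolean array."""
    best = run = 0
    for m in missing:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def classify_record(record: LactationRecord) -> str | None:
    """Return the first exclusion rule a record violates, or None if kept."""
    dims = set(record.yields)
    if not any(d <= 10 for d in dims):
        return TYPE_I
    if any(d not in dims for d in range(10, 71)):
        return TYPE_II
    missing = np.array([d not in dims for d in range(70, 281)])
    if _consecutive_missing(missing) > 10:
        return TYPE_III
    return None


def filter_lactations(records: list[LactationRecord]) -> FilterReport:
    """Apply the TYPE_I/II/III exclusion rules in order.

    Kept records are returned trimmed to the DIM 10..280 window; rejected
    records are returned untouched, each with exactly one reason (the
    first rule that fires).
    """
    kept: list[LactationRecord] = []
    rejected: list[tuple[LactationRecord, str]] = []
    for rec in records:
        reason = classify_record(rec)
        if reason is None:
            trimmed = {d: y for d, y in rec.yields.items() if 10 <= d <= 280}
            kept.append(LactationRecord(rec.animal_id, rec.parity, trimmed))
        else:
            rejected.append((rec, reason))
    return FilterReport(kept=kept, rejected=rejected)


def interpolate_gaps(record: LactationRecord) -> np.ndarray:
    """Fill a filter-passing record to a gap-free series on DIM 10..280.

    Interior gaps are filled linearly between the nearest flanking
    observations; a trailing gap (guaranteed <= 10 days) carries the last
    observed value forward. Raises ``ValueError`` if the record violates
    the guarantees the filters establish.
    """
    obs = {d: y for d, y in record.yields.items() if 10 <= d <= 280}
    if any(d not in obs for d in range(10, 71)):
        raise ValueError(
            f"{record.animal_id}: record has missing days in DIM 10..70; "
            "interpolate_gaps requires a filter-passing record"
        )
    missing = np.array([d not in obs for d in range(70, 281)])
    if _consecutive_missing(missing) > 10:
        raise ValueError(
            f"{record.animal_id}: >10 consecutive missing days in DIM 70..280"
        )
    dims = np.array(sorted(obs))
    vals = np.array([obs[d] for d in dims], dtype=float)
    # np.interp carries the last value forward past the final observation
    return np.interp(DIM_GRID, dims, vals)


def moving_average(series, window: int = 10) -> np.ndarray:
    """Centered moving average, truncated at the boundaries.

    For an even window the center is placed so that a 10-day window spans
    offsets -4..+5 around each day; at the edges the mean is taken over
    the in-window points that exist. Output length equals input length.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    x = np.asarray(series, dtype=float)
    back = (window - 1) // 2
    fwd = window - 1 - back
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        lo = max(i - back, 0)
        hi = min(i + fwd, n - 1)
        out[i] = x[lo : hi + 1].mean()
    return out


def znormalize(series) -> np.ndarray:
    """Z-score a series using the population SD (divide by N).

    Raises :class:`DegenerateCurveError` for a constant series.
    """
    x = np.asarray(series, dtype=float)
    sd = float(x.std())
    if sd < 1e-12:
        raise DegenerateCurveError("constant series has zero standard deviation")
    return (x - x.mean()) / sd


def build_curve_matrix(records: list[LactationRecord], window: int = 10) -> CurveMatrix:
    """Interpolate, smooth and Z-normalize filter-passing records.

    Pipeline order is interpolate -> moving average -> Z-normalize.
    Records whose smoothed curve is constant (not Z-normalizable) are
    dropped with a warning; an all-degenerate input raises ``ValueError``.
    """
    raws, smooths, znorms, ids, parities = [], [], [], [], []
    for rec in records:
        raw = interpolate_gaps(rec)
        smooth = moving_average(raw, window=window)
        try:
            z = znormalize(smooth)
        except DegenerateCurveError:
            warnings.warn(
                f"{rec.animal_id} parity {rec.parity}: constant curve excluded "
                "from the matrix",
                stacklevel=2,
            )
            continue
        raws.append(raw)
        smooths.append(smooth)
        znorms.append(z)
        ids.append(rec.animal_id)
        parities.append(rec.parity)
    if not raws:
        raise ValueError("no usable curves: every record was degenerate or empty")
    return CurveMatrix(
        grid=DIM_GRID.copy(),
        raw=np.vstack(raws),
        smoothed=np.vstack(smooths),
        znorm=np.vstack(znorms),
        ids=ids,
        parities=parities,
    )
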