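"""Synthetic daily milking records with known curve shapes and missingness.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be validated against ground truth: herds are a
mixture of lactation-curve *archetypes* (typical peaked multiparous curve,
flat late-peaking primiparous curve, undulating curve with a mid-lactation
dip, and a flat no-peak curve), each drawn on a daily DIM grid, perturbed
by multiplicative and/or additive noise, and thinned by structured
missingness designed to trigger each of the three exclusion rules
(late-start recording, a gap inside DIM 10-70, and a long gap inside
DIM 70-280).

Defaults give production levels and shapes typical of Holstein herds
(daily yields in the 30-55 L range, peaks between DIM 10 and 150).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lc_models import eval_model
from .preprocess import LactationRecord

__all__ = [
    "ArchetypeSpec",
    "MissingnessSpec",
    "HerdSpec",
    "archetype_curve",
    "default_archetypes",
    "default_herd",
    "generate_herd",
    "write_records_csv",
    "read_records_csv",
    "write_truth_csv",
]

RECORD_COLUMNS = ["animal_id", "parity", "dim", "yield_l"]


class RecordParseError(ValueError):
    """A records CSV row failed validation; the message names the line."""


@dataclass(frozen=True)
class ArchetypeSpec:
    """One lactation-curve shape family.

    ``base_model`` selects the noiseless curve: ``"wood"`` / ``"dijkstra"``
    use those model equations with ``base_params``; ``"flat"`` is a
    constant level with a slight linear trend (``base_params = (level,
    slope_per_day)``); ``"undulating"`` multiplies a Wood (3 params) or
    Dijkstra (4 params) base curve by a Gaussian dip
    ``1 - dip_depth * exp(-(t - dip_center)**2 / (2 * dip_width**2))``.
    """

    name: str
    base_model: str
    base_params: tuple[float, ...]
    dip_center: float | None = None
    dip_depth: float = 0.0
    dip_width: float | None = None

    def __post_init__(self) -> None:
        if self.base_model not in {"wood", "dijkstra", "flat", "undulating"}:
            raise ValueError(f"unknown base model {self.base_model!r}")
        if not 0.0 <= self.dip_depth < 1.0:
            raise ValueError("dip_depth must be in [0, 1)")
        if self.base_model == "undulating":
            if self.dip_center is None or self.dip_width is None:
                raise ValueError("undulating archetype needs dip_center and dip_width")
            if self.dip_width <= 0:
                raise ValueError("dip_width must be > 0")
        if self.base_model == "flat":
            if len(self.base_params) != 2 or self.base_params[0] <= 0:
                raise ValueError("flat archetype needs (level > 0, slope)")


@dataclass(frozen=True)
class MissingnessSpec:
    """Per-lactation probabilities of the structured missingness patterns.

    ``p_late_start`` makes recording begin after DIM 10 (late-start
    exclusion trigger); ``p_early_gap`` removes a 1-5-day gap inside
    DIM 10-70; ``p_long_gap`` removes a run of ``gap_length_range`` days
    (all > 10) inside DIM 70-280; ``p_random_drop`` thins every remaining
    day independently.
    """

    p_random_drop: float = 0.0
    p_late_start: float = 0.0
    p_early_gap: float = 0.0
    p_long_gap: float = 0.0
    gap_length_range: tuple[int, int] = (11, 25)

    def __post_init__(self) -> None:
        for name in ("p_random_drop", "p_late_start", "p_early_gap", "p_long_gap"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        lo, hi = self.gap_length_range
        if lo <= 10 or hi < lo:
            raise ValueError("gap_length_range must satisfy 10 < lo <= hi")


@dataclass(frozen=True)
class HerdSpec:
    """Composition of a synthetic herd.

    ``archetype_mix`` pairs each archetype with its mixture proportion
    (proportions must sum to 1). ``parity_dist`` maps archetype name to
    probabilities over parities (1, 2, 3, 4+); archetypes absent from the
    map get a uniform parity distribution. Noise is multiplicative
    (``yield * (1 + eps)``, ``eps ~ N(0, noise_cv**2)``) and/or additive
    Gaussian with SD ``noise_sd`` litres. Recording spans DIM
    ``dim_range[0]`` to a per-lactation last day drawn uniformly from
    ``dim_range[1] +/- 30``.
    """

    n_lactations: int
    archetype_mix: tuple[tuple[ArchetypeSpec, float], ...]
    parity_dist: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    noise_cv: float = 0.02
    noise_sd: float = 0.0
    dim_range: tuple[int, int] = (0, 360)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lactations < 0:
            raise ValueError("n_lactations must be >= 0")
        props = [p for _, p in self.archetype_mix]
        if self.archetype_mix and abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"archetype proportions must sum to 1, got {sum(props)}")
        if self.noise_cv < 0 or self.noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")


def archetype_curve(spec: ArchetypeSpec, dim_grid) -> np.ndarray:
    """Noiseless daily-yield curve of an archetype on a DIM grid (0-500)."""
    t = np.asarray(dim_grid, dtype=float)
    if np.any(t < 0) or np.any(t > 500):
        raise ValueError("dim_grid must lie within 0..500")
    if spec.base_model == "flat":
        level, slope = spec.base_params
        y = level + slope * t
    elif spec.base_model == "undulating":
        base = "wood" if len(spec.base_params) == 3 else "dijkstra"
        tt = np.maximum(t, 1e-6) if base == "wood" else t
        y = eval_model(base, spec.base_params, tt)
        dip = 1.0 - spec.dip_depth * np.exp(
            -((t - spec.dip_center) ** 2) / (2.0 * spec.dip_width**2)
        )
        y = y * dip
    else:
        tt = np.maximum(t, 1e-6) if spec.base_model == "wood" else t
        y = eval_model(spec.base_model, spec.base_params, tt)
    if np.any(y <= 0):
        raise ValueError(f"archetype {spec.name!r} produces non-positive yields")
    return y


def default_archetypes() -> dict[str, ArchetypeSpec]:
    """The four stock shape archetypes.

    Wood/Dijkstra parameter magnitudes are chosen so the shapes match the
    families seen in commercial Holstein herds: a typical multiparous
    curve peaking around DIM 55 at ~47 L; a flat primiparous curve with a
    late (~DIM 140) low peak; a high-level curve with an undulating
    mid-lactation dip; and a flat no-peak curve near 36 L.
    """
    return {
        "typical": ArchetypeSpec(
            "typical", "wood", (24.6645, 0.2142, 0.0039)
        ),
        "flat_primiparous": ArchetypeSpec(
            "flat_primiparous", "dijkstra", (21.3504, 0.0152, 0.0230, 0.0006)
        ),
        "undulating": ArchetypeSpec(
            "undulating",
            "undulating",
            (44.8198, 0.0170, 0.0016),
            dip_center=150.0,
            dip_depth=0.25,
            dip_width=30.0,
        ),
        "flat_no_peak": ArchetypeSpec("flat_no_peak", "flat", (36.0, -0.01)),
    }


def default_herd(n_lactations: int = 120, seed: int = 0, **kwargs) -> HerdSpec:
    """A four-archetype herd with parity skew mirroring field observation.

    The typical and undulating archetypes skew multiparous, the flat
    archetypes skew primiparous (flat curves with high persistency are
    characteristic of first-lactation cows).
    """
    arch = default_archetypes()
    mix = (
        (arch["typical"], 0.40),
        (arch["flat_primiparous"], 0.25),
        (arch["undulating"], 0.20),
        (arch["flat_no_peak"], 0.15),
    )
    parity = {
        "typical": (0.10, 0.35, 0.30, 0.25),
        "flat_primiparous": (0.70, 0.20, 0.07, 0.03),
        "undulating": (0.20, 0.40, 0.25, 0.15),
        "flat_no_peak": (0.80, 0.15, 0.04, 0.01),
    }
    return HerdSpec(
        n_lactations=n_lactations,
        archetype_mix=mix,
        parity_dist=parity,
        seed=seed,
        **kwargs,
    )


def generate_herd(
    herd: HerdSpec, missing: MissingnessSpec | None = None
) -> tuple[list[LactationRecord], pd.DataFrame]:
    """Draw a herd of daily records plus its ground-truth table.

    Returns ``(records, truth)`` where ``truth`` has one row per
    lactation with columns ``animal_id, parity, archetype,
    missingness_tags`` (semicolon-joined tags among ``late_start``,
    ``early_gap``, ``long_gap``). Deterministic for a fixed
    ``herd.seed``.
    """
    if missing is None:
        missing = MissingnessSpec()
    rng = np.random.default_rng(herd.seed)
    specs = [s for s, _ in herd.archetype_mix]
    props = np.array([p for _, p in herd.archetype_mix])
    records: list[LactationRecord] = []
    truth_rows: list[dict] = []
    for i in range(herd.n_lactations):
        spec = specs[int(rng.choice(len(specs), p=props))]
        pdist = herd.parity_dist.get(spec.name, (0.25, 0.25, 0.25, 0.25))
        parity = int(rng.choice([1, 2, 3, 4], p=np.asarray(pdist) / np.sum(pdist)))
        last_dim = int(rng.integers(herd.dim_range[1] - 30, herd.dim_range[1] + 31))
        grid = np.arange(herd.dim_range[0], min(last_dim, 500) + 1)
        y = archetype_curve(spec, grid)
        if herd.noise_cv > 0:
            y = y * (1.0 + rng.normal(0.0, herd.noise_cv, size=len(y)))
        if herd.noise_sd > 0:
            y = y + rng.normal(0.0, herd.noise_sd, size=len(y))
        y = np.maximum(y, 0.01)

        keep = np.ones(len(grid), dtype=bool)
        tags: list[str] = []
        if rng.random() < missing.p_late_start:
            start = int(rng.integers(11, 31))
            keep &= grid >= start
            tags.append("late_start")
        if rng.random() < missing.p_early_gap:
            gap_start = int(rng.integers(10, 66))
            gap_len = int(rng.integers(1, 6))
            keep &= ~((grid >= gap_start) & (grid < gap_start + gap_len))
            tags.append("early_gap")
        if rng.random() < missing.p_long_gap:
            lo, hi = missing.gap_length_range
            gap_len = int(rng.integers(lo, hi + 1))
            gap_start = int(rng.integers(70, 281 - gap_len))
            keep &= ~((grid >= gap_start) & (grid < gap_start + gap_len))
            tags.append("long_gap")
        if missing.p_random_drop > 0:
            keep &= rng.random(len(grid)) >= missing.p_random_drop

        animal_id = f"cow{i:04d}"
        yields = {int(d): float(v) for d, v in zip(grid[keep], y[keep])}
        records.append(LactationRecord(animal_id, parity, yields))
        truth_rows.append(
            {
                "animal_id": animal_id,
                "parity": parity,
                "archetype": spec.name,
                "missingness_tags": ";".join(tags),
            }
        )
    truth = pd.DataFrame(truth_rows, columns=["animal_id", "parity", "archetype",
                                              "missingness_tags"])
    return records, truth


def write_records_csv(records: list[LactationRecord], path) -> None:
    """Write records in long format (animal_id, parity, dim, yield_l)."""
    rows = [
        (rec.animal_id, rec.parity, dim, rec.yields[dim])
        for rec in records
        for dim in sorted(rec.yields)
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_records_csv(path) -> list[LactationRecord]:
    """Read long-format records; raises :class:`RecordParseError` with the
    1-based line number of the first malformed row."""
    df = pd.read_csv(path, dtype=str)
    missing_cols = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing_cols:
        raise RecordParseError(f"missing columns: {missing_cols}")
    out: dict[tuple[str, int], dict[int, float]] = {}
    order: list[tuple[str, int]] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        try:
            parity = int(row.parity)
            dim = int(row.dim)
            yield_l = float(row.yield_l)
        except (TypeError, ValueError) as exc:
            raise RecordParseError(f"line {line}: malformed row ({exc})") from None
        if parity < 1:
            raise RecordParseError(f"line {line}: parity must be >= 1, got {parity}")
        if dim < 0:
            raise RecordParseError(f"line {line}: negative DIM {dim}")
        if not np.isfinite(yield_l) or yield_l < 0:
            raise RecordParseError(f"line {line}: invalid yield {row.yield_l!r}")
        key = (str(row.animal_id), parity)
        if key not in out:
            out[key] = {}
            order.append(key)
        if dim in out[key]:
            raise RecordParseError(f"line {line}: duplicate DIM {dim} for {key}")
        out[key][dim] = yield_l
    return [LactationRecord(aid, parity, out[(aid, parity)]) for aid, parity in order]


def write_truth_csv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)
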