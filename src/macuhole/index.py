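"""Area arithmetic, cohort min-max normalization, and the bounded integrity index.

The index scores one eye *relative to its cohort*: photoreceptor-remnant area
(PRA) and luminal area (LA) are min-max normalized against the cohort range,
and the score is ``norm_pra / (norm_la + 1)``, which is bounded in [0, 1]
because both normalized inputs live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AreaSet",
    "NormalizationModel",
    "NormalizedAreas",
    "PiinScore",
    "DegenerateCohortError",
    "InconsistentSegmentationError",
    "OutOfCohortError",
    "compute_pra",
    "fit_normalization",
    "normalize",
    "compute_piin",
    "score_cohort",
    "score_table",
    "compute_deltas",
    "add_delta_columns",
    "classify_ivts",
]

_AREA_TOL = 1e-12


class DegenerateCohortError(ValueError):
    """Raised when a cohort has zero range in PRA or LA (normalization undefined)."""


class InconsistentSegmentationError(ValueError):
    """Raised when the luminal area exceeds the total hole area."""


class OutOfCohortError(ValueError):
    """Raised when an unclamped value falls outside the fitted cohort range."""


@dataclass(frozen=True)
class AreaSet:
    """TA / LA / PRA triple for one eye, in mm².

    The conservation identity ``photoreceptor_area == total_area - luminal_area``
    is enforced exactly at construction.
    """

    total_area: float
    luminal_area: float
    photoreceptor_area: float

    def __post_init__(self) -> None:
        if not self.total_area > 0:
            raise ValueError("non-zero total area required")
        if self.luminal_area < 0 or self.photoreceptor_area < 0:
            raise InconsistentSegmentationError(
                "inconsistent segmentation: negative area "
                f"(LA={self.luminal_area}, PRA={self.photoreceptor_area})"
            )
        residual = self.total_area - self.luminal_area - self.photoreceptor_area
        if abs(residual) > _AREA_TOL * max(1.0, self.total_area):
            raise ValueError(
                f"area identity violated: TA - LA - PRA = {residual!r}"
            )

    @classmethod
    def from_total_and_lumen(cls, total_area: float, luminal_area: float) -> "AreaSet":
        return compute_pra(total_area, luminal_area)


def compute_pra(total_area: float, luminal_area: float) -> AreaSet:
    """Derive the photoreceptor-remnant area as TA − LA.

    Parameters
    ----------
    total_area : float
        Hole area including the bright edge ring, mm². Must be > 0.
    luminal_area : float
        Dark central area, mm². Must satisfy 0 ≤ LA ≤ TA.
    """
    total_area = float(total_area)
    luminal_area = float(luminal_area)
    if not total_area > 0:
        raise ValueError(f"non-zero total area required (got {total_area})")
    if luminal_area < 0 or luminal_area > total_area:
        raise InconsistentSegmentationError(
            f"inconsistent segmentation: LA={luminal_area} outside [0, TA={total_area}]"
        )
    return AreaSet(
        total_area=total_area,
        luminal_area=luminal_area,
        photoreceptor_area=total_area - luminal_area,
    )


@dataclass(frozen=True)
class NormalizationModel:
    """Cohort min/max bounds that make the index computable."""

    pra_min: float
    pra_max: float
    la_min: float
    la_max: float
    cohort_size: int

    def __post_init__(self) -> None:
        if self.cohort_size < 2:
            raise DegenerateCohortError(
                f"degenerate cohort: need at least 2 eyes, got {self.cohort_size}"
            )
        if not (self.pra_max > self.pra_min and self.la_max > self.la_min):
            raise DegenerateCohortError(
                "degenerate cohort: zero range in PRA or LA"
            )


@dataclass(frozen=True)
class NormalizedAreas:
    norm_pra: float
    norm_la: float

    def __post_init__(self) -> None:
        for name, v in (("norm_pra", self.norm_pra), ("norm_la", self.norm_la)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class PiinScore:
    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"index value {self.value} outside [0, 1]")


def fit_normalization(cohort_areas: Sequence[AreaSet]) -> NormalizationModel:
    """Fit cohort min/max bounds for PRA and LA.

    Raises :class:`DegenerateCohortError` for cohorts of fewer than two eyes or
    with all-identical PRA (or LA) values: the normalization would divide by a
    zero range, and silently emitting 0/0 would corrupt downstream statistics.
    """
    areas = list(cohort_areas)
    if len(areas) < 2:
        raise DegenerateCohortError(
            f"degenerate cohort: need at least 2 eyes, got {len(areas)}"
        )
    pra = np.asarray([a.photoreceptor_area for a in areas], dtype=float)
    la = np.asarray([a.luminal_area for a in areas], dtype=float)
    if pra.max() == pra.min() or la.max() == la.min():
        raise DegenerateCohortError("degenerate cohort: zero range in PRA or LA")
    return NormalizationModel(
        pra_min=float(pra.min()),
        pra_max=float(pra.max()),
        la_min=float(la.min()),
        la_max=float(la.max()),
        cohort_size=len(areas),
    )


def _minmax(value: float, lo: float, hi: float, clamp: bool, label: str) -> float:
    if not clamp and not (lo <= value <= hi):
        raise OutOfCohortError(
            f"out-of-cohort value: {label}={value} outside fitted [{lo}, {hi}] "
            "(pass clamp=True to clip prospective eyes into [0, 1])"
        )
    x = (value - lo) / (hi - lo)
    return float(min(1.0, max(0.0, x)))


def normalize(
    model: NormalizationModel, area_set: AreaSet, clamp: bool = False
) -> NormalizedAreas:
    """Min-max normalize one eye's PRA and LA against the cohort bounds.

    The cohort minimum maps to 0 and the maximum to 1. With ``clamp`` enabled,
    out-of-range values from eyes outside the fitted cohort are clipped into
    [0, 1]; with it disabled such values raise :class:`OutOfCohortError`.
    """
    return NormalizedAreas(
        norm_pra=_minmax(
            area_set.photoreceptor_area, model.pra_min, model.pra_max, clamp, "PRA"
        ),
        norm_la=_minmax(
            area_set.luminal_area, model.la_min, model.la_max, clamp, "LA"
        ),
    )


def compute_piin(normalized: NormalizedAreas) -> PiinScore:
    """Bounded integrity index ``norm_pra / (norm_la + 1)``.

    The denominator is ≥ 1 by construction, so the score is always defined and
    lies in [0, 1]; it equals ``norm_pra`` exactly when ``norm_la`` is 0.
    Values near 0 mean poor photoreceptor survival at the hole edge, values
    near 1 mean a maximal surviving annulus.
    """
    return PiinScore(value=normalized.norm_pra / (normalized.norm_la + 1.0))


def score_cohort(
    eyes: Iterable[tuple[str, AreaSet]]
) -> tuple[list[tuple[str, PiinScore]], NormalizationModel]:
    """Fit normalization on the full cohort and score every eye.

    Deterministic; output order matches input order. Raises
    :class:`DegenerateCohortError` for cohorts the normalization cannot handle.
    """
    items = list(eyes)
    model = fit_normalization([a for _, a in items])
    scored = [
        (eye_id, compute_piin(normalize(model, a, clamp=False)))
        for eye_id, a in items
    ]
    return scored, model


# --- tabular plumbing -------------------------------------------------------

_MISSING = float("nan")


def compute_deltas(eye: Mapping[str, float]) -> dict[str, float]:
    """Absolute follow-up-minus-baseline changes for one eye.

    ``|Δ| = |value(T1) − value(T0)|`` for BCVA (logMAR) and the EZ/ELM defect
    lengths (µm). A missing T0 or T1 yields a missing delta — missingness is
    propagated, never imputed.
    """
    out: dict[str, float] = {}
    for t0_col, t1_col, delta_col in (
        ("bcva_t0_logmar", "bcva_t1_logmar", "delta_bcva_logmar"),
        ("ez_t0_um", "ez_t1_um", "delta_ez_um"),
        ("elm_t0_um", "elm_t1_um", "delta_elm_um"),
    ):
        t0 = eye.get(t0_col, _MISSING)
        t1 = eye.get(t1_col, _MISSING)
        if t0 is None or t1 is None or np.isnan(t0) or np.isnan(t1):
            out[delta_col] = _MISSING
        else:
            out[delta_col] = abs(float(t1) - float(t0))
    return out


def add_delta_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`compute_deltas` over a cohort table."""
    out = table.copy()
    for t0_col, t1_col, delta_col in (
        ("bcva_t0_logmar", "bcva_t1_logmar", "delta_bcva_logmar"),
        ("ez_t0_um", "ez_t1_um", "delta_ez_um"),
        ("elm_t0_um", "elm_t1_um", "delta_elm_um"),
    ):
        if t0_col in out.columns and t1_col in out.columns:
            out[delta_col] = (out[t1_col] - out[t0_col]).abs()
    return out


def classify_ivts(minimum_diameter: float) -> str:
    """Size class from the minimum aperture diameter (µm).

    ≤ 250 µm → ``small``; 250–400 µm → ``medium``; > 400 µm → ``large``.
    Boundary values are assigned to the smaller class.
    """
    d = float(minimum_diameter)
    if not d > 0:
        raise ValueError(f"minimum diameter must be positive (got {d})")
    if d <= 250:
        return "small"
    if d <= 400:
        return "medium"
    return "large"


def score_table(table: pd.DataFrame, clamp: bool = False) -> tuple[pd.DataFrame, NormalizationModel]:
    """Score a cohort table in place of the per-eye API.

    Requires ``ta_mm2`` and ``la_mm2`` columns; adds ``pra_mm2``, ``norm_pra``,
    ``norm_la``, ``piin`` and, when ``minimum_diameter_um`` is present,
    ``ivts_class``; delta columns are added when the T0/T1 pairs exist.
    """
    missing = [c for c in ("ta_mm2", "la_mm2") if c not in table.columns]
    if missing:
        raise KeyError(f"cohort table missing required columns: {missing}")
    areas = [
        compute_pra(ta, la) for ta, la in zip(table["ta_mm2"], table["la_mm2"])
    ]
    model = fit_normalization(areas)
    out = add_delta_columns(table)
    normed = [normalize(model, a, clamp=clamp) for a in areas]
    out["pra_mm2"] = [a.photoreceptor_area for a in areas]
    out["norm_pra"] = [nrm.norm_pra for nrm in normed]
    out["norm_la"] = [nrm.norm_la for nrm in normed]
    out["piin"] = [compute_piin(nrm).value for nrm in normed]
    if "minimum_diameter_um" in out.columns:
        out["ivts_class"] = [classify_ivts(d) for d in out["minimum_diameter_um"]]
    return out, model
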