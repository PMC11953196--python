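"""Phantom en-face rasters: a dark elliptical lumen inside a bright annular
ring on a mid-gray background, with optional boundary bumpiness and speckle,
plus analytic / quadrature ground-truth areas."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd

from ..index import AreaSet, compute_pra
from ..segmentation import EnFaceImage

__all__ = ["PhantomSpec", "generate_phantom", "render_cohort_phantoms", "ring_width_for_areas"]

_QUADRATURE_VERTICES = 4096


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity, and noise parameters for one phantom eye.

    All lengths in mm; the lumen is an ellipse with the given semi-axes, the
    bright ring extends ``ring_width`` beyond the lumen boundary along each
    polar ray, optionally perturbed by ``bump_amplitude·cos(bump_lobes·θ)``.
    """

    lumen_semi_axis_x: float = 0.20
    lumen_semi_axis_y: float = 0.20
    center_offset_x: float = 0.0
    center_offset_y: float = 0.0
    ring_width: float = 0.10
    bump_amplitude: float = 0.0
    bump_lobes: int = 0
    bump_phase: float = 0.0
    background_intensity: float = 0.45
    ring_intensity: float = 0.90
    lumen_intensity: float = 0.08
    speckle_sigma: float = 0.0
    pixel_size_um: float = 10.0
    field_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lumen_semi_axis_x <= 0 or self.lumen_semi_axis_y <= 0:
            raise ValueError("lumen semi-axes must be positive")
        if self.ring_width <= 0:
            raise ValueError("ring width must be positive")
        if self.bump_amplitude < 0 or self.bump_lobes < 0:
            raise ValueError("bump parameters must be non-negative")
        if self.bump_amplitude >= self.ring_width:
            raise ValueError("bump amplitude must stay below the ring width")
        extent = (
            max(self.lumen_semi_axis_x, self.lumen_semi_axis_y)
            + self.ring_width
            + self.bump_amplitude
            + max(abs(self.center_offset_x), abs(self.center_offset_y))
        )
        if extent > 0.8 * self.field_mm / 2.0:
            raise ValueError(
                f"phantom extent {extent:.3f} mm exceeds the central 80% of the "
                f"{self.field_mm} mm field"
            )

    def _lumen_radius(self, theta: np.ndarray) -> np.ndarray:
        a, b = self.lumen_semi_axis_x, self.lumen_semi_axis_y
        return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)

    def _outer_radius(self, theta: np.ndarray) -> np.ndarray:
        r = self._lumen_radius(theta) + self.ring_width
        if self.bump_amplitude > 0 and self.bump_lobes > 0:
            r = r + self.bump_amplitude * np.cos(self.bump_lobes * theta + self.bump_phase)
        return r

    def ground_truth(self, n_vertices: int = _QUADRATURE_VERTICES) -> AreaSet:
        """Exact areas: analytic lumen ellipse, polar quadrature for the outer
        boundary (`A = ½∮ r(θ)² dθ`, trapezoidal on a periodic grid)."""
        la = math.pi * self.lumen_semi_axis_x * self.lumen_semi_axis_y
        theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
        r = self._outer_radius(theta)
        ta = 0.5 * float(np.mean(r * r)) * 2.0 * math.pi
        return compute_pra(ta, la)


def generate_phantom(spec: PhantomSpec) -> tuple[EnFaceImage, AreaSet]:
    """Render the phantom raster and return it with its ground-truth areas.

    Deterministic per seed: the same spec always yields a bit-identical raster.
    """
    px_mm = spec.pixel_size_um / 1000.0
    n = int(round(spec.field_mm / px_mm))
    coords = (np.arange(n) + 0.5) * px_mm - spec.field_mm / 2.0
    xx, yy = np.meshgrid(coords, coords)
    dx = xx - spec.center_offset_x
    dy = yy - spec.center_offset_y
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    r_lumen = spec._lumen_radius(theta)
    r_outer = spec._outer_radius(theta)

    img = np.full((n, n), spec.background_intensity, dtype=float)
    img[rho <= r_outer] = spec.ring_intensity
    img[rho <= r_lumen] = spec.lumen_intensity

    if spec.speckle_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img * (1.0 + spec.speckle_sigma * rng.standard_normal(img.shape))
        img = np.clip(img, 0.0, 1.0)

    image = EnFaceImage(
        pixels=img, field_width_mm=spec.field_mm, field_height_mm=spec.field_mm
    )
    return image, spec.ground_truth()


def ring_width_for_areas(
    spec: PhantomSpec, luminal_area: float, total_area: float
) -> float:
    """Ring width making the phantom's outer-boundary area equal ``total_area``
    given lumen semi-axes already matching ``luminal_area``.

    With a smooth lumen boundary ``r(θ)``, the outer area is
    ``LA + w·∮r dθ/1 + π·w²`` in polar form, so ``w`` solves a quadratic.
    """
    theta = np.linspace(0.0, 2.0 * math.pi, _QUADRATURE_VERTICES, endpoint=False)
    r = spec._lumen_radius(theta)
    c1 = float(np.mean(r)) * 2.0 * math.pi  # ∮ r dθ
    la = 0.5 * float(np.mean(r * r)) * 2.0 * math.pi
    # π w² + c1 w + (la - TA) = 0
    disc = c1 * c1 - 4.0 * math.pi * (la - total_area)
    if disc <= 0:
        raise ValueError("no ring width reaches the requested total area")
    return (-c1 + math.sqrt(disc)) / (2.0 * math.pi)


def render_cohort_phantoms(
    cohort: pd.DataFrame,
    pixel_size_um: float = 10.0,
    seed: int = 0,
    speckle_sigma: float = 0.10,
    field_mm: float = 3.0,
    min_ring_width: float = 0.02,
    max_ring_width: float = 0.60,
) -> Iterator[tuple[str, EnFaceImage, AreaSet]]:
    """Render one phantom per cohort row with ground truth matching the table.

    For each eye an ellipse eccentricity is sampled, the semi-axes are solved
    from ``la_mm2`` and the ring width from ``ta_mm2`` (within 1% by
    construction). Eyes whose areas are infeasible under the geometry model
    are warned about and skipped.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9E3779B9]))
    for _, row in cohort.iterrows():
        eye_id = str(row["eye_id"])
        la = float(row["la_mm2"])
        ta = float(row["ta_mm2"])
        axis_ratio = float(rng.uniform(0.75, 0.95))
        eye_seed = int(rng.integers(0, 2**31 - 1))
        a = math.sqrt(la / (math.pi * axis_ratio))
        b = axis_ratio * a
        try:
            base = PhantomSpec(
                lumen_semi_axis_x=a,
                lumen_semi_axis_y=b,
                ring_width=0.05,  # placeholder, replaced below
                speckle_sigma=speckle_sigma,
                pixel_size_um=pixel_size_um,
                field_mm=field_mm,
                seed=eye_seed,
            )
            width = ring_width_for_areas(base, la, ta)
            if not (min_ring_width <= width <= max_ring_width):
                raise ValueError(
                    f"ring width {width:.3f} mm outside "
                    f"[{min_ring_width}, {max_ring_width}]"
                )
            spec = replace(base, ring_width=width)
        except ValueError as exc:
            warnings.warn(
                f"skipping eye {eye_id}: infeasible phantom geometry ({exc})",
                stacklevel=2,
            )
            continue
        image, truth = generate_phantom(spec)
        yield eye_id, image, truth
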