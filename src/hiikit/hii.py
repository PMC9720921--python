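"""The hematoma irregularity index (HII) and the expansion rule.

The index compares two equivalent-sphere radii computed from a hematoma's
surface area S (mm²) and volume V (mm³):

    R1 = sqrt(S / pi) / 2        radius of the sphere with surface area S
    R2 = (3 V / 4 pi)^(1/3)      radius of the sphere with volume V
    HII = 100 * R1 / R2

By the isoperimetric inequality (S³ >= 36 pi V² for any solid, with equality
only for the ball), HII >= 100, with 100 attained exactly by a sphere; the
more irregular (or disconnected) the shape, the larger the index. HII is
dimensionless and scale-invariant.

Hematoma expansion between baseline and follow-up CT uses the conventional
rule: growth of more than 33% relative or more than 12.5 mL absolute volume
increase — both inequalities strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .geometry import (
    DEFAULT_ANTIALIAS_SIGMA_VOX,
    extract_surface,
    mesh_surface_area,
    mesh_volume,
    smooth_mesh,
    voxel_volume,
)
from .volume_io import BinaryMask

__all__ = [
    "ShapeMetrics",
    "ExpansionRule",
    "compute_shape_metrics",
    "compute_hii_for_mask",
    "classify_expansion",
]


@dataclass(frozen=True)
class ShapeMetrics:
    surface_area_mm2: float
    volume_mm3: float
    volume_mL: float
    r1_mm: float
    r2_mm: float
    hii: float

    def as_dict(self) -> dict:
        return {
            "S_mm2": self.surface_area_mm2,
            "V_mm3": self.volume_mm3,
            "V_mL": self.volume_mL,
            "R1_mm": self.r1_mm,
            "R2_mm": self.r2_mm,
            "HII": self.hii,
        }


@dataclass(frozen=True)
class ExpansionRule:
    """Strict thresholds defining hematoma expansion."""

    relative_threshold: float = 0.33
    absolute_threshold_mL: float = 12.5

    def __post_init__(self) -> None:
        if self.relative_threshold <= 0 or self.absolute_threshold_mL <= 0:
            raise ValueError("expansion thresholds must be positive")


def compute_shape_metrics(surface_area: float, volume: float) -> ShapeMetrics:
    """Equivalent radii and HII from a surface area (mm²) and volume (mm³)."""
    if surface_area <= 0 or volume <= 0:
        raise ValueError(
            f"surface area and volume must be positive, got S={surface_area}, V={volume}"
        )
    r1 = math.sqrt(surface_area / math.pi) / 2.0
    r2 = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    return ShapeMetrics(
        surface_area_mm2=float(surface_area),
        volume_mm3=float(volume),
        volume_mL=float(volume) / 1000.0,
        r1_mm=r1,
        r2_mm=r2,
        hii=100.0 * r1 / r2,
    )


def compute_hii_for_mask(
    mask: BinaryMask,
    antialias_sigma_vox: float = DEFAULT_ANTIALIAS_SIGMA_VOX,
    taubin_iterations: int = 0,
    taubin_passband: float = 0.1,
) -> ShapeMetrics:
    """Full measurement pipeline: mask → surface → S, V → ShapeMetrics.

    Taubin mesh smoothing is off by default (``taubin_iterations=0``); both
    it and the field anti-aliasing are explicit knobs because any smoothing
    choice moves S and therefore HII, and should be recorded alongside the
    result.
    """
    mesh = extract_surface(mask, antialias_sigma_vox=antialias_sigma_vox)
    if taubin_iterations > 0:
        mesh = smooth_mesh(mesh, iterations=taubin_iterations, passband=taubin_passband)
    return compute_shape_metrics(mesh_surface_area(mesh), mesh_volume(mesh))


def classify_expansion(
    baseline_mL: float,
    followup_mL: float,
    rule: ExpansionRule | None = None,
) -> str:
    """'expansion' iff growth > 33% relative OR > 12.5 mL absolute (strict)."""
    rule = rule or ExpansionRule()
    if baseline_mL <= 0:
        raise ValueError(f"baseline volume must be positive, got {baseline_mL}")
    if followup_mL < 0:
        raise ValueError(f"follow-up volume must be non-negative, got {followup_mL}")
    delta = followup_mL - baseline_mL

    def strictly_greater(x: float, y: float) -> bool:
        # strict ">" robust to float representation: a value sitting exactly
        # on the threshold (up to rounding error) does not count as growth
        return x > y and not math.isclose(x, y, rel_tol=1e-9, abs_tol=1e-12)

    if strictly_greater(delta / baseline_mL, rule.relative_threshold) or strictly_greater(
        delta, rule.absolute_threshold_mL
    ):
        return "expansion"
    return "no_expansion"


def voxel_volume_mL(mask: BinaryMask) -> float:
    """Voxel-count volume in millilitres, for the expansion rule."""
    return voxel_volume(mask) / 1000.0
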