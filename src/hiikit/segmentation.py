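"""HU-window threshold segmentation of the hematoma.

Acute intraparenchymal blood is hyperdense on non-contrast CT, roughly
40-100 HU against ~0-40 HU brain parenchyma, so a closed [hu_low, hu_high]
window followed by connected-component selection is a scriptable stand-in for
the slice-by-slice semi-automatic labelling a rater would perform. The manual
clean-up step is represented by the seed/largest component rule plus an
optional exclusion mask (e.g. for intraventricular blood), not by a GUI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import AlignmentError, BinaryMask, CTVolume

__all__ = [
    "SegmentationConfig",
    "EmptySegmentationError",
    "segment_hematoma",
    "apply_exclusion_mask",
]

# 26-connectivity: the permissive 3D standard for a fully automatic rule
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class EmptySegmentationError(ValueError):
    """No voxel (or no acceptable component) inside the HU window.

    Carries a summary of the volume's HU histogram so a caller can see at a
    glance why the window missed (e.g. a wrong rescale intercept).
    """

    def __init__(self, message: str, hu_summary: dict | None = None):
        super().__init__(message)
        self.hu_summary = hu_summary or {}


def _hu_summary(voxels: np.ndarray) -> dict:
    qs = np.percentile(voxels, [0, 5, 25, 50, 75, 95, 100])
    return {
        "min": float(qs[0]),
        "p5": float(qs[1]),
        "p25": float(qs[2]),
        "median": float(qs[3]),
        "p75": float(qs[4]),
        "p95": float(qs[5]),
        "max": float(qs[6]),
    }


@dataclass
class SegmentationConfig:
    """Threshold window and component-selection rule.

    Endpoints are inclusive: a voxel at exactly ``hu_low`` or ``hu_high`` is
    inside the window.
    """

    hu_low: float = 40.0
    hu_high: float = 100.0
    component_rule: str = "largest"  # "largest" | "seeded"
    seed_point: tuple[int, int, int] | None = None
    min_component_voxels: int = 1

    def __post_init__(self) -> None:
        if not self.hu_low < self.hu_high:
            raise ValueError(f"hu_low must be < hu_high, got [{self.hu_low}, {self.hu_high}]")
        if self.component_rule not in ("largest", "seeded"):
            raise ValueError(f"unknown component_rule {self.component_rule!r}")
        if self.component_rule == "seeded" and self.seed_point is None:
            raise ValueError("seeded component rule requires a seed_point")
        if self.min_component_voxels < 1:
            raise ValueError("min_component_voxels must be >= 1")


def segment_hematoma(volume: CTVolume, config: SegmentationConfig | None = None) -> BinaryMask:
    """Threshold a CT volume to the HU window and keep one 26-connected component.

    The component is either the largest by voxel count or the one containing
    ``seed_point``; components smaller than ``min_component_voxels`` are
    discarded before selection.
    """
    config = config or SegmentationConfig()
    hu = np.asarray(volume.voxels)
    window = (hu >= config.hu_low) & (hu <= config.hu_high)
    if not window.any():
        raise EmptySegmentationError(
            f"no voxel in HU window [{config.hu_low}, {config.hu_high}]",
            hu_summary=_hu_summary(hu),
        )

    labels, n = ndimage.label(window, structure=_STRUCT_26)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    counts[counts < config.min_component_voxels] = 0
    if counts.max() == 0:
        raise EmptySegmentationError(
            f"all in-window components below min_component_voxels={config.min_component_voxels}",
            hu_summary=_hu_summary(hu),
        )

    if config.component_rule == "largest":
        chosen = int(np.argmax(counts))
    else:
        seed = tuple(int(i) for i in config.seed_point)
        chosen = int(labels[seed])
        if chosen == 0 or counts[chosen] == 0:
            raise EmptySegmentationError(
                f"seed point {seed} is not inside any acceptable in-window component",
                hu_summary=_hu_summary(hu),
            )

    return BinaryMask(
        voxels=(labels == chosen).astype(np.uint8),
        spacing_mm=volume.spacing_mm,
        origin_mm=volume.origin_mm,
    )


def apply_exclusion_mask(mask: BinaryMask, exclusion: BinaryMask) -> BinaryMask:
    """Remove excluded voxels (e.g. intraventricular blood): mask AND NOT exclusion."""
    if mask.shape != exclusion.shape:
        raise AlignmentError(
            f"mask shape {mask.shape} does not match exclusion shape {exclusion.shape}"
        )
    if not np.allclose(mask.spacing_mm, exclusion.spacing_mm):
        raise AlignmentError(
            f"mask spacing {mask.spacing_mm} does not match exclusion spacing {exclusion.spacing_mm}"
        )
    out = mask.voxels & ~exclusion.voxels.astype(bool)
    return BinaryMask(voxels=out.astype(np.uint8), spacing_mm=mask.spacing_mm, origin_mm=mask.origin_mm)
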