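"""Synthetic CT phantoms with analytic or brute-force ground truth.

Each generator rasterizes a solid on a regular grid (a voxel is foreground
iff its *center* lies inside the solid), embeds it as a hyperdense blob —
default 70 HU foreground on 30 HU background, straddling the 40 HU
segmentation threshold the way acute clot and brain parenchyma do — and
returns the volume together with a :class:`PhantomTruth` carrying the known
surface area, volume and HII. Spheres and spheroids have closed-form truth;
triaxial ellipsoids use Legendre's elliptic-integral form; lobulated unions
of spheres fall back to a brute-force oracle (the same rasterization and
measurement at a finer spacing).

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .geometry import extract_surface, mesh_surface_area, mesh_volume
from .hii import compute_shape_metrics
from .volume_io import BinaryMask, CTVolume

__all__ = [
    "PhantomTruth",
    "ResolutionError",
    "make_sphere_phantom",
    "make_ellipsoid_phantom",
    "make_lobulated_phantom",
    "resample_to_slices",
    "ellipsoid_surface_area",
    "phantom_mask",
]

DEFAULT_HU_FOREGROUND = 70.0
DEFAULT_HU_BACKGROUND = 30.0


class ResolutionError(ValueError):
    """The requested object is too small for the requested voxel spacing."""


@dataclass
class PhantomTruth:
    description: str
    analytic_S_mm2: float | None = None
    analytic_V_mm3: float | None = None
    analytic_hii: float | None = None
    oracle_note: str = "closed form"

    def __post_init__(self) -> None:
        if self.analytic_S_mm2 is not None and self.analytic_V_mm3 is not None:
            expected = compute_shape_metrics(self.analytic_S_mm2, self.analytic_V_mm3).hii
            if self.analytic_hii is None:
                self.analytic_hii = expected
            elif abs(self.analytic_hii - expected) > 1e-9 * max(1.0, expected):
                raise ValueError("analytic_hii inconsistent with analytic S, V")

    def as_dict(self) -> dict:
        return {
            "description": self.description,
            "analytic_S_mm2": self.analytic_S_mm2,
            "analytic_V_mm3": self.analytic_V_mm3,
            "analytic_hii": self.analytic_hii,
            "oracle_note": self.oracle_note,
        }


def _as_spacing(spacing_mm) -> tuple[float, float, float]:
    if np.isscalar(spacing_mm):
        spacing_mm = (spacing_mm,) * 3
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be a positive scalar or 3-tuple, got {spacing_mm!r}")
    return spacing


def _grid(extent_mm: np.ndarray, spacing: tuple[float, float, float]):
    """Centered voxel-center coordinates covering ±extent plus a 3-voxel margin."""
    axes = []
    for e, s in zip(extent_mm, spacing):
        n = int(np.ceil(2 * (e + 3 * s) / s))
        axes.append((np.arange(n) - (n - 1) / 2) * s)
    return np.meshgrid(*axes, indexing="ij")


def _embed(
    inside: np.ndarray,
    spacing: tuple[float, float, float],
    hu_foreground: float,
    hu_background: float,
    noise_sd: float,
    seed,
) -> CTVolume:
    hu = np.where(inside, hu_foreground, hu_background).astype(np.float64)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        hu += rng.normal(0.0, noise_sd, size=hu.shape)
    return CTVolume(voxels=hu, spacing_mm=spacing)


def _check_feature(size_mm: float, spacing: tuple[float, float, float], what: str) -> None:
    if size_mm < 4 * max(spacing):
        raise ResolutionError(
            f"{what} {size_mm} mm is below 4x the coarsest spacing component {max(spacing)} mm"
        )


def make_sphere_phantom(
    radius_mm: float,
    spacing_mm=0.5,
    hu_foreground: float = DEFAULT_HU_FOREGROUND,
    hu_background: float = DEFAULT_HU_BACKGROUND,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[CTVolume, PhantomTruth]:
    """A hyperdense ball; truth S = 4πr², V = (4/3)πr³, HII = 100."""
    spacing = _as_spacing(spacing_mm)
    _check_feature(radius_mm, spacing, f"sphere radius")
    X, Y, Z = _grid(np.array([radius_mm] * 3), spacing)
    inside = X**2 + Y**2 + Z**2 <= radius_mm**2
    vol = _embed(inside, spacing, hu_foreground, hu_background, noise_sd, seed)
    truth = PhantomTruth(
        description=f"sphere r={radius_mm} mm at spacing {spacing} mm",
        analytic_S_mm2=4.0 * math.pi * radius_mm**2,
        analytic_V_mm3=4.0 / 3.0 * math.pi * radius_mm**3,
    )
    return vol, truth


def ellipsoid_surface_area(a: float, b: float, c: float) -> float:
    """Surface area of an ellipsoid with semi-axes a, b, c.

    Uses the closed spheroid forms when two axes coincide (prolate:
    2πb²(1 + (a/(b e)) arcsin e); oblate analogue), and Legendre's
    incomplete-elliptic-integral formula for the triaxial case.
    """
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    a, b, c = sorted((a, b, c), reverse=True)  # a >= b >= c
    if math.isclose(a, c, rel_tol=1e-12):  # sphere
        return 4.0 * math.pi * a * a
    if math.isclose(b, c, rel_tol=1e-12):  # prolate: a > b = c
        e = math.sqrt(1.0 - (c / a) ** 2)
        return 2.0 * math.pi * c * c * (1.0 + (a / (c * e)) * math.asin(e))
    if math.isclose(a, b, rel_tol=1e-12):  # oblate: a = b > c
        e = math.sqrt(1.0 - (c / a) ** 2)
        return 2.0 * math.pi * a * a * (1.0 + ((1.0 - e * e) / e) * math.atanh(e))
    phi = math.acos(c / a)
    k2 = (a * a * (b * b - c * c)) / (b * b * (a * a - c * c))
    F = special.ellipkinc(phi, k2)
    E = special.ellipeinc(phi, k2)
    sin_phi = math.sin(phi)
    return float(
        2.0 * math.pi * c * c
        + (2.0 * math.pi * a * b / sin_phi) * (E * sin_phi**2 + F * math.cos(phi) ** 2)
    )


def make_ellipsoid_phantom(
    a_mm: float,
    b_mm: float,
    c_mm: float,
    spacing_mm=0.5,
    hu_foreground: float = DEFAULT_HU_FOREGROUND,
    hu_background: float = DEFAULT_HU_BACKGROUND,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[CTVolume, PhantomTruth]:
    """An ellipsoidal blob; V = (4/3)πabc, S closed-form/elliptic-integral."""
    spacing = _as_spacing(spacing_mm)
    for ax in (a_mm, b_mm, c_mm):
        _check_feature(ax, spacing, "ellipsoid semi-axis")
    X, Y, Z = _grid(np.array([a_mm, b_mm, c_mm]), spacing)
    inside = (X / a_mm) ** 2 + (Y / b_mm) ** 2 + (Z / c_mm) ** 2 <= 1.0
    vol = _embed(inside, spacing, hu_foreground, hu_background, noise_sd, seed)
    sorted_axes = sorted((a_mm, b_mm, c_mm), reverse=True)
    spheroid = math.isclose(sorted_axes[0], sorted_axes[1], rel_tol=1e-12) or math.isclose(
        sorted_axes[1], sorted_axes[2], rel_tol=1e-12
    )
    truth = PhantomTruth(
        description=f"ellipsoid a={a_mm} b={b_mm} c={c_mm} mm at spacing {spacing} mm",
        analytic_S_mm2=ellipsoid_surface_area(a_mm, b_mm, c_mm),
        analytic_V_mm3=4.0 / 3.0 * math.pi * a_mm * b_mm * c_mm,
        oracle_note="closed form" if spheroid else "Legendre elliptic integrals (machine precision)",
    )
    return vol, truth


def _sphere_union_inside(X, Y, Z, centers, radii) -> np.ndarray:
    inside = np.zeros(X.shape, dtype=bool)
    for (cx, cy, cz), r in zip(centers, radii):
        inside |= (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r * r
    return inside


def _union_connected(centers: np.ndarray, radii: np.ndarray) -> bool:
    """Connectivity of the overlap graph: spheres i,j overlap iff |ci-cj| < ri+rj."""
    n = len(radii)
    seen = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in range(n):
            if j not in seen and np.linalg.norm(centers[i] - centers[j]) < radii[i] + radii[j]:
                seen.add(j)
                frontier.append(j)
    return len(seen) == n


def make_lobulated_phantom(
    n_lobes: int = 5,
    lobe_radius_range_mm: tuple[float, float] = (6.0, 10.0),
    center_spread_mm: float = 10.0,
    spacing_mm=1.0,
    hu_foreground: float = DEFAULT_HU_FOREGROUND,
    hu_background: float = DEFAULT_HU_BACKGROUND,
    noise_sd: float = 0.0,
    seed: int | None = None,
    oracle_refinement: int = 4,
    compute_truth: bool = True,
    max_resamples: int = 200,
) -> tuple[CTVolume, PhantomTruth]:
    """An irregular blob: a connected union of randomly placed spheres.

    Lobe centers are drawn uniformly in a cube of half-width
    ``center_spread_mm`` and redrawn until the sphere-overlap graph is
    connected, so the phantom is a single hematoma-like object. Ground-truth
    S and V come from a brute-force oracle: the same union rasterized at
    ``oracle_refinement``-times finer spacing and measured with the same
    surface pipeline.
    """
    if n_lobes < 1:
        raise ValueError("n_lobes must be >= 1")
    spacing = _as_spacing(spacing_mm)
    r_lo, r_hi = lobe_radius_range_mm
    _check_feature(r_lo, spacing, "smallest lobe radius")
    rng = np.random.default_rng(seed)
    for _ in range(max_resamples):
        centers = rng.uniform(-center_spread_mm, center_spread_mm, size=(n_lobes, 3))
        radii = rng.uniform(r_lo, r_hi, size=n_lobes)
        if n_lobes == 1:
            centers = np.zeros((1, 3))
        if _union_connected(centers, radii):
            break
    else:
        raise RuntimeError(
            f"could not draw a connected {n_lobes}-lobe union in {max_resamples} attempts; "
            "increase lobe radii or decrease center_spread_mm"
        )

    extent = np.abs(centers).max(axis=0) + radii.max()
    X, Y, Z = _grid(extent, spacing)
    inside = _sphere_union_inside(X, Y, Z, centers, radii)
    vol = _embed(inside, spacing, hu_foreground, hu_background, noise_sd, seed)

    truth = PhantomTruth(
        description=f"lobulated union of {n_lobes} spheres (seed {seed})",
        oracle_note="truth not computed (compute_truth=False)",
    )
    if n_lobes == 1:
        truth = PhantomTruth(
            description=f"lobulated n_lobes=1 (sphere r={radii[0]:.3f} mm)",
            analytic_S_mm2=4.0 * math.pi * radii[0] ** 2,
            analytic_V_mm3=4.0 / 3.0 * math.pi * radii[0] ** 3,
        )
    elif compute_truth:
        fine = tuple(s / oracle_refinement for s in spacing)
        Xf, Yf, Zf = _grid(extent, fine)
        fine_mask = BinaryMask(
            voxels=_sphere_union_inside(Xf, Yf, Zf, centers, radii).astype(np.uint8),
            spacing_mm=fine,
        )
        mesh = extract_surface(fine_mask)
        S, V = mesh_surface_area(mesh), mesh_volume(mesh)
        truth = PhantomTruth(
            description=f"lobulated union of {n_lobes} spheres (seed {seed})",
            analytic_S_mm2=S,
            analytic_V_mm3=V,
            oracle_note=(
                f"brute-force: same union rasterized at {oracle_refinement}x finer spacing "
                f"{fine} mm and measured with the standard surface pipeline"
            ),
        )
    return vol, truth


def resample_to_slices(volume: CTVolume, slice_thickness_mm: float = 5.0) -> CTVolume:
    """Slab-average downsampling along the slice axis, emulating thick-slice CT.

    The slab width must be an integer multiple of the native slice spacing;
    a trailing partial slab is dropped.
    """
    native = volume.spacing_mm[0]
    if slice_thickness_mm < native:
        raise ValueError(
            f"slice thickness {slice_thickness_mm} mm is below native spacing {native} mm"
        )
    k = slice_thickness_mm / native
    if abs(k - round(k)) > 1e-6:
        raise ValueError(
            f"slice thickness {slice_thickness_mm} mm is not an integer multiple of native {native} mm"
        )
    k = int(round(k))
    if k == 1:
        return CTVolume(volume.voxels.copy(), volume.spacing_mm, volume.origin_mm)
    n = (volume.voxels.shape[0] // k) * k
    slabbed = volume.voxels[:n].reshape(n // k, k, *volume.voxels.shape[1:]).mean(axis=1)
    spacing = (native * k, volume.spacing_mm[1], volume.spacing_mm[2])
    return CTVolume(voxels=slabbed, spacing_mm=spacing, origin_mm=volume.origin_mm)


def phantom_mask(volume: CTVolume, threshold_hu: float = 40.0) -> BinaryMask:
    """Foreground mask of a noise-free phantom (HU >= threshold)."""
    return BinaryMask(
        voxels=(volume.voxels >= threshold_hu).astype(np.uint8),
        spacing_mm=volume.spacing_mm,
        origin_mm=volume.origin_mm,
    )
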