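"""Quantitative PET features: MTV, SUVmax, SUVmean, TLG and asphericity.

Asphericity (ASP) is the percentage excess of the tumor surface area over
that of a sphere with the same volume::

    ASP = 100 * ( S / ((36 pi)^(1/3) V^(2/3)) - 1 )

It is 0 for a perfect sphere and grows with shape irregularity.  The
surface is estimated by a curvature-corrected marching-cubes mesh (see
:func:`surface_area`); for the ASP ratio both S and V are taken from the
same mesh, which keeps the shape measure free of voxel-count digitization
noise.  MTV keeps its own definition (voxel count x voxel volume).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage import measure

from .volumes import PetVolume, TumorMask

__all__ = [
    "PetFeatureSet",
    "mask_volume",
    "suv_stats",
    "tlg",
    "surface_area",
    "asphericity",
    "compute_features",
]

#: Documented discretization tolerance of the mesh ASP estimator
#: (percentage points); the estimator is positively biased by roughly
#: 0.3-0.8 pp on digitized spheres of radius >= 5 voxels, so the
#: isoperimetric floor ASP >= -EPSILON_MESH holds with margin.
EPSILON_MESH = 0.5

_SMOOTH_SIGMA_VOX = 1.0  # one-voxel Gaussian pre-smoothing
_DISPLACEMENT_SMOOTH_PASSES = 2
_MIN_SMOOTHED_PEAK = 0.6  # below this, fall back to the unsmoothed mesh


@dataclass
class PetFeatureSet:
    """Per-lesion feature bundle.

    ``mtv_ml`` in mL; ``tlg`` = MTV x SUVmean (mL.SUV, exact identity);
    ``asp_percent`` from the mesh surface and mesh-enclosed volume;
    ``surface_mm2`` the mesh surface estimate; ``method_tags`` records the
    surface estimator used.
    """

    mtv_ml: float
    suv_max: float
    suv_mean: float
    tlg: float
    asp_percent: float
    surface_mm2: float
    method_tags: str = "mesh"

    def __post_init__(self) -> None:
        if self.mtv_ml <= 0:
            raise ValueError("mtv must be positive")
        if not self.suv_max >= self.suv_mean > 0:
            raise ValueError("require suv_max >= suv_mean > 0")


def mask_volume(mask: TumorMask) -> float:
    """Voxel count x voxel volume, in mL (1 mL = 1000 mm^3)."""
    n = mask.n_voxels
    if n == 0:
        raise ValueError("empty mask has no volume")
    return n * mask.voxel_volume_mm3 / 1000.0


def suv_stats(vol: PetVolume, mask: TumorMask) -> tuple[float, float]:
    """(SUVmax, SUVmean) over the mask voxels."""
    mask.check_congruent(vol)
    if mask.n_voxels == 0:
        raise ValueError("empty mask has no SUV statistics")
    values = vol.data[mask.data]
    return float(values.max()), float(values.mean())


def tlg(mtv_ml: float, suv_mean: float) -> float:
    """Total lesion glycolysis = MTV x SUVmean (exact product)."""
    return mtv_ml * suv_mean


def asphericity(surface_mm2: float, volume_mm3: float) -> float:
    """ASP in percent from a surface area (mm^2) and a volume (mm^3)."""
    if surface_mm2 <= 0 or volume_mm3 <= 0:
        raise ValueError("surface and volume must be positive")
    s_sphere = (36.0 * math.pi) ** (1.0 / 3.0) * volume_mm3 ** (2.0 / 3.0)
    return 100.0 * (surface_mm2 / s_sphere - 1.0)


def _check_interior(mask: TumorMask) -> None:
    d = mask.data
    if (
        d[0].any() or d[-1].any()
        or d[:, 0].any() or d[:, -1].any()
        or d[:, :, 0].any() or d[:, :, -1].any()
    ):
        raise ValueError("mask touches the grid boundary; pad the volume first")


def _corrected_mesh(mask: TumorMask) -> tuple[np.ndarray, np.ndarray]:
    """Curvature-corrected marching-cubes mesh of a binary mask.

    The 0.5 level set of a Gaussian-smoothed indicator sits inward of the
    true interface by approximately sigma^2 * H (H the local mean
    curvature), which systematically shrinks convex surfaces.  Vertices
    are therefore displaced outward by that amount, with H evaluated from
    finite-difference derivatives of the smoothed field and the
    displacement averaged over mesh neighbors to suppress interpolation
    noise.  Vertices are returned in mm (isotropic spacing changes scale
    the mesh exactly).
    """
    m = mask.data.astype(float)
    f = gaussian_filter(m, _SMOOTH_SIGMA_VOX)
    if f.max() <= _MIN_SMOOTHED_PEAK:
        # tiny mask: smoothing flattens it below the iso level; mesh the
        # raw binary cube surface instead
        verts, faces, _, _ = measure.marching_cubes(m, 0.5)
        return verts * np.asarray(mask.spacing), faces

    verts, faces, _, _ = measure.marching_cubes(f, 0.5)

    spacing = np.asarray(mask.spacing)
    grad = np.gradient(f, *mask.spacing)
    hess = [[np.gradient(grad[i], mask.spacing[j], axis=j) for j in range(3)] for i in range(3)]
    vi = verts.T  # voxel-index coordinates for interpolation
    g = np.stack([map_coordinates(grad[i], vi, order=1) for i in range(3)], axis=1)
    h = np.einsum(
        "ijn->nij",
        np.array([[map_coordinates(hess[i][j], vi, order=1) for j in range(3)] for i in range(3)]),
    )
    gn = np.maximum(np.linalg.norm(g, axis=1), 1e-12)
    trace = np.einsum("nii->n", h)
    quad = np.einsum("ni,nij,nj->n", g, h, g)
    kappa = (gn**2 * trace - quad) / gn**3  # div of the level-set normal
    sigma_mm2 = float(np.mean((_SMOOTH_SIGMA_VOX * spacing) ** 2))
    delta = -0.5 * sigma_mm2 * kappa  # outward-positive for convex regions

    if _DISPLACEMENT_SMOOTH_PASSES:
        delta = _average_over_neighbors(delta, faces, len(verts), _DISPLACEMENT_SMOOTH_PASSES)

    outward = -g / gn[:, None]
    verts_mm = verts * spacing + delta[:, None] * outward
    return verts_mm, faces


def _average_over_neighbors(values: np.ndarray, faces: np.ndarray, n_verts: int, passes: int) -> np.ndarray:
    from scipy.sparse import coo_matrix

    i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2], faces[:, 1], faces[:, 2], faces[:, 0]])
    j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0], faces[:, 0], faces[:, 1], faces[:, 2]])
    adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(n_verts, n_verts)).tocsr()
    adj.data[:] = 1.0
    degree = np.maximum(np.asarray(adj.sum(axis=1)).ravel(), 1.0)
    for _ in range(passes):
        values = (adj @ values) / degree
    return values


def _mesh_surface_and_volume(verts: np.ndarray, faces: np.ndarray) -> tuple[float, float]:
    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    surface = 0.5 * float(np.linalg.norm(cross, axis=1).sum())
    volume = abs(float(np.einsum("ij,ij->", tri[:, 0], cross)) / 6.0)
    return surface, volume


def surface_area(mask: TumorMask, method: str = "mesh") -> float:
    """Surface area of the mask in mm^2.

    ``mesh`` (default): curvature-corrected marching-cubes triangulation
    of the lightly smoothed binary mask.  ``voxel_faces``: exposed voxel
    faces x face areas — retained as a diagnostic only; it overestimates
    smooth surfaces by roughly 50 %.
    """
    if mask.n_voxels == 0:
        raise ValueError("empty mask has no surface")
    _check_interior(mask)
    if method == "mesh":
        verts, faces = _corrected_mesh(mask)
        surface, _ = _mesh_surface_and_volume(verts, faces)
        return surface
    if method == "voxel_faces":
        return _voxel_faces_area(mask)
    raise ValueError(f"unknown surface method {method!r}; expected 'mesh' or 'voxel_faces'")


def _voxel_faces_area(mask: TumorMask) -> float:
    d = mask.data
    sx, sy, sz = mask.spacing
    face_areas = (sy * sz, sx * sz, sx * sy)
    total = 0.0
    for axis, fa in enumerate(face_areas):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        exposed = d[tuple(sl_lo)] != d[tuple(sl_hi)]
        boundary = d.take(0, axis=axis).sum() + d.take(-1, axis=axis).sum()
        total += fa * (int(exposed.sum()) + int(boundary))
    return total


def mesh_asphericity(mask: TumorMask) -> tuple[float, float, float]:
    """(ASP percent, mesh surface mm^2, mesh volume mm^3) of a mask."""
    if mask.n_voxels == 0:
        raise ValueError("empty mask has no shape")
    _check_interior(mask)
    verts, faces = _corrected_mesh(mask)
    surface, volume = _mesh_surface_and_volume(verts, faces)
    return asphericity(surface, volume), surface, volume


def compute_features(vol: PetVolume, mask: TumorMask) -> PetFeatureSet:
    """Assemble the full per-lesion feature set (deterministic)."""
    mask.check_congruent(vol)
    mtv = mask_volume(mask)
    smax, smean = suv_stats(vol, mask)
    asp, surf, _ = mesh_asphericity(mask)
    return PetFeatureSet(
        mtv_ml=mtv,
        suv_max=smax,
        suv_mean=smean,
        tlg=tlg(mtv, smean),
        asp_percent=asp,
        surface_mm2=surf,
        method_tags="mesh:curvature_corrected",
    )
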