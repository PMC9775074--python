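"""ALPS index: ROI placement and perivascular diffusivity ratio.

The ALPS (analysis along the perivascular space) index probes glymphatic
transport at the lateral-ventricle body, where three structures are
mutually perpendicular: projection fibers run cranio-caudally (z),
association fibers antero-posteriorly (y), and the perivascular space of
the medullary veins left-right (x). Diffusivity along x in both fiber
regions therefore reflects perivascular water movement unconfounded by
fiber direction, and the index

    ALPS = mean(Dx_proj, Dx_asso) / mean(Dy_proj, Dz_asso)

is a ratio of perivascular to fiber-perpendicular diffusivity. As a ratio
it is invariant to global diffusivity elevation (e.g. from periventricular
white-matter hyperintensities). Values near 1 indicate no preferential
perivascular diffusion; healthy adults typically measure ~1.4-1.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dti import TensorField
from . import dti

__all__ = ["RoiSpec", "AlpsMeasurement", "build_sphere_roi", "measure_alps", "suggest_roi_centers"]


class RoiPlacementError(ValueError):
    """Raised when an ROI cannot be placed (out of bounds, masked, no candidate)."""


class DegenerateMeasurementError(ValueError):
    """Raised when the ALPS denominator is zero."""


@dataclass(frozen=True)
class RoiSpec:
    """A compact spherical ROI around a center voxel.

    ``target_voxel_count`` voxels nearest the center are selected (default
    12, the conventional ALPS ROI size). ``fiber_type`` tags the ROI as
    sampling the projection or association fiber region.
    """

    center_voxel: tuple[int, int, int]
    fiber_type: str
    target_voxel_count: int = 12

    def __post_init__(self) -> None:
        if self.fiber_type not in ("projection", "association"):
            raise ValueError("fiber_type must be 'projection' or 'association'")
        if self.target_voxel_count <= 0:
            raise ValueError("target_voxel_count must be positive")


@dataclass
class AlpsMeasurement:
    """The four ROI-mean diffusivities (mm^2/s) and their ALPS ratio."""

    dx_proj: float
    dy_proj: float
    dx_asso: float
    dz_asso: float
    alps_index: float
    roi_voxel_counts: tuple[int, int]


def build_sphere_roi(spec: RoiSpec, volume_shape: tuple[int, int, int]) -> np.ndarray:
    """Deterministic nearest-N voxel set around the ROI center.

    No lattice sphere contains exactly 12 voxels for generic radii, so the
    ROI is defined as the first N voxels ordered by (squared Euclidean
    distance from the center, then lexicographic index). Returns an
    ``(N, 3)`` integer index array.

    Raises :class:`RoiPlacementError` if the ROI would be clipped by the
    volume boundary — clipping is never silent.
    """
    center = np.asarray(spec.center_voxel, dtype=int)
    shape = np.asarray(volume_shape, dtype=int)
    if np.any(center < 0) or np.any(center >= shape):
        raise RoiPlacementError(f"ROI center {tuple(center)} outside volume {tuple(shape)}")

    # search neighborhood generously larger than any N we select
    r = int(np.ceil(spec.target_voxel_count ** (1 / 3))) + 2
    offsets = np.stack(
        np.meshgrid(*([np.arange(-r, r + 1)] * 3), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    d2 = (offsets**2).sum(axis=1)
    coords = center + offsets
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], d2))
    picked = coords[order[: spec.target_voxel_count]]
    if len(picked) < spec.target_voxel_count:
        raise RoiPlacementError("neighborhood too small for requested voxel count")
    if np.any(picked < 0) or np.any(picked >= shape):
        raise RoiPlacementError(
            f"ROI of {spec.target_voxel_count} voxels at {tuple(center)} "
            f"is clipped by the volume boundary {tuple(shape)}"
        )
    return picked


def _roi_mean(volume: np.ndarray, idx: np.ndarray) -> float:
    return float(volume[idx[:, 0], idx[:, 1], idx[:, 2]].mean())


def measure_alps(tf: TensorField, roi_proj: RoiSpec, roi_asso: RoiSpec) -> AlpsMeasurement:
    """Measure the ALPS index from paired projection/association ROIs.

    Means of the diagonal diffusivities are taken over each ROI:
    Dx and Dy over the projection ROI, Dx and Dz over the association ROI;
    the index is ``mean(Dx_proj, Dx_asso) / mean(Dy_proj, Dz_asso)``.

    All ROI voxels must lie inside the fitted mask; masked voxels raise an
    error listing their coordinates.
    """
    if roi_proj.fiber_type != "projection" or roi_asso.fiber_type != "association":
        raise ValueError("roi_proj must be a projection ROI and roi_asso an association ROI")
    out = []
    for roi in (roi_proj, roi_asso):
        idx = build_sphere_roi(roi, tf.shape)
        bad = idx[~tf.mask[idx[:, 0], idx[:, 1], idx[:, 2]]]
        if len(bad):
            raise RoiPlacementError(
                f"{roi.fiber_type} ROI contains masked voxels: {[tuple(v) for v in bad]}"
            )
        out.append(idx)
    idx_proj, idx_asso = out

    dx, dy, dz = dti.axis_diffusivity_maps(tf)
    dx_proj = _roi_mean(dx, idx_proj)
    dy_proj = _roi_mean(dy, idx_proj)
    dx_asso = _roi_mean(dx, idx_asso)
    dz_asso = _roi_mean(dz, idx_asso)

    denom = 0.5 * (dy_proj + dz_asso)
    if denom <= 0:
        raise DegenerateMeasurementError(
            "ALPS denominator mean(Dy_proj, Dz_asso) is non-positive"
        )
    index = 0.5 * (dx_proj + dx_asso) / denom
    return AlpsMeasurement(
        dx_proj=dx_proj,
        dy_proj=dy_proj,
        dx_asso=dx_asso,
        dz_asso=dz_asso,
        alps_index=index,
        roi_voxel_counts=(len(idx_proj), len(idx_asso)),
    )


def suggest_roi_centers(
    tf: TensorField,
    fa_floor: float = 0.2,
    target_voxel_count: int = 12,
) -> tuple[RoiSpec, RoiSpec]:
    """Propose projection/association ROI centers from the color-FA field.

    The projection candidate maximizes blue*FA (cranio-caudal fibers); the
    association candidate maximizes green*FA restricted to the same
    left-right and cranio-caudal coordinates — "parallel" placement on the
    same axial plane, shifted antero-posteriorly. Ties resolve to the
    lowest lexicographic voxel. These are suggestions; conventional
    practice is manual placement by a blinded rater, so callers should
    treat them as starting points.

    Raises :class:`RoiPlacementError` when no voxel exceeds ``fa_floor``.
    """
    rgb = dti.color_fa(tf)
    blue = rgb[..., 2] * tf.fa
    green = rgb[..., 1] * tf.fa
    eligible = tf.fa >= fa_floor
    if not np.any(eligible & (blue > 0)):
        raise RoiPlacementError(f"no projection-fiber candidate with FA >= {fa_floor}")

    score = np.where(eligible, blue, -np.inf)
    proj = np.unravel_index(int(np.argmax(score)), score.shape)  # argmax is lexicographic-first

    line = np.where(eligible[proj[0], :, proj[2]], green[proj[0], :, proj[2]], -np.inf)
    if not np.any(np.isfinite(line) & (line > 0)):
        raise RoiPlacementError(
            f"no association-fiber candidate with FA >= {fa_floor} on the axial "
            f"plane of the projection ROI"
        )
    asso_y = int(np.argmax(line))
    return (
        RoiSpec(center_voxel=tuple(int(c) for c in proj), fiber_type="projection",
                target_voxel_count=target_voxel_count),
        RoiSpec(center_voxel=(int(proj[0]), asso_y, int(proj[2])), fiber_type="association",
                target_voxel_count=target_voxel_count),
    )
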