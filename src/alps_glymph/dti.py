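"""Diffusion tensor fitting and derived scalar maps.

Fits the single-tensor diffusion model to a 4D diffusion-weighted volume by
log-linear least squares, and derives fractional anisotropy (FA), principal
diffusion directions, and the axis-aligned diagonal diffusivities Dx/Dy/Dz
that the ALPS measurement consumes.

Axis semantics follow the anatomical convention used throughout this
package: x = left-right, y = anterior-posterior, z = cranio-caudal. The
diagonal diffusivities are the *diagonal elements* of the tensor in that
frame, not eigenvalues: in regions where fibers are not aligned with an
axis the two quantities differ, and the ALPS index is defined on the
diagonal elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AXIS_LABELS",
    "DiffusionVolume",
    "TensorField",
    "fit_tensor",
    "color_fa",
    "axis_diffusivity_maps",
    "fractional_anisotropy",
]

#: canonical anatomical labels for array axes 0, 1, 2
AXIS_LABELS = ("LR", "AP", "CC")


class AxisConventionError(ValueError):
    """Raised when the anatomical axis mapping is missing or invalid."""


class GradientSchemeError(ValueError):
    """Raised when the diffusion gradient scheme cannot support a tensor fit."""


def _validate_axis_convention(axis_convention) -> tuple[str, str, str]:
    if axis_convention is None:
        raise AxisConventionError(
            "axis_convention is required: a permutation of "
            f"{AXIS_LABELS} naming the anatomical direction of each array axis"
        )
    conv = tuple(axis_convention)
    if sorted(conv) != sorted(AXIS_LABELS):
        raise AxisConventionError(
            f"axis_convention must be a permutation of {AXIS_LABELS}, got {conv!r}"
        )
    return conv  # type: ignore[return-value]


@dataclass
class DiffusionVolume:
    """A 4D diffusion-weighted acquisition.

    Parameters
    ----------
    signal
        Non-negative array of shape ``(nx, ny, nz, ngrad)``; one 3D frame
        per gradient.
    bvals
        b-value per gradient, s/mm^2.
    bvecs
        Unit gradient directions, shape ``(ngrad, 3)``; ignored for b = 0.
    voxel_size_mm
        Voxel edge lengths per array axis.
    axis_convention
        Permutation of ``("LR", "AP", "CC")`` naming the anatomical
        direction of each array axis. Defaults to the identity.
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.5)
    axis_convention: tuple[str, str, str] = AXIS_LABELS

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape == (3, self.bvals.size) and self.bvecs.shape[0] == 3:
            self.bvecs = self.bvecs.T
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, gradient)")
        if self.signal.shape[3] != self.bvals.size:
            raise ValueError(
                f"gradient count mismatch: signal has {self.signal.shape[3]} "
                f"frames but {self.bvals.size} b-values"
            )
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError("bvecs must have shape (ngrad, 3)")
        if not np.any(self.bvals == 0):
            raise ValueError("at least one b = 0 frame is required")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-3):
            raise ValueError("b-vectors must be unit norm for b > 0 frames")
        self.axis_convention = _validate_axis_convention(self.axis_convention)

    @property
    def n_gradients(self) -> int:
        return int(self.bvals.size)


@dataclass
class TensorField:
    """Per-voxel diffusion tensors with derived scalar maps.

    ``dxx``, ``dyy``, ``dzz`` are diagonal elements of the
    (eigenvalue-clamped) tensor along the left-right, anterior-posterior
    and cranio-caudal axes respectively. ``n_clamped`` counts voxels where
    negative eigenvalues were clamped to zero before deriving maps.
    """

    tensor: np.ndarray  # (nx, ny, nz, 3, 3), anatomical frame (LR, AP, CC)
    fa: np.ndarray
    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    principal_direction: np.ndarray  # (nx, ny, nz, 3)
    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.5)
    axis_convention: tuple[str, str, str] = AXIS_LABELS
    n_clamped: int = 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensor.shape[:3]


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Log-linear design matrix for the six unique tensor elements.

    Row i is ``b_i * (gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz)`` so that
    ``-ln(S/S0) = B @ (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)``.
    """
    g = np.asarray(bvecs, dtype=float)
    b = np.asarray(bvals, dtype=float)[:, None]
    return b * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def _six_to_tensor(d6: np.ndarray) -> np.ndarray:
    """Expand (..., 6) unique elements to (..., 3, 3) symmetric tensors."""
    out = np.empty(d6.shape[:-1] + (3, 3), dtype=float)
    out[..., 0, 0] = d6[..., 0]
    out[..., 1, 1] = d6[..., 1]
    out[..., 2, 2] = d6[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = d6[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = d6[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = d6[..., 5]
    return out


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """FA from tensor eigenvalues, ``sqrt(3/2 * sum((l-lbar)^2) / sum(l^2))``.

    Zero where all eigenvalues vanish.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = ((lam - mean) ** 2).sum(axis=-1)
    den = (lam**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, np.clip(fa, 0.0, 1.0), 0.0)


def _anatomical_permutation(axis_convention) -> np.ndarray:
    """Permutation p with p[k] = array axis holding anatomical axis k (LR, AP, CC)."""
    conv = _validate_axis_convention(axis_convention)
    return np.array([conv.index(lbl) for lbl in AXIS_LABELS])


def fit_tensor(dwi: DiffusionVolume, fa_mask_threshold: float = 0.0) -> TensorField:
    """Fit per-voxel diffusion tensors by ordinary log-linear least squares.

    Multiple b = 0 frames are averaged before forming the log ratio.
    Voxels with any non-positive signal are excluded from the mask.
    Negative eigenvalues (a noise artifact) are clamped to zero for the
    derived FA and diffusivity maps; the number of affected voxels is
    reported in ``TensorField.n_clamped``.

    Raises
    ------
    GradientSchemeError
        If fewer than six non-collinear diffusion directions are present.
    """
    dw = dwi.bvals > 0
    if dw.sum() < 6:
        raise GradientSchemeError(
            f"tensor fit needs >= 6 diffusion-weighted frames, got {int(dw.sum())}"
        )
    B = design_matrix(dwi.bvals[dw], dwi.bvecs[dw])
    if np.linalg.matrix_rank(B) < 6:
        raise GradientSchemeError(
            "gradient directions are rank deficient (collinear or coplanar "
            "scheme); at least 6 non-collinear directions are required"
        )

    s0 = dwi.signal[..., ~dw].mean(axis=-1)
    s = dwi.signal[..., dw]
    mask = (s0 > 0) & np.all(s > 0, axis=-1)

    shape = dwi.signal.shape[:3]
    nvox = int(np.prod(shape))
    y = np.zeros((nvox, int(dw.sum())))
    flat_mask = mask.ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        logratio = -np.log(s.reshape(nvox, -1) / s0.reshape(nvox, 1))
    y[flat_mask] = logratio[flat_mask]

    # shared design matrix across voxels: one pseudoinverse, one matmul
    d6 = y @ np.linalg.pinv(B).T
    tensor = _six_to_tensor(d6)

    # reorder array axes into the anatomical (LR, AP, CC) frame
    perm = _anatomical_permutation(dwi.axis_convention)
    tensor = tensor[:, perm][:, :, perm]

    evals, evecs = np.linalg.eigh(tensor)
    clamped = np.clip(evals, 0.0, None)
    n_clamped = int(np.count_nonzero(np.any((evals < 0) & flat_mask[:, None], axis=-1)))
    d_psd = np.einsum("vij,vj,vkj->vik", evecs, clamped, evecs)

    fa = fractional_anisotropy(clamped)
    principal = evecs[..., -1]  # eigh sorts ascending

    tensor = tensor.reshape(shape + (3, 3))
    d_psd = d_psd.reshape(shape + (3, 3))
    fa = np.where(flat_mask, fa, 0.0).reshape(shape)
    principal = np.where(flat_mask[:, None], principal, 0.0).reshape(shape + (3,))

    return TensorField(
        tensor=tensor,
        fa=fa,
        dxx=d_psd[..., 0, 0],
        dyy=d_psd[..., 1, 1],
        dzz=d_psd[..., 2, 2],
        principal_direction=principal,
        mask=mask,
        voxel_size_mm=dwi.voxel_size_mm,
        axis_convention=AXIS_LABELS,
        n_clamped=n_clamped,
    )


def color_fa(tf: TensorField) -> np.ndarray:
    """Direction-encoded color FA volume, shape ``(nx, ny, nz, 3)``.

    Radiological DEC convention: red = left-right, green =
    anterior-posterior, blue = cranio-caudal; each channel is
    ``|principal direction component| * FA``.
    """
    perm = _anatomical_permutation(tf.axis_convention)
    v = tf.principal_direction[..., perm]
    return np.abs(v) * tf.fa[..., None]


def axis_diffusivity_maps(tf: TensorField) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diagonal diffusivities (Dx, Dy, Dz) along LR, AP and CC axes.

    These are diagonal elements of the tensor in the anatomical frame,
    not eigenvalues.
    """
    _validate_axis_convention(tf.axis_convention)
    return tf.dxx, tf.dyy, tf.dzz
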