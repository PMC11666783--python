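"""Coordinate conventions, axial statistics and spindle/plate geometry.

Conventions used throughout the package:

* voxel arrays are indexed ``(z, y, x)``, 0-based;
* physical positions are in micrometres with the voxel-centre convention:
  voxel index ``i`` along an axis with spacing ``s`` sits at ``(i + 0.5) * s``;
* all public APIs take and return micrometre coordinates as ``(z, y, x)``
  arrays (CSV serialisation maps these to ``x_um, y_um, z_um`` columns);
* spindle axes are *axial* directions: unit vectors identified with their
  negation.  They are averaged through the orientation scatter matrix, never
  by naive vector addition, so the result is independent of the arbitrary
  sign of each input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .errors import AmbiguousAxisError, EmptyForegroundError, FlatImageError

__all__ = [
    "SpindleFrameModel",
    "RigidShift",
    "voxel_to_um",
    "um_to_voxel",
    "normalize_axis",
    "axial_mean",
    "chromosome_mass_center",
    "spindle_axis_from_pairs",
    "distance_from_plate",
    "register_translation",
    "alignment_dot",
]

#: tolerance for "tied" leading eigenvalues of the (weight-normalised)
#: orientation scatter matrix
_AXIS_TIE_TOL = 1e-9


def voxel_to_um(index, voxel_size):
    """Physical (z, y, x) position in um of a (possibly fractional) voxel index."""
    return (np.asarray(index, dtype=float) + 0.5) * np.asarray(voxel_size, dtype=float)


def um_to_voxel(pos_um, voxel_size):
    """Fractional voxel index of a physical (z, y, x) position in um."""
    return np.asarray(pos_um, dtype=float) / np.asarray(voxel_size, dtype=float) - 0.5


def normalize_axis(v):
    """Return ``v`` scaled to unit norm, as an axial direction."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0 or not np.isfinite(n):
        raise ValueError("cannot normalise a zero or non-finite vector")
    return v / n


@dataclass(frozen=True)
class SpindleFrameModel:
    """Spindle axis plus metaphase-plate centre for one time frame.

    The metaphase plate is the plane through ``plate_center`` (the
    intensity-weighted chromosome mass centre) with the spindle axis as its
    normal vector.
    """

    axis: np.ndarray
    plate_center: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "axis", normalize_axis(self.axis))
        object.__setattr__(self, "plate_center", np.asarray(self.plate_center, dtype=float))


@dataclass(frozen=True)
class RigidShift:
    """Translation (um, ``(z, y, x)``) registering a moving stack onto a reference.

    ``confidence`` is the normalised cross-correlation of the registered
    overlap; values near 0 indicate the shift is unreliable.
    """

    translation_um: np.ndarray
    confidence: float = 1.0

    def __post_init__(self):
        t = np.asarray(self.translation_um, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("shift must be finite")
        object.__setattr__(self, "translation_um", t)

    def apply(self, points_um):
        """Shift one point or an ``(n, 3)`` array of points."""
        return np.asarray(points_um, dtype=float) + self.translation_um


def axial_mean(directions, weights=None):
    """Average axial (sign-free) directions.

    Each direction is treated as a 180-degree rotation axis: the mean is the
    principal eigenvector of the weighted orientation scatter matrix
    ``sum_i w_i v_i v_i^T``, which is invariant to flipping the sign of any
    input.

    Parameters
    ----------
    directions : sequence of (3,) unit vectors
    weights : optional sequence of non-negative weights

    Returns
    -------
    (3,) unit vector (sign is arbitrary but deterministic)
    """
    vs = np.atleast_2d(np.asarray(directions, dtype=float))
    if vs.size == 0:
        raise ValueError("axial_mean requires at least one direction")
    norms = np.linalg.norm(vs, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length direction")
    vs = vs / norms[:, None]
    if weights is None:
        w = np.ones(len(vs))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(vs),):
            raise ValueError("weights must match directions")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    wsum = w.sum()
    if wsum == 0:
        raise ValueError("weights sum to zero")
    scatter = np.einsum("i,ij,ik->jk", w / wsum, vs, vs)
    evals, evecs = np.linalg.eigh(scatter)  # ascending order
    if evals[2] - evals[1] <= _AXIS_TIE_TOL:
        raise AmbiguousAxisError(
            "ambiguous axis: leading eigenvalues of the orientation scatter are tied "
            f"({evals[2]:.3g} vs {evals[1]:.3g})"
        )
    axis = evecs[:, 2]
    # deterministic sign: first non-zero component positive
    for c in axis:
        if abs(c) > 1e-12:
            if c < 0:
                axis = -axis
            break
    return axis


def chromosome_mass_center(dna_channel, voxel_size, sigma_um=0.5):
    """Intensity-weighted centre of the chromosome mass, in um.

    The channel is Gaussian-blurred at ``sigma_um``, thresholded globally with
    Otsu's method, and the centroid of above-threshold voxels is computed
    weighting each voxel by its (blurred) intensity.
    """
    img = np.asarray(dna_channel, dtype=float)
    if img.ndim != 3:
        raise ValueError("expected a 3D single-channel image")
    voxel_size = np.asarray(voxel_size, dtype=float)
    sigma_vox = float(sigma_um) / voxel_size
    blurred = ndimage.gaussian_filter(img, sigma=sigma_vox)
    if blurred.max() == blurred.min():
        raise EmptyForegroundError("image is flat; no chromosome mass to segment")
    thr = threshold_otsu(blurred)
    mask = blurred > thr
    if not mask.any():
        raise EmptyForegroundError("Otsu threshold left no foreground voxels")
    idx = np.argwhere(mask)
    wts = blurred[mask]
    centroid_vox = (idx * wts[:, None]).sum(axis=0) / wts.sum()
    return voxel_to_um(centroid_vox, voxel_size)


def spindle_axis_from_pairs(pairs):
    """Spindle axis from homologous kinetochore pairs.

    The axis is the axial mean of the normalised vectors connecting the two
    kinetochores of each pair; coincident pairs are skipped.
    """
    dirs = []
    for p, q in pairs:
        d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
        n = np.linalg.norm(d)
        if n > 0:
            dirs.append(d / n)
    if not dirs:
        raise ValueError("all pairs have coincident endpoints")
    return axial_mean(dirs)


def distance_from_plate(p, model: SpindleFrameModel):
    """Absolute distance of ``p`` from the metaphase plate, along the spindle axis."""
    return float(abs(np.dot(np.asarray(p, dtype=float) - model.plate_center, model.axis)))


def register_translation(ref_stack, mov_stack, voxel_size, upsample_factor=20):
    """Translation-only registration of ``mov_stack`` onto ``ref_stack``.

    Maximises the cross-correlation of the two stacks with subvoxel
    refinement; applying the returned shift to positions measured in the
    moving stack expresses them in the reference frame.
    """
    ref = np.asarray(ref_stack, dtype=float)
    mov = np.asarray(mov_stack, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError("stacks must have identical shapes")
    if ref.std() == 0 or mov.std() == 0:
        raise FlatImageError("cannot register a flat (contrast-free) stack")
    shift_vox, error, _ = phase_cross_correlation(
        ref, mov, upsample_factor=upsample_factor, normalization=None
    )
    # normalised correlation of the registered stacks as a confidence score
    mov_reg = ndimage.shift(mov, shift_vox, order=1, mode="constant", cval=mov.mean())
    a = ref - ref.mean()
    b = mov_reg - mov_reg.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    confidence = float((a * b).sum() / denom) if denom > 0 else 0.0
    translation = shift_vox * np.asarray(voxel_size, dtype=float)
    return RigidShift(translation_um=translation, confidence=confidence)


def alignment_dot(a, b):
    """|a . b| for two unit axes; 1 = parallel, 0 = perpendicular."""
    return float(np.clip(abs(np.dot(normalize_axis(a), normalize_axis(b))), 0.0, 1.0))
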