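"""Per-kinetochore measurements and classifications.

Covers TALE-based class assignment, kinetochore orientation to the spindle,
sister interkinetochore distances (raw and per-cell normalised), cohesin
ROI intensities (cylinder between sisters; sphere on the pericentromere),
Mad1-positive counting, telomere proximity/masking, cohesin-depletion
separation timing, and chromosome position in the GV nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import AmbiguousAxisError, EmptyForegroundError
from .geometry import normalize_axis
from .tracking import detect_spots

__all__ = [
    "ROIConfig",
    "Cylinder",
    "Sphere",
    "assign_tale_labels",
    "kinetochore_alignment",
    "pair_sisters",
    "sister_ikd_normalized",
    "roi_intensity",
    "per_cell_normalized",
    "count_mad1_positive",
    "classify_telomere_proximity",
    "classify_telomere_masking",
    "separation_times",
    "gv_nucleus_distances",
]


@dataclass
class ROIConfig:
    cylinder_radius_um: float = 0.5  # SMC3 cylinder between sisters
    sphere_radius_um: float = 1.0  # REC8 pericentromeric sphere
    tale_max_dist_um: float = 2.0  # beyond this: non-TALE-labelled
    telomere_proximity_radius_um: float = 1.0
    mad1_xy_diam_um: float = 1.73
    mad1_z_diam_um: float = 3.47
    mad1_match_radius_um: float = 1.0
    mad1_quality_nsigma: float = 3.0  # threshold = bg mean + n * bg SD

    def __post_init__(self):
        for r in (self.cylinder_radius_um, self.sphere_radius_um,
                  self.tale_max_dist_um, self.telomere_proximity_radius_um):
            if r <= 0:
                raise ValueError("radii must be positive")


@dataclass(frozen=True)
class Cylinder:
    """Round cylinder along the segment [p, q] with the given radius (um)."""

    p: tuple
    q: tuple
    radius: float


@dataclass(frozen=True)
class Sphere:
    center: tuple
    radius: float


def assign_tale_labels(kt_centroids, tale_centroids, shift=None, config: ROIConfig | None = None):
    """Boolean TALE label per kinetochore centroid.

    A kinetochore is labelled iff its distance to the nearest (shifted)
    TALE centroid is at most ``tale_max_dist_um`` (the boundary is
    inclusive: only centroids *further* than the cutoff are unlabelled).
    """
    cfg = config or ROIConfig()
    kts = np.atleast_2d(np.asarray(kt_centroids, dtype=float))
    if kts.size == 0:
        raise ValueError("empty kinetochore set")
    tales = np.atleast_2d(np.asarray(tale_centroids, dtype=float))
    if tales.size == 0:
        return np.zeros(len(kts), dtype=bool)
    if shift is not None:
        tales = shift.apply(tales)
    d = np.linalg.norm(kts[:, None, :] - tales[None, :, :], axis=2).min(axis=1)
    return d <= cfg.tale_max_dist_um


def kinetochore_alignment(region, spindle_axis, voxel_size=None, tie_tol=1e-6):
    """Alignment (|dot|) of a kinetochore label's main axis with the spindle.

    ``region`` is either an (n, 3) array of voxel indices (with
    ``voxel_size`` to scale them) or an (n, 3) array of um positions when
    ``voxel_size`` is None.  The main axis is the leading eigenvector of
    the region's second-moment tensor — the longest ellipsoid axis.
    """
    pts = np.atleast_2d(np.asarray(region, dtype=float))
    if len(pts) < 4:
        raise ValueError("region must have at least 4 voxels")
    if voxel_size is not None:
        pts = (pts + 0.5) * np.asarray(voxel_size, dtype=float)
    centred = pts - pts.mean(axis=0)
    tensor = centred.T @ centred / len(pts)
    evals, evecs = np.linalg.eigh(tensor)
    if evals[2] - evals[1] <= tie_tol * max(evals[2], 1e-30):
        raise AmbiguousAxisError("degenerate kinetochore shape: main axis undefined")
    main = evecs[:, 2]
    return float(np.clip(abs(np.dot(main, normalize_axis(spindle_axis))), 0, 1))


def pair_sisters(detections, max_dist_um=2.0):
    """Pair detections by mutual nearest neighbour within ``max_dist_um``.

    Returns an (n_pairs, 2) index array into ``detections`` (DataFrame with
    z_um, y_um, x_um or an (n, 3) array).
    """
    pos = detections[["z_um", "y_um", "x_um"]].to_numpy() if hasattr(detections, "columns") else np.asarray(detections, dtype=float)
    n = len(pos)
    if n < 2:
        return np.empty((0, 2), dtype=int)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)
    pairs = []
    for i in range(n):
        j = nn[i]
        if nn[j] == i and i < j and d[i, j] <= max_dist_um:
            pairs.append((i, j))
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


def sister_ikd_normalized(pairs_um):
    """Raw and within-cell-normalised sister interkinetochore distances.

    ``pairs_um`` is a sequence of (p, q) point pairs from one cell; the
    normalised distance is raw / (mean raw of the cell).
    """
    pairs = np.asarray(pairs_um, dtype=float)
    if pairs.ndim != 3 or len(pairs) == 0:
        raise ValueError("need at least one (p, q) pair")
    raw = np.linalg.norm(pairs[:, 0] - pairs[:, 1], axis=1)
    return pd.DataFrame({"ikd_um": raw, "ikd_norm": raw / raw.mean()})


def _roi_mask(shape, voxel_size, roi):
    vs = np.asarray(voxel_size, dtype=float)
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(shape, vs)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij", sparse=True)
    if isinstance(roi, Sphere):
        c = np.asarray(roi.center, dtype=float)
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        return d2 <= roi.radius**2
    if isinstance(roi, Cylinder):
        p = np.asarray(roi.p, dtype=float)
        q = np.asarray(roi.q, dtype=float)
        axis = q - p
        L = np.linalg.norm(axis)
        if L == 0:
            raise ValueError("cylinder endpoints coincide")
        axis = axis / L
        dz, dy, dx = zz - p[0], yy - p[1], xx - p[2]
        t = dz * axis[0] + dy * axis[1] + dx * axis[2]
        r2 = (dz - t * axis[0]) ** 2 + (dy - t * axis[1]) ** 2 + (dx - t * axis[2]) ** 2
        return (t >= 0) & (t <= L) & (r2 <= roi.radius**2)
    raise TypeError(f"unsupported ROI type {type(roi)!r}")


def roi_intensity(channel, voxel_size, roi, background=0.0):
    """Background-subtracted mean intensity over voxels whose centres lie in
    the ROI (a :class:`Cylinder` or :class:`Sphere`)."""
    img = np.asarray(channel, dtype=float)
    mask = _roi_mask(img.shape, voxel_size, roi)
    if not mask.any():
        raise ValueError("empty ROI: radius below the voxel size or ROI outside image")
    return float(img[mask].mean() - background)


def per_cell_normalized(values):
    """Normalise ROI measurements of one cell to their mean."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m == 0:
        raise ValueError("cannot normalise: cell mean is zero")
    return v / m


def count_mad1_positive(mad1_channel, voxel_size, kt_positions_um, config: ROIConfig | None = None):
    """Count kinetochores with a quality-filtered Mad1 spot nearby.

    Spots are detected at the Mad1 scales (1.73 um xy, 3.47 um z) and kept
    if their mean intensity exceeds background mean + n sigma; a kinetochore
    is positive if a surviving spot lies within the match radius.  Returns
    ``(count, fraction)`` over all kinetochores.
    """
    cfg = config or ROIConfig()
    img = np.asarray(mad1_channel, dtype=float)
    kts = np.atleast_2d(np.asarray(kt_positions_um, dtype=float))
    spots = detect_spots(img, voxel_size, cfg.mad1_xy_diam_um, cfg.mad1_z_diam_um,
                         quality_threshold=0.05)
    if len(spots) == 0 or len(kts) == 0:
        return 0, 0.0
    bg = np.median(img)
    sd = img[img <= np.percentile(img, 90)].std()
    thr = bg + cfg.mad1_quality_nsigma * sd
    spots = spots[spots["intensity"] > thr]
    if len(spots) == 0:
        return 0, 0.0
    sp = spots[["z_um", "y_um", "x_um"]].to_numpy()
    d = np.linalg.norm(kts[:, None, :] - sp[None, :, :], axis=2).min(axis=1)
    count = int((d <= cfg.mad1_match_radius_um).sum())
    return count, count / len(kts)


def classify_telomere_proximity(kt_pair, telomere_centroids, config: ROIConfig | None = None):
    """'proximal' iff any telomere lies within the proximity radius of either
    sister kinetochore."""
    cfg = config or ROIConfig()
    kts = np.atleast_2d(np.asarray(kt_pair, dtype=float))
    telos = np.atleast_2d(np.asarray(telomere_centroids, dtype=float))
    if telos.size == 0:
        return "non_proximal"
    d = np.linalg.norm(kts[:, None, :] - telos[None, :, :], axis=2).min()
    return "proximal" if d <= cfg.telomere_proximity_radius_um else "non_proximal"


def classify_telomere_masking(kt_pair_centroid, telomere_centroid, pole_direction, plate_side_sign):
    """'masked' iff the telomere centre of mass is shifted poleward of the
    sister-kinetochore pair; 'exposed' if shifted toward the spindle centre.

    ``pole_direction`` is the (axial) spindle direction; ``plate_side_sign``
    selects which pole this pair faces.  Zero displacement classifies as
    exposed.
    """
    poleward = normalize_axis(pole_direction) * float(np.sign(plate_side_sign) or 1.0)
    disp = float(np.dot(np.asarray(telomere_centroid, dtype=float)
                        - np.asarray(kt_pair_centroid, dtype=float), poleward))
    return "masked" if disp > 0 else "exposed"


def separation_times(times_min, classes=None):
    """Separation times relative to the egg's first event.

    Returns ``(relative_times, first_class)``; ``first_class`` is None when
    no classes are supplied.
    """
    t = np.asarray(times_min, dtype=float)
    if t.size == 0:
        raise ValueError("no separation events")
    i0 = int(np.argmin(t))
    rel = t - t[i0]
    first = None if classes is None else list(classes)[i0]
    return rel, first


def gv_nucleus_distances(spots_um, background_channel, voxel_size):
    """Distances of TALE spots from the nucleus centre.

    The nucleus is segmented by Otsu thresholding of the *inverted*
    background (cytoplasmic TALE) channel — the nucleus excludes the
    diffuse label, so it is bright after inversion; its centre is the mask
    centroid.
    """
    img = np.asarray(background_channel, dtype=float)
    if img.max() == img.min():
        raise EmptyForegroundError("flat background channel")
    inv = img.max() - img
    mask = inv > threshold_otsu(inv)
    if not mask.any():
        raise EmptyForegroundError("nucleus segmentation empty")
    vs = np.asarray(voxel_size, dtype=float)
    center = (np.asarray(ndimage.center_of_mass(mask)) + 0.5) * vs
    spots = np.atleast_2d(np.asarray(spots_um, dtype=float))
    return np.linalg.norm(spots - center, axis=1), center
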