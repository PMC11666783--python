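"""Joint 3D kinetochore tracking and homologue pairing by integer programming.

A single mixed-integer linear programme selects, for every frame, a set of
homologous kinetochore *pairs* and, between adjacent frames, *links* that
connect the same bivalent over time — tracking and pairing are optimised
simultaneously rather than sequentially.

Decision variables
    x_p   binary: candidate pair p (two detections in one frame) is selected
    y_pq  binary: selected pair p (frame f) continues as pair q (frame f+1)
    s_f   continuous slack: shortfall below the expected number of pairs

Objective (minimised)
    sum_p c_p x_p + sum_pq m_pq y_pq + penalty * sum_f s_f

with per-pair cost
    c_p = -w_signal * line_mean + w_signal_var * line_var
          + w_angle * (1 - |cos|) + w_angle_dist * dist * (1 - |cos|)
(the line statistics are the DNA signal sampled between the putative
homologues; |cos| is the alignment of the pair axis with the current
spindle-axis estimate) and per-link motion cost
    m_pq = w_motion * (mean displacement of the two kinetochores)^2.

Constraints: each detection joins at most one selected pair; selected pairs
form frame-spanning tracks (each selected pair has exactly one successor /
predecessor where a next/previous frame exists); pair segments of
simultaneously selected pairs stay ``min_segment_sep`` apart (pairwise
exclusion on a precomputed conflict list); every detection lies within
``spot_coverage_radius`` of a selected kinetochore; every connected
component of the Otsu-segmented chromosome signal is near at least one
selected pair; per frame, ``n_pairs_expected`` minus the number of selected
pairs is charged ``missing_pair_penalty`` per missing pair.

The spindle axis is re-estimated from the previous iterate's pairs and the
solve repeated until the pairing set is stable (at most 5 iterations).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.optimize import Bounds, LinearConstraint, milp
from skimage.filters import threshold_otsu

from .errors import InfeasibleModelError, StitchError
from .geometry import alignment_dot, spindle_axis_from_pairs

__all__ = [
    "TrackingConfig",
    "BivalentTrackSet",
    "detect_spots",
    "line_signal_stats",
    "solve_joint_tracking",
    "brute_force_oracle",
    "stitch_batches",
]

DET_COLS = ["z_um", "y_um", "x_um"]


@dataclass
class TrackingConfig:
    n_pairs_expected: int = 19
    max_pair_dist: float = 3.0  # um, homologue separation cap
    max_step_dist: float = 1.5  # um per frame, per kinetochore
    min_segment_sep: float = 0.4  # um between selected pair segments
    w_motion: float = 1.0  # per um^2
    w_signal: float = 1.0
    w_signal_var: float = 0.1
    w_angle: float = 0.5
    w_angle_dist: float = 0.1  # per um
    missing_pair_penalty: float = 100.0
    spot_coverage_radius: float = 1.5  # um
    component_coverage_radius: float = 2.0  # um beyond component radius
    batch_size: int = 100
    batch_overlap: int = 2
    gap_tol: float = 1e-6
    max_iterations: int = 5
    line_samples: int = 15

    def __post_init__(self):
        if min(self.w_motion, self.w_signal, self.w_signal_var, self.w_angle,
               self.w_angle_dist, self.missing_pair_penalty) < 0:
            raise ValueError("weights and penalties must be non-negative")


@dataclass
class BivalentTrackSet:
    """Selected pairs per frame with frame-to-frame track identity."""

    pairs: pd.DataFrame  # frame, track_id, det1, det2, z1..x2, pair_cost, link_cost
    objective: float
    axis: np.ndarray | None = None
    n_iterations: int = 1
    config: TrackingConfig | None = None
    objective_history: list = field(default_factory=list)

    def n_pairs(self, frame):
        return int((self.pairs["frame"] == frame).sum())

    @property
    def frames(self):
        return sorted(self.pairs["frame"].unique())


# ---------------------------------------------------------------------------
# detection


def detect_spots(channel, voxel_size, expected_diameter_xy, expected_diameter_z,
                 quality_threshold=0.2, origin_um=None):
    """Scale-matched Laplacian-of-Gaussian spot detection with subvoxel refinement.

    The LoG scale per axis is ``diameter / (2 * sqrt(3))``; the response is
    scale-normalised by the geometric-mean sigma so a matched unit-amplitude
    Gaussian blob scores about 0.5.  Maxima above ``quality_threshold`` are
    refined by an intensity-weighted centroid in a sigma-sized window.

    Returns a DataFrame with columns z_um, y_um, x_um, intensity, quality.
    If ``origin_um`` is given, coordinates are expressed relative to it
    (e.g. the chromosome-mass centre).
    """
    if expected_diameter_xy <= 0 or expected_diameter_z <= 0:
        raise ValueError("expected diameters must be positive")
    img = np.asarray(channel, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    sig_um = np.array([expected_diameter_z, expected_diameter_xy, expected_diameter_xy]) / (2 * np.sqrt(3.0))
    sig_vox = sig_um / vs
    resp = -ndimage.gaussian_laplace(img, sig_vox) * float(np.prod(sig_vox) ** (2.0 / 3.0))
    size = np.maximum(3, (2 * np.ceil(sig_vox) + 1).astype(int))
    is_max = (resp == ndimage.maximum_filter(resp, size=size)) & (resp > quality_threshold)
    peaks = np.argwhere(is_max)
    rows = []
    win = np.ceil(sig_vox).astype(int)
    for pk in peaks:
        lo = np.maximum(pk - win, 0)
        hi = np.minimum(pk + win + 1, img.shape)
        patch = img[tuple(slice(l, h) for l, h in zip(lo, hi))]
        w = np.clip(patch - patch.min(), 0, None)
        if w.sum() == 0:
            centroid = pk.astype(float)
        else:
            grids = np.indices(patch.shape)
            centroid = lo + np.array([(g * w).sum() / w.sum() for g in grids])
        pos = (centroid + 0.5) * vs
        rows.append((*pos, float(img[tuple(pk)]), float(resp[tuple(pk)])))
    det = pd.DataFrame(rows, columns=[*DET_COLS, "intensity", "quality"])
    if origin_um is not None and len(det):
        det[DET_COLS] = det[DET_COLS].to_numpy() - np.asarray(origin_um, dtype=float)
    return det.sort_values(DET_COLS, ignore_index=True) if len(det) else det


def line_signal_stats(dna_channel, voxel_size, p, q, n_samples=15):
    """Mean and variance of the image sampled on the segment [p, q] (um).

    Trilinear interpolation at ``n_samples`` equispaced points including the
    endpoints.  Raises if the segment leaves the image.
    """
    img = np.asarray(dna_channel, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.allclose(p, q):
        raise ValueError("segment endpoints coincide")
    t = np.linspace(0.0, 1.0, n_samples)
    pts_um = p[None, :] + t[:, None] * (q - p)[None, :]
    pts_vox = pts_um / vs - 0.5
    if np.any(pts_vox < -0.5) or np.any(pts_vox > np.asarray(img.shape) - 0.5):
        raise ValueError("segment extends outside the image")
    vals = ndimage.map_coordinates(img, pts_vox.T, order=1, mode="nearest")
    return float(vals.mean()), float(vals.var())


# ---------------------------------------------------------------------------
# candidate model


def _segment_distance(p1, p2, q1, q2):
    """Minimum distance between 3D segments [p1,p2] and [q1,q2]."""
    u = p2 - p1
    v = q2 - q1
    w0 = p1 - q1
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w0, v @ w0
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    tt = (b * s + e) / c if c > 1e-12 else 0.0
    tt = np.clip(tt, 0.0, 1.0)
    # refine s given clamped t
    if a > 1e-12:
        s = np.clip((b * tt - d) / a, 0.0, 1.0)
    return float(np.linalg.norm(p1 + s * u - (q1 + tt * v)))


class _FramePairs:
    """Candidate pairs and their static features for one frame."""

    def __init__(self, frame, det_idx, det_pos, config, dna=None, voxel_size=None):
        self.frame = frame
        self.det_idx = det_idx  # global detection row indices
        self.det_pos = det_pos  # (n, 3) um
        n = len(det_pos)
        pairs, dists, means, varis = [], [], [], []
        for i, j in itertools.combinations(range(n), 2):
            d = np.linalg.norm(det_pos[i] - det_pos[j])
            if d > config.max_pair_dist or d == 0:
                continue
            if dna is not None:
                m, v = line_signal_stats(dna, voxel_size, det_pos[i], det_pos[j], config.line_samples)
            else:
                m, v = 0.0, 0.0
            pairs.append((i, j))
            dists.append(d)
            means.append(m)
            varis.append(v)
        self.pairs = pairs
        self.dist = np.asarray(dists)
        self.line_mean = np.asarray(means)
        self.line_var = np.asarray(varis)
        # conflicts: segments closer than min_segment_sep (disjoint pairs only)
        self.conflicts = []
        for a, b in itertools.combinations(range(len(pairs)), 2):
            ia, ja = pairs[a]
            ib, jb = pairs[b]
            if {ia, ja} & {ib, jb}:
                continue
            sep = _segment_distance(det_pos[ia], det_pos[ja], det_pos[ib], det_pos[jb])
            if sep < config.min_segment_sep:
                self.conflicts.append((a, b))
        # spot coverage: candidate pairs with an endpoint near each detection
        self.coverage = []
        for d_i in range(n):
            near = [
                k for k, (i, j) in enumerate(pairs)
                if min(np.linalg.norm(det_pos[d_i] - det_pos[i]),
                       np.linalg.norm(det_pos[d_i] - det_pos[j])) <= config.spot_coverage_radius
            ]
            self.coverage.append(near)

    def costs(self, config, axis):
        """Per-pair costs for the current spindle-axis estimate."""
        c = -config.w_signal * self.line_mean + config.w_signal_var * self.line_var
        if axis is not None and len(self.pairs):
            cosv = np.array([
                alignment_dot(self.det_pos[j] - self.det_pos[i], axis)
                for i, j in self.pairs
            ])
            c = c + config.w_angle * (1 - cosv) + config.w_angle_dist * self.dist * (1 - cosv)
        return np.asarray(c, dtype=float)

    def midpoints(self):
        return np.array([(self.det_pos[i] + self.det_pos[j]) / 2 for i, j in self.pairs]).reshape(-1, 3)


def _link_candidates(fp_a, fp_b, config):
    """Feasible links between pairs of adjacent frames, with motion costs."""
    links = []
    for a, (i, j) in enumerate(fp_a.pairs):
        pa, pb = fp_a.det_pos[i], fp_a.det_pos[j]
        for b, (k, l) in enumerate(fp_b.pairs):
            qa, qb = fp_b.det_pos[k], fp_b.det_pos[l]
            best = None
            for (m1, m2) in ((qa, qb), (qb, qa)):
                d1 = np.linalg.norm(pa - m1)
                d2 = np.linalg.norm(pb - m2)
                if d1 <= config.max_step_dist and d2 <= config.max_step_dist:
                    mean_d = (d1 + d2) / 2
                    if best is None or mean_d < best:
                        best = mean_d
            if best is not None:
                links.append((a, b, config.w_motion * best**2))
    return links


def _dna_components(dna, voxel_size):
    """Centroids and equivalent radii of Otsu components of the DNA signal."""
    img = np.asarray(dna, dtype=float)
    if img.max() == img.min():
        return []
    mask = img > threshold_otsu(img)
    lab, nlab = ndimage.label(mask)
    out = []
    vs = np.asarray(voxel_size, dtype=float)
    voxvol = float(np.prod(vs))
    for i in range(1, nlab + 1):
        idx = np.argwhere(lab == i)
        if len(idx) < 10:  # speckles are not chromosome mass
            continue
        centroid = (idx.mean(axis=0) + 0.5) * vs
        radius = (3 * len(idx) * voxvol / (4 * np.pi)) ** (1 / 3)
        out.append((centroid, radius))
    return out


def _plate_normal_axis(df, frames):
    """Initial spindle-axis estimate: the minimum-variance principal axis of
    the per-frame-centred detection cloud (the plate normal)."""
    centred = []
    for f in frames:
        pos = df.loc[df["frame"] == f, DET_COLS].to_numpy()
        if len(pos):
            centred.append(pos - pos.mean(axis=0))
    pts = np.concatenate(centred, axis=0)
    if len(pts) < 3:
        return None
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] - evals[0] <= 1e-12:
        return None
    return evecs[:, 0]


def _group_detections(detections):
    df = detections.copy()
    if "frame" not in df.columns:
        df["frame"] = 0
    frames = sorted(df["frame"].unique())
    return df, frames


def _build_and_solve(frame_pairs, links_by_gap, costs_by_frame, config,
                     comp_cover=None):
    """Assemble and solve one MILP instance; returns (status, x, y, s, objective)."""
    nF = len(frame_pairs)
    nP = [len(fp.pairs) for fp in frame_pairs]
    offP = np.concatenate([[0], np.cumsum(nP)])
    nL = [len(l) for l in links_by_gap]
    offL = np.concatenate([[0], np.cumsum(nL)]) + offP[-1]
    n_slack = nF
    off_s = offL[-1] if nF > 1 else offP[-1]
    nvar = off_s + n_slack

    c = np.zeros(nvar)
    for f, fp in enumerate(frame_pairs):
        cc = costs_by_frame[f]
        # tiny lexicographic perturbation for deterministic tie-breaking
        c[offP[f]:offP[f + 1]] = cc + 1e-9 * np.arange(len(cc))
    for g, links in enumerate(links_by_gap):
        for li, (_, _, lc) in enumerate(links):
            c[offL[g] + li] = lc
    c[off_s:] = config.missing_pair_penalty

    rows, cols, vals, lb, ub = [], [], [], [], []
    r = 0

    def add_row(entries, lo, hi):
        nonlocal r
        for col, val in entries:
            rows.append(r)
            cols.append(col)
            vals.append(val)
        lb.append(lo)
        ub.append(hi)
        r += 1

    for f, fp in enumerate(frame_pairs):
        # each detection in at most one selected pair
        for d_i in range(len(fp.det_pos)):
            members = [k for k, (i, j) in enumerate(fp.pairs) if d_i in (i, j)]
            if members:
                add_row([(offP[f] + k, 1.0) for k in members], -np.inf, 1.0)
        # pair count + slack = expected
        add_row([(offP[f] + k, 1.0) for k in range(nP[f])] + [(off_s + f, 1.0)],
                config.n_pairs_expected, config.n_pairs_expected)
        # segment-separation conflicts
        for a, b in fp.conflicts:
            add_row([(offP[f] + a, 1.0), (offP[f] + b, 1.0)], -np.inf, 1.0)
        # spot coverage
        for near in fp.coverage:
            if near:
                add_row([(offP[f] + k, 1.0) for k in near], 1.0, np.inf)
            else:
                return "infeasible-coverage", None, None, None, None
        # chromatin-component coverage
        if comp_cover is not None and comp_cover[f]:
            mids = fp.midpoints()
            for centroid, radius in comp_cover[f]:
                near = [
                    k for k in range(nP[f])
                    if np.linalg.norm(mids[k] - centroid) <= radius + config.component_coverage_radius
                ]
                if near:
                    add_row([(offP[f] + k, 1.0) for k in near], 1.0, np.inf)
                else:
                    return "infeasible-component", None, None, None, None

    # link consistency: selected pairs continue across frames
    for g, links in enumerate(links_by_gap):
        out_of = [[] for _ in range(nP[g])]
        in_of = [[] for _ in range(nP[g + 1])]
        for li, (a, b, _) in enumerate(links):
            out_of[a].append(offL[g] + li)
            in_of[b].append(offL[g] + li)
            add_row([(offL[g] + li, 1.0), (offP[g] + a, -1.0)], -np.inf, 0.0)
            add_row([(offL[g] + li, 1.0), (offP[g + 1] + b, -1.0)], -np.inf, 0.0)
        for a in range(nP[g]):
            add_row([(col, 1.0) for col in out_of[a]] + [(offP[g] + a, -1.0)], 0.0, 0.0)
        for b in range(nP[g + 1]):
            add_row([(col, 1.0) for col in in_of[b]] + [(offP[g + 1] + b, -1.0)], 0.0, 0.0)

    A = sparse.csr_matrix((vals, (rows, cols)), shape=(r, nvar))
    integrality = np.ones(nvar)
    integrality[off_s:] = 0
    ubv = np.ones(nvar)
    ubv[off_s:] = config.n_pairs_expected
    res = milp(
        c=c,
        constraints=LinearConstraint(A, np.asarray(lb), np.asarray(ub)),
        integrality=integrality,
        bounds=Bounds(np.zeros(nvar), ubv),
        options={"mip_rel_gap": config.gap_tol},
    )
    if res.status == 2:
        return "infeasible", None, None, None, None
    if res.status != 0 or res.x is None:
        raise InfeasibleModelError(
            f"MILP solver did not converge (status {res.status}: {res.message})"
        )
    x = [np.round(res.x[offP[f]:offP[f + 1]]).astype(int) for f in range(nF)]
    y = [np.round(res.x[offL[g]:offL[g] + nL[g]]).astype(int) for g in range(len(links_by_gap))]
    s = res.x[off_s:]
    return "optimal", x, y, s, float(res.fun)


def _extract_tracks(frame_pairs, links_by_gap, x, y, costs_by_frame, frames, config):
    """Assemble the selected pairs + links into a track table."""
    track_of = {}
    next_track = 0
    rows = []
    for f, fp in enumerate(frame_pairs):
        for k in np.flatnonzero(x[f]):
            key = (f, k)
            if key not in track_of:
                track_of[key] = next_track
                next_track += 1
        if f < len(links_by_gap):
            for li in np.flatnonzero(y[f]):
                a, b, _ = links_by_gap[f][li]
                track_of[(f + 1, b)] = track_of[(f, a)]
    link_cost_of = {}
    for g, links in enumerate(links_by_gap):
        for li in np.flatnonzero(y[g]):
            a, b, lc = links[li]
            link_cost_of[(g + 1, b)] = lc
    for f, fp in enumerate(frame_pairs):
        for k in np.flatnonzero(x[f]):
            i, j = fp.pairs[k]
            p, q = fp.det_pos[i], fp.det_pos[j]
            rows.append(
                dict(
                    frame=frames[f],
                    track_id=track_of[(f, k)],
                    det1=int(fp.det_idx[i]),
                    det2=int(fp.det_idx[j]),
                    z1=p[0], y1=p[1], x1=p[2],
                    z2=q[0], y2=q[1], x2=q[2],
                    pair_cost=float(costs_by_frame[f][k]),
                    link_cost=float(link_cost_of.get((f, k), np.nan)),
                )
            )
    return pd.DataFrame(rows)


def solve_joint_tracking(detections, config: TrackingConfig | None = None,
                         dna_by_frame=None, voxel_size=None, initial_axis=None):
    """Jointly select homologous pairs and tracks minimising the MILP objective.

    Parameters
    ----------
    detections : DataFrame with columns frame, z_um, y_um, x_um
    config : TrackingConfig
    dna_by_frame : optional mapping frame -> DNA channel voxel image, used for
        line-signal costs and chromatin-component coverage constraints
    voxel_size : (z, y, x) um, required when ``dna_by_frame`` is given
    initial_axis : optional spindle-axis seed; when None the first solve runs
        without angle costs and the axis is estimated from its pairing
    """
    config = config or TrackingConfig()
    df, frames = _group_detections(detections)
    if not frames:
        raise ValueError("no detections")
    frame_pairs = []
    comp_cover = [] if dna_by_frame is not None else None
    for f in frames:
        sub = df[df["frame"] == f]
        dna = dna_by_frame.get(f) if dna_by_frame is not None else None
        fp = _FramePairs(f, sub.index.to_numpy(), sub[DET_COLS].to_numpy(), config,
                         dna=dna, voxel_size=voxel_size)
        frame_pairs.append(fp)
        if comp_cover is not None:
            comp_cover.append(_dna_components(dna, voxel_size) if dna is not None else [])
    links_by_gap = [
        _link_candidates(frame_pairs[g], frame_pairs[g + 1], config)
        for g in range(len(frames) - 1)
    ]

    if initial_axis is not None:
        axis = np.asarray(initial_axis, dtype=float)
    else:
        # the metaphase plate is a disk perpendicular to the spindle, so the
        # smallest principal axis of the detection cloud seeds the estimate
        axis = _plate_normal_axis(df, frames)
    prev_sel = None
    objective = np.nan
    history = []
    for it in range(1, config.max_iterations + 1):
        costs_by_frame = [fp.costs(config, axis) for fp in frame_pairs]
        status, x, y, s, objective = _build_and_solve(
            frame_pairs, links_by_gap, costs_by_frame, config, comp_cover
        )
        if status != "optimal":
            family = {
                "infeasible-coverage": "spot-coverage",
                "infeasible-component": "chromatin-component coverage",
                "infeasible": "pair/link constraint system",
            }[status]
            raise InfeasibleModelError(f"infeasible tracking model: {family} constraints")
        history.append(objective)
        sel = tuple(tuple(np.flatnonzero(xx)) for xx in x)
        pair_pts = [
            (fp.det_pos[i], fp.det_pos[j])
            for f, fp in enumerate(frame_pairs)
            for k in np.flatnonzero(x[f])
            for i, j in [fp.pairs[k]]
        ]
        if sel == prev_sel:
            break
        prev_sel = sel
        if pair_pts:
            try:
                axis = spindle_axis_from_pairs(pair_pts)
            except Exception:
                axis = axis  # keep previous estimate if degenerate
        else:
            break
    tracks = _extract_tracks(frame_pairs, links_by_gap, x, y, costs_by_frame, frames, config)
    return BivalentTrackSet(tracks, objective, axis=axis, n_iterations=it, config=config,
                            objective_history=history)


# ---------------------------------------------------------------------------
# exhaustive oracle


def brute_force_oracle(detections, config: TrackingConfig | None = None,
                       dna_by_frame=None, voxel_size=None, axis=None):
    """Exhaustively enumerate all feasible pairings and linkings.

    Same objective as :func:`solve_joint_tracking` with a fixed spindle
    axis (no iterative refinement).  Guarded to at most 8 detections per
    frame and 3 frames.
    """
    config = config or TrackingConfig()
    df, frames = _group_detections(detections)
    if len(frames) > 3:
        raise ValueError("oracle limited to 3 frames")
    frame_pairs = []
    comp_cover = [] if dna_by_frame is not None else None
    for f in frames:
        sub = df[df["frame"] == f]
        if len(sub) > 8:
            raise ValueError("oracle limited to 8 detections (4 pairs) per frame")
        fp = _FramePairs(f, sub.index.to_numpy(), sub[DET_COLS].to_numpy(), config,
                         dna=dna_by_frame.get(f) if dna_by_frame else None,
                         voxel_size=voxel_size)
        frame_pairs.append(fp)
        if comp_cover is not None:
            comp_cover.append(_dna_components(dna_by_frame.get(f), voxel_size)
                              if dna_by_frame.get(f) is not None else [])
    costs_by_frame = [fp.costs(config, axis) for fp in frame_pairs]
    link_maps = []
    for g in range(len(frames) - 1):
        lm = {}
        for a, b, lc in _link_candidates(frame_pairs[g], frame_pairs[g + 1], config):
            lm[(a, b)] = lc
        link_maps.append(lm)

    def feasible_subsets(f):
        fp = frame_pairs[f]
        npair = len(fp.pairs)
        mids = fp.midpoints()
        subs = []
        for rsize in range(min(npair, config.n_pairs_expected) + 1):
            for combo in itertools.combinations(range(npair), rsize):
                used = set()
                ok = True
                for k in combo:
                    i, j = fp.pairs[k]
                    if i in used or j in used:
                        ok = False
                        break
                    used.update((i, j))
                if not ok:
                    continue
                if any(a in combo and b in combo for a, b in fp.conflicts):
                    continue
                if any(not (set(near) & set(combo)) for near in fp.coverage):
                    continue
                if comp_cover is not None:
                    bad = False
                    for centroid, radius in comp_cover[f]:
                        if not any(
                            np.linalg.norm(mids[k] - centroid) <= radius + config.component_coverage_radius
                            for k in combo
                        ):
                            bad = True
                            break
                    if bad:
                        continue
                subs.append(combo)
        return subs

    all_subs = [feasible_subsets(f) for f in range(len(frames))]
    if any(not s for s in all_subs):
        raise InfeasibleModelError("oracle: no feasible pairing in some frame")

    best = (np.inf, None, None)
    for choice in itertools.product(*all_subs):
        sizes = {len(c) for c in choice}
        if len(sizes) > 1:
            continue  # continuity forces equal pair counts across frames
        k = sizes.pop()
        base = sum(costs_by_frame[f][list(c)].sum() for f, c in enumerate(choice))
        base += config.missing_pair_penalty * (config.n_pairs_expected - k) * len(frames)
        # enumerate bijections between consecutive frames
        def match_cost(g, perm):
            tot = 0.0
            for a, b in zip(choice[g], perm):
                lc = link_maps[g].get((a, b))
                if lc is None:
                    return None
                tot += lc
            return tot

        if len(frames) == 1:
            if base < best[0]:
                best = (base, choice, ())
            continue
        for perms in itertools.product(*[itertools.permutations(choice[g + 1]) for g in range(len(frames) - 1)]):
            tot = base
            ok = True
            for g, perm in enumerate(perms):
                mc = match_cost(g, perm)
                if mc is None:
                    ok = False
                    break
                tot += mc
            if ok and tot < best[0]:
                best = (tot, choice, perms)

    if best[1] is None:
        raise InfeasibleModelError("oracle: no feasible linking")
    obj, choice, perms = best
    rows = []
    track_of = {}
    next_track = 0
    for f, combo in enumerate(choice):
        for k in combo:
            if (f, k) not in track_of:
                track_of[(f, k)] = next_track
                next_track += 1
        if f < len(perms):
            for a, b in zip(combo, perms[f]):
                track_of[(f + 1, b)] = track_of[(f, a)]
    for f, combo in enumerate(choice):
        fp = frame_pairs[f]
        for k in combo:
            i, j = fp.pairs[k]
            p, q = fp.det_pos[i], fp.det_pos[j]
            rows.append(dict(frame=frames[f], track_id=track_of[(f, k)],
                             det1=int(fp.det_idx[i]), det2=int(fp.det_idx[j]),
                             z1=p[0], y1=p[1], x1=p[2], z2=q[0], y2=q[1], x2=q[2],
                             pair_cost=float(costs_by_frame[f][k]), link_cost=np.nan))
    return BivalentTrackSet(pd.DataFrame(rows), float(obj), axis=axis, config=config)


# ---------------------------------------------------------------------------
# batching


def solve_in_batches(detections, config: TrackingConfig | None = None, **kw):
    """Split a long series into overlapping batches, solve each, and stitch."""
    config = config or TrackingConfig()
    df, frames = _group_detections(detections)
    if len(frames) <= config.batch_size:
        return solve_joint_tracking(df, config, **kw)
    sols = []
    start = 0
    while start < len(frames):
        stop = min(start + config.batch_size, len(frames))
        batch = frames[start:stop]
        sols.append(solve_joint_tracking(df[df["frame"].isin(batch)], config, **kw))
        if stop == len(frames):
            break
        start = stop - config.batch_overlap
    return stitch_batches(sols, config)


def stitch_batches(solutions, config: TrackingConfig | None = None, match_dist=None):
    """Unify track ids of batch solutions through their overlap frames.

    Pairs in the first shared frame are matched by mutual nearest midpoints
    (within ``match_dist``, default ``max_step_dist``); the overlap frames
    keep the earlier batch's solution and double-counted costs are removed
    from the summed objective.
    """
    if not solutions:
        raise ValueError("no solutions to stitch")
    config = config or solutions[0].config or TrackingConfig()
    if match_dist is None:
        match_dist = config.max_step_dist
    out = solutions[0].pairs.copy()
    objective = solutions[0].objective
    next_track = out["track_id"].max() + 1 if len(out) else 0
    for sol in solutions[1:]:
        prev_frames = set(out["frame"])
        cur = sol.pairs.copy()
        overlap = sorted(prev_frames & set(cur["frame"]))
        if not overlap:
            raise StitchError("batches share no overlap frame")
        f0 = overlap[0]
        a = out[out["frame"] == f0]
        b = cur[cur["frame"] == f0]
        am = np.stack([a[["z1", "y1", "x1"]].to_numpy(), a[["z2", "y2", "x2"]].to_numpy()]).mean(axis=0)
        bm = np.stack([b[["z1", "y1", "x1"]].to_numpy(), b[["z2", "y2", "x2"]].to_numpy()]).mean(axis=0)
        dmat = np.linalg.norm(am[:, None, :] - bm[None, :, :], axis=2)
        mapping = {}
        conflicts = []
        for bi in range(len(bm)):
            ai = int(np.argmin(dmat[:, bi])) if len(am) else -1
            if ai < 0 or dmat[ai, bi] > match_dist or int(np.argmin(dmat[ai, :])) != bi:
                conflicts.append(int(b.iloc[bi]["track_id"]))
                continue
            mapping[int(b.iloc[bi]["track_id"])] = int(a.iloc[ai]["track_id"])
        if conflicts:
            raise StitchError(f"ambiguous overlap matching for batch tracks {sorted(set(conflicts))}")
        objective += sol.objective
        # remove double-counted overlap-frame terms from the second batch
        dup = cur[cur["frame"].isin(overlap)]
        objective -= float(dup["pair_cost"].sum())
        objective -= float(dup[dup["frame"] > min(overlap)]["link_cost"].fillna(0).sum())
        for f in overlap:
            k = int((cur["frame"] == f).sum())
            objective -= config.missing_pair_penalty * (config.n_pairs_expected - k)
        keep = cur[~cur["frame"].isin(prev_frames)].copy()
        new_ids = {}
        remapped = []
        for tid in keep["track_id"]:
            tid = int(tid)
            if tid in mapping:
                remapped.append(mapping[tid])
            else:
                if tid not in new_ids:
                    new_ids[tid] = next_track
                    next_track += 1
                remapped.append(new_ids[tid])
        keep["track_id"] = remapped
        out = pd.concat([out, keep], ignore_index=True)
        next_track = max(next_track, out["track_id"].max() + 1)
    return BivalentTrackSet(out.sort_values(["frame", "track_id"], ignore_index=True),
                            float(objective), axis=solutions[-1].axis, config=config)
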