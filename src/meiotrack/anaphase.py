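"""Alignment over time, anaphase-onset detection, lagging and ploidy calls.

Times are minutes relative to anaphase onset; the "centre of the spindle"
is operationalised as the zone within ``central_zone_fraction`` of the
inter-mass distance around the midplane between the two separating
chromosome masses.  Lagging is classified from exactly two probe times
(12 and 20 min after onset, snapped to the nearest acquired frame):
severe if the chromosome is still central at 20 min, mild if central at
12 min but not severe, none otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SpindleFrameModel, chromosome_mass_center, distance_from_plate, spindle_axis_from_pairs

__all__ = [
    "LaggingConfig",
    "PloidyConfig",
    "OutcomeRecord",
    "bivalent_plate_distances",
    "dna_axis_profile",
    "detect_anaphase_onset",
    "classify_lagging",
    "classify_segregation_outcome",
    "call_ploidy",
]


@dataclass
class LaggingConfig:
    t_mild_min: float = 12.0
    t_severe_min: float = 20.0
    frame_interval_min: float = 4.0
    central_zone_fraction: float = 0.25

    def __post_init__(self):
        if not (self.t_severe_min > self.t_mild_min > 0):
            raise ValueError("need t_severe > t_mild > 0")
        if not (0 < self.central_zone_fraction < 0.5):
            raise ValueError("central zone fraction must be in (0, 0.5)")


@dataclass
class PloidyConfig:
    expected_kinetochores: int = 38

    def __post_init__(self):
        if self.expected_kinetochores <= 0 or self.expected_kinetochores % 2:
            raise ValueError("expected kinetochore count must be a positive even integer")


@dataclass
class OutcomeRecord:
    chromosome_id: int
    centromere_class: str
    label: str
    fate: str  # correct | missegregation_misalignment | missegregation_lagging
    lagging: str  # none | mild | severe


def bivalent_plate_distances(tracks, dna_by_frame=None, voxel_size=None, sigma_um=0.5):
    """Per-frame distance of each bivalent midpoint from the metaphase plate.

    The spindle axis is re-estimated each frame from the tracked pairs and
    the plate centre from the blurred/Otsu-weighted chromosome mass (or, if
    no DNA image is supplied, from the mean pair midpoint).  Frames with
    fewer than 3 pairs are flagged axis-unreliable.
    """
    df = tracks.pairs
    if df.empty:
        raise ValueError("no tracked pairs")
    out = []
    for f, sub in df.groupby("frame"):
        p1 = sub[["z1", "y1", "x1"]].to_numpy()
        p2 = sub[["z2", "y2", "x2"]].to_numpy()
        pairs = list(zip(p1, p2))
        axis = spindle_axis_from_pairs(pairs)
        reliable = len(pairs) >= 3
        if dna_by_frame is not None and f in dna_by_frame:
            center = chromosome_mass_center(dna_by_frame[f], voxel_size, sigma_um)
        else:
            center = ((p1 + p2) / 2.0).mean(axis=0)
        model = SpindleFrameModel(axis, center)
        mids = (p1 + p2) / 2.0
        for (_, row), m in zip(sub.iterrows(), mids):
            out.append(
                dict(frame=f, track_id=int(row["track_id"]),
                     distance_um=distance_from_plate(m, model),
                     axis_reliable=reliable)
            )
    return pd.DataFrame(out)


def dna_axis_profile(dna_channel, voxel_size, axis, bin_um=0.4):
    """1D intensity profile of the DNA channel projected on the spindle axis."""
    img = np.asarray(dna_channel, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(img.shape, vs)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij", sparse=True)
    s = zz * axis[0] + yy * axis[1] + xx * axis[2]
    s = np.broadcast_to(s, img.shape).ravel()
    w = np.clip(img, 0, None).ravel()
    lo, hi = s.min(), s.max()
    nbins = max(int(np.ceil((hi - lo) / bin_um)), 2)
    prof, edges = np.histogram(s, bins=nbins, range=(lo, hi), weights=w)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, prof


def _is_bimodal(prof, bin_um, min_gap_um=0.8, depth=0.5):
    """A gap of >= min_gap_um where the profile drops below ``depth`` of both
    flanking maxima indicates two separating chromosome masses."""
    n = len(prof)
    if n < 3:
        return False
    prefix = np.maximum.accumulate(prof)
    suffix = np.maximum.accumulate(prof[::-1])[::-1]
    peak = prof.max()
    valid = np.zeros(n, bool)
    for i in range(1, n - 1):
        left, right = prefix[i - 1], suffix[i + 1]
        if left > 0.2 * peak and right > 0.2 * peak and prof[i] < depth * min(left, right):
            valid[i] = True
    run = 0
    need = int(np.ceil(min_gap_um / bin_um))
    for v in valid:
        run = run + 1 if v else 0
        if run >= need:
            return True
    return False


def detect_anaphase_onset(dna_by_frame, voxel_size, axis, bin_um=0.4,
                          min_gap_um=0.8, depth=0.5):
    """First frame whose axial DNA profile splits into two masses.

    Returns the frame index, or ``None`` if no frame shows an inter-mass
    gap (profile minimum below ``depth`` of both flanking maxima over at
    least ``min_gap_um``).
    """
    for f in sorted(dna_by_frame):
        _, prof = dna_axis_profile(dna_by_frame[f], voxel_size, axis, bin_um)
        if _is_bimodal(prof, bin_um, min_gap_um, depth):
            return f
    return None


def _probe_frame(onset_frame, t_min, interval, available):
    f = onset_frame + int(round(t_min / interval))
    if f not in available:
        raise ValueError(f"frame at onset+{t_min} min (frame {f}) not acquired")
    return f


def classify_lagging(positions_by_frame, masses, onset_frame, config: LaggingConfig | None = None):
    """Classify a chromosome as none/mild/severe lagging from two probe frames.

    Parameters
    ----------
    positions_by_frame : mapping frame -> axial coordinate (um) of the
        chromosome (its kinetochore position projected on the spindle axis)
    masses : DataFrame with columns frame, mass_neg, mass_pos (axial
        coordinates of the two separating chromosome masses)
    onset_frame : anaphase onset frame index
    """
    cfg = config or LaggingConfig()
    masses = masses.set_index("frame") if "frame" in getattr(masses, "columns", []) else masses
    available = set(positions_by_frame) & set(masses.index)

    def central(f):
        m = masses.loc[f]
        mid = (m["mass_neg"] + m["mass_pos"]) / 2
        dist = m["mass_pos"] - m["mass_neg"]
        return abs(positions_by_frame[f] - mid) < cfg.central_zone_fraction * dist

    f12 = _probe_frame(onset_frame, cfg.t_mild_min, cfg.frame_interval_min, available)
    f20 = _probe_frame(onset_frame, cfg.t_severe_min, cfg.frame_interval_min, available)
    if central(f20):
        return "severe"
    if central(f12):
        return "mild"
    return "none"


def classify_segregation_outcome(track_s1, track_s2, masses, onset_frame,
                                 lagging, plate_distance_at_onset,
                                 misalign_threshold_um=3.0,
                                 config: LaggingConfig | None = None):
    """Final segregation outcome of a bivalent.

    ``track_s1``/``track_s2`` are the two homologues' axial coordinates per
    frame.  Missegregation-by-misalignment: severely misaligned at onset
    (plate distance above threshold) and both homologues finish on one side
    of the inter-mass midplane.  Missegregation-by-lagging: severe lagging
    with both homologues finishing on one side.  Otherwise correct.
    """
    masses = masses.set_index("frame") if "frame" in getattr(masses, "columns", []) else masses
    common = sorted(set(track_s1) & set(track_s2) & set(masses.index))
    if not common or common[-1] <= onset_frame:
        raise ValueError("trace truncated before anaphase completion")
    fend = common[-1]
    m = masses.loc[fend]
    mid = (m["mass_neg"] + m["mass_pos"]) / 2
    same_side = (track_s1[fend] - mid) * (track_s2[fend] - mid) > 0
    if plate_distance_at_onset > misalign_threshold_um and same_side:
        return "missegregation_misalignment"
    if lagging == "severe" and same_side:
        return "missegregation_lagging"
    return "correct"


def call_ploidy(kinetochore_count, config: PloidyConfig | None = None):
    """Euploid iff exactly the expected number of kinetochores is detected."""
    cfg = config or PloidyConfig()
    if kinetochore_count < 0:
        raise ValueError("count must be non-negative")
    return "euploid" if int(kinetochore_count) == cfg.expected_kinetochores else "aneuploid"
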