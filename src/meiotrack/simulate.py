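"""Ground-truthed synthetic oocyte scenes.

This module generates the statistical structure observed in porcine (and,
for kinetochore masking, human) oocyte meiosis:

* a karyotype of 19 bivalents (6 acrocentric, 13 metacentric; human mode:
  23 bivalents, 5 acrocentric) with optional pericentromeric TALE labelling;
* metaphase-I congression trajectories in which acrocentric bivalents sit on
  average ~1 um further from the metaphase plate than metacentric ones;
* anaphase-I fates with class-conditional missegregation (8% acrocentric,
  1% metacentric) split between severe misalignment and severe lagging, and
  mild/severe lagging rates at 4x / 6x acro:meta risk ratios;
* metaphase-II sister pairs with class-conditional interkinetochore
  distances (1.09 +/- 0.18 um acrocentric, 0.96 +/- 0.13 um metacentric,
  0.97 +/- 0.11 um meta-labelled) and lower cohesin on acrocentrics;
* telomere placement that masks 20% (porcine) or 38% (human) of acrocentric
  kinetochore pairs poleward;
* cohesin-depletion (Trim-Away) separation times with hazard decreasing in
  cohesin level;
* volumetric rendering of every channel as Gaussian blobs with a Gaussian
  PSF folded in, plus Poisson and Gaussian read noise.

Every stochastic operation is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import MeiotrackError

__all__ = [
    "Chromosome",
    "KaryotypeModel",
    "SceneConfig",
    "GroundTruth",
    "RenderedScene",
    "make_karyotype",
    "simulate_congression",
    "simulate_anaphase",
    "simulate_mii_egg",
    "simulate_trimaway",
    "place_telomeres",
    "render_scene",
]

POINT_COLS = ["z_um", "y_um", "x_um"]

# spindle axis of all synthetic scenes: the array x-axis
SPINDLE_AXIS = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class Chromosome:
    id: int
    centromere_class: str  # 'acro' | 'meta'
    size_scale: float
    tale_labelled: bool


@dataclass(frozen=True)
class KaryotypeModel:
    species: str
    labelling_mode: str
    chromosomes: tuple

    @property
    def n(self):
        return len(self.chromosomes)

    def as_frame(self):
        rows = []
        for c in self.chromosomes:
            if c.tale_labelled:
                label = "acro_labelled" if c.centromere_class == "acro" else "meta_labelled"
            else:
                label = "meta" if c.centromere_class == "meta" else "unlabelled"
            rows.append(
                dict(
                    chromosome_id=c.id,
                    centromere_class=c.centromere_class,
                    label=label,
                    size_scale=c.size_scale,
                    tale_labelled=c.tale_labelled,
                )
            )
        return pd.DataFrame(rows)


def make_karyotype(species="porcine", labelling_mode="acro"):
    """Build the chromosome complement for a species and TALE labelling mode.

    Porcine: 19 bivalents, 6 acrocentric and 13 metacentric.  The
    acrocentric TALE labels all 6 acrocentrics; the metacentric TALE labels
    6 of the 13 metacentrics.  Human: 23 bivalents, 5 acrocentric
    (13-15, 21, 22); labelling modes are accepted for API symmetry but human
    analyses here use telomere proximity, not TALEs.
    """
    if species == "porcine":
        n_meta, n_acro = 13, 6
    elif species == "human":
        n_meta, n_acro = 18, 5
    else:
        raise ValueError(f"unknown species {species!r}")
    if labelling_mode not in ("acro", "meta", "both", "none"):
        raise ValueError(f"unknown labelling mode {labelling_mode!r}")

    meta_sizes = np.linspace(1.4, 0.7, n_meta)
    # acrocentrics split into a large and a small group
    acro_sizes = np.array([1.0] * (n_acro - n_acro // 2) + [0.6] * (n_acro // 2))
    chroms = []
    for i in range(n_meta):
        labelled = labelling_mode in ("meta", "both") and i < 6
        chroms.append(Chromosome(i + 1, "meta", float(meta_sizes[i]), labelled))
    for j in range(n_acro):
        labelled = labelling_mode in ("acro", "both")
        chroms.append(Chromosome(n_meta + j + 1, "acro", float(acro_sizes[j]), labelled))
    return KaryotypeModel(species, labelling_mode, tuple(chroms))


def _default_misseg():
    return {"acro": 0.08, "meta": 0.01}


def _default_lag_mild():
    # absolute rates chosen so the acro:meta risk ratio is 4
    return {"acro": 0.12, "meta": 0.03}


def _default_lag_severe():
    # absolute rates chosen so the acro:meta risk ratio is 6
    return {"acro": 0.06, "meta": 0.01}


def _default_ikd():
    return {
        "acro_labelled": (1.09, 0.18),
        "meta": (0.96, 0.13),
        "meta_labelled": (0.97, 0.11),
        "unlabelled": (0.96, 0.13),
    }


def _default_masked():
    return {"porcine": 0.20, "human": 0.38, "early": 0.26, "late": 0.14}


@dataclass
class SceneConfig:
    """All tunable parameters of the synthetic scene generator.

    Defaults encode the study conditions; see the methods note for the
    provenance of each value.
    """

    stage: str = "metaphase_I"
    labelling_mode: str = "acro"
    species: str = "porcine"
    seed: int = 0

    # imaging geometry (z, y, x)
    voxel_size_um: tuple = (0.32, 0.1, 0.1)
    shape: tuple = (48, 168, 168)
    psf_sigma_um: tuple = (0.35, 0.13, 0.13)

    # noise model
    noise: bool = True
    poisson_gain: float = 200.0  # photons per unit intensity
    read_noise_sigma: float = 0.01  # Gaussian read noise, intensity units

    # time sampling
    frame_interval_min: float = 4.0
    n_frames: int = 12
    onset_frame: int = 2  # anaphase onset (anaphase stage)

    # metaphase-I congression (OU relaxation toward the plate)
    plate_offset_um: float = 1.0  # extra stationary acro plate distance
    ou_tau_min: float = 8.0
    ou_sigma_um: float = 0.25  # stationary axial SD
    transverse_sigma_um: float = 0.1
    pair_dist_um: tuple = (2.0, 0.15)  # inter-homologue distance mean, SD
    pair_tilt_deg: float = 5.0
    plate_spacing_um: float = 2.2

    # anaphase
    mass_speed_um_min: float = 0.5
    onset_gap_um: float = 3.2  # inter-mass distance at onset (small visible gap)
    misseg_prob: dict = field(default_factory=_default_misseg)
    misalign_fraction: float = 1.0 / 3.0  # of missegregations (rest lag)
    lagging_mild_prob: dict = field(default_factory=_default_lag_mild)
    lagging_severe_prob: dict = field(default_factory=_default_lag_severe)
    misalign_offset_um: float = 3.5

    # metaphase II
    ikd_um: dict = field(default_factory=_default_ikd)
    mii_spacing_um: float = 2.4
    cohesin_ratio_acro: float = 0.8  # free parameter; only significance printed
    cohesin_jitter_sd: float = 0.1

    # telomeres
    masked_fraction: dict = field(default_factory=_default_masked)
    telomere_offset_um: float = 0.35
    telomere_noise_um: float = 0.05
    arm_length_um: float = 2.0

    # Mad1
    mad1_positive_fraction: float = 0.29
    mad1_sigma_um: tuple = (1.0, 0.5, 0.5)

    # Trim-Away separation kinetics
    separation_scale_min: float = 20.0
    separation_shape: float = 4.0

    # rendering
    body_sigma_um: float = 1.4
    kt_amplitude: float = 1.0
    cohesin_background: float = 0.05

    def replace(self, **kw):
        return dataclasses.replace(self, **kw)

    @property
    def extent_um(self):
        return np.asarray(self.shape) * np.asarray(self.voxel_size_um)

    def rng(self, *streams):
        """Seeded generator for a named sub-stream (pure in (config, seed))."""
        return np.random.default_rng([self.seed, *streams])

    def validate(self):
        for d in (self.misseg_prob, self.lagging_mild_prob, self.lagging_severe_prob):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"probability {v} outside [0, 1]")
        for v in self.masked_fraction.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"masked fraction {v} outside [0, 1]")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval must be positive")
        if self.ou_tau_min <= 0:
            raise ValueError("relaxation time must be positive")
        if self.separation_scale_min <= 0:
            raise ValueError("separation hazard scale must be positive")


@dataclass
class GroundTruth:
    """Simulator output consumed by every downstream stage.

    ``chromosomes`` holds one row per chromosome (static attributes and
    fates); ``points`` one row per (frame, chromosome, landmark) with
    landmark kinds ``kt1``/``kt2`` (the two kinetochores of a pair),
    ``telo1``/``telo2`` and ``tale``; ``frames`` one row per frame with the
    spindle axis, plate centre and (post-onset) anaphase mass coordinates.
    """

    stage: str
    config: SceneConfig
    chromosomes: pd.DataFrame
    points: pd.DataFrame
    frames: pd.DataFrame
    onset_frame: int | None = None

    def kt_pairs(self, frame=0):
        """(n, 2, 3) array of paired kinetochore positions for one frame."""
        sub = self.points[self.points["frame"] == frame]
        k1 = sub[sub["kind"] == "kt1"].reset_index(drop=True)
        k2 = sub[sub["kind"] == "kt2"].reset_index(drop=True)
        ids = k1["chromosome_id"].to_numpy()
        return ids, np.stack([k1[POINT_COLS].to_numpy(), k2[POINT_COLS].to_numpy()], axis=1)

    def detections(self, frame=0, kinds=("kt1", "kt2")):
        sub = self.points[(self.points["frame"] == frame) & self.points["kind"].isin(kinds)]
        return sub[POINT_COLS].to_numpy()


@dataclass
class RenderedScene:
    """Multi-channel voxel image plus its ground-truth sidecar."""

    channels: dict
    channel_map: dict
    truth: GroundTruth
    config: SceneConfig
    frame: int = 0

    @property
    def voxel_size_um(self):
        return np.asarray(self.config.voxel_size_um, dtype=float)


# ---------------------------------------------------------------------------
# placement helpers


def _plate_lattice(n, spacing, rng, jitter=0.25):
    """n jittered positions on a centred (z, y) grid in the plate plane."""
    side = int(np.ceil(np.sqrt(n)))
    zz, yy = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    order = rng.permutation(side * side)[:n]
    pos = np.stack([zz.ravel()[order], yy.ravel()[order]], axis=1).astype(float)
    pos -= pos.mean(axis=0)
    pos *= spacing
    pos += rng.normal(0.0, jitter, pos.shape)
    return pos  # (n, 2) -> (z, y) offsets in um


def _mean_abs_normal(mu, sigma):
    """E|N(mu, sigma)| in closed form."""
    if sigma == 0:
        return abs(mu)
    return mu * (1 - 2 * stats.norm.cdf(-mu / sigma)) + 2 * sigma * stats.norm.pdf(mu / sigma)


def _acro_offset_mu(offset, sigma):
    """Stationary OU mean so that E|s_acro| - E|s_meta| equals ``offset``."""
    target = offset + _mean_abs_normal(0.0, sigma)
    if offset <= 0:
        return 0.0
    return float(optimize.brentq(lambda m: _mean_abs_normal(m, sigma) - target, 0.0, offset + 6 * sigma + 1.0))


def _pair_axes(n, tilt_deg, rng):
    """Unit pair axes: spindle axis plus a small random tilt."""
    tilt = np.deg2rad(tilt_deg)
    axes = np.tile(SPINDLE_AXIS, (n, 1))
    axes = axes + rng.normal(0.0, np.tan(tilt) if tilt > 0 else 0.0, (n, 3)) * np.array([1.0, 1.0, 0.0])
    return axes / np.linalg.norm(axes, axis=1, keepdims=True)


def _frame_rows(cfg, n_frames, plate_center):
    t = np.arange(n_frames) * cfg.frame_interval_min
    return pd.DataFrame(
        dict(
            frame=np.arange(n_frames),
            time_min=t,
            axis_z=SPINDLE_AXIS[0],
            axis_y=SPINDLE_AXIS[1],
            axis_x=SPINDLE_AXIS[2],
            plate_z=plate_center[0],
            plate_y=plate_center[1],
            plate_x=plate_center[2],
            mass_neg_x=np.nan,
            mass_pos_x=np.nan,
        )
    )


def _chrom_table(karyo):
    df = karyo.as_frame()
    df["fate"] = "correct"
    df["lagging"] = "none"
    df["masking"] = "n/a"
    df["cohesin_level"] = np.nan
    df["attachment"] = "end_on"
    df["mad1_kt1"] = False
    df["mad1_kt2"] = False
    df["separation_time_min"] = np.nan
    return df


def _attachment_labels(df, cfg, rng):
    """Ground-truth attachment labels, class-conditional (annotation only)."""
    probs = {
        "acro": (0.50, 0.34, 0.16),
        "meta": (0.70, 0.14, 0.16),
    }
    cats = np.array(["end_on", "lateral_merotelic", "unattached"])
    lab = [
        cats[rng.choice(3, p=probs[c])]
        for c in df["centromere_class"]
    ]
    return lab


# ---------------------------------------------------------------------------
# stage simulators


def simulate_congression(config: SceneConfig) -> GroundTruth:
    """Metaphase-I bivalent trajectories relaxing toward the plate.

    Each bivalent centre follows an Ornstein-Uhlenbeck process along the
    spindle axis, started at stationarity.  Acrocentric bivalents relax to a
    stationary mean plate *distance* exceeding the metacentric one by
    ``plate_offset_um``; homologous kinetochores co-move at a fixed
    inter-homologue separation.
    """
    cfg = config
    cfg.validate()
    if cfg.stage != "metaphase_I":
        raise ValueError("simulate_congression requires stage='metaphase_I'")
    karyo = make_karyotype(cfg.species, cfg.labelling_mode)
    rng = cfg.rng(1)
    df = _chrom_table(karyo)
    n = len(df)
    df["attachment"] = _attachment_labels(df, cfg, rng)
    mad1 = rng.random((n, 2)) < cfg.mad1_positive_fraction
    df["mad1_kt1"], df["mad1_kt2"] = mad1[:, 0], mad1[:, 1]

    plate_center = cfg.extent_um / 2.0
    trans = _plate_lattice(n, cfg.plate_spacing_um, rng)
    mu_acro = _acro_offset_mu(cfg.plate_offset_um, cfg.ou_sigma_um)
    sides = rng.choice([-1.0, 1.0], n)
    mu = np.where(df["centromere_class"].to_numpy() == "acro", mu_acro * sides, 0.0)

    dt = cfg.frame_interval_min
    a = np.exp(-dt / cfg.ou_tau_min)
    sd_step = cfg.ou_sigma_um * np.sqrt(1 - a**2)

    pair_d = rng.normal(*cfg.pair_dist_um, n).clip(0.5)
    axes = _pair_axes(n, cfg.pair_tilt_deg, rng)

    s = mu + rng.normal(0.0, cfg.ou_sigma_um, n)  # stationary start
    tz = trans[:, 0] + rng.normal(0.0, cfg.transverse_sigma_um, n)
    ty = trans[:, 1] + rng.normal(0.0, cfg.transverse_sigma_um, n)

    rows = []
    for f in range(cfg.n_frames):
        if f > 0:
            s = mu + (s - mu) * a + rng.normal(0.0, sd_step, n)
            tz = trans[:, 0] + (tz - trans[:, 0]) * a + rng.normal(0.0, cfg.transverse_sigma_um * np.sqrt(1 - a**2), n)
            ty = trans[:, 1] + (ty - trans[:, 1]) * a + rng.normal(0.0, cfg.transverse_sigma_um * np.sqrt(1 - a**2), n)
        # axial coordinate s lives along x; (tz, ty) are in the plate plane
        centers = np.stack([plate_center[0] + tz, plate_center[1] + ty, plate_center[2] + s], axis=1)
        k1 = centers - axes * pair_d[:, None] / 2
        k2 = centers + axes * pair_d[:, None] / 2
        for arr, kind in ((k1, "kt1"), (k2, "kt2")):
            rows.append(
                pd.DataFrame(
                    dict(
                        frame=f,
                        chromosome_id=df["chromosome_id"],
                        kind=kind,
                        z_um=arr[:, 0],
                        y_um=arr[:, 1],
                        x_um=arr[:, 2],
                    )
                )
            )
    points = pd.concat(rows, ignore_index=True)
    frames = _frame_rows(cfg, cfg.n_frames, plate_center)
    gt = GroundTruth("metaphase_I", cfg, df, points, frames)
    _add_tale_foci(gt)
    return gt


def _add_tale_foci(gt: GroundTruth):
    """One pericentromeric TALE focus per labelled chromosome, at the pair centre.

    At confocal resolution the pericentromeric signals of the two homologues
    of a joined bivalent are adjacent and render as a single focus.
    """
    df = gt.chromosomes
    labelled = set(df.loc[df["tale_labelled"], "chromosome_id"])
    if not labelled:
        return
    pts = gt.points
    sub = pts[pts["kind"].isin(["kt1", "kt2"]) & pts["chromosome_id"].isin(labelled)]
    foci = sub.groupby(["frame", "chromosome_id"], as_index=False)[POINT_COLS].mean()
    foci["kind"] = "tale"
    gt.points = pd.concat([pts, foci[pts.columns.tolist()]], ignore_index=True)


def simulate_anaphase(config: SceneConfig) -> GroundTruth:
    """Anaphase-I trajectories with class-conditional fates and lagging.

    Fates are drawn per chromosome: missegregation with class probability
    (default 8% acro / 1% meta), split ``misalign_fraction`` :
    ``1 - misalign_fraction`` between severe misalignment and severe
    lagging.  Additional benign laggards are drawn so that total mild and
    severe lagging rates meet the configured class rates.  Laggards stay in
    the central spindle zone until 12 min (mild) or 20 min (severe) after
    onset and clear afterwards.
    """
    cfg = config
    cfg.validate()
    if cfg.stage != "anaphase_I":
        raise ValueError("simulate_anaphase requires stage='anaphase_I'")
    karyo = make_karyotype(cfg.species, cfg.labelling_mode)
    rng = cfg.rng(2)
    df = _chrom_table(karyo)
    n = len(df)
    cls = df["centromere_class"].to_numpy()

    p_mis = np.array([cfg.misseg_prob[c] for c in cls])
    u = rng.random(n)
    fate = np.where(
        u < p_mis * cfg.misalign_fraction,
        "missegregation_misalignment",
        np.where(u < p_mis, "missegregation_lagging", "correct"),
    )
    # lagging grades: missegregating laggards are severe by definition;
    # benign laggards are drawn so the *total* class rates equal the
    # configured lagging_mild_prob / lagging_severe_prob exactly
    lag = np.where(fate == "missegregation_lagging", "severe", "none")
    for i in range(n):
        if fate[i] != "correct":
            continue
        p_corr = 1.0 - p_mis[i]
        p_sev = max(0.0, cfg.lagging_severe_prob[cls[i]]
                    - cfg.misseg_prob[cls[i]] * (1 - cfg.misalign_fraction)) / p_corr
        p_mild = cfg.lagging_mild_prob[cls[i]] / p_corr
        r = rng.random()
        if r < p_sev:
            lag[i] = "severe"
        elif r < p_sev + p_mild:
            lag[i] = "mild"
    df["fate"] = fate
    df["lagging"] = lag

    plate_center = cfg.extent_um / 2.0
    trans = _plate_lattice(n, cfg.plate_spacing_um, rng)
    pair_d = rng.normal(*cfg.pair_dist_um, n).clip(0.5)

    n_frames = max(cfg.n_frames, cfg.onset_frame + 7)
    frames = _frame_rows(cfg, n_frames, plate_center)
    dt = cfg.frame_interval_min

    # destination side of missegregating pairs (both homologues together)
    missy_side = rng.choice([-1.0, 1.0], n)
    misalign_side = rng.choice([-1.0, 1.0], n)
    t_clear = {"none": 0.0, "mild": 12.0, "severe": 20.0}

    rows = []
    max_half = cfg.extent_um[2] / 2.0 - 1.5  # keep masses inside the volume
    for f in range(n_frames):
        t_rel = (f - cfg.onset_frame) * dt
        if t_rel < 0:
            half = 0.0
        else:
            half = min(cfg.mass_speed_um_min * t_rel / 2.0 + cfg.onset_gap_um / 2.0, max_half)
            frames.loc[f, "mass_neg_x"] = plate_center[2] - half
            frames.loc[f, "mass_pos_x"] = plate_center[2] + half
        s1 = np.empty(n)
        s2 = np.empty(n)
        for i in range(n):
            if t_rel < 0:
                s1[i], s2[i] = -pair_d[i] / 2, pair_d[i] / 2
                if fate[i] == "missegregation_misalignment":
                    base = misalign_side[i] * cfg.misalign_offset_um
                    s1[i] += base
                    s2[i] += base
                continue
            if fate[i] == "missegregation_misalignment":
                # stuck at its misaligned position; both end on one side
                base = misalign_side[i] * cfg.misalign_offset_um
                s1[i], s2[i] = base - pair_d[i] / 2, base + pair_d[i] / 2
            elif lag[i] != "none" and t_rel <= t_clear[lag[i]]:
                # lagging homologue in the central zone, partner segregates
                s1[i] = -half
                s2[i] = 0.0
            elif fate[i] == "missegregation_lagging":
                s1[i], s2[i] = -half, -half  # joined the wrong (same) side
            else:
                s1[i], s2[i] = -half, half
        jitter = rng.normal(0.0, 0.08, (n, 2, 3))
        for j, (s, kind) in enumerate(((s1, "kt1"), (s2, "kt2"))):
            pos = np.stack(
                [
                    plate_center[0] + trans[:, 0],
                    plate_center[1] + trans[:, 1],
                    plate_center[2] + s,
                ],
                axis=1,
            ) + jitter[:, j, :]
            rows.append(
                pd.DataFrame(
                    dict(frame=f, chromosome_id=df["chromosome_id"], kind=kind,
                         z_um=pos[:, 0], y_um=pos[:, 1], x_um=pos[:, 2])
                )
            )
    points = pd.concat(rows, ignore_index=True)
    gt = GroundTruth("anaphase_I", cfg, df, points, frames, onset_frame=cfg.onset_frame)
    _add_tale_foci(gt)
    return gt


def mii_fates_from_anaphase(gt: GroundTruth, rng=None):
    """Per-class dyad counts inherited by the egg after anaphase fates.

    Each missegregating bivalent sends both homologues to the egg or to the
    polar body with equal probability (one extra or one missing dyad).
    """
    if rng is None:
        rng = gt.config.rng(3)
    counts = []
    for _, row in gt.chromosomes.iterrows():
        if row["fate"] == "correct":
            counts.append((row["chromosome_id"], 1))
        else:
            counts.append((row["chromosome_id"], 2 if rng.random() < 0.5 else 0))
    return counts


def simulate_mii_egg(config: SceneConfig, fates=None) -> GroundTruth:
    """A metaphase-II egg: sister-kinetochore pairs facing opposite poles.

    ``fates`` is an optional list of (chromosome_id, copy_number) pairs (see
    :func:`mii_fates_from_anaphase`); by default the egg is euploid with one
    dyad per chromosome, i.e. 38 kinetochores for the porcine karyotype.
    """
    cfg = config
    cfg.validate()
    karyo = make_karyotype(cfg.species, cfg.labelling_mode)
    rng = cfg.rng(4)
    base = _chrom_table(karyo)
    if fates is None:
        fates = [(cid, 1) for cid in base["chromosome_id"]]
    rows = []
    for cid, copies in fates:
        src = base[base["chromosome_id"] == cid].iloc[0]
        for _ in range(copies):
            rows.append(src.copy())
    df = pd.DataFrame(rows).reset_index(drop=True)
    n = len(df)

    ratio = {"acro": cfg.cohesin_ratio_acro, "meta": 1.0}
    coh = np.array([ratio[c] for c in df["centromere_class"]])
    coh = coh * np.exp(rng.normal(0.0, cfg.cohesin_jitter_sd, n))
    df["cohesin_level"] = coh

    ikd = np.array([rng.normal(*cfg.ikd_um[l]) for l in df["label"]]).clip(0.4)
    df["ikd_true_um"] = ikd

    plate_center = cfg.extent_um / 2.0
    trans = _plate_lattice(n, cfg.mii_spacing_um, rng)
    axes = _pair_axes(n, cfg.pair_tilt_deg, rng)
    centers = np.stack(
        [plate_center[0] + trans[:, 0], plate_center[1] + trans[:, 1],
         plate_center[2] + rng.normal(0.0, 0.3, n)],
        axis=1,
    )
    k1 = centers - axes * ikd[:, None] / 2
    k2 = centers + axes * ikd[:, None] / 2
    pts = []
    for arr, kind in ((k1, "kt1"), (k2, "kt2")):
        pts.append(
            pd.DataFrame(
                dict(frame=0, chromosome_id=df["chromosome_id"], kind=kind,
                     z_um=arr[:, 0], y_um=arr[:, 1], x_um=arr[:, 2])
            )
        )
    points = pd.concat(pts, ignore_index=True)
    frames = _frame_rows(cfg, 1, plate_center)
    gt = GroundTruth("metaphase_II", cfg, df, points, frames)
    _add_tale_foci(gt)
    return gt


def simulate_trimaway(config: SceneConfig) -> GroundTruth:
    """Sister-separation times after acute cohesin depletion.

    Separation time is ``scale * cohesin * W`` with ``W`` Weibull-distributed
    (shape ``separation_shape``), i.e. the separation hazard decreases
    steeply and monotonically with cohesin level, so the low-cohesin class
    separates stochastically earlier.
    """
    cfg = config
    cfg.validate()
    gt = simulate_mii_egg(cfg.replace(stage="metaphase_II"))
    gt.stage = "trim_away"
    rng = cfg.rng(5)
    n = len(gt.chromosomes)
    w = rng.weibull(cfg.separation_shape, n)
    gt.chromosomes["separation_time_min"] = (
        cfg.separation_scale_min * gt.chromosomes["cohesin_level"].to_numpy() * w
    )
    return gt


def place_telomeres(config: SceneConfig, gt: GroundTruth) -> GroundTruth:
    """Attach telomere centroids to each kinetochore pair.

    Acrocentric pairs are telomere-masked with the configured species
    fraction: masked telomeres sit poleward of their kinetochore (outward
    along the pair axis), exposed ones toward the bivalent centre.
    Metacentric telomeres are placed a chromosome-arm length away,
    perpendicular to the pair axis, so they are never proximal.
    """
    cfg = config
    key = cfg.species if cfg.species in cfg.masked_fraction else "porcine"
    rng = cfg.rng(6)
    df = gt.chromosomes
    masked = rng.random(len(df)) < cfg.masked_fraction[key]
    df["masking"] = np.where(df["centromere_class"] == "acro", np.where(masked, "masked", "exposed"), "n/a")

    pts = gt.points
    k1 = pts[pts["kind"] == "kt1"].set_index(["frame", "chromosome_id"])[POINT_COLS]
    k2 = pts[pts["kind"] == "kt2"].set_index(["frame", "chromosome_id"])[POINT_COLS]
    new = []
    # fixed per-chromosome perpendicular direction for metacentric arms
    perp_angle = rng.uniform(0, 2 * np.pi, len(df))
    cls = df.set_index("chromosome_id")
    for (frame, cid), p1 in k1.iterrows():
        p1 = p1.to_numpy()
        p2 = k2.loc[(frame, cid)].to_numpy()
        center = (p1 + p2) / 2
        axis = p2 - p1
        nrm = np.linalg.norm(axis)
        axis = axis / nrm if nrm > 0 else SPINDLE_AXIS
        row = cls.loc[cid]
        i = cls.index.get_loc(cid)
        if row["centromere_class"] == "acro":
            sign = 1.0 if row["masking"] == "masked" else -1.0
            for p, out, kind in ((p1, -axis, "telo1"), (p2, axis, "telo2")):
                t = p + sign * cfg.telomere_offset_um * out + rng.normal(0, cfg.telomere_noise_um, 3)
                new.append((frame, cid, kind, *t))
        else:
            ang = perp_angle[i]
            perp = np.array([np.cos(ang), np.sin(ang), 0.0])  # in the plate plane
            arm = max(cfg.arm_length_um * float(row["size_scale"]), 1.3)
            for p, kind in ((p1, "telo1"), (p2, "telo2")):
                t = center + perp * arm + rng.normal(0, cfg.telomere_noise_um, 3)
                new.append((frame, cid, kind, *t))
    telo = pd.DataFrame(new, columns=["frame", "chromosome_id", "kind", *POINT_COLS])
    gt.points = pd.concat([pts[~pts["kind"].isin(["telo1", "telo2"])], telo], ignore_index=True)
    return gt


# ---------------------------------------------------------------------------
# rendering


def _add_gaussian(img, voxel_size, pos_um, sigma_um, amplitude):
    """Accumulate a Gaussian blob into ``img`` on a +/-4 sigma support box."""
    pos_vox = np.asarray(pos_um) / voxel_size - 0.5
    sig_vox = np.asarray(sigma_um, dtype=float) / voxel_size
    lo = np.maximum(np.floor(pos_vox - 4 * sig_vox).astype(int), 0)
    hi = np.minimum(np.ceil(pos_vox + 4 * sig_vox).astype(int) + 1, img.shape)
    if np.any(lo >= hi):
        return
    grids = np.ix_(*[np.arange(l, h) for l, h in zip(lo, hi)])
    q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, pos_vox, sig_vox))
    img[grids] += amplitude * np.exp(-0.5 * q)


def _body_positions(gt, frame):
    """Chromosome-body centres for the DNA channel."""
    pts = gt.points[gt.points["frame"] == frame]
    k1 = pts[pts["kind"] == "kt1"].set_index("chromosome_id")[POINT_COLS]
    k2 = pts[pts["kind"] == "kt2"].set_index("chromosome_id")[POINT_COLS]
    if gt.stage in ("anaphase_I",):
        # separated homologues: one body per kinetochore
        out = []
        for cid in k1.index:
            out.append((cid, k1.loc[cid].to_numpy()))
            out.append((cid, k2.loc[cid].to_numpy()))
        return out
    return [(cid, (k1.loc[cid].to_numpy() + k2.loc[cid].to_numpy()) / 2) for cid in k1.index]


def render_scene(gt: GroundTruth, config: SceneConfig | None = None, frame=0) -> RenderedScene:
    """Render one frame of a ground truth into a multi-channel voxel image.

    Kinetochores, TALE foci and telomeres are rendered as PSF-sized Gaussian
    spots; chromosome bodies as size-scaled Gaussian ellipsoids (the PSF is
    folded into the Gaussian widths).  Poisson shot noise and Gaussian read
    noise are applied per channel when ``config.noise`` is set.  The result
    is bit-exact for a fixed ``(config, seed, frame)``.
    """
    cfg = config or gt.config
    vs = np.asarray(cfg.voxel_size_um, dtype=float)
    extent = cfg.extent_um
    pts = gt.points[gt.points["frame"] == frame]
    if len(pts) == 0:
        raise ValueError(f"no ground-truth points for frame {frame}")
    coords = pts[POINT_COLS].to_numpy()
    oob = pts[(coords < 0.5).any(axis=1) | (coords > extent - 0.5).any(axis=1)]
    if len(oob):
        ids = sorted(oob["chromosome_id"].unique())
        raise MeiotrackError(f"objects out of image bounds for chromosomes {ids}")

    psf = np.asarray(cfg.psf_sigma_um, dtype=float)
    shape = tuple(cfg.shape)
    channels = {}

    # DNA: chromosome bodies
    dna = np.zeros(shape, dtype=np.float64)
    size = gt.chromosomes.set_index("chromosome_id")["size_scale"]
    body_scale = 1.0 if gt.stage == "metaphase_I" else 0.8
    seen = {}
    for cid, pos in _body_positions(gt, frame):
        s = cfg.body_sigma_um * body_scale * float(size.get(cid, 1.0)) ** (1 / 3)
        sigma = np.sqrt(np.array([s * 0.8, s, s]) ** 2 + psf**2)
        _add_gaussian(dna, vs, pos, sigma, 1.0)
        seen[cid] = True
    channels["dna"] = dna

    def spot_channel(kinds, sigma, amp=1.0, amplitudes=None):
        img = np.zeros(shape, dtype=np.float64)
        sub = pts[pts["kind"].isin(kinds)]
        for i, (_, r) in enumerate(sub.iterrows()):
            a = amp if amplitudes is None else amplitudes[i]
            _add_gaussian(img, vs, r[POINT_COLS].to_numpy(dtype=float), sigma, a)
        return img

    kt_sigma = np.sqrt(psf**2 + 0.08**2)
    channels["kinetochore"] = spot_channel(["kt1", "kt2"], kt_sigma, cfg.kt_amplitude)
    channels["tale"] = spot_channel(["tale"], np.sqrt(psf**2 + 0.12**2))
    channels["telomere"] = spot_channel(["telo1", "telo2"], np.sqrt(psf**2 + 0.1**2), 0.8)

    # cohesin (MII / trim-away) or Mad1 (MI) in the shared 5th channel
    extra = np.zeros(shape, dtype=np.float64)
    if gt.stage in ("metaphase_II", "trim_away"):
        # kt1/kt2 rows are emitted in chromosome-table order, so positional
        # pairing is valid even for aneuploid duplicates of one chromosome id
        k1 = pts[pts["kind"] == "kt1"].reset_index(drop=True)
        k2 = pts[pts["kind"] == "kt2"].reset_index(drop=True)
        coh = gt.chromosomes["cohesin_level"].to_numpy()
        for i in range(len(k1)):
            p1 = k1.loc[i, POINT_COLS].to_numpy(dtype=float)
            p2 = k2.loc[i, POINT_COLS].to_numpy(dtype=float)
            c = (p1 + p2) / 2
            # pericentromeric cohesin spans the inter-sister gap: axial extent
            # scales with the interkinetochore distance (FWHM ~ IKD), so a
            # fixed-radius cylinder between sisters samples the same relative
            # profile for every pair
            gap = np.linalg.norm(p2 - p1)
            coh_sigma = np.sqrt(np.array([0.25, 0.25, max(gap / 2.355, 0.25)]) ** 2 + psf**2)
            _add_gaussian(extra, vs, c, coh_sigma, float(coh[i]))
        extra += cfg.cohesin_background
        extra_name = "cohesin"
    else:
        mz = gt.chromosomes.set_index("chromosome_id")[["mad1_kt1", "mad1_kt2"]]
        for kind, col in (("kt1", "mad1_kt1"), ("kt2", "mad1_kt2")):
            sub = pts[pts["kind"] == kind]
            for _, r in sub.iterrows():
                if bool(mz.loc[r["chromosome_id"], col]):
                    _add_gaussian(extra, vs, r[POINT_COLS].to_numpy(dtype=float), np.asarray(cfg.mad1_sigma_um), 1.0)
        extra_name = "mad1"
    channels[extra_name] = extra

    if cfg.noise:
        names = sorted(channels)
        for ci, name in enumerate(names):
            rng = cfg.rng(7, frame, ci)
            img = channels[name]
            img = rng.poisson(np.clip(img, 0, None) * cfg.poisson_gain) / cfg.poisson_gain
            img = img + rng.normal(0.0, cfg.read_noise_sigma, img.shape)
            channels[name] = img.astype(np.float32)
    else:
        channels = {k: v.astype(np.float32) for k, v in channels.items()}

    channel_map = {
        "dna": "dna",
        "kinetochore": "kinetochore",
        "tale": "tale",
        "telomere": "telomere",
        "cohesin_or_mad1": extra_name,
    }
    return RenderedScene(channels, channel_map, gt, cfg, frame)
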