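"""Run configuration and end-to-end orchestration.

A run is fully described by a JSON-serialisable :class:`RunConfig`; the
same config and seed always produce byte-identical outputs, and every
output directory carries a provenance record (config hash, seed, package
versions) sufficient to re-run any stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anaphase import PloidyConfig, call_ploidy
from .errors import MeiotrackError
from .quantify import ROIConfig, assign_tale_labels, pair_sisters, sister_ikd_normalized
from .simulate import SceneConfig, render_scene, simulate_congression, simulate_mii_egg
from .stats import group_summary, t_test_unpaired_two_tailed
from .tracking import TrackingConfig, detect_spots, solve_in_batches

__all__ = ["RunConfig", "run_pipeline"]

KT_DIAM_XY = 0.5  # um, confocal kinetochore spot scale for detection
KT_DIAM_Z = 1.6


@dataclass
class RunConfig:
    stage: str = "metaphase_II"  # metaphase_II | metaphase_I
    seed: int = 0
    n_eggs: int = 3
    out_dir: str = "meiotrack_run"
    scene: dict = field(default_factory=dict)
    tracking: dict = field(default_factory=dict)
    roi: dict = field(default_factory=dict)
    ploidy: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self):
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)


def _provenance(cfg: RunConfig):
    text = cfg.to_json()
    return dict(
        config_sha256=hashlib.sha256(text.encode()).hexdigest(),
        seed=cfg.seed,
        meiotrack_version=__version__,
        numpy_version=np.__version__,
    )


def measure_mii_egg(scene, roi_cfg: ROIConfig | None = None):
    """Detect, pair and classify kinetochores of one rendered MII egg.

    Returns a tidy per-pair table (label, raw and normalised sister IKD)
    plus the detected kinetochore count.
    """
    roi_cfg = roi_cfg or ROIConfig()
    vs = scene.voxel_size_um
    det = detect_spots(scene.channels["kinetochore"], vs, KT_DIAM_XY, KT_DIAM_Z)
    tale = detect_spots(scene.channels["tale"], vs, 0.6, 1.8)
    pairs_idx = pair_sisters(det, max_dist_um=2.0)
    rows = []
    if len(pairs_idx):
        pos = det[["z_um", "y_um", "x_um"]].to_numpy()
        pair_pts = np.stack([pos[pairs_idx[:, 0]], pos[pairs_idx[:, 1]]], axis=1)
        ikd = sister_ikd_normalized(pair_pts)
        centroids = pair_pts.mean(axis=1)
        if len(tale):
            labelled = assign_tale_labels(centroids, tale[["z_um", "y_um", "x_um"]].to_numpy(),
                                          config=roi_cfg)
        else:
            labelled = np.zeros(len(centroids), dtype=bool)
        for i in range(len(pairs_idx)):
            rows.append(dict(label="acro_labelled" if labelled[i] else "meta",
                             ikd_um=float(ikd["ikd_um"][i]), ikd_norm=float(ikd["ikd_norm"][i])))
    return pd.DataFrame(rows), len(det)


def run_pipeline(config: RunConfig):
    """Execute the configured stages and write tables + provenance.

    metaphase_II: simulate/render ``n_eggs`` eggs, detect and pair sister
    kinetochores, call ploidy, compare class IKDs.  metaphase_I: simulate a
    congression series, run joint tracking, write the track table.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = {}
    if cfg.stage == "metaphase_II":
        ploidy_cfg = PloidyConfig(**cfg.ploidy)
        rows = []
        calls = []
        for e in range(cfg.n_eggs):
            sc = SceneConfig(stage="metaphase_II", seed=cfg.seed + e, **cfg.scene)
            scene = render_scene(simulate_mii_egg(sc))
            table, n_det = measure_mii_egg(scene, ROIConfig(**cfg.roi))
            table.insert(0, "cell_id", e)
            rows.append(table)
            calls.append(dict(cell_id=e, kinetochores=n_det, ploidy=call_ploidy(n_det, ploidy_cfg)))
        measurements = pd.concat(rows, ignore_index=True)
        measurements.to_csv(out / "measurements.csv", index=False)
        pd.DataFrame(calls).to_csv(out / "ploidy.csv", index=False)
        acro = measurements.loc[measurements["label"] == "acro_labelled", "ikd_um"]
        meta = measurements.loc[measurements["label"] == "meta", "ikd_um"]
        stats_out = {
            "acro_ikd": group_summary(acro) if len(acro) else None,
            "meta_ikd": group_summary(meta) if len(meta) else None,
        }
        if len(acro) > 1 and len(meta) > 1:
            t, df, p = t_test_unpaired_two_tailed(acro, meta)
            stats_out["t_test"] = dict(t=t, df=df, p=p)
        with open(out / "stats.json", "w") as fh:
            json.dump(stats_out, fh, indent=1, sort_keys=True)
        result.update(measurements=measurements, ploidy=pd.DataFrame(calls), stats=stats_out)
    elif cfg.stage == "metaphase_I":
        sc = SceneConfig(stage="metaphase_I", seed=cfg.seed, **cfg.scene)
        gt = simulate_congression(sc)
        det = gt.points[gt.points["kind"].isin(["kt1", "kt2"])][
            ["frame", "z_um", "y_um", "x_um"]
        ].reset_index(drop=True)
        tcfg = TrackingConfig(**cfg.tracking)
        tracks = solve_in_batches(det, tcfg)
        tracks.pairs.to_csv(out / "tracks.csv", index=False)
        result.update(tracks=tracks)
    else:
        raise MeiotrackError(f"pipeline stage {cfg.stage!r} not supported")
    with open(out / "provenance.json", "w") as fh:
        json.dump(_provenance(cfg), fh, indent=1, sort_keys=True)
    return result
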