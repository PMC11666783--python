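"""3D chromosome-volume segmentation.

The pipeline mirrors seeded chromosome-group volumetry: the volume is made
isotropic and background-subtracted, a multilevel Otsu scan picks the first
threshold whose foreground lands in a plausible total-chromatin volume
range (150-800 um^3), the mask is cleaned (hole filling, removal of
fragments at or below 20 voxels), oversegmented by watershed on the
smoothed distance map, and the fragments are recombined by solving a
seed-constrained multicut on the fragment contact graph: the total contact
area between different chromosomes is minimised subject to fragments
holding different seeds ending up in different clusters.

Conventions: fragment connectivity is 26-neighbourhood; contact area is
counted over face-adjacent (6-neighbourhood) voxel pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage, sparse
from scipy.optimize import Bounds, LinearConstraint, milp
from skimage.filters import threshold_multiotsu
from skimage.graph import MCP_Geometric
from skimage.segmentation import watershed

from .errors import EmptyForegroundError, InfeasibleModelError, MeiotrackError

__all__ = [
    "SegConfig",
    "MulticutSolution",
    "preprocess",
    "adaptive_multithreshold",
    "clean_mask",
    "watershed_split",
    "build_contact_graph",
    "solve_multicut",
    "split_multiseed_component",
    "assign_orphans",
    "segment_chromosomes",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegConfig:
    volume_range_um3: tuple = (150.0, 800.0)
    max_threshold_classes: int = 8
    sigma_um: float = 0.25
    min_fragment_voxels: int = 20
    background_percentile: float = 10.0
    dt_smooth_um: float = 0.3

    def __post_init__(self):
        if self.volume_range_um3[0] >= self.volume_range_um3[1]:
            raise ValueError("volume range min must be below max")
        if self.min_fragment_voxels < 0:
            raise ValueError("min fragment must be >= 0")


@dataclass
class MulticutSolution:
    cluster_of: dict  # node -> cluster id
    total_cut_area: float


def preprocess(image, voxel_size, config: SegConfig | None = None):
    """Interpolate z to isotropic voxels, smooth, subtract background.

    Returns ``(image, voxel_size)`` with cubic voxels of the xy spacing.
    Background is a constant per-image percentile estimate; the result is
    clipped at zero.
    """
    cfg = config or SegConfig()
    img = np.asarray(image, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    if vs[1] != vs[2]:
        raise ValueError("xy voxel size must be isotropic")
    if vs[0] != vs[1]:
        factor = vs[0] / vs[1]
        img = ndimage.zoom(img, (factor, 1.0, 1.0), order=1, mode="nearest")
        vs = np.array([vs[1], vs[1], vs[2]])
    if cfg.sigma_um > 0:
        img = ndimage.gaussian_filter(img, cfg.sigma_um / vs)
    bg = np.percentile(img, cfg.background_percentile)
    return np.clip(img - bg, 0, None), vs


def adaptive_multithreshold(image, voxel_size, config: SegConfig | None = None):
    """Foreground mask from the first multilevel-Otsu threshold whose volume
    falls inside the target chromatin range.

    The number of threshold levels k is increased from 1 to
    ``max_threshold_classes``; for each k the candidate thresholds are tried
    from the highest down, and the first foreground whose total volume lies
    in ``volume_range_um3`` wins.  The scan order is fixed, so the result is
    deterministic.
    """
    cfg = config or SegConfig()
    img = np.asarray(image, dtype=float)
    voxvol = float(np.prod(voxel_size))
    lo, hi = cfg.volume_range_um3
    if img.max() == img.min():
        raise EmptyForegroundError("volume range unreachable: image has no contrast")
    for k in range(1, cfg.max_threshold_classes + 1):
        try:
            thr = np.atleast_1d(threshold_multiotsu(img, classes=k + 1))
        except ValueError:
            continue  # too few distinct grey levels for this class count
        for t in sorted(thr, reverse=True):
            mask = img > t
            vol = mask.sum() * voxvol
            if lo <= vol <= hi:
                return mask
    raise MeiotrackError(
        f"volume range unreachable: no Otsu threshold up to {cfg.max_threshold_classes} "
        f"classes yields a foreground in [{lo}, {hi}] um^3"
    )


def clean_mask(mask, config: SegConfig | None = None):
    """Fill 3D holes and drop fragments at or below ``min_fragment_voxels``."""
    cfg = config or SegConfig()
    m = ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))
    lab, n = ndimage.label(m, structure=_CONN26)
    if n == 0:
        return m
    sizes = np.bincount(lab.ravel())
    keep = sizes > cfg.min_fragment_voxels
    keep[0] = False
    return keep[lab]


def watershed_split(mask, voxel_size, config: SegConfig | None = None):
    """Watershed of the negated smoothed distance map, seeded at its maxima.

    Returns a label map partitioning the mask into fragments.
    """
    cfg = config or SegConfig()
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise EmptyForegroundError("empty mask")
    vs = np.asarray(voxel_size, dtype=float)
    dt = ndimage.distance_transform_edt(m, sampling=vs)
    if cfg.dt_smooth_um > 0:
        dt = ndimage.gaussian_filter(dt, cfg.dt_smooth_um / vs)
    # regional maxima of the smoothed distance map as watershed seeds
    maxima = (dt == ndimage.maximum_filter(dt, size=3)) & m
    markers, _ = ndimage.label(maxima, structure=_CONN26)
    labels = watershed(-dt, markers=markers, mask=m)
    return labels


def _seed_nodes(labelmap, seeds_um, voxel_size):
    """Component label containing each seed (nearest component if background)."""
    lab = np.asarray(labelmap)
    vs = np.asarray(voxel_size, dtype=float)
    out = []
    _, idx = ndimage.distance_transform_edt(lab == 0, sampling=vs, return_indices=True)
    for s in np.atleast_2d(np.asarray(seeds_um, dtype=float)):
        vox = np.clip(np.round(s / vs - 0.5).astype(int), 0, np.array(lab.shape) - 1)
        node = int(lab[tuple(vox)])
        if node == 0:
            node = int(lab[tuple(idx[(slice(None), *vox)])])
        out.append(node)
    return out


def build_contact_graph(labelmap, voxel_size, seeds_um=None):
    """Fragment contact graph: nodes carry volume/centroid/seeds, edges carry
    face-contact area in um^2."""
    lab = np.asarray(labelmap)
    vs = np.asarray(voxel_size, dtype=float)
    voxvol = float(np.prod(vs))
    g = nx.Graph()
    ids = np.unique(lab)
    ids = ids[ids > 0]
    centroids = ndimage.center_of_mass(lab > 0, lab, ids)
    sizes = ndimage.sum_labels(np.ones_like(lab, dtype=float), lab, ids)
    for i, cid in enumerate(ids):
        g.add_node(int(cid), volume=float(sizes[i] * voxvol),
                   centroid=(np.asarray(centroids[i]) + 0.5) * vs, seeds=[])
    face_area = [vs[1] * vs[2], vs[0] * vs[2], vs[0] * vs[1]]
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        a = lab[tuple(sl_a)].ravel()
        b = lab[tuple(sl_b)].ravel()
        m = (a != b) & (a > 0) & (b > 0)
        if not m.any():
            continue
        pa, pb = np.minimum(a[m], b[m]), np.maximum(a[m], b[m])
        key = pa.astype(np.int64) * (lab.max() + 1) + pb
        uniq, counts = np.unique(key, return_counts=True)
        for k, cnt in zip(uniq, counts):
            u = int(k // (lab.max() + 1))
            v = int(k % (lab.max() + 1))
            area = float(cnt * face_area[ax])
            if g.has_edge(u, v):
                g[u][v]["area"] += area
            else:
                g.add_edge(u, v, area=area)
    if seeds_um is not None:
        for sid, node in enumerate(_seed_nodes(lab, seeds_um, vs)):
            g.nodes[node]["seeds"].append(sid)
    return g


def solve_multicut(graph, seeds=None):
    """Minimum-contact-area multicut with seed-separation constraints.

    Binary edge-cut variables; cycle-consistency and seed-separation
    constraints are added lazily (violated path inequalities) until the cut
    set is consistent with a node partition separating all seeds.

    ``seeds`` maps node -> seed id; by default it is read from the graph's
    node attribute ``seeds`` (raising if one node holds several seeds).
    """
    g = graph
    if seeds is None:
        seeds = {}
        for n, data in g.nodes(data=True):
            s = data.get("seeds", [])
            if len(s) > 1:
                raise InfeasibleModelError(
                    f"node {n} holds seeds {s}: split it with split_multiseed_component first"
                )
            if s:
                seeds[n] = s[0]
    edges = list(g.edges())
    weights = np.array([g[u][v].get("area", 1.0) for u, v in edges], dtype=float)
    eidx = {frozenset(e): i for i, e in enumerate(edges)}
    ne = len(edges)
    if ne == 0:
        clusters = {n: i for i, n in enumerate(sorted(g.nodes()))}
        return MulticutSolution(clusters, 0.0)

    rows_A, lb, ub = [], [], []

    def solve_current():
        if rows_A:
            data, ri, ci = [], [], []
            for r, entries in enumerate(rows_A):
                for col, val in entries:
                    ri.append(r)
                    ci.append(col)
                    data.append(val)
            A = sparse.csr_matrix((data, (ri, ci)), shape=(len(rows_A), ne))
            cons = [LinearConstraint(A, np.asarray(lb), np.asarray(ub))]
        else:
            cons = []
        res = milp(c=weights, constraints=cons, integrality=np.ones(ne),
                   bounds=Bounds(np.zeros(ne), np.ones(ne)))
        if res.status != 0:
            raise InfeasibleModelError(f"multicut ILP failed: {res.message}")
        return np.round(res.x).astype(int)

    for _ in range(200):
        y = solve_current()
        kept = nx.Graph()
        kept.add_nodes_from(g.nodes())
        kept.add_edges_from(e for i, e in enumerate(edges) if y[i] == 0)
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(kept)):
            for n in comp:
                comp_of[n] = ci
        violated = False
        # cycle consistency: a cut edge inside one component
        for i, (u, v) in enumerate(edges):
            if y[i] == 1 and comp_of[u] == comp_of[v]:
                path = nx.shortest_path(kept, u, v)
                entries = [(i, 1.0)]
                for a, b in zip(path[:-1], path[1:]):
                    entries.append((eidx[frozenset((a, b))], -1.0))
                rows_A.append(entries)
                lb.append(-np.inf)
                ub.append(0.0)
                violated = True
        # seed separation: different seeds joined in one component
        by_comp = {}
        for n, sid in seeds.items():
            by_comp.setdefault(comp_of[n], []).append((n, sid))
        for comp, members in by_comp.items():
            sids = {sid for _, sid in members}
            if len(sids) > 1:
                (n1, _), (n2, _) = members[0], next(m for m in members if m[1] != members[0][1])
                path = nx.shortest_path(kept, n1, n2)
                entries = [(eidx[frozenset((a, b))], 1.0) for a, b in zip(path[:-1], path[1:])]
                rows_A.append(entries)
                lb.append(1.0)
                ub.append(np.inf)
                violated = True
        if not violated:
            clusters = dict(comp_of)
            return MulticutSolution(clusters, float(weights[y == 1].sum()))
    raise InfeasibleModelError("multicut constraint generation did not converge")


def split_multiseed_component(labelmap, component, seeds_um, voxel_size):
    """Split a fragment holding several seeds by geodesic nearest-seed regions.

    Voxels of ``component`` are reassigned to new labels, one per seed, by
    geodesic distance within the component.
    """
    lab = np.asarray(labelmap).copy()
    vs = np.asarray(voxel_size, dtype=float)
    mask = lab == component
    seeds_um = np.atleast_2d(np.asarray(seeds_um, dtype=float))
    if len(seeds_um) < 2:
        return lab
    costs = np.where(mask, 1.0, np.inf)
    dists = []
    for s in seeds_um:
        vox = np.clip(np.round(s / vs - 0.5).astype(int), 0, np.array(lab.shape) - 1)
        mcp = MCP_Geometric(costs, sampling=tuple(vs))
        d, _ = mcp.find_costs([tuple(vox)])
        dists.append(d)
    dists = np.stack(dists)
    nearest = np.argmin(dists, axis=0)
    base = lab.max()
    for si in range(len(seeds_um)):
        lab[mask & (nearest == si)] = base + 1 + si
    return lab


def assign_orphans(solution: MulticutSolution, graph, seeds=None):
    """Merge seedless clusters into the cluster of the nearest seed.

    Distance is Euclidean between cluster centroid and seed-fragment
    centroid; ties break toward the lowest seed id.
    """
    g = graph
    if seeds is None:
        seeds = {n: d["seeds"][0] for n, d in g.nodes(data=True) if d.get("seeds")}
    if not seeds:
        raise MeiotrackError("no seeds to assign orphans to")
    cl = dict(solution.cluster_of)
    seeded_clusters = {cl[n]: n for n in seeds}
    clusters = {}
    for n, c in cl.items():
        clusters.setdefault(c, []).append(n)
    for c, members in clusters.items():
        if c in seeded_clusters:
            continue
        w = np.array([g.nodes[n]["volume"] for n in members])
        cent = np.average([g.nodes[n]["centroid"] for n in members], axis=0, weights=w)
        best = None
        for n, sid in sorted(seeds.items(), key=lambda kv: kv[1]):
            d = float(np.linalg.norm(cent - np.asarray(g.nodes[n]["centroid"])))
            if best is None or d < best[0] - 1e-12:
                best = (d, cl[n])
        for n in members:
            cl[n] = best[1]
    return MulticutSolution(cl, solution.total_cut_area)


def segment_chromosomes(image, voxel_size, seeds_um, config: SegConfig | None = None):
    """Full seeded segmentation: threshold, clean, watershed, multicut.

    Returns ``(cluster_labelmap, fragment_labelmap, graph, solution)`` on the
    isotropic grid produced by :func:`preprocess` (its voxel size is also
    returned).
    """
    cfg = config or SegConfig()
    img, vs = preprocess(image, voxel_size, cfg)
    mask = adaptive_multithreshold(img, vs, cfg)
    mask = clean_mask(mask, cfg)
    frags = watershed_split(mask, vs, cfg)
    # separate fragments containing several seeds by geodesic distance
    graph = build_contact_graph(frags, vs, seeds_um)
    for n, data in list(graph.nodes(data=True)):
        if len(data.get("seeds", [])) > 1:
            frags = split_multiseed_component(frags, n, np.asarray(seeds_um)[data["seeds"]], vs)
    graph = build_contact_graph(frags, vs, seeds_um)
    sol = solve_multicut(graph)
    sol = assign_orphans(sol, graph)
    out = np.zeros_like(frags)
    seeds_of_cluster = {}
    for n, data in graph.nodes(data=True):
        if data.get("seeds"):
            seeds_of_cluster[sol.cluster_of[n]] = data["seeds"][0]
    for n in graph.nodes():
        cid = sol.cluster_of[n]
        out[frags == n] = seeds_of_cluster.get(cid, -1) + 1
    return out, frags, graph, sol, vs
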