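"""Geographic barrier detection on a network of sample sites.

Sites are triangulated (Delaunay) in an equirectangular projection; every
Delaunay edge carries the lexical distance between its endpoint variants and
has a dual Voronoi segment.  Monmonier's maximum-difference algorithm seeds
a barrier at the unused edge with the largest distance and extends its dual
polyline in both directions, always crossing the adjacent unused edge with
the largest distance, until it exits the network or closes a loop.
Successive barriers exclude the edges crossed by earlier ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Voronoi

from .cognate import DistanceMatrix
from .errors import DataError, GeometryError

log = logging.getLogger(__name__)

Edge = tuple[int, int]  # Delaunay edge as (min site index, max site index)


@dataclass
class GeoNetwork:
    """Delaunay triangulation of sites with its Voronoi dual.

    ``dual`` maps each Delaunay edge to its Voronoi segment as a pair of
    vertex keys; finite Voronoi vertices are ints, clipped infinite ends are
    unique ``("out", edge)`` keys that act as network boundary points.
    ``vertex_coords`` positions every vertex key in projected space.
    """

    ids: list[str]
    lonlat: np.ndarray            # (n, 2) degrees
    xy: np.ndarray                # (n, 2) projected
    edges: list[Edge]
    edge_distance: dict[Edge, float]
    dual: dict[Edge, tuple]
    vertex_coords: dict
    vertex_edges: dict = field(default_factory=dict)  # vertex key -> incident edges

    def __post_init__(self):
        if not self.vertex_edges:
            for e, (a, b) in self.dual.items():
                self.vertex_edges.setdefault(a, []).append(e)
                self.vertex_edges.setdefault(b, []).append(e)

    def is_boundary_vertex(self, v) -> bool:
        return isinstance(v, tuple) and v[0] == "out"


@dataclass
class Barrier:
    """Ordered Voronoi polyline with the Delaunay edges it crosses."""

    segments: list[tuple]          # consecutive (v_from, v_to) vertex keys
    crossed: list[Edge]            # one Delaunay edge per segment, in order
    termination: str               # "network-limit" or "loop"

    def polyline(self, net: GeoNetwork) -> list[tuple[float, float]]:
        pts = [self.segments[0][0]] + [s[1] for s in self.segments]
        return [tuple(net.vertex_coords[v]) for v in pts]


def project(lonlat: np.ndarray) -> np.ndarray:
    """Equirectangular projection: lon scaled by cos(mean latitude)."""
    lat0 = math.radians(float(np.mean(lonlat[:, 1])))
    out = np.array(lonlat, dtype=float)
    out[:, 0] = out[:, 0] * math.cos(lat0)
    return out


def build_network(ids, lonlat, d: DistanceMatrix) -> GeoNetwork:
    """Triangulate the sites and attach lexical distances and Voronoi duals.

    The Voronoi diagram's infinite ridges are clipped to a bounding box
    padded by 20% of the site extent; their clipped endpoints mark the
    "limit of the network" for the barrier traversal.
    """
    ids = list(ids)
    lonlat = np.asarray(lonlat, dtype=float)
    if len(ids) < 3:
        raise GeometryError("need at least 3 sites")
    if len({tuple(p) for p in lonlat.round(9)}) < len(ids):
        raise GeometryError("duplicate site coordinates")
    missing = [t for t in ids if t not in d.taxa]
    if missing:
        raise DataError(f"distance matrix lacks sites: {missing}")
    xy = project(lonlat)
    span = xy.max(axis=0) - xy.min(axis=0)
    if np.any(span <= 0) or _collinear(xy):
        raise GeometryError("sites are collinear or degenerate")
    try:
        vor = Voronoi(xy)
        n_delaunay = _delaunay_edge_count(xy)
        if len(vor.ridge_points) < n_delaunay:
            # cocircular degeneracy dropped ridges; joggle the input
            vor = Voronoi(xy, qhull_options="Qbb Qc QJ")
    except Exception as exc:
        raise GeometryError(f"triangulation failed: {exc}") from exc
    pad = 0.2 * float(span.max())
    lo = xy.min(axis=0) - pad
    hi = xy.max(axis=0) + pad
    center = xy.mean(axis=0)
    tidx = {t: i for i, t in enumerate(d.taxa)}
    edges: list[Edge] = []
    edge_distance: dict[Edge, float] = {}
    dual: dict[Edge, tuple] = {}
    vertex_coords: dict = {i: tuple(v) for i, v in enumerate(vor.vertices)}
    for (p, q), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        p, q = int(p), int(q)
        e: Edge = (min(p, q), max(p, q))
        edges.append(e)
        edge_distance[e] = float(d.d[tidx[ids[e[0]]], tidx[ids[e[1]]]])
        if v1 >= 0 and v2 >= 0:
            dual[e] = (v1, v2)
        else:
            fin = v2 if v1 < 0 else v1
            # direction of the infinite end: perpendicular to the edge,
            # pointing away from the site centroid
            t = xy[q] - xy[p]
            t /= np.linalg.norm(t)
            n = np.array([-t[1], t[0]])
            midpoint = (xy[p] + xy[q]) / 2
            if np.dot(midpoint - center, n) < 0:
                n = -n
            far = _clip_ray(np.array(vor.vertices[fin]), n, lo, hi)
            key = ("out", e)
            vertex_coords[key] = tuple(far)
            dual[e] = (fin, key)
    edges.sort()
    return GeoNetwork(ids, lonlat, xy, edges, edge_distance, dual, vertex_coords)


def _delaunay_edge_count(xy: np.ndarray) -> int:
    from scipy.spatial import Delaunay

    tri = Delaunay(xy)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
    return len(edges)


def _collinear(xy: np.ndarray) -> bool:
    v = xy - xy[0]
    return np.linalg.matrix_rank(v, tol=1e-9) < 2


def _clip_ray(origin, direction, lo, hi):
    """Point where the ray leaves the padded bounding box (or origin+dir if
    the origin already lies outside)."""
    ts = []
    for dim in range(2):
        if abs(direction[dim]) > 1e-12:
            for bound in (lo[dim], hi[dim]):
                t = (bound - origin[dim]) / direction[dim]
                if t > 1e-12:
                    ts.append(t)
    t = min(ts) if ts else 1.0
    return origin + direction * t


def monmonier_barrier(net: GeoNetwork, used: set[Edge] | None = None) -> Barrier:
    """Trace one barrier by Monmonier's maximum-difference traversal.

    Seeds at the unused Delaunay edge with the largest attached distance
    (ties: smallest ``(i, j)`` index pair) and grows the dual polyline from
    both ends, each step crossing the adjacent unused, uncrossed edge with
    the largest distance.  An end stops at the network limit (a clipped
    Voronoi vertex) or when the polyline revisits one of its own vertices
    (loop).
    """
    used = set(used or ())
    free = [e for e in net.edges if e not in used]
    if not free:
        raise DataError("no unused edges left for barrier extraction")
    seed = max(free, key=lambda e: (net.edge_distance[e], (-e[0], -e[1])))
    v1, v2 = net.dual[seed]
    crossed = {seed}
    visited = {v1, v2}
    # grow two arms from the seed segment; each arm is a list of (from, to)
    arms: list[list[tuple]] = [[], []]
    terminations = []
    for arm_i, tip in enumerate((v1, v2)):
        cur = tip
        reason = None
        while True:
            if net.is_boundary_vertex(cur):
                reason = "network-limit"
                break
            cand = [e for e in net.vertex_edges.get(cur, ())
                    if e not in used and e not in crossed]
            if not cand:
                reason = "network-limit"  # dead end: nowhere further to go
                break
            nxt = max(cand, key=lambda e: (net.edge_distance[e], (-e[0], -e[1])))
            a, b = net.dual[nxt]
            new_tip = b if a == cur else a
            crossed.add(nxt)
            arms[arm_i].append((cur, new_tip))
            if new_tip in visited:
                reason = "loop"
                cur = new_tip
                break
            visited.add(new_tip)
            cur = new_tip
        terminations.append(reason)
    # assemble ordered polyline: arm0 reversed, seed segment, arm1
    segments = [(b, a) for a, b in reversed(arms[0])] + [(v1, v2)] + arms[1]
    crossed_ordered = [_edge_of_segment(net, s, crossed) for s in segments]
    termination = "loop" if "loop" in terminations else "network-limit"
    return Barrier(segments, crossed_ordered, termination)


def _edge_of_segment(net: GeoNetwork, seg: tuple, crossed: set) -> Edge:
    a, b = seg
    for e in crossed:
        if set(net.dual[e]) == {a, b}:
            return e
    raise DataError("internal: segment without a crossed edge")


def extract_barriers(net: GeoNetwork, n: int) -> list[Barrier]:
    """Extract ``n`` barriers sequentially, each excluding the Delaunay
    edges crossed by earlier ones; returns fewer (with a warning) if the
    network runs out of edges."""
    if n < 1:
        raise DataError("n must be >= 1")
    used: set[Edge] = set()
    out: list[Barrier] = []
    for i in range(n):
        try:
            b = monmonier_barrier(net, used)
        except DataError:
            log.warning("network exhausted after %d of %d barriers", i, n)
            break
        out.append(b)
        used.update(b.crossed)
    return out


# ---------------------------------------------------------------------------
# I/O


def read_sites(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Sites CSV with columns id, lon, lat."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    for col in ("id", "lon", "lat"):
        if col not in df.columns:
            raise DataError(f"sites file missing column {col!r}")
    return [str(i) for i in df["id"]], df[["lon", "lat"]].to_numpy(dtype=float)


def barriers_to_geojson(barriers: list[Barrier], net: GeoNetwork) -> dict:
    """Barriers as GeoJSON LineStrings in projected coordinates."""
    feats = []
    for i, b in enumerate(barriers):
        feats.append({
            "type": "Feature",
            "properties": {
                "barrier": i + 1,
                "termination": b.termination,
                "crossed_edges": [[net.ids[e[0]], net.ids[e[1]]] for e in b.crossed],
            },
            "geometry": {"type": "LineString",
                         "coordinates": [list(p) for p in b.polyline(net)]},
        })
    return {"type": "FeatureCollection", "features": feats}
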