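"""Parametric septum outline, triangulation and anatomical landmark regions.

The cartilage midplane lives in the x-y (sagittal) plane: x runs posterior to
anterior ("anteroposterior"), y inferior to superior ("cephalocaudal"); the
out-of-plane axis z is lateral.  Outline coordinates are millimetres; meshes
are converted to SI metres.

The idealized outline is a hexagon whose six edges carry the anatomical
boundary labels: the rigid bony interfaces (``nasal_bone``, ``ethmoid``,
``vomer``, ``hard_palate``) and the two free edges (``dorsal_free``,
``caudal_free``).  The anterior septal angle (ASA, taken as the nasal tip)
is the junction of the two free edges; the anterior nasal spine (ANS) is the
anterior end of the inferior fixed edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

BOUNDARY_LABELS = ("nasal_bone", "ethmoid", "vomer", "hard_palate", "dorsal_free", "caudal_free")
FIXED_LABELS = ("nasal_bone", "ethmoid", "vomer", "hard_palate")
FREE_LABELS = ("dorsal_free", "caudal_free")

MM = 1e-3  # mm -> m


class GeometryError(ValueError):
    """Raised for degenerate or self-intersecting outline geometry."""


class MeshingError(RuntimeError):
    """Raised when triangulation fails to conform to the outline."""


@dataclass(frozen=True)
class OutlineParams:
    """Dimension set of the idealized septum outline (all lengths mm).

    Only the nasal-bone overlap length is an anatomically reported constant
    (normal range 3-15 mm, default 14 mm); the remaining dimensions are
    documented surrogates for a typical adult quadrangular cartilage.
    """

    inferior_length: float = 38.0      # hard-palate (maxillary crest) edge
    posterior_height: float = 26.0     # vomer + ethmoid posterior edge
    caudal_length: float = 24.0        # free caudal edge, ANS -> tip
    nasal_bone_overlap: float = 14.0   # bony overlap along the dorsum
    caudal_rake_deg: float = 20.0      # anterior tilt of the caudal edge from vertical
    ethmoid_fraction: float = 0.55     # upper fraction of the posterior edge that is ethmoid

    def validate(self) -> None:
        for name in ("inferior_length", "posterior_height", "caudal_length", "nasal_bone_overlap"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"dimension {name!r} must be positive")
        if not (3.0 <= self.nasal_bone_overlap <= 15.0):
            raise GeometryError(
                f"nasal_bone_overlap = {self.nasal_bone_overlap} mm outside the normal 3-15 mm range"
            )
        if not (0.0 < self.ethmoid_fraction < 1.0):
            raise GeometryError("ethmoid_fraction must lie in (0, 1)")


@dataclass
class SeptumOutline:
    """Labeled simple polygon of the cartilage midplane (mm).

    ``vertices`` is an ordered (counter-clockwise) array of shape (n, 2);
    ``edge_labels[i]`` labels the segment from vertex i to vertex i+1 (cyclic).
    """

    vertices: np.ndarray
    edge_labels: list[str]
    tip_point: np.ndarray
    ans_point: np.ndarray
    nasal_bone_overlap: float

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise GeometryError("vertices must be an (n, 2) array")
        if len(self.edge_labels) != len(self.vertices):
            raise GeometryError("need one edge label per polygon segment")
        unknown = set(self.edge_labels) - set(BOUNDARY_LABELS)
        if unknown:
            raise GeometryError(f"unknown edge labels: {sorted(unknown)}")
        poly = self.polygon
        if not poly.is_valid or not poly.is_simple:
            raise GeometryError("outline polygon is self-intersecting or otherwise invalid")
        if self.area <= 0:
            raise GeometryError("outline must be counter-clockwise with positive area")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        """Signed shoelace area (mm^2); positive for CCW orientation."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def mean_radius(self) -> float:
        c = self.vertices.mean(axis=0)
        return float(np.linalg.norm(self.vertices - c, axis=1).mean())

    def segments(self):
        """Yield (start, end, label) per polygon segment."""
        n = len(self.vertices)
        for i in range(n):
            yield self.vertices[i], self.vertices[(i + 1) % n], self.edge_labels[i]


@dataclass
class LabeledMesh:
    """Triangulated midplane in SI metres with labeled boundary node sets.

    ``node_sets`` maps each boundary label to node indices on it (corner
    nodes belong to both adjacent sets) plus singleton sets ``tip`` and
    ``ans``.  ``boundary_edges`` maps each label to an (m, 2) array of node
    pairs so that every boundary edge of the triangulation carries exactly
    one label.  ``thickness`` is per-element (m).
    """

    nodes: np.ndarray
    triangles: np.ndarray
    node_sets: dict[str, np.ndarray]
    boundary_edges: dict[str, np.ndarray]
    thickness: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    @property
    def tip_node(self) -> int:
        return int(self.node_sets["tip"][0])

    @property
    def ans_node(self) -> int:
        return int(self.node_sets["ans"][0])

    def triangle_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                      - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def with_thickness(self, thickness: np.ndarray) -> "LabeledMesh":
        t = np.broadcast_to(np.asarray(thickness, dtype=float), (self.n_elements,)).copy()
        if np.any(t <= 0):
            raise GeometryError("thickness must be positive everywhere")
        return LabeledMesh(self.nodes, self.triangles, self.node_sets, self.boundary_edges, t)

    def tip_adjacent_nodes(self) -> tuple[int, int]:
        """The two boundary nodes flanking the tip (one dorsal, one caudal)."""
        tip = self.tip_node
        out = []
        for label in ("dorsal_free", "caudal_free"):
            edges = self.boundary_edges[label]
            nbrs = np.unique(edges[np.any(edges == tip, axis=1)])
            nbrs = nbrs[nbrs != tip]
            if len(nbrs) == 0:
                raise GeometryError(f"tip node has no neighbour on {label} edge")
            out.append(int(nbrs[0]))
        return tuple(out)


@dataclass
class LandmarkRegions:
    """Element-index sets around the four anatomical fatigue landmarks."""

    regions: dict[str, np.ndarray]
    radius: float

    def __getitem__(self, name: str) -> np.ndarray:
        return self.regions[name]

    def names(self):
        return list(self.regions)


def build_idealized_outline(params: OutlineParams | None = None) -> SeptumOutline:
    """Construct the hexagonal idealized cartilage outline from a dimension set.

    Vertices run counter-clockwise from the posterior-inferior corner:
    hard palate -> ANS -> (caudal free) -> tip/ASA -> (dorsal free) ->
    BC junction -> (nasal bone) -> posterior-superior corner -> (ethmoid) ->
    VEJ -> (vomer) -> back to start.
    """
    p = params or OutlineParams()
    p.validate()

    rake = math.radians(p.caudal_rake_deg)
    p0 = np.array([0.0, 0.0])                       # posterior-inferior corner
    p1 = np.array([p.inferior_length, 0.0])         # ANS
    tip = p1 + p.caudal_length * np.array([math.sin(rake), math.cos(rake)])  # ASA
    p4 = np.array([0.0, p.posterior_height])        # posterior-superior corner
    dorsal = tip - p4
    dorsal_len = float(np.linalg.norm(dorsal))
    if p.nasal_bone_overlap >= dorsal_len:
        raise GeometryError("nasal-bone overlap exceeds the dorsal edge length")
    p3 = p4 + dorsal * (p.nasal_bone_overlap / dorsal_len)  # BC junction
    p5 = np.array([0.0, p.posterior_height * (1.0 - p.ethmoid_fraction)])  # VEJ

    vertices = np.array([p0, p1, tip, p3, p4, p5])
    labels = ["hard_palate", "caudal_free", "dorsal_free", "nasal_bone", "ethmoid", "vomer"]
    return SeptumOutline(vertices, labels, tip.copy(), p1.copy(), p.nasal_bone_overlap)


def _subdivide_boundary(outline: SeptumOutline, h_mm: float):
    """Sample the outline at spacing <= h_mm.

    Returns (points (n, 2), labels: per-point set of segment labels,
    edge_label: per consecutive point pair (cyclic) the single label of the
    outline segment it lies on).
    """
    pts: list[np.ndarray] = []
    labels: list[set] = []
    edge_label: list[str] = []
    for a, b, lab in outline.segments():
        seg = b - a
        length = float(np.linalg.norm(seg))
        if length <= 1e-12:
            raise GeometryError("outline contains a zero-length segment")
        ndiv = max(1, int(math.ceil(length / h_mm)))
        for k in range(ndiv):  # k = 0 is the segment's start vertex
            pts.append(a + seg * (k / ndiv))
            labels.append({lab})
            edge_label.append(lab)
    pts_arr = np.asarray(pts)
    # each outline vertex starts one segment and ends the previous one:
    # give it both labels so fixed/free corners land in the fixed node set
    n_seg = len(outline.vertices)
    start_of_segment = 0
    starts = []
    for a, b, lab in outline.segments():
        starts.append(start_of_segment)
        length = float(np.linalg.norm(b - a))
        start_of_segment += max(1, int(math.ceil(length / h_mm)))
    for i in range(n_seg):
        labels[starts[i]].add(outline.edge_labels[i - 1])
    assert len(edge_label) == len(pts_arr)
    return pts_arr, labels, edge_label


def _repair_slivers(points: np.ndarray, tris: np.ndarray, rel_tol: float = 1e-9) -> np.ndarray:
    """Remove (near-)zero-area triangles by flipping their long-edge diagonal.

    Collinear boundary triples occasionally survive Delaunay filtering as
    degenerate slivers; flipping the edge shared with the neighbouring
    triangle restores two positive-area elements without moving any node.
    """
    tris = tris.copy()

    def area2(t):
        a, b, c = points[t[0]], points[t[1]], points[t[2]]
        return (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])

    for _ in range(10):
        a2 = np.array([abs(area2(t)) for t in tris])
        tol = rel_tol * a2.max()
        bad = np.flatnonzero(a2 <= tol)
        if len(bad) == 0:
            return tris
        edge_map: dict[frozenset, list[int]] = {}
        for e, t in enumerate(tris):
            for pair in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                edge_map.setdefault(frozenset(map(int, pair)), []).append(e)
        e0 = int(bad[0])
        t = tris[e0]
        # long edge = the one opposite the middle (collinear) vertex
        lens = [np.linalg.norm(points[t[(i + 1) % 3]] - points[t[(i + 2) % 3]]) for i in range(3)]
        mid = int(np.argmax(lens))
        i, j = int(t[(mid + 1) % 3]), int(t[(mid + 2) % 3])
        b = int(t[mid])
        nbrs = [e for e in edge_map[frozenset((i, j))] if e != e0]
        if nbrs:
            # flip the long-edge diagonal with the neighbouring triangle
            e1 = nbrs[0]
            d = int(next(v for v in tris[e1] if v not in (i, j)))
            tris[e0] = (i, b, d)
            tris[e1] = (b, j, d)
        else:
            # zero-width flap on a straight boundary run: its short edges are
            # also carried by interior triangles, so it can be dropped
            if (len(edge_map[frozenset((b, i))]) < 2
                    or len(edge_map[frozenset((b, j))]) < 2):
                raise MeshingError("degenerate boundary sliver without a repair")
            tris = np.delete(tris, e0, axis=0)
    raise MeshingError("sliver repair did not converge")


def _triangulation_edges(tris: np.ndarray) -> set:
    e = set()
    for a, b, c in tris:
        e.add(frozenset((int(a), int(b))))
        e.add(frozenset((int(b), int(c))))
        e.add(frozenset((int(c), int(a))))
    return e


def mesh_outline(outline: SeptumOutline, target_edge_length: float,
                 thickness: float = 2e-3) -> LabeledMesh:
    """Triangulate the outline with roughly uniform element size.

    ``target_edge_length`` and ``thickness`` are in metres (SI).  Boundary
    nodes are placed exactly on the outline so that the mesh tiles the
    polygon; total triangle area matches the shoelace area to ~1e-9
    relative tolerance, otherwise a :class:`MeshingError` is raised.
    """
    if target_edge_length <= 0:
        raise GeometryError("target_edge_length must be positive")
    h_mm = target_edge_length / MM
    # compare against contiguous same-label chains: densified (perturbed)
    # outlines legitimately contain many sub-h polyline pieces
    chain_lengths: dict[int, float] = {}
    chain_id = 0
    prev_label = None
    first_label = outline.edge_labels[0]
    for a, b, lab in outline.segments():
        if lab != prev_label:
            chain_id += 1
            prev_label = lab
        chain_lengths[chain_id] = chain_lengths.get(chain_id, 0.0) + float(
            np.linalg.norm(b - a)
        )
    if len(chain_lengths) > 1 and outline.edge_labels[-1] == first_label:
        # cyclic wrap: last chain continues into the first
        chain_lengths[1] += chain_lengths.pop(chain_id)
    if h_mm >= min(chain_lengths.values()):
        raise GeometryError(
            "target edge length must be smaller than the shortest labeled outline segment"
        )

    poly = outline.polygon
    bpts, blabels, edge_label = _subdivide_boundary(outline, h_mm)

    for attempt in range(6):
        n_bnd = len(bpts)
        # interior candidates: staggered grid, kept clear of the boundary so
        # boundary edges stay Delaunay-conforming
        xmin, ymin = bpts.min(axis=0) - h_mm
        xmax, ymax = bpts.max(axis=0) + h_mm
        xs = np.arange(xmin, xmax, h_mm)
        ys = np.arange(ymin, ymax, h_mm * math.sqrt(3) / 2)
        gx, gy = np.meshgrid(xs, ys)
        gx[1::2] += 0.5 * h_mm
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        inside = shapely.contains_xy(poly, grid[:, 0], grid[:, 1])
        grid = grid[inside]
        if len(grid):
            ring = shapely.LineString(np.vstack([bpts, bpts[:1]]))
            d = shapely.distance(shapely.points(grid), ring)
            grid = grid[d >= 0.71 * h_mm]

        points = np.vstack([bpts, grid]) if len(grid) else bpts.copy()
        tri = Delaunay(points)
        cents = points[tri.simplices].mean(axis=1)
        keep = shapely.contains_xy(poly, cents[:, 0], cents[:, 1])
        tris = _repair_slivers(points, tri.simplices[keep])

        edges = _triangulation_edges(tris)
        missing = [i for i in range(n_bnd)
                   if frozenset((i, (i + 1) % n_bnd)) not in edges]
        if not missing:
            break
        # split non-conforming boundary edges and retry
        new_pts, new_lab, new_elab = [], [], []
        for i in range(n_bnd):
            new_pts.append(bpts[i]); new_lab.append(blabels[i])
            lab = edge_label[i]
            if i in missing:
                mid = 0.5 * (bpts[i] + bpts[(i + 1) % n_bnd])
                new_pts.append(mid); new_lab.append({lab})
                new_elab.extend([lab, lab])
            else:
                new_elab.append(lab)
        bpts, blabels, edge_label = np.array(new_pts), new_lab, new_elab
    else:
        raise MeshingError(
            f"triangulation failed to conform to the outline near boundary "
            f"point(s) {missing[:5]} after refinement"
        )

    # drop orphan nodes (interior points not used by any kept triangle)
    used = np.unique(tris)
    if len(used) < len(points):
        remap = -np.ones(len(points), dtype=int)
        remap[used] = np.arange(len(used))
        if np.any(remap[:len(bpts)] < 0):
            raise MeshingError("a boundary node was orphaned during triangulation")
        points = points[used]
        tris = remap[tris]

    # orient all triangles CCW
    p = points[tris]
    a2 = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
          - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    flip = a2 < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    areas = np.abs(a2) / 2.0

    total = float(areas.sum())
    if abs(total - outline.area) > 1e-9 * outline.area:
        raise MeshingError(
            f"mesh area {total:.9g} mm^2 does not match outline area "
            f"{outline.area:.9g} mm^2 (non-conforming boundary)"
        )
    if np.any(areas <= 0):
        raise MeshingError("triangulation produced degenerate elements")

    n_bnd = len(bpts)
    node_sets: dict[str, list] = {lab: [] for lab in BOUNDARY_LABELS}
    for i in range(n_bnd):
        for lab in blabels[i]:
            node_sets[lab].append(i)
    bedges: dict[str, list] = {lab: [] for lab in BOUNDARY_LABELS}
    for i in range(n_bnd):
        bedges[edge_label[i]].append((i, (i + 1) % n_bnd))

    sets = {lab: np.array(sorted(ix), dtype=int) for lab, ix in node_sets.items()}
    tip_i = int(np.argmin(np.linalg.norm(bpts - outline.tip_point, axis=1)))
    ans_i = int(np.argmin(np.linalg.norm(bpts - outline.ans_point, axis=1)))
    sets["tip"] = np.array([tip_i], dtype=int)
    sets["ans"] = np.array([ans_i], dtype=int)

    mesh = LabeledMesh(
        nodes=points * MM,
        triangles=np.ascontiguousarray(tris, dtype=int),
        node_sets=sets,
        boundary_edges={lab: np.array(e, dtype=int).reshape(-1, 2) for lab, e in bedges.items()},
        thickness=np.full(len(tris), float(thickness)),
    )
    if np.any(mesh.thickness <= 0):
        raise GeometryError("thickness must be positive")
    return mesh


# landmark locations: ANS node, BC junction (dorsal_free/nasal_bone corner),
# VEJ (ethmoid/vomer corner), vomerine groove (whole inferior fixed edge)

def _corner_node(mesh: LabeledMesh, label_a: str, label_b: str) -> int:
    common = np.intersect1d(mesh.node_sets[label_a], mesh.node_sets[label_b])
    if len(common) == 0:
        raise GeometryError(f"no node joins {label_a!r} and {label_b!r}")
    return int(common[0])


def landmark_regions(mesh: LabeledMesh, radius: float) -> LandmarkRegions:
    """Elements within ``radius`` (m) of each anatomical landmark.

    The vomerine groove is treated as the whole inferior (hard-palate) fixed
    edge rather than a point: its region collects elements within the radius
    of any point of that edge.
    """
    if radius <= 0:
        raise GeometryError("radius must be positive")
    cents = mesh.centroids()
    anchors = {
        "ANS": mesh.nodes[mesh.ans_node],
        "BC_junction": mesh.nodes[_corner_node(mesh, "dorsal_free", "nasal_bone")],
        "VEJ": mesh.nodes[_corner_node(mesh, "ethmoid", "vomer")],
    }
    regions: dict[str, np.ndarray] = {}
    for name, pt in anchors.items():
        d = np.linalg.norm(cents - pt, axis=1)
        regions[name] = np.flatnonzero(d <= radius)

    groove = shapely.MultiLineString(
        [mesh.nodes[e].tolist() for e in mesh.boundary_edges["hard_palate"]]
    )
    d = shapely.distance(shapely.points(cents), groove)
    regions["vomerine_groove"] = np.flatnonzero(d <= radius)

    empty = [k for k, v in regions.items() if len(v) == 0]
    if empty:
        raise GeometryError(f"landmark region(s) empty at radius {radius}: {empty}")
    return LandmarkRegions(regions, radius)
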