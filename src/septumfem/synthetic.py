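"""Patient-like geometry surrogates and analytic validation fixtures.

Real septa differ from the idealized hexagon by smooth boundary variation
and a spatially varying cartilage thickness.  This module emulates both with
low-order harmonic perturbations driven by a single seeded generator, and
provides a simply-supported rectangular Kirchhoff plate whose closed-form
frequencies serve as the independent oracle for the bending solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fem_core import Material
from .geometry import GeometryError, LabeledMesh, SeptumOutline, MM


@dataclass(frozen=True)
class PerturbationSpec:
    """Smooth random variation standing in for a CT-derived patient model.

    boundary_amplitude: max vertex displacement as a fraction of the mean
    outline radius; thickness_amplitude: max deviation as a fraction of the
    2 mm mean; n_harmonics: number of low-order trigonometric terms (higher
    means wigglier but still smooth); seed: reproducibility.
    """

    boundary_amplitude: float = 0.05
    thickness_amplitude: float = 0.25
    n_harmonics: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("boundary_amplitude", "thickness_amplitude"):
            v = getattr(self, name)
            if not (0.0 <= v < 0.5):
                raise ValueError(f"{name} must lie in [0, 0.5)")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")


def _harmonic_profile(s: np.ndarray, rng: np.random.Generator, n_harm: int) -> np.ndarray:
    """Smooth periodic profile on s in [0, 1), normalized to max |.| = 1."""
    out = np.zeros_like(s)
    for k in range(1, n_harm + 1):
        a, b = rng.normal(size=2) / k
        out += a * np.cos(2 * np.pi * k * s) + b * np.sin(2 * np.pi * k * s)
    peak = np.abs(out).max()
    if peak == 0.0:  # pragma: no cover - measure-zero draw
        return out
    return out / peak


def perturb_outline(outline: SeptumOutline, spec: PerturbationSpec,
                    resample_mm: float = 2.0) -> SeptumOutline:
    """Smoothly perturb an outline along its vertex normals.

    The outline is densified to ~``resample_mm`` spacing first so the
    harmonic displacement renders as a smooth polyline; labels follow their
    segments and the tip/ANS points move with the boundary.  Zero amplitude
    returns the input unchanged.  If the perturbed polygon self-intersects
    the amplitude is halved and retried before failing.
    """
    if spec.boundary_amplitude == 0.0:
        return SeptumOutline(outline.vertices.copy(), list(outline.edge_labels),
                             outline.tip_point.copy(), outline.ans_point.copy(),
                             outline.nasal_bone_overlap)

    # densify: subdivide each labeled segment
    pts, labels = [], []
    tip_idx = ans_idx = None
    for a, b, lab in outline.segments():
        L = float(np.linalg.norm(b - a))
        ndiv = max(1, int(math.ceil(L / resample_mm)))
        for k in range(ndiv):
            p = a + (b - a) * (k / ndiv)
            if np.allclose(p, outline.tip_point):
                tip_idx = len(pts)
            if np.allclose(p, outline.ans_point):
                ans_idx = len(pts)
            pts.append(p)
            labels.append(lab)
    pts = np.asarray(pts)
    n = len(pts)
    if tip_idx is None or ans_idx is None:
        raise GeometryError("tip/ANS points must coincide with outline vertices")

    # vertex normals: average of adjacent segment outward normals (CCW ring)
    nxt = np.roll(pts, -1, axis=0)
    seg = nxt - pts
    seg_n = np.column_stack([seg[:, 1], -seg[:, 0]])
    seg_n /= np.linalg.norm(seg_n, axis=1, keepdims=True)
    vert_n = seg_n + np.roll(seg_n, 1, axis=0)
    norm = np.linalg.norm(vert_n, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    vert_n /= norm

    # arc-length parameter
    ds = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(ds)[:-1]]) / ds.sum()

    rng = np.random.default_rng(spec.seed)
    profile = _harmonic_profile(s, rng, spec.n_harmonics)

    amp = spec.boundary_amplitude * outline.mean_radius
    for _ in range(4):
        newpts = pts + amp * profile[:, None] * vert_n
        try:
            out = SeptumOutline(newpts, labels, newpts[tip_idx].copy(),
                                newpts[ans_idx].copy(), outline.nasal_bone_overlap)
            return out
        except GeometryError:
            amp *= 0.5
    raise GeometryError("perturbation produced a self-intersecting outline even after damping")


def thickness_field(mesh: LabeledMesh, spec: PerturbationSpec, mean_mm: float = 2.0) -> np.ndarray:
    """Smooth per-element thickness (m), mean exactly ``mean_mm``.

    A zero-mean low-order harmonic in x and y scaled so the field stays
    within mean*(1 +/- amplitude); zero amplitude gives the uniform plate.
    """
    mean_t = mean_mm * MM
    n_el = mesh.n_elements
    if spec.thickness_amplitude == 0.0:
        return np.full(n_el, mean_t)

    cents = mesh.centroids()
    lo = cents.min(axis=0)
    span = cents.max(axis=0) - lo
    span[span == 0] = 1.0
    u = (cents - lo) / span  # to [0, 1]^2

    rng = np.random.default_rng(spec.seed + 1)  # decorrelated from the boundary draw
    g = np.zeros(n_el)
    for k in range(1, spec.n_harmonics + 1):
        a, b, c, d = rng.normal(size=4) / k
        g += (a * np.cos(np.pi * k * u[:, 0]) + b * np.sin(np.pi * k * u[:, 0])
              + c * np.cos(np.pi * k * u[:, 1]) + d * np.sin(np.pi * k * u[:, 1]))

    areas = mesh.triangle_areas()
    g -= np.average(g, weights=areas)  # area-weighted zero mean
    peak = np.abs(g).max()
    if peak > 0:
        g /= peak
    return mean_t * (1.0 + spec.thickness_amplitude * g)


def kirchhoff_plate_frequencies(a: float, b: float, material: Material, t: float,
                                m_max: int = 3, n_max: int = 3) -> list[tuple[float, int, int]]:
    """Closed-form simply-supported plate frequencies f_mn (Hz), sorted.

    f_mn = (pi/2) (m^2/a^2 + n^2/b^2) sqrt(D / (rho t)).
    """
    D = material.bending_rigidity(t)
    c = 0.5 * np.pi * math.sqrt(D / (material.rho * t))
    out = [
        (c * (m * m / a**2 + n * n / b**2), m, n)
        for m in range(1, m_max + 1)
        for n in range(1, n_max + 1)
    ]
    out.sort()
    return out


def rectangular_plate_fixture(a: float, b: float, material: Material, t: float,
                              bc: str = "simply_supported",
                              target_edge_length: float | None = None,
                              ) -> tuple[LabeledMesh, list[float]]:
    """Structured right-triangle mesh of an a x b plate plus analytic frequencies.

    The mesh reuses the septum boundary labels purely as containers: the
    four plate edges are stored under ``hard_palate`` (y=0), ``ethmoid``
    (x=0), ``nasal_bone`` (y=b) and ``vomer`` (x=a); a ``boundary`` node set
    collects all edge nodes for the simply-supported (w = 0) constraint.
    """
    if a <= 0 or b <= 0 or t <= 0:
        raise ValueError("plate dimensions and thickness must be positive")
    if bc != "simply_supported":
        raise ValueError(f"unsupported boundary condition {bc!r}")
    h = target_edge_length if target_edge_length is not None else min(a, b) / 8.0
    nx = max(2, int(round(a / h)))
    ny = max(2, int(round(b / h)))
    xs = np.linspace(0.0, a, nx + 1)
    ys = np.linspace(0.0, b, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            n00, n10, n01, n11 = nid(i, j), nid(i + 1, j), nid(i, j + 1), nid(i + 1, j + 1)
            tris.append((n00, n10, n11))
            tris.append((n00, n11, n01))
    tris = np.array(tris, dtype=int)

    edge_sets = {
        "hard_palate": np.array([nid(i, 0) for i in range(nx + 1)]),
        "nasal_bone": np.array([nid(i, ny) for i in range(nx + 1)]),
        "ethmoid": np.array([nid(0, j) for j in range(ny + 1)]),
        "vomer": np.array([nid(nx, j) for j in range(ny + 1)]),
    }
    boundary = np.unique(np.concatenate(list(edge_sets.values())))
    node_sets = dict(edge_sets)
    node_sets["boundary"] = boundary
    node_sets["dorsal_free"] = np.array([], dtype=int)
    node_sets["caudal_free"] = np.array([], dtype=int)
    node_sets["tip"] = np.array([nid(nx, ny)], dtype=int)
    node_sets["ans"] = np.array([nid(nx, 0)], dtype=int)

    bedges = {
        "hard_palate": np.array([(nid(i, 0), nid(i + 1, 0)) for i in range(nx)]),
        "nasal_bone": np.array([(nid(i, ny), nid(i + 1, ny)) for i in range(nx)]),
        "ethmoid": np.array([(nid(0, j), nid(0, j + 1)) for j in range(ny)]),
        "vomer": np.array([(nid(nx, j), nid(nx, j + 1)) for j in range(ny)]),
        "dorsal_free": np.zeros((0, 2), dtype=int),
        "caudal_free": np.zeros((0, 2), dtype=int),
    }

    mesh = LabeledMesh(
        nodes=nodes, triangles=tris, node_sets=node_sets,
        boundary_edges=bedges, thickness=np.full(len(tris), float(t)),
    )
    freqs = [f for f, _, _ in kirchhoff_plate_frequencies(a, b, material, t)]
    return mesh, freqs
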