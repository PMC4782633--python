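"""Mode-shape taxonomy: tilt (I), C-shape (II), S-shape (III) or in-plane ("-").

A mode is first screened by its out-of-plane modal-mass fraction; below the
threshold ``tau`` the mode vibrates in-plane and carries no deformation
shape (the dash entry).  Out-of-plane modes are labeled by the number of
connected same-sign lobes of the transverse field w: one lobe is a septal
tilt, two lobes (one nodal line) a C-shape, three or more lobes an S-shape
(counts above three are folded into type III with a warning, since the
clinical taxonomy stops at the S-shape).  C-shape orientation follows the
principal axis of the nodal band: a nodal line running along x is an
"anteroposterior" C, along y "cephalocaudal".

Each classification also carries a ranking of the four anatomical fatigue
landmarks by the peak modal von Mises stress inside their regions.  Modal
amplitudes are arbitrary, so only hotspot locations and rankings are
meaningful — never absolute stress values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .fem_core import Material, cst_b_matrix, dkt_b_matrix
from .geometry import LabeledMesh, LandmarkRegions
from .modal import Mode, ModeSet
from .preload import von_mises_plane

TYPE_NAMES = {0: "-", 1: "I", 2: "II", 3: "III"}


@dataclass
class ModeClassification:
    """Per-mode deviation label and anatomical stress-hotspot ranking."""

    mode_index: int                      # 1-based position in the merged set
    frequency: float                     # Hz
    family: str
    out_of_plane_fraction: float
    type_label: str                      # "I" | "II" | "III" | "-"
    type_numeric: int                    # 1 | 2 | 3 | 0 (dash)
    sign_region_count: int | None        # undefined (None) for dash modes
    nodal_line_orientation: str          # anteroposterior | cephalocaudal | mixed | none
    hotspots: list[tuple[str, float]] = field(default_factory=list)  # (landmark, peak modal vM)


def out_of_plane_fraction(mode: Mode, Mb: sp.csr_array, Mm: sp.csr_array) -> float:
    """Transverse share of the modal mass, in [0, 1].

    For the decoupled flat-plate families this is 0 for membrane modes and
    ~1 for bending modes (the consistent mass assigns a small
    rotary-inertia share of order t^2/L^2 to the rotations, so the value is
    slightly below 1); the quadratic-form definition also covers synthetic
    mixed vectors.  The in-plane screen only needs the value to clear the
    threshold tau, which it does by an order of magnitude.
    """
    if mode.family == "membrane":
        total = float(mode.shape @ (Mm @ mode.shape))
        if total <= 0:
            raise ValueError("zero total modal mass")
        return 0.0
    phi = mode.shape
    total = float(phi @ (Mb @ phi))
    if total <= 0:
        raise ValueError("zero total modal mass")
    phi_w = np.zeros_like(phi)
    phi_w[0::3] = phi[0::3]
    transverse = float(phi_w @ (Mb @ phi_w))
    return min(max(transverse / total, 0.0), 1.0)


def _node_adjacency(mesh: LabeledMesh) -> sp.csr_array:
    t = mesh.triangles
    rows = np.concatenate([t[:, 0], t[:, 1], t[:, 2]])
    cols = np.concatenate([t[:, 1], t[:, 2], t[:, 0]])
    data = np.ones(len(rows))
    n = mesh.n_nodes
    A = sp.csr_array((data, (rows, cols)), shape=(n, n))
    return A + A.T


def count_sign_regions(mesh: LabeledMesh, w: np.ndarray, eps: float = 0.02,
                       min_peak_fraction: float = 0.1) -> tuple[int, str]:
    """Count connected same-sign lobes of a nodal transverse field.

    Nodes with \\|w\\| < eps * max\\|w\\| form the nodal band and separate lobes.
    Lobes whose peak amplitude is below ``min_peak_fraction`` of the global
    maximum are ignored as numerical debris.  Returns (count, orientation of
    the nodal band's principal axis).
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (mesh.n_nodes,):
        raise ValueError("w must be a per-node scalar field")
    wmax = float(np.abs(w).max())
    if wmax == 0.0:
        raise ValueError("all-zero transverse field")
    if not (0.0 < eps < 0.1):
        raise ValueError("eps must lie in (0, 0.1)")

    nodal = np.abs(w) < eps * wmax
    active = ~nodal
    sign = np.sign(w)

    A = _node_adjacency(mesh).tocoo()
    keep = active[A.row] & active[A.col] & (sign[A.row] == sign[A.col])
    Af = sp.csr_array((A.data[keep], (A.row[keep], A.col[keep])), shape=A.shape)
    n_comp, labels = connected_components(Af, directed=False)

    peaks: dict[int, float] = {}
    for lab in np.unique(labels[active]):
        peaks[lab] = float(np.abs(w[active & (labels == lab)]).max())
    count = sum(1 for p in peaks.values() if p >= min_peak_fraction * wmax)
    count = max(count, 1)

    orientation = "none"
    if count >= 2:
        crossings = _nodal_line_points(mesh, w)
        if len(crossings) >= 2:
            pts = crossings - crossings.mean(axis=0)
            _, eigvec = np.linalg.eigh(pts.T @ pts)
            principal = eigvec[:, -1]  # direction of the nodal line(s)
            ang = np.degrees(np.arctan2(abs(principal[1]), abs(principal[0])))
            if ang <= 30.0:
                orientation = "anteroposterior"
            elif ang >= 60.0:
                orientation = "cephalocaudal"
            else:
                orientation = "mixed"
    return count, orientation


def _nodal_line_points(mesh: LabeledMesh, w: np.ndarray) -> np.ndarray:
    """Zero crossings of w on mesh edges: points lying on interior nodal lines.

    Edges whose endpoint values have strictly opposite signs are bisected by
    the nodal line at the linear-interpolation root; fixed edges (w = 0
    exactly) never produce a strict sign change, so the outline does not
    pollute the fit.
    """
    t = mesh.triangles
    ea = np.concatenate([t[:, 0], t[:, 1], t[:, 2]])
    eb = np.concatenate([t[:, 1], t[:, 2], t[:, 0]])
    keys = np.unique(np.sort(np.stack([ea, eb], axis=1), axis=1), axis=0)
    wa, wb = w[keys[:, 0]], w[keys[:, 1]]
    cross = wa * wb < 0
    if not np.any(cross):
        return np.zeros((0, 2))
    wa, wb = wa[cross], wb[cross]
    s = wa / (wa - wb)
    pa = mesh.nodes[keys[cross, 0]]
    pb = mesh.nodes[keys[cross, 1]]
    return pa + s[:, None] * (pb - pa)


def modal_von_mises(mode: Mode, mesh: LabeledMesh, material: Material) -> np.ndarray:
    """Per-element modal von Mises stress (arbitrary modal scale, Pa-shaped).

    Bending modes: surface stress at z = t/2 from the DKT curvature field,
    sigma = (t/2) * C_plane_stress @ (kxx, kyy, 2 kxy).  Membrane modes:
    CST plane stress from the in-plane shape.
    """
    n_el = mesh.n_elements
    D = material.plane_stress()
    s = np.zeros((n_el, 3))
    if mode.family == "bending":
        for e, tri in enumerate(mesh.triangles):
            B = dkt_b_matrix(mesh.nodes[tri], 1.0 / 3.0, 1.0 / 3.0)
            ue = np.concatenate([mode.shape[3 * i: 3 * i + 3] for i in tri])
            kappa = B @ ue
            s[e] = (float(mesh.thickness[e]) / 2.0) * (D @ kappa)
    else:
        for e, tri in enumerate(mesh.triangles):
            B, _ = cst_b_matrix(mesh.nodes[tri])
            ue = np.concatenate([mode.shape[2 * i: 2 * i + 2] for i in tri])
            s[e] = D @ B @ ue
    return von_mises_plane(s)


def _hotspots(vm: np.ndarray, regions: LandmarkRegions) -> list[tuple[str, float]]:
    ranked = [(name, float(vm[idx].max())) for name, idx in regions.regions.items()]
    ranked.sort(key=lambda kv: -kv[1])
    return ranked


def classify_mode(mode: Mode, mesh: LabeledMesh, regions: LandmarkRegions,
                  material: Material, Mb: sp.csr_array, Mm: sp.csr_array,
                  mode_index: int = 1, tau: float = 0.1, eps: float = 0.02) -> ModeClassification:
    """Classify one mode and rank its landmark stress hotspots."""
    frac = out_of_plane_fraction(mode, Mb, Mm)
    vm = modal_von_mises(mode, mesh, material)
    hot = _hotspots(vm, regions)

    if frac < tau:
        return ModeClassification(
            mode_index=mode_index, frequency=mode.frequency, family=mode.family,
            out_of_plane_fraction=frac, type_label="-", type_numeric=0,
            sign_region_count=None, nodal_line_orientation="none", hotspots=hot,
        )

    w = mode.shape[0::3]
    count, orientation = count_sign_regions(mesh, w, eps=eps)
    if count > 3:
        warnings.warn(
            f"mode {mode_index}: {count} sign lobes exceed the S-shape taxonomy; "
            "labeling as type III", stacklevel=2,
        )
    numeric = min(count, 3)
    return ModeClassification(
        mode_index=mode_index, frequency=mode.frequency, family=mode.family,
        out_of_plane_fraction=frac, type_label=TYPE_NAMES[numeric], type_numeric=numeric,
        sign_region_count=count, nodal_line_orientation=orientation, hotspots=hot,
    )


def classify_modeset(modes: ModeSet, mesh: LabeledMesh, regions: LandmarkRegions,
                     material: Material, Mb: sp.csr_array, Mm: sp.csr_array,
                     tau: float = 0.1, eps: float = 0.02) -> list[ModeClassification]:
    """Classify every mode of a merged set (index-aligned, 1-based)."""
    if len(modes) == 0:
        raise ValueError("empty mode set")
    return [
        classify_mode(m, mesh, regions, material, Mb, Mm, mode_index=i + 1, tau=tau, eps=eps)
        for i, m in enumerate(modes)
    ]


def type_summary(classifications: list[ModeClassification]) -> dict[str, int]:
    """Count of each type label across a classified mode set."""
    out = {"I": 0, "II": 0, "III": 0, "-": 0}
    for c in classifications:
        out[c.type_label] += 1
    return out
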