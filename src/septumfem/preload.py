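"""Membrane preload: load vectors, static solve, stress recovery, geometric stiffness.

Both loading conditions are in-plane, since only in-plane preload shifts the
bending eigenmodes of a flat plate:

* ``anteroposterior_couple`` — a pair of 1 N forces with horizontal and
  vertical components at the two nodes flanking the nasal tip, emulating an
  oblique frontal blow concentrated at the tip (simultaneously a net
  posterior push and a couple);
* ``dorsal_caudal_pressure`` — a uniform 2000 Pa pressure acting on the
  dorsal and caudal free edges, carried as an inward in-plane edge traction
  of p*t per unit length and integrated consistently.

The resulting constant-per-element membrane stresses feed the
initial-stress (geometric) stiffness used by the prestressed eigensolve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem_core import SystemMatrices, cst_b_matrix, element_geometric_stiffness, Material
from .geometry import LabeledMesh

LOAD_KINDS = ("anteroposterior_couple", "dorsal_caudal_pressure")


@dataclass(frozen=True)
class LoadCase:
    """One of the two frontal-loading conditions.

    force_magnitude is the magnitude of each force component of the tip
    couple (N); pressure_magnitude the free-edge pressure (Pa).  Exactly the
    parameter matching ``kind`` is used.
    """

    kind: str = "anteroposterior_couple"
    force_magnitude: float = 1.0
    pressure_magnitude: float = 2000.0

    def __post_init__(self) -> None:
        if self.kind not in LOAD_KINDS:
            raise ValueError(f"unknown load kind {self.kind!r}; choose from {LOAD_KINDS}")
        if self.force_magnitude < 0 or self.pressure_magnitude < 0:
            raise ValueError("load magnitudes must be non-negative")


@dataclass
class MembraneState:
    """In-plane static response: nodal displacements and per-element stresses (Pa)."""

    displacements: np.ndarray        # full (2n,) nodal u, v
    stresses: np.ndarray             # (n_el, 3): sxx, syy, txy
    von_mises: np.ndarray            # (n_el,)
    residual: float                  # relative solver residual


def _edge_element_map(mesh: LabeledMesh) -> dict[frozenset, int]:
    out: dict[frozenset, int] = {}
    for e, (a, b, c) in enumerate(mesh.triangles):
        for pair in ((a, b), (b, c), (c, a)):
            out.setdefault(frozenset((int(pair[0]), int(pair[1]))), e)
    return out


def build_load_vector(mesh: LabeledMesh, case: LoadCase) -> np.ndarray:
    """Full membrane force vector (2n,) for a load case."""
    f = np.zeros(2 * mesh.n_nodes)
    if case.kind == "anteroposterior_couple":
        # two oblique forces of magnitude F each at the tip-flanking nodes:
        # posterior push with opposed vertical components => net force + couple
        c = case.force_magnitude / np.sqrt(2.0)
        dorsal_nbr, caudal_nbr = mesh.tip_adjacent_nodes()
        f[2 * dorsal_nbr] += -c
        f[2 * dorsal_nbr + 1] += -c
        f[2 * caudal_nbr] += -c
        f[2 * caudal_nbr + 1] += +c
        return f

    p = case.pressure_magnitude
    e2el = _edge_element_map(mesh)
    for label in ("dorsal_free", "caudal_free"):
        edges = mesh.boundary_edges.get(label)
        if edges is None or len(edges) == 0:
            raise ValueError(f"mesh lacks boundary edges for {label!r}")
        for a, b in edges:
            xa, xb = mesh.nodes[a], mesh.nodes[b]
            d = xb - xa
            L = float(np.linalg.norm(d))
            # boundary loop is CCW: outward normal of edge (dx, dy) is (dy, -dx)
            n_out = np.array([d[1], -d[0]]) / L
            el = e2el.get(frozenset((int(a), int(b))))
            if el is None:
                raise ValueError("boundary edge not attached to any element")
            t = float(mesh.thickness[el])
            half = -n_out * (p * t * L / 2.0)  # inward traction, consistent (lumped-equal) split
            f[2 * a: 2 * a + 2] += half
            f[2 * b: 2 * b + 2] += half
    return f


def solve_membrane_static(sys: SystemMatrices, f: np.ndarray, mesh: LabeledMesh,
                          material: Material) -> MembraneState:
    """Solve Km u = f on free DOFs and recover CST stresses.

    ``f`` may be the full (2n,) vector or already reduced to free DOFs.
    """
    Kff, _ = sys.reduced("membrane")
    f = np.asarray(f, dtype=float)
    if f.shape == (2 * sys.n_nodes,):
        ff = f[sys.free_m]
    elif f.shape == (len(sys.free_m),):
        ff = f
    else:
        raise ValueError("force vector does not conform to the membrane DOF space")

    if len(ff) == 0:
        raise ValueError("no free membrane DOFs")
    lu = spla.splu(sp.csc_matrix(Kff))
    uf = lu.solve(ff)
    res_num = float(np.linalg.norm(Kff @ uf - ff))
    res_den = float(np.linalg.norm(ff))
    residual = res_num / res_den if res_den > 0 else 0.0
    if res_den > 0 and residual > 1e-10:
        raise RuntimeError(f"membrane static solve residual {residual:.2e} exceeds 1e-10")

    u = sys.expand("membrane", uf)
    D = material.plane_stress()
    n_el = mesh.n_elements
    stresses = np.zeros((n_el, 3))
    for e, tri in enumerate(mesh.triangles):
        B, _ = cst_b_matrix(mesh.nodes[tri])
        ue = np.concatenate([u[2 * i: 2 * i + 2] for i in tri])
        stresses[e] = D @ B @ ue
    vm = von_mises_plane(stresses)
    return MembraneState(displacements=u, stresses=stresses, von_mises=vm, residual=residual)


def von_mises_plane(stresses: np.ndarray) -> np.ndarray:
    """Plane-stress von Mises equivalent: sqrt(sxx^2 - sxx syy + syy^2 + 3 txy^2)."""
    s = np.asarray(stresses, dtype=float)
    sxx, syy, txy = s[..., 0], s[..., 1], s[..., 2]
    return np.sqrt(np.maximum(sxx**2 - sxx * syy + syy**2 + 3.0 * txy**2, 0.0))


def assemble_geometric_stiffness(mesh: LabeledMesh, state: MembraneState) -> sp.csr_array:
    """Global initial-stress stiffness on the bending DOF space (3n x 3n).

    Linear in the membrane stress state; only transverse (w) DOFs couple.
    """
    if state.stresses.shape != (mesh.n_elements, 3):
        raise ValueError("membrane state does not match the mesh")
    n = mesh.n_nodes
    rows, cols, vals = [], [], []
    for e, tri in enumerate(mesh.triangles):
        sxx, syy, txy = state.stresses[e]
        sigma = np.array([[sxx, txy], [txy, syy]])
        kg = element_geometric_stiffness(mesh.nodes[tri], float(mesh.thickness[e]), sigma)
        dofs = np.concatenate([np.arange(3) + 3 * i for i in tri])
        r, c = np.meshgrid(dofs, dofs, indexing="ij")
        rows.append(r.ravel())
        cols.append(c.ravel())
        vals.append(kg.ravel())
    Kg = sp.csr_array(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n, 3 * n),
    )
    Kg.sum_duplicates()
    return 0.5 * (Kg + Kg.T)
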