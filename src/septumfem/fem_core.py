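"""Plate finite elements and global operator assembly.

Two decoupled families live on the flat midplane:

* membrane (in-plane) — constant-strain triangles (CST), 2 DOF/node (u, v);
* bending (out-of-plane) — discrete-Kirchhoff triangles (DKT), 3 DOF/node
  (w, thx, thy) with thx = dw/dy and thy = -dw/dx (rotation-of-normal
  convention).

For a flat, midplane-symmetric plate the two families are exactly
decoupled; membrane preload couples into bending only through the
geometric (initial-stress) stiffness assembled in :mod:`septumfem.preload`.

The nasal tip is supported by a grounded spring of equal stiffness along
the three orthogonal axes, standing in for the elastic recoil of the lower
lateral cartilages; its stiffness follows the tip-cartilage cantilever
model k = 3EI/L^3 = E w h^3 / (4 L^3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import LabeledMesh, FIXED_LABELS

# DKT quadrature: mid-edge points integrate the quadratic integrand exactly
_DKT_GP = ((0.5, 0.0), (0.5, 0.5), (0.0, 0.5))


class ElementError(ValueError):
    """Raised for degenerate element geometry or invalid material data."""


@dataclass(frozen=True)
class Material:
    """Homogeneous, isotropic, linearly elastic cartilage model.

    E : Young's modulus (Pa); nu : Poisson ratio; rho : density (kg/m^3).
    """

    E: float = 5e6
    nu: float = 0.32
    rho: float = 2000.0

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ElementError("Young's modulus must be positive")
        if not (0.0 <= self.nu < 0.5):
            raise ElementError("Poisson ratio must lie in [0, 0.5)")
        if self.rho <= 0:
            raise ElementError("density must be positive")

    def plane_stress(self) -> np.ndarray:
        """Plane-stress constitutive matrix (3x3, Pa)."""
        E, nu = self.E, self.nu
        return (E / (1.0 - nu * nu)) * np.array(
            [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]]
        )

    def bending_rigidity(self, t: float) -> float:
        """Kirchhoff flexural rigidity D = E t^3 / (12 (1 - nu^2)), N m."""
        return self.E * t**3 / (12.0 * (1.0 - self.nu**2))


@dataclass(frozen=True)
class TipSpring:
    """Grounded spring at the anterior septal angle, k per orthogonal axis (N/m)."""

    k: float = 20e3

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ElementError("spring stiffness must be non-negative")


def tip_spring_from_cantilever(E: float, width: float, height: float, length: float) -> float:
    """Tip-cartilage cantilever stiffness k = 3EI/L^3 with I = w h^3 / 12 (N/m)."""
    for name, v in (("E", E), ("width", width), ("height", height), ("length", length)):
        if v <= 0:
            raise ElementError(f"{name} must be positive")
    return E * width * height**3 / (4.0 * length**3)


def _tri_geometry(tri_coords: np.ndarray):
    c = np.asarray(tri_coords, dtype=float)
    if c.shape != (3, 2):
        raise ElementError("tri_coords must be a (3, 2) array")
    x1, y1 = c[0]
    x2, y2 = c[1]
    x3, y3 = c[2]
    two_a = (x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)
    if abs(two_a) < 1e-30:
        raise ElementError("degenerate (zero-area) triangle")
    return c, two_a


def cst_b_matrix(tri_coords: np.ndarray) -> tuple[np.ndarray, float]:
    """CST strain-displacement matrix (3x6) and triangle area."""
    c, two_a = _tri_geometry(tri_coords)
    (x1, y1), (x2, y2), (x3, y3) = c
    y23, y31, y12 = y2 - y3, y3 - y1, y1 - y2
    x32, x13, x21 = x3 - x2, x1 - x3, x2 - x1
    B = np.array(
        [
            [y23, 0, y31, 0, y12, 0],
            [0, x32, 0, x13, 0, x21],
            [x32, y23, x13, y31, x21, y12],
        ]
    ) / two_a
    return B, abs(two_a) / 2.0


def element_membrane_stiffness(tri_coords: np.ndarray, material: Material, thickness: float) -> np.ndarray:
    """6x6 CST plane-stress stiffness, DOF order (u1, v1, u2, v2, u3, v3)."""
    B, area = cst_b_matrix(tri_coords)
    D = material.plane_stress()
    return thickness * area * B.T @ D @ B


def element_membrane_mass(tri_coords: np.ndarray, material: Material, thickness: float) -> np.ndarray:
    """6x6 consistent CST mass matrix."""
    _, area = _tri_geometry(tri_coords)
    area = abs(area) / 2.0
    m = material.rho * thickness * area / 12.0
    M = np.zeros((6, 6))
    pat = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]])
    for d in range(2):
        M[d::2, d::2] = m * pat
    return M


def _dkt_rotation_coeffs(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nodal coefficient matrices (6x9) of the DKT rotation field.

    The plate rotations beta = (bx, by) with bx = -w,x and by = -w,y are
    interpolated quadratically over the 6-node triangle (corners 0-2,
    midsides 3: edge 2-3, 4: edge 3-1, 5: edge 1-2).  Corner rotations
    come straight from the nodal DOFs (w, thx, thy) with thx = w,y and
    thy = -w,x; midside rotations enforce the discrete Kirchhoff
    constraints: the edge-normal rotation varies linearly, and the
    edge-tangential rotation matches the slope of the cubic Hermite
    deflection along the edge at its midpoint.
    Returns (Cx, Cy) so that bx(6 nodes) = Cx @ u, by = Cy @ u.
    """
    Cx = np.zeros((6, 9))
    Cy = np.zeros((6, 9))
    for i in range(3):
        Cx[i, 3 * i + 2] = 1.0    # bx_i = -w,x = thy
        Cy[i, 3 * i + 1] = -1.0   # by_i = -w,y = -thx
    edges = ((1, 2), (2, 0), (0, 1))  # midside node 3+k lies on edge (i, j)
    for k, (i, j) in enumerate(edges):
        d = c[j] - c[i]
        L = float(np.hypot(d[0], d[1]))
        tx, ty = d[0] / L, d[1] / L
        nx, ny = ty, -tx
        # rows picking w, thx, thy of nodes i, j
        wi, wj = 3 * i, 3 * j

        def slope_row(node):  # w,s = tx*w,x + ty*w,y = -tx*thy + ty*thx
            row = np.zeros(9)
            row[3 * node + 1] = ty
            row[3 * node + 2] = -tx
            return row

        # w,s at the edge midpoint of the Hermite cubic
        ws_mid = np.zeros(9)
        ws_mid[wj] += 3.0 / (2.0 * L)
        ws_mid[wi] -= 3.0 / (2.0 * L)
        ws_mid -= 0.25 * (slope_row(i) + slope_row(j))
        bs_mid = -ws_mid  # Kirchhoff: beta_s = -w,s

        # normal rotation: linear along the edge
        bn_i = nx * Cx[i] + ny * Cy[i]
        bn_j = nx * Cx[j] + ny * Cy[j]
        bn_mid = 0.5 * (bn_i + bn_j)

        Cx[3 + k] = bs_mid * tx + bn_mid * nx
        Cy[3 + k] = bs_mid * ty + bn_mid * ny
    return Cx, Cy


def _p2_shape_derivs(xi: float, eta: float) -> tuple[np.ndarray, np.ndarray]:
    """d/dxi and d/deta of the 6-node quadratic shape functions.

    Area coordinates L1 = 1 - xi - eta, L2 = xi, L3 = eta; corner functions
    Li(2Li - 1), midside 4 L_i L_j with midsides ordered (23, 31, 12).
    """
    L1, L2, L3 = 1.0 - xi - eta, xi, eta
    dL = {  # derivatives of (L1, L2, L3) wrt (xi, eta)
        "xi": np.array([-1.0, 1.0, 0.0]),
        "eta": np.array([-1.0, 0.0, 1.0]),
    }
    L = np.array([L1, L2, L3])
    out = []
    for var in ("xi", "eta"):
        d = dL[var]
        corner = (4.0 * L - 1.0) * d
        mid = np.array([
            4.0 * (d[1] * L[2] + L[1] * d[2]),  # edge 2-3
            4.0 * (d[2] * L[0] + L[2] * d[0]),  # edge 3-1
            4.0 * (d[0] * L[1] + L[0] * d[1]),  # edge 1-2
        ])
        out.append(np.concatenate([corner, mid]))
    return out[0], out[1]


def dkt_b_matrix(tri_coords: np.ndarray, xi: float, eta: float) -> np.ndarray:
    """DKT curvature-displacement matrix (3x9) at area coordinate (xi, eta).

    DOF order per node: (w, thx, thy) with thx = w,y and thy = -w,x.
    Returns curvatures (bx,x ; by,y ; bx,y + by,x) of the rotation field
    beta = -grad w, i.e. the negative of the deflection curvatures; the
    bending energy and recovered stress magnitudes are unaffected.
    """
    c, two_a = _tri_geometry(tri_coords)
    Cx, Cy = _dkt_rotation_coeffs(c)
    dN_xi, dN_eta = _p2_shape_derivs(xi, eta)

    (x1, y1), (x2, y2), (x3, y3) = c
    # inverse Jacobian of the affine map (xi, eta) -> (x, y)
    y31, y12 = y3 - y1, y1 - y2
    x13, x21 = x1 - x3, x2 - x1
    dN_x = (y31 * dN_xi + y12 * dN_eta) / two_a
    dN_y = (x13 * dN_xi + x21 * dN_eta) / two_a

    B = np.empty((3, 9))
    B[0] = dN_x @ Cx
    B[1] = dN_y @ Cy
    B[2] = dN_y @ Cx + dN_x @ Cy
    return B


def element_bending_stiffness(tri_coords: np.ndarray, material: Material, thickness: float) -> np.ndarray:
    """9x9 DKT bending stiffness, DOF order (w, thx, thy) per node."""
    c, two_a = _tri_geometry(tri_coords)
    D = material.bending_rigidity(thickness) * np.array(
        [
            [1.0, material.nu, 0.0],
            [material.nu, 1.0, 0.0],
            [0.0, 0.0, (1.0 - material.nu) / 2.0],
        ]
    )
    K = np.zeros((9, 9))
    for xi, eta in _DKT_GP:
        B = dkt_b_matrix(c, xi, eta)
        K += (abs(two_a) / 6.0) * B.T @ D @ B
    return K


def element_bending_mass(tri_coords: np.ndarray, material: Material, thickness: float) -> np.ndarray:
    """9x9 consistent bending mass: linear interpolation of w plus rotary inertia."""
    _, two_a = _tri_geometry(tri_coords)
    area = abs(two_a) / 2.0
    pat = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0
    M = np.zeros((9, 9))
    M[0::3, 0::3] = material.rho * thickness * area * pat
    rot = material.rho * thickness**3 / 12.0 * area * pat
    M[1::3, 1::3] = rot
    M[2::3, 2::3] = rot
    return M


def linear_gradient_matrix(tri_coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Gradient operator G (2x3) of the linear nodal interpolant and area."""
    c, two_a = _tri_geometry(tri_coords)
    (x1, y1), (x2, y2), (x3, y3) = c
    G = np.array(
        [
            [y2 - y3, y3 - y1, y1 - y2],
            [x3 - x2, x1 - x3, x2 - x1],
        ]
    ) / two_a
    return G, abs(two_a) / 2.0


def element_geometric_stiffness(tri_coords: np.ndarray, thickness: float, sigma: np.ndarray) -> np.ndarray:
    """9x9 initial-stress stiffness from a constant membrane stress state.

    Only the transverse DOFs are loaded: Kg = t A G^T [sigma] G with the
    linear interpolant of w, where sigma is the 2x2 in-plane stress tensor.
    """
    G, area = linear_gradient_matrix(tri_coords)
    s = np.asarray(sigma, dtype=float)
    if s.shape != (2, 2):
        raise ElementError("sigma must be a 2x2 stress tensor")
    Kw = thickness * area * G.T @ s @ G
    Kg = np.zeros((9, 9))
    Kg[0::3, 0::3] = Kw
    return Kg


# ----------------------------------------------------------------- assembly

def _assemble(mesh: LabeledMesh, elem_fn, ndof: int) -> sp.csr_array:
    n = mesh.n_nodes
    rows, cols, vals = [], [], []
    for e, tri in enumerate(mesh.triangles):
        ke = elem_fn(mesh.nodes[tri], float(mesh.thickness[e]))
        dofs = np.concatenate([np.arange(ndof) + ndof * i for i in tri])
        r, c = np.meshgrid(dofs, dofs, indexing="ij")
        rows.append(r.ravel())
        cols.append(c.ravel())
        vals.append(ke.ravel())
    A = sp.csr_array(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof * n, ndof * n),
    )
    A.sum_duplicates()
    return 0.5 * (A + A.T)  # enforce exact symmetry against roundoff


def assemble_membrane(mesh: LabeledMesh, material: Material) -> tuple[sp.csr_array, sp.csr_array]:
    """Full (unconstrained) membrane stiffness and consistent mass."""
    Km = _assemble(mesh, lambda c, t: element_membrane_stiffness(c, material, t), 2)
    Mm = _assemble(mesh, lambda c, t: element_membrane_mass(c, material, t), 2)
    return Km, Mm


def assemble_bending(mesh: LabeledMesh, material: Material) -> tuple[sp.csr_array, sp.csr_array]:
    """Full (unconstrained) DKT bending stiffness and consistent mass."""
    Kb = _assemble(mesh, lambda c, t: element_bending_stiffness(c, material, t), 3)
    Mb = _assemble(mesh, lambda c, t: element_bending_mass(c, material, t), 3)
    return Kb, Mb


@dataclass
class SystemMatrices:
    """Assembled global operators plus free-DOF maps after fixing bony edges.

    Membrane DOFs are ordered (u, v) per node, bending DOFs (w, thx, thy).
    ``free_m`` / ``free_b`` index the retained DOFs of each family.
    """

    Km: sp.csr_array
    Mm: sp.csr_array
    Kb: sp.csr_array
    Mb: sp.csr_array
    free_m: np.ndarray
    free_b: np.ndarray
    n_nodes: int
    tip_node: int
    spring_k: float

    def reduced(self, which: str) -> tuple[sp.csr_array, sp.csr_array]:
        """Constrained (free-DOF) stiffness and mass of a family."""
        if which == "membrane":
            f = self.free_m
            return self.Km[np.ix_(f, f)], self.Mm[np.ix_(f, f)]
        if which == "bending":
            f = self.free_b
            return self.Kb[np.ix_(f, f)], self.Mb[np.ix_(f, f)]
        raise ValueError(f"unknown family {which!r}")

    def expand(self, which: str, x_free: np.ndarray) -> np.ndarray:
        """Scatter a free-DOF vector back to the full DOF vector (zeros on fixed)."""
        if which == "membrane":
            full = np.zeros(2 * self.n_nodes)
            full[self.free_m] = x_free
        else:
            full = np.zeros(3 * self.n_nodes)
            full[self.free_b] = x_free
        return full


def assemble_system(
    mesh: LabeledMesh,
    material: Material,
    spring: TipSpring | None = None,
    fixed_labels: tuple[str, ...] = FIXED_LABELS,
) -> SystemMatrices:
    """Assemble both families, add the tip spring, and build free-DOF maps.

    All DOFs of nodes on ``fixed_labels`` edges are eliminated (rigid bony
    interfaces).  A grounded tip spring adds k to the tip node's u, v
    (membrane) and w (bending) diagonal entries.
    """
    unknown = set(fixed_labels) - set(FIXED_LABELS)
    if unknown:
        raise ValueError(f"unknown fixed labels: {sorted(unknown)} (bony labels are {FIXED_LABELS})")

    Km, Mm = assemble_membrane(mesh, material)
    Kb, Mb = assemble_bending(mesh, material)

    tip = mesh.tip_node
    k = float(spring.k) if spring is not None else 0.0
    if k > 0.0:
        Km = sp.lil_array(Km)
        Kb = sp.lil_array(Kb)
        Km[2 * tip, 2 * tip] += k
        Km[2 * tip + 1, 2 * tip + 1] += k
        Kb[3 * tip, 3 * tip] += k
        Km = sp.csr_array(Km)
        Kb = sp.csr_array(Kb)

    fixed_nodes = np.unique(np.concatenate([mesh.node_sets[lab] for lab in fixed_labels]))
    if tip in fixed_nodes and k > 0.0:
        raise ValueError("tip node lies on a fixed edge; spring attachment invalid")
    all_nodes = np.arange(mesh.n_nodes)
    free_nodes = np.setdiff1d(all_nodes, fixed_nodes)
    if len(free_nodes) == 0:
        raise ValueError("no free DOFs remain after fixing the bony interfaces")

    free_m = np.sort(np.concatenate([2 * free_nodes, 2 * free_nodes + 1]))
    free_b = np.sort(np.concatenate([3 * free_nodes, 3 * free_nodes + 1, 3 * free_nodes + 2]))

    return SystemMatrices(
        Km=Km, Mm=Mm, Kb=Kb, Mb=Mb,
        free_m=free_m, free_b=free_b,
        n_nodes=mesh.n_nodes, tip_node=tip, spring_k=k,
    )
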