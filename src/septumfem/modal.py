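"""Generalized symmetric eigensolves for the bending and membrane families.

Solves (K + Kg) phi = omega^2 M phi on the constrained DOFs of each family,
mass-normalizes the shapes, and merges both families into a single
frequency-ordered list of the first N modes (N = 10 by default, mode 1
being the fundamental).

Small systems are solved with a dense generalized eigensolver (fully
deterministic); larger ones with shift-invert Lanczos from a fixed start
vector, so repeated runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem_core import SystemMatrices

DENSE_LIMIT = 2500  # free-DOF count below which the dense path is used

FAMILIES = ("bending", "membrane")


class EigenSolveError(RuntimeError):
    pass


class BuckledError(EigenSolveError):
    """The preload made the prestressed bending operator indefinite."""


@dataclass
class Mode:
    """One eigenmode: frequency (Hz), family tag, full mass-normalized shape.

    Bending shapes hold (w, thx, thy) per node, membrane shapes (u, v).
    """

    frequency: float
    family: str
    shape: np.ndarray


@dataclass
class ModeSet:
    """Frequency-ordered modes (1-based indexing in reports)."""

    modes: list[Mode] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.modes)

    def __iter__(self):
        return iter(self.modes)

    def __getitem__(self, i: int) -> Mode:
        return self.modes[i]

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([m.frequency for m in self.modes])

    @property
    def fundamental(self) -> Mode:
        """Mode 1, the lowest natural frequency of the merged set."""
        return self.modes[0]


def _solve_gep(K: sp.csr_array, M: sp.csr_array, n_modes: int, label: str) -> tuple[np.ndarray, np.ndarray]:
    """Smallest n_modes eigenpairs of K phi = lam M phi; M-orthonormal phi."""
    n = K.shape[0]
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if n_modes > n:
        raise EigenSolveError(f"{label}: requested {n_modes} modes from {n} DOFs")
    if n <= DENSE_LIMIT:
        Kd = K.toarray() if sp.issparse(K) else np.asarray(K, float)
        Md = M.toarray() if sp.issparse(M) else np.asarray(M, float)
        lam, vec = la.eigh(Kd, Md, subset_by_index=[0, n_modes - 1])
    else:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        try:
            lam, vec = spla.eigsh(
                sp.csc_matrix(K), k=n_modes, M=sp.csc_matrix(M),
                sigma=0.0, which="LM", v0=v0, maxiter=5000,
            )
        except spla.ArpackNoConvergence as err:  # pragma: no cover
            raise EigenSolveError(f"{label}: eigensolver failed to converge: {err}") from err
        order = np.argsort(lam)
        lam, vec = lam[order], vec[:, order]

    if lam[0] <= 0:
        raise BuckledError(
            f"{label}: non-positive eigenvalue {lam[0]:.3e}; structure buckled under preload"
        )
    # residual check and deterministic sign convention
    for j in range(n_modes):
        r = K @ vec[:, j] - lam[j] * (M @ vec[:, j])
        denom = np.linalg.norm(M @ vec[:, j]) * lam[j]
        if np.linalg.norm(r) / denom > 1e-8:
            raise EigenSolveError(f"{label}: eigenpair {j} residual exceeds 1e-8")
        i_max = int(np.argmax(np.abs(vec[:, j])))
        if vec[i_max, j] < 0:
            vec[:, j] = -vec[:, j]
    return lam, vec


def solve_bending_modes(sys: SystemMatrices, Kg: sp.csr_array | None, n_modes: int) -> ModeSet:
    """First ``n_modes`` transverse plate modes of (Kb + Kg) phi = w^2 Mb phi."""
    Kff, Mff = sys.reduced("bending")
    if Kg is not None:
        f = sys.free_b
        Kff = sp.csr_array(Kff + Kg[np.ix_(f, f)])
    lam, vec = _solve_gep(sp.csr_array(Kff), sp.csr_array(Mff), n_modes, "bending")
    modes = [
        Mode(float(np.sqrt(lam[j]) / (2.0 * np.pi)), "bending", sys.expand("bending", vec[:, j]))
        for j in range(n_modes)
    ]
    return ModeSet(modes)


def solve_membrane_modes(sys: SystemMatrices, n_modes: int) -> ModeSet:
    """First ``n_modes`` in-plane modes of Km phi = w^2 Mm phi."""
    Kff, Mff = sys.reduced("membrane")
    lam, vec = _solve_gep(sp.csr_array(Kff), sp.csr_array(Mff), n_modes, "membrane")
    modes = [
        Mode(float(np.sqrt(lam[j]) / (2.0 * np.pi)), "membrane", sys.expand("membrane", vec[:, j]))
        for j in range(n_modes)
    ]
    return ModeSet(modes)


def merge_and_sort(bending: ModeSet, membrane: ModeSet, n: int = 10) -> ModeSet:
    """Globally lowest ``n`` modes across both families.

    Stable tie-break: bending before membrane at equal frequency, then each
    family's own ascending order.
    """
    tagged = [(m.frequency, 0, i, m) for i, m in enumerate(bending)]
    tagged += [(m.frequency, 1, i, m) for i, m in enumerate(membrane)]
    if len(tagged) < n:
        raise ValueError(f"only {len(tagged)} modes available, {n} requested")
    tagged.sort(key=lambda t: (t[0], t[1], t[2]))
    return ModeSet([t[3] for t in tagged[:n]])
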