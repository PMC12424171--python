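"""Per-atom excitation contributions from transition-type density matrices.

A one-electron transition density matrix (1TDM) or a density-difference
(DD) matrix ``T``, given in the orthonormal MO (active-orbital) basis,
is analysed in two ways:

* electron/hole decomposition (``qeh``): D^e = T^T T locates where the
  excited electron arrives and D^h = T T^T where it departs; Löwdin
  populations of both give per-atom charges q^e_A, q^h_A, combined as
  q_A = |q^e_A| + |q^h_A| so that electron and hole participation never
  cancel;
* transition charges (``qtr``): Löwdin populations of the 1TDM itself,
  q_A = |q^tr_A|.

The Löwdin analysis transforms the matrix to the AO basis
(D_ao = C D C^T), symmetrically orthogonalizes with the principal
square root of the AO overlap S, and sums diagonal elements of
S^{1/2} D_ao S^{1/2} per atom.  With S-orthonormal MOs the populations
sum to the trace of the MO-basis matrix, which for a normalized
transition equals the squared Frobenius norm of T — the invariant the
tests lean on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import ContractError, ContributionSet

#: eigenvalue floor below which the AO overlap counts as linearly dependent
S_EIGENVALUE_FLOOR = 1e-10


@dataclass
class BasisMap:
    """Assignment of basis functions to atoms."""

    n_atoms: int
    atom_of_function: np.ndarray

    def __post_init__(self) -> None:
        self.atom_of_function = np.asarray(self.atom_of_function, dtype=int)
        if self.atom_of_function.ndim != 1:
            raise ContractError("atom_of_function must be one-dimensional")
        if self.atom_of_function.size and (
            self.atom_of_function.min() < 0 or self.atom_of_function.max() >= self.n_atoms
        ):
            raise ContractError("atom index out of range in basis map")

    @property
    def n_basis(self) -> int:
        return self.atom_of_function.shape[0]


@dataclass
class MatrixBundle:
    """AO overlap, MO coefficients and a transition-type matrix.

    ``kind`` records whether ``T`` is a 1TDM or a DD matrix; the
    electron/hole decomposition applies to either, transition charges
    only to the 1TDM.
    """

    S: np.ndarray
    C_mo: np.ndarray
    T: np.ndarray
    kind: str  #: "1TDM" or "DD"

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.C_mo = np.asarray(self.C_mo, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.kind not in ("1TDM", "DD"):
            raise ContractError(f"unknown matrix kind {self.kind!r}")

    @property
    def n_basis(self) -> int:
        return self.S.shape[0]

    @property
    def n_orb(self) -> int:
        return self.C_mo.shape[1]

    def validate(self, mo_tol: float = 1e-8) -> None:
        """Check symmetry of S and S-orthonormality of the MOs."""
        if self.S.shape[0] != self.S.shape[1]:
            raise ContractError("AO overlap must be square")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ContractError("AO overlap must be symmetric")
        if self.C_mo.shape[0] != self.n_basis:
            raise ContractError("MO coefficient rows must match the AO dimension")
        gram = self.C_mo.T @ self.S @ self.C_mo
        if not np.allclose(gram, np.eye(self.n_orb), atol=mo_tol):
            raise ContractError("MOs are not orthonormal under the AO overlap")
        if self.T.shape != (self.n_orb, self.n_orb):
            raise ContractError("transition matrix must be n_orb x n_orb")


def electron_hole_matrices(T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Electron and hole one-particle matrices of a transition matrix.

    ``D_e[p, q] = sum_r T[r, p] T[r, q]`` and
    ``D_h[p, q] = sum_r T[p, r] T[q, r]``; both are symmetric positive
    semidefinite with trace equal to ||T||_F^2.
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ContractError("transition matrix must be square")
    return T.T @ T, T @ T.T


def overlap_sqrt(S: np.ndarray, floor: float = S_EIGENVALUE_FLOOR) -> np.ndarray:
    """Principal (symmetric) square root of a positive-definite overlap.

    Raises if any eigenvalue falls below ``floor`` (near linear
    dependence of the basis).
    """
    w, V = np.linalg.eigh(np.asarray(S, dtype=float))
    if w.min() < floor:
        raise ContractError(f"overlap eigenvalue {w.min():.3e} below floor {floor:.0e}")
    return (V * np.sqrt(w)) @ V.T


def lowdin_populations(D_mo: np.ndarray, bundle: MatrixBundle, basis_map: BasisMap) -> np.ndarray:
    """Per-atom Löwdin populations of an MO-basis one-particle matrix.

    Transforms to the AO basis, forms S^{1/2} D_ao S^{1/2}, and sums its
    diagonal per atom.  The returned values sum to trace(D_mo) when the
    MOs are orthonormal under S.
    """
    D_mo = np.asarray(D_mo, dtype=float)
    if D_mo.shape != (bundle.n_orb, bundle.n_orb):
        raise ContractError("matrix dimension must equal the number of MOs")
    if basis_map.n_basis != bundle.n_basis:
        raise ContractError("basis map length must equal the AO dimension")
    D_ao = bundle.C_mo @ D_mo @ bundle.C_mo.T
    S_half = overlap_sqrt(bundle.S)
    diag = np.einsum("ij,ji->i", S_half @ D_ao, S_half)
    return np.bincount(basis_map.atom_of_function, weights=diag, minlength=basis_map.n_atoms)


def atomic_contributions(bundle: MatrixBundle, basis_map: BasisMap, mode: str) -> ContributionSet:
    """Combined per-atom contributions q_A for one transition.

    ``mode="qeh"`` decomposes ``bundle.T`` into electron and hole parts
    and returns q_A = |q^e_A| + |q^h_A|; ``mode="qtr"`` analyses the
    1TDM directly and returns q_A = |q^tr_A| (only defined for 1TDM
    bundles).
    """
    bundle.validate()
    if mode == "qeh":
        D_e, D_h = electron_hole_matrices(bundle.T)
        q_e = lowdin_populations(D_e, bundle, basis_map)
        q_h = lowdin_populations(D_h, bundle, basis_map)
        return ContributionSet(
            q=np.abs(q_e) + np.abs(q_h),
            mode=f"qeh/{bundle.kind}",
            q_e=q_e,
            q_h=q_h,
        )
    if mode == "qtr":
        if bundle.kind != "1TDM":
            raise ContractError("transition charges are defined on the 1TDM only")
        q_tr = lowdin_populations(bundle.T, bundle, basis_map)
        return ContributionSet(q=np.abs(q_tr), mode="qtr", q_tr=q_tr)
    raise ContractError(f"unknown contribution mode {mode!r}")


# ---------------------------------------------------------------------------
# plain-text matrix dumps (fixtures and interoperability, not a QC format)
# ---------------------------------------------------------------------------


def write_matrix(path, M: np.ndarray) -> None:
    """Write a dense matrix with a one-line ``rows cols`` header."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    with open(path, "w") as fh:
        fh.write(f"{M.shape[0]} {M.shape[1]}\n")
        for row in M:
            fh.write(" ".join(f"{x:.17g}" for x in row) + "\n")


def read_matrix(path) -> np.ndarray:
    with open(path) as fh:
        rows, cols = (int(x) for x in fh.readline().split())
        M = np.loadtxt(fh, ndmin=2)
    if M.shape != (rows, cols):
        raise ContractError(f"matrix dump header {(rows, cols)} disagrees with body {M.shape}")
    return M


def write_basis_map(path, basis_map: BasisMap) -> None:
    """One atom index per line, preceded by an ``n_atoms`` header."""
    with open(path, "w") as fh:
        fh.write(f"{basis_map.n_atoms}\n")
        for a in basis_map.atom_of_function:
            fh.write(f"{a}\n")


def read_basis_map(path) -> BasisMap:
    with open(path) as fh:
        n_atoms = int(fh.readline())
        idx = [int(line) for line in fh if line.strip()]
    return BasisMap(n_atoms=n_atoms, atom_of_function=np.asarray(idx, dtype=int))


def load_bundle(directory, kind: str = "1TDM") -> tuple[MatrixBundle, BasisMap]:
    """Read ``S.dat``, ``C_mo.dat``, ``T.dat`` and ``basis_map.dat`` from a directory."""
    d = Path(directory)
    bundle = MatrixBundle(
        S=read_matrix(d / "S.dat"),
        C_mo=read_matrix(d / "C_mo.dat"),
        T=read_matrix(d / "T.dat"),
        kind=kind,
    )
    return bundle, read_basis_map(d / "basis_map.dat")


def dump_bundle(directory, bundle: MatrixBundle, basis_map: BasisMap) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_matrix(d / "S.dat", bundle.S)
    write_matrix(d / "C_mo.dat", bundle.C_mo)
    write_matrix(d / "T.dat", bundle.T)
    write_basis_map(d / "basis_map.dat", basis_map)
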