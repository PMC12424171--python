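"""Analytic model potentials and synthetic fixtures.

The dynamics engine is exercised on small diabatic vibronic models with
closed-form energies, gradients and nonadiabatic coupling vectors, so
every rescaling scheme can be tested without electronic-structure
software.  The shipped default is a two-state avoided-crossing model of
two "chromophore" atoms whose relative stretch is the tuning
coordinate, optionally augmented with free spectator atoms that carry
kinetic energy but no excitation character — the construction that
exposes the size-consistency defect of uniform velocity rescaling.

Per-atom contributions of the models are supplied analytically (mode
``direct``); the Löwdin charge analysis is exercised separately on
random matrix bundles generated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .charge_analysis import BasisMap, MatrixBundle
from .core import AtomicSystem, ContractError, ContributionSet, ElectronicSnapshot

#: adiabatic gap below which NACV evaluation refuses to proceed
NACV_DEGENERACY_FLOOR = 1e-8


@dataclass
class WignerSpec:
    """Ground-state harmonic Wigner distribution of a set of normal modes.

    ``displacements[m]`` is the mass-weighted mode shape of mode ``m``
    (orthonormal in mass-weighted coordinates), shape ``(n_atoms, 3)``;
    ``frequencies[m]`` its angular frequency in a.u.  Temperature is
    fixed at zero (ground vibrational state).
    """

    frequencies: np.ndarray
    displacements: np.ndarray
    temperature: float = 0.0

    def __post_init__(self) -> None:
        self.frequencies = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        self.displacements = np.asarray(self.displacements, dtype=float)
        if np.any(self.frequencies <= 0):
            raise ContractError("mode frequencies must be positive")
        if self.temperature != 0.0:
            raise ContractError("only the ground vibrational state (T = 0) is supported")
        if self.displacements.shape[0] != self.frequencies.shape[0]:
            raise ContractError("one displacement vector per frequency required")

    @property
    def n_modes(self) -> int:
        return self.frequencies.shape[0]


@dataclass
class ModelSystem:
    """A diabatic model: potential matrix, gradients and contribution rule.

    ``diabatic_potential(positions)`` returns the symmetric diabatic
    matrix ``V`` of shape ``(n_states, n_states)`` and its gradient
    ``dV`` of shape ``(n_states, n_states, n_atoms, 3)``.
    ``contribution_rule(positions, (i, j))`` returns the per-atom
    contributions q_A of the (i, j) transition.
    """

    n_atoms: int
    n_states: int
    masses: np.ndarray
    labels: list
    diabatic_potential: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]
    contribution_rule: Callable[[np.ndarray, tuple[int, int]], np.ndarray]
    ref_positions: np.ndarray
    wigner: Optional[WignerSpec] = None
    initial_state: int = 1
    #: standard deviation of spectator velocity components (free atoms only)
    spectator_sigma: np.ndarray = field(default=None)
    #: boolean mask of spectator atoms (no excitation character)
    spectator_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.ref_positions = np.asarray(self.ref_positions, dtype=float).reshape(-1, 3)
        if self.spectator_mask is None:
            self.spectator_mask = np.zeros(self.n_atoms, dtype=bool)

    def sample_initial(self, rng: np.random.Generator) -> AtomicSystem:
        """Draw one initial condition: Wigner sample on the model's modes,
        plus Gaussian velocities for free spectator atoms."""
        if self.wigner is not None:
            positions, velocities = wigner_sample(self.wigner, self.masses, self.ref_positions, rng)
        else:
            positions = self.ref_positions.copy()
            velocities = np.zeros_like(positions)
        if np.any(self.spectator_mask):
            sigma = self.spectator_sigma
            for a in np.flatnonzero(self.spectator_mask):
                velocities[a, 0] = rng.normal(0.0, sigma[a])
        return AtomicSystem(list(self.labels), self.masses.copy(), positions, velocities)


# ---------------------------------------------------------------------------
# adiabatization
# ---------------------------------------------------------------------------


def evaluate_adiabatic(
    model: ModelSystem,
    positions: np.ndarray,
    prev_basis: Optional[np.ndarray] = None,
    need_nacv: bool = True,
) -> ElectronicSnapshot:
    """Diagonalize the diabatic model at ``positions``.

    Returns adiabatic energies (ascending), state gradients
    <i|dV|i>, NACVs d_ij = <i|dV|j> / (E_j - E_i), the overlap of the
    previous basis with the current one (identity when no previous basis
    is given), and the model's per-atom contributions for every state
    pair.  Eigenvector phases are fixed for continuity: each column's
    sign is chosen so its overlap with the previous basis (diagonal
    element) is positive.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    V, dV = model.diabatic_potential(positions)
    energies, U = np.linalg.eigh(V)

    if prev_basis is not None:
        overlap = prev_basis.T @ U
        signs = np.where(np.diag(overlap) < 0, -1.0, 1.0)
        U = U * signs
        overlap = overlap * signs
    else:
        overlap = np.eye(model.n_states)

    # adiabatic representation of dV: W[i, j] = <i| dV |j>, per atom/coord
    W = np.einsum("pi,pqac,qj->ijac", U, dV, U)
    n = model.n_states
    gradients = W[np.arange(n), np.arange(n)]

    nacv = None
    if need_nacv:
        gaps = energies[None, :] - energies[:, None]
        off = ~np.eye(n, dtype=bool)
        if np.any(np.abs(gaps[off]) < NACV_DEGENERACY_FLOOR):
            raise ContractError("adiabatic gap below the NACV degeneracy floor")
        nacv = np.zeros_like(W)
        nacv[off] = W[off] / gaps[off][:, None, None]

    contributions = {}
    for i in range(n):
        for j in range(i + 1, n):
            q = np.asarray(model.contribution_rule(positions, (i, j)), dtype=float)
            contributions[(i, j)] = ContributionSet(q=q, mode="direct")

    return ElectronicSnapshot(
        energies=energies,
        gradients=gradients,
        nacv=nacv,
        overlap_prev=overlap,
        contributions=contributions,
        basis=U,
    )


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------


def avoided_crossing_model(
    mass: float = 1000.0,
    force_constant: float = 0.1,
    gap_fc: float = 0.02,
    slope: float = 0.05,
    coupling: float = 0.002,
    r_eq: float = 4.0,
    transverse_fc: float = 0.288,
    coupling_transverse: float = 0.06,
) -> ModelSystem:
    """Two-state, two-atom avoided-crossing model.

    The tuning coordinate is the bond stretch q = (x1 - x0) - r_eq.  In
    the diabatic picture both states share a harmonic stretch
    0.5 k q^2; the excited diabat is shifted up by ``gap_fc`` at the
    Franck-Condon point and tilted by ``-slope * q``, so the diabats
    cross at q = gap_fc / slope.  The diabatic coupling is constant.
    Both atoms carry equal excitation contributions.

    Each atom additionally vibrates in a state-independent transverse
    (y) harmonic well.  With ``coupling_transverse`` = 0 these are pure
    spectator *modes*: the coupling and the NACV stay along the stretch,
    but the transverse zero-point motion carries kinetic energy that
    uniform rescaling treats as available for hops while the NACV
    projection does not — the intra-molecular analog of the
    spectator-atom problem.  A nonzero ``coupling_transverse`` g makes
    the diabatic coupling geometry dependent,
    lambda(dy) = sqrt(lambda0^2 + g^2 dy^2) with dy = y1 - y0 (smooth
    and bounded below by lambda0, so no conical intersection is
    reachable), which tilts the NACV into the slow transverse
    coordinate the way coupling vectors of real molecules point
    partly along modes with little momentum.

    Defaults (a.u.): mass 1000, k 0.1 (stretch frequency 0.014, period
    about 11 fs), vertical gap 0.02 (about 0.54 eV), slope 0.05,
    coupling 0.002 (minimal adiabatic gap 0.004), transverse force
    constant 0.288 (frequency 0.017), transverse coupling slope 0.06.
    The light mass gives the zero-point ensemble a wide spread of
    crossing-arrival times, which dephases the passages and keeps the
    classical and quantum ensemble populations consistent.
    """
    masses = np.array([mass, mass])
    ref = np.array([[0.0, 0.0, 0.0], [r_eq, 0.0, 0.0]])

    def diabatic(positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        q = (positions[1, 0] - positions[0, 0]) - r_eq
        y = positions[:2, 1]
        dy = y[1] - y[0]
        lam = np.sqrt(coupling**2 + (coupling_transverse * dy) ** 2)
        common = 0.5 * force_constant * q * q + 0.5 * transverse_fc * float(np.sum(y * y))
        V = np.array([
            [common, lam],
            [lam, gap_fc - slope * q + common],
        ])
        dV = np.zeros((2, 2, 2, 3))
        # dq/dx0 = -1, dq/dx1 = +1
        dV[0, 0, 0, 0] = -force_constant * q
        dV[0, 0, 1, 0] = force_constant * q
        dV[1, 1, 0, 0] = slope - force_constant * q
        dV[1, 1, 1, 0] = -slope + force_constant * q
        for a in range(2):
            dV[0, 0, a, 1] += transverse_fc * y[a]
            dV[1, 1, a, 1] += transverse_fc * y[a]
        dlam_dy = coupling_transverse**2 * dy / lam  # d lambda / d(dy)
        dV[0, 1, 0, 1] = dV[1, 0, 0, 1] = -dlam_dy
        dV[0, 1, 1, 1] = dV[1, 0, 1, 1] = dlam_dy
        return V, dV

    def contributions(positions: np.ndarray, pair: tuple[int, int]) -> np.ndarray:
        return np.array([0.5, 0.5])

    # normal modes: the stretch (reduced mass mass/2, mass-weighted shape
    # (-1, +1)/sqrt(2)) and one transverse y mode per atom
    omega_stretch = np.sqrt(2.0 * force_constant / mass)
    omega_y = np.sqrt(transverse_fc / mass)
    L = np.zeros((3, 2, 3))
    L[0, 0, 0] = -1.0 / np.sqrt(2.0)
    L[0, 1, 0] = 1.0 / np.sqrt(2.0)
    L[1, 0, 1] = 1.0
    L[2, 1, 1] = 1.0
    wigner = WignerSpec(
        frequencies=np.array([omega_stretch, omega_y, omega_y]), displacements=L,
    )

    return ModelSystem(
        n_atoms=2,
        n_states=2,
        masses=masses,
        labels=["X1", "X2"],
        diabatic_potential=diabatic,
        contribution_rule=contributions,
        ref_positions=ref,
        wigner=wigner,
        initial_state=1,
    )


def make_spectator_model(
    core: ModelSystem,
    n_spectators: int,
    spectator_masses,
    spectator_kinetic: float = 0.01,
) -> ModelSystem:
    """Append non-interacting spectator atoms to a model.

    Spectators feel a flat potential (free particles), contribute q_A =
    0 to every transition and have zero NACV components, so the core
    dynamics must be unaffected under the size-consistent schemes.
    ``spectator_kinetic`` sets the mean kinetic energy per spectator for
    initial-condition sampling (velocity drawn along x with
    sigma = sqrt(2 E / M)); with n_spectators = 0 the core model is
    returned unchanged.
    """
    if n_spectators == 0:
        return core
    if n_spectators < 0:
        raise ContractError("n_spectators must be non-negative")
    spectator_masses = np.broadcast_to(
        np.asarray(spectator_masses, dtype=float), (n_spectators,)
    ).copy()
    n_core = core.n_atoms
    n_tot = n_core + n_spectators
    masses = np.concatenate([core.masses, spectator_masses])
    labels = list(core.labels) + [f"Sp{k + 1}" for k in range(n_spectators)]
    span = np.ptp(core.ref_positions[:, 0]) + 10.0
    ref = np.vstack([
        core.ref_positions,
        np.column_stack([
            span + 10.0 * np.arange(n_spectators),
            np.zeros(n_spectators),
            np.zeros(n_spectators),
        ]),
    ])

    def diabatic(positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        V, dV_core = core.diabatic_potential(positions[:n_core])
        dV = np.zeros((core.n_states, core.n_states, n_tot, 3))
        dV[:, :, :n_core] = dV_core
        return V, dV

    def contributions(positions: np.ndarray, pair: tuple[int, int]) -> np.ndarray:
        q_core = np.asarray(core.contribution_rule(positions[:n_core], pair), dtype=float)
        return np.concatenate([q_core, np.zeros(n_spectators)])

    wigner = None
    if core.wigner is not None:
        L = np.zeros((core.wigner.n_modes, n_tot, 3))
        L[:, :n_core] = core.wigner.displacements
        wigner = WignerSpec(frequencies=core.wigner.frequencies.copy(), displacements=L)

    sigma = np.zeros(n_tot)
    sigma[n_core:] = np.sqrt(2.0 * spectator_kinetic / spectator_masses)
    mask = np.zeros(n_tot, dtype=bool)
    mask[n_core:] = True
    mask[:n_core] = core.spectator_mask

    return ModelSystem(
        n_atoms=n_tot,
        n_states=core.n_states,
        masses=masses,
        labels=labels,
        diabatic_potential=diabatic,
        contribution_rule=contributions,
        ref_positions=ref,
        wigner=wigner,
        initial_state=core.initial_state,
        spectator_sigma=sigma,
        spectator_mask=mask,
    )


def contrast_model(n_spectators: int = 2, spectator_kinetic: float = 0.12, **kwargs) -> ModelSystem:
    """The shipped default: the avoided-crossing chromophore plus free
    spectators that inflate the total kinetic energy but carry no
    excitation character.  This is the desk-scale construction on which
    uniform rescaling (v_full) accepts upward hops that the
    excitation-weighted, thresholded and NACV schemes frustrate."""
    return make_spectator_model(
        avoided_crossing_model(**kwargs),
        n_spectators=n_spectators,
        spectator_masses=2000.0,
        spectator_kinetic=spectator_kinetic,
    )


# ---------------------------------------------------------------------------
# Wigner sampling
# ---------------------------------------------------------------------------


def wigner_sample(
    spec: WignerSpec,
    masses: np.ndarray,
    ref_positions: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw positions and velocities from the ground-state Wigner function.

    Each mode's mass-weighted coordinate and momentum are independent
    zero-mean Gaussians with variances 1/(2 omega) and omega/2; the
    Cartesian displacement is ref + M^{-1/2} L Q and the velocity
    M^{-1/2} L P.  The expected total energy per mode is the zero-point
    energy omega/2.
    """
    masses = np.asarray(masses, dtype=float)
    Q = rng.normal(0.0, np.sqrt(0.5 / spec.frequencies))
    P = rng.normal(0.0, np.sqrt(0.5 * spec.frequencies))
    inv_sqrt_m = 1.0 / np.sqrt(masses)[:, None]
    dx = np.einsum("m,mac->ac", Q, spec.displacements) * inv_sqrt_m
    v = np.einsum("m,mac->ac", P, spec.displacements) * inv_sqrt_m
    return np.asarray(ref_positions, dtype=float) + dx, v


# ---------------------------------------------------------------------------
# random matrix bundles (charge-analysis fixtures)
# ---------------------------------------------------------------------------


def random_matrix_bundle(
    n_basis: int,
    n_orb: int,
    rng: np.random.Generator,
    n_atoms: int = 2,
    kind: str = "1TDM",
) -> tuple[MatrixBundle, BasisMap]:
    """Generate a consistent (overlap, MOs, transition matrix) fixture.

    The AO overlap is A A^T + eps I with eps chosen to keep the
    condition number at or below 1e6; the MOs are S-orthonormal by
    construction; T is a random matrix normalized to unit Frobenius norm
    (a normalized transition); basis functions are assigned to atoms
    round-robin.
    """
    if n_orb > n_basis:
        raise ContractError("cannot have more orthonormal MOs than basis functions")
    A = rng.normal(size=(n_basis, n_basis))
    S0 = A @ A.T
    w = np.linalg.eigvalsh(S0)
    eps = max(w.max() / 1e6 - w.min(), 1e-6 * w.max())
    S = S0 + eps * np.eye(n_basis)
    C0 = rng.normal(size=(n_basis, n_orb))
    gram = C0.T @ S @ C0
    gw, gV = np.linalg.eigh(gram)
    C_mo = C0 @ (gV / np.sqrt(gw)) @ gV.T
    T = rng.normal(size=(n_orb, n_orb))
    T /= np.linalg.norm(T)
    basis_map = BasisMap(n_atoms=n_atoms, atom_of_function=np.arange(n_basis) % n_atoms)
    return MatrixBundle(S=S, C_mo=C_mo, T=T, kind=kind), basis_map
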