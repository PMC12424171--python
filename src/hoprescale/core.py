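"""Shared domain types and unit conventions.

Everything internal is in Hartree atomic units: energies in hartree,
lengths in bohr, time in a.u. of time, masses in electron masses.
Configuration and file I/O may use femtoseconds, electron-volts and
angstroms; conversion happens at the boundary, never inside the
dynamics.

State indices are 0-based in code and displayed 1-based (S0, S1, ...)
in reports, matching the usual spectroscopic labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# ---------------------------------------------------------------------------
# unit conversions (CODATA 2018)
# ---------------------------------------------------------------------------

FS_TO_AU = 41.341374575751  #: one femtosecond in atomic time units
AU_TO_FS = 1.0 / FS_TO_AU
HARTREE_TO_EV = 27.211386245988
EV_TO_HARTREE = 1.0 / HARTREE_TO_EV
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM
AMU_TO_ME = 1822.888486209  #: unified atomic mass unit in electron masses

#: valid per-atom contribution modes
CONTRIBUTION_MODES = ("qeh/1TDM", "qeh/DD", "qtr", "direct")


class ContractError(ValueError):
    """A precondition or invariant of a domain type was violated."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AtomicSystem:
    """Classical subsystem: atoms with masses, positions and velocities.

    Parameters
    ----------
    labels
        Per-atom text tags (element symbols or arbitrary names).
    masses
        Atomic masses in electron-mass units, shape ``(n_atoms,)``.
    positions
        Cartesian coordinates in bohr, shape ``(n_atoms, 3)``.
    velocities
        Cartesian velocities in bohr per a.u. time, shape ``(n_atoms, 3)``.
    """

    labels: list
    masses: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
        n = self.masses.shape[0]
        if n < 1:
            raise ContractError("a system needs at least one atom")
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ContractError("positions/velocities must be (n_atoms, 3)")
        if len(self.labels) != n:
            raise ContractError("one label per atom required")
        if not np.all(self.masses > 0):
            raise ContractError("masses must be strictly positive")
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.velocities))):
            raise ContractError("positions and velocities must be finite")

    @property
    def n_atoms(self) -> int:
        return self.masses.shape[0]

    def kinetic_energy(self) -> float:
        """Total kinetic energy 0.5 * sum_A M_A v_A . v_A, in hartree."""
        return 0.5 * float(np.sum(self.masses * np.einsum("ij,ij->i", self.velocities, self.velocities)))

    def per_atom_kinetic(self) -> np.ndarray:
        """Per-atom kinetic energies, shape ``(n_atoms,)``."""
        return 0.5 * self.masses * np.einsum("ij,ij->i", self.velocities, self.velocities)

    def copy(self) -> "AtomicSystem":
        return AtomicSystem(
            list(self.labels),
            self.masses.copy(),
            self.positions.copy(),
            self.velocities.copy(),
        )


@dataclass
class ContributionSet:
    """Per-atom contributions of one electronic transition.

    ``q`` is the combined non-negative contribution q_A used by the
    weighted and thresholded rescaling schemes.  For mode ``qeh/*`` it is
    |q^e_A| + |q^h_A|; for mode ``qtr`` it is |q^tr_A|; mode ``direct``
    means the model supplied q_A analytically rather than from matrices.
    """

    q: np.ndarray
    mode: str
    q_e: Optional[np.ndarray] = None
    q_h: Optional[np.ndarray] = None
    q_tr: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.mode not in CONTRIBUTION_MODES:
            raise ContractError(f"unknown contribution mode {self.mode!r}")
        if np.any(self.q < 0):
            raise ContractError("combined contributions q_A must be non-negative")

    @property
    def n_atoms(self) -> int:
        return self.q.shape[0]


@dataclass
class ElectronicSnapshot:
    """Electronic-structure quantities at one nuclear geometry.

    ``energies`` are adiabatic state energies sorted ascending;
    ``gradients[i]`` is the gradient of state i (negative force), shape
    ``(n_atoms, 3)``; ``nacv[i, j]`` the derivative coupling d_ij with
    the antisymmetry d_ij = -d_ji; ``overlap_prev[i, j]`` the overlap
    <psi_i(previous geometry) | psi_j(this geometry)>, approximately
    orthogonal for a small enough step.  ``contributions`` maps an
    unordered state pair ``(i, j)`` with i < j to a :class:`ContributionSet`.
    ``basis`` optionally carries the adiabatic eigenvectors for phase
    tracking by whoever produces the next snapshot.
    """

    energies: np.ndarray
    gradients: np.ndarray
    nacv: Optional[np.ndarray] = None
    overlap_prev: Optional[np.ndarray] = None
    contributions: dict = field(default_factory=dict)
    basis: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.gradients = np.asarray(self.gradients, dtype=float)
        if np.any(np.diff(self.energies) < 0):
            raise ContractError("adiabatic energies must be sorted ascending")

    @property
    def n_states(self) -> int:
        return self.energies.shape[0]

    def contribution(self, i: int, j: int) -> ContributionSet:
        """Contribution set for the (unordered) state pair ``(i, j)``."""
        key = (min(i, j), max(i, j))
        try:
            return self.contributions[key]
        except KeyError:
            raise ContractError(f"no contributions stored for state pair {key}") from None


@dataclass
class TrajectoryState:
    """Everything carried along one surface-hopping trajectory."""

    time: float
    system: AtomicSystem
    active_state: int
    coefficients: np.ndarray
    total_energy_ref: float = 0.0
    rng: Optional[np.random.Generator] = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        norm = float(np.sum(np.abs(self.coefficients) ** 2))
        if abs(norm - 1.0) > 1e-8:
            raise ContractError(f"coefficient norm {norm} deviates from 1")
        if not 0 <= self.active_state < self.coefficients.shape[0]:
            raise ContractError("active state index out of range")

    @property
    def n_states(self) -> int:
        return self.coefficients.shape[0]

    def populations(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2


@dataclass
class HopEvent:
    """Record of one attempted surface hop."""

    time: float
    from_state: int
    to_state: int
    delta_E: float  #: E_pot(to) - E_pot(from), hartree
    scheme: str
    available_kinetic: float  #: scheme-specific reservoir at the attempt
    outcome: str  #: "accepted" or "frustrated"
    velocity_before: np.ndarray
    velocity_after: np.ndarray

    def __post_init__(self) -> None:
        if self.outcome not in ("accepted", "frustrated"):
            raise ContractError(f"unknown hop outcome {self.outcome!r}")

    @property
    def is_upward(self) -> bool:
        return self.delta_E > 0

    def to_dict(self) -> dict:
        return {
            "time": self.time,
            "from_state": self.from_state,
            "to_state": self.to_state,
            "delta_E": self.delta_E,
            "scheme": self.scheme,
            "available_kinetic": self.available_kinetic,
            "outcome": self.outcome,
        }


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def total_energy(state: TrajectoryState, snapshot: ElectronicSnapshot) -> float:
    """Total (kinetic + active-state potential) energy in hartree.

    The snapshot must correspond to the positions stored in ``state``.
    """
    if not 0 <= state.active_state < snapshot.n_states:
        raise ContractError("active state index out of range for snapshot")
    return state.system.kinetic_energy() + float(snapshot.energies[state.active_state])
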