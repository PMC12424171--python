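"""Post-hop velocity adjustment schemes and their frustration criteria.

After a surface hop the nuclear kinetic energy must change by the
potential-energy gap so that the total energy is conserved.  Four
schemes are implemented:

``v_full``
    Uniform rescaling of every velocity by sqrt(E_kin_new / E_kin_old).
    Simple, but size-inconsistent: non-interacting spectator atoms
    enlarge the kinetic-energy reservoir and can turn a frustrated hop
    into an accepted one.
``d``
    Adjustment of the velocity component along the nonadiabatic
    coupling vector (NACV), the physically preferred direction.  The
    available energy is b^2/(4a) with b = sum_A v_A . d_A and
    a = 0.5 * sum_A |d_A|^2 / M_A.
``v_w``
    Excitation-weighted rescaling: per-atom factors built from
    normalized weights w_A = c_A^2 of the atoms' contributions to the
    electronic transition, with a global factor restoring exact energy
    conservation.  The reservoir is the weighted kinetic energy
    0.5 * sum_A w_A M_A v_A^2, which spectator atoms (w_A = 0) cannot
    inflate.
``v_t``
    Excitation-thresholded rescaling: uniform rescaling restricted to
    the atoms whose contribution exceeds a fraction ``n`` of the largest
    one; all other velocities are untouched.

Accepted hops conserve total energy to machine precision by
construction; frustrated hops leave velocities unchanged (momentum
direction preserved, no reversal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import AtomicSystem, ContractError, ElectronicSnapshot, HopEvent, TrajectoryState

logger = logging.getLogger(__name__)

SCHEMES = ("v_full", "d", "v_w", "v_t")


class RescaleError(ContractError):
    """A rescaling operation was called outside its domain."""


@dataclass
class RescaleSpec:
    """Scheme selection and its parameters.

    ``alpha`` tunes the strength of the weighting in ``v_w`` (0 means
    uniform); ``threshold_n`` in [0, 1] is the significance threshold of
    ``v_t``; ``charge_mode`` records which contribution definition the
    snapshots carry (``qeh/1TDM``, ``qeh/DD``, ``qtr`` or ``direct``).
    """

    scheme: str
    alpha: float = 0.0
    threshold_n: float = 0.3
    charge_mode: str = "direct"

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ContractError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ContractError("alpha must be finite and non-negative")
        if not 0.0 <= self.threshold_n <= 1.0:
            raise ContractError("threshold_n must lie in [0, 1]")

    def label(self) -> str:
        if self.scheme == "v_w":
            return f"v_w({self.charge_mode}, alpha={self.alpha:g})"
        if self.scheme == "v_t":
            return f"v_t({self.charge_mode}, n={self.threshold_n:g})"
        return self.scheme


@dataclass
class RescaleResult:
    velocities: np.ndarray
    outcome: str  #: "accepted" or "frustrated"
    available_kinetic: float
    scale_diagnostics: np.ndarray = field(default=None)  #: per-atom effective factors

    @property
    def accepted(self) -> bool:
        return self.outcome == "accepted"


def _frustrated(system: AtomicSystem, available: float) -> RescaleResult:
    return RescaleResult(
        velocities=system.velocities.copy(),
        outcome="frustrated",
        available_kinetic=available,
        scale_diagnostics=np.ones(system.n_atoms),
    )


# ---------------------------------------------------------------------------
# uniform rescaling (v_full)
# ---------------------------------------------------------------------------


def rescale_uniform(system: AtomicSystem, E_kin_new: float) -> RescaleResult:
    """Scale every velocity by sqrt(E_kin_new / E_kin_old).

    Frustrated iff ``E_kin_new`` is negative (the gap exceeds the total
    kinetic energy).
    """
    E_kin_old = system.kinetic_energy()
    if E_kin_new < 0:
        return _frustrated(system, E_kin_old)
    if E_kin_new == 0.0:
        return RescaleResult(np.zeros_like(system.velocities), "accepted", E_kin_old,
                             np.zeros(system.n_atoms))
    if E_kin_old == 0.0:
        raise RescaleError("cannot rescale a system at rest to positive kinetic energy")
    kappa = np.sqrt(E_kin_new / E_kin_old)
    return RescaleResult(system.velocities * kappa, "accepted", E_kin_old,
                         np.full(system.n_atoms, kappa))


# ---------------------------------------------------------------------------
# excitation-weighted rescaling (v_w)
# ---------------------------------------------------------------------------


def normalized_weights(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized coefficients c_A = q_A / sqrt(sum_B q_B^2) and weights w_A = c_A^2.

    The weights sum to one.  Raises on an all-zero contribution vector
    (no excitation character); callers fall back to uniform rescaling.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ContractError("contributions must be non-negative")
    norm = np.sqrt(np.sum(q * q))
    if norm == 0.0:
        raise RescaleError("all-zero contribution vector: weights are undefined")
    c = q / norm
    return c, c * c


def available_kinetic_weighted(w: np.ndarray, system: AtomicSystem) -> float:
    """Weighted kinetic-energy reservoir 0.5 * sum_A w_A M_A v_A . v_A.

    Atoms with zero weight contribute nothing, which is what makes the
    scheme size-consistent.
    """
    w = np.asarray(w, dtype=float)
    if w.shape[0] != system.n_atoms:
        raise ContractError("one weight per atom required")
    return 0.5 * float(np.sum(w * system.masses * np.einsum("ij,ij->i", system.velocities, system.velocities)))


def rescale_weighted(system: AtomicSystem, w: np.ndarray, alpha: float, E_kin_new: float) -> RescaleResult:
    """Excitation-weighted velocity rescaling.

    Per-atom factors f_A = sqrt(E_kin_new/E_kin_old) * [1 + alpha*(w_A - mean(w))]
    are renormalized by a global N = sqrt(E_kin_new / E*_kin), where
    E*_kin is the kinetic energy of the f-scaled velocities, so the new
    kinetic energy equals ``E_kin_new`` exactly.  With alpha = 0 this
    reduces to uniform rescaling.

    An upward hop is frustrated iff the gap exceeds the weighted
    reservoir :func:`available_kinetic_weighted`.
    """
    w = np.asarray(w, dtype=float)
    E_kin_old = system.kinetic_energy()
    reservoir = available_kinetic_weighted(w, system)
    delta_E = E_kin_old - E_kin_new  # potential-energy gap of the hop
    if delta_E > reservoir:
        return _frustrated(system, reservoir)
    if E_kin_old <= 0.0:
        raise RescaleError("cannot rescale a system at rest")
    f = np.sqrt(E_kin_new / E_kin_old) * (1.0 + alpha * (w - w.mean()))
    if np.any(f <= 0):
        raise RescaleError(
            f"non-positive per-atom factor at alpha={alpha}: the weighting overwhelms the baseline"
        )
    E_star = 0.5 * float(np.sum(system.masses * (f * np.linalg.norm(system.velocities, axis=1)) ** 2))
    if E_star == 0.0:
        raise RescaleError("scaled kinetic energy vanished; cannot normalize")
    N = np.sqrt(E_kin_new / E_star)
    return RescaleResult(system.velocities * (f * N)[:, None], "accepted", reservoir, f * N)


# ---------------------------------------------------------------------------
# excitation-thresholded rescaling (v_t)
# ---------------------------------------------------------------------------


def select_significant_atoms(q: np.ndarray, n: float) -> np.ndarray:
    """Indices of atoms with q_A > n * max(q).

    The maximal contributor is always included, so the set is never
    empty even at n = 1 or with ties at the maximum.
    """
    q = np.asarray(q, dtype=float)
    if not 0.0 <= n <= 1.0:
        raise ContractError("threshold n must lie in [0, 1]")
    q_max = q.max()
    if q_max <= 0.0:
        raise RescaleError("all-zero contribution vector: no significant atoms")
    idx = np.flatnonzero(q > n * q_max)
    if idx.size == 0:
        idx = np.array([int(np.argmax(q))])
    return idx


def rescale_thresholded(system: AtomicSystem, subset: np.ndarray, delta_E: float) -> RescaleResult:
    """Uniform rescaling restricted to a subset of atoms.

    The subset velocities are scaled by a common factor
    kappa = sqrt(1 - delta_E / E_kin_S) with E_kin_S the subset kinetic
    energy; everything outside the subset is untouched (bit-identical).
    Frustrated iff delta_E exceeds E_kin_S.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ContractError("subset must be non-empty")
    E_kin_S = 0.5 * float(
        np.sum(system.masses[subset] * np.einsum("ij,ij->i", system.velocities[subset], system.velocities[subset]))
    )
    if delta_E > E_kin_S:
        return _frustrated(system, E_kin_S)
    if E_kin_S == 0.0:
        if delta_E < 0.0:
            # subset at rest cannot absorb released energy by scaling
            return _frustrated(system, E_kin_S)
        return RescaleResult(system.velocities.copy(), "accepted", E_kin_S, np.ones(system.n_atoms))
    kappa = np.sqrt(1.0 - delta_E / E_kin_S)
    v_new = system.velocities.copy()
    v_new[subset] *= kappa
    diag = np.ones(system.n_atoms)
    diag[subset] = kappa
    return RescaleResult(v_new, "accepted", E_kin_S, diag)


# ---------------------------------------------------------------------------
# NACV-direction adjustment (d)
# ---------------------------------------------------------------------------


def _nacv_coefficients(system: AtomicSystem, d: np.ndarray) -> tuple[float, float]:
    d = np.asarray(d, dtype=float).reshape(-1, 3)
    if not np.any(d):
        raise RescaleError("NACV direction is identically zero")
    b = float(np.sum(system.velocities * d))
    a = 0.5 * float(np.sum(np.einsum("ij,ij->i", d, d) / system.masses))
    return a, b


def available_kinetic_nacv(system: AtomicSystem, d: np.ndarray) -> float:
    """Kinetic energy available along the NACV direction, b^2 / (4a).

    This is the maximum of E_kin(v) - E_kin(v - gamma d / M) over gamma,
    i.e. the most kinetic energy that removing momentum along d can free
    up.  It equals the full kinetic energy when d is parallel to the
    mass-weighted velocity.
    """
    a, b = _nacv_coefficients(system, d)
    return b * b / (4.0 * a)


def rescale_along_nacv(system: AtomicSystem, d: np.ndarray, delta_E: float) -> RescaleResult:
    """Adjust the velocity component along the NACV by v <- v - gamma d / M.

    gamma is the smaller-magnitude real root of
    a gamma^2 - b gamma + delta_E = 0 (minimal perturbation).
    Frustrated iff the discriminant is negative (b^2 < 4 a delta_E):
    insufficient projected momentum.  Atoms where d vanishes are
    untouched.
    """
    a, b = _nacv_coefficients(system, d)
    available = b * b / (4.0 * a)
    disc = b * b - 4.0 * a * delta_E
    if disc < 0.0:
        return _frustrated(system, available)
    roots = np.array([(b - np.sqrt(disc)) / (2 * a), (b + np.sqrt(disc)) / (2 * a)])
    gamma = float(roots[np.argmin(np.abs(roots))])
    d = np.asarray(d, dtype=float).reshape(-1, 3)
    v_new = system.velocities - gamma * d / system.masses[:, None]
    speeds = np.linalg.norm(system.velocities, axis=1)
    new_speeds = np.linalg.norm(v_new, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        diag = np.where(speeds > 0, new_speeds / np.where(speeds > 0, speeds, 1.0), 1.0)
    return RescaleResult(v_new, "accepted", available, diag)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def attempt_hop(
    state: TrajectoryState,
    snapshot: ElectronicSnapshot,
    target: int,
    spec: RescaleSpec,
) -> HopEvent:
    """Attempt a hop from the active state to ``target`` under ``spec``.

    Computes the gap Delta E = E(target) - E(active), evaluates the
    scheme's reservoir, applies the matching rescale on acceptance
    (updating ``state`` in place: active state and velocities), and
    leaves the state untouched on frustration.  Returns the
    :class:`HopEvent` record either way.

    Schemes ``v_w`` and ``v_t`` with an all-zero contribution vector
    fall back to uniform rescaling with a logged warning (the weights
    are undefined without excitation character).
    """
    active = state.active_state
    if target == active:
        raise ContractError("hop target must differ from the active state")
    system = state.system
    delta_E = float(snapshot.energies[target] - snapshot.energies[active])
    E_kin_old = system.kinetic_energy()
    E_kin_new = E_kin_old - delta_E
    v_before = system.velocities.copy()

    scheme = spec.scheme
    if scheme in ("v_w", "v_t"):
        q = snapshot.contribution(active, target).q
        if not np.any(q > 0):
            logger.warning(
                "all-zero contributions for pair (%d, %d); falling back to uniform rescaling",
                active, target,
            )
            scheme = "v_full"

    if scheme == "v_full":
        result = rescale_uniform(system, E_kin_new)
    elif scheme == "d":
        if snapshot.nacv is None:
            raise ContractError("scheme 'd' requires NACVs in the snapshot")
        result = rescale_along_nacv(system, snapshot.nacv[active, target], delta_E)
    elif scheme == "v_w":
        _, w = normalized_weights(q)
        result = rescale_weighted(system, w, spec.alpha, E_kin_new)
    else:  # v_t
        subset = select_significant_atoms(q, spec.threshold_n)
        result = rescale_thresholded(system, subset, delta_E)

    if result.accepted:
        system.velocities = result.velocities
        state.active_state = target
    event = HopEvent(
        time=state.time,
        from_state=active,
        to_state=target,
        delta_E=delta_E,
        scheme=spec.label(),
        available_kinetic=result.available_kinetic,
        outcome=result.outcome,
        velocity_before=v_before,
        velocity_after=system.velocities.copy(),
    )
    return event
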