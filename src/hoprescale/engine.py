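"""Fewest-switches surface-hopping propagation on model potentials.

One nuclear step consists of: a velocity-Verlet step on the active
adiabatic surface; propagation of the electronic amplitudes with the
local-diabatization scheme (built from wave-function overlaps between
consecutive geometries, so no NACVs are needed for the electronic
equation of motion); energy-based decoherence damping of the inactive
amplitudes; and a stochastic fewest-switches hop decision whose
acceptance and velocity adjustment are delegated to the configured
rescaling scheme.

Determinism contract: a trajectory consumes exactly one uniform random
number per nuclear step, drawn from its own seeded generator, so
ensembles run with different rescaling schemes at the same seed see
identical hop-attempt times up to the first diverging accept/frustrate
outcome — the setup used to compare schemes trajectory by trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core import (
    EV_TO_HARTREE,
    FS_TO_AU,
    AtomicSystem,
    ContractError,
    ElectronicSnapshot,
    HopEvent,
    TrajectoryState,
    total_energy,
)
from .model_systems import ModelSystem, evaluate_adiabatic
from .rescaling import RescaleSpec, attempt_hop

logger = logging.getLogger(__name__)


@dataclass
class PropagatorConfig:
    """Numerical parameters of the propagation.

    ``dt`` is the nuclear time step (default 0.2 fs in a.u.);
    ``n_substeps`` the electronic substeps per nuclear step;
    ``decoherence_C`` the energy-based decoherence parameter (0.1
    hartree, the usual empirical value); ``drift_tolerance`` the total
    energy variation beyond which a trajectory is flagged and excluded
    from ensemble statistics (default 0.20 eV in hartree).
    """

    dt: float = 0.2 * FS_TO_AU
    n_substeps: int = 25
    decoherence_C: float = 0.1
    n_steps: int = 250
    max_time: Optional[float] = None
    drift_tolerance: float = 0.20 * EV_TO_HARTREE
    seed: int = 0
    #: apply decoherence before the hop decision instead of after it.
    #: The default (after) computes hop probabilities from the raw
    #: propagated amplitudes; damping them first biases the population
    #: flux downward and degrades classical/quantum internal consistency.
    decoherence_before_hop: bool = False
    store_geometry: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ContractError("time step must be positive")
        if self.n_substeps < 1:
            raise ContractError("at least one electronic substep required")
        if self.decoherence_C < 0:
            raise ContractError("decoherence parameter must be non-negative")
        if self.max_time is not None:
            self.n_steps = int(round(self.max_time / self.dt))
        if self.n_steps < 1:
            raise ContractError("at least one nuclear step required")


# ---------------------------------------------------------------------------
# nuclear step
# ---------------------------------------------------------------------------


def velocity_verlet_step(
    state: TrajectoryState,
    snapshot: ElectronicSnapshot,
    dt: float,
    evaluate: Callable[[np.ndarray, Optional[np.ndarray]], ElectronicSnapshot],
) -> ElectronicSnapshot:
    """Advance positions and velocities one velocity-Verlet step.

    Forces are the negative gradient of the active adiabatic state; the
    second force evaluation at the new geometry (through ``evaluate``,
    which also receives the previous adiabatic basis for phase
    continuity) completes the velocity update.  ``state`` is advanced in
    place; the snapshot at the new geometry is returned.
    """
    system = state.system
    a0 = -snapshot.gradients[state.active_state] / system.masses[:, None]
    if not np.all(np.isfinite(a0)):
        raise ContractError("non-finite forces at the current geometry")
    system.positions = system.positions + system.velocities * dt + 0.5 * a0 * dt * dt
    snap_new = evaluate(system.positions, snapshot.basis)
    a1 = -snap_new.gradients[state.active_state] / system.masses[:, None]
    if not np.all(np.isfinite(a1)):
        raise ContractError("non-finite forces at the advanced geometry")
    system.velocities = system.velocities + 0.5 * (a0 + a1) * dt
    state.time += dt
    return snap_new


# ---------------------------------------------------------------------------
# electronic step: local diabatization
# ---------------------------------------------------------------------------


def _nearest_orthogonal(overlap: np.ndarray) -> np.ndarray:
    """Löwdin symmetric orthogonalization with diagonal-sign phase fixing."""
    U, _, Vt = np.linalg.svd(overlap)
    T = U @ Vt
    diag = np.diag(T)
    if np.any(np.abs(diag) < 1e-3):
        logger.warning("near-zero overlap diagonal after orthogonalization (trivial crossing?)")
    return T * np.where(diag < 0, -1.0, 1.0)


def propagate_coefficients_ld(
    C: np.ndarray,
    E_prev: np.ndarray,
    E_curr: np.ndarray,
    overlap: np.ndarray,
    dt: float,
    n_substeps: int = 25,
) -> np.ndarray:
    """Propagate electronic amplitudes over one nuclear step.

    The overlap matrix O[i, j] = <psi_i(t) | psi_j(t + dt)> is
    orthogonalized to the nearest orthogonal matrix T (Löwdin), which
    defines a locally diabatic basis over the step.  In that basis the
    Hamiltonian interpolates linearly between diag(E_prev) and
    T diag(E_curr) T^T; the time-ordered propagator is accumulated over
    midpoint substeps and composed with the rotation back to the new
    adiabatic basis.  Exactly unitary, so the amplitude norm is
    conserved to rounding.
    """
    C = np.asarray(C, dtype=complex)
    T = _nearest_orthogonal(np.asarray(overlap, dtype=float))
    H0 = np.diag(np.asarray(E_prev, dtype=float))
    H1 = T @ np.diag(np.asarray(E_curr, dtype=float)) @ T.T
    # fourth-order commutator-free scheme: for an H linear in time it is the
    # product of exact exponentials at nodes 1/6 and 5/6 of each substep,
    # each over half a substep
    k = np.arange(n_substeps)
    s = np.empty(2 * n_substeps)
    s[0::2] = (k + 1.0 / 6.0) / n_substeps
    s[1::2] = (k + 5.0 / 6.0) / n_substeps
    H = H0[None] + s[:, None, None] * (H1 - H0)[None]
    w, V = np.linalg.eigh(H)
    phases = np.exp(-1j * w * (0.5 * dt / n_substeps))
    # substep propagators V exp(-i w tau) V^T, applied in time order
    U_sub = (V * phases[:, None, :]) @ np.swapaxes(V, 1, 2)
    psi = C
    for j in range(2 * n_substeps):
        psi = U_sub[j] @ psi
    return T.T @ psi


# ---------------------------------------------------------------------------
# hopping probabilities and decoherence
# ---------------------------------------------------------------------------


def hop_probability(C_before: np.ndarray, C_after: np.ndarray, active: int) -> np.ndarray:
    """Fewest-switches hop probabilities from the population flux.

    When the active-state population decreases over the step, the total
    hop probability equals the fractional loss, distributed over the
    states whose populations grew, proportionally to their gains.  All
    probabilities are non-negative, g_active = 0, and the sum never
    exceeds one.
    """
    p_before = np.abs(np.asarray(C_before)) ** 2
    p_after = np.abs(np.asarray(C_after)) ** 2
    g = np.zeros_like(p_before)
    if p_before[active] <= 0.0:
        logger.warning("active-state population vanished; no hop probabilities")
        return g
    loss = p_before[active] - p_after[active]
    if loss <= 0.0:
        return g
    gains = np.clip(p_after - p_before, 0.0, None)
    gains[active] = 0.0
    total_gain = gains.sum()
    if total_gain <= 0.0:
        return g
    return (loss / p_before[active]) * gains / total_gain


def apply_decoherence(
    C: np.ndarray,
    energies: np.ndarray,
    active: int,
    E_kin: float,
    C_param: float,
    dt: float,
) -> np.ndarray:
    """Energy-based decoherence damping of inactive amplitudes.

    Each inactive amplitude decays with timescale
    tau_k = (1 + C_param / E_kin) / |E_k - E_active|; the active
    amplitude is rescaled, phase preserved, to restore unit norm.
    Degenerate states (E_k = E_active) and E_kin = 0 give no damping.
    """
    C = np.asarray(C, dtype=complex).copy()
    if E_kin <= 0.0:
        return C
    gaps = np.abs(np.asarray(energies, dtype=float) - energies[active])
    factor = np.ones_like(gaps)
    nz = gaps > 0.0
    factor[nz] = np.exp(-dt * gaps[nz] / (1.0 + C_param / E_kin))
    factor[active] = 1.0
    C *= factor
    p_active = abs(C[active]) ** 2
    p_others = float(np.sum(np.abs(C) ** 2)) - p_active
    if p_active > 1e-300:
        C[active] *= np.sqrt(max(1.0 - p_others, 0.0) / p_active)
    else:
        norm = np.sqrt(np.sum(np.abs(C) ** 2))
        if norm > 0:
            C /= norm
    return C


# ---------------------------------------------------------------------------
# trajectory and ensemble drivers
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryRecord:
    """Per-step log of one trajectory plus its hop events."""

    times: np.ndarray
    energies: np.ndarray  #: (n_steps + 1, n_states) adiabatic energies
    active: np.ndarray  #: (n_steps + 1,) active-state index
    quantum_pops: np.ndarray  #: (n_steps + 1, n_states) |C_i|^2
    kinetic: np.ndarray
    total: np.ndarray
    events: list
    flagged: bool = False
    flag_reason: str = ""
    positions: Optional[np.ndarray] = None
    velocities: Optional[np.ndarray] = None

    @property
    def n_states(self) -> int:
        return self.energies.shape[1]

    @property
    def max_drift(self) -> float:
        return float(np.max(np.abs(self.total - self.total[0])))


def run_trajectory(
    model: ModelSystem,
    init: TrajectoryState,
    spec: RescaleSpec,
    cfg: PropagatorConfig,
    rng: Optional[np.random.Generator] = None,
) -> TrajectoryRecord:
    """Propagate one surface-hopping trajectory.

    The loop per step: nuclear velocity-Verlet step, local-diabatization
    electronic propagation, decoherence (before the hop decision by
    default; switchable via ``cfg.decoherence_before_hop``), one uniform
    random draw, fewest-switches hop decision, and — on a selected
    target — the scheme-specific hop attempt.  The trajectory is flagged
    when the total energy drifts beyond ``cfg.drift_tolerance`` from its
    initial value (accepted hops conserve it by construction).
    """
    if rng is None:
        rng = init.rng if init.rng is not None else np.random.default_rng(cfg.seed)
    state = init
    n_states = state.n_states
    need_nacv = spec.scheme == "d"

    def evaluate(positions, prev_basis):
        return evaluate_adiabatic(model, positions, prev_basis, need_nacv=need_nacv)

    n_steps = cfg.n_steps
    times = np.empty(n_steps + 1)
    energies = np.empty((n_steps + 1, n_states))
    active_log = np.empty(n_steps + 1, dtype=int)
    pops = np.empty((n_steps + 1, n_states))
    kinetic = np.empty(n_steps + 1)
    total = np.empty(n_steps + 1)
    geom = np.empty((n_steps + 1, state.system.n_atoms, 3)) if cfg.store_geometry else None
    vel = np.empty((n_steps + 1, state.system.n_atoms, 3)) if cfg.store_geometry else None
    events: list[HopEvent] = []
    flagged = False
    flag_reason = ""

    snap = evaluate(state.system.positions, None)
    state.total_energy_ref = total_energy(state, snap)

    def log(i: int, snapshot: ElectronicSnapshot) -> None:
        times[i] = state.time
        energies[i] = snapshot.energies
        active_log[i] = state.active_state
        pops[i] = state.populations()
        kinetic[i] = state.system.kinetic_energy()
        total[i] = kinetic[i] + snapshot.energies[state.active_state]
        if geom is not None:
            geom[i] = state.system.positions
            vel[i] = state.system.velocities

    log(0, snap)

    for step in range(1, n_steps + 1):
        try:
            C_start = state.coefficients
            snap_new = velocity_verlet_step(state, snap, cfg.dt, evaluate)
            C = propagate_coefficients_ld(
                C_start, snap.energies, snap_new.energies, snap_new.overlap_prev,
                cfg.dt, cfg.n_substeps,
            )
            if cfg.decoherence_before_hop:
                C = apply_decoherence(
                    C, snap_new.energies, state.active_state,
                    state.system.kinetic_energy(), cfg.decoherence_C, cfg.dt,
                )
            g = hop_probability(C_start, C, state.active_state)
            r = rng.random()  # one draw per step, hop or not
            state.coefficients = C
            target = _select_target(g, r)
            if target is not None:
                events.append(attempt_hop(state, snap_new, target, spec))
            if not cfg.decoherence_before_hop:
                state.coefficients = apply_decoherence(
                    state.coefficients, snap_new.energies, state.active_state,
                    state.system.kinetic_energy(), cfg.decoherence_C, cfg.dt,
                )
        except ContractError as err:
            flagged = True
            flag_reason = f"terminated at step {step}: {err}"
            logger.warning("trajectory %s", flag_reason)
            times[step:] = times[step - 1]
            energies[step:] = energies[step - 1]
            active_log[step:] = active_log[step - 1]
            pops[step:] = pops[step - 1]
            kinetic[step:] = kinetic[step - 1]
            total[step:] = total[step - 1]
            if geom is not None:
                geom[step:] = geom[step - 1]
                vel[step:] = vel[step - 1]
            break
        log(step, snap_new)
        if not flagged and abs(total[step] - state.total_energy_ref) > cfg.drift_tolerance:
            flagged = True
            flag_reason = (
                f"energy drift {abs(total[step] - state.total_energy_ref):.3e} hartree "
                f"exceeded tolerance at t = {state.time:.1f}"
            )
        snap = snap_new

    return TrajectoryRecord(
        times=times, energies=energies, active=active_log, quantum_pops=pops,
        kinetic=kinetic, total=total, events=events,
        flagged=flagged, flag_reason=flag_reason, positions=geom, velocities=vel,
    )


def _select_target(g: np.ndarray, r: float) -> Optional[int]:
    """Fewest-switches target selection from stacked probability intervals."""
    edges = np.cumsum(g)
    if edges.size == 0 or r >= edges[-1]:
        return None
    return int(np.searchsorted(edges, r, side="right"))


def trajectory_rngs(seed: int, n_traj: int) -> tuple[list, list]:
    """Deterministic per-trajectory generators for initial conditions and dynamics.

    Derived from independent spawn keys of one seed sequence, so
    ensembles at the same seed share initial conditions and random
    streams across rescaling schemes.
    """
    ic = [np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, k))) for k in range(n_traj)]
    dyn = [np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, k))) for k in range(n_traj)]
    return ic, dyn


def run_ensemble(
    model: ModelSystem,
    initial_conditions: Optional[Sequence[AtomicSystem]],
    spec: RescaleSpec,
    cfg: PropagatorConfig,
    n_traj: int,
):
    """Run an ensemble of independent trajectories and aggregate statistics.

    Initial geometries/velocities are Wigner-sampled per trajectory from
    ``cfg.seed`` unless ``initial_conditions`` supplies them explicitly.
    Flagged trajectories (energy drift, model failure) are kept in the
    record but excluded from the population averages and hop counts, and
    reported through ``n_traj_excluded``.
    """
    from .analysis import EnsembleResult  # deferred: analysis imports no engine symbols

    if n_traj < 1:
        raise ContractError("n_traj must be at least one")
    ic_rngs, dyn_rngs = trajectory_rngs(cfg.seed, n_traj)
    records = []
    for k in range(n_traj):
        if initial_conditions is not None:
            system = initial_conditions[k].copy()
        else:
            system = model.sample_initial(ic_rngs[k])
        C0 = np.zeros(model.n_states, dtype=complex)
        C0[model.initial_state] = 1.0
        state = TrajectoryState(
            time=0.0, system=system, active_state=model.initial_state, coefficients=C0,
        )
        records.append(run_trajectory(model, state, spec, cfg, rng=dyn_rngs[k]))

    included = [rec for rec in records if not rec.flagged]
    n_used = len(included)
    if n_used == 0:
        raise ContractError("every trajectory was excluded; nothing to aggregate")
    times = included[0].times
    n_states = included[0].n_states
    classical = np.zeros((n_states, times.size))
    quantum = np.zeros((n_states, times.size))
    for rec in included:
        classical[rec.active, np.arange(times.size)] += 1.0
        quantum += rec.quantum_pops.T
    classical /= n_used
    quantum /= n_used
    return EnsembleResult(
        times=times,
        classical_pops=classical,
        quantum_pops=quantum,
        events=[rec.events for rec in included],
        n_traj_used=n_used,
        n_traj_excluded=len(records) - n_used,
        records=records,
        scheme=spec.label(),
    )
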