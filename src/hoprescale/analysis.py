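"""Ensemble statistics, report tables and text-file output.

Classical populations are trajectory fractions N_i(t) / N_traj over the
non-excluded trajectories; quantum populations are the ensemble mean of
the state probabilities |C_i(t)|^2.  Confidence bands use the binomial
normal approximation Gamma = p +/- 1.96 sqrt(p (1 - p) / N_traj).  Hop
tables count accepted hops, back-hops (accepted upward hops) and
frustrated hops per ordered state pair, raw and per trajectory.

All outputs are plain text (CSV, JSON lines, multi-frame XYZ) and are
byte-identical across reruns at a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    AU_TO_FS,
    BOHR_TO_ANGSTROM,
    AtomicSystem,
    ContractError,
    ContributionSet,
    HopEvent,
)
from .rescaling import (
    available_kinetic_nacv,
    available_kinetic_weighted,
    normalized_weights,
    select_significant_atoms,
)

SCHEMA_VERSION = "hoprescale-1"


@dataclass
class EnsembleResult:
    """Aggregated outcome of a trajectory ensemble."""

    times: np.ndarray
    classical_pops: np.ndarray  #: (n_states, n_times) trajectory fractions
    quantum_pops: np.ndarray  #: (n_states, n_times) mean |C_i|^2
    events: list  #: per included trajectory, list of HopEvent
    n_traj_used: int
    n_traj_excluded: int
    records: list = field(default_factory=list)
    scheme: str = ""

    @property
    def n_states(self) -> int:
        return self.classical_pops.shape[0]

    def all_events(self) -> list:
        return [ev for traj in self.events for ev in traj]


def state_label(i: int) -> str:
    """Display label of a 0-based state index (S0, S1, ...)."""
    return f"S{i}"


# ---------------------------------------------------------------------------
# populations and confidence intervals
# ---------------------------------------------------------------------------


def classical_populations(active_logs: Sequence[np.ndarray], n_states: int) -> np.ndarray:
    """Fraction of trajectories whose active state is i at each time.

    ``active_logs`` holds one active-state index array per non-excluded
    trajectory, all on the same time grid.
    """
    if len(active_logs) == 0:
        raise ContractError("empty ensemble: no populations to compute")
    n_times = active_logs[0].shape[0]
    pops = np.zeros((n_states, n_times))
    cols = np.arange(n_times)
    for log in active_logs:
        if log.shape[0] != n_times:
            raise ContractError("trajectories must share a common time grid")
        pops[log, cols] += 1.0
    return pops / len(active_logs)


def confidence_interval(p, n_traj: int) -> tuple:
    """95% binomial confidence band p +/- 1.96 sqrt(p(1-p)/N), clipped to [0, 1]."""
    p = np.asarray(p, dtype=float)
    half = 1.96 * np.sqrt(p * (1.0 - p) / n_traj)
    return np.clip(p - half, 0.0, 1.0), np.clip(p + half, 0.0, 1.0)


# ---------------------------------------------------------------------------
# hop tables
# ---------------------------------------------------------------------------


def hop_statistics(result: EnsembleResult) -> pd.DataFrame:
    """Hops, back-hops and frustrated hops per ordered state pair.

    One row per transition observed, with raw counts and counts per
    non-excluded trajectory.  Back-hops are accepted hops with
    Delta E > 0 from a lower to a higher state.
    """
    n_traj = result.n_traj_used
    rows: dict[tuple, dict] = {}
    for ev in result.all_events():
        key = (ev.from_state, ev.to_state, ev.outcome)
        row = rows.setdefault(key, {
            "transition": f"{state_label(ev.from_state)}->{state_label(ev.to_state)}",
            "kind": (
                "frustrated" if ev.outcome == "frustrated"
                else ("back-hop" if ev.delta_E > 0 else "hop")
            ),
            "count": 0,
        })
        row["count"] += 1
    table = pd.DataFrame(
        [rows[k] for k in sorted(rows)],
        columns=["transition", "kind", "count"],
    )
    table["per_trajectory"] = table["count"] / n_traj if len(table) else pd.Series(dtype=float)
    return table


def count_events(result: EnsembleResult) -> dict:
    """Totals over all transitions: accepted hops, back-hops, frustrated hops."""
    hops = back = frust = 0
    for ev in result.all_events():
        if ev.outcome == "frustrated":
            frust += 1
        elif ev.delta_E > 0:
            back += 1
        else:
            hops += 1
    n = result.n_traj_used
    return {
        "n_hop": hops, "n_backhop": back, "n_frustrated": frust, "n_traj": n,
        "hop_per_traj": hops / n, "backhop_per_traj": back / n, "frustrated_per_traj": frust / n,
    }


# ---------------------------------------------------------------------------
# available-energy and contribution comparisons
# ---------------------------------------------------------------------------


def available_energy_report(
    entries: Sequence[dict],
    threshold_n: float = 0.3,
) -> pd.DataFrame:
    """Available kinetic energy under each scheme at recorded geometries.

    Each entry is a dict with an :class:`AtomicSystem` under ``system``,
    per-atom contributions ``q``, and optionally the NACV ``d`` of the
    state pair; the columns give the reservoir each scheme would see at
    that point: the full kinetic energy (v_full), the NACV-projected
    energy (d; NaN when no NACV is available), the weighted reservoir
    (v_w) and the significant-subset kinetic energy (v_t).
    """
    rows = []
    for entry in entries:
        system: AtomicSystem = entry["system"]
        q = np.asarray(entry["q"], dtype=float)
        _, w = normalized_weights(q)
        subset = select_significant_atoms(q, threshold_n)
        d = entry.get("d")
        rows.append({
            "E_avail_v_full": system.kinetic_energy(),
            "E_avail_d": available_kinetic_nacv(system, d) if d is not None else np.nan,
            "E_avail_v_w": available_kinetic_weighted(w, system),
            "E_avail_v_t": float(np.sum(system.per_atom_kinetic()[subset])),
        })
    return pd.DataFrame(rows)


def contribution_report(
    contributions: Sequence[ContributionSet],
    nacvs: Optional[Sequence[np.ndarray]] = None,
) -> pd.DataFrame:
    """Per-atom averages of the normalized contributions and NACV magnitudes.

    For every recorded event the contribution coefficients c_A and (when
    available) the per-atom NACV norms |d_A| / ||d|| are averaged over
    events — the comparison of where the schemes put their weight versus
    where the coupling vector points.
    """
    if len(contributions) == 0:
        raise ContractError("no events to report on")
    c_rows = []
    for cs in contributions:
        c, _ = normalized_weights(cs.q)
        c_rows.append(c)
    c_mean = np.mean(c_rows, axis=0)
    out = {"atom": np.arange(c_mean.shape[0]), "mean_c": c_mean}
    if nacvs is not None:
        d_rows = []
        for d in nacvs:
            d = np.asarray(d, dtype=float).reshape(-1, 3)
            norms = np.linalg.norm(d, axis=1)
            total = np.linalg.norm(d)
            d_rows.append(norms / total if total > 0 else np.zeros_like(norms))
        out["mean_nacv"] = np.mean(d_rows, axis=0)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# text output
# ---------------------------------------------------------------------------


def write_populations_csv(path, result: EnsembleResult) -> None:
    """Time grid (fs) with classical and quantum populations per state."""
    cols = {"time_fs": result.times * AU_TO_FS}
    for i in range(result.n_states):
        cols[f"classical_{state_label(i)}"] = result.classical_pops[i]
    for i in range(result.n_states):
        cols[f"quantum_{state_label(i)}"] = result.quantum_pops[i]
    frame = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION} populations; scheme: {result.scheme}; "
                 f"n_traj: {result.n_traj_used}; excluded: {result.n_traj_excluded}\n")
        frame.to_csv(fh, index=False, float_format="%.12g")


def write_events_jsonl(path, result: EnsembleResult) -> None:
    """One JSON object per hop event, tagged with its trajectory index."""
    with open(path, "w") as fh:
        fh.write(json.dumps({"schema": SCHEMA_VERSION, "kind": "hop_events",
                             "scheme": result.scheme}) + "\n")
        for i_traj, traj in enumerate(result.events):
            for ev in traj:
                rec = ev.to_dict()
                rec["trajectory"] = i_traj
                fh.write(json.dumps(rec) + "\n")


def write_xyz(path, labels: Sequence[str], frames: np.ndarray, comment: str = "") -> None:
    """Multi-frame XYZ in angstrom (coordinates are bohr internally)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    with open(path, "w") as fh:
        for i, frame in enumerate(frames):
            fh.write(f"{len(labels)}\n")
            fh.write(f"units=angstrom frame={i} {comment}\n")
            for label, xyz in zip(labels, frame * BOHR_TO_ANGSTROM):
                fh.write(f"{label} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}\n")


def read_xyz(path) -> tuple[list, np.ndarray]:
    """Read a multi-frame XYZ written by :func:`write_xyz`; returns bohr."""
    frames = []
    labels: list = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            fh.readline()  # comment
            labels = []
            coords = np.empty((n, 3))
            for a in range(n):
                parts = fh.readline().split()
                labels.append(parts[0])
                coords[a] = [float(x) for x in parts[1:4]]
            frames.append(coords / BOHR_TO_ANGSTROM)
    return labels, np.array(frames)


def write_ensemble(outdir, result: EnsembleResult) -> None:
    """Populations CSV, hop-event JSONL and a summary table under one directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_populations_csv(out / "populations.csv", result)
    write_events_jsonl(out / "hop_events.jsonl", result)
    table = hop_statistics(result)
    with open(out / "hop_statistics.csv", "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION} hop_statistics; scheme: {result.scheme}\n")
        table.to_csv(fh, index=False, float_format="%.12g")
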