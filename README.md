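# hoprescale

Velocity rescaling in fewest-switches surface hopping (FSSH), driven by
per-atom contributions to the electronic transition.

When a surface-hopping trajectory hops between adiabatic states, the
nuclear kinetic energy must change by the potential gap ΔE so the total
energy is conserved. The common choice — rescale every velocity
uniformly by √(E_kin_new/E_kin_old) — is *size-inconsistent*: atoms
that have nothing to do with the transition (a solvent shell, a second
chromophore, any spectator subsystem) enlarge the kinetic-energy
reservoir, so hops that should be frustrated get accepted, funded by
slowing down uninvolved atoms. The physically preferred alternative,
adjusting the momentum along the nonadiabatic coupling vector (NACV),
is often unavailable.

`hoprescale` implements two excitation-based schemes that keep the
adjustment local to the atoms actually involved, plus both references,
inside a self-contained FSSH engine running on analytic model
potentials:

| scheme | reservoir for a hop | velocity update |
|---|---|---|
| `v_full` | total kinetic energy | uniform factor √(E_kin_new/E_kin_old) |
| `d` | b²/4a along the NACV | v_A ← v_A − γ d_A/M_A, smaller-\|γ\| root of aγ² − bγ + ΔE = 0 |
| `v_w` | ½ Σ_A w_A M_A v_A² | v_A ← v_A f_A N, f_A = √(E_kin_new/E_kin_old)[1 + α(w_A − mean w)] |
| `v_t` | kinetic energy of atoms with q_A > n·max(q) | uniform factor on that subset only |

with w_A = c_A², c_A = q_A/√(Σ_B q_B²), and q_A the per-atom
contribution of the transition: from a Löwdin population analysis of
the one-electron transition density matrix or the density-difference
matrix (electron/hole combination q_A = |q^e_A| + |q^h_A| or transition
charges q_A = |q^tr_A|), or supplied directly by a model. The global
factor N = √(E_kin_new/E*_kin) makes energy conservation at accepted
hops exact to machine precision under every scheme.

The engine provides velocity-Verlet nuclear integration,
local-diabatization propagation of the electronic amplitudes
(wave-function overlaps, no NACVs needed), fewest-switches hopping,
energy-based decoherence (C = 0.1 a.u.), Wigner initial sampling, and
ensemble statistics (classical and quantum populations with 95%
confidence bands, hop/back-hop/frustrated-hop tables, available-energy
and per-atom-contribution reports). Shipped model systems — a two-atom
avoided-crossing chromophore and a spectator-augmented contrast model —
make every scheme testable without electronic-structure software.
See `docs/methods.md` for the full model description.

## Worked example

Compare the schemes on the contrast model (a two-atom chromophore whose
bond stretch carries the transition, plus two free spectator atoms with
zero excitation character):

```sh
hoprescale run --model contrast --scheme vfull --ntraj 200 --steps 250 --seed 1 --outdir out_vfull
hoprescale run --model contrast --scheme vw --alpha 1.0 --ntraj 200 --steps 250 --seed 1 --outdir out_vw
hoprescale run --model contrast --scheme d --ntraj 200 --steps 250 --seed 1 --outdir out_d
```

prints (identical seeds, so the ensembles are paired trajectory by
trajectory):

```
scheme v_full: 200 trajectories used, 0 excluded
hops/traj 1.975, back-hops/traj 1.275, frustrated/traj 0.040
scheme v_w(direct, alpha=1): 186 trajectories used, 14 excluded
hops/traj 1.747, back-hops/traj 1.075, frustrated/traj 0.715
scheme d: 200 trajectories used, 0 excluded
hops/traj 1.550, back-hops/traj 0.725, frustrated/traj 1.040
```

Uniform rescaling (`v_full`) accepts the most upward back-hops and
frustrates almost none: the spectator kinetic energy bankrolls
transitions the chromophore cannot afford. The excitation-weighted
scheme (`v_w`) and the NACV reference (`d`) see only the chromophore's
(weighted or projected) kinetic energy and frustrate a visible fraction
of the attempts, with `v_w` sitting between `v_full` and `d` in both
counts. Trajectories whose total energy drifts beyond 0.20 eV are
excluded from the statistics and reported separately. Each
output directory contains `populations.csv` (classical and quantum
populations per state over time), `hop_events.jsonl` (one record per
attempt) and `hop_statistics.csv` (counts per transition, raw and per
trajectory).

The same comparison per atom: `hoprescale charges <dir>` computes
Löwdin electron/hole or transition charges from plain-text matrix
dumps (`S.dat`, `C_mo.dat`, `T.dat`, `basis_map.dat`), and
`hoprescale fixtures` generates consistent random bundles to try it on.

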