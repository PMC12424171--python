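# Methods

## The problem

In fewest-switches surface hopping (FSSH), nuclei move classically on
one adiabatic potential-energy surface at a time and switch surfaces
stochastically. At a hop the potential energy jumps by the gap
ΔE = E_new − E_old, so the nuclear velocities must be adjusted to keep
the total energy E_tot = E_kin + E_pot constant. *How* that kinetic
energy is added or removed — from which atoms, along which direction —
is a modelling choice with real consequences: it decides which upward
hops are energetically allowed ("frustrated" hops are rejected
attempts) and therefore shapes back-hopping and the long-time
populations.

Two standard choices bracket the field. Uniform rescaling (here
`v_full`) multiplies every velocity by √(E_kin_new / E_kin_old). It is
cheap but size-inconsistent: a non-interacting spectator subsystem
enlarges the kinetic-energy reservoir, so a hop that is impossible for
the chromophore alone becomes possible in the combined system, funded
by slowing down atoms that have nothing to do with the transition.
Adjusting the velocity component along the nonadiabatic coupling
vector (`d`) is the physically preferred direction but NACVs are often
unavailable or expensive.

This package implements, alongside those two references, the two
excitation-based schemes that interpolate between them using only
per-atom charges derived from the electronic transition:

* **Excitation-weighted rescaling** (`v_w`). Per-atom contributions
  q_A ≥ 0 give normalized coefficients c_A = q_A / √(Σ_B q_B²) and
  weights w_A = c_A² (Σ w_A = 1). The reservoir available for a hop is
  the weighted kinetic energy E_avail = ½ Σ_A w_A M_A v_A²; an upward
  hop with ΔE > E_avail is frustrated. On acceptance each atom gets a
  factor f_A = √(E_kin_new/E_kin_old)·[1 + α(w_A − mean(w))] and a
  global factor N = √(E_kin_new/E*_kin) (E*_kin the kinetic energy of
  the f-scaled velocities) restores energy conservation exactly;
  v_A ← v_A f_A N. α = 0 reduces to uniform rescaling; because N
  renormalizes the total, any positive constant prefactor of f would
  yield identical final velocities (unit-tested as a property).
* **Excitation-thresholded rescaling** (`v_t`). Atoms with
  q_A > n·max(q), n ∈ [0, 1], form the significant subset; uniform
  rescaling is applied to that subset only and the gap is balanced
  against the subset kinetic energy. The arg-max atom is always kept,
  so the subset is never empty (n = 1 and ties included).

Both schemes are size-consistent by construction: spectator atoms with
q_A = 0 contribute neither to the reservoir nor to the rescaling.

The per-atom charges come from a Löwdin population analysis of a
transition-type matrix **T** — either the one-electron transition
density matrix (1TDM) or the density difference (DD) of the two states.
Mode `qeh` decomposes **T** into electron and hole parts,
D^e = TᵀT and D^h = TTᵀ, and combines their per-atom populations as
q_A = |q^e_A| + |q^h_A| (absolute values so electron and hole
participation cannot cancel); mode `qtr` uses the populations of the
1TDM itself, q_A = |q^tr_A|. The analysis chain is: transform the
MO-basis matrix to the AO basis (D_ao = C D C ᵀ), form
S^{1/2} D_ao S^{1/2} with the principal square root of the AO overlap,
and sum diagonal elements per atom. With S-orthonormal MOs the
populations sum to trace(D); for a Frobenius-normalized **T** the
electron and hole populations each sum to one — the invariant the
tests and the acceptance script check. The model potentials instead
supply q_A analytically (mode `direct`), since they have no AO basis.

### NACV-direction adjustment

With b = Σ_A v_A·d_A and a = ½ Σ_A |d_A|²/M_A, the velocity change
v_A ← v_A − γ d_A/M_A conserves energy when a γ² − b γ + ΔE = 0; the
smaller-|γ| root is taken (minimal perturbation), and the hop is
frustrated when b² < 4a ΔE. The maximum removable energy along d is
b²/(4a), which the tests verify against a brute-force one-dimensional
scan over γ.

## Dynamics machinery

* **Nuclear integration**: velocity Verlet on the active adiabatic
  surface, Δt = 0.2 fs by default.
* **Electronic propagation**: local diabatization. The overlap matrix
  between adiabatic states at consecutive geometries is symmetrized to
  the nearest orthogonal matrix T (Löwdin/polar), with column signs
  fixed so the diagonal is positive. In the locally diabatic basis the
  Hamiltonian interpolates linearly between diag(E_prev) and
  T diag(E_curr) Tᵀ; the time-ordered propagator is accumulated over
  25 substeps and composed with Tᵀ. The substep integrator is the
  fourth-order commutator-free scheme, which for a linearly
  interpolated Hamiltonian reduces to exact exponentials at nodes 1/6
  and 5/6 of each substep (half-step each); against a 1000-substep
  reference it is accurate to ~1e-8 at the default settings, and it is
  exactly unitary, so the amplitude norm is conserved to rounding.
* **Hopping**: fewest-switches probabilities built from the population
  flux: when the active population decreases over a step, the total
  hop probability is the fractional loss, distributed over states whose
  populations grew in proportion to their gains; negative fluxes are
  clipped. One uniform random number is drawn per nuclear step whether
  or not a hop is attempted, so ensembles run with different rescaling
  schemes at the same seed see identical attempt times up to the first
  diverging accept/frustrate decision — the paired-trajectory setup
  used for scheme comparisons.
* **Decoherence**: energy-based damping of inactive amplitudes with
  timescale τ_k = (1 + C/E_kin)/|E_k − E_active|, C = 0.1 hartree; the
  active amplitude is rescaled (phase preserved) to restore the norm.
* **Ordering**: the hop decision uses the raw propagated amplitudes of
  the step; decoherence is applied afterwards. Damping before the
  decision shrinks the inactive-state gains and the active-state loss,
  biases the fewest-switches flux low, and measurably breaks the
  agreement between classical (trajectory-fraction) and quantum
  (mean |C_i|²) populations; with the chosen ordering the two agree
  within the 95% binomial band on the shipped models. The alternative
  ordering remains available via
  `PropagatorConfig(decoherence_before_hop=True)`.
* **Frustrated hops**: velocities are left untouched (momentum
  direction preserved; no reversal variant).
* **Energy accounting**: the reference total energy is fixed at t = 0.
  Accepted hops conserve it to machine precision by construction, so
  any drift is the integrator's. Trajectories whose drift exceeds a
  tolerance (default 0.20 eV) are flagged and excluded from population
  averages and hop tables, and reported separately.

## Shipped model systems

All units are Hartree atomic units unless stated.

**Avoided-crossing chromophore** (`avoided_crossing_model`): two atoms
of mass 1000, tuning coordinate q = stretch of the bond. Both diabats
share the harmonic stretch ½kq² (k = 0.1; stretch frequency ≈ 0.014,
period ≈ 11 fs); the excited diabat is raised by 0.02 (≈ 0.54 eV) at
the reference geometry and tilted by −0.05·q, so the diabats cross at
q = 0.4. The diabatic coupling is λ(Δy) = √(λ0² + g²Δy²) with
λ0 = 0.002, g = 0.06 and Δy the relative transverse displacement —
bounded below by λ0 (no reachable conical intersection, minimal
adiabatic gap 0.004) and giving the NACV a component along the
transverse modes. Each atom also sits in a state-independent
transverse harmonic well (force constant 0.288, frequency ≈ 0.017):
those modes carry zero-point kinetic energy that the uniform scheme
counts as available for hopping while the NACV projection does not —
the intra-molecular analog of the spectator problem. Initial
conditions are Wigner-sampled from the three modes (stretch + two
transverse) with the trajectory started on the upper adiabatic state.
The light mass is deliberate: it widens the zero-point spread of
crossing-arrival times, which dephases the passages across the
ensemble. With heavy, synchronized ensembles the classical
(trajectory-fraction) populations transiently lag the coherent quantum
transfer during each passage; the dephased ensemble removes that
transient and keeps the two population measures statistically
consistent.

**Contrast model** (`contrast_model`): the chromophore plus two free
(flat-potential) spectator atoms of mass 2000 with Gaussian initial
velocities carrying ≈ 0.12 hartree per spectator on average. Spectator
q_A, NACV components and gradients are identically zero, so the
size-consistent schemes must reproduce the core-only dynamics bitwise
(property-tested); uniform rescaling sees the spectator kinetic energy
and accepts upward hops the other schemes frustrate. The parameters
were chosen so that, at desk scale (500 trajectories × 50 fs), the
scheme ordering seen in on-the-fly benchmarks is resolved: uniform
rescaling accepts the most back-hops and frustrates almost none, while
the weighted and NACV schemes frustrate a visible fraction.

**What the synthetic models do not emulate**: real multidimensional
seams (one tuning coordinate only), anharmonicity, geometry-dependent
per-atom contributions (the model's q_A are constant), Franck-Condon
excitation-window selection of initial conditions, and of course any
specific molecule's surfaces. Passing the ensemble tests shows the
schemes behave as designed under controlled conditions, not that any
particular molecular result is reproduced.

**Matrix-bundle fixtures** (`random_matrix_bundle`): AO overlap
S = AAᵀ + εI with ε keeping the condition number ≤ 1e6, S-orthonormal
MOs by construction, and a Frobenius-normalized random **T** — enough
structure to exercise every invariant of the charge analysis on a
nontrivial overlap.

## Numerical choices and degenerate inputs

* Löwdin square root by eigendecomposition with an eigenvalue floor of
  1e-10; below it the basis counts as linearly dependent and the
  analysis refuses.
* NACV evaluation refuses below an adiabatic gap of 1e-8 (the coupling
  diverges at a conical intersection); the trajectory is then flagged.
* All-zero contribution vectors (no excitation character) make the
  weights of `v_w`/`v_t` undefined; both fall back to uniform rescaling
  with a logged warning.
* `select_significant_atoms` keeps the arg-max atom even when the
  strict inequality excludes everything (n = 1, ties).
* Non-positive per-atom factors f_A (pathological α) raise instead of
  being clipped; the useful range explored is α ≤ 1.
* A subset at rest cannot absorb or supply energy by scaling, so `v_t`
  reports such hops frustrated rather than dividing by zero.
* Per-trajectory random streams are spawned from the ensemble seed and
  the trajectory index, so ensembles are reproducible bit-for-bit and
  comparable across schemes at a fixed seed.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run 500-trajectory ensembles
of 250 steps (50 fs at 0.2 fs) on the 2- and 4-atom models, 1000
randomized hop instances, 100 random matrix bundles, 100 NACV oracle
instances and 1e5 Wigner draws. These sizes resolve the scheme
ordering and the statistical checks comfortably on a single CPU.

## Known limitations

* The engine targets analytic diabatic models (≤ ~10 atoms, ≤ 5
  states); there is no interface to electronic-structure codes.
* Only the ground-vibrational-state (T = 0) Wigner distribution is
  implemented.
* The DD-based electron/hole split applies the decomposition formula
  to whichever matrix is supplied; for a DD matrix the "electron" and
  "hole" labels are conventional rather than rigorous, which mirrors
  how the analysis is used in practice.
* Internal consistency of FSSH is approximate by nature; the shipped
  models keep classical and quantum populations within the 95%
  binomial band, but stronger coherent recrossing regimes need not.
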