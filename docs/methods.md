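# Methods

`gatekit` implements the computational machinery of an activation-gating
study of a tetrameric potassium channel (the KcsA pore domain is the
shipped preset): a one-dimensional reaction coordinate built from the
difference between two crystal conformations, essential-dynamics (ED)
driving along that coordinate, umbrella sampling with a self-contained
WHAM solver, largest-sphere pore profiling, and the per-frame gating
metrics (chi1 rotamer states, opposite-subunit distances, hydrogen-bond
counts). Everything is exercisable at desk scale on a coarse-grained toy
channel and analytic landscapes with known ground truth.

## Reaction coordinate

The coordinate is the single non-trivial eigenvector of a covariance
PCA over a two-frame "trajectory" holding the closed and open backbone
conformations (without loops). For two frames the covariance matrix has
rank one and its eigenvector is the normalised, least-squares-fitted
coordinate difference; `collective.covariance_pca` computes the general
PCA (eigenvalues in nm², rank tolerance 1e-10 nm², configurable) and
`build_difference_ev` wraps the two-frame case into a
`CollectiveVector` with the sign convention that opening projects
positive: the closed structure projects to exactly 0, the open one to
the path length |dx|. Every projection first removes rigid-body motion
by a Kabsch superposition onto the reference over the fit selection
(default: the same backbone-without-loops atoms). The covariance is
unweighted by default (`mass_weighted` flag available; conventions
differ and the choice does not affect the two-frame coordinate
direction for equal-mass selections).

## Selections and preparation

"Backbone" means {N, CA, C, O} (configurable). The KcsA segment preset
is TM1 29–51, turret loop 52–61, P-helix 62–74, selectivity filter
75–79, loop 80–85, TM2 86–118; loop segments are dropped unless
requested. Channel preparation trims every chain to the inclusive range
29–118 — which contains 90 residues; the residue count per chain is
surfaced so users can reconcile their own bookkeeping — and the
wild-type correction at residue 117 is a name-only relabeling (all
computations on crystal inputs here are backbone-based, so no
side-chain rebuilding is attempted). Missing residues produce coverage
warnings, never silent truncation.

## Essential-dynamics driving

ED here is the linear fixed-increment expansion scheme: each
integration step performs one unconstrained dynamics update of all
coordinates and then corrects the positions of the collective-vector
atoms so the projection equals the prescribed target exactly, the
target advancing by a fixed increment per step. The correction is
applied along the eigenvector in the fitted frame and rotated back;
because the fit itself shifts under the correction, the (fit, correct)
pair is iterated to convergence (|s − target| < 1e-12 nm in practice,
contract 1e-9 nm). No forces act along the coordinate — it is a
positional constraint, so the accumulated displacement telescopes to
exactly n·increment.

Increments follow the pacing rule of the reference protocol: the target
projection reaches the endpoint path length after two thirds of the
run, after which the constraint holds the endpoint while the remaining
steps relax (`clamp_at`). On the toy system increments are rescaled
from the path length; the atomistic reference increments
(1.28e-6 nm/step for four subunits, 1.89e-7/6.27e-7/9.24e-7 for
one/two/three) are recorded in the default config for provenance; the
implied total displacement (n_steps × increment) is logged rather than
asserting any derivation rule for the per-k values. Success verdicts
compare the mean RMSD over the final 5% of steps (a single end frame is
too noisy a reading at finite temperature) with 0.2 nm for opening and
0.23 nm for closing. Optional harmonic position restraints stand in for
the helical restraints used to prevent C-terminal unwinding during
closing; exact dihedral restraints are out of scope at bead resolution.

## The toy channel

`toysim.make_toy_channel` builds a C4-symmetric tetramer, two bead
helices per subunit (static outer TM1, mobile inner TM2, six beads
each, one CA pseudo-atom per bead-residue), with the TM2 C-terminal
(gate) bead at radius 0.35 nm when closed and 1.35 nm when open. The
closed/open backbone RMSD is ≈0.43 nm, deliberately on the same scale
as the 4 Å separation of the real channel states.

The energy (`CooperativeChannelEnergy`) is a dual-basin *morphing*
elastic network with explicitly cooperative subunits:

* each subunit carries a geometric openness order parameter
  o_u = (r_u − r_closed)/(r_open − r_closed), where r_u is the
  in-plane distance of its gate bead from the channel center;
* the subunit's intra-subunit contact network (cutoff 2.0 nm, spring
  800 kJ mol⁻¹ nm⁻²) has rest lengths linearly interpolated between
  the closed and open geometry with weight clip(o_u, 0, 1) — the chain
  is held stiffly around the interpolated geometry at every stage, and
  the identity morph exerts no spurious force on o itself;
* a quartic bistable potential B·o²(1−o)² (B = 500 kJ/mol, barrier
  B/16 ≈ 31 kJ/mol) with a per-subunit bias of
  double_well_bias/4 = 10 kJ/mol on the open well makes the fully
  closed channel the global minimum (the open channel sits
  40 kJ/mol higher in energy). The bias is deliberately larger than
  the open state's perpendicular-entropy advantage (the splayed
  geometry is floppier), so the closed *free-energy* well stays the
  deeper one — the designed "pore is intrinsically more stable
  closed" property;
* adjacent subunits couple ferroelastically, J/2·(o_u − o_v)² per ring
  pair with J = 85 kJ/mol; inter-subunit elastic contacts are
  restricted to geometry-preserving ones (rest-length change ≤
  0.05 nm between endpoints, including longer-range cross-bracing
  pairs at 400 kJ mol⁻¹ nm⁻²), because a contact that changes length a
  lot during opening would mechanically drag a neighbour along, which
  the iris-like motion of a real gate avoids;
* an azimuthal registration term keeps adjacent gate beads at right
  angles about the pore axis, suppressing a soft tangential swing of a
  splayed TM2 that would otherwise relax on longer timescales than the
  driven runs.

The barrier/coupling ratio is what makes gating cooperative by
construction: the openness pull of a single open neighbour (J per
interface) cannot overcome the quartic barrier slope, while two open
neighbours (2J) can. Driving one or two subunits therefore leaves the
rest closed; driving three recruits the fourth. This mirrors the
at-least-three-subunits cooperativity signature of the reference
analysis, and the parameter choices above were made analytically from
that force balance (stay-closed margin ≈ 57 kJ/mol per unit openness,
flip margin ≈ 28, robust to driven neighbours fluctuating around
o ≈ 0.9).

Dynamics are overdamped Langevin (Euler–Maruyama), unit reduced mass,
default dt = 0.002 ps, friction 50 ps⁻¹, 310 K (kT = 2.5775 kJ/mol
with k_B = 0.0083145 kJ mol⁻¹ K⁻¹, centralised in `constants`). The
step was chosen against the stability bound of the stiffest per-atom
spring aggregate; equilibrium thermal backbone RMSD in either basin is
≈ 0.06–0.09 nm, comfortably below the 0.2 nm success threshold. The
stationary distribution is exp(−U/kT) independent of the friction
constant, which is all the statistical tests rely on; no inertial or
solvent realism is attempted.

## Analytic landscapes and umbrella sampling

`AnalyticLandscape` is a sum of Gaussians (negative depths are barrier
bumps) plus harmonic confining walls; its Boltzmann density is known by
quadrature, making it an exact oracle. The bundled default has three
wells near s = 1.2, 5.4, 10.1 nm with the first (closed) well deepest
and barrier tops near 4 and 9 nm — the qualitative layout of the
published gating profile; the depths (20/14/10 kJ/mol wells, 5/7
kJ/mol bumps) are package defaults chosen for clearly resolved
desk-scale barriers, not published numbers.

Umbrella windows restrain the projection with k/2 (s−s0)². On the
analytic landscape, windows are drawn by rejection sampling against a
piecewise-constant grid envelope (i.i.d. samples; the envelope is
checked and a leak past the grid raises). On the toy channel, windows
are Brownian-dynamics runs under the bias, with the bias force obtained
by the chain rule through the fitted projection (neglecting the
rotation derivative, the standard small-correction approximation).
The first half of every window is discarded, mirroring the 50-of-100 ns
equilibration discard of the reference protocol (for i.i.d. draws this
only reduces the count but keeps one contract for both paths).

The reference force constants (1 kJ mol⁻¹ nm⁻² for 33 of 39 windows,
100 for six barrier windows) are recorded in the default config.
Desk-scale presets are stiffer: 30 kJ mol⁻¹ nm⁻² for the analytic
oracle and 2000 for the toy channel, chosen so that the biased
standard deviation sqrt(kT/k) stays within ~2 window spacings —
overlap that the reference system gets from long sampling must come
from the bias at desk scale. Both values live in config, with the
reference values, and the run manifest records what was used.

## WHAM and bootstrap

`wham.wham` is the standard self-consistent histogram method: pooled
histograms over a fixed bin grid (default 200 bins over the sampled
range), window biases evaluated at bin centers, window constants f_i
iterated until max |Δf| < 1e-7 kJ/mol (gauge f_0 = 0), then
F = −kT ln p with the minimum shifted to zero; unvisited bins are NaN
and adjacent windows without a shared occupied bin trigger an overlap
warning. Errors are whole-window bootstrap: every window's samples are
redrawn with replacement, WHAM re-solved on the same grid, replicates
aligned at their minima (WHAM fixes only relative free energies) and
the per-bin SD over 50 replicates reported. Where a coverage statement
is made, "the SE brackets the true error" means |F − U| ≤ 2·SE
(nominal ~95% normal coverage).

On the toy channel the PMF is hard to converge in the barrier region —
at fixed total projection the four subunit switches are individually
bistable, so a window seeded on the symmetric all-subunits-together
interpolation sits on four quartic hilltops at once and falls into a
random substate, ruining the histogram chaining. The packaged workflow
therefore seeds 49 windows from the *subunit-sequential* interpolation
path (`sequential_opening_path`), along which every intermediate is a
well-defined substate that the bias (1200 kJ mol⁻¹ nm⁻², stiff enough
that its curvature along a single subunit's flip direction exceeds the
quartic's negative curvature) holds in place; the f-iteration
tolerance is relaxed to 1e-5 kJ/mol there (far below the tens-of-
kJ/mol well-depth scale being read off). The measured open-minus-
closed well difference (≈ 20–45 kJ/mol across seeds) sits below the
bare 40 kJ/mol energy bias because the open basin's extra
perpendicular entropy partially offsets it; only the ordering (closed
deeper) is asserted.

## Pore profiling

`poreprof.pore_profile` is the classic largest-sphere search: at each
axial position the largest sphere centred in that plane touching no
atom (3-D distances, element hard-sphere radii C 0.185 / N 0.175 /
O 0.165 nm by default — a config artifact, not a claim) is found by
simulated-annealing Monte-Carlo seeded from the previous slab, followed
by a deterministic Nelder–Mead polish. The search is confined to a
lateral disc (default 2 nm); a slab whose optimum presses against the
bound has opened into bulk and either raises, truncates the profile, or
is merely flagged (`on_lost`), the last being appropriate when only a
constriction below the leak region is being read. The default axis is
the symmetry axis of the selection (the covariance eigenvector whose
eigenvalue is most separated from the other, degenerate pair). The
activation-gate diameter is twice the minimum radius within a z-window
defaulting to the intracellular half of the profile; backbone-only
selections are the default for crystal-structure profiles.

## Rotamer and distance metrics

chi1 is the N–CA–CB–gamma dihedral wrapped to (−180, 180]. The up
state is chi1 in [−72, −55]°, the down state [−185, −166]° interpreted
circularly ([−180, −166] ∪ [175, 180]); the strict classifier returns
`unassigned` outside both ranges and the state-fraction report excludes
unassigned frames from the two-state denominator while reporting their
share separately; a nearest-center mode (centers −63.5° and −175.5°)
is provided because published percentages imply a two-state readout.
The gate-opening distance metric is the Cα–Cα distance between
opposite subunits at a marker residue (T112 in the KcsA preset),
reported per diagonal pair and as their mean (the default, both are
emitted). Hydrogen bonds are geometric: donor–acceptor distance ≤
0.35 nm and H–D–A angle ≤ 30°, both configurable; no head-group
chemistry is attempted — callers supply donor/acceptor selections.

## Synthetic channel-state stand-ins

`toysim.synthetic_kcsa` builds idealised backbone tetramers for the
closed/intermediate/open states: ideal helix geometry for TM1, the
pore helix and TM2, schematic loops and filter strand, four chains,
residues 22–124 with the channel sequence motifs at the marker
positions (F103, T112, W113, F114, Q/R117). TM2 runs to a
bundle-crossing hinge at residue 104 and splays below it with the
state. These are **synthetic** structures, not the deposited crystal
structures: the TM2 gate radius is self-calibrated (bisection against
a direct on-axis enumeration oracle with the default radii) so the
gate constriction diameters equal the published backbone-derived
values (5.9 / 8.3 / 11.8 Å), and the C-terminal splay is calibrated so
the closed/open backbone-without-loops RMSD is 4 Å. Tests on these
models therefore validate the full preparation → selection →
measurement chain against known geometry; they do not re-measure the
deposited structures, and nothing beyond the calibrated quantities
should be read as channel realism.

## Problem sizes and determinism

Default desk-scale sizes: 48-bead toy channel, 3000-step ED runs
(drive phase 2000 steps), 39 umbrella windows × 1e4 kept samples on
the analytic oracle and 49 windows × ~300 kept projections (3000 BD
steps, thinned) on the toy channel, 50 bootstrap replicates, 0.025 nm
pore slabs with 250 annealing moves. All stochastic stages draw from
explicitly passed seeded generators; pipelines write a JSON manifest
(config snapshot, seed, version, SHA-256 of every output) and re-runs
with the same seed reproduce the CSVs byte for byte.

## Known limitations

* The toy channel's cooperativity is built in by the barrier/coupling
  force balance; it demonstrates that the driving and analysis
  machinery resolves such a mechanism, not that the real channel has
  these constants.
* The toy PMF along the collective coordinate is read only
  qualitatively (well ordering); mid-path windows carry metastable
  subunit substates and their absolute barrier heights are
  protocol-dependent.
* Backbone-only pore walls leak between helices above the gate; the
  profiler flags such slabs rather than inventing side-chain bulk.
* The Brownian propagator has no inertia, solvent structure or
  hydrodynamics; time constants are not comparable to molecular
  dynamics, only stationary statistics are.
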