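# gatekit

Analysis toolkit for ion-channel **activation gating**: build a
one-dimensional reaction coordinate between two channel conformations,
drive the transition along it by essential dynamics, map the free-energy
profile by umbrella sampling + WHAM with bootstrap errors, and quantify
gating with pore-radius profiles, chi1 rotamer statistics,
opposite-subunit distances and hydrogen-bond counts.

The shipped presets target the pore domain of the bacterial potassium
channel KcsA — a homotetramer whose four TM2 helices form the
intracellular activation gate — but every residue range, atom set,
radius and force constant is configuration, not code. A coarse-grained
toy tetramer with a cooperative dual-basin energy and analytic
triple-well landscapes with exactly known Boltzmann statistics make the
whole pipeline runnable (and testable against ground truth) on a laptop
in minutes.

## The method in brief

Given closed and open conformations with coordinates x_c, x_o
(backbone without loops, Kabsch-superposed), the covariance PCA of the
two-frame trajectory has exactly one non-zero eigenvalue; its
eigenvector **v** ∝ x_o − x_c is the reaction coordinate. A structure
projects to s = vᵀ(x − x_c) after superposition, so s = 0 is closed
and s = |x_o − x_c| is open.

*Essential dynamics*: each step performs one free dynamics update and
then corrects the positions along **v** so that s equals a target that
advances by a fixed increment δ per step — a positional constraint, no
biasing force. Driving a subset of subunits uses the chain-restricted
difference eigenvector, which is how gating cooperativity is probed
(on the toy channel at least three of the four subunits must be driven
before the gate opens).

*Umbrella sampling / WHAM*: windows restrain s with k/2 (s − s₀)²;
the weighted-histogram equations

    p(b) = Σᵢ hᵢ(b) / Σᵢ Nᵢ exp(−β(wᵢ(b) − fᵢ)),
    exp(−β fᵢ) = Σᵦ exp(−β wᵢ(b)) p(b)

are iterated to self-consistency and F(s) = −kT ln p(s), with
whole-window bootstrap standard errors.

*Pore geometry*: the classic largest-sphere search — at each axial
position the biggest sphere touching no atom, found by simulated
annealing plus a local polish — gives radius(z); twice the minimum in
the intracellular half is the activation-gate diameter.

## Worked example

```bash
gatekit demo --out demo --seed 1
```

runs the all-toy pipeline end to end. Abbreviated output:

```
[1/3] ED opening replicas ...
{
  "success_rate": 1.0,
  "final_rmsd_nm": [
    0.09138984525974916,
    0.09826016247435324
  ]
}
[2/3] umbrella/WHAM on the analytic landscape ...
  PMF RMSE vs exact landscape: 0.335 kJ/mol
[3/3] cooperativity scan ...
 k_subunits  increment_nm  path_length_nm  final_rmsd_nm  success  gate_metric_nm
          1      0.000629        0.838945       0.341734    False        0.411163
          2      0.001370        1.826218       0.261229    False        0.823186
          3      0.001883        2.510143       0.168163     True        1.094675
          4      0.002225        2.966479       0.095697     True        1.270294
```

Reading: both replicated 4-subunit drives reach the open state (final
backbone RMSD to the open endpoint below 1 Å, well under the 2 Å-scale
success threshold); the reconstructed free-energy profile matches the
exact triple-well landscape to a fraction of kT; and the per-k scan
shows the cooperativity signature — driving one or two subunits leaves
the gate near its closed radius (0.41/0.82 nm vs closed 0.35 nm) with
the RMSD stuck high, while three driven subunits recruit the fourth
and open the gate (1.09–1.27 nm, approaching the open 1.35 nm).

Library use mirrors the CLI:

```python
from gatekit import (make_toy_channel, build_difference_ev, project,
                     run_ed, EDProtocol)
from gatekit.toysim import toy_selection_spec
from gatekit.structio import resolve_selection

closed, open_, energy = make_toy_channel()
sel = toy_selection_spec()
cv = build_difference_ev(closed, open_, sel)
L = project(open_.coords, cv)          # path length, ~2.97 nm
protocol = EDProtocol(cv=cv, increment=L / 2000, n_steps=3000, clamp_at=L)
result = run_ed(energy, closed, protocol, open_,
                resolve_selection(closed, sel), seed=1)
print(result.success, result.final_rmsd)   # True, ~0.07 nm
```

Crystal structures go through the same machinery via
`gatekit prepare`, `gatekit build-ev` and `gatekit pore` (PDB in,
residues 29–118 kept, backbone-without-loops selections from the
config). The package also generates *synthetic* stand-in tetramers for
the closed/intermediate/open channel states
(`gatekit.toysim.synthetic_kcsa`), self-calibrated to the published
gate diameters (5.9 / 8.3 / 11.8 Å) and closed–open backbone RMSD
(4 Å), which exercise that chain end to end without redistributing
deposited coordinates.

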