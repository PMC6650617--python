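# surfbind

Post-simulation analysis of surfactant binding to globular proteins
(serum-albumin-type systems), built as an importable Python library.
Given docked poses or molecular-dynamics trajectories of a
protein–amphiphile complex — or synthetic stand-ins with known ground
truth — it computes:

- **Binding-site contacts**: protein residues with a heavy atom within a
  cutoff (default 3.5 Å) of the ligand.
- **Hydrogen bonds**: geometric detection (donor–acceptor ≤ 3.5 Å,
  H–D–A angle ≤ 30°, or distance-only for hydrogen-free poses),
  regular/bifurcated classification (a bifurcated interaction counts as
  two bonds: total = 2·n_bif + n_reg), water-mediated
  protein–water–ligand bridges, and per-frame existence series h(t).
- **Hydrogen-bond kinetics**: the existence autocorrelation
  C(t) = (⟨h(0)h(t)⟩ − ⟨h⟩²)/(⟨h⟩(1 − ⟨h⟩)), multi-exponential fits and
  the relaxation time τ_R = Σ aᵢτᵢ, continuous-segment lifetimes,
  breaking/reforming rate constants from −dC/dt = k·C − k′·N, and the
  Eyring free energy of bond breaking ΔG = RT·ln(k_B·T·τ_R/h).
- **Nonbonded energy decomposition**: pairwise Coulomb (plain cutoff or
  reaction-field-zero, f·qᵢqⱼ(1/r + r²/2r_c³ − 3/2r_c)) and GROMOS-form
  Lennard-Jones (C12/r¹² − C6/r⁶, geometric combination) energies between
  named atom groups (head/α/tail vs surrounding), with block-averaged
  window statistics, plus partial-charge group sums and charge-transfer
  bookkeeping.
- **LIE binding free energies**:
  ΔG_bind = β⟨ΔU_el⟩ + α⟨ΔU_vdw⟩ + γ, OLS calibration of (β, α[, γ]),
  K_D conversion ΔG = RT·ln K_D, literature averaging and mean absolute
  error.
- **Structural metrics**: Kabsch superposition, per-frame RMSD, and
  per-residue RMSF.

A first-class synthetic-data module generates inputs with analytic
truth — telegraph (two-state Markov) bond series, random point-charge/LJ
complexes, LIE training tables, Gaussian-jittered trajectories — so every
stage is validated without a docking engine, MD package, or
electronic-structure code.

## Worked example

```python
import surfbind as sb

spec = sb.TelegraphSpec(k_off=0.05, k_on=0.05, dt=0.1, n_steps=500_000, seed=1)
series = sb.HBondSeries.from_array(sb.gen_telegraph_series(spec), spec.dt)
kin = sb.analyze_kinetics(series, temperature=298.0)
print(kin.lifetime, kin.relaxation_time, kin.free_energy)
```

Running `python examples/hbond_kinetics.py` prints:

```
occupancy          : 0.499   (truth 0.500)
lifetime           :   19.75 ps (truth 1/k_off = 20)
relaxation time    :    9.69 ps (truth 1/(k_on+k_off) = 10)
k_break, k_reform  : 0.0517, 0.0521 ps^-1
Eyring dG(break)   :   10.15 kJ/mol
```

The lifetime is the mean duration of completed bond-on segments (truth
1/k_off = 20 ps), the relaxation time is the integral of the fitted
autocorrelation decay (truth 1/(k_on + k_off) = 10 ps), and the free
energy converts the relaxation time into an activation barrier for bond
breaking at 298 K. The other scripts under `examples/` walk through
contacts/bridges, energy decomposition, LIE calibration, and RMSD/RMSF
the same way, each printing its analytic truth next to the computed
number.

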