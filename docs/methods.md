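# Methods

This note records the models, conventions, and numerical choices behind
surfbind, and what its synthetic-data validation does and does not show.

## System model and units

A `MolecularSystem` is an ordered atom table (PDB serial, name, element,
residue, chain) carrying per-atom force-field parameters: partial charge
in electron units and GROMOS-style Lennard-Jones coefficients C6
(kJ mol⁻¹ nm⁶) and C12 (kJ mol⁻¹ nm¹²). Coordinates are stored in
ångströms (PDB native) throughout; energies are in kJ/mol; the
electrostatics cutoff follows force-field convention in nanometres. The
single Å→nm conversion lives in the energy module. Atom indexing is
0-based internally, with PDB serials preserved for reporting.

Every ligand atom carries one of the closed group labels
{head, alpha, tail}; everything else is protein/water/ion/other by
residue name (water set {HOH, SOL, WAT, TIP3, SPC}, configurable). The
α-methylene group — the first tail carbon adjacent to the polar head —
is labelled `alpha` and counted **with the tail** in charge sums by
default; `group_charge_sums(..., alpha_in_head=True)` switches to the
head-inclusive convention. The net charge is head + (α + tail) under
either convention, and the labelling itself never changes.

Hydrogen-bond donors are (heavy atom, hydrogen) pairs; for
heavy-atom-only structures (docking poses with hydrogens stripped) the
donor list can be supplied without hydrogens and detection falls back to
a distance-only criterion, flagged in the output (`angle = None`).

## Contacts and hydrogen bonds

A contact is a protein residue with ≥ 1 heavy atom within the contact
cutoff (default 3.5 Å) of ≥ 1 ligand heavy atom; the minimum distance
and closest ligand atom are reported. Hydrogen bonds require
donor–acceptor distance ≤ 3.5 Å and H–D–A angle ≤ 30°; only the
distance criterion is part of the published protocol, the angle is the
convention of the MD package family the energy model follows, and both
distance-only and angular modes are provided. A bond is *bifurcated*
when its donor hydrogen (donor heavy atom in distance-only mode)
satisfies the criteria with ≥ 2 acceptors in the same frame, or its
acceptor with ≥ 2 donors; each bifurcated interaction contributes two
bonds to totals (total = 2b + r). Classification is per frame; report
tables evaluate it on frame 0, the docked-pose snapshot. Minimum-image
distances are used whenever a frame carries an orthorhombic box.

A water bridge is one water simultaneously hydrogen-bonded (as donor or
acceptor) to ≥ 1 protein atom and ≥ 1 ligand atom. Water counts near a
group use a 0.35 nm cutoff; a water counts if any of its atoms is within
the cutoff of any group atom.

Bond-length distributions are binned at 0.1 Å for display; the mean is
always computed from the raw pooled samples, not the bins.

## Hydrogen-bond kinetics

The bond-existence function h(t) is pooled over all bonds of a complex
and all time origins. Three autocorrelation estimators are provided:

- fluctuation (default): C(t) = (⟨h(0)h(t)⟩ − ⟨h⟩²)/(⟨h⟩(1 − ⟨h⟩)),
  which decays 1 → 0 and fits cleanly with exponentials;
- intermittent: ⟨h(0)h(t)⟩/⟨h⟩, which plateaus at ⟨h⟩;
- continuous: h is zeroed after the first break (computed exactly from
  run lengths).

C is fitted with Σ aᵢ·exp(−t/τᵢ), aᵢ ≥ 0, Σaᵢ = 1 (amplitudes on the
simplex via a softmax parametrization, Levenberg–Marquardt least
squares); the relaxation time is the analytic integral τ_R = Σ aᵢτᵢ. The
default fit window runs to the first lag where C < 0.03 or one third of
the lag grid, whichever is smaller — beyond that, tail noise dominates
the residuals. Constant series (never or always bonded) make the
fluctuation normalization undefined and raise an error naming the bond.

The lifetime τ_HB is, by default, the mean duration of *completed*
continuous on-segments (segments touching either series boundary are
censored and discarded); the integral of the continuous autocorrelation
is exposed as a flagged alternative, since published "lifetime" columns
do not state which estimator was used.

Breaking/reforming rates (k, k′) solve −dC/dt = k·C − k′·N by linear
least squares, with C the intermittent correlation and
N(t) = ⟨h(0)(1 − h(t))⟩/⟨h⟩ the crossing correlation. This N treats
every originally bonded pair as still available to re-form — the
appropriate contract for a ligand held in a binding site, where the
partners cannot diffuse apart; no additional distance gate is applied.
The rate fit is restricted to lags below 5·τ_R because the equilibrium
plateau (dC/dt ≈ 0) otherwise dominates the normal equations and shrinks
both rates. Rate extraction is secondary to the relaxation-time fit.

The free energy of breaking a bond uses the Eyring transition-state form
applied to the relaxation time,

    ΔG = R·T·ln(k_B·T·τ_R / h),

with CODATA k_B = 1.380649×10⁻²³ J/K, h = 6.62607015×10⁻³⁴ J·s and
R = 8.314 J mol⁻¹ K⁻¹. This convention reproduces all six published
relaxation-time → free-energy pairs (direct and water-mediated bonds at
298 K) to within 0.05 kJ/mol, which is shipped as a test; τ_R = h/(k_B·T)
gives exactly zero.

## Nonbonded energies

Pair energies: Coulomb f·qᵢqⱼ/r with f = 138.935458 kJ mol⁻¹ nm e⁻²,
either plainly truncated at r_c or in reaction-field-zero form
f·qᵢqⱼ(1/r + r²/(2r_c³) − 3/(2r_c)), which vanishes (with zero slope) at
the cutoff; Lennard-Jones C12/r¹² − C6/r⁶ with geometric combination
C6 = √(c6ᵢc6ⱼ), C12 = √(c12ᵢc12ⱼ), truncated at the same cutoff. The
defaults — r_c = 1.0 nm, reaction-field-zero — match decomposable reruns
of mesh-Ewald trajectories; mesh-Ewald itself is out of scope because its
energy is not pairwise decomposable. No bonded or intra-group terms are
computed, and no 1–4 scaling is needed since intra-ligand pairs are never
summed.

Group energies sum all cross pairs of two disjoint index sets
("surrounding" = protein + water, plus ions by default with a flag to
exclude them, since published ligand-surrounding averages do not state
the ion treatment). Time series report the analysis-window mean and a
block-averaged standard error (5 contiguous blocks). Energy additivity
over any disjoint ligand partition and exact agreement (≤ 1e-10
relative) with a brute-force double-loop oracle are enforced by tests.

Head-charge/energy scaling uses ordinary least squares on
(|q_head|, E_coulomb) points with the Pearson correlation; for
zwitterionic heads the |q| feature is the mean of the absolute charges
of the two oppositely charged sub-heads.

## LIE free energies

ΔG_bind = β·(⟨U_el⟩_b − ⟨U_el⟩_f) + α·(⟨U_vdw⟩_b − ⟨U_vdw⟩_f) + γ. The
published calibration for the protein–surfactant training set
(β, α, γ) = (0.16, 0.5, 0) ships as the default model; calibration is
ordinary least squares with γ fixed at zero unless explicitly freed (no
robust-regression variant is offered because none was published).
Prediction uncertainty is propagated linearly,
σ² = β²·var(ΔU_el) + α²·var(ΔU_vdw), with each difference variance the
sum of the squared block-averaged standard errors of its two ensemble
averages; the published error model is unstated, so this propagation is
the package's own documented choice. K_D converts via ΔG = RT·ln K_D
(K_D in mol/L, so favourable binding means K_D < 1 M and negative ΔG);
literature magnitudes are averaged arithmetically and reported to two
decimals, and model quality is summarized as the mean absolute error
over complexes.

## Structural metrics

Superposition is weighted Kabsch (SVD with proper-rotation correction,
via scipy's rotation alignment); degenerate inputs (< 3 atoms or
collinear sets) are rejected. RMSD is measured after superposition on
the selection ("backbone" = atom names N, CA, C, O of protein residues).
RMSF is per-atom √⟨|rᵢ(t) − ⟨rᵢ⟩|²⟩ after superposing every frame to the
reference frame (superposition before RMSF is the default and
toggleable — without it, drift is conflated with fluctuation), averaged
within residues. Whether a ligand RMSD should align on protein or ligand
atoms is left to the caller via the selection argument.

## Synthetic data: what it emulates, and what it does not

- **Telegraph series** emulate two-state bond dynamics with prescribed
  breaking/reforming rates. The chain is sampled at interval dt with
  per-step switch probability 1 − exp(−k·dt) (exact, not the first-order
  k·dt, so coarse sampling stays unbiased); dwell segments are drawn
  geometrically, which is distributionally identical to stepping the
  chain. The sampled mean on-dwell is dt/(1 − exp(−k_off·dt)), a
  +k_off·dt/2 relative bias (≈ 0.25% at the default k_off·dt = 0.005).
  At 10⁶ steps the segment-mean lifetime estimator has ≈ 2% (1σ)
  sampling error (≈ 2.5×10³ completed segments) and the fitted
  relaxation rate < 1%; the recovery tests run at the package's default
  seed stream and their tolerances (2% and 5%) should be read against
  those precisions.
- **Toy complexes** are random point clouds with a 0.8 Å minimum
  separation, uniform charges/LJ coefficients in realistic carbon-like
  ranges, a ligand split into head/tail halves, and rigid 3-site waters.
  Waters carry fixed SPC-like charges and oxygen LJ parameters so that
  bridging chemistry is sensible; they are the only donors. Toy systems
  exercise geometry and energy kernels exactly (against brute-force
  oracles) but are not physical conformations — passing these tests
  shows the *operators* are correct, not that any force field is
  reproduced.
- **LIE training tables** draw energy differences uniformly
  (ΔU_el ∈ [−50, 10], ΔU_vdw ∈ [−70, −5] kJ/mol, van der Waals more
  favourable bound as observed for amphiphiles) and add Gaussian noise
  to the linear response. Noiseless recovery is exact by linear algebra;
  at noise 1 kJ/mol and n = 50 the coefficient standard errors are
  ≈ 0.01.
- **Jittered trajectories** add i.i.d. Gaussian noise (σ per axis) to a
  reference structure, so the per-atom fluctuation is exactly σ√3.
  Fitting the 6 rigid-body parameters during superposition absorbs
  6 of the 3N coordinate degrees of freedom, depressing measured
  RMSD/RMSF by roughly a factor √(1 − 2/N); recovery tests use N ≈ 100
  atoms, where the depression is ≈ 1%. Real MD fluctuations are
  correlated in time and anisotropic; these fixtures validate the
  estimator algebra only.

All generators are deterministic under a fixed seed; pipeline stages
derive sub-seeds by hashing the stage name with the global seed, so
adding a stage does not shift the streams of the others.

Problem sizes in the shipped tests and the acceptance script (10⁶
telegraph steps, 100-seed toy-complex sweeps, 2000-frame jitter
trajectories, 50-ligand training sets) were chosen so each statistical
check resolves its tolerance comfortably while the whole suite stays in
the seconds-to-minutes range.

## Known limitations

- Mesh-Ewald/PME electrostatics, polarizable models, bonded terms, and
  cell-list neighbor searching are not implemented; energy sums are
  dense vectorized O(N²), ample at binding-site scale.
- Cation–π, salt bridges and π-stacking are not detected.
- GROMACS binary trajectory/topology formats, PDBQT, and mmCIF are not
  read; structures come from (multi-model) PDB plus TSV parameter
  tables.
- The kinetics free energy adopts the Eyring-on-τ_R convention because
  it reproduces the published values exactly; a genuine
  equilibrium-constant formulation (K = ⟨h⟩/(1 − ⟨h⟩)) would need
  occupancy data that printed tables do not provide.
- Whether a published "lifetime" is a segment mean or a reciprocal rate
  is unstated; both estimators are exposed and the default is the
  segment mean.
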