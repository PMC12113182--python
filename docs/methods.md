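# Methods

This note documents the models and numerical choices behind `poreramp`: the
analysis stages, the surrogate trajectory generator that stands in for
coarse-grained MD, and what passing tests do and do not establish.

## System model and units

The membrane is a Martini-mapped DPPC bilayer: 12 beads per lipid — choline
NC3 (+1 e), phosphate PO4 (−1 e), glycerols GL1/GL2, and two four-bead
tails C1A–C4A / C1B–C4B — with single-bead Na⁺/Cl⁻ ions and four-to-one CG
water beads.  The Martini partial-charge magnitudes for the headgroup are
taken as ±1 e and recorded as a package constant (`BEAD_CHARGES`).
Coordinates are nm, times ns, charges e, forces kJ/mol/nm, fields V/nm,
pressures bar; conversions happen only at I/O boundaries.  Internally beads
are 0-based contiguous arrays; GRO's 1-based wrapping serials exist only in
the I/O layer.

Leaflets are assigned from the sign of each lipid's PO4 z offset from the
per-frame membrane midplane.  The midplane is found wrap-aware (circular
mean of PO4 z over the periodic box) and the offsets are re-centred on
their median, so a membrane drifting through the periodic boundary is still
split correctly; a zero-spread configuration raises a "monolayer or
collapsed membrane" error rather than guessing.

## Field protocol

E(t) ramps linearly from 0 to the peak over `rise_time`, holds the peak,
and optionally falls linearly to 0.  The plateau is open-ended by default
because the constant phase in the emulated experiments lasts until pore
formation; the generator concretises the plateau length when a pore appears
(or at the 50 ns plateau cap).  `field_at` evaluates the plateau branch for
t ≥ rise_time, so E(rise_time) equals the peak *exactly* (no floating-point
ramp arithmetic at the boundary).  Replicate seeds are derived per
condition from `(base_seed, peak, rise, replicate)` through a
`SeedSequence`, so adding or removing conditions never perturbs the
other conditions' random streams.

## Surrogate trajectory generator

The generator is an emulator, not an MD engine.  It manufactures
trajectories with the causal structure the analyses probe —
ramp → deformation → tension → pore hazard — and makes no claim of physical
accuracy; parameters are chosen once so that the qualitative orderings hold
robustly, not to reproduce any measured numbers.

Per output step (default cadence 0.1 ns, matching the typical coordinate
output of CG electroporation runs):

1. **Tilt field.**  Each ~1 nm² grid cell carries a tilt angle that relaxes
   exponentially (timescale `tilt_relax_tau` = 0.3 ns, the middle of the
   0.1–0.5 ns headgroup rotational range) toward an equilibrium tilt
   arctan(A_eq·|∇u|), plus Gaussian noise with stationary SD
   `thermal_noise_sigma`.  `u` is a fixed random sum of low-wavevector
   Fourier modes normalised to unit RMS slope, so the target amplitude A_eq
   fully controls the tilt scale.
2. **Two-timescale field response.**  A_eq has a fast alignment part,
   `undulation_amp0 · exp(−align_coupling·E²)` — a stronger instantaneous
   field pulls normals toward Z — plus a slow deformation part,
   `deformation_amp · D(t)`, where D relaxes toward 1 under field with
   timescale `deformation_tau` = 15 ns.  The slow mode is what
   differentiates ramps: with a 0.3 ns tilt timescale alone the tilt would
   track E(t) adiabatically and 1 ns and 30 ns ramps would end their ramps
   in identical states; the accumulating deformation encodes the mechanism
   that slow ramps leave time for the membrane to deform before the peak.
3. **Posing.**  The membrane surface is the height map A_inst·u with A_inst
   chosen so the posed mean tilt matches the state's mean tilt; whole
   lipids ride the surface vertically.  Waters and ions keep their build
   positions (no diffusion — the analyses never use solvent dynamics
   outside the pore).
4. **Tension and pressure.**  γ(t) = `baseline_tension` +
   `deformation_tension_coupling` · ⟨tilt²⟩ (mN/m, tilt in degrees).  The
   emitted pressure triple inverts the tension formula exactly with
   P_zz = 1 bar and P_xx = P_yy (the simplest triple consistent with
   semi-isotropic pressure coupling), so the mechanics stage can round-trip
   γ(t) to machine precision.
5. **Forces.**  Per bead, the Coulomb force has magnitude |q|·E·96.485
   kJ/mol/nm, directed along the local surface normal: F_z ∝ cos θ_local
   and an in-plane part ∝ sin θ_local along a fixed random direction per
   trajectory (the symmetry-breaking of the dominant deformation mode —
   without it the XY vector sum over a symmetric undulation cancels
   identically), plus Gaussian noise.  Deformation therefore weakens the
   summed Z force and grows the XY vector sum.
6. **Pore nucleation.**  A single pore per trajectory nucleates as a
   Bernoulli event per step with hazard λ = `nucleation_rate0` ·
   exp(`field_susceptibility`·E² − `tension_penalty`·γ): the E² term because
   electroporation energetics scale with the square of the transmembrane
   voltage, the −γ term so that the higher tension reached during long
   ramps suppresses nucleation.  On nucleation the nearest water beads are
   re-posed into a transmembrane column (bead spacing 0.4 nm) and lipids
   are displaced radially; the radius grows at `pore_growth_rate` to
   `pore_radius_cap`.  Under a falling edge, a pore smaller than
   `recovery_radius_threshold` at fall onset reseals during the fall;
   larger (box-scale) pores persist.

Generation is bit-reproducible for fixed (system, protocol, params, seed).
Runs always cover the full ramp (so end-of-ramp analyses are defined), end
`post_pore` = 3 ns after nucleation or at a 50 ns plateau cap, and with a
falling edge hold the plateau `fall_delay` = 4 ns past nucleation before
applying the edge — long enough at the default growth rate for the pore to
reach the cap, matching the persistent box-scale pores of the emulated
falling-edge experiments.

Default hazard constants (`nucleation_rate0` 2×10⁻⁴/ns,
`field_susceptibility` 360 (V/nm)⁻², `tension_penalty` 0.1 (mN/m)⁻¹) put
pore times at ~2 ns for a 1 ns ramp and ~32 ns for a 30 ns ramp at
0.16 V/nm — the same qualitative spread, at desk scale, as the emulated
experiments.

**What the surrogate does not emulate:** thermostats/barostats, nonbonded
interactions, solvent dynamics, lipid lateral diffusion and flip-flop,
multi-pore competition, and any absolute magnitudes (pore times, tensions,
forces).  Tests passing on surrogate data therefore validate the *analysis
implementations* and the *orderings designed into the generator*, not the
physics of real membranes.

## Analysis choices

- **Local normal.**  The per-subregion fitting method is a total
  least-squares plane (SVD) on the leaflet's PO4 beads, with coordinates
  unwrapped about the cell centre (minimum image).  At ~0.58 nm²/lipid a
  1 nm² cell holds <2 lipids, so cells with fewer than three beads gain
  neighbours within a 0.5 nm halo; still-degenerate cells are MISSING (NaN)
  and excluded from both the numerator and denominator of the fraction.
  Normals are oriented with n_z ≥ 0; tilt = arccos(n_z) ∈ [0°, 90°].
- **Grid geometry.**  n_x = floor(L_x / 1 nm) cells tile the box exactly
  (effective width L_x/n_x ≈ 1.018 nm for the 17.3 nm box), avoiding a
  remainder strip; the grid is periodic in both directions.
- **Thresholding.**  "Below 45°" is a strict inequality; a cell at exactly
  45° counts as not-below.  Both leaflets are analysed and averaged by
  default (a single mid-surface would hide leaflet asymmetry near pores);
  single-leaflet analysis is available.
- **Water-chain detection.**  Cutoff 0.6 nm — just above the CG water
  contact distance (~0.47 nm), so a contiguous column connects while
  reservoir-to-reservoir contact across an intact bilayer cannot occur.
  The hydrophobic slab is the region between the mean leaflet PO4 planes
  shrunk by a 0.3 nm margin (headgroup-bound waters must not short-circuit
  it).  Connectivity uses the periodic minimum image in XY only: a chain
  through the Z-periodic solvent reservoir is not transmembrane.  A
  3-frame persistence filter (0.3 ns at the default cadence) rejects
  transient flickers; these operational constants are declared, not
  inferred, and all are exposed in the run config.
- **Pore timing conventions.**  Reported both as total time from t = 0
  (ramp included) and as time from the field peak; the post-peak value is
  negative when the pore forms during the ramp (possible at high peaks with
  long ramps) and is reported as-is rather than clamped.
- **Pore size.**  Equivalent radius √(A/π) of the largest XY-connected
  patch (periodic connectivity, union-find across the seams) of 0.5 nm
  cells inside the slab containing water but no tail beads.  Resolution-
  limited to ~±0.25 nm.
- **Surface tension.**  The lateral-difference variant of the tension
  formula, γ = ½L_z·P_zz − ½(P_xx − P_yy), found in parts of the
  literature, is nonzero for an isotropic fluid, so the package defaults to
  the standard mechanical form γ = (L_z/2)[P_zz − (P_xx+P_yy)/2] and keeps
  the literal variant behind `literal_form=True` for fidelity experiments.
  Output is mN/m; the bar·nm value is a fixed factor of 10 away.
- **Window statistics.**  Mean and *population* SD (the convention is
  declared here; sample SD would differ by √(n/(n−1))) over samples with
  |t − t_pore| ≤ 0.5 ns and t ≥ rise_time, i.e. a 1 ns window centred on
  the pore moment excluding the ramp.
- **Force decomposition.**  The summed signed Z force over a full
  zwitterionic membrane cancels exactly (+NC3 against −PO4 under a uniform
  field), so the pipeline's default bead selection for the reported split
  is the choline (NC3) beads; other selections (headgroups, all lipid
  beads, all charged beads) are available.  The decomposition itself is
  agnostic to whether the per-bead forces are field-only or include
  intramembrane contributions.

## Pipeline

`generate` writes, per grid condition and seed, a multi-frame GRO
trajectory, the pressure series, the per-frame force component sums over
the configured bead selection (per-bead force trajectories stay in memory;
writing them as text would dominate runtime for no analysis benefit), the
concretised protocol, and a manifest.  `analyze` re-reads only those
artifacts — it never consults generator internals, so pore times come from
chain detection, not from the generator's nucleation record — and emits one
row per run plus per-condition means ± SD.  `report` renders the rise-time
trends in plain text.  The full chain is deterministic: identical config →
byte-identical tables.

Problem sizes: the default configuration is the full 90-run production
grid on the 1024-lipid system; the smoke configuration (one peak, rises
{1, 30} ns, three seeds, 128 lipids in a 6.2 × 6.2 × 12.5 nm box,
2600 waters, 30+30 ions, 0.25 ns cadence) is the package's reduced study
system, chosen as the smallest membrane that keeps ≥ 6 grid cells per side
and a realistic area per lipid (~0.60 nm²) while the end-to-end chain runs
in about a minute.

## Known limitations

- The surrogate's membrane surface is a low-mode height field; it cannot
  produce overhangs, thickness fluctuations, or independent leaflet
  undulations, so leaflet-asymmetric observables are trivial on surrogate
  data.
- Plane-fit tilt underestimates the analytic surface tilt when the cell
  size approaches the undulation wavelength; the 2° RMS agreement is
  established for wavelengths ≥ L/2 on the production box.
- `read_gro` accepts only the bead vocabulary of this system (DPPC/W/ION);
  arbitrary topologies are out of scope, as are binary trajectory formats
  (bring XTC/TRR through a trajectory library and export GRO).
- Pore radius is meaningful only up to the box scale and the 0.5 nm grid;
  sub-nm pores near the detection threshold are noisy.
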