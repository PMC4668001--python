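# Methods

This note defines the quantities the package computes, the conventions it
fixes, and how the synthetic test system is calibrated. Units are
Angstrom, picosecond and kcal/mol throughout; kB = 0.0019872041
kcal/mol/K and the default temperature is 300 K (kT ≈ 0.596 kcal/mol).

## Geometric descriptors

**Cα pair distances.** Seven pairs track the detachment of the BC-CT from
the hydrophobic core, ordered from the hinge outward: F24–L15, F25–L15,
Y26–V12, T27–V12, P28–G8, L29–G8, T30–G8. Each series is the Euclidean
distance between the two Cα atoms, per frame. Selections resolve on
chain, residue number and atom name and must be unique; ambiguous or
empty selections are errors, not warnings.

**Aromatic contacts.** For the aromatic residues F24 and Y26 the contact
distance to a partner residue is the minimum, over the partner's
side-chain carbons, of the distance to the centroid of the six ring
carbons (CG, CD1, CD2, CE1, CE2, CZ). Tracked contacts: F24/L15, Y26/I2
(A chain), Y26/L11, Y26/V12.

**Core hydration.** Water oxygens within 9 Å of the L15 Cγ are counted
per frame (boundary inclusive). In crystal structures that sphere already
contains 9 waters that do not contact the core, so the corrected count is
max(raw − 9, 0); a positive corrected count means water has actually
entered the core. On synthetic trajectories the generator's counts
exclude those outer waters but include the 2–3 residual waters a closed
core retains, so there the baseline is the residual allowance (4) instead
of 9; both paths expose the same `WaterCountSeries` interface.

**RMSD** uses quaternion (QCP) superposition with centering, reference
frame 0 by default.

## State classification

Frames are labelled from one indicator distance, Y26–V12 by default:

- closed: d < θ_open
- open: θ_open ≤ d < θ_wide
- wide_open: d ≥ θ_wide

Intervals are half-open; a frame exactly at a threshold belongs to the
more open state. Defaults are 8.7 / 10.7 Å for Y26–V12 and 9.5 / 15 Å
for P28–G8. The wide-open boundary is fixed configuration; the open
boundary can instead be **calibrated from water entry**: distances are
binned at 0.1 Å, a bin is "wet" when at least half of its frames have a
positive corrected water count, and θ_open is the left edge of the
smallest sampled bin that is wet together with every sampled bin above
it. When the data cannot support this (no wet bins, or no dry bins) the
published default is returned with a warning.

Occupancy tables report the fraction of frames per state with binomial
standard errors. Because consecutive frames are correlated, the error
bars can use an effective sample size instead of the frame count: ESS =
n/τ with τ the integrated autocorrelation time from Geyer's
initial-positive-sequence truncation, taken conservatively as the
smallest ESS over the three state-indicator series.

## Potentials of mean force

For each pair distance a probability density is histogrammed on 0.2 Å
bins (range = sampled extent padded by one bin) and inverted:

W(r) = −kT ln(ρ(r)/ρ0),

with ρ0 the modal density, so min W = 0. Bins that were never sampled
carry no information and stay masked; they are never assigned a large
placeholder value. Profiles from different pairs are compared after
aligning each minimum to position 0 (ties resolve to the leftmost
minimum, with a warning). The scalar readout `opening_energy(profile, Δ)`
interpolates W at Δ Å past the minimum and refuses to extrapolate past
the contiguously sampled window around the minimum ("insufficient
sampling"). T30–G8 moves almost freely and is excluded from the PMF set
by default.

The zipper signature is that the opening energy at a fixed displacement
is non-decreasing from L29–G8 toward the hinge pair F24–L15: outer
residues detach cheaply, inner ones do not.

## Hinge-breaking restraint

The bias is half-harmonic and repulsive only:

U(r) = ½ k (r − r0)² for r < r0, 0 otherwise,

with k = 30 kcal/mol/Å² and r0 = (closed-state mean distance) + 9.8 Å,
applied to F24–L15 and P28–G8. The protocol runs 200 ps biased, then
releases the restraint and continues freely (default 30 ns). On the
wild-type landscape the BC-CT re-closes after release; on the F24E-like
landscape, whose hinge minimum is removed, it stays wide-open. The bias
phase uses a smaller integration step because the added harmonic
curvature tightens the stability bound of the integrator.

## Synthetic zipper landscape

The surrogate evolves the seven pair distances directly (there are no
Cartesian atoms) under overdamped Langevin dynamics,

dx = −(1/γ) ∇U dt + √(2kT dt/γ) ξ,

with γ = 5 ps⁻¹, dt = 0.1 ps (0.02 ps under bias) and one recorded frame
per 10 ps. Each coordinate moves on a log-sum-of-Gaussians multi-well
potential (well centers/widths/depths per pair); neighbouring coordinates
are coupled through smooth open/closed indicator functions with strength
1.2 kcal/mol so that an outer residue opening lowers the cost of its
inner neighbour opening — the zipper. A validator rejects landscapes
whose escape barriers do not decrease from the hinge outward. Water
counts come from a gated immigration–death process: a residual component
(mean 2.5, cap 4) is always active, and an entry component switches on
while the Y26–V12 gate exceeds 8.7 Å, up to a capacity of 12.

**Calibration.** Well parameters were fixed against the model's *exact*
stationary distribution, computed by quadrature of the nearest-neighbour
transfer operator (`stationary_marginals`, `threshold_occupancies`), not
against sampled trajectories: the WT preset is solved to closed / open /
wide-open occupancies of 0.64 / 0.31 / 0.05 on the 8.7 / 10.7 Å
thresholds, closed-state means sit inside the tabulated closed-state
bands, and the exact opening energies at +1.0 Å are strictly increasing
toward the hinge with gaps ≥ 0.13 kcal/mol so that sampled estimates
(whose noise is dominated by the ~slope × bin-width quantisation of the
minimum bin) preserve the ordering reliably at 2 × 10⁵ frames. Presets
`Y26G` (gate well flattened; wide-open dominant) and `F24E` (hinge
minimum removed; stays open) modify single coordinates.

The generator also writes small synthetic PDB files: a toy multi-model
structure and a single-model reference structure whose Cα and ring
geometry reproduce the tabulated crystal distances exactly, built from
two-sphere intersection constructions. These exercise the full
parse/select/measure path in tests without shipping third-party data.

## Determinism and problem sizes

All stochastic components consume explicit integer seeds (internally
reduced mod 2³¹); identical seeds give byte-identical report files. The
default run length of 2 × 10⁴ frames (200 ns at the surrogate's frame
interval) keeps a full pipeline run in seconds; the zipper-ordering
check uses 2 × 10⁵ frames per seed as noted above.

## Limitations

- The surrogate is a phenomenological landscape model: its kinetics
  (friction, dwell times, water rates) are chosen for statistical
  convenience, not fitted to molecular dynamics.
- The restraint protocol biases the landscape coordinates directly; bias
  and free durations are configuration, not physical kinetics.
- The water-entry calibration assumes a monotone wetting transition along
  the indicator distance; landscapes violating that assumption trigger
  the published-default fallback.
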