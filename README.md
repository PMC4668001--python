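# bcct

Analysis toolkit for the opening of the insulin B-chain C-terminal segment
(BC-CT), bundled with a synthetic "zipper-landscape" generator that serves
as its test bed.

The BC-CT (residues G20–T30 of the B chain) detaches from the hydrophobic
core of insulin when the hormone activates; the detachment propagates
residue by residue from the C terminus toward the hinge residue F24, like
a zipper. This package implements the standard trajectory analyses for
that process — Cα pair distances, aromatic core contacts, core hydration,
three-state classification, Boltzmann-inversion free-energy profiles and a
half-harmonic hinge-breaking restraint protocol — and a self-contained
Langevin surrogate that reproduces the zipper phenomenology so everything
can be exercised and validated without molecular-dynamics infrastructure.

## Quick start

```bash
# full pipeline on the bundled wild-type-like landscape
bcct report --preset WT --n-frames 20000 --seed 1 --out wt_report

# compare presets (occupancy table, one row per preset)
bcct report --compare WT,Y26G --n-frames 20000 --seed 1 --out cmp

# hinge-breaking protocol: 200 ps bias, then free relaxation
bcct restraint --preset WT --seed 1 --out hinge.csv
```

Or from Python:

```python
from bcct import RunConfig, run_pipeline

bundle = run_pipeline(RunConfig(preset="WT", n_frames=20000, seed=1,
                                out_dir="wt_report"))
print(bundle.occupancies.probabilities)
```

`run_pipeline` writes a closed-state distance table (`table1.csv`), a
state-occupancy table with autocorrelation-corrected error bars
(`table3.csv`), per-frame labels, per-pair PMF profiles, a calibration
report and a parameter log. Runs are deterministic for a given seed.

Real structures work through the same pipeline: pass `structure_path`
(a PDB file, multi-model accepted) instead of `preset`, or `series_csv`
for precomputed distance series.

## What is implemented

- **Descriptors** (`bcct.descriptors`): Cα–Cα distance series for seven
  tracked BC-CT/core pairs, minimum distances from aromatic ring centroids
  (F24, Y26) to partner side-chain carbons, water counts inside a 9 Å
  sphere around the L15 Cγ (with a crystallographic baseline of 9
  subtracted), and superposition RMSD.
- **States** (`bcct.states`): closed / open / wide-open classification on
  the Y26–V12 distance (defaults 8.7 / 10.7 Å; P28–G8 at 9.5 / 15 Å
  supported). The open threshold can be recalibrated from the data as the
  smallest distance beyond which most frames carry excess core water.
- **PMFs** (`bcct.pmf`): W(r) = −kT ln(ρ/ρ0) on 0.2 Å bins, ρ0 the modal
  density, unsampled bins masked, profiles alignable on their minima, and
  an `opening_energy` readout at a fixed displacement past the minimum.
- **Restraint** (`bcct.restraint`): half-harmonic repulsive bias
  U = ½k(r−r0)² for r < r0 (k = 30 kcal/mol/Å², r0 = closed-state mean
  + 9.8 Å) applied to F24–L15 and P28–G8 for 200 ps, then released.
- **Synthetic generator** (`bcct.synthetic`): overdamped Langevin dynamics
  on coupled multi-well landscapes with presets `WT`, `Y26G` and `F24E`, a
  gated water-entry process, and exact stationary marginals computed by
  transfer-operator quadrature — the oracle the analyses are tested
  against. It also writes small synthetic PDB structures with known
  geometry for testing the structure pipeline.

See `docs/methods.md` for definitions, conventions and calibration
details.

## Tests and acceptance

```bash
pytest                                    # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script runs the main analyses end to end and records the
computed quantities (crystal-geometry distances, analytic checks on the
Boltzmann inversion and restraint, wild-type occupancies against the
exact stationary distribution, zipper opening-energy ordering, and
hinge-break outcome counts) in one JSON file.
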