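# pahgeom

Geometry-based stability prediction for polycyclic aromatic hydrocarbons
(PAHs). From plain XYZ coordinates the package computes fast geometric
descriptors of a fused aromatic carbon skeleton — harmonic-oscillator
aromaticity (HOMA, plus fused-bond and perimeter-bond variants), bond-length
and bond-angle alternation, summed and RMS bond-angle strain, the total
dihedral deviation from planarity, pyramidalization RMSD, and the maximal
out-of-plane extent Δz — and fits MAD-minimizing (least-absolute-deviations)
linear models of isomerization energy on any combination of them. A published
fixed-coefficient three-descriptor model is bundled for direct prediction.

## Layout

- `pahgeom.structio` — XYZ read/write, distance-window bond perception,
  smallest-ring basis of the carbon skeleton, fused/perimeter bond
  classification, best-fit-plane alignment, highly-connected-ring count.
- `pahgeom.descriptors` — the full descriptor panel (`compute_all`) and each
  descriptor as a standalone operation.
- `pahgeom.modeling` — isomerization energies, error statistics
  (MAD/RMSD/MSD/MaxD), weighted LAD regression via linear programming,
  linear correction of semiempirical energies, planarity partition at
  Δz = 1.0 Å, optimal-bond-length scan, per-formula transferability fits.
- `pahgeom.predictor` — the published model
  `ΔE = 0.0207·ΣDihedral − 339.00·HOMA + 16.44·θRMSD + 236.09` (kcal/mol)
  and generic application of any fitted model with a ±training-MAD bound.
- `pahgeom.synthdata` — idealized fused-hexagon benzenoids on a honeycomb
  lattice, controlled distortions (twist / bend / noise / Kekulé
  alternation), and seeded synthetic descriptor/energy tables.
- `pahgeom.cli` — the `pahgeom` command.

## CLI

```sh
# descriptor panel, one CSV row per structure
pahgeom descriptors molecules/*.xyz -o descriptors.csv

# MAD-minimizing fit of selected descriptor columns against e_ref
pahgeom fit table.csv -d sum_dihedral -d homa -o fit.json

# predictions with the published model (or --model fit.json)
pahgeom predict --xyz molecule.xyz
pahgeom predict --model fit.json --table descriptors.csv -o pred.csv

# error statistics between two columns
pahgeom stats table.csv --pred-col e_pred --ref-col e_ref

# sensitivity scan of the optimal aromatic bond length
pahgeom scan-ropt molecules/*.xyz --energies energies.csv

# synthetic fixtures
pahgeom synth --kind structure --acene 4 --distort twist:15 -o acene4.xyz
pahgeom synth --kind table --n-per-formula 100 --seed 1 -o table.csv
```

Defaults follow the reference constants: R_opt = 1.388 Å, α = 257.7,
C–C bond cutoff 1.75 Å, C–H cutoff 1.30 Å, planarity threshold Δz = 1.0 Å.

## Table conventions

Isomer tables are CSV with columns `id`, `formula` (CxHy), descriptor
columns named as in `pahgeom.descriptors.DESCRIPTOR_COLUMNS`, and energies
`e_ref` / `e_xtb` in kcal/mol. Isomerization energies are computed per
formula group (`add_isomerization_energies` adds `de_ref` / `de_xtb`
columns). Fitted models serialize to JSON via `FitResult.to_json`.
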