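# micellometry

Small-angle X-ray scattering (SAXS) characterization of surfactant
micelles, built for systems like saponin self-assemblies: amphiphiles
with sugar-decorated hydrophilic shells and buried hydrophobic cores
that form elongated micelles of D_max ≈ 75 Å. The package implements the
full model-independent analysis chain a line-collimation (Kratky camera)
measurement needs, plus the coordinate-space descriptors used to compare
scattering results with molecular models — all exercised end to end on
synthetic bead-model micelles with known ground truth, so no external
data are required.

## What it computes

**Reduction** (`micellometry.smearing`) — cubic Savitzky–Golay smoothing,
slit (line-beam) smearing Ĩ(q) = 2∫₀^tmax W(t) I(√(q²+t²)) dt and its
iterative multiplicative (Lake-type) inverse, and absolute-intensity
scaling against the water standard (1.68 × 10⁻²).

**Inversion** (`micellometry.ift`) — the indirect Fourier transform: the
pair-distance distribution is expanded in N cubic B-splines on
[0, D_max],

&nbsp;&nbsp;&nbsp; p(r) = Σᵢ cᵢ φᵢ(r),&nbsp;&nbsp;&nbsp;
I(q) = 4π ∫₀^{D_max} p(r) sin(qr)/(qr) dr,

with coefficients from stabilized least squares (second-difference
penalty λ‖Δ²c‖², automatic λ, p(0) = p(D_max) = 0 pinned). The transform
support D_max is selected by a scan: the smallest candidate whose χ² has
reached the plateau and whose p(r) tapers smoothly to zero at the
support end.

**Shape** (`micellometry.shape`) — D_max, Rg from p(r) moments
(Rg² = ∫r²p dr / 2∫p dr), the transverse cross-section from the
inflection point of p(r) between its maximum and the linear decay
region, and the equivalent axial ratio D_max / cross-section.

**Forward model** (`micellometry.scattering`) — the exact Debye sum
I(q) = Σᵢⱼ wᵢwⱼ sin(q rᵢⱼ)/(q rᵢⱼ) for bead models, the analytic sphere
form factor and p(r) as oracles, and least-squares scaling of a
theoretical curve onto an experimental one with the χ discrepancy.

**Structure** (`micellometry.structure`) — radius of gyration,
principal-axis height/width/axial ratio, radial distribution functions
g(r) (periodic or open), Shrake–Rupley solvent-accessible surface area
with a deterministic point set, glycosidic-convention torsion angles
(φ = O5–C1–O1–CX, ψ = C1–O1–CX–C(X−1), ω = O28A–C28–C17–C16), and
logarithmic aggregation-growth trend fits dimension = a + b ln n.

**Titration** (`micellometry.titration`) — Henderson–Hasselbalch fits
λ(pH) = λ_A + (λ_B − λ_A)/(1 + 10^(pKa − pH)) with automatic
initialization and a pKa standard error.

**Synthetic data** (`micellometry.synthetic`) — seeded generators for
bead ellipsoids and core–shell spheres with closed-form ground truth,
head-out/tail-in amphiphile aggregates, solvated boxes, noisy
(optionally slit-smeared) curves and sigmoidal titration tables.

## Worked example

`examples/02_reduce_and_invert.py` runs the whole chain on a synthetic
prolate micelle (75 × 42 × 42 Å, 5000 beads, 1% noise, slit-smeared):

```
simulated a smeared, 1%-noise curve with 150 points
recommended D_max    : 70.0 A   (truth 75.0)
Rg from p(r) moments : 21.61 A  (truth 21.39)
cross-section        : 37.7 A
axial ratio          : 1.85  (truth 1.79)
```

The recommended D_max is the smallest transform support consistent with
the data; for smooth elongated particles the last few Å of the
pair-distance spectrum carry almost no intensity, so the reading sits
slightly inside the geometric maximum (see `docs/methods.md`). Rg and
the axial ratio recover the ground truth closely; the cross-section
lands at the true inflection point of this geometry's p(r) (≈ 37.5 Å for
a uniform 75 × 42 Å prolate).

The other examples cover forward scattering and the transform-pair
identity (`01`), aggregate geometry, solvent shielding of buried tails
and SASA (`03`), and titration pKa fitting (`04`).

A thin CLI wraps the same functions:

```sh
micellometry simulate --shape prolate --dims 37.5,21,21 --seed 1 --out sim
micellometry ift --in sim_curve.dat --scan-dmax 40:120:5 --out fit
micellometry shape --pr fit_pr.dat --out report.yaml
```

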