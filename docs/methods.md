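# Methods

## The measurement model

A dilute solution of monodisperse particles scatters X-rays with
intensity I(q), q = 4π sin θ/λ, related to the pair-distance
distribution p(r) by the sine transform

    I(q) = 4π ∫₀^{D_max} p(r) sin(qr)/(qr) dr,

where p(r) is the contrast-weighted histogram of intra-particle pair
distances and D_max the particle's maximum dimension. A line-collimation
camera records the slit-smeared curve

    Ĩ(q) = 2 ∫₀^{t_max} W(t) I(√(q² + t²)) dt

with a beam-length profile W(t) normalized to ∫W dt = 1/2. The package's
analysis chain inverts this measurement: smooth → desmear → indirect
Fourier transform → shape descriptors.

Assumptions: dilute (no structure factor — the low-q interference that
concentrated samples show is handled by cutting points below
`q_min_cut`, default 0.04 Å⁻¹), monodisperse, isotropic orientation
average, single contrast level unless a core–shell bead model is used.

## Indirect Fourier transform

Direct inversion over a finite q window is ill-posed, so p(r) is
expanded in N cubic B-splines on a clamped uniform knot vector over
[0, D_max] and the coefficients fit by weighted least squares through
the design matrix A[k,i] = 4π∫φᵢ(r) sinc(q_k r) dr (trapezoid
quadrature, 20 points per knot span; columns can be slit-smeared to fit
smeared data directly). A second-difference penalty λ‖Δ²c‖² stabilizes
the solution; the first and last coefficients are pinned to zero so
p(0) = p(D_max) = 0 exactly. Non-negativity is *not* enforced; negative
tail oscillations are reported as a diagnostic score instead.

**Basis size.** The default knot spacing is 4.5 Å, i.e.
N = ceil(D_max/4.5) + 3 (N = 20 at D_max = 75 Å). Keeping the spacing
fixed rather than N matters in the D_max scan: with N fixed, large
supports get knots too coarse to reproduce the four-decade high-q
falloff and their χ² explodes for numerical, not physical, reasons.

**Stabilization weight.** λ is chosen by bisection as the largest value
whose χ² stays below max(n, 1.05·χ²_min): the discrepancy principle when
the stated uncertainties are trustworthy, falling back to
"within 5% of the best achievable misfit" when they underestimate the
effective noise. The latter always happens after desmearing, which
amplifies and correlates errors (empirically χ²/n ≈ 10 against the
propagated σ at 1% input noise). An L-curve corner criterion was tried
and rejected: on these smooth, decade-spanning curves the corner is too
weak to locate and the chosen λ over-smoothed p(r) grossly.

**Choosing D_max.** `scan_dmax` fits every candidate support with the
*same* number of splines (sized for the largest candidate) so the χ²
values have equal degrees of freedom — letting N grow with the support
would keep buying spurious χ² improvement from correlated noise. A
candidate is *adequate* when its χ² lies within 5% of the plateau level
(median χ² over the upper half of the range, robust to drift and
outliers). The recommendation is the smallest adequate candidate whose
p(r) also converges smoothly to zero at the support end: tail
negativity ≤ 5% of the peak and an end-slope score
|p′(D_max)|·D_max/max(p) ≤ 1 — a truncating support forces the spline
to plunge (score ≳ 3 in validation), an adequate one lets it taper
(≲ 1). When heavy tail noise leaves no candidate looking smooth, the
plateau onset itself is returned rather than chasing the χ² minimum
into arbitrarily large supports. Without the smoothness conditions the
recommendation is noise-decided once the support is adequate.

**Smoothness-constrained refit.** After the support is chosen,
`analyze_curve` refits with λ escalated tenfold per step (at most 10⁵×)
until the p(r) diagnostics pass. Desmeared curves occasionally carry a
noise realization that the χ²-targeted λ under-smooths; the resulting
p(r) oscillations would derail the second-derivative cross-section
reading. Across validation seeds the refit triggers rarely and leaves
χ² within a factor ~2 of the unconstrained fit.

**Information limit on D_max.** For smooth convex elongated particles
p(r) approaches zero at D_max with high-order contact (measured tail
exponent ≈ 2.9 for a 75 × 42 Å prolate): the last ~5 Å of the
pair-distance spectrum hold well under 1% of the peak amplitude. In
consequence (i) any threshold reading of p(r) (e.g. `dmax_from_pr`'s 1%
floor) is a lower bound — the exact p(r) of that prolate crosses the 1%
floor at 65.8 Å — and (ii) after desmearing, supports from ~65 Å upward
are statistically indistinguishable at 1% noise, so the scan recommends
70 ± 5 Å for a true 75 Å particle. This is a property of the data, not
of the algorithm; the package reports the scan recommendation as its
D_max estimate and the floor reading as a diagnostic.

## Shape descriptors

Rg² = ∫r²p dr / (2∫p dr) on the evaluated grid (trapezoid). Note the
relation assumes the continuous p(r) convention; for a discrete
two-bead "particle" the missing self-pair term makes it d/√2 rather
than d/2 (irrelevant for n ≫ 1 models).

The transverse cross-section is the inflection point of p(r) between
its maximum and the linear decay region, located as the first
negative-to-positive zero crossing of the smoothed second derivative
after the mode (Savitzky–Golay, cubic, window = 1/10 of the grid,
linearly interpolated crossing). On the exact p(r) of a uniform
75 × 42 Å prolate the rule gives 37.5 Å; it is a rough transverse-scale
estimator, biased below the geometric diameter for mild elongation, and
for a uniform sphere it returns 2R·x* with 10x*³ − 9x* + 2 = 0
(x* ≈ 0.805) rather than failing. The axial ratio is
D_max / cross-section.

## Smearing and desmearing

The default beam profile is trapezoidal (flat to t₁, linear to t_max);
the synthetic studies use t₁ = 0.05, t_max = 0.15 Å⁻¹, a moderate
Kratky-camera width chosen once for the emulation. The smearing
integral needs I beyond the measured window; a power law fitted to the
top half-decade of q closes the tail. Desmearing is the multiplicative
iteration I⁽ᵏ⁺¹⁾ = I⁽ᵏ⁾·Ĩ_obs/smear(I⁽ᵏ⁾), started at the observed
curve. The default cap of 20 iterations is deliberate regularization:
the fully converged limit is the exact inverse and maximally amplifies
noise. Uncertainties are propagated by preserving relative error, an
approximation that understates the post-desmearing correlated noise
(absorbed by the λ selection fallback above). Non-positive intensities
are clipped to a 10⁻¹² floor with a warning.

## Forward model

The Debye sum is evaluated exactly (O(n²) pairwise distances, chunked
at 5×10⁷ pairs to bound memory); bead models up to n = 20 000 stay
desk-scale. `pr_exact` normalizes the pair histogram as a density
p(r) = Σ wᵢwⱼ δ(r − rᵢⱼ)/(2π) so that its sine transform reproduces the
Debye sum up to the Σw² self term — the package's central transform-pair
oracle, accurate to ~1% over the measured window at n = 3000.
`scale_to` uses χ = √(min Σ[(I_exp − sI_th)/σ]²/(n−1)).

## Coordinate descriptors

Principal extents: height is the extent along the leading covariance
eigenvector; because square-section and spheroidal bodies have a
degenerate transverse covariance (eigenvectors arbitrary in the plane),
the transverse axes are fixed by the minimum-area enclosing rectangle
of the transverse projection (rotating calipers over the convex hull) —
deterministic, rotation-invariant, and exact for axis-aligned boxes.
Width is the mean of the two transverse extents.

RDF: g(r) = counts/(4πr²Δr·ρ·N_ref), minimum-image distances and
ρ = N/V_box when a periodic box is present; otherwise ρ from the
bounding sphere of the target set (documented approximation for open
systems). SASA: Shrake–Rupley with golden-spiral point sets (default
960 points, probe 1.4 Å; radii C 1.70, O 1.52, N 1.55, H 1.20,
S/P 1.80 Å) — fully deterministic, no RNG. Torsions use the standard
atan2-of-cross-products signed convention. Growth trends are
least-squares fits of dimension = a + b ln n with the Pearson R between
observed and fitted values.

## Synthetic generators

Ellipsoids are filled by rejection sampling (no lattice, to keep
distance spectra smooth); ground truth uses the uniform-ellipsoid closed
forms D_max = 2a, Rg = √((a²+b²+c²)/5). Aggregates emulate micellar
organization: one monomer per golden-spiral surface direction
(jittered), hydrophilic head anchored at 0.90–0.99 of the envelope
radius, tail axis pointing inward with a random spin, clash-resampled
below 1.5 Å. Noise is multiplicative Gaussian (1 + ε), ε ~ N(0, f),
with σ = f·I_true recorded — emulating counting statistics at the ~1%
level of a well-exposed curve. All generators are bit-reproducible
under a fixed seed.

What the generators do *not* emulate: inter-micelle interference
(structure factor), polydispersity, instrument background and dark
counts, wavelength smear, detector point spread, or the internal
core–shell contrast profile of a real sugar-shelled micelle (available
separately via `make_core_shell_sphere`, but the benchmark prolate is
uniform). Passing tests therefore demonstrate correctness of the
analysis chain under clean, known-truth conditions, not robustness to
every artifact of real data. On a real micelle with a hydrated
high-contrast shell the p(r) tail and inflection shift outward relative
to the uniform-ellipsoid benchmark; the benchmark's cross-section
(≈ 37.5 Å) is the true inflection of the uniform geometry, a little
below its 42 Å transverse diameter.

## Benchmark studies and problem sizes

`micellometry.studies` fixes the benchmark conditions: 75 × 42 × 42 Å
uniform prolate, 5000 beads, q ∈ [0.02, 0.6] Å⁻¹ at 150 points, 1%
noise, the trapezoidal slit profile above, D_max candidates 40–120 Å in
5 Å steps, low-q cut 0.04 Å⁻¹; and for titration pH 2.4–11.1 in 0.5
steps, plateaus 340/440 nm, 0.2 nm noise, 100 replicates. The bead
count keeps the Debye stage around a minute on one CPU while holding
Monte-Carlo error on the curve well below the 1% noise floor; tests use
smaller models (800–3000 beads) except where an oracle's tolerance
requires 20 000.

## Known limitations

- D_max recovery is information-limited to ≈ −5 Å for smooth elongated
  particles at 1% noise (see above); the scan grid quantizes the
  estimate to 5 Å.
- The desmearing σ propagation ignores error correlation; reduced χ²
  after desmearing is not interpretable against the nominal σ.
- The open-system RDF density normalization is approximate; use a
  periodic box for quantitative g(r).
- No polydispersity, structure factor, or hydration-shell contrast in
  the forward model.
- PDB fixed-column fields limit coordinates to |x| < 10⁴ Å and residue
  ids to 4 digits (delegated to biotite's writer).
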