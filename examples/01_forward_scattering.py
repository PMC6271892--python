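"""Forward scattering from a bead-model micelle.

Builds a uniform prolate bead ellipsoid with micelle-like dimensions
(75 x 42 x 42 Å), computes its exact Debye intensity, and checks the
transform-pair identity against the pair-distance histogram.
"""

import numpy as np

import micellometry as m

model, truth = m.make_ellipsoid(37.5, 21.0, 21.0, n_beads=3000, seed=1)
print(f"ground truth: D_max = {truth.d_max:.1f} A, Rg = {truth.rg:.2f} A, "
      f"axial ratio = {truth.axial_ratio:.2f}")

q = np.linspace(0.02, 0.6, 80)
curve = m.debye_intensity(model, q)
print(f"I(q_min)/I(q_max) = {curve.intensity[0] / curve.intensity[-1]:.0f}  "
      "(the curve spans several decades, as SAXS data do)")

# p(r) of the same beads, and its sine transform back to I(q)
pr = m.pr_exact(model, bin_width=0.25)
back = m.back_transform(pr, q)
coherent = curve.intensity - np.sum(model.weights**2)  # drop the self term
window = q <= 0.3
err = np.max(np.abs(back.intensity[window] / coherent[window] - 1.0))
print(f"p(r) mode at r = {pr.r[np.argmax(pr.p)]:.1f} A; "
      f"back-transform matches the Debye curve to {100 * err:.2f}% for q <= 0.3")
print("The mode of p(r) sits near the transverse diameter; the identity "
      "between histogram transform and Debye sum validates both routes.")
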