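"""The full measurement-emulation and analysis chain.

Slit-smears a noisy synthetic curve (as a line-collimation camera would
record it), desmears it, selects the transform support by scanning,
inverts to p(r) and reads off the shape descriptors.
"""

import numpy as np

import micellometry as m

model, truth = m.make_ellipsoid(37.5, 21.0, 21.0, n_beads=5000, seed=7)
profile = m.SlitProfile.trapezoidal(0.05, 0.15)
q = np.linspace(0.02, 0.6, 150)
curve = m.make_noisy_curve(model, q, noise_frac=0.01,
                           smear_profile=profile, seed=8)
print(f"simulated a smeared, 1%-noise curve with {len(curve)} points")

report = m.analyze_curve(curve, smear_profile=profile)
s = report.summary()
print(f"recommended D_max    : {s['d_max']:.1f} A   (truth {truth.d_max})")
print(f"Rg from p(r) moments : {s['rg']:.2f} A  (truth {truth.rg:.2f})")
print(f"cross-section        : {s['cross_section']:.1f} A")
print(f"axial ratio          : {s['axial_ratio']:.2f}  (truth {truth.axial_ratio:.2f})")
print("D_max comes from the support scan (where chi^2 stops improving and "
      "p(r) tapers smoothly to zero); the cross-section is the inflection "
      "of p(r) between its maximum and the linear decay region.")
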