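"""Size parameters of a solid sphere, computed purely from channel sums.

The Shannon intensities of a 25 A sphere are known in closed form, so the
channel-sum estimators can be checked against textbook sphere values:
R_g = sqrt(3/5) R, r_avg = 36R/35, V_p = 4 pi R^3 / 3, l_c = 3R/2.
"""

import numpy as np

from shanift import compute_size_parameters, sphere_shannon_In

R = 25.0
coeffs = sphere_shannon_In(R, 100_000)
p = compute_size_parameters(coeffs, tail_correction=True)

exact = {
    "I(0)": 1.0,
    "Rg": np.sqrt(3 / 5) * R,
    "ravg": 36 * R / 35,
    "Vp": 4 * np.pi * R**3 / 3,
    "Vc": (4 * np.pi * R**3 / 3) / (2 * np.pi * 1.5 * R),
    "lc": 1.5 * R,
}
computed = {"I(0)": p.I0, "Rg": p.rg, "ravg": p.ravg, "Vp": p.vp, "Vc": p.vc, "lc": p.lc}

print(f"{'parameter':>10} {'channel sum':>14} {'exact':>14}")
for k in exact:
    print(f"{k:>10} {computed[k]:>14.4f} {exact[k]:>14.4f}")
print("\nEach row should agree to <0.5%: the channel sums converge to the")
print("classical sphere invariants as the number of Shannon channels grows.")
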