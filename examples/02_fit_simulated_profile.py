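"""Fit a noisy simulated sphere profile at known D and report parameters.

Simulates the standard scenario (R = 25 A sphere, data to the 8th Shannon
point, 500 points, 2% noise), selects the regularization weight by the
10%-chi2-rise rule, fits the Shannon intensities and prints the recovered
size parameters with their propagated 1-sigma errors.
"""

from shanift import compute_size_parameters, fit_In, scan_alpha, simulate_profile

profile = simulate_profile(R=25.0, seed=1)
alpha, report = scan_alpha(profile, D=50.0)
fit = fit_In(profile, D=50.0, alpha=alpha, extend=True)
p = compute_size_parameters(fit.coeffs)

print(f"chi2_best = {report.chi2_best:.4f}, selected alpha = {alpha:.3g}")
print(f"chi2 at selected alpha = {fit.chi2:.4f} "
      f"(ratio {fit.chi2 / report.chi2_best:.3f}, target ~1.10)")
print(f"I(0)  = {p.I0:.4f} +- {p.I0_err:.4f}   (true 1.0)")
print(f"Rg    = {p.rg:.3f} +- {p.rg_err:.3f}  (true 19.365)")
print(f"ravg  = {p.ravg:.3f} +- {p.ravg_err:.3f}  (true 25.714)")
print("\nThe fitted values sit within a few error bars of the sphere truth;")
print("the chi2 ratio shows the smoothing cost the 10% rule allows.")
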