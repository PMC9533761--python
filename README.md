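# shanift

Indirect Fourier transform (IFT) of small-angle scattering (SAS) profiles
through a reduced set of intensities sampled at the Shannon points.

## The problem

A particle of maximum dimension *D* tumbling in solution produces an
isotropic scattering profile *I(q)* that is band limited: by Shannon
sampling, the entire curve is determined by its values at the points
*q<sub>n</sub> = nπ/D*, the *Shannon channels*. Writing
*I<sub>n</sub> = I(q<sub>n</sub>)*, the profile and the pair distribution
function *P(r)* (the histogram of intraparticle pair distances, supported
on [0, *D*]) are

```
I(q) = Σₙ Iₙ Bₙ(q),          Bₙ(q) = 2(−1)ⁿ⁺¹ (nπ)² sin(qD) / [qD((nπ)² − (qD)²)]
P(r) = Σₙ Iₙ Sₙ(r),          Sₙ(r) = n r sin(nπr/D) / (2D²)
```

with *I(q) = 4π ∫₀ᴰ P(r) sinc(qr) dr*. Because the coefficients are
intensities rather than abstract series weights, every classical SAS size
parameter becomes a closed-form channel sum, e.g.

```
I(0)  = 2 Σₙ (−1)ⁿ⁺¹ Iₙ
R_g²  = D² Σₙ (−1)ⁿ⁺¹ Iₙ (1 − 6/(nπ)²) / (2 Σₙ (−1)ⁿ⁺¹ Iₙ)
Q     = (π³/D³) Σₙ n² Iₙ                    V_p = 2π² I(0)/Q
∫qI dq = (2π/D²) Σₙ n Si(nπ) Iₙ             V_c = I(0)/∫qI dq,   ℓ_c = π∫qI dq / Q
```

The *I<sub>n</sub>* are estimated from an oversampled experimental profile
(*q, I, σ*) by regularized weighted least squares,

```
minimize  T = Σᵢ [(Iₑ(qᵢ) − Σₙ Iₙ Bₙ(qᵢ))/σᵢ]² + α ∫₀ᴰ [P″(r)]² dr,
```

where the smoothness penalty is an exact quadratic form in the
*I<sub>n</sub>* (no numerical differentiation), and the coefficient
covariance from the normal equations propagates to 1σ errors on every
curve and parameter. *D* and α are estimated automatically from the data:
*D* from where the (cosine-taper filtered) *P(r)* decays to 1% of its
peak, α from where χ² rises 10% above its unregularized minimum.
Molecular weight uses the Porod-volume calibration MW = V<sub>p</sub>/1.6
(V<sub>p</sub> in Å³, MW in Da), with V<sub>p</sub>, V<sub>c</sub>, ℓ<sub>c</sub>
stabilised by a deliberately oversmoothed auxiliary fit (10α, q ≤ 8/R<sub>g</sub>).

For whom: SAS practitioners who want *P(r)*, *I(0)*, *R<sub>g</sub>*,
r̄, *V<sub>p</sub>*, *V<sub>c</sub>*, ℓ<sub>c</sub> and MW with honest
error bars from a single `.dat` profile, and method developers who need a
fully analytic, testable IFT with a built-in sphere oracle.

## Worked example

Blind analysis of a simulated 25 Å sphere profile (2% noise, data to the
8th Shannon channel) — `python examples/03_auto_pipeline.py`:

```
Guinier Rg estimate : 18.26  (method: guinier)
initial D = 7 Rg    : 127.85
estimated D         : 49.67   (true 2R = 50)
selected alpha      : 1.18e+11
final reduced chi2  : 1.0856
I(0) = 1.0010 +- 0.0020
Rg   = 19.420 +- 0.009
Vp   = 67215 +- 872  (exact sphere volume 65450)
MW   = 42.0 kDa  (from Vp/1.6)
```

The pipeline recovered the true maximum dimension (50 Å) to 0.7% and the
sphere's radius of gyration (√(3/5)·25 = 19.36 Å) to 0.3% with no prior
knowledge of the particle; the χ² sits ~9% above the unregularized
optimum, the price the 10% rule pays for a smooth *P(r)*. See
`examples/01_sphere_oracle.py` (analytic channel sums vs textbook sphere
values) and `examples/02_fit_simulated_profile.py` (fit at known *D*).

From the shell:

```sh
shanift simulate -o sphere --seed 1     # writes sphere.dat
shanift -f sphere.dat -o sphere_run     # writes sphere_run.fit, sphere_run_pr.dat
```

The `.fit` file holds `q I_e sigma I_c` with all parameters in the
header and the model extrapolated to *q* = 0 (σ = 0 sentinel rows); the
`_pr.dat` file holds `r P(r) sigma_P` on [0, *D*].

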