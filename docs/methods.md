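# Methods

## Model

A particle with maximum pair distance *D* has *P(r)* supported on
[0, *D*], so *Q(r) = P(r)/r* admits a sine series on that interval and
the Fourier mate *qI(q)* is band limited. Sampling at the Shannon points
*q_n = nπ/D* and re-parameterising the series weights as the intensities
*I_n = I(q_n)* gives the cardinal series used throughout:

- reciprocal space: `B_n(q) = 2(−1)^{n+1}(nπ)² sin(qD)/[qD((nπ)²−(qD)²)]`,
  with `B_n(q_m) = δ_nm` and `B_n(0) = 2(−1)^{n+1}`;
- real space: `S_n(r) = n r sin(nπr/D)/(2D²)`;
- normalisation: `I(q) = 4π ∫₀^D P(r) sinc(qr) dr`, hence
  `∫P dr = I(0)/4π`.

All package formulas (basis functions, parameter channel sums, the
regularizer matrix) were derived from this pair of series and are
cross-checked in the test suite against independent numerical quadrature
and against the closed-form solid sphere, for which every output is known
exactly (`R_g = √(3/5)R`, `r̄ = 36R/35`, `V_p = 4πR³/3`, `ℓ_c = 3R/2`,
`V_c = V_p/(2πℓ_c)`, and Shannon intensities `9(2/nπ)⁶` / `9(2/nπ)⁴` for
odd/even *n*).

## Estimation

The fit minimises `T = χ²_unreduced + α·S` with
`S = ∫₀^D [P″(r)]² dr`, an exact quadratic form `Iᵀ M I`:

```
M_nn = n⁴π²(11/4 + n²π²/6)/(4D⁵)
M_mn = (−1)^{m+n} m²n²π²/(2D⁵) · (1 + 2m²n²/(m²−n²)²)     (m ≠ n)
```

Solving the normal equations `(AᵀWA + αM) I = AᵀW I_e`
(`W = diag(1/σᵢ²)`) yields the coefficients and their covariance
`C = (AᵀWA + αM)⁻¹`; every derived parameter error is first-order
propagation `σ = √(gᵀCg)` through the exact gradient of its channel sum.
σᵢ are taken at face value (no rescaling by reduced χ²).

Channels above the measured band (`n_max < n ≤ 3n_max`) may float when
α > 0, removing the implicit zero-bias at high *q*; with α = 0 they are
entirely unconstrained, so the fit falls back to `n_total = n_max` with a
warning.

## Numerical choices

- **B_n at its removable singularities.** Two algebraically equivalent
  forms are used, each regular on its half of the axis:
  `2(−1)^{n+1}(nπ)² sinc(qD)/((nπ)²−(qD)²)` for `qD < nπ/2` and
  `2(nπ)² sinc(qD−nπ)/(qD(qD+nπ))` beyond. This is exact at `q = 0` and
  `q = q_n` with no series truncation.
- **χ² convention.** Reduced, with `dof = N_points − n_max`; extension
  channels are penalty-constrained, not counted as free parameters.
- **Solver.** Cholesky factorization of the normal matrix; when its
  condition number exceeds 1e12 (typical for floating extension channels
  at tiny α) an eigenvalue-clipped pseudo-inverse takes over.
- **α units.** `S` carries units intensity²·length⁻⁵, so absolute α
  values are convention dependent; only the behaviour of the
  10%-χ²-rise selection is contractual.
- **P(r) output grid.** 501 even points on [0, *D*]; `S_n` is forced to
  exactly zero at *r* = 0 and *r* = *D*.
- **Porod tail.** The invariant sum `Σ n²I_n` converges as 1/n² for
  Porod-decaying particles; the oracle path optionally adds the analytic
  tail `K·ψ′(N+1)` with the Porod constant *K* read off the last 10% of
  channels. The fitted-data path leaves the correction off (8–30 noisy
  channels carry no usable tail information).

## Automatic D and α

1. Rough `R_g` from a weighted Guinier fit of the first 20 points
   (window shortened until `q·R_g ≤ 1.3`; non-positive intensities
   dropped). If the slope is non-negative the Guinier-peak method takes
   over: the interior maximum of `q·I(q)` sits at `qR_g = √(3/2)` for an
   ideal Guinier region, refined by fitting `c·q·exp(−q²R_g²/3)` around
   the observed peak. No interior peak is a hard error (supply *D*
   manually).
2. `D₀ = 7R_g` (deliberately generous), unregularized fit, then a cosine
   taper is applied to the channel series before evaluating the decision
   *P(r)*. The taper is a Tukey window — flat to `n_max/2`, Hann
   roll-off to `n_max`. A full-band Hann taper was evaluated and
   rejected: it halves the effective resolution, smearing *P(r)* by about
   half a Shannon spacing and biasing *D* high by ~9% on sphere data,
   while the half-band taper removes the termination ripple and recovers
   *D* to ~1% noise-free and within 10% on 50/50 noisy seeds (1–3%
   noise).
3. *D* = first radius past the *P(r)* maximum where the filtered curve
   drops to ≤ 1% of its peak (boundary inclusive); the channels are then
   re-fit at the new *D*.
4. α scan: χ²_best at α = 0, then `α = 10^k, k = −20..20`; the selected
   α log-interpolates the first crossing of `1.1·χ²_best`. The scan runs
   with extension channels disabled so χ²(α) is well posed down to
   vanishing α (it then equals χ²_best to <0.1% at α = 10⁻²⁰) and rises
   monotonically; the selected α is applied to the production fit with
   extension enabled, which lands within the same [1.05, 1.15]·χ²_best
   band on the default scenario.

## Oversmoothed V_p, V_c, ℓ_c and MW

These high-*q*-sensitive parameters are re-estimated from an auxiliary
fit at `10α` restricted to `q ≤ 8/R_g`, which suppresses shape scattering
and enforces a Porod-like decay; the primary fit, *P(r)* and the other
parameters are untouched. If the floating channels of the auxiliary fit
drive the Porod invariant negative (possible when α is far below the
scan-selected scale), the auxiliary fit is retried without them.
`MW = V_p/1.6` (Å³ → Da); nm-unit inputs are converted (×1000) for MW
only.

## Synthetic data generator

`simulate_profile` emulates a beamline measurement of a solid sphere:
default R = 25, 500 evenly spaced points on (0, 8π/50] (exactly eight
Shannon channels for *D* = 2R), Gaussian noise with
`σ(q) = 0.02·(I(q) + 0.01·I(0))` — 2% proportional noise with a floor so
the error bars stay meaningful at the form-factor minima — and a seeded
`numpy` generator as the package's only randomness source. It does not
emulate real-data features such as interparticle interference,
polydispersity, buffer-subtraction offsets, smearing, or q-dependent
systematic error; passing tests therefore demonstrate correctness of the
estimators under the stated noise model, not robustness to those
systematics (the oversmoothed path exists precisely because real data
violate pure Porod decay).

## Problem sizes

The analytic oracle uses 10⁵ channels (milliseconds; sums are simple
vector reductions). Stochastic suites use 20–200 seeded noise
realizations of the 500-point default profile and 50 seeds for the D
estimator; the full test suite runs in a few seconds.

## Known limitations

- No positivity constraint on *P(r)* and no Bayesian α selection.
- No slit-smearing/desmearing; single-curve fits only.
- The Guinier-peak fallback needs an interior peak of `q·I(q)`.
- MW calibration (V_p/1.6) is for globular biomacromolecules in Å-based
  units; it is not meaningful for strongly flexible or extended
  particles.
- Estimated errors are statistical (propagated from σᵢ); systematic
  deviations, which dominate V_p-based MW on real data, are not modelled.
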