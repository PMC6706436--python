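# Methods

This note records the statistical model, the numerical choices and the
design decisions behind `wilsonplan`, and what the synthetic-data tests do
and do not demonstrate.

## Model

A crystal's mean diffraction intensity at resolution s = sin θ/λ (Å⁻¹)
follows Wilson's law ⟨I⟩ = C⁻² Σⱼ fⱼ²(s) exp(−2⟨B⟩s²), where the sum runs
over all atoms in the unit cell, fⱼ is the four-Gaussian X-ray form factor
(coefficients for H, C, N, O, S, Cl ship with the package; user tables may
override per element), ⟨B⟩ the overall isotropic displacement parameter
(Å²) and C an unknown detector scale.  Individual intensities at fixed s
are exponential (acentric) or scaled-χ²₁ (centric), both with mean
Σ(s) = Σⱼ fⱼ² exp(−2⟨B⟩s²); `scipy.stats` supplies both laws.

The estimator's data vector is S_m = ⟨I⟩_m / Σⱼ fⱼ²(s_m) over contiguous
half-open shells (s_lo, s_lo + w].  S is kept on the raw detector scale;
the default point estimate is scale-invariant, so no preliminary scaling
is needed.  Negative measured intensities are retained in the shell means
(optional clamping exists, off by default).  The shell's representative
resolution is its midpoint — unbiased for the narrow default width and
cheap to align across data sets (all boundaries sit at integer multiples
of the width).

## Bayesian estimation of ⟨B⟩

The posterior P(⟨B⟩ | S) is proportional to the likelihood times a uniform
prior on (0, b_max].  Each shell enters the log likelihood with weight
S_m on the per-event log density of observing intensity at resolution s_m.
Two normalizations of that per-event density are implemented:

* **printed** — normalized over all resolutions 0 < s < ∞, giving the
  per-shell factor [(2B/π)^{1/2} exp(−2Bs_m²)]^{S_m}.  With a uniform
  prior the posterior is a Gamma density, shape 1 + ΣS_m/2, rate
  2ΣS_m s_m², truncated to the prior range; its mode
  ΣS_m/(4ΣS_m s_m²) is exactly invariant under S → kS.  This closed form
  is used as a cross-check oracle throughout the tests.
* **range_normalized** (default) — normalized over the shells actually
  measured: P(s_m|B) = exp(−2Bs_m²)/Σ_k exp(−2Bs_k²).  Its score vanishes
  when the S-weighted and model-weighted mean s² agree, so on noiseless
  data truncated to *any* resolution window the maximum sits exactly at
  the generating B.  The all-resolution normalization is structurally
  biased upward on truncated data — on noiseless synthetic data complete
  to s = 0.65 Å⁻¹ the printed variant overshoots by roughly +30%, and the
  bias approaches +49% in the continuum limit — which is why the
  renormalized form is the default.  Both variants are always computable
  and `estimate_B(compare=True)` reports both side by side.

Numerics: the density is evaluated on an equally spaced grid (default
10,000 points on (0, 50] Å²), normalized by trapezoidal quadrature; the
reported MAP is refined off-grid by Brent root-finding on the analytic
score inside the bracketing grid interval, with the shell weights
normalized to unit sum first (the likelihood is linear in S, so this
changes nothing mathematically but makes the refined mode numerically
independent of the detector scale to well below 1e−9 relative).  The mean
and the equal-tailed 95% credible interval come from the grid CDF.  A mode
within two grid steps of either bound raises an error instead of returning
a truncated posterior.  The conventional Wilson-plot estimate (unweighted
OLS of ln S on s², slope −2B) is provided for comparison; shells with
S ≤ 0 are skipped with a logged count.

Whether the field's reference implementation reports the posterior mode or
mean is not documented in accessible material; both are always reported,
and the mode is the headline because it is exactly scale-free for the
printed variant.  The validation data that could adjudicate the variant
default empirically (published per-shell S tables and deposited
structures) must be downloaded and are therefore outside the offline test
suite; the default rests on the consistency argument above.

## Symmetry and geometry

Resolution comes from the reciprocal metric tensor, s = ½√(hᵀG*h).
Shipped space groups (P1, P−1, P2₁, P2₁/c, P2₁/n, C2/c, Pbca) carry their
Laue class and systematic-absence rules; any other group can be supplied
as a Laue class plus absence rules (pairs of Python predicates over
h, k, l) in the config.  Unique-reflection enumeration scans the covering
hkl box, removes absences, and merges Laue orbits (Friedel pairs always
included) to the lexicographically greatest representative.  The
enumeration, orbit merging and absence rules are validated in the test
suite against gemmi as an independent symmetry oracle and against a
brute-force enumerator.  Epsilon factors for special reflection classes
are deliberately out of scope: intensity statistics here use only the
centric/acentric dichotomy.

The default fixture cell is the room-temperature taurine literature cell
(a = 5.2853, b = 11.6456, c = 7.9347 Å, β = 94.14°, P2₁/c), which yields
exactly 28 unique reflections in the (0.490, 0.500] Å⁻¹ shell — the count
the planning example works with.

## Exposure-time planning

For a target I/σ ratio r, each sampled intensity receives σᵢ = Iᵢ/r; after
sorting in decreasing order, an adjacent pair overlaps iff
I_a − I_b < σ_a + σ_b.  Two counts are reported: the number of overlapping
adjacent pairs and the number of distinct intensities involved in at least
one such pair.  The *pair* count is the headline: in 2000-replicate
simulations of the 28-reflection taurine shell, both published single-draw
counts (10 at I/σ = 20 and 1 at I/σ = 65) fall inside the central 90% of
the pair-count distribution (5th–95th percentiles [6, 13] and [1, 6]),
whereas 1 falls below the involved-intensities distribution ([2, 12]); the
mean pair counts are ≈9.5 and ≈3.5.  A single draw landing at the 5th
percentile also means a mean-based ratio recommendation is stricter than
the published anecdote: pushing the *mean* pair count below 1 needs
I/σ ≈ 200 under these conditions.  Overlap counts are exactly invariant
under rescaling of all intensities (the rule is homogeneous), so the
absolute scale of Σ never matters for planning.

The weakest-bin overlap probability is the squared probability of the
lowest intensity bin [0, 0.01] of the highest resolution shell, with Σ on
the absolute scale (C = 1, electrons²) and the bin width read on that same
scale; for the taurine conditions this gives 4.42 × 10⁻⁵, within ~4% of
the published 4.62 × 10⁻⁵ (residual differences trace to coefficient-table
and cell choices).  It exactly equals the squared lowest-I/highest-s entry
of the exported probability surface built with the same bins.

Sampling offers exact generators (inverse transform; Σ·Z²) and a scalar
slice sampler (initial point Σ, step-out width Σ, burn-in 1000, thinning
10) matching the MCMC scheme named for this problem in the original
analysis; the exact samplers are the distributional ground truth and the
two agree in two-sample Kolmogorov–Smirnov tests.  All sampling is
seed-deterministic; replicate streams are spawned from a single root seed.

## Synthetic data: what it shows and what it does not

The generator draws every unique reflection's true intensity from the
Wilson law and adds Gaussian noise with σ = I_true/noise_ratio — I/σ is
the only quality dial, mirroring how exposure time is reasoned about.
Preliminary subsets are uniform or low-s-deficient (logistic inclusion
probability in s, midpoint at the 15th percentile, slope 0.02 Å⁻¹),
reproducing the situation where a quick scan misses low-resolution shells.
Default conditions for the headline recovery experiment: coverage 0.15,
I/σ = 10, 200 replicates, ⟨B⟩ = 1.53 Å², s_max = 0.65 Å⁻¹.

Passing tests therefore demonstrate internal statistical consistency of
the estimators under the model's own assumptions.  Real diffraction data
additionally contain extinction (strong low-order reflections weakened —
handled only as user-specified shell exclusions), absorption, scale drift,
non-Gaussian counting error at low counts, special-position intensity
statistics and resolution-dependent σ structure; none of these are
emulated, so agreement on synthetic data bounds but does not guarantee
performance on a given instrument.

## Problem sizes and runtime defaults

Shell width 0.005 Å⁻¹ (the 0.01 Å⁻¹ conventional-plot illustration width
is available); posterior grid 10,000 × b_max = 50 Å² (2,000 points in the
replicated recovery experiments, where the refinement step makes the grid
resolution uncritical); 500 replicates for overlap simulations; 200
replicates for the sparse/noisy recovery comparison.  These sizes were
chosen so each experiment's Monte-Carlo error is comfortably below the
effects being measured.

## Known limitations

* No epsilon-factor or special-reflection statistics; centric/acentric only.
* The small symmetry engine covers the shipped groups; anything else needs
  user-supplied Laue class and absence rules.
* The printed-variant closed form assumes the uniform prior; other priors
  would be grid-only.
* The noise model ties σ to the *true* intensity; real integration software
  reports σ from counting statistics and profile fits.
* HKLF4 batch numbers are ignored on read; HKLF5-style twin flags are not
  supported.
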