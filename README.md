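# wilsonplan

Pre-analysis evaluation of single-crystal X-ray diffraction experiments
from a *small preliminary data set* — before committing to a full,
time-consuming data collection.

Selecting a suitable crystal and a favorable exposure time is usually done
by eye, because the preliminary data are far too sparse for structure
solution.  `wilsonplan` extracts what the preliminary intensities *do*
contain: the overall isotropic displacement parameter ⟨B⟩ and, from it, the
full statistical distribution of the intensities that a complete data
collection would record.  Two practical questions are answered:

1. **What crystal quality can I expect?**  ⟨B⟩ reflects thermal motion,
   packing rigidity and lattice regularity; comparing ⟨B⟩ between
   isomorphic crystals distinguishes e.g. different guest molecules in a
   host framework without solving either structure.
2. **What target I/σ (exposure time) do I need?**  By Monte-Carlo sampling
   the predicted intensity distribution of the weakest resolution shell,
   the package counts how many to-be-collected intensities would be
   mutually indistinguishable within their uncertainties ("overlapping"),
   and how that count falls as the target I/σ rises.

## The model

Wilson statistics give the mean diffraction intensity at resolution
s = sin θ/λ:

    ⟨I⟩ = (1/C)² · Σⱼ fⱼ²(s) · exp(−2⟨B⟩ s²),

with C an unknown scale factor and fⱼ the atomic scattering factors of the
unit-cell contents.  Individual intensities around that mean follow

    P(I) = Σ⁻¹ exp(−I/Σ)               (acentric)
    P(I) = (2πΣI)^(−1/2) exp(−I/2Σ)    (centric),

both with mean Σ(s) = Σⱼ fⱼ² exp(−2⟨B⟩s²).

The data vector is the per-shell normalized ratio
S_m = ⟨I⟩_m / Σⱼ fⱼ²(s_m) over narrow resolution shells (default width
0.005 Å⁻¹).  The conventional estimate of ⟨B⟩ is a least-squares line
through (s², ln S) — noisy when only a handful of shells are populated.
`wilsonplan` instead updates a uniform prior over ⟨B⟩ with every S_m acting
as an observation weight, and reports the posterior mode, mean and 95%
credible interval.  Because each shell contributes with weight S_m rather
than as a single point, the Bayesian estimate is far more stable on sparse,
noisy preliminary data (see the worked example below).

## Worked example

Everything below runs without any input files; the synthetic generator
plays the role of the diffractometer.  The study conditions are a
taurine-like molecular crystal: space group P2₁/c, unit-cell contents
C₈H₂₈N₄O₁₂S₄, true ⟨B⟩ = 1.53 Å².

```python
import numpy as np
from wilsonplan import (taurine_spec, generate_full_dataset,
                        generate_preliminary_subset, bin_to_shells,
                        posterior, wilson_plot_fit, max_overlap_probability,
                        simulate_overlap_experiment, get_space_group)

# a sparse, noisy preliminary data set (~15% coverage, I/sigma ~ 10)
spec = taurine_spec(noise_ratio=10.0, seed=42)
full = generate_full_dataset(spec)
prelim = generate_preliminary_subset(full, 0.15, "low_s_deficient", seed=42)

series = bin_to_shells(prelim, 0.005, spec.composition, s_range=(0, 0.65))
post = posterior(series)                      # Bayesian, range-normalized
fit = wilson_plot_fit(series)                 # conventional Wilson plot
print(f"Bayes MAP {post.map:.2f}  ci95 ({post.ci95[0]:.2f}, "
      f"{post.ci95[1]:.2f})  Wilson fit {fit.B:.2f}  true 1.53")
```

prints

```
Bayes MAP 1.92  ci95 (0.24, 4.44)  Wilson fit 0.38  true 1.53
```

On this single replicate the Bayesian estimate lands within 0.4 Å² of the
generating value (the wide credible interval honestly reflects how little
a 15%-coverage scan knows), while the conventional fit collapses to 0.38 Å²
— its characteristic failure mode on sparse, noisy shell means is severe
underestimation.  Over 200 such replicates the Bayesian median |error| is
about half an Å² against more than one Å² for the Wilson fit (run
`scripts/acceptance.py` to reproduce).  Planning the exposure
time for the highest shell of a 0.5 Å⁻¹ preliminary scan:

```python
sg = get_space_group("P21/c")
p2 = max_overlap_probability(spec.composition, 1.53, (0.490, 0.500),
                             0.01, centric=True)
sim20 = simulate_overlap_experiment(spec.composition, 1.53, spec.cell, sg,
                                    (0.490, 0.500), ratio=20, replicates=500,
                                    sampler="slice", seed=1)
sim65 = simulate_overlap_experiment(spec.composition, 1.53, spec.cell, sg,
                                    (0.490, 0.500), ratio=65, replicates=500,
                                    sampler="slice", seed=2)
print(f"n = {sim20.n}, weakest-bin overlap probability {p2:.2e}")
print(f"mean overlapping pairs: {sim20.pair_counts.mean():.1f} (I/sigma 20), "
      f"{sim65.pair_counts.mean():.1f} (I/sigma 65)")
```

prints

```
n = 28, weakest-bin overlap probability 4.42e-05
mean overlapping pairs: 9.6 (I/sigma 20), 3.4 (I/sigma 65)
```

Of the 28 unique reflections expected in the (0.490, 0.500] Å⁻¹ shell,
about ten are indistinguishable from a neighbor at I/σ = 20; raising the
exposure to I/σ = 65 cuts that to a few — the quantitative argument for a
longer exposure when valence-electron-level precision is the goal.

The same workflow is available from the shell (`wilsonplan estimate`,
`match`, `plan`, `surface`, `simulate`); measured data enter as SHELX
HKLF4 files plus a YAML config with the cell, space group and unit-cell
composition, or as pre-computed per-shell S tables (CSV).

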