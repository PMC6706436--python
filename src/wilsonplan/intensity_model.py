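"""Forward prediction of to-be-collected diffraction intensities.

At a given resolution the intensity of a random-atom crystal follows the
Wilson distribution

    P(I) = Sigma^-1 exp(-I/Sigma)                 (acentric)
    P(I) = (2 pi Sigma I)^-1/2 exp(-I/(2 Sigma))  (centric),

both with mean Sigma(s) = sum_j f_j(s)^2 exp(-2<B> s^2) (absolute scale,
unit scale factor).  The centric case is a chi^2 with one degree of freedom
scaled by Sigma; the acentric case is exponential.  scipy.stats supplies
both densities.

The planning workflow evaluates, for the weakest-intensity bin of the
highest measured resolution shell, the probability that two reflections
fall in it together (the squared bin probability) and Monte-Carlo samples
of the to-be-collected intensities of that shell: assign uncertainties
sigma_i = I_i / ratio for a target I/sigma, sort descending, and count
adjacent pairs whose difference is smaller than the sum of their
uncertainties ("overlapping" intensities, indistinguishable at that
exposure).  Sampling offers the exact inverse-transform/normal samplers and
a scalar slice sampler (the MCMC scheme used for this problem in the
original analysis); both are seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reflection_data import (CellParameters, SpaceGroupSetting,
                              enumerate_unique_reflections)
from .scattering import sum_f_squared

__all__ = [
    "WilsonIntensityModel",
    "OverlapReport",
    "OverlapSimulation",
    "ProbabilitySurface",
    "sigma_param",
    "probability_surface",
    "max_overlap_probability",
    "sample_intensities",
    "assign_sigmas",
    "count_overlaps",
    "simulate_overlap_experiment",
    "recommend_ratio",
]

SLICE_BURN_IN = 1000
SLICE_THINNING = 10


def sigma_param(composition: Mapping[str, float], B: float, s: float,
                table=None) -> float:
    """Wilson mean intensity Sigma(s) in electrons^2 (absolute scale)."""
    if B < 0:
        raise ValueError("B must be >= 0")
    return float(sum_f_squared(composition, s, table=table)
                 * math.exp(-2.0 * B * s * s))


@dataclass(frozen=True)
class WilsonIntensityModel:
    """Per-shell intensity distribution: exponential or scaled chi^2_1."""

    sigma_param: float
    centric: bool

    def __post_init__(self) -> None:
        if self.sigma_param <= 0:
            raise ValueError("sigma_param must be positive")

    def _dist(self):
        if self.centric:
            return stats.chi2(df=1, scale=self.sigma_param)
        return stats.expon(scale=self.sigma_param)

    def pdf(self, I):
        if np.any(np.asarray(I) < 0):
            raise ValueError("intensity must be >= 0")
        return self._dist().pdf(I)

    def cdf(self, I):
        if np.any(np.asarray(I) < 0):
            raise ValueError("intensity must be >= 0")
        return self._dist().cdf(I)

    def log_pdf_unnormalized(self, I: float) -> float:
        if I <= 0:
            return -math.inf
        if self.centric:
            return -0.5 * math.log(I) - I / (2.0 * self.sigma_param)
        return -I / self.sigma_param

    @property
    def mean(self) -> float:
        return self.sigma_param


@dataclass(frozen=True)
class ProbabilitySurface:
    """Per-shell, per-intensity-bin probabilities (resolution x intensity)."""

    s_mid: np.ndarray          # (n_shells,)
    i_edges: np.ndarray        # (n_bins + 1,)
    probabilities: np.ndarray  # (n_shells, n_bins)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, s in enumerate(self.s_mid):
            for b in range(len(self.i_edges) - 1):
                rows.append({"s_mid": s, "I_lo": self.i_edges[b],
                             "I_hi": self.i_edges[b + 1],
                             "probability": self.probabilities[m, b]})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def probability_surface(composition: Mapping[str, float], B: float,
                        s_range: tuple[float, float], shell_width: float,
                        i_range: tuple[float, float], i_binwidth: float,
                        centric: bool, table=None) -> ProbabilitySurface:
    """Bin probabilities ``cdf(I_hi) - cdf(I_lo)`` per resolution shell.

    Shell models are built at each shell's midpoint.  Row sums approach 1
    as the intensity range grows.
    """
    if shell_width <= 0 or i_binwidth <= 0:
        raise ValueError("widths must be positive")
    s_lo, s_hi = s_range
    n_shells = int(math.ceil((s_hi - s_lo) / shell_width - 1e-9))
    if n_shells < 1:
        raise ValueError("empty resolution range")
    s_mid = s_lo + shell_width * (np.arange(n_shells) + 0.5)
    i_lo, i_hi = i_range
    n_bins = int(math.ceil((i_hi - i_lo) / i_binwidth - 1e-9))
    if n_bins < 1:
        raise ValueError("empty intensity range")
    edges = i_lo + i_binwidth * np.arange(n_bins + 1)
    edges[-1] = min(edges[-1], i_hi) if edges[-1] > i_hi else edges[-1]
    probs = np.empty((n_shells, n_bins))
    for m, s in enumerate(s_mid):
        model = WilsonIntensityModel(sigma_param(composition, B, s, table),
                                     centric)
        cdf = model.cdf(np.maximum(edges, 0.0))
        probs[m] = np.diff(cdf)
    return ProbabilitySurface(s_mid, edges, probs)


def max_overlap_probability(composition: Mapping[str, float], B: float,
                            shell: tuple[float, float], i_bin: float,
                            centric: bool, table=None) -> float:
    """Squared probability of the weakest-intensity bin of a shell.

    The model is built at the shell midpoint with Sigma on the absolute
    composition scale; ``i_bin`` is the upper edge of the weakest bin
    [0, i_bin] on that same scale.  Squaring gives the probability that two
    to-be-collected intensities fall in the bin together — the paper-style
    upper bound on intensity-overlap probability.
    """
    if i_bin <= 0:
        raise ValueError("i_bin must be positive")
    s_mid = 0.5 * (shell[0] + shell[1])
    model = WilsonIntensityModel(sigma_param(composition, B, s_mid, table),
                                 centric)
    p = float(model.cdf(i_bin))
    return p * p


# --------------------------------------------------------------------------
# Sampling
# --------------------------------------------------------------------------

def _sample_exact(model: WilsonIntensityModel, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    if model.centric:
        z = rng.standard_normal(n)
        return model.sigma_param * z * z
    return -model.sigma_param * np.log(rng.random(n))


def _sample_slice(model: WilsonIntensityModel, n: int,
                  rng: np.random.Generator,
                  burn_in: int = SLICE_BURN_IN,
                  thinning: int = SLICE_THINNING) -> np.ndarray:
    """Scalar slice sampler with step-out (initial point and width Sigma)."""
    logf = model.log_pdf_unnormalized
    w = model.sigma_param
    x = model.sigma_param
    lf_x = logf(x)
    out = np.empty(n)
    total = burn_in + n * thinning
    kept = 0
    for it in range(total):
        log_y = lf_x + math.log(rng.random())
        left = x - w * rng.random()
        right = left + w
        while left > 0 and logf(left) > log_y:
            left -= w
        left = max(left, 0.0)
        while logf(right) > log_y:
            right += w
        while True:
            cand = left + (right - left) * rng.random()
            lf_c = logf(cand)
            if lf_c > log_y:
                x, lf_x = cand, lf_c
                break
            if cand < x:
                left = cand
            else:
                right = cand
        if it >= burn_in and (it - burn_in) % thinning == thinning - 1:
            out[kept] = x
            kept += 1
    return out


def sample_intensities(model: WilsonIntensityModel, n: int,
                       sampler: str = "exact",
                       seed: int | np.random.SeedSequence | None = None,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` intensities from the Wilson distribution.

    ``sampler`` is ``"exact"`` (inverse transform / squared normal) or
    ``"slice"`` (MCMC with burn-in and thinning).  Randomness comes only
    from ``seed`` (or an explicit generator); identical inputs give
    identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or generator) is required")
        rng = np.random.default_rng(seed)
    if sampler == "exact":
        return _sample_exact(model, n, rng)
    if sampler == "slice":
        return _sample_slice(model, n, rng)
    raise ValueError(f"unknown sampler {sampler!r}")


# --------------------------------------------------------------------------
# Overlap evaluation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapReport:
    """Overlap evaluation of one sampled set of intensities."""

    n: int
    ratio: float
    intensities: np.ndarray        # sorted descending
    sigmas: np.ndarray
    overlapping_pairs: int
    intensities_involved: int
    sampler: str
    seed: int | None = None
    zero_intensities: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n, "ratio": self.ratio, "sampler": self.sampler,
            "seed": self.seed,
            "overlapping_pairs": self.overlapping_pairs,
            "intensities_involved": self.intensities_involved,
            "intensities": self.intensities.tolist(),
            "sigmas": self.sigmas.tolist(),
        }


def assign_sigmas(intensities, ratio: float) -> np.ndarray:
    """Uncertainties satisfying I/sigma = ratio: sigma_i = I_i / ratio."""
    if ratio <= 0:
        raise ValueError("target I/sigma ratio must be positive")
    arr = np.asarray(intensities, dtype=float)
    if np.any(arr < 0):
        raise ValueError("intensities must be >= 0")
    return arr / ratio


def count_overlaps(intensities, sigmas, ratio: float = math.nan,
                   sampler: str = "none",
                   seed: int | None = None) -> OverlapReport:
    """Sort descending and count adjacent pairs closer than their sigma sum.

    For the sorted sequence I_a >= I_b, the pair overlaps iff
    ``I_a - I_b < sigma_a + sigma_b``.  ``intensities_involved`` counts the
    distinct intensities taking part in at least one overlapping pair.
    """
    I = np.asarray(intensities, dtype=float)
    sig = np.asarray(sigmas, dtype=float)
    if I.shape != sig.shape:
        raise ValueError("intensities and sigmas must have equal length")
    if np.any(sig < 0):
        raise ValueError("sigmas must be >= 0")
    order = np.argsort(-I, kind="stable")
    I_s, sig_s = I[order], sig[order]
    diff = I_s[:-1] - I_s[1:]
    overlap = diff < (sig_s[:-1] + sig_s[1:])
    involved = np.zeros(len(I_s), dtype=bool)
    involved[:-1] |= overlap
    involved[1:] |= overlap
    return OverlapReport(
        n=len(I_s), ratio=ratio, intensities=I_s, sigmas=sig_s,
        overlapping_pairs=int(overlap.sum()),
        intensities_involved=int(involved.sum()),
        sampler=sampler, seed=seed,
        zero_intensities=int((I_s == 0).sum()))


@dataclass(frozen=True)
class OverlapSimulation:
    """Replicated overlap experiments for one target I/sigma."""

    n: int
    ratio: float
    sampler: str
    seed: int
    reports: tuple[OverlapReport, ...]

    @property
    def involved_counts(self) -> np.ndarray:
        return np.array([r.intensities_involved for r in self.reports])

    @property
    def pair_counts(self) -> np.ndarray:
        return np.array([r.overlapping_pairs for r in self.reports])

    def summary(self) -> dict:
        inv, pairs = self.involved_counts, self.pair_counts
        return {
            "n": self.n, "ratio": self.ratio, "sampler": self.sampler,
            "seed": self.seed, "replicates": len(self.reports),
            "mean_involved": float(inv.mean()),
            "median_involved": float(np.median(inv)),
            "mean_pairs": float(pairs.mean()),
            "median_pairs": float(np.median(pairs)),
        }


def simulate_overlap_experiment(composition: Mapping[str, float], B: float,
                                cell: CellParameters, sg: SpaceGroupSetting,
                                shell: tuple[float, float], ratio: float,
                                replicates: int = 1,
                                sampler: str = "slice",
                                seed: int | np.random.SeedSequence = 0,
                                n: int | None = None,
                                table=None) -> OverlapSimulation:
    """Sample the shell's expected reflection count and count overlaps.

    ``n`` defaults to the number of symmetry-unique reflections expected in
    the shell for the given cell and space group.  Each replicate draws n
    intensities, assigns sigma = I/ratio and counts overlapping adjacent
    intensities.  Overlap counts are invariant to the absolute scale of
    Sigma (the rule is homogeneous in I).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if n is None:
        n = len(enumerate_unique_reflections(cell, sg, shell[0], shell[1]))
    if n == 0:
        raise ValueError(f"no reflections expected in shell {shell}")
    s_mid = 0.5 * (shell[0] + shell[1])
    model = WilsonIntensityModel(sigma_param(composition, B, s_mid, table),
                                 sg.centrosymmetric)
    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    seed_int = seed if isinstance(seed, int) else -1
    reports = []
    for ss in root.spawn(replicates):
        I = sample_intensities(model, n, sampler=sampler,
                               rng=np.random.default_rng(ss))
        sig = assign_sigmas(I, ratio)
        rpt = count_overlaps(I, sig, ratio=ratio, sampler=sampler,
                             seed=seed_int)
        reports.append(rpt)
    return OverlapSimulation(n=n, ratio=ratio, sampler=sampler, seed=seed_int,
                             reports=tuple(reports))


def recommend_ratio(composition: Mapping[str, float], B: float,
                    cell: CellParameters, sg: SpaceGroupSetting,
                    shell: tuple[float, float], target_involved: float,
                    ratios: Sequence[float], replicates: int = 100,
                    sampler: str = "exact", seed: int = 0,
                    n: int | None = None, table=None) -> float:
    """Smallest candidate I/sigma whose mean involved count meets the target.

    Candidates must be sorted ascending.  Raises when no candidate reaches
    the target, reporting the best achieved mean.
    """
    ratios = list(ratios)
    if not ratios:
        raise ValueError("candidate ratio list is empty")
    if any(b > a for a, b in zip(ratios[1:], ratios)):
        raise ValueError("candidate ratios must be sorted ascending")
    best = math.inf
    child_seeds = np.random.SeedSequence(seed).spawn(len(ratios))
    for ratio, ss in zip(ratios, child_seeds):
        sim = simulate_overlap_experiment(
            composition, B, cell, sg, shell, ratio, replicates=replicates,
            sampler=sampler, seed=ss, n=n, table=table)
        mean_inv = sim.involved_counts.mean()
        best = min(best, mean_inv)
        if mean_inv <= target_involved:
            return ratio
    raise ValueError(
        f"no candidate ratio reaches target {target_involved}; best mean "
        f"involved count achieved was {best:.2f}")
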