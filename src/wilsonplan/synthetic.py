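"""Synthetic diffraction data with the statistical structure the method
assumes.

The forward model draws each symmetry-unique reflection's true intensity
from the Wilson distribution with mean ``Sigma(s)/C^2`` (centric or
acentric per the space group) and adds Gaussian measurement noise with
``sigma = I_true / noise_ratio`` — the I/sigma ratio is the single quality
dial, mirroring how exposure time enters the planning workflow.  Subsets
emulate preliminary data sets: either a uniform random subsample or a
low-resolution-deficient one in which the inclusion probability rises
logistically with s, preferentially emptying low-order shells the way a
quick partial scan does.

The default study conditions are a taurine-like crystal: space group
P2_1/c, unit-cell contents C8 H28 N4 O12 S4 (Z = 4), true <B> 1.53 A^2,
data to s = 0.65 1/A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .b_estimation import posterior, wilson_plot_fit
from .intensity_model import WilsonIntensityModel
from .reflection_data import (CellParameters, Reflection, SpaceGroupSetting,
                              enumerate_unique_reflections, get_space_group,
                              resolution_s)
from .scattering import sum_f_squared
from .shells import bin_to_shells

__all__ = [
    "SyntheticSpec",
    "taurine_spec",
    "generate_full_dataset",
    "generate_preliminary_subset",
    "recovery_experiment",
]

#: Room-temperature taurine cell from the small-molecule literature.
TAURINE_CELL = CellParameters(5.2853, 11.6456, 7.9347, 90.0, 94.14, 90.0)
TAURINE_COMPOSITION = {"C": 8.0, "H": 28.0, "N": 4.0, "O": 12.0, "S": 4.0}
TAURINE_B = 1.53


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating conditions for one synthetic data set."""

    cell: CellParameters
    sg: SpaceGroupSetting
    composition: Mapping[str, float]
    b_true: float
    scale: float = 1.0           # the Wilson-plot scale factor C
    s_max: float = 0.65
    coverage_fraction: float = 1.0
    noise_ratio: float = math.inf  # target I/sigma; inf = noiseless
    seed: int = 0

    def __post_init__(self) -> None:
        if self.b_true < 0:
            raise ValueError("b_true must be >= 0")
        if not 0 < self.coverage_fraction <= 1:
            raise ValueError("coverage_fraction must lie in (0, 1]")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def taurine_spec(**overrides) -> SyntheticSpec:
    """The default taurine-like fixture (P2_1/c, <B> = 1.53 A^2)."""
    base = dict(cell=TAURINE_CELL, sg=get_space_group("P21/c"),
                composition=TAURINE_COMPOSITION, b_true=TAURINE_B,
                s_max=0.65, seed=0)
    base.update(overrides)
    return SyntheticSpec(**base)


def generate_full_dataset(spec: SyntheticSpec,
                          table=None) -> list[Reflection]:
    """Draw one full data set over all unique reflections to ``s_max``.

    True intensities follow the Wilson distribution with mean
    ``Sigma(s)/C^2``; the recorded sigma is ``I_true/noise_ratio`` and the
    recorded intensity adds one Gaussian deviate of that width (so observed
    intensities can go negative at low I/sigma).  Deterministic per seed.
    """
    hkl = enumerate_unique_reflections(spec.cell, spec.sg, 0.0, spec.s_max)
    if len(hkl) == 0:
        raise ValueError("no reflections to generate in (0, s_max]")
    s = resolution_s(hkl, spec.cell)
    sigma_mean = sum_f_squared(spec.composition, s, table=table) \
        * np.exp(-2.0 * spec.b_true * s * s) / spec.scale ** 2
    rng = np.random.default_rng(spec.seed)
    if spec.sg.centrosymmetric:
        i_true = sigma_mean * rng.standard_normal(len(hkl)) ** 2
    else:
        i_true = -sigma_mean * np.log(rng.random(len(hkl)))
    if math.isinf(spec.noise_ratio):
        sig = np.zeros(len(hkl))
        i_obs = i_true
    else:
        sig = i_true / spec.noise_ratio
        i_obs = i_true + sig * rng.standard_normal(len(hkl))
    return [Reflection(int(h), int(k), int(l), float(i), float(e), float(si))
            for (h, k, l), i, e, si in zip(hkl, i_obs, sig, s)]


def generate_preliminary_subset(full: Sequence[Reflection],
                                coverage_fraction: float,
                                pattern: str = "random",
                                seed: int = 0) -> list[Reflection]:
    """Subsample a full data set the way a short preliminary scan would.

    ``pattern="random"`` keeps each record with equal probability;
    ``pattern="low_s_deficient"`` uses a logistic inclusion probability in
    s centred at the 15th percentile of the resolution distribution, so
    low-resolution shells are preferentially emptied.  Either way the
    expected kept fraction equals ``coverage_fraction``.
    """
    if not 0 < coverage_fraction <= 1:
        raise ValueError("coverage_fraction must lie in (0, 1]")
    full = list(full)
    if not full:
        raise ValueError("full data set is empty")
    if coverage_fraction == 1.0:
        return list(full)
    rng = np.random.default_rng(seed)
    n = len(full)
    if pattern == "random":
        keep = rng.random(n) < coverage_fraction
    elif pattern == "low_s_deficient":
        s = np.array([r.s if r.s is not None else np.nan for r in full])
        if np.isnan(s).any():
            raise ValueError("low_s_deficient pattern needs s on records")
        s0 = np.quantile(s, 0.15)
        raw = 1.0 / (1.0 + np.exp(-(s - s0) / 0.02))
        p = raw * (coverage_fraction * n / raw.sum())
        keep = rng.random(n) < np.minimum(p, 1.0)
    else:
        raise ValueError(f"unknown subset pattern {pattern!r}")
    subset = [r for r, k in zip(full, keep) if k]
    if not subset:
        raise ValueError("subset came out empty; increase coverage_fraction")
    return subset


_ESTIMATORS = ("bayes_range_normalized", "bayes_printed", "wilson_fit")


def _estimate_one(series, estimator: str, b_max: float,
                  grid_points: int) -> float:
    if estimator == "wilson_fit":
        return wilson_plot_fit(series).B
    if estimator == "bayes_printed":
        return posterior(series, variant="printed", b_max=b_max,
                         grid_points=grid_points).map
    if estimator == "bayes_range_normalized":
        return posterior(series, variant="range_normalized", b_max=b_max,
                         grid_points=grid_points).map
    raise ValueError(f"unknown estimator {estimator!r}")


def recovery_experiment(specs: Sequence[SyntheticSpec], replicates: int,
                        estimators: Sequence[str] = _ESTIMATORS,
                        shell_width: float = 0.005,
                        subset_pattern: str = "low_s_deficient",
                        b_max: float = 50.0, grid_points: int = 2000,
                        master_seed: int = 0) -> pd.DataFrame:
    """Parameter-recovery table: simulate, subset, estimate, aggregate.

    For each condition (spec) and estimator the table reports the mean bias
    and the median absolute error of the B estimate over ``replicates``
    independently generated preliminary data sets, plus the count of
    replicates where an estimator failed (too few usable shells etc.).
    Deterministic for a given ``master_seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    root = np.random.SeedSequence(master_seed)
    for cond, spec in enumerate(specs):
        cond_seeds = root.spawn(replicates)
        errors: dict[str, list[float]] = {e: [] for e in estimators}
        failures = {e: 0 for e in estimators}
        for ss in cond_seeds:
            child = ss.generate_state(2)
            full = generate_full_dataset(
                SyntheticSpec(spec.cell, spec.sg, spec.composition,
                              spec.b_true, spec.scale, spec.s_max,
                              1.0, spec.noise_ratio,
                              seed=int(child[0] % (2 ** 31))))
            if spec.coverage_fraction < 1.0:
                subset = generate_preliminary_subset(
                    full, spec.coverage_fraction, pattern=subset_pattern,
                    seed=int(child[1] % (2 ** 31)))
            else:
                subset = full
            series = bin_to_shells(subset, shell_width, spec.composition,
                                   s_range=(0.0, spec.s_max))
            for est in estimators:
                try:
                    b_hat = _estimate_one(series, est, b_max, grid_points)
                    errors[est].append(b_hat - spec.b_true)
                except (ValueError, IndexError):
                    failures[est] += 1
        for est in estimators:
            err = np.array(errors[est])
            rows.append({
                "condition": cond,
                "b_true": spec.b_true,
                "coverage_fraction": spec.coverage_fraction,
                "noise_ratio": spec.noise_ratio,
                "estimator": est,
                "n_ok": len(err),
                "n_failed": failures[est],
                "bias": float(err.mean()) if len(err) else math.nan,
                "median_abs_error": float(np.median(np.abs(err)))
                if len(err) else math.nan,
            })
    return pd.DataFrame(rows)
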