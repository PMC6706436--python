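"""Resolution-shell binning and per-shell Wilson statistics.

Reflections are binned into contiguous half-open shells ``(s_lo, s_lo + w]``
of constant width ``w`` in ``s = sin(theta)/lambda``.  Each populated shell
carries the arithmetic mean intensity <I>, the composition sum
``sum_j n_j f_j(s_mid)^2`` and their ratio

    S = <I> / sum_j n_j f_j(s_mid)^2,

which on an absolute intensity scale equals ``exp(-2<B> s^2)``.  The ordered
collection of per-shell S values is the data vector consumed by the
B-factor estimators.  S is kept on the raw detector scale (the unknown
scale factor of the measurement is not divided out); the default point
estimator downstream is scale-invariant.

Shells with no reflections are flagged ``excluded`` with reason ``empty``.
Cross-data-set comparisons use :func:`match_shells` to flag shells of a
reference series that are unavailable in a subject series, and
:func:`exclude_shells` applies user exclusions (e.g. extinction-affected
low-order shells).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reflection_data import Reflection
from .scattering import sum_f_squared

logger = logging.getLogger(__name__)

__all__ = [
    "ResolutionShell",
    "ShellSeries",
    "bin_to_shells",
    "match_shells",
    "exclude_shells",
    "series_to_csv",
    "series_from_csv",
]

_EDGE_TOL = 1e-9


@dataclass(frozen=True)
class ResolutionShell:
    index: int
    s_lo: float
    s_hi: float
    s_mid: float
    n_obs: int
    mean_I: float | None
    sum_f_sq: float
    S: float | None
    excluded: bool = False
    reason: str | None = None  # one of: empty, matched_out, user

    def __post_init__(self) -> None:
        if not self.s_lo < self.s_hi:
            raise ValueError("shell requires s_lo < s_hi")
        if self.n_obs == 0 and not self.excluded:
            raise ValueError("empty shell must be flagged excluded")


@dataclass(frozen=True)
class ShellSeries:
    """Ordered, contiguous resolution shells with their Wilson statistics."""

    shells: tuple[ResolutionShell, ...]
    width: float
    s_range: tuple[float, float]
    composition: Mapping[str, float] | None = None

    @property
    def n(self) -> int:
        """Number of usable (non-excluded) shells."""
        return sum(1 for sh in self.shells if not sh.excluded)

    def usable(self) -> list[ResolutionShell]:
        return [sh for sh in self.shells if not sh.excluded]

    def data_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(s_mid, S) arrays over usable shells — the estimator's input."""
        use = self.usable()
        return (np.array([sh.s_mid for sh in use]),
                np.array([sh.S for sh in use]))


def bin_to_shells(reflections: Sequence[Reflection], width: float,
                  composition: Mapping[str, float],
                  s_range: tuple[float, float] | None = None,
                  clamp_negative: bool = False,
                  table=None) -> ShellSeries:
    """Bin reflections into constant-width shells and compute S per shell.

    ``s_range`` defaults to ``(0, ceil(max s / width) * width)`` so that
    shell boundaries are aligned at integer multiples of the width, which
    makes independently binned data sets comparable shell-by-shell.
    Negative measured intensities are kept in the shell means unless
    ``clamp_negative`` is set.
    """
    if width <= 0:
        raise ValueError("shell width must be positive")
    if composition is None or not composition:
        raise ValueError("a unit-cell composition is required to compute S")
    refl = [r for r in reflections]
    if any(r.s is None for r in refl):
        raise ValueError("reflections must carry s (attach_resolution first)")
    s = np.array([r.s for r in refl])
    intensity = np.array([r.intensity for r in refl], dtype=float)
    if clamp_negative:
        intensity = np.maximum(intensity, 0.0)
    if s_range is None:
        if len(refl) == 0:
            raise ValueError("no reflections to bin")
        s_range = (0.0, math.ceil(s.max() / width - _EDGE_TOL) * width)
    lo, hi = s_range
    if not lo < hi:
        raise ValueError("s_range must satisfy lo < hi")
    in_range = (s > lo) & (s <= hi)
    if not in_range.any():
        raise ValueError("no reflections fall inside s_range")
    n_outside = int((~in_range).sum())
    if n_outside:
        logger.info("binning: %d reflections outside (%g, %g] ignored",
                    n_outside, lo, hi)
    s, intensity = s[in_range], intensity[in_range]

    n_shells = int(round((hi - lo) / width)) if \
        abs((hi - lo) / width - round((hi - lo) / width)) < 1e-6 \
        else int(math.ceil((hi - lo) / width - _EDGE_TOL))
    # half-open (edge, edge+width]: points exactly on an edge go below
    idx = np.ceil((s - lo) / width - _EDGE_TOL).astype(int) - 1
    idx = np.clip(idx, 0, n_shells - 1)

    shells = []
    for m in range(n_shells):
        s_lo = lo + m * width
        s_hi = min(lo + (m + 1) * width, hi)
        s_mid = 0.5 * (s_lo + s_hi)
        sel = idx == m
        n_obs = int(sel.sum())
        sfs = float(sum_f_squared(composition, s_mid, table=table))
        if n_obs:
            mean_i = float(intensity[sel].mean())
            shells.append(ResolutionShell(m, s_lo, s_hi, s_mid, n_obs,
                                          mean_i, sfs, mean_i / sfs))
        else:
            shells.append(ResolutionShell(m, s_lo, s_hi, s_mid, 0, None, sfs,
                                          None, excluded=True, reason="empty"))
    return ShellSeries(tuple(shells), width, (lo, hi), dict(composition))


def _aligned(a: ShellSeries, b: ShellSeries) -> bool:
    if abs(a.width - b.width) > _EDGE_TOL:
        return False
    offset = (a.s_range[0] - b.s_range[0]) / a.width
    return abs(offset - round(offset)) < 1e-6


def match_shells(subject: ShellSeries, reference: ShellSeries) -> ShellSeries:
    """Flag reference shells unavailable in the subject as ``matched_out``.

    Both series must use the same width and aligned boundaries.  A reference
    shell is matched out when the corresponding subject shell is empty,
    excluded, or missing entirely (outside the subject's s range).  The
    subject is not modified.
    """
    if not _aligned(subject, reference):
        raise ValueError("shell series have mismatched widths or boundaries")
    subj_by_edge = {round(sh.s_lo / subject.width): sh
                    for sh in subject.shells}
    new_shells = []
    n_matched_out = 0
    for sh in reference.shells:
        key = round(sh.s_lo / reference.width)
        subj = subj_by_edge.get(key)
        if (subj is None or subj.excluded) and not sh.excluded:
            sh = replace(sh, excluded=True, reason="matched_out")
            n_matched_out += 1
        new_shells.append(sh)
    logger.info("match_shells: %d reference shells matched out", n_matched_out)
    return replace(reference, shells=tuple(new_shells))


def exclude_shells(series: ShellSeries,
                   indices: Iterable[int] = (),
                   s_intervals: Iterable[tuple[float, float]] = ()
                   ) -> ShellSeries:
    """Apply user exclusions by shell index or by s interval.

    An s interval ``(lo, hi]`` excludes every shell whose midpoint falls in
    it.  Downstream estimators skip excluded shells.
    """
    indices = set(indices)
    intervals = list(s_intervals)
    n_shells = len(series.shells)
    for i in indices:
        if not 0 <= i < n_shells:
            raise IndexError(f"shell index {i} out of range 0..{n_shells - 1}")
    new_shells = []
    for sh in series.shells:
        hit = sh.index in indices or any(
            lo < sh.s_mid <= hi for lo, hi in intervals)
        if hit and not sh.excluded:
            sh = replace(sh, excluded=True, reason="user")
        new_shells.append(sh)
    return replace(series, shells=tuple(new_shells))


# --------------------------------------------------------------------------
# CSV interchange
# --------------------------------------------------------------------------

_CSV_COLUMNS = ["index", "s_lo", "s_hi", "s_mid", "n_obs", "mean_I",
                "sum_f_sq", "S", "excluded", "reason"]


def series_to_frame(series: ShellSeries) -> pd.DataFrame:
    rows = [{
        "index": sh.index, "s_lo": sh.s_lo, "s_hi": sh.s_hi,
        "s_mid": sh.s_mid, "n_obs": sh.n_obs, "mean_I": sh.mean_I,
        "sum_f_sq": sh.sum_f_sq, "S": sh.S, "excluded": sh.excluded,
        "reason": sh.reason or "",
    } for sh in series.shells]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def series_to_csv(series: ShellSeries, path) -> None:
    series_to_frame(series).to_csv(path, index=False)


def series_from_csv(path, composition=None) -> ShellSeries:
    """Read a shell table written by :func:`series_to_csv`."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - {"reason"} - set(df.columns)
    if missing:
        raise ValueError(f"shell table missing columns: {sorted(missing)}")
    shells = []
    for _, row in df.iterrows():
        reason = row.get("reason")
        reason = None if (pd.isna(reason) or reason == "") else str(reason)
        shells.append(ResolutionShell(
            int(row["index"]), float(row["s_lo"]), float(row["s_hi"]),
            float(row["s_mid"]), int(row["n_obs"]),
            None if pd.isna(row["mean_I"]) else float(row["mean_I"]),
            float(row["sum_f_sq"]),
            None if pd.isna(row["S"]) else float(row["S"]),
            bool(row["excluded"]), reason))
    if not shells:
        raise ValueError("empty shell table")
    width = shells[0].s_hi - shells[0].s_lo
    s_range = (shells[0].s_lo, shells[-1].s_hi)
    return ShellSeries(tuple(shells), width, s_range, composition)
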