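"""Reflection records, HKLF4 I/O, resolution geometry and unique-reflection
enumeration.

Resolution is expressed throughout as ``s = sin(theta)/lambda = 1/(2d)`` in
1/Angstrom, computed from the reciprocal metric tensor of the unit cell.
Symmetry support is deliberately small: a handful of space groups common for
molecular crystals ship with their Laue class and systematic-absence rules;
any other group can be supplied as a Laue class plus user absence rules.
Equivalent reflections are merged under the Laue group (Friedel pairs always
merged), with the lexicographically greatest index triple as the canonical
orbit representative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CellParameters",
    "SpaceGroupSetting",
    "Reflection",
    "get_space_group",
    "resolution_s",
    "read_hklf4",
    "write_hklf4",
    "enumerate_unique_reflections",
    "coverage",
    "canonical_hkl",
]


# --------------------------------------------------------------------------
# Unit cell geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CellParameters:
    """Unit-cell lengths (A) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if np.linalg.det(self.metric_tensor()) <= 0:
            raise ValueError("cell metric tensor is not positive definite")

    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric tensor G (A^2)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        return np.array([
            [a * a, a * b * cg, a * c * cb],
            [a * b * cg, b * b, b * c * ca],
            [a * c * cb, b * c * ca, c * c],
        ])

    def reciprocal_metric_tensor(self) -> np.ndarray:
        """Reciprocal metric tensor G* = G^-1 (1/A^2)."""
        return np.linalg.inv(self.metric_tensor())


def resolution_s(hkl, cell: CellParameters):
    """Resolution ``s = sin(theta)/lambda = 1/(2d)`` in 1/A.

    ``hkl`` may be one triple or an (N, 3) array; the result is a float or an
    (N,) array.  Invariant under hkl -> -hkl.
    """
    g_star = cell.reciprocal_metric_tensor()
    h = np.asarray(hkl, dtype=float)
    s = 0.5 * np.sqrt(np.einsum("...i,ij,...j->...", h, g_star, h))
    return float(s) if s.ndim == 0 else s


# --------------------------------------------------------------------------
# Space groups: Laue classes, absence rules
# --------------------------------------------------------------------------

def _closure(generators: list[np.ndarray]) -> np.ndarray:
    """Close a set of integer 3x3 matrices under multiplication."""
    ops = {tuple(np.eye(3, dtype=int).ravel())}
    frontier = [np.eye(3, dtype=int)]
    gens = [np.asarray(g, dtype=int) for g in generators]
    while frontier:
        m = frontier.pop()
        for g in gens:
            p = g @ m
            key = tuple(p.ravel())
            if key not in ops:
                ops.add(key)
                frontier.append(p)
    return np.array([np.array(o, dtype=int).reshape(3, 3) for o in sorted(ops)])


_INV = -np.eye(3, dtype=int)
_LAUE_GENERATORS: dict[str, list] = {
    # rotational generators; the inversion (Friedel) is always added
    "-1": [],
    "2/m": [[[-1, 0, 0], [0, 1, 0], [0, 0, -1]]],          # b-unique
    "mmm": [[[-1, 0, 0], [0, -1, 0], [0, 0, 1]],
            [[-1, 0, 0], [0, 1, 0], [0, 0, -1]]],
    "4/m": [[[0, -1, 0], [1, 0, 0], [0, 0, 1]]],
    "4/mmm": [[[0, -1, 0], [1, 0, 0], [0, 0, 1]],
              [[1, 0, 0], [0, -1, 0], [0, 0, -1]]],
    "-3": [[[0, 1, 0], [-1, -1, 0], [0, 0, 1]]],
    "-3m": [[[0, 1, 0], [-1, -1, 0], [0, 0, 1]],
            [[0, 1, 0], [1, 0, 0], [0, 0, -1]]],
    "6/m": [[[1, 1, 0], [-1, 0, 0], [0, 0, 1]]],
    "6/mmm": [[[1, 1, 0], [-1, 0, 0], [0, 0, 1]],
              [[0, 1, 0], [1, 0, 0], [0, 0, -1]]],
    "m-3": [[[0, 0, 1], [1, 0, 0], [0, 1, 0]],
            [[-1, 0, 0], [0, -1, 0], [0, 0, 1]],
            [[-1, 0, 0], [0, 1, 0], [0, 0, -1]]],
    "m-3m": [[[0, 0, 1], [1, 0, 0], [0, 1, 0]],
             [[0, -1, 0], [1, 0, 0], [0, 0, 1]],
             [[1, 0, 0], [0, -1, 0], [0, 0, -1]]],
}


def laue_operations(laue_class: str) -> np.ndarray:
    """All rotation matrices of a Laue group acting on (h, k, l) columns.

    The inversion is always included, so Friedel mates fall in one orbit.
    """
    try:
        gens = list(_LAUE_GENERATORS[laue_class])
    except KeyError:
        raise ValueError(
            f"unknown Laue class {laue_class!r}; "
            f"choose one of {sorted(_LAUE_GENERATORS)}"
        ) from None
    return _closure([np.asarray(g) for g in gens] + [_INV])


#: An absence rule is (condition, forbidden): both Python expressions over
#: integers h, k, l.  A reflection matching ``condition`` is systematically
#: absent when ``forbidden`` evaluates true.
AbsenceRule = tuple[str, str]

_EVAL_NAMES = {"__builtins__": {}}


def _rule_hits(rule: AbsenceRule, h: int, k: int, l: int) -> bool:
    env = {"h": h, "k": k, "l": l}
    cond, forb = rule
    return bool(eval(cond, _EVAL_NAMES, env)) and bool(eval(forb, _EVAL_NAMES, env))


@dataclass(frozen=True)
class SpaceGroupSetting:
    """Space-group information needed for intensity statistics.

    Only the Laue class (for merging), the centrosymmetric flag (for the
    intensity distribution) and the systematic-absence rules matter here;
    full symmetry operations are out of scope.
    """

    symbol: str
    centrosymmetric: bool
    laue_class: str
    absence_rules: tuple[AbsenceRule, ...] = ()

    def is_absent(self, hkl) -> bool:
        h, k, l = (int(x) for x in hkl)
        return any(_rule_hits(r, h, k, l) for r in self.absence_rules)

    def operations(self) -> np.ndarray:
        return laue_operations(self.laue_class)


_SHIPPED: dict[str, SpaceGroupSetting] = {}


def _register(sg: SpaceGroupSetting) -> None:
    _SHIPPED[sg.symbol.replace(" ", "").lower()] = sg


_register(SpaceGroupSetting("P1", False, "-1"))
_register(SpaceGroupSetting("P-1", True, "-1"))
_register(SpaceGroupSetting("P21", False, "2/m", (
    ("h == 0 and l == 0", "k % 2 != 0"),
)))
_register(SpaceGroupSetting("P21/c", True, "2/m", (
    ("h == 0 and l == 0", "k % 2 != 0"),
    ("k == 0", "l % 2 != 0"),
)))
_register(SpaceGroupSetting("P21/n", True, "2/m", (
    ("h == 0 and l == 0", "k % 2 != 0"),
    ("k == 0", "(h + l) % 2 != 0"),
)))
_register(SpaceGroupSetting("C2/c", True, "2/m", (
    ("True", "(h + k) % 2 != 0"),
    ("k == 0", "l % 2 != 0"),
)))
_register(SpaceGroupSetting("Pbca", True, "mmm", (
    ("h == 0", "k % 2 != 0"),
    ("k == 0", "l % 2 != 0"),
    ("l == 0", "h % 2 != 0"),
)))


def get_space_group(symbol: str) -> SpaceGroupSetting:
    """Look up a shipped space-group setting by Hermann-Mauguin symbol."""
    key = symbol.replace(" ", "").lower()
    try:
        return _SHIPPED[key]
    except KeyError:
        raise ValueError(
            f"space group {symbol!r} is not shipped; supply laue_class, "
            f"centrosymmetric flag and absence rules explicitly "
            f"(shipped: {sorted(sg.symbol for sg in _SHIPPED.values())})"
        ) from None


# --------------------------------------------------------------------------
# Reflection records and HKLF4 I/O
# --------------------------------------------------------------------------

@dataclass
class Reflection:
    """One measured intensity record; ``s`` is attached from the cell."""

    h: int
    k: int
    l: int
    intensity: float
    sigma: float | None = None
    s: float | None = None

    @property
    def hkl(self) -> tuple[int, int, int]:
        return (self.h, self.k, self.l)


def attach_resolution(reflections: Iterable[Reflection],
                      cell: CellParameters) -> list[Reflection]:
    """Return reflections with ``s`` computed from the cell metrics."""
    refl = list(reflections)
    if not refl:
        return []
    hkl = np.array([r.hkl for r in refl])
    s = resolution_s(hkl, cell)
    return [Reflection(r.h, r.k, r.l, r.intensity, r.sigma, float(si))
            for r, si in zip(refl, s)]


def _parse_fixed(line: str, lineno: int) -> tuple[int, int, int, float, float]:
    try:
        h = int(line[0:4])
        k = int(line[4:8])
        l = int(line[8:12])
        i = float(line[12:20])
        sig = float(line[20:28])
    except ValueError as exc:
        raise ValueError(f"HKLF4 line {lineno}: malformed fixed-width field "
                         f"({line!r})") from exc
    return h, k, l, i, sig


def read_hklf4(source) -> list[Reflection]:
    """Read a SHELX HKLF4 reflection file (format 3I4,2F8.2).

    ``source`` is a path or an open text stream.  Reading stops at the
    all-zero terminator record if present; blank or short trailing lines are
    ignored.  A trailing batch-number column is ignored.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    out: list[Reflection] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if len(line.rstrip()) < 28:
            if line.strip():
                raise ValueError(
                    f"HKLF4 line {lineno}: line too short for 3I4,2F8.2 "
                    f"({line!r})")
            continue
        h, k, l, i, sig = _parse_fixed(line, lineno)
        if h == 0 and k == 0 and l == 0 and i == 0.0 and sig == 0.0:
            break  # SHELX terminator record
        out.append(Reflection(h, k, l, i, sig))
    return out


def write_hklf4(reflections: Iterable[Reflection]) -> str:
    """Serialize reflections as HKLF4 text (3I4,2F8.2 plus terminator)."""
    lines = []
    for r in reflections:
        for idx in (r.h, r.k, r.l):
            if not -999 <= idx <= 9999:
                raise ValueError(f"index overflows I4 field in record {r}")
        sig = 0.0 if r.sigma is None else r.sigma
        for val in (r.intensity, sig):
            if not -99999.99 <= val <= 999999.99:
                raise ValueError(f"value {val} overflows F8.2 field "
                                 f"in record {r}")
        lines.append(f"{r.h:4d}{r.k:4d}{r.l:4d}{r.intensity:8.2f}{sig:8.2f}")
    lines.append(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Unique-reflection enumeration and coverage
# --------------------------------------------------------------------------

def _canonical_images(hkl: np.ndarray, ops: np.ndarray) -> np.ndarray:
    """Lexicographically greatest Laue image of each row of ``hkl``."""
    # images[n, m, :] = ops[m] @ hkl[n]
    images = np.einsum("mij,nj->nmi", ops, hkl)
    span = int(np.abs(images).max()) + 1
    base = 2 * span + 1
    key = ((images[..., 0] + span) * base + (images[..., 1] + span)) * base \
        + (images[..., 2] + span)
    best = np.argmax(key, axis=1)
    return images[np.arange(len(hkl)), best]


def canonical_hkl(hkl, sg: SpaceGroupSetting) -> np.ndarray:
    """Canonical (lexicographically greatest) Laue-orbit representatives."""
    arr = np.atleast_2d(np.asarray(hkl, dtype=int))
    return _canonical_images(arr, sg.operations())


def enumerate_unique_reflections(cell: CellParameters, sg: SpaceGroupSetting,
                                 s_min: float, s_max: float) -> np.ndarray:
    """All symmetry-unique reflections with ``s_min < s <= s_max``.

    Systematic absences are removed and Laue-equivalent reflections (Friedel
    pairs included) merged to their canonical representative.  Returns an
    (N, 3) integer array sorted lexicographically.
    """
    if not 0 <= s_min < s_max:
        raise ValueError("require 0 <= s_min < s_max")
    g_star = cell.reciprocal_metric_tensor()
    limits = [int(math.ceil(2 * s_max / math.sqrt(g_star[i, i])))
              for i in range(3)]
    axes = [np.arange(-m, m + 1) for m in limits]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    s = 0.5 * np.sqrt(np.einsum("ni,ij,nj->n", grid, g_star, grid))
    mask = (s > s_min) & (s <= s_max)
    hkl = grid[mask]
    if len(hkl) == 0:
        return np.empty((0, 3), dtype=int)
    if sg.absence_rules:
        present = np.array([not sg.is_absent(t) for t in hkl])
        hkl = hkl[present]
    if len(hkl) == 0:
        return np.empty((0, 3), dtype=int)
    canon = _canonical_images(hkl, sg.operations())
    uniq = np.unique(canon, axis=0)
    return uniq


def coverage(observed: Sequence[Reflection], cell: CellParameters,
             sg: SpaceGroupSetting, s_min: float, s_max: float) -> float:
    """Fraction of expected unique reflections present in ``observed``.

    Observed records are mapped to canonical Laue-orbit representatives and
    de-duplicated; records outside ``(s_min, s_max]`` are ignored (their
    count is logged).
    """
    expected = enumerate_unique_reflections(cell, sg, s_min, s_max)
    if len(expected) == 0:
        raise ValueError("no expected reflections in the requested s range")
    obs = list(observed)
    if not obs:
        return 0.0
    hkl = np.array([r.hkl for r in obs])
    s = resolution_s(hkl, cell)
    in_range = (s > s_min) & (s <= s_max)
    n_outside = int((~in_range).sum())
    if n_outside:
        logger.info("coverage: ignoring %d observed reflections outside "
                    "(%g, %g]", n_outside, s_min, s_max)
    hkl = hkl[in_range]
    if len(hkl) == 0:
        return 0.0
    canon = np.unique(_canonical_images(hkl, sg.operations()), axis=0)
    expected_keys = {tuple(row) for row in expected}
    n_hit = sum(tuple(row) in expected_keys for row in canon)
    return n_hit / len(expected)
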