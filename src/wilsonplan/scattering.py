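"""Atomic scattering factors and unit-cell composition sums.

X-ray atomic form factors are represented by the standard four-Gaussian
parameterization

    f(s) = sum_{i=1..4} a_i * exp(-b_i * s^2) + c,

with ``s = sin(theta)/lambda`` in 1/Angstrom.  At ``s = 0`` the form factor
of a neutral atom equals its atomic number (number of electrons).  A small
coefficient table for the light elements common in organic crystals
(H, C, N, O, S, Cl) ships with the package; users may override or extend it
with their own whitespace-delimited table of the same layout.

The composition sum ``sum_j n_j * f_j(s)^2`` over all atoms in the unit cell
is the normalization that turns a mean diffraction intensity into the
dimensionless Wilson ratio ``S``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "ScatteringCoefficients",
    "UnknownElementError",
    "load_coefficient_table",
    "default_coefficient_table",
    "form_factor",
    "sum_f_squared",
    "parse_formula",
]

#: Atomic numbers used to validate f(0) for shipped/user tables.
ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "I": 53,
}

#: Tolerance on |f(0) - Z| for neutral-atom coefficient sets.
F0_TOLERANCE = 0.05


class UnknownElementError(KeyError):
    """Raised when no scattering coefficients are available for an element."""

    def __init__(self, element: str):
        super().__init__(element)
        self.element = element

    def __str__(self) -> str:  # KeyError quotes its arg; give a real message
        return f"no scattering coefficients for element {self.element!r}"


@dataclass(frozen=True)
class ScatteringCoefficients:
    """Four-Gaussian form-factor coefficients for one element.

    ``a`` are amplitudes in electrons, ``b`` widths in A^2, ``c`` the
    constant term in electrons.
    """

    element: str
    a: tuple[float, float, float, float]
    b: tuple[float, float, float, float]
    c: float

    def __post_init__(self) -> None:
        if len(self.a) != 4 or len(self.b) != 4:
            raise ValueError(
                f"{self.element}: exactly 4 (a, b) Gaussian pairs required"
            )
        if any(b < 0 for b in self.b):
            raise ValueError(f"{self.element}: Gaussian widths b must be >= 0")
        z = ATOMIC_NUMBERS.get(self.element)
        if z is not None and abs(self.f0 - z) > F0_TOLERANCE:
            raise ValueError(
                f"{self.element}: f(0) = {self.f0:.4f} deviates from atomic "
                f"number {z} by more than {F0_TOLERANCE}"
            )

    @property
    def f0(self) -> float:
        """Form factor at s = 0 (the electron count for neutral atoms)."""
        return sum(self.a) + self.c

    def __call__(self, s):
        """Evaluate f(s); ``s`` may be a scalar or array (1/A)."""
        s2 = np.square(np.asarray(s, dtype=float))
        a = np.asarray(self.a)
        b = np.asarray(self.b)
        f = np.sum(a * np.exp(-b * s2[..., None]), axis=-1) + self.c
        return f if f.ndim else float(f)


def load_coefficient_table(path) -> dict[str, ScatteringCoefficients]:
    """Read a whitespace-delimited coefficient table.

    Columns: element a1 b1 a2 b2 a3 b3 a4 b4 c.  Lines starting with '#'
    are comments.
    """
    table: dict[str, ScatteringCoefficients] = {}
    text = Path(path).read_text() if not hasattr(path, "read") else path.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 10:
            raise ValueError(
                f"coefficient table line {lineno}: expected 10 fields, "
                f"got {len(fields)}"
            )
        el = fields[0]
        vals = [float(x) for x in fields[1:]]
        table[el] = ScatteringCoefficients(
            element=el,
            a=(vals[0], vals[2], vals[4], vals[6]),
            b=(vals[1], vals[3], vals[5], vals[7]),
            c=vals[8],
        )
    return table


_DEFAULT_TABLE: dict[str, ScatteringCoefficients] | None = None


def default_coefficient_table() -> dict[str, ScatteringCoefficients]:
    """The shipped neutral-atom table (H, C, N, O, S, Cl), loaded once."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        ref = importlib.resources.files("wilsonplan").joinpath(
            "data/sfac_coefficients.txt"
        )
        _DEFAULT_TABLE = load_coefficient_table(ref)
    return _DEFAULT_TABLE


def _lookup(element: str, table=None) -> ScatteringCoefficients:
    tab = default_coefficient_table() if table is None else table
    try:
        return tab[element]
    except KeyError:
        raise UnknownElementError(element) from None


def form_factor(element: str, s, table=None):
    """Atomic form factor f(s) in electrons for ``element`` at resolution ``s``.

    ``table`` may be a user-supplied coefficient mapping; by default the
    shipped table is used.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise ValueError("resolution s must be >= 0")
    return _lookup(element, table)(s)


def sum_f_squared(composition: Mapping[str, float], s, table=None):
    """Composition sum ``sum_j n_j * f_j(s)^2`` in electrons^2.

    ``composition`` maps element symbols to per-unit-cell atom counts
    (fractional counts are allowed for partial occupancy).  Linear in the
    counts and strictly decreasing in ``s`` for neutral-atom compositions.
    """
    items = [(el, n) for el, n in composition.items() if n != 0]
    if not items:
        raise ValueError("composition is empty")
    if any(n < 0 for _, n in items):
        raise ValueError("composition counts must be non-negative")
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise ValueError("resolution s must be >= 0")
    total = 0.0
    for el, n in items:
        f = _lookup(el, table)(s)
        total = total + n * np.square(f)
    return total


def parse_formula(formula: str) -> dict[str, float]:
    """Parse a simple chemical formula like ``"C8H28N4O12S4"``.

    Only flat element-count formulas are supported (no parentheses).
    """
    import re

    comp: dict[str, float] = {}
    pos = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*\.?\d*)", formula):
        if m.start() != pos:
            break
        el, num = m.group(1), m.group(2)
        comp[el] = comp.get(el, 0.0) + (float(num) if num else 1.0)
        pos = m.end()
    if pos != len(formula) or not comp:
        raise ValueError(f"cannot parse chemical formula {formula!r}")
    return comp
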