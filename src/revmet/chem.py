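"""Elemental composition arithmetic and adduct mass bookkeeping.

All masses are monoisotopic, in daltons. Compositions are plain
``{element: count}`` dicts so they stay hashable-free and trivially
serializable; helpers here treat them as immutable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping

Composition = Dict[str, int]

# CODATA/NIST monoisotopic atomic masses (most abundant isotope), Da.
MONOISOTOPIC_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

#: Mass of a proton (H minus the electron), the positive-mode charge carrier.
PROTON_MASS = 1.007276

#: Monoisotopic mass of water, used for amide condensation and water loss.
WATER_MASS = 18.010565

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownElementError(ValueError):
    """Raised when a composition references an element outside the mass table."""


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass of an elemental composition, in Da.

    Parameters
    ----------
    formula
        Mapping of element symbol to atom count. An empty mapping has mass 0.

    Raises
    ------
    UnknownElementError
        If a symbol is not in the supported table (C, H, N, O, S, P, Na, K).
    """
    total = 0.0
    for element, count in formula.items():
        try:
            total += MONOISOTOPIC_MASS[element] * count
        except KeyError:
            raise UnknownElementError(
                f"element {element!r} is not in the monoisotopic mass table"
            ) from None
    return total


def parse_formula(text: str) -> Composition:
    """Parse a Hill-order formula string like ``'C6H11NO4'`` into a composition."""
    comp: Composition = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos or not match.group(0):
            break
        element = match.group(1)
        count = int(match.group(2)) if match.group(2) else 1
        comp[element] = comp.get(element, 0) + count
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"malformed formula string: {text!r}")
    return comp


def formula_to_string(formula: Mapping[str, int]) -> str:
    """Render a composition in Hill order (C, H, then alphabetical)."""
    parts = []
    rest = {k: v for k, v in formula.items() if v}
    for element in ("C", "H"):
        if element in rest:
            n = rest.pop(element)
            parts.append(element if n == 1 else f"{element}{n}")
    for element in sorted(rest):
        n = rest[element]
        parts.append(element if n == 1 else f"{element}{n}")
    return "".join(parts)


def combine_formulas(*formulas: Mapping[str, int]) -> Composition:
    """Element-wise sum of compositions."""
    out: Composition = {}
    for formula in formulas:
        for element, count in formula.items():
            out[element] = out.get(element, 0) + count
    return {k: v for k, v in out.items() if v}


def subtract_formula(a: Mapping[str, int], b: Mapping[str, int]) -> Composition:
    """Element-wise difference ``a - b``; raises if any count would go negative."""
    out: Composition = dict(a)
    for element, count in b.items():
        remaining = out.get(element, 0) - count
        if remaining < 0:
            raise ValueError(
                f"cannot subtract {formula_to_string(b)} from {formula_to_string(a)}:"
                f" element {element} would go negative"
            )
        out[element] = remaining
    return {k: v for k, v in out.items() if v}


@dataclass(frozen=True)
class AdductSpec:
    """A positive-mode ion form: name, mass offset from the neutral, charge +1."""

    name: str
    mass_delta: float
    charge: int = 1


# Singly-protonated positive-mode conventions; the electron mass is folded
# into the proton value. Water-loss in-source fragment treated adduct-like.
ADDUCTS: Dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", 1.007276),
    "[M+Na]+": AdductSpec("[M+Na]+", 22.989218),
    "[M+K]+": AdductSpec("[M+K]+", 38.963158),
    "[M+NH4]+": AdductSpec("[M+NH4]+", 18.033823),
    "[M-H2O+H]+": AdductSpec("[M-H2O+H]+", -17.003289),
}

# Short aliases accepted on the command line, e.g. "M+H,M+Na".
_ADDUCT_ALIASES = {
    "M+H": "[M+H]+",
    "M+Na": "[M+Na]+",
    "M+K": "[M+K]+",
    "M+NH4": "[M+NH4]+",
    "M-H2O+H": "[M-H2O+H]+",
}


def get_adduct(name: str) -> AdductSpec:
    """Look up an adduct by canonical name or short alias."""
    key = _ADDUCT_ALIASES.get(name, name)
    try:
        return ADDUCTS[key]
    except KeyError:
        raise ValueError(
            f"unknown adduct {name!r}; known: {sorted(ADDUCTS)}"
        ) from None


def adduct_mz(M: float, adduct: AdductSpec) -> float:
    """m/z of the singly-charged ion of a neutral of monoisotopic mass ``M``."""
    if M <= 0:
        raise ValueError(f"neutral mass must be positive, got {M}")
    return M + adduct.mass_delta


def neutral_mass(mz: float, adduct: AdductSpec) -> float:
    """Invert :func:`adduct_mz`: neutral monoisotopic mass from an ion m/z."""
    return mz - adduct.mass_delta


def ppm_window(mz: float, ppm: float) -> float:
    """Half-width in Da of a ±ppm window around ``mz``."""
    return mz * ppm / 1e6


def parse_adduct_list(spec: str) -> list[AdductSpec]:
    """Parse a comma-separated adduct list such as ``'M+H,M+Na,M+NH4'``."""
    return [get_adduct(tok.strip()) for tok in spec.split(",") if tok.strip()]


def enumerate_subformulas(
    parent: Mapping[str, int], max_mass: float | None = None
) -> "tuple":
    """All element-wise sub-compositions of ``parent`` with their masses.

    Returns ``(masses, comps)`` where ``masses`` is a sorted numpy array and
    ``comps`` is the matching list of compositions. Enumeration is an exact
    element-count grid walk with early mass pruning; parents in this pipeline
    are at most ~C60 so the grid stays small.
    """
    import numpy as np

    elements = [e for e in parent if parent[e] > 0]
    masses = [0.0]
    comps: list[Composition] = [{}]
    for element in elements:
        try:
            unit = MONOISOTOPIC_MASS[element]
        except KeyError:
            raise UnknownElementError(element) from None
        new_masses: list[float] = []
        new_comps: list[Composition] = []
        for mass, comp in zip(masses, comps):
            for n in range(parent[element] + 1):
                m = mass + unit * n
                if max_mass is not None and m > max_mass + 1.0:
                    break
                c = dict(comp)
                if n:
                    c[element] = n
                new_masses.append(m)
                new_comps.append(c)
        masses, comps = new_masses, new_comps
    order = np.argsort(masses, kind="stable")
    return np.asarray(masses)[order], [comps[i] for i in order]
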