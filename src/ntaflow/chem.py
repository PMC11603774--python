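"""Mass-spectrometry chemistry helpers: monoisotopic masses and ppm arithmetic."""

from __future__ import annotations

import math
import re

from scipy import constants as _const

#: Monoisotopic masses (Da) of elements commonly seen in small-molecule formulas.
MONOISOTOPIC_MASSES: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Na": 22.98976928,
    "K": 38.9637069,
    "Cl": 34.96885271,
    "F": 18.99840322,
    "Br": 78.9183376,
    "I": 126.904468,
    "Si": 27.9769265327,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def truncate(value: float, decimals: int) -> float:
    """Truncate (not round) ``value`` to ``decimals`` decimal places."""
    factor = 10.0 ** decimals
    return math.floor(value * factor) / factor


def hydrogen_monoisotopic_mass() -> float:
    """Monoisotopic mass of a hydrogen atom in unified atomic mass units.

    Computed from CODATA proton and electron masses relative to the atomic
    mass constant. The ~13.6 eV electron binding energy (~1.5e-8 u) is far
    below the five-decimal precision used anywhere in this package.
    """
    m_p = _const.proton_mass
    m_e = _const.electron_mass
    u = _const.atomic_mass
    return (m_p + m_e) / u


#: The hydrogen mass applied when neutralizing [M+H]+ / [M-H]- m/z values,
#: truncated to five decimals (the precision at which alignment software
#: reports it).
HYDROGEN_MASS: float = truncate(hydrogen_monoisotopic_mass(), 5)


def formula_monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass of an elemental composition string like ``C6H12O6``.

    Raises ``ValueError`` on unknown element symbols or a string that does
    not fully tokenize into element/count pairs.
    """
    if not formula:
        raise ValueError("empty formula")
    pos = 0
    total = 0.0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"unparseable formula {formula!r} at offset {pos}")
        if not match.group(0):
            break
        element, count = match.group(1), match.group(2)
        if element not in MONOISOTOPIC_MASSES:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        total += MONOISOTOPIC_MASSES[element] * (int(count) if count else 1)
        pos = match.end()
    if pos != len(formula):
        raise ValueError(f"unparseable formula {formula!r} at offset {pos}")
    return total


def ppm_error(observed: float, reference: float) -> float:
    """Signed mass error of ``observed`` against ``reference`` in ppm."""
    return (observed - reference) / reference * 1e6


def ppm_difference(a: float, b: float) -> float:
    """Absolute ppm difference of two masses relative to their mean."""
    mean = 0.5 * (a + b)
    return abs(a - b) / mean * 1e6
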