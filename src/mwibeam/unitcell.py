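"""Lumped-circuit closed forms for a complementary split-ring resonator unit cell.

The metasurface patch that loads the imaging antennas behaves, to first
order, as a passive LC resonator: the split gap contributes capacitance, the
metal loop inductance.  These are the standard transmission-line design
formulas:

    f = 1 / (pi * sqrt(L * C))                       resonant frequency
    C = eps0 * eps_r * A / d                         parallel-plate split gap
    L(nH) = 2e-4 * l * [ln(l/(w+t)) + 1.193
                        + 0.02235 (w+t)/l] * K_g     microstrip inductance

with the microstrip dimensions l, w, t in micrometers (the convention under
which the 2e-4 prefactor yields nanohenries) and the ground correction
K_g = 0.57 - 0.145 ln(w'/h').  One source defines w' as the substrate
*thickness* and h' as the substrate *width* — the reverse of the usual
transmission-line convention; both orderings are exposed via ``convention``
(default ``"as_printed"``) rather than silently corrected.
"""

from __future__ import annotations

import warnings

import numpy as np

from .simulate import EPS0


def resonant_frequency(L: float, C: float) -> float:
    """LC resonance f = 1 / (pi sqrt(LC)); L in henries, C in farads, f in Hz."""
    if L <= 0 or C <= 0:
        raise ValueError(f"L and C must be > 0, got L={L}, C={C}")
    return 1.0 / (np.pi * np.sqrt(L * C))


def split_capacitance(eps_r: float, A: float, d: float) -> float:
    """Parallel-plate capacitance of the split gap: eps0 eps_r A / d (farads).

    ``A`` is the split area in m^2 and ``d`` the split length in m; linear in
    ``A`` and ``eps_r``, inverse in ``d``.
    """
    if A <= 0 or d <= 0:
        raise ValueError(f"A and d must be > 0, got A={A}, d={d}")
    if eps_r < 1:
        raise ValueError(f"eps_r must be >= 1, got {eps_r}")
    return EPS0 * eps_r * A / d


def microstrip_kg(w_sub_mm: float, h_sub_mm: float,
                  convention: str = "as_printed") -> float:
    """Ground-plane correction factor K_g = 0.57 - 0.145 ln(w'/h').

    ``convention="as_printed"`` uses w' = substrate thickness (``w_sub_mm``)
    and h' = substrate width (``h_sub_mm``); ``"literature"`` swaps the ratio.
    """
    if w_sub_mm <= 0 or h_sub_mm <= 0:
        raise ValueError("substrate dimensions must be > 0")
    if convention == "as_printed":
        ratio = w_sub_mm / h_sub_mm
    elif convention == "literature":
        ratio = h_sub_mm / w_sub_mm
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return 0.57 - 0.145 * np.log(ratio)


def microstrip_inductance(
    l_mm: float,
    w_mm: float,
    t_mm: float,
    w_sub_mm: float | None = None,
    h_sub_mm: float | None = None,
    kg: float | None = None,
    convention: str = "as_printed",
) -> float:
    """Equivalent inductance of a microstrip segment, in nanohenries.

    Dimensions are passed in millimeters and converted to the micrometer
    convention internally.  Either a precomputed ``kg`` or the substrate
    dimensions (from which K_g is derived) must be supplied.  Non-physical
    regimes — a non-positive K_g, or a strip so short that the bracketed term
    changes sign — emit a warning but still return the formula value, flagged
    for the caller to inspect.
    """
    if l_mm <= 0 or w_mm <= 0 or t_mm <= 0:
        raise ValueError("l, w, t must all be > 0")
    if kg is None:
        if w_sub_mm is None or h_sub_mm is None:
            raise ValueError("provide either kg or both substrate dimensions")
        kg = microstrip_kg(w_sub_mm, h_sub_mm, convention=convention)
    l_um, w_um, t_um = 1e3 * l_mm, 1e3 * w_mm, 1e3 * t_mm
    bracket = np.log(l_um / (w_um + t_um)) + 1.193 + 0.02235 * (w_um + t_um) / l_um
    if bracket <= 0:
        warnings.warn(
            "microstrip length is too short relative to its cross-section: "
            "the log term changes sign and the formula leaves its validity range",
            RuntimeWarning, stacklevel=2,
        )
    if kg <= 0:
        warnings.warn(
            f"non-physical ground correction K_g = {kg:.4g} <= 0 for this geometry",
            RuntimeWarning, stacklevel=2,
        )
    return 2e-4 * l_um * bracket * kg
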