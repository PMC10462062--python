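"""Filament stoichiometry and load-sharing helpers.

F-actin is a two-start helix whose subunits on adjacent strands are
offset by a 2.73 nm rise, so a filament of length L micrometres contains
1000*L/2.73 subunits.  With one trackable barbed end per filament, the
filament-end concentration of a polymerization reaction is the G-actin
concentration divided by the subunits per filament.
"""

from __future__ import annotations

import math

from .core import ParameterError

__all__ = [
    "RISE_PER_SUBUNIT_NM",
    "subunits_from_length",
    "end_concentration",
    "per_filament_load",
    "round_sig",
]

RISE_PER_SUBUNIT_NM = 2.73


def round_sig(value: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return round(value, -exponent + sig - 1)


def subunits_from_length(
    length_um: float,
    rise_nm: float = RISE_PER_SUBUNIT_NM,
    rounding: str = "none",
) -> float:
    """Number of actin subunits in a filament of the given length.

    count = 1000 * length_um / rise_nm.  ``rounding`` is one of
    ``"none"`` (exact real count), ``"nearest"`` (nearest integer) or
    ``"sig1"`` (one significant figure, the convention behind quoted
    round numbers like "approximately 3,000 subunits" for a median
    8.6 um filament).
    """
    if length_um <= 0 or rise_nm <= 0:
        raise ParameterError("length and rise must be positive")
    count = 1000.0 * length_um / rise_nm
    if rounding == "none":
        return count
    if rounding == "nearest":
        return float(round(count))
    if rounding == "sig1":
        return round_sig(count, 1)
    raise ParameterError(f"unknown rounding mode {rounding!r}")


def end_concentration(
    total_actin_conc: float, subunits_per_filament: float
) -> float:
    """Barbed-end concentration given total actin and filament size.

    conc = total_actin_conc / subunits_per_filament, assuming one
    trackable barbed end per filament (no annealing or severing
    correction).  Units follow ``total_actin_conc`` (e.g. molar in,
    molar out).
    """
    if total_actin_conc <= 0 or subunits_per_filament <= 0:
        raise ParameterError("concentration and subunit count must be positive")
    return total_actin_conc / subunits_per_filament


def per_filament_load(F_total: float, n: float) -> float:
    """Load borne by each filament of an n-filament bundle under F_total.

    Equal load sharing: F_total / n, strictly decreasing in n — the
    quantity hypothesized to drive enrichment of force-activated
    binders on small bundles.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if F_total < 0:
        raise ParameterError("F_total must be >= 0")
    return F_total / n
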