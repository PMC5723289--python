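"""Genetic map functions and the selfed-RIL recombination correction.

Two conventions for recombination fractions coexist in RIL mapping and are
kept strictly separate here:

* ``r`` — the per-meiosis recombination fraction between two loci;
* ``R`` — the fraction of recombinant *lines* observed in a fully selfed
  RIL population.  Repeated rounds of meiosis during inbreeding inflate
  the observed fraction to the Haldane-Waddington equilibrium
  ``R = 2r / (1 + 2r)``.

Map distances are in centimorgans.  The Kosambi function
``d = 25 * ln((1+2r)/(1-2r))`` allows for partial crossover interference;
Haldane ``d = -50 * ln(1-2r)`` assumes none.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "kosambi_cm",
    "kosambi_r",
    "haldane_cm",
    "haldane_r",
    "ril_observed",
    "ril_meiotic",
    "map_function_convert",
]


def _check_r(r):
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5) (unlinked loci have no finite map distance)")
    return r


def _check_d(d):
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    return d


def kosambi_cm(r):
    """Kosambi map distance (cM) for meiotic recombination fraction ``r``."""
    r = _check_r(r)
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_r(d_cm):
    """Inverse Kosambi: meiotic recombination fraction for a distance in cM."""
    d = _check_d(d_cm)
    return 0.5 * np.tanh(d / 50.0)


def haldane_cm(r):
    """Haldane (no-interference) map distance in cM."""
    r = _check_r(r)
    return -50.0 * np.log(1.0 - 2.0 * r)


def haldane_r(d_cm):
    d = _check_d(d_cm)
    return 0.5 * (1.0 - np.exp(-d / 50.0))


def ril_observed(r):
    """Observed RIL recombination fraction R = 2r/(1+2r) for meiotic ``r``."""
    r = _check_r(r)
    return 2.0 * r / (1.0 + 2.0 * r)


def ril_meiotic(R):
    """Meiotic fraction r = R/(2(1-R)) from the observed RIL fraction."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0) or np.any(R >= 0.5):
        raise ValueError("observed RIL fraction must lie in [0, 0.5)")
    return R / (2.0 * (1.0 - R))


_MAP_CM = {"kosambi": kosambi_cm, "haldane": haldane_cm}
_MAP_R = {"kosambi": kosambi_r, "haldane": haldane_r}


def map_function_convert(value, direction: str, function: str = "kosambi"):
    """Convert between r, d (cM) and the observed RIL fraction R.

    ``direction`` is one of ``"r_to_cM"``, ``"cM_to_r"``, ``"r_to_R"``,
    ``"R_to_r"``.  ``function`` selects the map function for the distance
    conversions and is ignored for the RIL correction.
    """
    if function not in _MAP_CM:
        raise ValueError(f"unknown map function {function!r}")
    if direction == "r_to_cM":
        return _MAP_CM[function](value)
    if direction == "cM_to_r":
        return _MAP_R[function](value)
    if direction == "r_to_R":
        return ril_observed(value)
    if direction == "R_to_r":
        return ril_meiotic(value)
    raise ValueError(f"unknown direction {direction!r}")
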