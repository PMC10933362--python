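"""Published cultivar-specific clr nutrient standards for southern-Brazil onion.

Reference ranges for four onion cultivars ('Caeté', 'Mulata', 'Omega',
'SCS373 Valessul') derived from nutritionally balanced specimens yielding
more than 50 Mg bulbs/ha in Santa Catarina fertilizer trials: per-part clr
confidence intervals at P = 0.01 and the back-transformed centroid
concentrations (g/kg).  These intervals seed the synthetic generator's
cultivar ionome centres and serve as fixed points for the back-transform:
closing the exponentiated interval midpoints to 1000 g/kg reproduces the
centroid column.

The published Valessul K lower bound is typeset "3/234"; the interval parser
reads a slash in place of the decimal point (with a warning) and the stored
value is the corrected 3.234.
"""

from __future__ import annotations

import re
import warnings

import numpy as np

from .compositions import DEFAULT_KAPPA, PARTS, ClrVector, Composition, clr_back_transform

__all__ = [
    "REFERENCE_CULTIVARS",
    "CLR_INTERVALS",
    "CENTROIDS",
    "QUARTILES",
    "parse_clr_interval",
    "reference_clr_midpoints",
    "reference_centroid",
]

REFERENCE_CULTIVARS: tuple[str, ...] = ("Caete", "Mulata", "Omega", "SCS373 Valessul")

#: Per-cultivar clr confidence intervals (P = 0.01), part order N..Fe, Fv last.
CLR_INTERVALS: dict[str, list[tuple[float, float]]] = {
    "Caete": [
        (2.859, 2.935), (0.854, 1.008), (2.685, 2.749), (1.748, 1.813),
        (0.644, 0.712), (1.449, 1.575), (-3.859, -3.726), (-3.951, -3.850),
        (-3.332, -3.241), (-2.794, -2.366), (-3.364, -3.138), (6.259, 6.329),
    ],
    "Mulata": [
        (3.334, 3.418), (0.995, 1.106), (3.370, 3.504), (2.560, 2.725),
        (0.724, 0.898), (0.823, 1.023), (-3.815, -3.611), (-4.862, -4.406),
        (-3.681, -3.395), (-2.825, -2.655), (-4.362, -3.983), (6.522, 6.592),
    ],
    "Omega": [
        (3.109, 3.177), (1.073, 1.137), (3.265, 3.341), (2.624, 2.726),
        (0.917, 1.017), (0.912, 1.013), (-3.619, -3.536), (-5.067, -4.832),
        (-3.628, -3.464), (-2.913, -2.813), (-4.040, -3.842), (6.701, 6.743),
    ],
    # K lower bound published as "3/234"; corrected to 3.234 (see module docstring).
    "SCS373 Valessul": [
        (3.172, 3.262), (1.864, 1.913), (3.234, 3.314), (2.011, 2.117),
        (0.864, 0.919), (1.369, 1.475), (-4.063, -3.973), (-4.687, -4.398),
        (-3.873, -3.784), (-4.089, -3.954), (-3.147, -3.058), (6.722, 6.789),
    ],
}

#: Published centroid concentrations, g/kg, same part order (Fv last).
CENTROIDS: dict[str, list[float]] = {
    "Caete": [30.7, 4.3, 25.7, 10.1, 3.3, 7.7, 0.038, 0.034, 0.063, 0.129, 0.066, 917.9],
    "Mulata": [37.2, 3.6, 39.5, 17.9, 2.9, 3.2, 0.031, 0.012, 0.037, 0.082, 0.020, 895.5],
    "Omega": [25.6, 3.3, 30.1, 16.1, 2.9, 2.9, 0.031, 0.008, 0.032, 0.063, 0.021, 918.9],
    "SCS373 Valessul": [26.8, 7.1, 28.4, 8.5, 2.6, 4.4, 0.019, 0.011, 0.023, 0.019, 0.048, 922.1],
}

#: Published lower/upper quartiles of raw concentrations (g/kg), nutrients only
#: (no Fv), for balanced specimens above the 50 Mg/ha cutoff.
QUARTILES: dict[str, dict[str, tuple[float, float]]] = {
    "Caete": {
        "N": (29.4, 33.4), "P": (3.9, 4.7), "K": (23.4, 28.3), "Ca": (9.2, 10.8),
        "Mg": (3.0, 3.7), "S": (7.0, 9.0), "B": (0.030, 0.047), "Cu": (0.030, 0.040),
        "Zn": (0.053, 0.073), "Mn": (0.078, 0.154), "Fe": (0.058, 0.084),
    },
    "Mulata": {
        "N": (35.4, 38.7), "P": (3.4, 4.1), "K": (38.0, 44.8), "Ca": (15.3, 21.3),
        "Mg": (2.5, 3.3), "S": (2.6, 4.2), "B": (0.024, 0.040), "Cu": (0.010, 0.019),
        "Zn": (0.027, 0.052), "Mn": (0.069, 0.098), "Fe": (0.013, 0.028),
    },
    "Omega": {
        "N": (22.4, 29.1), "P": (3.0, 3.7), "K": (25.9, 34.4), "Ca": (13.5, 19.6),
        "Mg": (2.5, 3.6), "S": (2.4, 3.5), "B": (0.026, 0.036), "Cu": (0.005, 0.014),
        "Zn": (0.022, 0.047), "Mn": (0.051, 0.079), "Fe": (0.016, 0.032),
    },
    "SCS373 Valessul": {
        "N": (23.1, 29.2), "P": (6.3, 7.8), "K": (26.9, 29.6), "Ca": (6.6, 10.6),
        "Mg": (2.4, 2.9), "S": (4.0, 4.8), "B": (0.018, 0.021), "Cu": (0.008, 0.024),
        "Zn": (0.021, 0.025), "Mn": (0.016, 0.023), "Fe": (0.045, 0.050),
    },
}

_INTERVAL_RE = re.compile(r"^\(?\s*(?P<lo>[-−\s\d./]+?)\s*,\s*(?P<hi>[-−\s\d./]+?)\s*\)?$")


def _parse_bound(text: str) -> float:
    text = text.replace("−", "-").replace(" ", "")
    if "/" in text:
        warnings.warn(
            f"interval bound {text!r} uses '/' where a decimal point is expected; "
            "reading it as a decimal point",
            UserWarning,
            stacklevel=3,
        )
        text = text.replace("/", ".")
    return float(text)


def parse_clr_interval(text: str) -> tuple[float, float]:
    """Parse a printed clr interval like ``"(2.859, 2.935)"``.

    Tolerates unicode minus signs and a slash typo for the decimal point
    (e.g. ``"(3/234, 3.314)"`` -> ``(3.234, 3.314)`` with a warning).
    """
    match = _INTERVAL_RE.match(text.strip())
    if match is None:
        raise ValueError(f"cannot parse clr interval: {text!r}")
    lo = _parse_bound(match.group("lo"))
    hi = _parse_bound(match.group("hi"))
    if lo >= hi:
        raise ValueError(f"interval bounds out of order in {text!r}")
    return lo, hi


def reference_clr_midpoints(cultivar: str) -> ClrVector:
    """Midpoints of the published clr confidence intervals for a cultivar."""
    if cultivar not in CLR_INTERVALS:
        raise KeyError(f"unknown cultivar {cultivar!r}; have {sorted(CLR_INTERVALS)}")
    mids = np.array([(lo + hi) / 2 for lo, hi in CLR_INTERVALS[cultivar]])
    return ClrVector(PARTS, mids)


def reference_centroid(cultivar: str, kappa: float = DEFAULT_KAPPA) -> Composition:
    """Back-transform of the published clr midpoints, closed to kappa."""
    return clr_back_transform(reference_clr_midpoints(cultivar), kappa=kappa)
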