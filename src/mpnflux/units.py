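"""Unit constants and rounding conventions shared across the package.

All fluxes are carried internally in SI-adjacent units (mol, litres, hours)
and converted at the edges to the field's customary units: zeptomoles
(zmol, 1e-21 mol) for hourly per-cell rates and attomoles (amol, 1e-18 mol)
for daily rates and cell quotas.
"""

from __future__ import annotations

import math

#: Disintegrations per minute in one curie (definitional).
DPM_PER_CI: float = 2.22e12

#: 1 zmol = 1e-21 mol; 1 amol = 1e-18 mol; 1 amol = 1e3 zmol.
MOL_PER_ZMOL: float = 1e-21
MOL_PER_AMOL: float = 1e-18
ZMOL_PER_AMOL: float = 1e3


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, to `ndigits` decimals.

    Python's built-in round() is banker's rounding (0.215 -> 0.21 at 2 d.p.);
    reported rates and percentages here follow the half-up convention instead,
    which is what reproduces printed values such as 0.215 -> 0.22.
    """
    if not math.isfinite(x):
        return x
    factor = 10.0 ** ndigits
    scaled = x * factor
    # nudge past binary-representation shortfalls (e.g. 0.215*100 = 21.499...96)
    eps = math.ulp(scaled) * 4
    return math.floor(abs(scaled) + 0.5 + eps) / factor * (1 if x >= 0 else -1)
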