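"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention of printed assay tables).

    Python's built-in ``round`` is banker's rounding; analytical reports round
    2.5 -> 3 and -2.5 -> -3.
    """
    factor = 10.0**ndigits
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    return rounded / factor
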