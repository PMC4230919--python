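"""Small shared numeric helpers."""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int) -> float:
    """Round ``x`` to ``ndigits`` decimals, halves away from zero.

    Python's built-in ``round`` uses banker's rounding; reported tables here
    use the away-from-zero convention so printed values are reproducible.
    """
    if not math.isfinite(x):
        return x
    factor = 10.0 ** ndigits
    scaled = abs(x) * factor
    # nudge by one ulp so values that are exactly representable halves
    # (e.g. 0.5 * factor) do not fall below the threshold
    rounded = math.floor(scaled + 0.5 + 1e-12)
    return math.copysign(rounded / factor, x)
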