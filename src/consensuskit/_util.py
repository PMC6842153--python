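"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (spreadsheet-style), not banker's.

    Used for all displayed percentages; full precision is kept internally.
    """
    factor = 10.0 ** ndigits
    scaled = x * factor
    # nudge by an epsilon-free floor/ceil construction to avoid fp ties drifting
    if scaled >= 0:
        return math.floor(scaled + 0.5) / factor
    return math.ceil(scaled - 0.5) / factor
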