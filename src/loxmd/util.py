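"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (report/table convention).

    Python's built-in ``round`` rounds ties to even, which is wrong for
    mimicking hand-rounded table cells (e.g. 2.25 -> 2.3, not 2.2).
    """
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
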