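"""Small shared helpers: reporting-time rounding and packaged-data access."""

from __future__ import annotations

import math
from importlib import resources


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (table convention; Python's round() is half-to-even)."""
    scale = 10.0**ndigits
    scaled = x * scale
    rounded = math.floor(abs(scaled) + 0.5) * math.copysign(1.0, scaled)
    out = rounded / scale
    return out if ndigits > 0 else float(int(out))


def data_path(*parts: str):
    """Traversable path to a packaged data file."""
    node = resources.files("wgcea").joinpath("data")
    for p in parts:
        node = node.joinpath(p)
    return node
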