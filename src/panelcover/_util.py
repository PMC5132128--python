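"""Small shared helpers."""
from __future__ import annotations

import hashlib
import math
from pathlib import Path


def percent(fraction: float, decimals: int = 1) -> float:
    """Render a fraction as a percentage rounded half-away-from-zero.

    Clinical reports conventionally print one decimal place (e.g. a
    diagnostic yield of 22/57 prints as 38.6). Banker's rounding would
    occasionally disagree with that convention, so rounding is explicit.
    """
    scale = 10 ** decimals
    value = fraction * 100.0 * scale
    return math.copysign(math.floor(abs(value) + 0.5), value) / scale


def percent_str(fraction: float, decimals: int = 1) -> str:
    return f"{percent(fraction, decimals):.{decimals}f}"


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
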