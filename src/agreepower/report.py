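"""Report formatting: rounding convention and JSON payload builders.

All internal arithmetic is double precision with no intermediate rounding;
only this layer rounds, half away from zero, to the requested number of
decimals (3 by default, matching how agreement tables are conventionally
printed).  JSON payloads carry both the full-precision values and their
rounded display counterparts.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_report", "display_map"]


def round_report(x: float | None, digits: int = 3) -> float | None:
    """Round half away from zero (so .0005 -> .001 and -.0005 -> -.001)."""
    if x is None:
        return None
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def display_map(values: dict, digits: int = 3) -> dict:
    """Rounded companions for every numeric entry of ``values``."""
    out = {}
    for k, v in values.items():
        if isinstance(v, (int, float)) or v is None:
            out[k] = round_report(v, digits)
    return out
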