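"""Small shared helpers."""

from __future__ import annotations

import logging
import sys
from decimal import ROUND_HALF_UP, Decimal


def percent(count: int, total: int, decimals: int = 1) -> float:
    """``100 * count / total`` rounded half away from zero.

    Matches the convention used when reporting call-set percentages
    (e.g. ``percent(475, 558) == 85.1``).
    """
    if total == 0:
        raise ZeroDivisionError("percent of an empty total")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    )


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr with a compact format."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("linkco")
    if not root.handlers:
        root.addHandler(handler)
    root.setLevel(level)
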