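"""Small shared helpers: reporting-grade rounding and file digests."""

from __future__ import annotations

import hashlib
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as printed tables conventionally do.

    Python's built-in ``round`` is banker's rounding; reported percentages here
    follow the half-up convention instead (5.25 -> 5.3 at 1 digit).
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def sha256_file(path: Path | str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
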