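"""Shared helpers: error taxonomy, display rounding, file digests."""

from __future__ import annotations

import hashlib
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path


class ConfigError(ValueError):
    """Invalid configuration (rates out of range, bad counts, malformed files)."""


class InvariantError(RuntimeError):
    """A structural invariant was violated (partition, containment, truth consistency)."""


class InestimableError(RuntimeError):
    """A required estimate is undefined (e.g. zero denominator after exclusions)."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as printed tables do (not banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_rate_percent(rate: float) -> str:
    """Render a proportion as a percent string: integer at >= 10%, one decimal below.

    An exactly-zero rate prints as "0".
    """
    if rate == 0:
        return "0"
    v = rate * 100.0
    if v >= 10:
        return str(int(round_half_up(v)))
    return f"{round_half_up(v, 1):.1f}"


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()
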