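"""Study-level reference counts bundled for reporting.

Culture-establishment attempt/success counts for the PTC model versus
conventional tumor spheres, as tabulated in the source study's figures.
These are inputs to percentage reporting, not measured by this package.
"""

from __future__ import annotations

__all__ = ["CULTURE_SUCCESS_COUNTS", "success_rate_percent"]

# model -> (successes, attempts)
CULTURE_SUCCESS_COUNTS: dict[str, tuple[int, int]] = {
    "PTC": (241, 254),
    "sphere": (4, 13),
}


def success_rate_percent(successes: int, attempts: int, ndigits: int = 1) -> float:
    """Percentage of successful cultures, rounded as conventionally printed."""
    if attempts <= 0:
        raise ValueError("attempts must be > 0")
    if not 0 <= successes <= attempts:
        raise ValueError("successes must be in [0, attempts]")
    return round(100.0 * successes / attempts, ndigits)
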