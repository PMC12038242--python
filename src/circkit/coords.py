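"""Coordinate conventions.

Internally every interval is 0-based half-open ``[start, end)``.  Reports
follow the 1-based inclusive ``chrN: start-end`` convention that circRNA
databases and publications use.  The two helpers here are the only place
the conversion happens, so a round trip is guaranteed lossless.
"""

from __future__ import annotations


def internal_to_report(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    if start >= end:
        raise ValueError(f"empty or inverted interval [{start}, {end})")
    return start + 1, end


def report_to_internal(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    if start1 > end1 or start1 < 1:
        raise ValueError(f"invalid 1-based inclusive interval {start1}-{end1}")
    return start1 - 1, end1


def format_region(chrom: str, start: int, end: int) -> str:
    """Render an internal interval as ``chrN:start-end`` (1-based inclusive)."""
    s1, e1 = internal_to_report(start, end)
    return f"{chrom}:{s1}-{e1}"


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse ``chrN:start-end`` (1-based inclusive) to internal coordinates."""
    chrom, _, span = text.replace(" ", "").partition(":")
    if not span:
        raise ValueError(f"cannot parse region {text!r}")
    a, _, b = span.partition("-")
    start, end = report_to_internal(int(a), int(b))
    return chrom, start, end
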