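"""Genomic regions, window grids and sliding-window generation.

All coordinates are 1-based inclusive, so a window ``[45,403,046,
45,405,045]`` spans exactly 2000 bp.  A window grid is anchored at the
region start and advanced by the slide; the final windows are truncated
at the region end, giving exactly ``ceil(L / slide)`` windows for a
region of length ``L``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass


@dataclass(frozen=True)
class Region:
    """A genomic interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def from_string(cls, spec: str) -> "Region":
        """Parse ``chrom:start-end`` (commas in numbers allowed)."""
        m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", spec.strip())
        if m is None:
            raise ValueError(f"cannot parse region {spec!r}; expected chrom:start-end")
        return cls(m.group(1), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", "")))


@dataclass(frozen=True)
class WindowSpec:
    """A (window size, slide) scan configuration in base pairs."""

    window_size: int
    slide: int

    def __post_init__(self) -> None:
        if not 0 < self.slide <= self.window_size:
            raise ValueError("slide must satisfy 0 < slide <= window_size")

    @property
    def label(self) -> str:
        return f"{self.window_size}/{self.slide}"


#: The scan grid used throughout: 5 kb, 2 kb, 1 kb and 500 bp windows,
#: each slid by half its size.
DEFAULT_SPECS: tuple[WindowSpec, ...] = (
    WindowSpec(5000, 2500),
    WindowSpec(2000, 1000),
    WindowSpec(1000, 500),
    WindowSpec(500, 250),
)


@dataclass(frozen=True)
class Window:
    """A concrete scan window inside a region, 1-based inclusive."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


def n_windows(region_length: int, slide: int) -> int:
    """Window count for a region: ``ceil(L / slide)``."""
    return -(-region_length // slide)


def generate_windows(region: Region, spec: WindowSpec) -> list[Window]:
    """Sliding windows anchored at ``region.start``.

    Window ``k`` starts at ``region.start + k * slide``; its end is
    truncated at ``region.end``.  For a 1 Mb region this yields m = 400,
    1000, 2000 and 4000 windows for the four default specs.
    """
    if region.length < spec.slide:
        raise ValueError("region shorter than the slide")
    count = n_windows(region.length, spec.slide)
    out = []
    for k in range(count):
        start = region.start + k * spec.slide
        end = min(start + spec.window_size - 1, region.end)
        out.append(Window(start, end))
    return out
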