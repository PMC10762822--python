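"""Calendar-quarter arithmetic.

All timing in claims extracts is collapsed to calendar quarters keyed as
``(year, 1..4)``.  A :class:`Quarter` is an immutable, totally ordered value
supporting integer offsets, so windows such as "the two quarters preceding
an outcome quarter" are plain arithmetic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering
from typing import Iterator


@total_ordering
@dataclass(frozen=True)
class Quarter:
    """A calendar quarter, e.g. ``Quarter(2015, 3)`` for 2015Q3."""

    year: int
    q: int

    def __post_init__(self) -> None:
        if not 1 <= self.q <= 4:
            raise ValueError(f"quarter index must be 1..4, got {self.q}")

    @property
    def index(self) -> int:
        """Linear index (quarters since year 0), enabling ordering/offsets."""
        return self.year * 4 + (self.q - 1)

    @classmethod
    def from_index(cls, idx: int) -> "Quarter":
        return cls(idx // 4, idx % 4 + 1)

    @classmethod
    def parse(cls, text: str) -> "Quarter":
        """Parse '2015Q3', '2015-Q3' or '2015.3' style strings."""
        m = re.fullmatch(r"(\d{4})[-.]?[Qq]?(\d)", str(text).strip())
        if m is None:
            raise ValueError(f"unparseable quarter: {text!r}")
        return cls(int(m.group(1)), int(m.group(2)))

    def __add__(self, n: int) -> "Quarter":
        return Quarter.from_index(self.index + int(n))

    def __sub__(self, other):
        if isinstance(other, Quarter):
            return self.index - other.index
        return Quarter.from_index(self.index - int(other))

    def __lt__(self, other: "Quarter") -> bool:
        return self.index < other.index

    def __str__(self) -> str:
        return f"{self.year}Q{self.q}"

    def range_to(self, last: "Quarter") -> Iterator["Quarter"]:
        """Quarters from self through ``last`` inclusive."""
        for idx in range(self.index, last.index + 1):
            yield Quarter.from_index(idx)


def lookback_quarters(target: Quarter, length: int = 2) -> tuple[Quarter, ...]:
    """The ``length`` calendar quarters immediately preceding ``target``.

    The default 6-month (two-quarter) window is the utilization lookback used
    to decide which providers form a patient-centered network for an outcome
    quarter.  The window never contains ``target`` itself and the returned
    quarters are consecutive and ascending.
    """
    if length < 1:
        raise ValueError("lookback length must be >= 1")
    return tuple(target - k for k in range(length, 0, -1))
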