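"""Calendar months as first-class keys.

The whole data model is month-indexed: claims reports, eligibility counts
and the price index are all published once per calendar month, and
day-level dates never enter the pipeline. A :class:`Month` is an ordered,
hashable (year, month) pair whose serialised form is ISO ``YYYY-MM``.
"""

from __future__ import annotations

import calendar
import functools
import re
from dataclasses import dataclass

from .errors import DataValidationError

_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")


@functools.total_ordering
@dataclass(frozen=True)
class Month:
    """A calendar month, e.g. ``Month(2021, 5)`` ↔ ``"2021-05"``."""

    year: int
    month: int

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise DataValidationError(f"month must be in 1..12, got {self.month}")

    @classmethod
    def parse(cls, text: str | Month) -> Month:
        if isinstance(text, Month):
            return text
        m = _MONTH_RE.match(str(text).strip())
        if m is None:
            raise DataValidationError(f"cannot parse month {text!r}; expected 'YYYY-MM'")
        return cls(int(m.group(1)), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"

    @property
    def index(self) -> int:
        """Months elapsed since year 0, for arithmetic and ordering."""
        return self.year * 12 + (self.month - 1)

    @classmethod
    def from_index(cls, index: int) -> Month:
        return cls(index // 12, index % 12 + 1)

    def __add__(self, n: int) -> Month:
        return Month.from_index(self.index + n)

    def __sub__(self, other: Month | int):
        """Month − Month → month count; Month − int → earlier Month."""
        if isinstance(other, int):
            return Month.from_index(self.index - other)
        return self.index - other.index

    def __lt__(self, other: Month) -> bool:
        return self.index < other.index

    @property
    def days(self) -> int:
        """Number of calendar days (the default disruption weight)."""
        return calendar.monthrange(self.year, self.month)[1]


def month_range(start: Month | str, end: Month | str) -> list[Month]:
    """All months from *start* to *end*, inclusive on both ends."""
    start, end = Month.parse(start), Month.parse(end)
    if start > end:
        raise DataValidationError(f"month range start {start} is after end {end}")
    return [Month.from_index(i) for i in range(start.index, end.index + 1)]
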