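"""WHO ATC classification codes and hierarchy relations.

The Anatomical Therapeutic Chemical (ATC) system codes medications in five
nested levels: level 1 is a single letter for the anatomical/physiological
system (``A`` alimentary tract, ``N`` nervous system, ...), level 2 appends
two digits for the therapeutic group (``A02`` drugs for acid-related
disorders), levels 3 and 4 each append one letter (pharmacological and
chemical subgroups), and level 5 appends two digits for the chemical
substance (``A02BC02`` pantoprazole).

The level is fully determined by the shape of the code, so a code string is
all the hierarchy needs: the ancestor of a code at a shallower level is a
prefix of it. Medications sit at level 5, therapeutic groups at level 2 and
physiological systems at level 1; levels 3/4 are representable because some
non-medication product groups are published at the 3rd level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AtcParseError

#: code length for each ATC level
LEVEL_LENGTHS = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}
_LENGTH_TO_LEVEL = {v: k for k, v in LEVEL_LENGTHS.items()}

# character class expected at each 0-based position of a full-length code
_POSITION_CLASS = ["letter", "digit", "digit", "letter", "letter", "digit", "digit"]


def _derived_level(code: str) -> int:
    """Level implied by the shape of *code*; raises on malformed input."""
    if not code:
        raise AtcParseError("ATC code is empty")
    n = len(code)
    if n not in _LENGTH_TO_LEVEL:
        raise AtcParseError(
            f"ATC code {code!r} has length {n}; valid lengths are 1, 3, 4, 5 or 7"
        )
    for pos, ch in enumerate(code):
        want = _POSITION_CLASS[pos]
        ok = ch.isalpha() if want == "letter" else ch.isdigit()
        if not ok:
            raise AtcParseError(
                f"ATC code {code!r}: position {pos + 1} must be a {want}, got {ch!r}"
            )
    return _LENGTH_TO_LEVEL[n]


@dataclass(frozen=True)
class AtcCode:
    """An ATC code with its derived level and optional display name.

    Entities are keyed by code; ``name`` is carried metadata only (display
    names vary in spelling and case across monthly files) and is excluded
    from equality and hashing.
    """

    code: str
    level: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        derived = _derived_level(self.code)
        if self.code != self.code.upper():
            raise AtcParseError(f"ATC code {self.code!r} must be stored uppercase")
        if self.level != derived:
            raise AtcParseError(
                f"stored level {self.level} disagrees with level {derived} "
                f"derived from code {self.code!r}"
            )

    def __str__(self) -> str:
        return self.code


def parse_atc(code: str, name: str | None = None) -> AtcCode:
    """Parse and validate an ATC code string.

    Lowercase input is accepted and normalised to uppercase (portal files
    vary in casing). Malformed codes raise :class:`AtcParseError` naming
    the offending position.
    """
    if not isinstance(code, str) or not code.strip():
        raise AtcParseError("ATC code is empty")
    normalised = code.strip().upper()
    return AtcCode(normalised, _derived_level(normalised), name=name)


def ancestor(code: AtcCode | str, target_level: int) -> AtcCode:
    """The ancestor of *code* at *target_level* (a prefix of the code).

    ``ancestor(x, x.level)`` is ``x`` itself.
    """
    if isinstance(code, str):
        code = parse_atc(code)
    if not 1 <= target_level <= code.level:
        raise AtcParseError(
            f"target level {target_level} is not in 1..{code.level} "
            f"for code {code.code!r}"
        )
    prefix = code.code[: LEVEL_LENGTHS[target_level]]
    return AtcCode(prefix, target_level, name=code.name if target_level == code.level else None)


def is_strict_descendant(child: AtcCode | str, parent: AtcCode | str) -> bool:
    """True iff *parent* is a strictly higher-level ancestor of *child*."""
    if isinstance(child, str):
        child = parse_atc(child)
    if isinstance(parent, str):
        parent = parse_atc(parent)
    if parent.level >= child.level:
        return False
    return ancestor(child, parent.level).code == parent.code
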