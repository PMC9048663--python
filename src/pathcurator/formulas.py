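"""Chemical formula parsing and arithmetic.

A formula is a multiset of element counts, e.g. ``C6H12O6`` ->
``{"C": 6, "H": 12, "O": 6}``.  Database formulas frequently contain
generic-group placeholders (``R`` for an arbitrary residue, ``X`` for a
halogen-like leaving group, ``*`` for a polymer repeat); such formulas are
kept, but flagged *indeterminate* so that downstream mass-balance checking
reports "undetermined" rather than guessing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["ChemicalFormula", "FormulaError", "parse_formula", "GENERIC_GROUPS"]

#: Tokens that stand for an unspecified chemical group rather than an element.
GENERIC_GROUPS = frozenset({"R", "X", "*"})

_TOKEN = re.compile(r"([A-Z][a-z]?|\*)(\d*)")


class FormulaError(ValueError):
    """Raised when a formula string does not match the supported grammar."""


@dataclass(frozen=True)
class ChemicalFormula:
    """Parsed elemental composition.

    ``element_counts`` maps element symbols (or generic-group tokens) to
    positive integer counts.  ``indeterminate`` is true when any generic
    group token is present, in which case element arithmetic on this
    formula is not meaningful.
    """

    element_counts: dict[str, int] = field(default_factory=dict)
    indeterminate: bool = False

    def __post_init__(self) -> None:
        for sym, n in self.element_counts.items():
            if n < 1:
                raise FormulaError(f"count for {sym!r} must be >= 1, got {n}")

    def __str__(self) -> str:  # Hill-ish: C, H, then alphabetical
        keys = sorted(
            self.element_counts,
            key=lambda s: (s != "C", s != "H", s),
        )
        return "".join(
            f"{k}{self.element_counts[k] if self.element_counts[k] != 1 else ''}"
            for k in keys
        )


def _parse_run(text: str, offset: int, counts: dict[str, int]) -> bool:
    """Accumulate element tokens of ``text`` into ``counts``.

    Returns whether a generic-group token was seen.  ``offset`` is the
    position of ``text`` within the original string, for error messages.
    """
    indeterminate = False
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            raise FormulaError(
                f"illegal character {text[pos]!r} at position {offset + pos}"
            )
        sym, digits = m.group(1), m.group(2)
        count = int(digits) if digits else 1
        counts[sym] = counts.get(sym, 0) + count
        if sym in GENERIC_GROUPS:
            indeterminate = True
        pos = m.end()
    return indeterminate


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a formula string such as ``C10H12N5O13P3`` or ``CH3(CH2)2CH3``.

    Repeated symbols are summed; a single level of parenthesised groups
    with an optional trailing multiplier is expanded.  Generic-group tokens
    (R, X, ``*``) are retained in the counts and mark the result
    indeterminate.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    indeterminate = False
    pos = 0
    while pos < len(text):
        ch = text[pos]
        if ch == "(":
            close = text.find(")", pos)
            if close == -1:
                raise FormulaError(f"unclosed '(' at position {pos}")
            inner = text[pos + 1 : close]
            m = re.match(r"\d+", text[close + 1 :])
            mult = int(m.group(0)) if m else 1
            group: dict[str, int] = {}
            if _parse_run(inner, pos + 1, group):
                indeterminate = True
            for sym, n in group.items():
                counts[sym] = counts.get(sym, 0) + n * mult
            pos = close + 1 + (m.end() if m else 0)
        else:
            nxt = text.find("(", pos)
            chunk = text[pos:nxt] if nxt != -1 else text[pos:]
            if _parse_run(chunk, pos, counts):
                indeterminate = True
            pos += len(chunk)
    return ChemicalFormula(element_counts=counts, indeterminate=indeterminate)
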