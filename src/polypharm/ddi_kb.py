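"""Knowledge base of potentially serious ("black dot") interaction pairs.

A single knowledge base — the analogue of one edition of a national
formulary's interaction appendix — is applied to every index date in a
run, so that prevalence comparisons between periods measure changes in
prescribing, not changes in interaction knowledge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from .formulary import Formulary, FormularyError, _read_delimited, code_key

__all__ = ["InteractionPair", "InteractionKB", "load_ddi_kb", "has_interaction"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionPair:
    """Unordered pair of class codes flagged potentially serious.

    Canonical form: ``class_a < class_b`` under numeric-segment code
    ordering; self-pairs are invalid.
    """

    class_a: str
    class_b: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.class_a == self.class_b:
            raise FormularyError(f"self-interaction pair {self.class_a!r}")
        if code_key(self.class_a) > code_key(self.class_b):
            raise FormularyError(
                f"pair ({self.class_a}, {self.class_b}) not in canonical order"
            )

    @classmethod
    def canonical(cls, x: str, y: str, label: str = "") -> "InteractionPair":
        """Build a pair in canonical order from codes in either order."""
        if code_key(x) > code_key(y):
            x, y = y, x
        return cls(x, y, label)

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.class_a, self.class_b))


class InteractionKB:
    """Set of canonical interaction pairs with O(1) membership queries."""

    def __init__(self, pairs: list[InteractionPair]):
        self.pairs: list[InteractionPair] = sorted(
            pairs, key=lambda p: (code_key(p.class_a), code_key(p.class_b))
        )
        self._index: dict[frozenset[str], InteractionPair] = {
            p.key: p for p in self.pairs
        }
        if len(self._index) != len(self.pairs):
            raise FormularyError("duplicate unordered pair in knowledge base")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[InteractionPair]:
        return iter(self.pairs)

    def has_interaction(self, code_x: str, code_y: str) -> bool:
        """True iff {x, y} is a listed pair. Symmetric; False when x == y
        and for codes with no listed interaction (unknown codes included).
        """
        if code_x == code_y:
            return False
        return frozenset((code_x, code_y)) in self._index

    def lookup(self, code_x: str, code_y: str) -> InteractionPair | None:
        return self._index.get(frozenset((code_x, code_y)))


def load_ddi_kb(path: str | Path, formulary: Formulary) -> InteractionKB:
    """Load interaction pairs from delimited text (class_a, class_b, label).

    Pairs are canonicalised; duplicates (including reversed restatements)
    collapse to one pair with a logged warning. Pairs referencing classes
    absent from the formulary, and self-pairs, are validation errors.
    """
    df = _read_delimited(Path(path))
    required = {"class_a", "class_b"}
    if not required.issubset(df.columns):
        raise FormularyError(
            f"DDI file missing columns {sorted(required - set(df.columns))}"
        )
    seen: dict[frozenset[str], InteractionPair] = {}
    for row in df.itertuples(index=False):
        a, b = row.class_a.strip(), row.class_b.strip()
        for c in (a, b):
            if c not in formulary:
                raise FormularyError(f"DDI pair ({a}, {b}): unknown class {c!r}")
        label = getattr(row, "label", "") or ""
        pair = InteractionPair.canonical(a, b, label)
        if pair.key in seen:
            logger.warning(
                "duplicate interaction pair (%s, %s) collapsed", pair.class_a, pair.class_b
            )
            continue
        seen[pair.key] = pair
    return InteractionKB(list(seen.values()))


def has_interaction(kb: InteractionKB, code_x: str, code_y: str) -> bool:
    """Functional wrapper around :meth:`InteractionKB.has_interaction`."""
    return kb.has_interaction(code_x, code_y)
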