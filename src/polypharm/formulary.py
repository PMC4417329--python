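"""Hierarchical drug-class ontology (BNF-style) and product-to-class mapping.

Drug classes are identified by dot-separated numeric codes whose first
segment is the chapter (``"2.4"`` -> chapter 2, beta-blockers in the real
BNF). Combination products map to two or more constituent class codes and
each constituent is counted separately downstream. Classes flagged
``excluded`` (devices, dressings, stoma/catheter products, vaccines) are
kept in the ontology so that reports can audit them, but never contribute
to polypharmacy counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DrugClass",
    "Formulary",
    "FormularyError",
    "UnmappedProductError",
    "code_key",
    "chapter_of",
    "load_formulary",
    "classify_product",
]

_CODE_RE = re.compile(r"^\d+(\.\d+)*$")


class FormularyError(ValueError):
    """Raised when a formulary file violates a structural invariant."""


class UnmappedProductError(KeyError):
    """Raised in strict mode when a product code has no class mapping."""


def code_key(code: str) -> tuple[int, ...]:
    """Sort key for class codes: numeric comparison segment by segment.

    ``"2.9.2" > "2.9.1" > "2.4"`` and ``"2.10" > "2.9"`` (numeric, not
    lexicographic on the string). Used for canonical interaction-pair
    ordering, so it must be a total order on valid codes.
    """
    if not _CODE_RE.match(code):
        raise FormularyError(f"malformed class code: {code!r}")
    return tuple(int(s) for s in code.split("."))


def chapter_of(code: str) -> int:
    """Chapter of a class code: the integer before the first dot."""
    return code_key(code)[0]


@dataclass(frozen=True)
class DrugClass:
    """One countable drug class (a BNF-style subsection)."""

    code: str
    name: str
    chapter: int
    excluded: bool = False

    def __post_init__(self) -> None:
        ch = chapter_of(self.code)
        if ch != self.chapter:
            raise FormularyError(
                f"class {self.code!r}: chapter field {self.chapter} does not "
                f"match leading code segment {ch}"
            )


@dataclass
class Formulary:
    """A validated drug-class ontology plus the product -> classes map.

    ``product_map`` values are ordered tuples of class codes; length >= 2
    exactly for combination products. ``combinations`` records which
    product codes were flagged as combinations in the source file.
    """

    classes: dict[str, DrugClass]
    product_map: dict[str, tuple[str, ...]]
    combinations: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for product, codes in self.product_map.items():
            if len(set(codes)) != len(codes):
                raise FormularyError(
                    f"product {product!r} maps to a duplicated class code"
                )
            for c in codes:
                if c not in self.classes:
                    raise FormularyError(
                        f"product {product!r} references unknown class {c!r}"
                    )
            if product in self.combinations and len(codes) < 2:
                raise FormularyError(
                    f"product {product!r} flagged combination but maps to "
                    f"{len(codes)} class(es)"
                )

    def __contains__(self, code: str) -> bool:
        return code in self.classes

    def is_excluded(self, code: str) -> bool:
        return self.classes[code].excluded

    def chapter(self, code: str) -> int:
        return self.classes[code].chapter

    @property
    def class_codes(self) -> list[str]:
        """All class codes in canonical (numeric-segment) order."""
        return sorted(self.classes, key=code_key)

    def countable_codes(self) -> list[str]:
        """Class codes that may contribute to polypharmacy counts."""
        return [c for c in self.class_codes if not self.classes[c].excluded]

    def products_for(self, code: str) -> list[str]:
        """Product codes whose expansion includes ``code`` (sim support)."""
        return sorted(p for p, cs in self.product_map.items() if code in cs)


def _read_delimited(path: Path) -> pd.DataFrame:
    """Read a tab- or comma-delimited text file, sniffing from the header."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def load_formulary(class_path: str | Path, product_path: str | Path | None = None) -> Formulary:
    """Load and validate a formulary from delimited text.

    Parameters
    ----------
    class_path
        Columns ``code, name, chapter, excluded`` (excluded as 0/1).
    product_path
        Columns ``product_code, class_codes, combination`` where
        ``class_codes`` is semicolon-separated. Optional; omitting it
        yields an identity product map (every class code doubles as a
        product code), which is convenient for toy inputs.
    """
    df = _read_delimited(Path(class_path))
    required = {"code", "name", "chapter", "excluded"}
    if not required.issubset(df.columns):
        raise FormularyError(
            f"formulary file missing columns {sorted(required - set(df.columns))}"
        )
    classes: dict[str, DrugClass] = {}
    for row in df.itertuples(index=False):
        code = row.code.strip()
        try:
            chapter = int(row.chapter)
        except ValueError as exc:
            raise FormularyError(
                f"class {code!r}: malformed chapter {row.chapter!r}"
            ) from exc
        if code in classes:
            raise FormularyError(f"duplicate class code {code!r}")
        classes[code] = DrugClass(
            code=code,
            name=row.name.strip(),
            chapter=chapter,
            excluded=row.excluded.strip() in {"1", "true", "True"},
        )

    if product_path is None:
        product_map = {c: (c,) for c in classes}
        combos: frozenset[str] = frozenset()
    else:
        pdf = _read_delimited(Path(product_path))
        preq = {"product_code", "class_codes", "combination"}
        if not preq.issubset(pdf.columns):
            raise FormularyError(
                f"product file missing columns {sorted(preq - set(pdf.columns))}"
            )
        product_map = {}
        combo_list = []
        for row in pdf.itertuples(index=False):
            product = row.product_code.strip()
            if product in product_map:
                raise FormularyError(f"duplicate product code {product!r}")
            codes = tuple(c.strip() for c in row.class_codes.split(";") if c.strip())
            if not codes:
                raise FormularyError(f"product {product!r} maps to no classes")
            product_map[product] = codes
            if row.combination.strip() in {"1", "true", "True"}:
                combo_list.append(product)
        combos = frozenset(combo_list)

    return Formulary(classes=classes, product_map=product_map, combinations=combos)


def classify_product(
    formulary: Formulary, product_code: str, strict: bool = True
) -> list[str]:
    """Expand a product code into its constituent class codes.

    Single-ingredient products return one code; combination products
    return every constituent. Excluded-class codes are returned as-is
    (exposure building filters them). Unknown products raise
    :class:`UnmappedProductError` in strict mode and return ``[]`` in
    lenient mode (the caller is expected to log the skip).
    """
    try:
        return list(formulary.product_map[product_code])
    except KeyError:
        if strict:
            raise UnmappedProductError(product_code) from None
        return []


def validate_codes_exist(formulary: Formulary, codes: Iterable[str], context: str) -> None:
    """Raise FormularyError naming the first code absent from the formulary."""
    for c in codes:
        if c not in formulary:
            raise FormularyError(f"{context}: unknown class code {c!r}")
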