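"""Per-patient exposure profiles: distinct drug classes and polypharmacy bands.

Polypharmacy is measured as the number of *distinct* drug classes
dispensed inside the exposure window. Combination products contribute
each constituent class; excluded classes (devices, dressings, vaccines)
never count; repeat dispensings of the same class count once. Patients
with no dispensing in the window are kept with a count of zero so that
the denominator is always the full registered adult population.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from .formulary import Formulary, classify_product

__all__ = [
    "POLYPHARMACY_BANDS",
    "CHAPTER_COUNT_BANDS",
    "polypharmacy_band",
    "build_exposure",
    "chapter_profile",
]

logger = logging.getLogger(__name__)

# Band edges: [lo, hi] inclusive; upper band open-ended.
POLYPHARMACY_BANDS: tuple[tuple[str, int, float], ...] = (
    ("0", 0, 0),
    ("1-4", 1, 4),
    ("5-9", 5, 9),
    ("10-14", 10, 14),
    ("15+", 15, float("inf")),
)

CHAPTER_COUNT_BANDS: tuple[str, ...] = ("0", "1", "2", "3", "4", "5+")


def polypharmacy_band(n: int) -> str:
    """Map a distinct-class count onto its reporting band.

    0 -> "0"; 1-4 -> "1-4"; 5-9 -> "5-9"; 10-14 -> "10-14"; >= 15 -> "15+".
    """
    if n < 0:
        raise ValueError(f"class count must be non-negative, got {n}")
    for label, lo, hi in POLYPHARMACY_BANDS:
        if lo <= n <= hi:
            return label
    raise AssertionError("unreachable")


def chapter_count_band(n: int) -> str:
    """Band for the number of distinct chapters: 0..4 literal, >= 5 -> "5+"."""
    if n < 0:
        raise ValueError(f"chapter count must be non-negative, got {n}")
    return str(n) if n < 5 else "5+"


def build_exposure(
    records: pd.DataFrame,
    formulary: Formulary,
    patient_ids: Sequence[str] | Iterable[str],
    strict: bool = True,
) -> pd.DataFrame:
    """Build one exposure profile per cohort patient.

    Parameters
    ----------
    records
        Window-filtered dispensing records.
    patient_ids
        The full cohort; patients without records appear with
        ``n_classes = 0``. Records for patients outside the cohort are
        ignored (they belong to rejected rows).
    strict
        Unknown product codes abort in strict mode; in lenient mode they
        are logged and skipped.

    Returns
    -------
    DataFrame indexed by patient_id with columns ``class_set``
    (frozenset of countable class codes), ``n_classes``, ``band``,
    ``chapter_set``, ``n_chapters``.
    """
    patient_ids = list(patient_ids)
    cohort = set(patient_ids)

    # product -> countable classes, resolved once per distinct product
    expansion: dict[str, tuple[str, ...]] = {}
    n_unmapped = 0
    for product in records["product_code"].unique():
        codes = classify_product(formulary, product, strict=strict)
        if not codes:
            n_unmapped += 1
            continue
        expansion[product] = tuple(
            c for c in codes if not formulary.is_excluded(c)
        )
    if n_unmapped:
        logger.warning("skipped %d unmapped product code(s) (lenient mode)", n_unmapped)

    sets: dict[str, set[str]] = {pid: set() for pid in patient_ids}
    for pid, product in zip(records["patient_id"], records["product_code"]):
        if pid not in cohort:
            continue
        codes = expansion.get(product)
        if codes:
            sets[pid].update(codes)

    rows = []
    for pid in patient_ids:
        cls = frozenset(sets[pid])
        chapters = frozenset(formulary.chapter(c) for c in cls)
        rows.append(
            (pid, cls, len(cls), polypharmacy_band(len(cls)), chapters, len(chapters))
        )
    out = pd.DataFrame(
        rows,
        columns=["patient_id", "class_set", "n_classes", "band", "chapter_set", "n_chapters"],
    ).set_index("patient_id")
    return out


def chapter_profile(profiles: pd.DataFrame, chapters: Sequence[int] = tuple(range(1, 14))) -> dict:
    """Tabulate chapter representation across the cohort.

    Returns a dict with
    ``per_chapter``: Series, patients dispensed >= 1 class from each
    chapter (a patient counts once per chapter represented), and
    ``n_chapters_dist``: Series over bands 0,1,2,3,4,5+ of the number of
    distinct chapters per patient.
    """
    per_chapter = pd.Series(0, index=list(chapters), dtype=int)
    for chset in profiles["chapter_set"]:
        for ch in chset:
            if ch in per_chapter.index:
                per_chapter[ch] += 1
    dist = (
        profiles["n_chapters"].map(chapter_count_band)
        .value_counts()
        .reindex(CHAPTER_COUNT_BANDS, fill_value=0)
    )
    return {"per_chapter": per_chapter, "n_chapters_dist": dist}


def write_profiles(profiles: pd.DataFrame, path) -> None:
    """Write the audit profile table (semicolon-joined class sets)."""
    out = profiles.copy()
    out["class_set"] = out["class_set"].map(lambda s: ";".join(sorted(s)))
    out["chapter_set"] = out["chapter_set"].map(
        lambda s: ";".join(str(c) for c in sorted(s))
    )
    out.to_csv(path, sep="\t")
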