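"""Detection of potentially serious drug-drug interactions in exposure profiles.

A DDI is present when *both* members of a listed pair were dispensed
anywhere inside the same exposure window; no overlap of supply dates is
required. This deliberately mirrors claims-based screening practice (and
its acknowledged limitation: a patient may have stopped one drug before
starting the other), keeping the measure identical across periods so
that between-period comparisons are fair.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ddi_kb import InteractionKB, InteractionPair
from .formulary import Formulary

__all__ = ["DDI_BANDS", "ddi_band", "detect_ddis", "detect_ddis_cohort", "ddi_chapter_table"]

DDI_BANDS: tuple[str, ...] = ("0", "1", "2", "3", "4+")


def ddi_band(n: int) -> str:
    """Band for the number of interacting pairs: 0..3 literal, >= 4 -> "4+"."""
    if n < 0:
        raise ValueError(f"DDI count must be non-negative, got {n}")
    return str(n) if n < 4 else "4+"


@dataclass
class PatientDDIResult:
    patient_id: str
    pairs_present: list[InteractionPair]
    n_ddis: int
    chapters_implicated: frozenset[int]
    band: str


def detect_ddis(
    patient_id: str,
    class_set: frozenset[str] | set[str],
    kb: InteractionKB,
    formulary: Formulary,
) -> PatientDDIResult:
    """Enumerate every KB pair fully contained in one patient's class set.

    Output order is the KB's canonical pair order, so results are
    deterministic. Chapters implicated are the union of the chapters of
    every class appearing in any present pair.
    """
    present = [
        p for p in kb if p.class_a in class_set and p.class_b in class_set
    ]
    chapters = frozenset(
        formulary.chapter(c) for p in present for c in (p.class_a, p.class_b)
    )
    return PatientDDIResult(
        patient_id=patient_id,
        pairs_present=present,
        n_ddis=len(present),
        chapters_implicated=chapters,
        band=ddi_band(len(present)),
    )


def detect_ddis_cohort(
    profiles: pd.DataFrame, kb: InteractionKB, formulary: Formulary
) -> pd.DataFrame:
    """Per-patient DDI table for a whole cohort of exposure profiles.

    Returns a DataFrame indexed like ``profiles`` with columns
    ``n_ddis``, ``ddi_band``, ``pairs`` (list of InteractionPair),
    ``chapters_implicated`` (frozenset of int).
    """
    rows = []
    for pid, class_set in zip(profiles.index, profiles["class_set"]):
        r = detect_ddis(pid, class_set, kb, formulary)
        rows.append((pid, r.n_ddis, r.band, r.pairs_present, r.chapters_implicated))
    return pd.DataFrame(
        rows, columns=["patient_id", "n_ddis", "ddi_band", "pairs", "chapters_implicated"]
    ).set_index("patient_id")


def ddi_chapter_table(
    results: pd.DataFrame, chapters=tuple(range(1, 14))
) -> pd.Series:
    """Patients with >= 1 DDI involving a class from each chapter.

    A patient increments every chapter implicated by any of their pairs,
    but never the same chapter more than once.
    """
    counts = pd.Series(0, index=list(chapters), dtype=int)
    for chset in results["chapters_implicated"]:
        for ch in chset:
            if ch in counts.index:
                counts[ch] += 1
    return counts


def write_ddi_table(results: pd.DataFrame, path) -> None:
    """Audit output: pairs as "a|b" tokens, semicolon-joined."""
    out = results.copy()
    out["pairs"] = out["pairs"].map(
        lambda ps: ";".join(f"{p.class_a}|{p.class_b}" for p in ps)
    )
    out["chapters_implicated"] = out["chapters_implicated"].map(
        lambda s: ";".join(str(c) for c in sorted(s))
    )
    out.to_csv(path, sep="\t")
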