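"""Crude and directly age-sex standardised prevalences and their comparison.

Direct standardisation re-weights stratum-specific event proportions by
a reference population's stratum shares, removing differences in age-sex
structure between periods. The standardised relative risk (sRR) compares
the later period's standardised prevalence with the earlier period's
crude prevalence, the convention used when the earlier period supplies
the reference structure. Confidence intervals: the variance of a
directly standardised proportion is sum_s w_s^2 p_s (1 - p_s) / n_s; sRR
intervals are computed on the log scale treating the two periods as
independent; proportion differences use the Wald (normal-approximation)
interval — the standard large-sample choices at population denominators
of order 10^5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AGE_BANDS",
    "assign_age_band",
    "stratify",
    "StandardisedRate",
    "RateComparison",
    "direct_standardise",
    "crude_rate",
    "standardised_rr",
    "proportion_difference",
]

logger = logging.getLogger(__name__)

AGE_BANDS: tuple[str, ...] = ("20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+")

Z95 = 1.959963984540054  # Phi^{-1}(0.975)


def assign_age_band(age: int) -> str:
    """Decade band for an adult age; 80+ is open-ended."""
    if age < 20:
        raise ValueError(f"age {age} below the adult cohort minimum of 20")
    if age >= 80:
        return "80+"
    lo = (age // 10) * 10
    return f"{lo}-{lo + 9}"


def stratify(patients: pd.DataFrame, event: pd.Series) -> pd.DataFrame:
    """Tally totals and events by sex x age band.

    Parameters
    ----------
    patients
        Must carry ``sex`` and ``age`` columns; every patient falls in
        exactly one stratum.
    event
        Boolean Series aligned with ``patients`` (by position or index).

    Returns a DataFrame indexed by (sex, age_band) over the full 14-cell
    grid with columns ``n_total``, ``n_event`` (zero-filled where empty).
    """
    if len(patients) == 0:
        idx = pd.MultiIndex.from_product([["M", "F"], list(AGE_BANDS)],
                                         names=["sex", "age_band"])
        return pd.DataFrame({"n_total": 0, "n_event": 0}, index=idx)
    ev = np.asarray(event, dtype=bool)
    if len(ev) != len(patients):
        raise ValueError("event flags not aligned with patients")
    df = pd.DataFrame({
        "sex": patients["sex"].to_numpy(),
        "age_band": patients["age"].map(assign_age_band).to_numpy(),
        "event": ev,
    })
    g = df.groupby(["sex", "age_band"], sort=False)
    out = g.agg(n_total=("event", "size"), n_event=("event", "sum"))
    idx = pd.MultiIndex.from_product([["M", "F"], list(AGE_BANDS)],
                                     names=["sex", "age_band"])
    return out.reindex(idx, fill_value=0).astype(int)


@dataclass
class StandardisedRate:
    """A prevalence as crude and (optionally) standardised percentages.

    ``var_crude`` / ``var_std`` are variances of the corresponding
    *proportions* (not percentages).
    """

    crude_pct: float
    standardised_pct: float
    n: int
    n_event: int
    var_crude: float
    var_std: float
    reference_id: str = "self"


@dataclass
class RateComparison:
    srr: float
    srr_ci: tuple[float, float]
    diff_pct: float
    diff_ci: tuple[float, float]


def crude_rate(strata: pd.DataFrame) -> StandardisedRate:
    """Crude prevalence of a stratified table, with binomial variance."""
    n = int(strata["n_total"].sum())
    k = int(strata["n_event"].sum())
    if n == 0:
        raise ValueError("empty population")
    p = k / n
    return StandardisedRate(
        crude_pct=100 * p, standardised_pct=100 * p, n=n, n_event=k,
        var_crude=p * (1 - p) / n, var_std=p * (1 - p) / n, reference_id="self",
    )


def direct_standardise(
    study: pd.DataFrame, reference: pd.DataFrame, reference_id: str = "reference"
) -> StandardisedRate:
    """Directly standardise the study prevalence to a reference structure.

    standardised% = 100 * sum_s w_s (n_event_s / n_total_s) with
    w_s = reference n_total_s / sum(reference n_total). Weights sum to 1
    by construction. Study strata with zero denominator contribute a zero
    rate with a logged warning (their reference weight is retained, so
    the result is conservative for events concentrated there).
    """
    if not study.index.equals(reference.index):
        raise ValueError("study and reference strata grids differ")
    ref_tot = reference["n_total"].to_numpy(dtype=float)
    if ref_tot.sum() <= 0:
        raise ValueError("reference population is empty")
    w = ref_tot / ref_tot.sum()
    n_s = study["n_total"].to_numpy(dtype=float)
    k_s = study["n_event"].to_numpy(dtype=float)
    empty = n_s == 0
    if empty.any() and w[empty].sum() > 0:
        logger.warning(
            "%d study stratum(s) empty; they contribute rate 0 to the "
            "standardised estimate", int(empty.sum()),
        )
    p_s = np.where(empty, 0.0, k_s / np.where(empty, 1.0, n_s))
    std = float(np.sum(w * p_s))
    var_std = float(np.sum(
        np.where(empty, 0.0, w**2 * p_s * (1 - p_s) / np.where(empty, 1.0, n_s))
    ))
    crude = crude_rate(study)
    return StandardisedRate(
        crude_pct=crude.crude_pct, standardised_pct=100 * std,
        n=crude.n, n_event=crude.n_event,
        var_crude=crude.var_crude, var_std=var_std, reference_id=reference_id,
    )


def standardised_rr(
    std_late: StandardisedRate, crude_early: StandardisedRate, ci_level: float = 0.95
) -> RateComparison:
    """Standardised relative risk: standardised late % / crude early %.

    The CI is log-normal, var(log sRR) = var_std/p_std^2 + var_crude/p_crude^2,
    treating the two periods' populations as independent. Also reports
    the difference of the same two percentages with a Wald interval.
    """
    from scipy.stats import norm

    z = norm.ppf(0.5 + ci_level / 2)
    p_late = std_late.standardised_pct / 100
    p_early = crude_early.crude_pct / 100
    if p_early <= 0:
        raise ZeroDivisionError("early-period crude rate is zero; sRR undefined")
    srr = p_late / p_early
    if p_late > 0:
        var_log = std_late.var_std / p_late**2 + crude_early.var_crude / p_early**2
        lo, hi = srr * math.exp(-z * math.sqrt(var_log)), srr * math.exp(z * math.sqrt(var_log))
    else:
        lo = hi = 0.0
    diff = 100 * (p_late - p_early)
    se_diff = 100 * math.sqrt(std_late.var_std + crude_early.var_crude)
    return RateComparison(
        srr=srr, srr_ci=(lo, hi),
        diff_pct=diff, diff_ci=(diff - z * se_diff, diff + z * se_diff),
    )


def proportion_difference(
    k1: int, n1: int, k2: int, n2: int, ci_level: float = 0.95
) -> RateComparison:
    """Wald difference of two independent binomial proportions, in
    percentage points (p1 - p2), with the corresponding risk ratio.

    Degenerate proportions (0 or 1 in both groups) give SE 0 and a
    zero-width interval with a logged warning.
    """
    from scipy.stats import norm

    if n1 <= 0 or n2 <= 0:
        raise ValueError("denominators must be positive")
    z = norm.ppf(0.5 + ci_level / 2)
    p1, p2 = k1 / n1, k2 / n2
    se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    if se == 0:
        logger.warning("degenerate proportions (both variance 0); zero-width CI")
    diff = 100 * (p1 - p2)
    rr = p1 / p2 if p2 > 0 else math.inf
    if p1 > 0 and p2 > 0:
        var_log = (1 - p1) / (n1 * p1) + (1 - p2) / (n2 * p2)
        rr_ci = (rr * math.exp(-z * math.sqrt(var_log)), rr * math.exp(z * math.sqrt(var_log)))
    else:
        rr_ci = (0.0, math.inf)
    return RateComparison(
        srr=rr, srr_ci=rr_ci,
        diff_pct=diff, diff_ci=(diff - z * 100 * se, diff + z * 100 * se),
    )
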