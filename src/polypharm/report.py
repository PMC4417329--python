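"""Analysis-table builders: two-period prevalence tables and model tables.

These compose the lower-level modules into the study's reporting units:
polypharmacy band and chapter prevalence per period with directly
age-sex standardised percentages and standardised relative risks
(later period standardised to the earlier period's structure), DDI
count-band and chapter tables in the same layout, and the multilevel
model tables (univariate and adjusted odds ratios plus the empty-model
ICC). Percentages are rounded only at the presentation layer; the
returned frames keep full precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ddi_detect import DDI_BANDS, detect_ddis_cohort
from .exposure import CHAPTER_COUNT_BANDS, POLYPHARMACY_BANDS
from .formulary import Formulary
from .glmm import Covariate, GlmmSpec, fit_random_intercept_logit, odds_ratios
from .ingest import URBAN_RURAL_LEVELS
from .rates import (
    AGE_BANDS,
    assign_age_band,
    crude_rate,
    direct_standardise,
    standardised_rr,
    stratify,
)

logger = logging.getLogger(__name__)

BAND_LABELS = [b[0] for b in POLYPHARMACY_BANDS]

POLY_COVARIATES = [
    Covariate("age_band", tuple(AGE_BANDS), "20-29"),
    Covariate("sex", ("M", "F"), "M"),
    Covariate("simd_quintile", ("1", "2", "3", "4", "5"), "1"),
    Covariate("urban_rural", tuple(URBAN_RURAL_LEVELS), "primary_city"),
    Covariate("residence", ("own_home", "care_home"), "own_home"),
]
DDI_COVARIATES = [
    Covariate("age_band", tuple(AGE_BANDS), "20-29"),
    Covariate("sex", ("M", "F"), "M"),
    Covariate("residence", ("own_home", "care_home"), "own_home"),
    Covariate("drug_band", ("2-4", "5-9", "10-14", "15+"), "2-4"),
]


def _comparison_row(patients_early, event_early, patients_late, event_late):
    """Crude %, standardised % and sRR for one binary event, standardising
    the later period to the earlier period's age-sex structure."""
    s_early = stratify(patients_early, event_early)
    s_late = stratify(patients_late, event_late)
    std_late = direct_standardise(s_late, s_early, reference_id="early-period")
    cr_early = crude_rate(s_early)
    if cr_early.n_event == 0:  # no early-period events: sRR undefined, as "-" in reports
        return {
            "n_t1": 0, "pct_t1": 0.0,
            "n_t2": std_late.n_event, "pct_t2": std_late.crude_pct,
            "standardised_pct_t2": std_late.standardised_pct,
            "srr": np.nan, "srr_lo": np.nan, "srr_hi": np.nan,
        }
    cmp_ = standardised_rr(std_late, cr_early)
    return {
        "n_t1": cr_early.n_event, "pct_t1": cr_early.crude_pct,
        "n_t2": std_late.n_event, "pct_t2": std_late.crude_pct,
        "standardised_pct_t2": std_late.standardised_pct,
        "srr": cmp_.srr, "srr_lo": cmp_.srr_ci[0], "srr_hi": cmp_.srr_ci[1],
    }


def polypharmacy_comparison(
    patients_early: pd.DataFrame, profiles_early: pd.DataFrame,
    patients_late: pd.DataFrame, profiles_late: pd.DataFrame,
    formulary: Formulary,
) -> dict[str, pd.DataFrame]:
    """Two-period polypharmacy report: drug-count bands, chapter
    membership, and number-of-chapters distribution."""
    pe = profiles_early.loc[patients_early["patient_id"]]
    pl = profiles_late.loc[patients_late["patient_id"]]

    rows = {}
    for band in BAND_LABELS:
        rows[band] = _comparison_row(
            patients_early, (pe["band"] == band).to_numpy(),
            patients_late, (pl["band"] == band).to_numpy(),
        )
    band_table = pd.DataFrame(rows).T.rename_axis("band")

    ch_rows = {}
    for ch in range(1, 14):
        ch_rows[ch] = _comparison_row(
            patients_early, pe["chapter_set"].map(lambda s: ch in s).to_numpy(),
            patients_late, pl["chapter_set"].map(lambda s: ch in s).to_numpy(),
        )
    chapter_table = pd.DataFrame(ch_rows).T.rename_axis("chapter")

    nch_rows = {}
    for lab in CHAPTER_COUNT_BANDS:
        def in_band(n, lab=lab):
            return (str(n) == lab) if lab != "5+" else n >= 5
        nch_rows[lab] = _comparison_row(
            patients_early, pe["n_chapters"].map(in_band).to_numpy(),
            patients_late, pl["n_chapters"].map(in_band).to_numpy(),
        )
    nch_table = pd.DataFrame(nch_rows).T.rename_axis("n_chapters")

    return {"bands": band_table, "chapters": chapter_table, "n_chapters": nch_table}


def ddi_comparison(
    patients_early, profiles_early, patients_late, profiles_late,
    kb, formulary: Formulary,
) -> dict[str, pd.DataFrame]:
    """Two-period DDI report: any-DDI row, count bands, chapter rows."""
    res_early = detect_ddis_cohort(profiles_early.loc[patients_early["patient_id"]], kb, formulary)
    res_late = detect_ddis_cohort(profiles_late.loc[patients_late["patient_id"]], kb, formulary)

    out_rows = {"any": _comparison_row(
        patients_early, (res_early["n_ddis"] >= 1).to_numpy(),
        patients_late, (res_late["n_ddis"] >= 1).to_numpy(),
    )}
    for band in DDI_BANDS:
        out_rows[band] = _comparison_row(
            patients_early, (res_early["ddi_band"] == band).to_numpy(),
            patients_late, (res_late["ddi_band"] == band).to_numpy(),
        )
    band_table = pd.DataFrame(out_rows).T.rename_axis("n_ddis")

    ch_rows = {}
    for ch in range(1, 14):
        ch_rows[ch] = _comparison_row(
            patients_early, res_early["chapters_implicated"].map(lambda s: ch in s).to_numpy(),
            patients_late, res_late["chapters_implicated"].map(lambda s: ch in s).to_numpy(),
        )
    chapter_table = pd.DataFrame(ch_rows).T.rename_axis("chapter")
    return {"bands": band_table, "chapters": chapter_table,
            "results_early": res_early, "results_late": res_late}


def _model_frame(patients: pd.DataFrame, profiles: pd.DataFrame,
                 ddi_results: pd.DataFrame | None = None) -> pd.DataFrame:
    """Patient-level modelling frame with categorical covariates coded
    as the analysis tables expect."""
    prof = profiles.loc[patients["patient_id"]]
    df = patients.copy()
    df["age_band"] = df["age"].map(assign_age_band)
    df["simd_quintile"] = df["simd_quintile"].astype(str)
    df["residence"] = np.where(df["care_home"], "care_home", "own_home")
    df["n_classes"] = prof["n_classes"].to_numpy()
    df["poly10"] = (df["n_classes"] >= 10).astype(int)
    if ddi_results is not None:
        df["n_ddis"] = ddi_results.loc[patients["patient_id"], "n_ddis"].to_numpy()
        df["any_ddi"] = (df["n_ddis"] >= 1).astype(int)
        df["drug_band"] = pd.cut(
            df["n_classes"], bins=[2, 4, 9, 14, np.inf],
            labels=["2-4", "5-9", "10-14", "15+"], include_lowest=True,
        ).astype(str)
    return df


@dataclass
class ModelReport:
    outcome: str
    univariate: pd.DataFrame
    adjusted: pd.DataFrame
    empty_icc: float
    empty_sigma_u: float
    adjusted_fit: object
    n: int
    n_clusters: int


def fit_model_report(
    patients: pd.DataFrame, profiles: pd.DataFrame,
    kb=None, formulary: Formulary | None = None,
    outcome: str = "poly10", n_quadrature: int = 15,
) -> ModelReport:
    """Univariate + adjusted multilevel ORs and the empty-model ICC.

    ``outcome="poly10"`` models dispensing of >= 10 drug classes on the
    full cohort; ``outcome="any_ddi"`` models presence of >= 1 potentially
    serious interaction on the subset dispensed >= 2 classes (a DDI needs
    two drugs, so patients below that cannot have the outcome).
    """
    if outcome == "poly10":
        covs = POLY_COVARIATES
        ddi_results = None
        if patients["care_home"].sum() == 0:  # early period: no care-home flag
            covs = [c for c in covs if c.name != "residence"]
        frame = _model_frame(patients, profiles)
    elif outcome == "any_ddi":
        if kb is None or formulary is None:
            raise ValueError("any_ddi model needs the interaction KB and formulary")
        ddi_results = detect_ddis_cohort(profiles.loc[patients["patient_id"]], kb, formulary)
        frame = _model_frame(patients, profiles, ddi_results)
        frame = frame[frame["n_classes"] >= 2].reset_index(drop=True)
        covs = DDI_COVARIATES
    else:
        raise ValueError(f"unknown outcome {outcome!r}")

    uni_tables = []
    for cov in covs:
        fit = fit_random_intercept_logit(
            frame, GlmmSpec(outcome, [cov]), n_quadrature=n_quadrature
        )
        t = odds_ratios(fit)
        uni_tables.append(t)
    univariate = pd.concat(uni_tables, ignore_index=True)

    adj_fit = fit_random_intercept_logit(
        frame, GlmmSpec(outcome, list(covs)), n_quadrature=n_quadrature
    )
    adjusted = odds_ratios(adj_fit)

    empty_fit = fit_random_intercept_logit(
        frame, GlmmSpec(outcome, []), n_quadrature=n_quadrature
    )
    return ModelReport(
        outcome=outcome, univariate=univariate, adjusted=adjusted,
        empty_icc=empty_fit.icc, empty_sigma_u=empty_fit.sigma_u,
        adjusted_fit=adj_fit, n=adj_fit.n_obs, n_clusters=adj_fit.n_clusters,
    )


def round_for_presentation(table: pd.DataFrame) -> pd.DataFrame:
    """Percentages to 1 dp, ratios to 2 dp (presentation only)."""
    out = table.copy()
    for c in out.columns:
        if c.startswith("n_"):
            out[c] = out[c].astype(int)
        elif c.startswith("pct") or c.startswith("standardised"):
            out[c] = out[c].astype(float).round(1)
        elif c in {"srr", "srr_lo", "srr_hi", "or_", "ci_lo", "ci_hi"}:
            out[c] = out[c].astype(float).round(2)
    return out
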