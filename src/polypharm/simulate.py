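"""Synthetic populations, practices, and dispensing records.

The generator emulates the statistical structure the analysis assumes in
a two-period regional dispensing dataset: adults clustered in general
practices, per-class dispensing probabilities on the logit scale with an
age gradient that steepens from middle age, a deprivation slope, a
care-home effect concentrated in the oldest bands, a shared patient
"frailty" that makes class counts overdispersed (so interactions
concentrate steeply among high-count patients), a practice-level random
intercept producing a small intraclass correlation, and extra
co-occurrence for designated interacting pairs. Dispensed classes emit
1-3 records at uniform-random dates inside the 84-day exposure window,
in exactly the file formats the ingest module reads.

Everything is reproducible from the config seed, and the returned truth
record stores every parameter for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .exposure import POLYPHARMACY_BANDS
from .formulary import Formulary, code_key
from .ingest import URBAN_RURAL_LEVELS
from .rates import AGE_BANDS

__all__ = [
    "SimConfig",
    "default_config",
    "simulate_population",
    "expected_summary",
    "simulate_clustered_logit",
    "write_population",
]

_AGE_RANGES = {
    "20-29": (20, 29), "30-39": (30, 39), "40-49": (40, 49), "50-59": (50, 59),
    "60-69": (60, 69), "70-79": (70, 79), "80+": (80, 95),
}


@dataclass
class SimConfig:
    """Full parameterisation of one simulated period.

    ``class_baselines`` are per-class logit intercepts for a reference
    patient (age 20-29, SIMD quintile 3, male, own home, zero random
    effects). ``age_offsets``/``simd_slope``/``sex_offset``/
    ``care_home_offset`` shift every class's logit identically.
    ``cooccurrence_boosts`` maps ``"a|b"`` (canonical pair order) to a
    logit boost applied to the later class when the earlier one was
    dispensed. ``period_offset`` shifts all baselines, giving the
    low-prevalence earlier period and high-prevalence later period.
    """

    seed: int = 0
    n_practices: int = 60
    patients_per_practice_mean: float = 250.0
    patients_per_practice_dispersion: float = 8.0  # negative-binomial shape
    age_band_dist: dict = field(default_factory=dict)
    sex_female_prob: float = 0.515
    simd_dist: tuple = (0.18, 0.30, 0.17, 0.16, 0.19)
    urban_rural_dist: tuple = (0.39, 0.26, 0.25, 0.10)
    care_home_prob_by_band: dict = field(default_factory=dict)
    class_baselines: dict = field(default_factory=dict)
    age_offsets: dict = field(default_factory=dict)
    simd_slope: float = 0.10
    sex_offset: float = 0.18
    care_home_offset: float = 0.8
    frailty_sd: float = 1.3
    practice_sd: float = 0.22
    cooccurrence_boosts: dict = field(default_factory=dict)
    records_per_class_dist: tuple = (0.45, 0.35, 0.20)  # P(1), P(2), P(3)
    period_offset: float = 0.0
    index_date: str = "2010-03-31"
    window_days: int = 84

    def validate(self) -> None:
        for name, dist in [("age_band_dist", tuple(self.age_band_dist.values())),
                           ("simd_dist", self.simd_dist),
                           ("urban_rural_dist", self.urban_rural_dist),
                           ("records_per_class_dist", self.records_per_class_dist)]:
            if abs(sum(dist) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {sum(dist)}")
            if any(p < 0 for p in dist):
                raise ValueError(f"{name} has negative probabilities")
        if set(self.age_band_dist) != set(AGE_BANDS):
            raise ValueError("age_band_dist must cover exactly the 7 age bands")
        if self.frailty_sd < 0 or self.practice_sd < 0:
            raise ValueError("random-effect SDs must be non-negative")
        for band, p in self.care_home_prob_by_band.items():
            if not 0 <= p <= 1:
                raise ValueError(f"care_home probability for {band} outside [0,1]")
        if self.n_practices < 1 or self.patients_per_practice_mean <= 0:
            raise ValueError("practice structure invalid")

    def to_dict(self) -> dict:
        return asdict(self)


# Calibrated once against the published population structure this
# generator is meant to emulate (age-graded class counts, small practice
# ICC, deprivation and care-home gradients, DDI prevalence rising
# steeply with drug count); see docs/methods.md.
_BASE_BY_CHAPTER = {
    1: -4.55, 2: -4.70, 3: -5.15, 4: -4.80, 5: -4.85, 6: -5.10,
    7: -5.55, 8: -6.70, 9: -5.80, 10: -5.15, 11: -5.80, 12: -5.85,
    13: -5.10, 14: -6.30,
}
_CLASS_ADJ = {  # a few classes made commoner/rarer than their chapter norm
    "1.3.5": 0.55, "2.12": 0.75, "2.5.5.1": 0.45, "2.9.1": 0.55, "2.4": 0.30,
    "2.8.2": -0.55, "2.8.1": -2.1, "2.9.2": -0.9, "2.2.3": -0.9,
    "4.7.1": 0.55, "4.3.3": 0.35, "10.1.1": 0.45, "5.1.1": 0.35,
    "6.1.1": -1.0, "7.3.1": 0.45, "8.2.1": -0.4,
}

_AGE_OFFSETS_2010 = {
    "20-29": 0.0, "30-39": 0.32, "40-49": 0.72, "50-59": 1.18,
    "60-69": 1.62, "70-79": 2.02, "80+": 2.30,
}
_AGE_DIST_2010 = {
    "20-29": 0.164, "30-39": 0.153, "40-49": 0.193, "50-59": 0.169,
    "60-69": 0.151, "70-79": 0.106, "80+": 0.064,
}
_AGE_DIST_1995 = {
    "20-29": 0.195, "30-39": 0.175, "40-49": 0.185, "50-59": 0.160,
    "60-69": 0.140, "70-79": 0.097, "80+": 0.048,
}
_CARE_HOME_2010 = {
    "20-29": 0.0005, "30-39": 0.0005, "40-49": 0.001, "50-59": 0.002,
    "60-69": 0.006, "70-79": 0.025, "80+": 0.10,
}
_BOOSTS = {
    "2.2.3|2.5.5.1": 1.2, "2.6.2|2.12": 1.2, "2.9.1|10.1.1": 0.6,
    "2.5.5.1|10.1.1": 0.75, "4.3.3|4.7.2": 0.75,
}


def default_config(formulary: Formulary, period: str = "2010", seed: int = 0) -> SimConfig:
    """Study-condition defaults for one period.

    ``period`` is "2010" (reference, higher prevalence, older
    population) or "1995" (logit offset -0.5, younger age structure, no
    care-home flag in the source data so probability 0).
    """
    if period not in {"1995", "2010"}:
        raise ValueError("period must be '1995' or '2010'")
    baselines = {}
    for code in formulary.class_codes:
        ch = formulary.chapter(code)
        baselines[code] = _BASE_BY_CHAPTER.get(ch, -4.5) + _CLASS_ADJ.get(code, 0.0)
    late = period == "2010"
    return SimConfig(
        seed=seed,
        age_band_dist=dict(_AGE_DIST_2010 if late else _AGE_DIST_1995),
        care_home_prob_by_band=dict(_CARE_HOME_2010) if late
        else {b: 0.0 for b in AGE_BANDS},
        class_baselines=baselines,
        age_offsets=dict(_AGE_OFFSETS_2010),
        cooccurrence_boosts=dict(_BOOSTS),
        period_offset=0.0 if late else -0.5,
        index_date="2010-03-31" if late else "1995-03-31",
    )


def _class_order(cfg: SimConfig) -> list[str]:
    return sorted(cfg.class_baselines, key=code_key)


def _boost_map(cfg: SimConfig, order: list[str]) -> dict[int, list[tuple[int, float]]]:
    """index of later class -> [(index of earlier partner, boost)]."""
    pos = {c: i for i, c in enumerate(order)}
    out: dict[int, list[tuple[int, float]]] = {}
    for key, b in cfg.cooccurrence_boosts.items():
        a, c = key.split("|")
        if a not in pos or c not in pos:
            raise ValueError(f"cooccurrence boost references unknown class in {key!r}")
        i, j = sorted((pos[a], pos[c]))
        out.setdefault(j, []).append((i, b))
    return out


def _patient_logits(cfg: SimConfig, order, age_band, simd, sex_f, care) -> np.ndarray:
    base = np.array([cfg.class_baselines[c] for c in order])
    return (
        base + cfg.period_offset + cfg.age_offsets[age_band]
        + cfg.simd_slope * (simd - 3)
        + (cfg.sex_offset if sex_f else 0.0)
        + (cfg.care_home_offset if care else 0.0)
    )


def _sample_classes(rng, logits, boosts) -> np.ndarray:
    """Sequential draw in canonical class order; boosted classes shift
    their logit when an already-drawn partner is present."""
    n = len(logits)
    out = np.zeros(n, dtype=bool)
    u = rng.random(n)
    for j in range(n):
        lj = logits[j]
        for i, b in boosts.get(j, ()):
            if out[i]:
                lj += b
        out[j] = u[j] < expit(lj)
    return out


def simulate_population(
    cfg: SimConfig, formulary: Formulary
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (patients, dispensing records, truth record) for one period.

    Patients live in negative-binomially sized practices; every class in
    the formulary (excluded ones included — they exercise the exclusion
    rule downstream) is dispensed with probability
    logit^-1(baseline + offsets + frailty_i + practice_j), and each
    dispensed class emits 1-3 records at uniform dates inside the window
    using that class's single-ingredient product code.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    order = _class_order(cfg)
    boosts = _boost_map(cfg, order)
    index_date = date.fromisoformat(cfg.index_date)
    bands = list(AGE_BANDS)
    band_p = np.array([cfg.age_band_dist[b] for b in bands])

    # practice sizes: gamma-Poisson (negative binomial)
    shape = cfg.patients_per_practice_dispersion
    lam = rng.gamma(shape, cfg.patients_per_practice_mean / shape, cfg.n_practices)
    sizes = np.maximum(1, rng.poisson(lam))
    practice_effects = rng.normal(0.0, cfg.practice_sd, cfg.n_practices)

    pat_rows, rec_rows = [], []
    pid = 0
    for j in range(cfg.n_practices):
        practice_id = f"PR{j:03d}"
        for _ in range(int(sizes[j])):
            pid += 1
            patient_id = f"PT{pid:07d}"
            band = bands[rng.choice(len(bands), p=band_p)]
            lo, hi = _AGE_RANGES[band]
            age = int(rng.integers(lo, hi + 1))
            sex_f = rng.random() < cfg.sex_female_prob
            simd = int(rng.choice(5, p=np.asarray(cfg.simd_dist))) + 1
            urban = URBAN_RURAL_LEVELS[
                int(rng.choice(4, p=np.asarray(cfg.urban_rural_dist)))
            ]
            care = rng.random() < cfg.care_home_prob_by_band[band]
            frailty = rng.normal(0.0, cfg.frailty_sd)
            logits = (
                _patient_logits(cfg, order, band, simd, sex_f, care)
                + frailty + practice_effects[j]
            )
            dispensed = _sample_classes(rng, logits, boosts)
            pat_rows.append((
                patient_id, age, "F" if sex_f else "M", simd, urban,
                int(care), practice_id,
            ))
            for k in np.flatnonzero(dispensed):
                n_rec = 1 + int(rng.choice(3, p=np.asarray(cfg.records_per_class_dist)))
                offsets = rng.integers(0, cfg.window_days, n_rec)
                for off in offsets:
                    rec_rows.append((
                        patient_id,
                        (index_date - timedelta(days=int(off))).isoformat(),
                        "D" + order[k],
                    ))

    patients = pd.DataFrame(
        pat_rows,
        columns=["patient_id", "age", "sex", "simd_quintile", "urban_rural",
                 "care_home", "practice_id"],
    )
    records = pd.DataFrame(
        rec_rows, columns=["patient_id", "dispense_date", "product_code"]
    )
    truth = {
        "config": cfg.to_dict(),
        "practice_effects": practice_effects,
        "class_order": order,
        "n_patients": len(patients),
    }
    return patients, records, truth


def write_population(patients: pd.DataFrame, records: pd.DataFrame, out_dir,
                     prefix: str = "") -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ppath = out_dir / f"{prefix}patients.tsv"
    rpath = out_dir / f"{prefix}dispensing.tsv"
    pat = patients.copy()
    pat["care_home"] = pat["care_home"].astype(int)
    pat.to_csv(ppath, sep="\t", index=False)
    records.to_csv(rpath, sep="\t", index=False)
    return ppath, rpath


# -- oracles ----------------------------------------------------------------

def _cell_grid(cfg: SimConfig):
    """Covariate cells (age band x simd x sex x care home) with weights."""
    for band in AGE_BANDS:
        pb = cfg.age_band_dist[band]
        pc = cfg.care_home_prob_by_band[band]
        for simd in range(1, 6):
            ps = cfg.simd_dist[simd - 1]
            for sex_f, psex in ((True, cfg.sex_female_prob),
                                (False, 1 - cfg.sex_female_prob)):
                for care, pcare in ((True, pc), (False, 1 - pc)):
                    w = pb * ps * psex * pcare
                    if w > 0:
                        yield w, band, simd, sex_f, care


def _subset_distribution(probs: np.ndarray, boosts, countable: np.ndarray,
                         pair_idx: list[tuple[int, int]]):
    """Exact enumeration over class subsets under the sequential model.

    Returns (distribution over countable-class counts, P(>=1 listed pair
    fully present)). Only feasible for small class lists; callers guard.
    """
    n = len(probs)
    logits = logit(np.clip(probs, 1e-12, 1 - 1e-12))
    n_count = int(countable.sum())
    count_dist = np.zeros(n_count + 1)
    p_ddi = 0.0

    def rec(j, present, prob):
        nonlocal p_ddi
        if prob == 0.0:
            return
        if j == n:
            k = sum(1 for i in present if countable[i])
            count_dist[k] += prob
            if any(a in present and b in present for a, b in pair_idx):
                p_ddi += prob
            return
        lj = logits[j]
        for i, b in boosts.get(j, ()):
            if i in present:
                lj += b
        pj = float(expit(lj))
        rec(j + 1, present | {j}, prob * pj)
        rec(j + 1, present, prob * (1 - pj))

    rec(0, frozenset(), 1.0)
    return count_dist, p_ddi


def expected_summary(
    cfg: SimConfig,
    formulary: Formulary,
    kb_pairs: list[tuple[str, str]] | None = None,
    n_mc: int = 200_000,
    mc_seed: int = 12345,
) -> dict:
    """Expected polypharmacy band fractions and DDI prevalence under cfg.

    With no random effects and at most 12 classes the implied
    distribution of distinct-class counts is computed by exact
    enumeration (a Poisson-binomial when no co-occurrence boosts apply);
    otherwise by Monte-Carlo over covariate cells, frailty, and practice
    effects, independent of the record-level simulation path.

    Returns ``{"band_fractions": {band: frac}, "p_ddi": float,
    "mean_n_classes": float, "method": "exact"|"mc"}``.
    """
    cfg.validate()
    order = _class_order(cfg)
    boosts = _boost_map(cfg, order)
    pos = {c: i for i, c in enumerate(order)}
    countable = np.array([not formulary.is_excluded(c) if c in formulary else True
                          for c in order])
    pair_idx = []
    for a, b in (kb_pairs or []):
        if a in pos and b in pos:
            pair_idx.append(tuple(sorted((pos[a], pos[b]))))

    exact = (cfg.frailty_sd == 0 and cfg.practice_sd == 0 and len(order) <= 12)
    n_count = int(countable.sum())
    if exact:
        dist = np.zeros(n_count + 1)
        p_ddi = 0.0
        for w, band, simd, sex_f, care in _cell_grid(cfg):
            probs = expit(_patient_logits(cfg, order, band, simd, sex_f, care))
            d, pd_ = _subset_distribution(probs, boosts, countable, pair_idx)
            dist += w * d
            p_ddi += w * pd_
        method = "exact"
    else:
        rng = np.random.default_rng(mc_seed)
        cells = list(_cell_grid(cfg))
        weights = np.array([c[0] for c in cells])
        weights = weights / weights.sum()
        choice = rng.choice(len(cells), size=n_mc, p=weights)
        dist = np.zeros(n_count + 1)
        n_ddi = 0
        frail = rng.normal(0.0, cfg.frailty_sd, n_mc)
        prac = rng.normal(0.0, cfg.practice_sd, n_mc)
        for m in range(n_mc):
            _, band, simd, sex_f, care = cells[choice[m]]
            logits = (_patient_logits(cfg, order, band, simd, sex_f, care)
                      + frail[m] + prac[m])
            drawn = _sample_classes(rng, logits, boosts)
            dist[int(drawn[countable].sum())] += 1
            if any(drawn[a] and drawn[b] for a, b in pair_idx):
                n_ddi += 1
        dist /= n_mc
        p_ddi = n_ddi / n_mc
        method = "mc"

    ks = np.arange(n_count + 1)
    band_fractions = {label: float(dist[(ks >= lo) & (ks <= hi)].sum())
                      for label, lo, hi in POLYPHARMACY_BANDS}
    return {
        "band_fractions": band_fractions,
        "p_ddi": float(p_ddi),
        "mean_n_classes": float((ks * dist).sum()),
        "method": method,
    }


def simulate_clustered_logit(
    beta: np.ndarray,
    sigma_u: float,
    n_clusters: int,
    cluster_size: int,
    seed: int,
    x_sd: float = 1.0,
) -> pd.DataFrame:
    """Direct Bernoulli-logit simulation for model-recovery tests.

    ``beta[0]`` is the intercept; remaining coefficients multiply iid
    N(0, x_sd^2) covariates. Returns columns x1.., y, cluster.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    p_cov = len(beta) - 1
    n = n_clusters * cluster_size
    X = rng.normal(0.0, x_sd, (n, p_cov))
    cluster = np.repeat(np.arange(n_clusters), cluster_size)
    u = rng.normal(0.0, sigma_u, n_clusters)
    eta = beta[0] + X @ beta[1:] + u[cluster]
    y = rng.random(n) < expit(eta)
    df = pd.DataFrame(X, columns=[f"x{i+1}" for i in range(p_cov)])
    df["y"] = y.astype(int)
    df["cluster"] = cluster
    return df
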