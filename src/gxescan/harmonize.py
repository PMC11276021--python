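"""Centralized harmonization: raw cohort data to analysis-ready traits and designs.

The protocol, applied per cohort:

1. average multiple within-visit BP readings;
2. restrict to age >= 18 and total sleep time (TST) in [3, 14] h, complete
   cases only;
3. add back the treatment effect of antihypertensive medication
   (SBP +15 mmHg, DBP +10 mmHg) for treated samples;
4. derive pulse pressure PP = SBP - DBP;
5. winsorize each trait at 6 standard deviations from its mean
   (single pass, mean/sd from the pre-clamping vector);
6. dichotomize sleep: regress TST on age, sex and age x sex, and set
   short-TST (STST) = 1 for residuals at or below the 20th percentile and
   long-TST (LTST) = 1 for residuals at or above the 80th percentile,
   derived once on the pooled filtered sample and reused in sex strata;
7. build the interaction design C1 (intercept, E, age, age^2, sex, age*E,
   age^2*E, sex*E, PCs, center dummies) and the reduced design C2
   (intercept, age, age^2, sex, PCs, center dummies); sex columns are
   dropped in sex-stratified analyses.

Medication adjustment precedes winsorization and PP derivation, so the
invariant PP(treated) - PP(untreated) = +5 mmHg holds exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import RawCohort

__all__ = [
    "HarmonizedCohort",
    "average_bp_readings",
    "adjust_medication",
    "derive_pp",
    "winsorize",
    "filter_samples",
    "derive_sleep_exposures",
    "build_designs",
    "harmonize",
]

SBP_MED_ADJUST = 15.0
DBP_MED_ADJUST = 10.0
SEX_GROUPS = ("combined", "female", "male")


def average_bp_readings(readings) -> np.ndarray:
    """Mean of the within-visit readings per sample; NaN when none are present.

    ``readings`` is an (n, k) array-like (NaN-padded) or a sequence of
    per-sample sequences.
    """
    if isinstance(readings, np.ndarray) and readings.ndim == 2:
        arr = readings.astype(float)
    else:
        n = len(readings)
        k = max((len(np.atleast_1d(r)) for r in readings), default=0)
        arr = np.full((n, max(k, 1)), np.nan)
        for i, r in enumerate(readings):
            r = np.atleast_1d(r).astype(float)
            arr[i, : len(r)] = r
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN
        return np.nanmean(arr, axis=1)


def adjust_medication(sbp, dbp, med) -> tuple[np.ndarray, np.ndarray]:
    """Add +15 / +10 mmHg to SBP / DBP of medicated samples."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    med = np.asarray(med, dtype=float)
    return sbp + SBP_MED_ADJUST * med, dbp + DBP_MED_ADJUST * med


def derive_pp(sbp, dbp) -> np.ndarray:
    """Pulse pressure = SBP - DBP (on medication-adjusted values)."""
    return np.asarray(sbp, dtype=float) - np.asarray(dbp, dtype=float)


def winsorize(values, k: float = 6.0) -> np.ndarray:
    """Clamp to mean +/- k*sd, with mean/sd from the input vector (single pass)."""
    x = np.asarray(values, dtype=float)
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if sd == 0.0:
        warnings.warn("winsorize: constant vector returned unchanged", stacklevel=2)
        return x.copy()
    m = float(np.mean(x))
    return np.clip(x, m - k * sd, m + k * sd)


def filter_samples(
    samples: pd.DataFrame,
    age_min: float = 18.0,
    tst_range: tuple[float, float] = (3.0, 14.0),
    required: list[str] | None = None,
) -> tuple[np.ndarray, dict[str, int]]:
    """Inclusion mask (age >= 18, TST in [3, 14] h, complete case) plus drop counts.

    Purely a subset operation: no values are modified.
    """
    if required is None:
        required = [c for c in samples.columns if c not in ("sample_id", "center")]
    n = len(samples)
    age_ok = samples["age"].to_numpy(dtype=float) >= age_min
    tst = samples["tst_hours"].to_numpy(dtype=float)
    tst_ok = (tst >= tst_range[0]) & (tst <= tst_range[1])
    complete = ~samples[required].isna().any(axis=1).to_numpy()
    if "center" in samples.columns:
        complete &= samples["center"].notna().to_numpy()
    keep = age_ok & tst_ok & complete
    counts = {
        "n_input": n,
        "dropped_age": int((~age_ok).sum()),
        "dropped_tst": int((age_ok & ~tst_ok).sum()),
        "dropped_missing": int((age_ok & tst_ok & ~complete).sum()),
        "n_kept": int(keep.sum()),
    }
    return keep, counts


def derive_sleep_exposures(tst, age, sex) -> tuple[np.ndarray, np.ndarray]:
    """Residual-percentile sleep exposures.

    OLS of TST on intercept, age, sex and age x sex; STST = 1 for residuals
    <= their 20th percentile, LTST = 1 for residuals >= their 80th
    percentile (boundary ties are exposed).  If sex is constant the sex and
    interaction terms are dropped.
    """
    tst = np.asarray(tst, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    cols = [np.ones_like(tst), age]
    if np.ptp(sex) > 0:
        cols += [sex, age * sex]
    x = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(x, tst, rcond=None)
    resid = tst - x @ beta
    q20, q80 = np.quantile(resid, [0.2, 0.8])  # linear-interpolation quantile
    stst = (resid <= q20).astype(int)
    ltst = (resid >= q80).astype(int)
    return stst, ltst


def _center_dummies(center: pd.Series) -> pd.DataFrame:
    d = pd.get_dummies(center.astype(str), prefix="center", drop_first=True, dtype=float)
    return d


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the columns whose removal restores full rank
        _, r = np.linalg.qr(x)
        bad = [names[j] for j in range(x.shape[1]) if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or 'unidentified'}")


def build_designs(
    covariates: pd.DataFrame,
    exposure: np.ndarray,
    sex_group: str = "combined",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build C1 (with exposure terms) and C2 (reduced) design frames.

    ``covariates`` must carry age, sex, pc* columns and optionally center.
    Sex and sex-by-exposure columns are omitted in sex-stratified runs.
    """
    if sex_group not in SEX_GROUPS:
        raise ValueError(f"sex_group must be one of {SEX_GROUPS}")
    e = np.asarray(exposure, dtype=float)
    if np.ptp(e) == 0:
        raise ValueError("exposure has no variance in this sample")
    age = covariates["age"].to_numpy(dtype=float)
    age_c = age - 50.0  # centred to tame the age/age^2 conditioning
    sex = covariates["sex"].to_numpy(dtype=float)
    stratified = sex_group != "combined"

    c1 = {"const": np.ones_like(age), "E": e, "age": age_c, "age2": age_c**2}
    c2 = {"const": np.ones_like(age), "age": age_c, "age2": age_c**2}
    if not stratified:
        c1["sex"] = sex
        c2["sex"] = sex
    c1["age_E"] = age_c * e
    c1["age2_E"] = age_c**2 * e
    if not stratified:
        c1["sex_E"] = sex * e
    c1f = pd.DataFrame(c1, index=covariates.index)
    c2f = pd.DataFrame(c2, index=covariates.index)
    pcs = covariates[[c for c in covariates.columns if c.startswith("pc")]]
    c1f = pd.concat([c1f, pcs], axis=1)
    c2f = pd.concat([c2f, pcs], axis=1)
    if "center" in covariates.columns:
        dummies = _center_dummies(covariates["center"])
        c1f = pd.concat([c1f, dummies], axis=1)
        c2f = pd.concat([c2f, dummies], axis=1)
    _check_rank(c1f.to_numpy(dtype=float), list(c1f.columns))
    _check_rank(c2f.to_numpy(dtype=float), list(c2f.columns))
    return c1f, c2f


@dataclass
class HarmonizedCohort:
    """Analysis-ready cohort: traits, exposures, covariates and dosages."""

    name: str
    population: str
    samples: pd.DataFrame                 # kept samples (filtered, ordered)
    traits: dict[str, np.ndarray]         # SBP/DBP/PP, adjusted + winsorized
    exposures: dict[str, np.ndarray]      # STST/LTST in {0,1}
    dosages: np.ndarray                   # (n_kept, n_variants)
    variants: pd.DataFrame
    filter_counts: dict[str, int] = field(default_factory=dict)

    @property
    def kept_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sex_mask(self, sex_group: str) -> np.ndarray:
        sex = self.samples["sex"].to_numpy(dtype=float)
        if sex_group == "combined":
            return np.ones(len(sex), dtype=bool)
        if sex_group == "female":
            return sex == 1
        if sex_group == "male":
            return sex == 0
        raise ValueError(f"sex_group must be one of {SEX_GROUPS}")

    def design(self, exposure: str, sex_group: str = "combined"):
        """(C1, C2, mask) for one exposure/sex-group analysis."""
        mask = self.sex_mask(sex_group)
        cov = self.samples.loc[mask]
        c1, c2 = build_designs(cov, self.exposures[exposure][mask], sex_group)
        return c1, c2, mask


def harmonize(raw: RawCohort, winsor_sd: float = 6.0) -> HarmonizedCohort:
    """Apply the full harmonization protocol to one raw cohort."""
    samples = raw.samples.copy()

    # within-visit reading averaging when multi-reading columns are present
    for trait, prefix in (("sbp_raw", "sbp_"), ("dbp_raw", "dbp_")):
        if trait not in samples.columns:
            reading_cols = [
                c for c in samples.columns if c.startswith(prefix) and c[len(prefix):].isdigit()
            ]
            if not reading_cols:
                raise ValueError(f"no {trait} or {prefix}* reading columns found")
            samples[trait] = average_bp_readings(samples[reading_cols].to_numpy(dtype=float))

    keep, counts = filter_samples(samples)
    if not keep.any():
        raise ValueError("no samples remain after harmonization filters")
    samples = samples.loc[keep].reset_index(drop=True)
    dosages = raw.dosages[keep]

    sbp, dbp = adjust_medication(
        samples["sbp_raw"], samples["dbp_raw"], samples["med_bp"]
    )
    pp = derive_pp(sbp, dbp)
    traits = {
        "SBP": winsorize(sbp, winsor_sd),
        "DBP": winsorize(dbp, winsor_sd),
        "PP": winsorize(pp, winsor_sd),
    }
    stst, ltst = derive_sleep_exposures(
        samples["tst_hours"], samples["age"], samples["sex"]
    )
    return HarmonizedCohort(
        name=raw.name,
        population=raw.population,
        samples=samples,
        traits=traits,
        exposures={"STST": stst, "LTST": ltst},
        dosages=dosages,
        variants=raw.variants.copy(),
        filter_counts=counts,
    )
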