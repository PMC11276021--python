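"""Per-cohort genome-wide gene-by-exposure interaction scan.

For every variant passing quality filters two linear models are fitted by
ordinary least squares with heteroskedasticity-robust (sandwich) standard
errors:

    M1:  Y = b0 + bE*E + bG*G + bGxE*(G*E) + bC1*C1   (interaction model)
    M2:  Y = b0 + bG*G + bC2*C2                        (marginal model)

where Y is a blood-pressure trait, E a dichotomous sleep-duration exposure
and G the genotype dosage.  Reported per variant: the marginal effect
(from M2), the main and interaction effects (from M1) with their robust
covariance, four Wald tests -- three 1df tests (marginal, main,
interaction) and the 2df joint test of (bG, bGxE) -- and the
degrees-of-freedom diagnostics MAC x R^2 in the exposed, unexposed and
total samples.

P-values are computed in log space so genome-wide scans on large samples
survive |z| beyond the double-precision underflow point; the natural-log
p accompanies every p-value column (LNP_*).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .harmonize import HarmonizedCohort, SEX_GROUPS

__all__ = [
    "FilterConfig",
    "ols_fit",
    "robust_covariance",
    "wald_1df",
    "wald_2df",
    "variant_filters",
    "fit_variant",
    "GwisModel",
    "GwisResults",
    "scan",
    "SUMMARY_COLUMNS",
]

logger = logging.getLogger(__name__)

TRAITS = ("SBP", "DBP", "PP")
EXPOSURES = ("STST", "LTST")
ROBUST_KINDS = ("hc0", "hc1", "hc3")
_TINY_P = 5e-324  # smallest subnormal double; p-values are clipped into (0, 1]

SUMMARY_COLUMNS = [
    "SNPID", "CHR", "POS", "EA", "OA", "EAF", "N",
    "BETA_MARG", "SE_MARG", "BETA_MAIN", "SE_MAIN", "BETA_INT", "SE_INT",
    "COV_MAIN_INT", "P_MARG", "P_MAIN", "P_INT", "P_JOINT",
    "LNP_MARG", "LNP_MAIN", "LNP_INT", "LNP_JOINT",
    "DF_TOT", "DF_EXP", "DF_UNEXP",
]


@dataclass(frozen=True)
class FilterConfig:
    """Variant-level quality filters."""

    maf_min: float = 0.001
    rsq_min: float = 0.3
    df_min: float = 20.0  # MAC x R^2 floor in exposed, unexposed and total samples

    def validate(self) -> None:
        if min(self.maf_min, self.rsq_min, self.df_min) <= 0:
            raise ValueError("all filter thresholds must be positive")


# ---------------------------------------------------------------------------
# numerical core


def ols_fit(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares coefficients and residuals; errors on rank deficiency."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("X and y have incompatible shapes")
    beta, _, rank, _ = linalg.lstsq(x, y, lapack_driver="gelsd")
    if rank < x.shape[1]:
        raise np.linalg.LinAlgError(f"design is rank deficient (rank {rank} < {x.shape[1]})")
    return beta, y - x @ beta


def robust_covariance(x: np.ndarray, residuals: np.ndarray, kind: str = "hc0") -> np.ndarray:
    """Heteroskedasticity-consistent sandwich covariance of the OLS coefficients.

    HC0: (X'X)^-1 X' diag(r^2) X (X'X)^-1; HC1 rescales by n/(n-p); HC3
    uses leverage-adjusted residuals r/(1-h).
    """
    kind = kind.lower()
    if kind not in ROBUST_KINDS:
        raise ValueError(f"robust kind must be one of {ROBUST_KINDS}")
    x = np.asarray(x, dtype=float)
    r = np.asarray(residuals, dtype=float)
    n, p = x.shape
    xtx = x.T @ x
    try:
        bread = linalg.inv(xtx)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("X'X is singular") from exc
    if kind == "hc3":
        h = np.einsum("ij,jk,ik->i", x, bread, x)
        w = (r / (1.0 - h)) ** 2
    else:
        w = r**2
        if kind == "hc1":
            w = w * n / (n - p)
    meat = (x * w[:, None]).T @ x
    return bread @ meat @ bread


def wald_1df(beta: float, se: float) -> tuple[float, float, float]:
    """Two-sided normal Wald test: returns (z, p, ln p), log-space safe."""
    if se <= 0:
        raise ValueError("se must be positive")
    z = beta / se
    lnp = np.log(2.0) + stats.norm.logsf(abs(z))
    return float(z), float(max(np.exp(lnp), _TINY_P)), float(lnp)


def wald_2df(beta: np.ndarray, cov: np.ndarray) -> tuple[float, float, float]:
    """2df joint Wald test of (b_G, b_GxE): chi2 = b'V^-1 b, chi2_2 tail."""
    beta = np.asarray(beta, dtype=float)
    cov = np.asarray(cov, dtype=float)
    try:
        c = linalg.cho_factor(cov)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("2df covariance is not positive definite") from exc
    chi2 = float(beta @ linalg.cho_solve(c, beta))
    lnp = stats.chi2.logsf(chi2, df=2)  # = -chi2/2 exactly for 2 df
    return chi2, float(max(np.exp(lnp), _TINY_P)), float(lnp)


# ---------------------------------------------------------------------------
# filters


def _mac(g: np.ndarray) -> float:
    s = float(np.sum(g))
    return min(s, 2.0 * len(g) - s)


def variant_filters(
    variants: pd.DataFrame,
    dosages: np.ndarray,
    exposure: np.ndarray,
    config: FilterConfig = FilterConfig(),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Keep mask + per-variant diagnostics for the standard scan filters.

    Drops: non-autosomes; duplicated chrom:pos:alleles (first kept);
    monomorphic variants; MAF < maf_min; imputation R^2 < rsq_min; and
    MAC x R^2 < df_min in any of the exposed / unexposed / total samples.
    MAC is min(sum g, 2n - sum g) within the subgroup, from dosages as-is.
    """
    config.validate()
    e = np.asarray(exposure, dtype=float) > 0
    m = len(variants)
    keep = np.ones(m, dtype=bool)
    reasons = np.full(m, "", dtype=object)
    chrom = variants["chrom"].to_numpy()
    autosome = np.isin(chrom, np.arange(1, 23))
    keep &= autosome
    reasons[~autosome] = "non_autosome"

    key = (
        variants["chrom"].astype(str) + ":" + variants["pos"].astype(str)
        + ":" + variants["oa"].astype(str) + ":" + variants["ea"].astype(str)
    )
    dup = key.duplicated(keep="first").to_numpy()
    newly = keep & dup
    keep &= ~dup
    reasons[newly] = "duplicate"

    rsq = variants["rsq"].to_numpy(dtype=float)
    df_tot = np.empty(m)
    df_exp = np.empty(m)
    df_unexp = np.empty(m)
    eaf = np.empty(m)
    for j in range(m):
        g = dosages[:, j]
        eaf[j] = float(np.mean(g)) / 2.0
        df_tot[j] = _mac(g) * rsq[j]
        df_exp[j] = _mac(g[e]) * rsq[j]
        df_unexp[j] = _mac(g[~e]) * rsq[j]
        if keep[j] and np.ptp(g) == 0:
            keep[j] = False
            reasons[j] = "monomorphic"
    maf = np.minimum(eaf, 1.0 - eaf)
    for cond, tag in (
        (maf < config.maf_min, "maf"),
        (rsq < config.rsq_min, "rsq"),
        (np.minimum.reduce([df_tot, df_exp, df_unexp]) < config.df_min, "df"),
    ):
        newly = keep & cond
        keep &= ~cond
        reasons[newly] = tag

    diag = pd.DataFrame(
        {
            "id": variants["id"].to_numpy(),
            "eaf": eaf,
            "df_tot": df_tot,
            "df_exp": df_exp,
            "df_unexp": df_unexp,
            "keep": keep,
            "drop_reason": reasons,
        }
    )
    return keep, diag


# ---------------------------------------------------------------------------
# per-variant fit


def fit_variant(
    g: np.ndarray,
    y: np.ndarray,
    c1: np.ndarray,
    c2: np.ndarray,
    e: np.ndarray,
    robust: str = "hc0",
) -> dict | None:
    """Fit M1 ([C1 | G | G*E]) and M2 ([C2 | G]) for one variant.

    Returns the estimate dictionary, or None when the variant is degenerate
    in this sample (constant dosage, or no exposed carriers so the G*E
    column is identically zero).
    """
    g = np.asarray(g, dtype=float)
    if np.ptp(g) == 0:
        return None
    ge = g * e
    if np.ptp(ge) == 0:
        return None
    x1 = np.column_stack([c1, g, ge])
    x2 = np.column_stack([c2, g])
    beta1, r1 = ols_fit(x1, y)
    beta2, r2 = ols_fit(x2, y)
    v1 = robust_covariance(x1, r1, robust)
    v2 = robust_covariance(x2, r2, robust)
    i_g, i_ge = x1.shape[1] - 2, x1.shape[1] - 1
    se_main = float(np.sqrt(v1[i_g, i_g]))
    se_int = float(np.sqrt(v1[i_ge, i_ge]))
    cov_mi = float(v1[i_g, i_ge])
    se_marg = float(np.sqrt(v2[-1, -1]))
    _, p_main, lnp_main = wald_1df(beta1[i_g], se_main)
    _, p_int, lnp_int = wald_1df(beta1[i_ge], se_int)
    _, p_marg, lnp_marg = wald_1df(beta2[-1], se_marg)
    bvec = np.array([beta1[i_g], beta1[i_ge]])
    vmat = np.array([[v1[i_g, i_g], cov_mi], [cov_mi, v1[i_ge, i_ge]]])
    chi2, p_joint, lnp_joint = wald_2df(bvec, vmat)
    return {
        "N": len(y),
        "EAF": float(np.mean(g)) / 2.0,
        "BETA_MARG": float(beta2[-1]),
        "SE_MARG": se_marg,
        "BETA_MAIN": float(beta1[i_g]),
        "SE_MAIN": se_main,
        "BETA_INT": float(beta1[i_ge]),
        "SE_INT": se_int,
        "COV_MAIN_INT": cov_mi,
        "P_MARG": p_marg,
        "P_MAIN": p_main,
        "P_INT": p_int,
        "P_JOINT": p_joint,
        "LNP_MARG": lnp_marg,
        "LNP_MAIN": lnp_main,
        "LNP_INT": lnp_int,
        "LNP_JOINT": lnp_joint,
        "CHI2_JOINT": chi2,
        "nuisance_m1": beta1[: x1.shape[1] - 2],
        "nuisance_m2": beta2[: x2.shape[1] - 1],
    }


# ---------------------------------------------------------------------------
# model / results objects


class GwisModel:
    """One trait x exposure x sex-group interaction scan over a cohort.

    Parameters
    ----------
    cohort
        Harmonized cohort (traits, exposures, dosages).
    trait, exposure, sex_group
        Which of the 3 x 2 x 3 analysis combinations to run.
    filters
        Variant-level quality filters (MAF, imputation R^2, MAC x R^2 floor).
    robust
        Sandwich flavour: hc0 (default), hc1 or hc3.
    """

    def __init__(
        self,
        cohort: HarmonizedCohort,
        trait: str = "SBP",
        exposure: str = "STST",
        sex_group: str = "combined",
        filters: FilterConfig = FilterConfig(),
        robust: str = "hc0",
    ):
        if trait not in TRAITS:
            raise ValueError(f"trait must be one of {TRAITS}")
        if exposure not in EXPOSURES:
            raise ValueError(f"exposure must be one of {EXPOSURES}")
        if sex_group not in SEX_GROUPS:
            raise ValueError(f"sex_group must be one of {SEX_GROUPS}")
        if robust.lower() not in ROBUST_KINDS:
            raise ValueError(f"robust must be one of {ROBUST_KINDS}")
        filters.validate()
        self.cohort = cohort
        self.trait = trait
        self.exposure = exposure
        self.sex_group = sex_group
        self.filters = filters
        self.robust = robust.lower()

    def fit(self) -> "GwisResults":
        cohort = self.cohort
        c1f, c2f, mask = cohort.design(self.exposure, self.sex_group)
        c1 = c1f.to_numpy(dtype=float)
        c2 = c2f.to_numpy(dtype=float)
        y = cohort.traits[self.trait][mask]
        e = cohort.exposures[self.exposure][mask].astype(float)
        dos = cohort.dosages[mask]
        variants = cohort.variants

        order = np.lexsort(
            (
                variants["oa"].to_numpy(),
                variants["ea"].to_numpy(),
                variants["pos"].to_numpy(),
                variants["chrom"].to_numpy(),
            )
        )
        variants = variants.iloc[order].reset_index(drop=True)
        dos = dos[:, order]

        keep, diag = variant_filters(variants, dos, e, self.filters)
        rows = []
        skipped = []
        for j in np.flatnonzero(keep):
            g = dos[:, j]
            finite = np.isfinite(g)
            if not finite.all():
                res = fit_variant(
                    g[finite], y[finite], c1[finite], c2[finite], e[finite], self.robust
                )
            else:
                res = fit_variant(g, y, c1, c2, e, self.robust)
            meta = variants.iloc[j]
            if res is None:
                skipped.append(meta["id"])
                logger.debug("variant %s skipped: degenerate in sample", meta["id"])
                continue
            d = diag.iloc[j]
            rows.append(
                {
                    "SNPID": meta["id"],
                    "CHR": int(meta["chrom"]),
                    "POS": int(meta["pos"]),
                    "EA": meta["ea"],
                    "OA": meta["oa"],
                    "DF_TOT": d["df_tot"],
                    "DF_EXP": d["df_exp"],
                    "DF_UNEXP": d["df_unexp"],
                    **{k: v for k, v in res.items() if not k.startswith("nuisance")},
                }
            )
        frame = pd.DataFrame(rows, columns=SUMMARY_COLUMNS + ["CHI2_JOINT"])
        n_exposed = int(e.sum())
        if n_exposed < 2:
            logger.warning(
                "%s x %s x %s: fewer than 2 exposed samples; empty table",
                self.trait, self.exposure, self.sex_group,
            )
        return GwisResults(self, frame, diag, skipped)


class GwisResults:
    """Scan results: one summary-statistics row per fitted variant."""

    def __init__(self, model: GwisModel, frame: pd.DataFrame, diagnostics, skipped):
        self.model = model
        self.frame = frame
        self.diagnostics = diagnostics
        self.skipped = list(skipped)

    @property
    def n_variants(self) -> int:
        return len(self.frame)

    def summary(self, top: int = 10) -> str:
        m = self.model
        lines = [
            "Gene-by-sleep-duration interaction scan",
            f"  cohort:   {m.cohort.name} ({m.cohort.population})",
            f"  analysis: {m.trait} x {m.exposure} x {m.sex_group} sex, robust={m.robust}",
            f"  samples:  {int(m.cohort.sex_mask(m.sex_group).sum())}"
            f"   variants fitted: {self.n_variants}"
            f"   skipped: {len(self.skipped)}",
            "",
            "Top variants by interaction p-value:",
        ]
        cols = ["SNPID", "CHR", "POS", "EAF", "BETA_INT", "SE_INT", "P_INT", "P_JOINT"]
        if self.n_variants:
            tab = self.frame.nsmallest(top, "P_INT")[cols]
            lines.append(tab.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        else:
            lines.append("  (no variants fitted)")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.8g")

    def qq_plot(self, ax=None, which: str = "P_INT"):
        """Quantile-quantile plot of -log10 p against the uniform null."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = np.sort(self.frame[which].to_numpy())
        n = len(p)
        exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
        ax.plot(exp, -np.log10(p), ".", ms=3)
        lim = max(exp.max(), -np.log10(p.min()))
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        return ax

    def manhattan(self, ax=None, which: str = "P_INT"):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        df = self.frame
        offset = 0
        for c, grp in df.groupby("CHR"):
            ax.plot(grp["POS"] + offset, -np.log10(grp[which]), ".", ms=3)
            offset += grp["POS"].max() + 1
        ax.set_xlabel("genomic position")
        ax.set_ylabel(f"-log10 {which}")
        return ax


def scan(
    cohort: HarmonizedCohort,
    traits=TRAITS,
    exposures=EXPOSURES,
    sex_groups=SEX_GROUPS,
    filters: FilterConfig = FilterConfig(),
    robust: str = "hc0",
) -> dict[tuple[str, str, str], GwisResults]:
    """Run all requested trait x exposure x sex-group combinations (18 by default)."""
    out = {}
    for trait in traits:
        for exposure in exposures:
            for sex_group in sex_groups:
                model = GwisModel(cohort, trait, exposure, sex_group, filters, robust)
                out[(trait, exposure, sex_group)] = model.fit()
    return out
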