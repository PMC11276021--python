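"""Multi-cohort meta-analysis of interaction-scan summary statistics.

Two-level paradigm: cohorts are first combined within each population
group (fixed-effects inverse-variance weighting for the three 1df effects,
generalized-least-squares pooling of the (b_G, b_GxE) vector with its
2x2 robust covariance for the 2df joint test), with genomic-control (GC)
correction of the pooled statistics; the cross-population meta-analysis
(CPMA) then combines the population-group results the same way, treating
each group as one "cohort", followed by a second GC pass.

GC divides each family's test statistic by its inflation factor
lambda = median(chi2) / theoretical null median, clamped at 1 so that
lambda < 1 never deflates.  Lambda is computed per effect family
(marginal, main, interaction, joint) separately because the four tests
have different nulls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gwis import wald_1df, wald_2df, _TINY_P

__all__ = [
    "LambdaReport",
    "align_alleles",
    "ivw_meta_1df",
    "joint_meta_2df",
    "genomic_lambda",
    "gc_correct",
    "population_meta",
    "cross_population_meta",
    "qc_allele_freq",
]

logger = logging.getLogger(__name__)

#: theoretical chi-square medians for 1 and 2 df
CHI2_MEDIAN = {1: float(stats.chi2.median(1)), 2: float(stats.chi2.median(2))}

_FAMILIES_1DF = ("MARG", "MAIN", "INT")
_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


@dataclass
class LambdaReport:
    """Genomic-control inflation factors at one meta-analysis level."""

    level: str                                  # cohort | population-group | cross-population
    lambda_1df: dict[str, float] = field(default_factory=dict)  # per 1df family
    lambda_2df: float = 1.0

    def as_dict(self) -> dict:
        return {
            "level": self.level,
            **{f"lambda_{k.lower()}": v for k, v in self.lambda_1df.items()},
            "lambda_joint": self.lambda_2df,
        }


# ---------------------------------------------------------------------------
# allele alignment


def _is_ambiguous(ea: str, oa: str) -> bool:
    return {str(ea).upper(), str(oa).upper()} in _AMBIGUOUS


def align_alleles(frames: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Express every cohort's effects on one reference effect allele per variant.

    The first cohort reporting a variant defines the reference EA/OA.
    Cohorts with swapped alleles get negated betas and complemented
    frequency (covariances are sign-invariant under a whole-genotype
    flip).  Irreconcilable allele pairs are dropped with a log entry;
    strand-ambiguous (A/T, C/G) variants are flagged in AMBIGUOUS.
    """
    ref: dict[str, tuple[str, str]] = {}
    for name, df in frames.items():
        for snp, ea, oa in zip(df["SNPID"], df["EA"], df["OA"]):
            ref.setdefault(snp, (ea, oa))
    out = {}
    for name, df in frames.items():
        df = df.copy()
        ea_ref = df["SNPID"].map(lambda s: ref[s][0])
        oa_ref = df["SNPID"].map(lambda s: ref[s][1])
        same = (df["EA"] == ea_ref) & (df["OA"] == oa_ref)
        flipped = (df["EA"] == oa_ref) & (df["OA"] == ea_ref)
        bad = ~(same | flipped)
        if bad.any():
            for snp in df.loc[bad, "SNPID"]:
                logger.info("cohort %s: variant %s dropped (irreconcilable alleles)", name, snp)
            df = df.loc[~bad].copy()
            same, flipped = same[~bad], flipped[~bad]
        flip_idx = flipped.to_numpy()
        for col in ("BETA_MARG", "BETA_MAIN", "BETA_INT"):
            if col in df.columns:
                df.loc[flip_idx, col] = -df.loc[flip_idx, col]
        if "EAF" in df.columns:
            df.loc[flip_idx, "EAF"] = 1.0 - df.loc[flip_idx, "EAF"]
        df.loc[flip_idx, ["EA", "OA"]] = df.loc[flip_idx, ["OA", "EA"]].to_numpy()
        df["AMBIGUOUS"] = [_is_ambiguous(a, b) for a, b in zip(df["EA"], df["OA"])]
        out[name] = df
    return out


# ---------------------------------------------------------------------------
# pooling primitives


def ivw_meta_1df(betas, ses) -> tuple[float, float, float, float]:
    """Fixed-effects inverse-variance pooled (beta, se, p, ln p)."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0:
        raise ValueError("no estimates to meta-analyze")
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    w = ses**-2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    _, p, lnp = wald_1df(beta, se)
    return beta, se, p, lnp


def joint_meta_2df(estimates) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """GLS pooling of per-cohort (beta 2-vector, 2x2 covariance) pairs.

    V_meta = (sum V_i^-1)^-1, beta_meta = V_meta sum V_i^-1 beta_i; the
    pooled 2df chi-square is beta' V_meta^-1 beta.  Cohorts with singular
    covariance are dropped with a log entry.
    """
    prec = np.zeros((2, 2))
    score = np.zeros(2)
    used = 0
    for beta, v in estimates:
        beta = np.asarray(beta, dtype=float)
        v = np.asarray(v, dtype=float)
        det = v[0, 0] * v[1, 1] - v[0, 1] * v[1, 0]
        if det <= 0 or min(v[0, 0], v[1, 1]) <= 0:
            logger.info("joint_meta_2df: cohort dropped (singular covariance)")
            continue
        vinv = np.array([[v[1, 1], -v[0, 1]], [-v[1, 0], v[0, 0]]]) / det
        prec += vinv
        score += vinv @ beta
        used += 1
    if used == 0:
        raise ValueError("no usable cohorts for 2df meta-analysis")
    v_meta = np.linalg.inv(prec)
    beta_meta = v_meta @ score
    chi2, p, lnp = wald_2df(beta_meta, v_meta)
    return beta_meta, v_meta, chi2, p, lnp


def genomic_lambda(statistics=None, p=None, df: int = 1, min_variants: int = 100) -> float:
    """Genomic-control inflation: median chi-square over its theoretical median.

    Supply chi-square ``statistics`` directly or two-sided ``p`` values
    (converted through the chi-square quantile at the given df).  Below the
    ``min_variants`` floor a lambda of 1 is returned with a warning.
    """
    if statistics is None:
        if p is None:
            raise ValueError("supply statistics or p")
        p = np.clip(np.asarray(p, dtype=float), _TINY_P, 1.0)
        statistics = stats.chi2.isf(p, df)
    statistics = np.asarray(statistics, dtype=float)
    if statistics.size < min_variants:
        logger.warning(
            "genomic_lambda: %d statistics < floor %d; lambda set to 1",
            statistics.size, min_variants,
        )
        return 1.0
    return float(np.median(statistics) / CHI2_MEDIAN[df])


def _recompute_1df(frame: pd.DataFrame, family: str) -> None:
    beta = frame[f"BETA_{family}"].to_numpy(dtype=float)
    se = frame[f"SE_{family}"].to_numpy(dtype=float)
    z = np.zeros_like(beta)
    ok = se > 0
    z[ok] = beta[ok] / se[ok]
    lnp = np.log(2.0) + stats.norm.logsf(np.abs(z))
    frame[f"LNP_{family}"] = lnp
    frame[f"P_{family}"] = np.maximum(np.exp(lnp), _TINY_P)


def gc_correct(frame: pd.DataFrame, report: LambdaReport) -> pd.DataFrame:
    """Apply genomic-control correction to a summary-statistics frame.

    1df families: se <- se * sqrt(max(lambda, 1)) and p recomputed; 2df:
    chi2 <- chi2 / max(lambda2, 1) with the pooled covariance inflated by
    the same factor so the statistic stays consistent with the carried
    (beta, V).  Lambda < 1 never deflates.
    """
    frame = frame.copy()
    for family in _FAMILIES_1DF:
        lam = max(report.lambda_1df.get(family, 1.0), 1.0)
        if lam > 1.0 and f"SE_{family}" in frame.columns:
            frame[f"SE_{family}"] = frame[f"SE_{family}"] * np.sqrt(lam)
            _recompute_1df(frame, family)
    lam2 = max(report.lambda_2df, 1.0)
    if lam2 > 1.0 and "CHI2_JOINT" in frame.columns:
        frame["CHI2_JOINT"] = frame["CHI2_JOINT"] / lam2
        lnp = stats.chi2.logsf(frame["CHI2_JOINT"].to_numpy(dtype=float), 2)
        frame["LNP_JOINT"] = lnp
        frame["P_JOINT"] = np.maximum(np.exp(lnp), _TINY_P)
        for col in ("V2_MAIN", "V2_INT", "V2_COV"):
            if col in frame.columns:
                frame[col] = frame[col] * lam2
    return frame


# ---------------------------------------------------------------------------
# level runners


def _joint_components(df: pd.DataFrame) -> pd.DataFrame:
    """Per-row (b_G, b_GxE) and 2x2 covariance entries for 2df pooling.

    Cohort-level scan output carries the M1 robust pieces in
    BETA_MAIN/SE_MAIN/BETA_INT/SE_INT/COV_MAIN_INT; meta output carries the
    pooled vector in B2_*/V2_* which, when present, takes precedence so
    covariances propagate unchanged to the next level.
    """
    out = pd.DataFrame(index=df.index)
    if "B2_MAIN" in df.columns:
        out["b_g"] = df["B2_MAIN"]
        out["b_ge"] = df["B2_INT"]
        out["v_gg"] = df["V2_MAIN"]
        out["v_ee"] = df["V2_INT"]
        out["v_ge"] = df["V2_COV"]
    else:
        out["b_g"] = df["BETA_MAIN"]
        out["b_ge"] = df["BETA_INT"]
        out["v_gg"] = df["SE_MAIN"] ** 2
        out["v_ee"] = df["SE_INT"] ** 2
        out["v_ge"] = df["COV_MAIN_INT"]
    return out


def _pool(frames: dict[str, pd.DataFrame], level: str, gc: bool) -> tuple[pd.DataFrame, LambdaReport]:
    frames = align_alleles(frames)
    names = sorted(frames)
    pieces = []
    for name in names:
        df = frames[name].copy()
        df["_COHORT"] = name
        pieces.append(df)
    stack = pd.concat(pieces, ignore_index=True)
    jc = _joint_components(stack)
    det = jc["v_gg"] * jc["v_ee"] - jc["v_ge"] ** 2
    usable = (det > 0) & (jc["v_gg"] > 0) & (jc["v_ee"] > 0)
    n_bad = int((~usable).sum())
    if n_bad:
        logger.info("%s meta: %d cohort rows dropped from 2df pooling (singular V)", level, n_bad)
    # closed-form 2x2 inverses, summed per variant
    stack = stack.assign(
        _p_gg=np.where(usable, jc["v_ee"] / det, 0.0),
        _p_ee=np.where(usable, jc["v_gg"] / det, 0.0),
        _p_ge=np.where(usable, -jc["v_ge"] / det, 0.0),
        _usable=usable.astype(int),
    )
    stack["_s_g"] = stack["_p_gg"] * jc["b_g"] + stack["_p_ge"] * jc["b_ge"]
    stack["_s_ge"] = stack["_p_ge"] * jc["b_g"] + stack["_p_ee"] * jc["b_ge"]
    for fam in _FAMILIES_1DF:
        stack[f"_w_{fam}"] = stack[f"SE_{fam}"] ** -2.0
        stack[f"_wb_{fam}"] = stack[f"_w_{fam}"] * stack[f"BETA_{fam}"]

    grp = stack.groupby("SNPID", sort=False)
    first = grp[["CHR", "POS", "EA", "OA"]].first()
    agg = grp.agg(
        N=("N", "sum"),
        _wsum_af=("EAF", lambda s: np.nan),  # placeholder, replaced below
        K_COHORTS=("_COHORT", "nunique"),
        AMBIGUOUS=("AMBIGUOUS", "max"),
        _pg=("_p_gg", "sum"), _pe=("_p_ee", "sum"), _pc=("_p_ge", "sum"),
        _sg=("_s_g", "sum"), _sge=("_s_ge", "sum"), _k2=("_usable", "sum"),
    )
    # sample-size-weighted pooled allele frequency
    stack["_naf"] = stack["EAF"] * stack["N"]
    agg["_wsum_af"] = grp["_naf"].sum() / agg["N"]
    agg = agg.rename(columns={"_wsum_af": "EAF"})
    # direction string: per-cohort interaction-effect sign, cohorts in sorted order
    sign = np.where(stack["BETA_INT"] > 0, "+", np.where(stack["BETA_INT"] < 0, "-", "0"))
    stack["_sign"] = sign
    dir_map = stack.pivot_table(
        index="SNPID", columns="_COHORT", values="_sign", aggfunc="first"
    ).reindex(columns=names)
    agg["DIRECTIONS"] = dir_map.fillna("?").agg("".join, axis=1)

    out = first.join(agg)
    for fam in _FAMILIES_1DF:
        w = grp[f"_w_{fam}"].sum()
        wb = grp[f"_wb_{fam}"].sum()
        out[f"BETA_{fam}"] = wb / w
        out[f"SE_{fam}"] = w**-0.5
        _recompute_1df(out, fam)
    # pooled 2df: invert the summed precision
    det_m = out["_pg"] * out["_pe"] - out["_pc"] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_gg = out["_pe"] / det_m
        v_ee = out["_pg"] / det_m
        v_ge = -out["_pc"] / det_m
        out["B2_MAIN"] = v_gg * out["_sg"] + v_ge * out["_sge"]
        out["B2_INT"] = v_ge * out["_sg"] + v_ee * out["_sge"]
    out["V2_MAIN"] = v_gg
    out["V2_INT"] = v_ee
    out["V2_COV"] = v_ge
    # the pooled main/interaction covariance also fills the exchange-format
    # COV_MAIN_INT slot so meta output is readable as summary statistics
    out["COV_MAIN_INT"] = v_ge
    chi2 = (
        out["B2_MAIN"] ** 2 * out["_pg"]
        + 2.0 * out["B2_MAIN"] * out["B2_INT"] * out["_pc"]
        + out["B2_INT"] ** 2 * out["_pe"]
    )
    bad2 = (out["_k2"] == 0) | ~np.isfinite(chi2)
    chi2 = chi2.where(~bad2)
    out["CHI2_JOINT"] = chi2
    lnp = stats.chi2.logsf(chi2.to_numpy(dtype=float), 2)
    out["LNP_JOINT"] = lnp
    out["P_JOINT"] = np.maximum(np.exp(lnp), _TINY_P)
    out = out.drop(columns=["_pg", "_pe", "_pc", "_sg", "_sge", "_k2"])
    out = out.reset_index()
    out = out.sort_values(["CHR", "POS", "EA", "OA"]).reset_index(drop=True)

    report = LambdaReport(level=level)
    z2 = {
        fam: (out[f"BETA_{fam}"] / out[f"SE_{fam}"]) ** 2 for fam in _FAMILIES_1DF
    }
    for fam in _FAMILIES_1DF:
        report.lambda_1df[fam] = genomic_lambda(statistics=z2[fam].to_numpy(), df=1)
    valid2 = out["CHI2_JOINT"].dropna().to_numpy()
    report.lambda_2df = genomic_lambda(statistics=valid2, df=2)
    if gc:
        out = gc_correct(out, report)
    return out, report


def population_meta(
    cohort_frames: dict[str, pd.DataFrame], gc: bool = True
) -> tuple[pd.DataFrame, LambdaReport]:
    """Combine cohort summary-statistics tables within one population group."""
    if not cohort_frames:
        raise ValueError("no cohort tables supplied")
    return _pool(cohort_frames, level="population-group", gc=gc)


def cross_population_meta(
    group_frames: dict[str, pd.DataFrame], gc: bool = True
) -> tuple[pd.DataFrame, LambdaReport]:
    """Second-level meta over population-group results (each group = one 'cohort')."""
    if not group_frames:
        raise ValueError("no population-group tables supplied")
    return _pool(group_frames, level="cross-population", gc=gc)


# ---------------------------------------------------------------------------
# QC


def qc_allele_freq(
    frame: pd.DataFrame, reference: pd.DataFrame, tol: float = 0.2
) -> pd.Series:
    """Flag variants whose allele frequency departs from the reference by > tol.

    ``reference`` carries SNPID and AF columns (in this artifact the
    simulation's true population frequencies).  Variants without a
    reference entry are left unflagged with a note.
    """
    ref = reference.set_index("SNPID")["AF"]
    af_ref = frame["SNPID"].map(ref)
    missing = af_ref.isna()
    if missing.any():
        logger.info("qc_allele_freq: %d variants missing from reference (unflagged)", int(missing.sum()))
    diff = (frame["EAF"] - af_ref).abs()
    return (diff > tol).fillna(False)
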