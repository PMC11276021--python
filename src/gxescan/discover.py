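"""Locus discovery and prioritization from meta-analysis output.

Significant variants come from three routes:

* 1df route: interaction p < 5e-9 and BH-FDR q < 0.05 (FDR over all
  variants in the analysis);
* 2df route: joint p < 5e-9 and q < 0.05;
* two-step route: screen on the marginal effect (p < 1e-5, giving z
  variants), then keep screened variants with interaction
  p < 0.05 / N_G and within-screen FDR q < 0.05, where N_G is the
  effective number of independent tests from a principal-components
  decomposition of the screened-variant dosage correlation matrix
  (simpleM convention, 99.5% variance explained).

Selected variants are masked against the MHC (chr6:28,510,120-33,480,577
on hg38, with a 1 Mb buffer), clumped greedily into loci of +/-500 kb
around each lead, leads merged when their dosage LD r^2 >= 0.1, and each
locus classified: interaction-driven vs supported (2df loci) and novel
(> 1 Mb from known loci).  Sex heterogeneity of lead interaction effects
is assessed with a two-sample Z-test at the Bonferroni level 0.05/Q.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SignificanceConfig",
    "Locus",
    "MHC_HG38",
    "eligibility",
    "exclude_mhc",
    "bh_fdr",
    "select_1df",
    "select_2df",
    "effective_tests",
    "two_step",
    "ld_r2",
    "clump",
    "classify_loci",
    "sex_heterogeneity",
    "discover",
    "loci_frame",
]

logger = logging.getLogger(__name__)

#: GRCh38 major histocompatibility complex interval on chromosome 6.
MHC_HG38 = (28_510_120, 33_480_577)
MHC_BUFFER = 1_000_000


@dataclass(frozen=True)
class SignificanceConfig:
    p_gw: float = 5e-9
    fdr_max: float = 0.05
    p_screen: float = 1e-5
    region_kb: float = 500.0        # clump radius around the lead, in kb
    ld_r2_max: float = 0.1
    novelty_mb: float = 1.0
    n_min: int = 20000
    k_cohorts_min: int = 3
    pca_var_explained: float = 0.995

    def validate(self) -> None:
        vals = (self.p_gw, self.fdr_max, self.p_screen, self.region_kb,
                self.ld_r2_max, self.novelty_mb, self.n_min,
                self.k_cohorts_min, self.pca_var_explained)
        if any(v <= 0 for v in vals):
            raise ValueError("all significance thresholds must be positive")


@dataclass
class Locus:
    lead: str
    chrom: int
    pos: int
    members: list[str]
    route: str                       # '1df' | '2df' | 'two-step'
    p_lead: float
    trait: str = ""
    exposure: str = ""
    sex_group: str = ""
    population: str = ""
    driven_by_interaction: bool | None = None
    novel: bool | None = None
    sex_het: tuple[float, float, bool] | None = None  # (Z, p, significant)
    locus_class: str = ""            # 'X' | 'Y' | 'Z' | ''


# ---------------------------------------------------------------------------
# gates and helpers


def eligibility(frame: pd.DataFrame, config: SignificanceConfig = SignificanceConfig()) -> bool:
    """A meta table is processed iff pooled N > n_min or >= k_cohorts_min cohorts."""
    if frame.empty:
        return False
    n = float(frame["N"].max())
    k = int(frame["K_COHORTS"].max()) if "K_COHORTS" in frame.columns else 1
    return n > config.n_min or k >= config.k_cohorts_min


def exclude_mhc(frame: pd.DataFrame) -> pd.DataFrame:
    """Drop variants within 1 Mb of the MHC region (chr6, hg38)."""
    lo = MHC_HG38[0] - MHC_BUFFER
    hi = MHC_HG38[1] + MHC_BUFFER
    inside = (frame["CHR"] == 6) & (frame["POS"] >= lo) & (frame["POS"] <= hi)
    return frame.loc[~inside].copy()


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return stats.false_discovery_control(p, method="bh")


def select_1df(frame: pd.DataFrame, config: SignificanceConfig = SignificanceConfig()) -> pd.DataFrame:
    """Class-i variants: genome-wide significant interaction effect with FDR control."""
    frame = frame.copy()
    frame["Q_INT"] = bh_fdr(frame["P_INT"]) if len(frame) else []
    sel = (frame["P_INT"] < config.p_gw) & (frame["Q_INT"] < config.fdr_max)
    return frame.loc[sel].copy()


def select_2df(frame: pd.DataFrame, config: SignificanceConfig = SignificanceConfig()) -> pd.DataFrame:
    """Class-j variants: genome-wide significant 2df joint effect with FDR control."""
    frame = frame.copy()
    frame["Q_JOINT"] = bh_fdr(frame["P_JOINT"]) if len(frame) else []
    sel = (frame["P_JOINT"] < config.p_gw) & (frame["Q_JOINT"] < config.fdr_max)
    return frame.loc[sel].copy()


def effective_tests(dosage_matrix: np.ndarray, var_explained: float = 0.995) -> int:
    """simpleM effective number of tests among screened variants.

    Eigen-decomposes the z x z dosage correlation matrix and returns the
    smallest k whose top-k eigenvalue sum reaches ``var_explained`` of the
    total; 1 <= N_G <= z.
    """
    g = np.asarray(dosage_matrix, dtype=float)
    z = g.shape[1]
    if z == 0:
        raise ValueError("no screened variants")
    if z == 1:
        return 1
    sd = g.std(axis=0)
    corr = np.corrcoef(g, rowvar=False)
    # constant columns produce NaN rows; treat them as independent (r = 0)
    if np.isnan(corr).any():
        corr = np.where(np.isnan(corr), 0.0, corr)
        np.fill_diagonal(corr, 1.0)
    eig = np.linalg.eigvalsh(corr)[::-1]
    eig = np.clip(eig, 0.0, None)
    csum = np.cumsum(eig)
    target = var_explained * csum[-1]
    n_g = int(np.searchsorted(csum, target - 1e-12) + 1)
    return max(1, min(n_g, z))


def two_step(
    frame: pd.DataFrame,
    dosages: dict[str, np.ndarray],
    config: SignificanceConfig = SignificanceConfig(),
) -> tuple[pd.DataFrame, int]:
    """Class-k variants via marginal screening then Bonferroni-at-N_G interaction test.

    Returns (selected rows, N_G).  FDR is computed within the screened set.
    """
    screened = frame.loc[frame["P_MARG"] < config.p_screen].copy()
    z = len(screened)
    if z == 0:
        return screened, 0
    have_g = [s for s in screened["SNPID"] if s in dosages]
    if have_g:
        g = np.column_stack([dosages[s] for s in have_g])
        n_g = effective_tests(g, config.pca_var_explained)
        # screened variants missing from the LD source still count as tests
        n_g = min(z, n_g + (z - len(have_g)))
    else:
        n_g = z
    screened["Q_INT_SCREEN"] = bh_fdr(screened["P_INT"])
    sel = (screened["P_INT"] < 0.05 / n_g) & (screened["Q_INT_SCREEN"] < config.fdr_max)
    return screened.loc[sel].copy(), n_g


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (allele-flip invariant)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if np.ptp(g1) == 0 or np.ptp(g2) == 0:
        warnings.warn("ld_r2: constant dosage vector, r^2 undefined -> 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# clumping


def clump(
    sig: pd.DataFrame,
    dosages: dict[str, np.ndarray] | None,
    config: SignificanceConfig = SignificanceConfig(),
    p_col: str = "P_SELECT",
) -> list[Locus]:
    """Greedy clumping of significant variants into loci.

    The most significant unassigned variant becomes a lead; all unassigned
    significant variants within +/- region_kb on its chromosome join its
    locus.  Loci whose leads are in LD (r^2 >= ld_r2_max) are then merged
    into the stronger locus.  Ties on p break by larger |beta| then lower
    position.  Without an LD source, one lead per region is retained.
    """
    if sig.empty:
        return []
    df = sig.copy()
    beta_col = "BETA_INT" if "BETA_INT" in df.columns else None
    absbeta = df[beta_col].abs() if beta_col else pd.Series(0.0, index=df.index)
    order = np.lexsort((df["POS"].to_numpy(), -absbeta.to_numpy(), df[p_col].to_numpy()))
    df = df.iloc[order].reset_index(drop=True)
    window = config.region_kb * 1000.0
    assigned = np.zeros(len(df), dtype=bool)
    loci: list[Locus] = []
    for i in range(len(df)):
        if assigned[i]:
            continue
        lead = df.iloc[i]
        near = (
            ~assigned
            & (df["CHR"].to_numpy() == lead["CHR"])
            & (np.abs(df["POS"].to_numpy() - lead["POS"]) <= window)
        )
        members = df.loc[near, "SNPID"].tolist()
        assigned |= near
        loci.append(
            Locus(
                lead=lead["SNPID"],
                chrom=int(lead["CHR"]),
                pos=int(lead["POS"]),
                members=members,
                route=str(lead.get("ROUTE", "")),
                p_lead=float(lead[p_col]),
            )
        )
    # merge LD-dependent leads into the stronger (earlier) locus
    if dosages:
        merged: list[Locus] = []
        for loc in loci:
            target = None
            for kept in merged:
                g1 = dosages.get(loc.lead)
                g2 = dosages.get(kept.lead)
                if g1 is not None and g2 is not None and ld_r2(g1, g2) >= config.ld_r2_max:
                    target = kept
                    break
            if target is None:
                merged.append(loc)
            else:
                target.members = target.members + loc.members
        loci = merged
    return loci


# ---------------------------------------------------------------------------
# classification


def _near_known(chrom: int, pos: int, known: pd.DataFrame | None, mb: float) -> bool | None:
    if known is None:
        return None
    hits = known.loc[known["chrom"] == chrom]
    if hits.empty:
        return False
    return bool((np.abs(hits["pos"].to_numpy() - pos) <= mb * 1e6).any())


def classify_loci(
    loci: list[Locus],
    frame: pd.DataFrame,
    known_bp_loci: pd.DataFrame | None = None,
    known_gxe_loci: pd.DataFrame | None = None,
    config: SignificanceConfig = SignificanceConfig(),
) -> list[Locus]:
    """Assign classes X/Y/Z, interaction-driven flags and novelty to loci.

    1df/two-step loci form class X when > novelty_mb from known gene-sleep
    interaction loci.  2df loci enter prioritization only with an
    insignificant marginal effect (p > p_gw and q > fdr_max) and distance
    > novelty_mb from known BP loci; they are class Y (driven) when the
    lead's interaction p is below its main-effect p, class Z (supported)
    otherwise.  Known-loci tables carry chrom/pos columns; when absent,
    novelty is left undetermined (None), never assumed.
    """
    lookup = frame.set_index("SNPID")
    q_marg = pd.Series(bh_fdr(frame["P_MARG"]), index=frame["SNPID"])
    out = []
    for loc in loci:
        row = lookup.loc[loc.lead]
        near_bp = _near_known(loc.chrom, loc.pos, known_bp_loci, config.novelty_mb)
        near_gxe = _near_known(loc.chrom, loc.pos, known_gxe_loci, config.novelty_mb)
        loc.driven_by_interaction = bool(row["P_INT"] < row["P_MAIN"])
        if loc.route in ("1df", "two-step"):
            loc.novel = None if near_gxe is None else not near_gxe
            loc.locus_class = "X" if loc.novel else ""
        else:  # 2df route
            marg_insig = (row["P_MARG"] > config.p_gw) and (q_marg[loc.lead] > config.fdr_max)
            loc.novel = None if near_bp is None else not near_bp
            if marg_insig and loc.novel:
                loc.locus_class = "Y" if loc.driven_by_interaction else "Z"
            else:
                loc.locus_class = ""
        out.append(loc)
    return out


def sex_heterogeneity(
    beta_f: float, se_f: float, beta_m: float, se_m: float, q: int
) -> tuple[float, float, bool]:
    """Two-sample Z-test of female vs male effects, Bonferroni at 0.05/Q."""
    if q < 1:
        raise ValueError("Q must be >= 1")
    if se_f <= 0 or se_m <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta_f - beta_m) / np.sqrt(se_f**2 + se_m**2)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p, p < 0.05 / q


# ---------------------------------------------------------------------------
# orchestration


def discover(
    frame: pd.DataFrame,
    dosages: dict[str, np.ndarray] | None = None,
    config: SignificanceConfig = SignificanceConfig(),
    known_bp_loci: pd.DataFrame | None = None,
    known_gxe_loci: pd.DataFrame | None = None,
    sex_frames: dict[str, pd.DataFrame] | None = None,
    labels: dict[str, str] | None = None,
) -> list[Locus]:
    """Full discovery pass over one (GC-corrected) meta table.

    Applies the eligibility gate and MHC mask, selects variants by the
    three routes, clumps, classifies, and -- when female and male meta
    tables are supplied -- tests lead interaction effects for sex
    heterogeneity with Q = number of loci tested.
    """
    config.validate()
    if not eligibility(frame, config):
        logger.info("meta table fails eligibility (N <= %d and < %d cohorts)",
                    config.n_min, config.k_cohorts_min)
        return []
    frame = exclude_mhc(frame)
    if frame.empty:
        return []

    c1 = select_1df(frame, config)
    c2 = select_2df(frame, config)
    ck, _ = two_step(frame, dosages or {}, config)

    route = {}
    p_sel = {}
    for snp, p in zip(c2["SNPID"], c2["P_JOINT"]):
        route[snp], p_sel[snp] = "2df", p
    for snp, p in zip(ck["SNPID"], ck["P_INT"]):
        route[snp], p_sel[snp] = "two-step", p
    for snp, p in zip(c1["SNPID"], c1["P_INT"]):
        route[snp], p_sel[snp] = "1df", p
    if not route:
        return []
    sig = frame.loc[frame["SNPID"].isin(route)].copy()
    sig["ROUTE"] = sig["SNPID"].map(route)
    sig["P_SELECT"] = sig["SNPID"].map(p_sel)

    loci = clump(sig, dosages, config)
    loci = classify_loci(loci, frame, known_bp_loci, known_gxe_loci, config)
    for loc in loci:
        for attr in ("trait", "exposure", "sex_group", "population"):
            if labels and attr in labels:
                setattr(loc, attr, labels[attr])

    if sex_frames and {"female", "male"} <= set(sex_frames):
        fem = sex_frames["female"].set_index("SNPID")
        mal = sex_frames["male"].set_index("SNPID")
        q = len(loci)
        for loc in loci:
            if loc.lead in fem.index and loc.lead in mal.index and q >= 1:
                loc.sex_het = sex_heterogeneity(
                    float(fem.loc[loc.lead, "BETA_INT"]),
                    float(fem.loc[loc.lead, "SE_INT"]),
                    float(mal.loc[loc.lead, "BETA_INT"]),
                    float(mal.loc[loc.lead, "SE_INT"]),
                    q,
                )
    return loci


def loci_frame(loci: list[Locus]) -> pd.DataFrame:
    """Locus report table (one row per locus)."""
    rows = []
    for i, loc in enumerate(loci, start=1):
        z, p, _sig = loc.sex_het if loc.sex_het else (np.nan, np.nan, False)
        rows.append(
            {
                "LOCUS_ID": f"L{i:03d}",
                "LEAD_SNP": loc.lead,
                "CHR": loc.chrom,
                "POS": loc.pos,
                "ROUTE": loc.route,
                "EXPOSURE": loc.exposure,
                "TRAIT": loc.trait,
                "SEX": loc.sex_group,
                "POP": loc.population,
                "CLASS": loc.locus_class,
                "P_LEAD": loc.p_lead,
                "DRIVEN": loc.driven_by_interaction,
                "NOVEL": loc.novel,
                "Z_SEXDIFF": z,
                "P_SEXDIFF": p,
                "N_MEMBERS": len(loc.members),
                "MEMBERS": ",".join(loc.members),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "LOCUS_ID", "LEAD_SNP", "CHR", "POS", "ROUTE", "EXPOSURE", "TRAIT",
            "SEX", "POP", "CLASS", "P_LEAD", "DRIVEN", "NOVEL",
            "Z_SEXDIFF", "P_SEXDIFF", "N_MEMBERS", "MEMBERS",
        ],
    )
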