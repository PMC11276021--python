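"""Synthetic multi-population cohort generator with planted genetic effects.

Emulates the kind of individual-level data a gene-by-sleep-duration
interaction study of blood pressure consumes: imputed genotype dosages
over a minor-allele-frequency spectrum that includes rare variants,
population groups with diverged allele frequencies, total sleep time
depending on age and sex, and SBP/DBP generated with configurable genetic
main effects, gene-by-exposure interaction effects, covariate effects and
Gaussian noise. Every planted effect is emitted as a truth record so
downstream stages can be tested for parameter recovery.

Allele-frequency divergence between population groups follows the
Balding-Nichols model: a population's frequency is drawn from
Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral frequency p, with F the
divergence (Fst-like) parameter. Genotypes are Hardy-Weinberg draws
expressed as dosages in [0, 2]. Imputation R^2 is simulated Uniform[0.3, 1]
per variant and consumed only by filtering arithmetic, never used to
perturb the dosages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "ExposureModel",
    "PlantedEffect",
    "SimulationConfig",
    "TruthRecord",
    "RawCohort",
    "GenotypeSet",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohorts",
    "write_cohort",
    "read_cohort",
    "write_truth",
    "read_truth",
]

TRAITS = ("SBP", "DBP", "PP")
EXPOSURES = ("STST", "LTST")

#: Default population-group labels, cycled when more groups are requested.
POP_LABELS = ("EUR", "AFR", "HIS", "EAS", "SAS")


@dataclass(frozen=True)
class ExposureModel:
    """Generative model for total sleep time (TST, hours).

    TST ~ Normal(mean + age_slope*(age - 50) + sex_offset*sex, sd),
    truncated to [lo, hi].  The truncation bounds are deliberately wider
    than the downstream analysis window [3, 14] h so the harmonization
    filter is exercised.
    """

    mean_hours: float = 7.5
    sd_hours: float = 1.2
    age_slope: float = -0.005  # hours per year, centred at age 50
    sex_offset: float = 0.10   # additional hours for sex == 1 (female)
    lo: float = 2.0
    hi: float = 15.0


@dataclass(frozen=True)
class PlantedEffect:
    """One planted genetic effect: main and/or interaction, in mmHg per allele.

    ``trait`` is one of SBP/DBP/PP; PP effects are injected through SBP so
    that the derived PP = SBP - DBP inherits them.  ``exposure`` selects
    which dichotomized sleep indicator the interaction acts through.
    """

    variant_index: int
    trait: str = "SBP"
    exposure: str = "STST"
    beta_main: float = 0.0
    beta_gxe: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated multi-population data set."""

    n_samples: int = 2000          # per cohort / population
    n_variants: int = 500
    maf_range: tuple[float, float] = (0.001, 0.5)
    n_populations: int = 1
    divergence: float = 0.01       # Balding-Nichols F
    exposure_model: ExposureModel = field(default_factory=ExposureModel)
    effect_table: tuple[PlantedEffect, ...] = ()
    noise_sd: float = 15.0         # mmHg, residual sd of each BP trait
    med_prevalence: float = 0.25
    n_pcs: int = 2
    n_centers: int = 1
    pos_spacing: int = 1_000_000   # bp between consecutive variants on a chromosome
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if self.n_variants <= 0:
            raise ValueError("n_variants must be positive")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi < 1, got {self.maf_range}")
        if not (0.0 <= self.divergence <= 0.5):
            raise ValueError("divergence must be in [0, 0.5]")
        if not 0.0 < self.noise_sd:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.med_prevalence < 1.0:
            raise ValueError("med_prevalence must be in [0, 1)")
        for eff in self.effect_table:
            if not 0 <= eff.variant_index < self.n_variants:
                raise ValueError(f"effect_table index {eff.variant_index} out of range")
            if eff.trait not in TRAITS:
                raise ValueError(f"unknown trait {eff.trait!r}")
            if eff.exposure not in EXPOSURES:
                raise ValueError(f"unknown exposure {eff.exposure!r}")


@dataclass(frozen=True)
class TruthRecord:
    variant_id: str
    trait: str
    exposure: str
    beta_main: float
    beta_gxe: float


@dataclass
class GenotypeSet:
    """Per-population dosage matrices over a shared variant panel.

    ``dosages[p]`` is an (n_samples, n_variants) float array for population
    index p; ``variants`` carries id, chrom, pos, effect/other allele, the
    ancestral frequency, each population's drawn frequency (``af_pop{p}``)
    and the simulated imputation R^2.
    """

    dosages: dict[int, np.ndarray]
    variants: pd.DataFrame
    pop_afs: np.ndarray  # (n_populations, n_variants)


@dataclass
class RawCohort:
    """One cohort's raw (pre-harmonization) data."""

    name: str
    population: str
    samples: pd.DataFrame     # sample_id, age, sex, tst_hours, sbp_raw, dbp_raw, med_bp, center, pc1..
    dosages: np.ndarray       # (n_samples, n_variants)
    variants: pd.DataFrame    # id, chrom, pos, ea, oa, af, rsq

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


# ---------------------------------------------------------------------------
# genotypes


def _variant_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_variants
    idx = np.arange(n)
    chrom = (idx % 22) + 1
    pos = 1_000_000 + (idx // 22) * config.pos_spacing
    # non-palindromic allele pairs only, so strand-ambiguity flags are opt-in
    ea = np.where(idx % 2 == 0, "A", "C")
    oa = np.where(idx % 2 == 0, "G", "T")
    lo, hi = config.maf_range
    # log-uniform over the MAF range covers the rare tail evenly
    af = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    rsq = rng.uniform(0.3, 1.0, size=n)
    return pd.DataFrame(
        {
            "id": [f"v{i:05d}" for i in idx],
            "chrom": chrom.astype(int),
            "pos": pos.astype(int),
            "ea": ea,
            "oa": oa,
            "ancestral_af": af,
            "rsq": rsq,
        }
    )


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeSet:
    """Draw per-population allele frequencies and Hardy-Weinberg dosages."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    variants = _variant_table(config, rng)
    p0 = variants["ancestral_af"].to_numpy()
    f = config.divergence
    pop_afs = np.empty((config.n_populations, config.n_variants))
    for p in range(config.n_populations):
        if f == 0.0:
            pop_afs[p] = p0
        else:
            a = p0 * (1.0 - f) / f
            b = (1.0 - p0) * (1.0 - f) / f
            pop_afs[p] = np.clip(rng.beta(a, b), 1e-4, 1.0 - 1e-4)
    dosages = {}
    for p in range(config.n_populations):
        g = rng.binomial(2, pop_afs[p], size=(config.n_samples, config.n_variants))
        dosages[p] = g.astype(float)
        variants[f"af_pop{p}"] = pop_afs[p]
    return GenotypeSet(dosages=dosages, variants=variants, pop_afs=pop_afs)


# ---------------------------------------------------------------------------
# phenotypes

# Fixed covariate effects of the generative BP model (mmHg).
_BP_BASE = {"SBP": 120.0, "DBP": 75.0}
_AGE_EFFECT = {"SBP": 0.45, "DBP": 0.18}      # per year, age centred at 50
_SEX_EFFECT = {"SBP": -2.5, "DBP": -1.5}      # female offset
_PC_EFFECT = 0.5                               # per unit of each PC
_CENTER_EFFECT = 1.0                           # per center index


def _true_exposures(tst: np.ndarray, age: np.ndarray, sex: np.ndarray) -> dict[str, np.ndarray]:
    # the same residual-percentile construction harmonization re-derives
    from .harmonize import derive_sleep_exposures

    stst, ltst = derive_sleep_exposures(tst, age, sex)
    return {"STST": stst.astype(float), "LTST": ltst.astype(float)}


def simulate_phenotypes(
    genotypes: GenotypeSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    cohort_names: list[str] | None = None,
    populations: list[str] | None = None,
) -> tuple[list[RawCohort], list[TruthRecord]]:
    """Generate one raw cohort per population plus the planted-truth records.

    Blood pressure is built as intercept + age and sex effects + PC and
    center effects + planted genetic terms + Gaussian noise.  The exposure
    indicator entering the planted interaction terms is derived from the
    generated TST with the same residual-percentile rule harmonization
    applies, so the planted interaction is recoverable downstream.
    Medicated samples (Bernoulli ``med_prevalence``) have their *observed*
    raw BP lowered by 15/10 mmHg so that the standard medication adjustment
    recovers the underlying values.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n_pop = config.n_populations
    if cohort_names is None:
        cohort_names = [f"cohort{p}" for p in range(n_pop)]
    if populations is None:
        populations = [POP_LABELS[p % len(POP_LABELS)] for p in range(n_pop)]

    var = genotypes.variants
    for eff in config.effect_table:
        mono = all(
            np.all(genotypes.dosages[p][:, eff.variant_index] == genotypes.dosages[p][0, eff.variant_index])
            for p in range(n_pop)
        )
        if mono:
            warnings.warn(
                f"planted effect on monomorphic variant {var['id'].iloc[eff.variant_index]}",
                stacklevel=2,
            )

    cohorts: list[RawCohort] = []
    for p in range(n_pop):
        n = config.n_samples
        age = rng.uniform(20.0, 80.0, size=n)
        sex = rng.integers(0, 2, size=n).astype(float)  # 0 = male, 1 = female
        em = config.exposure_model
        tst = rng.normal(
            em.mean_hours + em.age_slope * (age - 50.0) + em.sex_offset * sex,
            em.sd_hours,
            size=n,
        )
        tst = np.clip(tst, em.lo, em.hi)
        e_true = _true_exposures(tst, age, sex)
        pcs = rng.normal(0.0, 1.0, size=(n, config.n_pcs))
        center = rng.integers(0, config.n_centers, size=n)

        g = genotypes.dosages[p]
        bp = {}
        for trait in ("SBP", "DBP"):
            y = (
                _BP_BASE[trait]
                + _AGE_EFFECT[trait] * (age - 50.0)
                + _SEX_EFFECT[trait] * sex
                + _PC_EFFECT * pcs.sum(axis=1)
                + _CENTER_EFFECT * center
            )
            bp[trait] = y
        for eff in config.effect_table:
            target = "SBP" if eff.trait in ("SBP", "PP") else "DBP"
            gv = g[:, eff.variant_index]
            ev = e_true[eff.exposure]
            bp[target] = bp[target] + eff.beta_main * gv + eff.beta_gxe * gv * ev
        for trait in ("SBP", "DBP"):
            bp[trait] = bp[trait] + rng.normal(0.0, config.noise_sd, size=n)

        med = (rng.uniform(size=n) < config.med_prevalence).astype(int)
        sbp_raw = bp["SBP"] - 15.0 * med
        dbp_raw = bp["DBP"] - 10.0 * med

        samples = pd.DataFrame(
            {
                "sample_id": [f"{cohort_names[p]}_s{i:06d}" for i in range(n)],
                "age": age,
                "sex": sex.astype(int),
                "tst_hours": tst,
                "sbp_raw": sbp_raw,
                "dbp_raw": dbp_raw,
                "med_bp": med,
            }
        )
        samples["center"] = [f"c{j}" for j in center]
        for k in range(config.n_pcs):
            samples[f"pc{k + 1}"] = pcs[:, k]

        cvar = var[["id", "chrom", "pos", "ea", "oa", "rsq"]].copy()
        cvar["af"] = genotypes.pop_afs[p]
        cohorts.append(
            RawCohort(
                name=cohort_names[p],
                population=populations[p],
                samples=samples,
                dosages=g.copy(),
                variants=cvar.reset_index(drop=True),
            )
        )

    truth = [
        TruthRecord(
            variant_id=var["id"].iloc[eff.variant_index],
            trait=eff.trait,
            exposure=eff.exposure,
            beta_main=eff.beta_main,
            beta_gxe=eff.beta_gxe,
        )
        for eff in config.effect_table
    ]
    return cohorts, truth


def simulate_cohorts(
    config: SimulationConfig,
    cohort_names: list[str] | None = None,
    populations: list[str] | None = None,
) -> tuple[list[RawCohort], list[TruthRecord]]:
    """Convenience: genotypes + phenotypes from one config and its seed."""
    rng = np.random.default_rng(config.seed)
    genos = simulate_genotypes(config, rng)
    return simulate_phenotypes(genos, config, rng, cohort_names, populations)


# ---------------------------------------------------------------------------
# I/O


def write_cohort(cohort: RawCohort, vcf_path, pheno_path) -> None:
    """Write a cohort as an uncompressed VCF 4.2 (FORMAT/DS) plus a phenotype TSV."""
    if cohort.n_samples == 0 or cohort.n_variants == 0:
        raise ValueError("refusing to write an empty cohort")
    header = pysam.VariantHeader()
    for c in sorted(cohort.variants["chrom"].unique()):
        header.add_line(f"##contig=<ID={int(c)}>")
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Effect allele frequency">')
    header.add_line('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">')
    header.add_line('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">')
    sample_ids = cohort.samples["sample_id"].tolist()
    for s in sample_ids:
        header.add_sample(s)
    order = np.lexsort((cohort.variants["pos"].to_numpy(), cohort.variants["chrom"].to_numpy()))
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vf:
        for j in order:
            row = cohort.variants.iloc[j]
            rec = vf.new_record(
                contig=str(int(row["chrom"])),
                start=int(row["pos"]) - 1,
                alleles=(str(row["oa"]), str(row["ea"])),  # ALT = effect allele
                id=str(row["id"]),
            )
            rec.info["AF"] = (float(row["af"]),)
            rec.info["R2"] = float(row["rsq"])
            for i, s in enumerate(sample_ids):
                rec.samples[s]["DS"] = float(cohort.dosages[i, j])
            vf.write(rec)
    cohort.samples.to_csv(pheno_path, sep="\t", index=False)


def read_cohort(vcf_path, pheno_path, name: str = "cohort", population: str = "EUR") -> RawCohort:
    """Read a cohort back from a DS-dosage VCF and its phenotype TSV."""
    samples = pd.read_csv(pheno_path, sep="\t")
    ids, chroms, poss, eas, oas, afs, rsqs, rows = [], [], [], [], [], [], [], []
    with pysam.VariantFile(str(vcf_path)) as vf:
        vcf_samples = list(vf.header.samples)
        for rec in vf:
            ids.append(rec.id)
            chroms.append(int(rec.contig))
            poss.append(rec.pos)
            oas.append(rec.ref)
            eas.append(rec.alts[0])
            af = rec.info.get("AF", (np.nan,))
            afs.append(float(af[0] if isinstance(af, tuple) else af))
            rsqs.append(float(rec.info.get("R2", 1.0)))
            rows.append([rec.samples[s]["DS"] for s in vcf_samples])
    if samples["sample_id"].tolist() != vcf_samples:
        samples = samples.set_index("sample_id").loc[vcf_samples].reset_index()
    variants = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "ea": eas, "oa": oas, "af": afs, "rsq": rsqs}
    )
    dosages = np.asarray(rows, dtype=float).T  # (n_samples, n_variants)
    return RawCohort(name=name, population=population, samples=samples, dosages=dosages, variants=variants)


def write_truth(truth: list[TruthRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "variant_id": t.variant_id,
                "trait": t.trait,
                "exposure": t.exposure,
                "beta_main": t.beta_main,
                "beta_gxe": t.beta_gxe,
            }
            for t in truth
        ],
        columns=["variant_id", "trait", "exposure", "beta_main", "beta_gxe"],
    ).to_csv(path, sep="\t", index=False)


def read_truth(path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [TruthRecord(**row) for row in df.to_dict("records")]
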