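"""Run configuration, file exchange and end-to-end orchestration.

A single YAML config drives the whole run: simulate multi-population
cohorts, harmonize each, scan every requested trait x exposure x sex-group
combination per cohort, meta-analyze within population groups, run the
cross-population meta-analysis (CPMA), and discover loci.  A fixed config
and seed reproduce the output tree byte-for-byte; a manifest JSON records
every emitted file with its checksum, and structured logs record sample
and variant counts at each filter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .harmonize import harmonize as _harmonize
from . import meta as metamod
from . import synth
from .discover import SignificanceConfig, discover as _discover, loci_frame
from .gwis import SUMMARY_COLUMNS, FilterConfig, GwisModel
from .synth import ExposureModel, PlantedEffect, RawCohort, SimulationConfig

__all__ = [
    "CohortSpec",
    "RunConfig",
    "validate_config",
    "read_summary_stats",
    "write_summary_stats",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "SNPID", "CHR", "POS", "EA", "OA", "EAF", "N",
    "BETA_MARG", "SE_MARG", "BETA_MAIN", "SE_MAIN", "BETA_INT", "SE_INT",
    "COV_MAIN_INT", "P_MARG", "P_MAIN", "P_INT", "P_JOINT",
]
ROBUST_CHOICES = ("hc0", "hc1", "hc3")


@dataclass(frozen=True)
class CohortSpec:
    name: str
    population: str
    vcf: str | None = None    # optional pre-existing inputs; simulated when absent
    pheno: str | None = None


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "gxescan_run"
    cohorts: list[CohortSpec] = field(default_factory=list)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)
    robust: str = "hc0"
    gc: bool = True
    traits: tuple[str, ...] = ("SBP", "DBP", "PP")
    exposures: tuple[str, ...] = ("STST", "LTST")
    sex_groups: tuple[str, ...] = ("combined", "female", "male")

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["effect_table"] = [
            dataclasses.asdict(e) for e in self.simulation.effect_table
        ]
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        if "exposure_model" in sim and isinstance(sim["exposure_model"], dict):
            sim["exposure_model"] = ExposureModel(**sim["exposure_model"])
        if "effect_table" in sim:
            sim["effect_table"] = tuple(
                e if isinstance(e, PlantedEffect) else PlantedEffect(**e)
                for e in sim["effect_table"]
            )
        if "maf_range" in sim:
            sim["maf_range"] = tuple(sim["maf_range"])
        cohorts = [
            c if isinstance(c, CohortSpec) else CohortSpec(**c)
            for c in d.pop("cohorts", [])
        ]
        filters = d.pop("filters", {})
        sig = d.pop("significance", {})
        for key in ("traits", "exposures", "sex_groups"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(
            cohorts=cohorts,
            simulation=SimulationConfig(**sim),
            filters=filters if isinstance(filters, FilterConfig) else FilterConfig(**filters),
            significance=sig if isinstance(sig, SignificanceConfig) else SignificanceConfig(**sig),
            **d,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def validate_config(config: RunConfig) -> list[dict]:
    """Machine-readable issue list; entries carry severity 'fatal' or 'warning'."""
    issues = []

    def fatal(msg):
        issues.append({"severity": "fatal", "message": msg})

    if not config.cohorts:
        fatal("cohort manifest is empty")
    if config.robust not in ROBUST_CHOICES:
        fatal(f"unknown robust estimator {config.robust!r}; valid: {ROBUST_CHOICES}")
    try:
        config.simulation.validate()
    except ValueError as exc:
        fatal(f"simulation: {exc}")
    try:
        config.filters.validate()
    except ValueError as exc:
        fatal(f"filters: {exc}")
    try:
        config.significance.validate()
    except ValueError as exc:
        fatal(f"significance: {exc}")
    for c in config.cohorts:
        for path in (c.vcf, c.pheno):
            if path is not None and not Path(path).exists():
                fatal(f"cohort {c.name}: input file not found: {path}")
    for t in config.traits:
        if t not in ("SBP", "DBP", "PP"):
            fatal(f"unknown trait {t!r}")
    for e in config.exposures:
        if e not in ("STST", "LTST"):
            fatal(f"unknown exposure {e!r}")
    for s in config.sex_groups:
        if s not in ("combined", "female", "male"):
            fatal(f"unknown sex group {s!r}")
    return issues


# ---------------------------------------------------------------------------
# summary-statistics exchange


def write_summary_stats(frame: pd.DataFrame, path, lambdas: dict | None = None) -> None:
    """Write a summary-statistics TSV, with lambda header comment lines if given."""
    cols = [c for c in frame.columns if c in set(SUMMARY_COLUMNS) | {
        "K_COHORTS", "DIRECTIONS", "CHI2_JOINT", "AMBIGUOUS",
        "B2_MAIN", "B2_INT", "V2_MAIN", "V2_INT", "V2_COV",
    }]
    with open(path, "w") as fh:
        if lambdas:
            for k, v in sorted(lambdas.items()):
                if isinstance(v, float):
                    fh.write(f"# {k}={v:.6g}\n")
                else:
                    fh.write(f"# {k}={v}\n")
        frame[cols].to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_summary_stats(path) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read and validate a summary-statistics TSV.

    Rows with missing, invalid or out-of-range statistics (non-positive
    SEs, p outside (0, 1], frequency outside [0, 1]) and duplicated SNPIDs
    are dropped, with per-reason counts returned alongside the table.
    Missing required columns raise; unknown columns warn.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"summary statistics missing required columns: {missing}")
    known = set(SUMMARY_COLUMNS) | {
        "K_COHORTS", "DIRECTIONS", "CHI2_JOINT", "AMBIGUOUS",
        "B2_MAIN", "B2_INT", "V2_MAIN", "V2_INT", "V2_COV",
    }
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        logger.warning("summary statistics: unknown columns ignored: %s", unknown)
    counts = {"n_input": len(frame)}
    numeric = [c for c in REQUIRED_COLUMNS if c not in ("SNPID", "EA", "OA")]
    ok = ~frame[numeric].isna().any(axis=1)
    counts["dropped_missing"] = int((~ok).sum())
    frame = frame.loc[ok]
    valid = (
        (frame[["SE_MARG", "SE_MAIN", "SE_INT"]] > 0).all(axis=1)
        & (frame[["P_MARG", "P_MAIN", "P_INT", "P_JOINT"]] > 0).all(axis=1)
        & (frame[["P_MARG", "P_MAIN", "P_INT", "P_JOINT"]] <= 1).all(axis=1)
        & frame["EAF"].between(0.0, 1.0)
    )
    counts["dropped_invalid"] = int((~valid).sum())
    frame = frame.loc[valid]
    dup = frame["SNPID"].duplicated(keep="first")
    if dup.any():
        for snp in frame.loc[dup, "SNPID"]:
            logger.info("summary statistics: duplicated SNPID %s dropped", snp)
    counts["dropped_duplicate"] = int(dup.sum())
    frame = frame.loc[~dup].reset_index(drop=True)
    counts["n_kept"] = len(frame)
    return frame, counts


# ---------------------------------------------------------------------------
# orchestration


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _simulate_cohorts(config: RunConfig) -> tuple[list[RawCohort], list[synth.TruthRecord]]:
    """One shared variant panel; per-group allele frequencies; per-cohort draws."""
    groups = sorted({c.population for c in config.cohorts})
    sim = replace(config.simulation, n_populations=len(groups), seed=config.seed)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.cohorts) + 1)
    genos = synth.simulate_genotypes(sim, np.random.default_rng(children[0]))
    cohorts = []
    truth: list[synth.TruthRecord] = []
    for i, spec in enumerate(config.cohorts):
        gi = groups.index(spec.population)
        rng = np.random.default_rng(children[i + 1])
        g = rng.binomial(
            2, genos.pop_afs[gi], size=(sim.n_samples, sim.n_variants)
        ).astype(float)
        single = synth.GenotypeSet(
            dosages={0: g},
            variants=genos.variants,
            pop_afs=genos.pop_afs[[gi]],
        )
        one = replace(sim, n_populations=1)
        cohs, tr = synth.simulate_phenotypes(
            single, one, rng, cohort_names=[spec.name], populations=[spec.population]
        )
        cohorts.append(cohs[0])
        if not truth:
            truth = tr
    return cohorts, truth


def run_pipeline(config: RunConfig, write_cohort_files: bool = True) -> dict:
    """Execute the full pipeline and return the manifest dictionary."""
    issues = validate_config(config)
    fatal = [i for i in issues if i["severity"] == "fatal"]
    if fatal:
        raise ValueError("invalid configuration: " + "; ".join(i["message"] for i in fatal))

    out = Path(config.out_dir)
    for sub in ("cohorts", "gwis", "meta", "cpma", "loci"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    # --- stage: simulate / load ----------------------------------------
    loaded = [c for c in config.cohorts if c.vcf and c.pheno]
    if loaded and len(loaded) != len(config.cohorts):
        raise ValueError("either all cohorts or none must supply vcf/pheno paths")
    if loaded:
        cohorts = [
            synth.read_cohort(c.vcf, c.pheno, name=c.name, population=c.population)
            for c in config.cohorts
        ]
        truth = []
    else:
        cohorts, truth = _simulate_cohorts(config)
        if write_cohort_files:
            for coh in cohorts:
                synth.write_cohort(
                    coh, out / "cohorts" / f"{coh.name}.vcf", out / "cohorts" / f"{coh.name}.pheno.tsv"
                )
            synth.write_truth(truth, out / "cohorts" / "truth.tsv")

    # --- stage: harmonize ----------------------------------------------
    harmonized = []
    for coh in cohorts:
        hc = _harmonize(coh)
        logger.info("harmonize %s: %s", coh.name, hc.filter_counts)
        with open(out / "cohorts" / f"{coh.name}.filters.json", "w") as fh:
            json.dump(hc.filter_counts, fh, indent=1, sort_keys=True)
        harmonized.append(hc)

    combos = [
        (t, e, s)
        for t in config.traits
        for e in config.exposures
        for s in config.sex_groups
    ]

    # --- stage: per-cohort scans ----------------------------------------
    scan_frames: dict[tuple, dict[str, pd.DataFrame]] = {c: {} for c in combos}
    for hc in harmonized:
        for combo in combos:
            t, e, s = combo
            res = GwisModel(hc, t, e, s, config.filters, config.robust).fit()
            path = out / "gwis" / f"{hc.name}.{t}.{e}.{s}.tsv"
            res.to_tsv(path)
            scan_frames[combo][hc.name] = res.frame
            logger.info(
                "gwis %s %s: %d variants fitted, %d skipped",
                hc.name, combo, res.n_variants, len(res.skipped),
            )

    # --- stage: population meta + CPMA -----------------------------------
    groups: dict[str, list] = {}
    for hc in harmonized:
        groups.setdefault(hc.population, []).append(hc.name)
    meta_frames: dict[tuple, dict[str, pd.DataFrame]] = {c: {} for c in combos}
    cpma_frames: dict[tuple, pd.DataFrame] = {}
    for combo in combos:
        t, e, s = combo
        for group, names in sorted(groups.items()):
            tables = {n: scan_frames[combo][n] for n in names if len(scan_frames[combo][n])}
            if not tables:
                continue
            mf, rep = metamod.population_meta(tables, gc=config.gc)
            write_summary_stats(mf, out / "meta" / f"{group}.{t}.{e}.{s}.tsv", rep.as_dict())
            meta_frames[combo][group] = mf
        if meta_frames[combo]:
            cf, crep = metamod.cross_population_meta(meta_frames[combo], gc=config.gc)
            write_summary_stats(cf, out / "cpma" / f"CPMA.{t}.{e}.{s}.tsv", crep.as_dict())
            cpma_frames[combo] = cf

    # --- stage: discovery -------------------------------------------------
    pooled_dosages: dict[str, np.ndarray] = {}
    ids = harmonized[0].variants["id"].tolist()
    stacks = [hc.dosages for hc in harmonized]
    full = np.vstack(stacks)
    for j, snp in enumerate(ids):
        pooled_dosages[snp] = full[:, j]

    all_loci = []
    for t in config.traits:
        for e in config.exposures:
            combo = (t, e, "combined")
            if combo not in cpma_frames:
                continue
            sex_frames = {}
            for s in ("female", "male"):
                if (t, e, s) in cpma_frames:
                    sex_frames[s] = cpma_frames[(t, e, s)]
            loci = _discover(
                cpma_frames[combo],
                pooled_dosages,
                config.significance,
                sex_frames=sex_frames or None,
                labels={"trait": t, "exposure": e, "sex_group": "combined", "population": "CPMA"},
            )
            all_loci.extend(loci)
    report = loci_frame(all_loci)
    report.to_csv(out / "loci" / "loci.tsv", sep="\t", index=False, float_format="%.8g")

    # --- manifest ---------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "n_cohorts": len(cohorts),
        "n_loci": len(all_loci),
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
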