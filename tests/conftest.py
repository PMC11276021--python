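import numpy as np
import pandas as pd
import pytest

import gxescan as gx
from gxescan.harmonize import harmonize


@pytest.fixture(scope="session")
def small_cohort():
    """One harmonized cohort: 800 samples, 40 common variants, no planted effects."""
    cfg = gx.SimulationConfig(n_samples=800, n_variants=40, maf_range=(0.1, 0.5), seed=42)
    cohorts, _ = gx.simulate_cohorts(cfg)
    return harmonize(cohorts[0])


@pytest.fixture(scope="session")
def planted_cohort():
    """Harmonized cohort with a strong planted interaction at the first variant."""
    cfg = gx.SimulationConfig(
        n_samples=3000,
        n_variants=30,
        maf_range=(0.2, 0.5),
        seed=7,
        effect_table=(gx.PlantedEffect(0, "SBP", "STST", beta_main=1.0, beta_gxe=-8.0),),
    )
    cohorts, truth = gx.simulate_cohorts(cfg)
    return harmonize(cohorts[0]), truth


def make_summary_frame(n=20, seed=0, chrom=1, pos0=1_000_000, spacing=100_000):
    """A syntactically valid null summary-statistics table for plumbing tests."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n, 3))
    se = rng.uniform(0.5, 2.0, size=(n, 3))
    chi2 = rng.chisquare(2, size=n)
    from scipy import stats

    df = pd.DataFrame(
        {
            "SNPID": [f"s{i:04d}" for i in range(n)],
            "CHR": chrom,
            "POS": pos0 + spacing * np.arange(n),
            "EA": "A",
            "OA": "G",
            "EAF": rng.uniform(0.05, 0.95, size=n),
            "N": 1000,
            "BETA_MARG": z[:, 0] * se[:, 0],
            "SE_MARG": se[:, 0],
            "BETA_MAIN": z[:, 1] * se[:, 1],
            "SE_MAIN": se[:, 1],
            "BETA_INT": z[:, 2] * se[:, 2],
            "SE_INT": se[:, 2],
            "COV_MAIN_INT": 0.1 * se[:, 1] * se[:, 2],
            "P_MARG": 2 * stats.norm.sf(np.abs(z[:, 0])),
            "P_MAIN": 2 * stats.norm.sf(np.abs(z[:, 1])),
            "P_INT": 2 * stats.norm.sf(np.abs(z[:, 2])),
            "P_JOINT": stats.chi2.sf(chi2, 2),
            "LNP_MARG": np.log(2 * stats.norm.sf(np.abs(z[:, 0]))),
            "LNP_MAIN": np.log(2 * stats.norm.sf(np.abs(z[:, 1]))),
            "LNP_INT": np.log(2 * stats.norm.sf(np.abs(z[:, 2]))),
            "LNP_JOINT": stats.chi2.logsf(chi2, 2),
            "CHI2_JOINT": chi2,
            "DF_TOT": 500.0,
            "DF_EXP": 100.0,
            "DF_UNEXP": 400.0,
            "K_COHORTS": 4,
        }
    )
    return df
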