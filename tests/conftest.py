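import pandas as pd
import pytest

from mrpipe.simulate import (
    SimConfig,
    simulate_exposure_gwas,
    simulate_instruments,
    simulate_outcome_gwas,
    simulate_region,
)

__all__ = ["make_sumstats", "simulate_instruments", "study_dataset"]


def make_sumstats(rows, path=None):
    """Build a canonical summary-statistics DataFrame (optionally on disk)."""
    df = pd.DataFrame(
        rows,
        columns=["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N", "INFO"],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return df


@pytest.fixture(scope="session")
def study_dataset():
    """One simulated four-cohort exposure GWAS plus outcome GWAS."""
    cfg = SimConfig(seed=7)
    region = simulate_region(cfg)
    panels = simulate_exposure_gwas(region, cfg.cohort_ns, seed=cfg.seed,
                                    sequenced_cohort=cfg.sequenced_cohort)
    outcome = simulate_outcome_gwas(region, theta=cfg.theta, n_out=cfg.n_out,
                                    seed=cfg.seed)
    return cfg, region, panels, outcome
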