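import numpy as np
import pytest

from pleioscan import CohortConfig, SnpSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with one SNP of each effect class."""
    specs = [
        SnpSpec("rs_pleio", 0.3, "pleiotropic", beta_crp=0.3, beta_adip=0.3,
                target_adiposity="BMI", chrom="1", pos=1_000_000),
        SnpSpec("rs_med", 0.3, "mediated", beta_crp=0.4,
                target_adiposity="BMI", chrom="2", pos=2_000_000),
        SnpSpec("rs_single", 0.25, "single_trait", beta_adip=0.3,
                target_adiposity="WHR", chrom="3", pos=3_000_000),
        SnpSpec("rs_null", 0.2, "null", chrom="4", pos=4_000_000),
    ]
    cfg = CohortConfig(n_individuals=1500, snp_specs=specs, seed=42)
    return simulate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def null_cohort():
    """All-null cohort for calibration checks."""
    rng = np.random.default_rng(7)
    specs = [
        SnpSpec(f"null{i:04d}", float(m), "null", chrom=str(i % 22 + 1),
                pos=2_000_000 * (i // 22 + 1))
        for i, m in enumerate(rng.uniform(0.1, 0.5, size=400))
    ]
    cfg = CohortConfig(n_individuals=1200, snp_specs=specs, seed=43)
    return simulate_cohort(cfg), cfg
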