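import pandas as pd
import pytest

from panumr import SimConfig, ThresholdConfig, generate_pair, run_bundle


@pytest.fixture(scope="session")
def cfg():
    return ThresholdConfig()


def small_sim_config(seed=1, **overrides):
    """Two 1-Mb chromosomes with 20 planted UMRs — quick end-to-end scale."""
    defaults = dict(
        seed=seed, n_chroms=2, chrom_bp=1_000_000,
        n_identical=5, n_partial=5, n_polymorphic_chh=4,
        n_polymorphic_cg_chg=3, n_polymorphic_cg_only=3,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_pair(small_sim_config())


@pytest.fixture(scope="session")
def small_results(small_bundle):
    return run_bundle(small_bundle)


def track_from_string(labels: str, chrom: str = "chr1") -> pd.DataFrame:
    """Build a domain track from a compact string: U=unmethylated,
    m=missing_data, H=heterochromatin, R=rddm, C=cg_only, I=intermediate."""
    code = {
        "U": "unmethylated", "m": "missing_data", "H": "heterochromatin",
        "R": "rddm", "C": "cg_only", "I": "intermediate",
    }
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": [i * 100 for i in range(len(labels))],
            "end": [(i + 1) * 100 for i in range(len(labels))],
            "label": [code[c] for c in labels],
        }
    )
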