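import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from twosample_mr.harmonize import HarmonizedInstrument

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_instrument(beta_exp, beta_out, se_out=1.0, se_exp=1.0, snp_id="rs1", action="as_is"):
    return HarmonizedInstrument(
        snp_id=snp_id,
        beta_exp=float(beta_exp),
        se_exp=float(se_exp),
        beta_out=float(beta_out),
        se_out=float(se_out),
        effect_allele="A",
        action=action,
    )


def make_instruments(bx, by, se_out=None, se_exp=None):
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    se_out = np.ones_like(bx) if se_out is None else np.asarray(se_out, dtype=float)
    se_exp = np.ones_like(bx) if se_exp is None else np.asarray(se_exp, dtype=float)
    return [
        make_instrument(bx[i], by[i], se_out[i], se_exp[i], snp_id=f"rs{i + 1}")
        for i in range(len(bx))
    ]


@pytest.fixture
def random_instances():
    """100 small random instrument sets for oracle-equivalence checks."""
    rng = np.random.default_rng(20240517)
    instances = []
    for _ in range(100):
        j = int(rng.integers(3, 12))
        bx = rng.normal(0.05, 0.03, j)
        bx[bx == 0.0] = 0.01
        se_exp = rng.uniform(0.002, 0.01, j)
        se_out = rng.uniform(0.005, 0.05, j)
        by = rng.normal(0.3 * bx, se_out)
        instances.append(make_instruments(bx, by, se_out, se_exp))
    return instances
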