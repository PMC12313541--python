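import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tsmr import HarmonizedSet, SummaryStatRecord

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_hset(bx, by, sey, sex=None, snp_ids=None) -> HarmonizedSet:
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sey = np.broadcast_to(np.asarray(sey, dtype=float), bx.shape).copy()
    sex = (
        np.full_like(bx, 0.01)
        if sex is None
        else np.broadcast_to(np.asarray(sex, dtype=float), bx.shape).copy()
    )
    ids = snp_ids or [f"rs{i + 1}" for i in range(bx.size)]
    return HarmonizedSet(
        snp_ids=list(ids),
        beta_exposure=bx,
        se_exposure=sex,
        beta_outcome=by,
        se_outcome=sey,
        eaf=np.full_like(bx, np.nan),
    )


def make_record(
    snp_id="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.01,
    pval=1e-8,
    **kw,
) -> SummaryStatRecord:
    return SummaryStatRecord(
        snp_id=snp_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        pval=pval,
        **kw,
    )


@pytest.fixture
def hset_factory():
    return make_hset


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def three_snp_hset():
    """The bx=(0.1,0.2,0.3), by=(0.06,0.10,0.12), sey=0.01 worked fixture."""
    return make_hset([0.1, 0.2, 0.3], [0.06, 0.10, 0.12], 0.01)
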