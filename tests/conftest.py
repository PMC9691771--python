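import numpy as np
import pytest

from causalmr import AssocRecord, HarmonizedSet
from causalmr.simulate import make_fixture_suite


def make_record(
    variant_id="rs1",
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pval=None,
    n=100_000.0,
    trait_id="exposure",
):
    from scipy import stats

    if pval is None:
        pval = max(float(2 * stats.norm.sf(abs(beta / se))), 1e-300)
    return AssocRecord(
        variant_id=variant_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
        trait_id=trait_id,
    )


def make_harmonized(gamma, se_gamma, Gamma, se_Gamma, **kwargs):
    gamma = np.asarray(gamma, dtype=float)
    return HarmonizedSet(
        variant_ids=[f"rs{i + 1}" for i in range(gamma.size)],
        gamma=gamma,
        se_gamma=np.asarray(se_gamma, dtype=float),
        Gamma=np.asarray(Gamma, dtype=float),
        se_Gamma=np.asarray(se_Gamma, dtype=float),
        eaf_exposure=np.full(gamma.size, 0.3),
        **kwargs,
    )


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """The deterministic named fixture directories, generated once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    return make_fixture_suite(out, seed=2024)
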