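import numpy as np
import pandas as pd
import pytest

from mrprofile import HarmonizedStudy, SNPRecord


def study_from_arrays(Gamma, se_Gamma, gamma, se_gamma, sel_p=None,
                      snp_ids=None) -> HarmonizedStudy:
    """Build a small harmonized study directly from numeric arrays."""
    Gamma = np.asarray(Gamma, float)
    gamma = np.atleast_2d(np.asarray(gamma, float))
    if gamma.shape[0] != len(Gamma):
        gamma = gamma.T
    se_gamma = np.broadcast_to(np.asarray(se_gamma, float), gamma.shape)
    se_Gamma = np.broadcast_to(np.asarray(se_Gamma, float), Gamma.shape)
    if sel_p is None:
        sel_p = np.full(gamma.shape, 1e-10)
    else:
        sel_p = np.broadcast_to(np.asarray(sel_p, float), gamma.shape)
    if snp_ids is None:
        snp_ids = [f"rs{j}" for j in range(len(Gamma))]
    records = [
        SNPRecord(snp_id=snp_ids[j], effect_allele="A", other_allele="G",
                  gamma_hat=gamma[j], se_gamma=se_gamma[j],
                  Gamma_hat=float(Gamma[j]), se_Gamma=float(se_Gamma[j]),
                  sel_pvalues=sel_p[j])
        for j in range(len(Gamma))
    ]
    K = gamma.shape[1]
    return HarmonizedStudy(records=records,
                           trait_names=["outcome"] + [f"x{k}" for k in range(K)])


def make_trait_table(snp_ids, effect, other, beta, se=0.01, pval=1e-10):
    n = len(snp_ids)
    return pd.DataFrame({
        "SNP": snp_ids,
        "effect_allele": effect,
        "other_allele": other,
        "beta": np.asarray(beta, float),
        "se": np.broadcast_to(np.asarray(se, float), (n,)),
        "pval": np.broadcast_to(np.asarray(pval, float), (n,)),
    })


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
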