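import numpy as np
import pytest

from bimr import HarmonizedSet, SummaryDataset, SummaryRecord


def make_record(
    snp_id="rs1",
    chrom="1",
    pos=1000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pval=1e-10,
    n=21758,
) -> SummaryRecord:
    return SummaryRecord(
        snp_id=snp_id,
        chrom=chrom,
        pos=pos,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
    )


def make_dataset(records, trait_id="trait", trait_type="continuous") -> SummaryDataset:
    return SummaryDataset(trait_id=trait_id, trait_type=trait_type, records=records)


def hset_from_ratios(theta, w, se_out=None) -> HarmonizedSet:
    """Build a harmonized set with prescribed Wald ratios and IVW weights.

    With se_out fixed at 1, choosing beta_exp = sqrt(w) gives IVW weight
    w exactly and Wald ratio theta via beta_out = theta * beta_exp.
    """
    theta = np.asarray(theta, dtype=float)
    w = np.asarray(w, dtype=float)
    se_out = np.ones_like(theta) if se_out is None else np.asarray(se_out, float)
    beta_exp = np.sqrt(w) * se_out
    beta_out = theta * beta_exp
    return HarmonizedSet.from_arrays(
        beta_exp, np.full_like(theta, 1e-3), beta_out, se_out
    )


def random_hset(rng, j=12, theta=0.2) -> HarmonizedSet:
    beta_exp = rng.uniform(0.05, 0.4, j) * rng.choice([-1.0, 1.0], j)
    se_exp = rng.uniform(0.005, 0.02, j)
    se_out = rng.uniform(0.002, 0.05, j)
    beta_out = theta * beta_exp + rng.normal(0, se_out)
    return HarmonizedSet.from_arrays(beta_exp, se_exp, beta_out, se_out)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
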